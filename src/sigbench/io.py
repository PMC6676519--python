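"""Expression-matrix, metadata, signature and gene-set I/O, plus gene pools.

File formats are deliberately plain: tab-delimited expression matrices
(genes in rows, first column ``gene_id``, samples in columns), a six-column
metadata table, two-column directional signatures, GMT gene-set collections
and one-id-per-line exclusion lists.  Gene identifiers are opaque strings;
no probe/symbol mapping is attempted.  A cohort's platform universe is the
set of genes present in its own matrix, mirroring the fact that different
array platforms carry different gene content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

DIAGNOSIS_LABELS = ("CTL", "MCI", "AD")
SEX_LABELS = ("F", "M")

METADATA_COLUMNS = ("sample_id", "cohort_id", "age", "sex", "diagnosis", "batch")

#: accepted spellings for signature directions
_DIRECTION_ALIASES = {
    "+1": 1, "1": 1, "up": 1,
    "-1": -1, "down": -1,
}

POOL_PROVENANCES = ("all", "background", "expressed", "filtered")


class ExpressionIOError(ValueError):
    """Raised for malformed expression/metadata/signature inputs."""


@dataclass
class ExpressionCohort:
    """One cohort's log2-intensity matrix (genes x samples) plus identity.

    ``values`` is a float DataFrame whose index is the platform gene
    universe and whose columns are the cohort's sample ids.  Per-sample
    rank matrices (the basis of all scoring) are computed lazily and
    cached, since they are reused across thousands of gene-set
    evaluations.
    """

    cohort_id: str
    values: pd.DataFrame
    platform_id: str
    _ranks: np.ndarray | None = field(default=None, repr=False, compare=False)
    _row_index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0:
            raise ExpressionIOError(f"cohort {self.cohort_id!r}: no genes")
        if v.shape[1] == 0:
            raise ExpressionIOError(f"cohort {self.cohort_id!r}: no samples")
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ExpressionIOError(
                f"cohort {self.cohort_id!r}: duplicate gene id {dup!r}"
            )
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ExpressionIOError(
                f"cohort {self.cohort_id!r}: duplicate sample id {dup!r}"
            )
        try:
            self.values = v.astype(float)
        except (TypeError, ValueError) as exc:
            raise ExpressionIOError(
                f"cohort {self.cohort_id!r}: non-numeric expression value ({exc})"
            ) from exc
        if self.values.isna().any().any():
            g, s = next(
                (g, s)
                for g in self.values.index
                for s in self.values.columns
                if pd.isna(self.values.at[g, s])
            )
            raise ExpressionIOError(
                f"cohort {self.cohort_id!r}: missing value at gene {g!r}, "
                f"sample {s!r} (missing data are not imputed)"
            )

    # -- accessors -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(self.values.index)

    def ranks(self) -> np.ndarray:
        """Within-sample (column-wise) ascending ranks, average-tied."""
        if self._ranks is None:
            self._ranks = rankdata(self.values.to_numpy(), axis=0)
        return self._ranks

    def row_indices(self, genes: Sequence[str]) -> np.ndarray:
        """Row positions of ``genes``; KeyError for genes off the platform."""
        if self._row_index is None:
            self._row_index = {g: i for i, g in enumerate(self.values.index)}
        return np.array([self._row_index[g] for g in genes], dtype=np.intp)

    def column_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.values.columns)}
        return np.array([lookup[s] for s in samples], dtype=np.intp)


@dataclass(frozen=True)
class DirectionalSignature:
    """A gene list in which each gene carries an expected direction (+1/-1)."""

    name: str
    genes: tuple[str, ...]
    directions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r}: at least one gene required")
        if len(self.genes) != len(self.directions):
            raise ValueError(f"signature {self.name!r}: genes/directions length mismatch")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise ValueError(f"signature {self.name!r}: duplicate gene {dup!r}")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError(f"signature {self.name!r}: directions must be +1 or -1")

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, int]]) -> "DirectionalSignature":
        genes, dirs = zip(*pairs)
        return cls(name, tuple(genes), tuple(int(d) for d in dirs))

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def up(self) -> tuple[str, ...]:
        return tuple(g for g, d in zip(self.genes, self.directions) if d == 1)

    @property
    def down(self) -> tuple[str, ...]:
        return tuple(g for g, d in zip(self.genes, self.directions) if d == -1)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def flipped(self) -> "DirectionalSignature":
        return DirectionalSignature(
            self.name + "_flipped", self.genes, tuple(-d for d in self.directions)
        )


@dataclass(frozen=True)
class GenePool:
    """A named set of genes eligible for random gene-set sampling.

    ``provenance`` records how the pool was built (whole platform,
    below-detection background, expressed genes, or an exclusion-filtered
    universe); ``excluded`` keeps the removed ids for audit.
    """

    name: str
    platform_id: str
    gene_ids: frozenset[str]
    provenance: str
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.provenance not in POOL_PROVENANCES:
            raise ValueError(f"unknown pool provenance {self.provenance!r}")
        if self.gene_ids & self.excluded:
            raise ValueError(f"pool {self.name!r}: gene_ids overlap excluded set")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def sorted_genes(self) -> list[str]:
        return sorted(self.gene_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_cohort(path, cohort_id: str, platform_id: str) -> ExpressionCohort:
    """Read a tab-delimited genes-x-samples matrix.

    First column holds gene identifiers, the header row sample identifiers.
    Duplicate gene ids, non-numeric cells and missing values are hard
    errors; rank scoring is undefined on missing data so nothing is imputed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ExpressionIOError(f"{path}: no genes (empty body)")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ExpressionIOError(f"{path}: duplicate gene id {dup!r}")
    try:
        numeric = df.astype(float)  # correctly-rounded parse, bit-exact round trip
    except (TypeError, ValueError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        g = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[g]][0]
        raise ExpressionIOError(
            f"{path}: non-numeric value {df.at[g, s]!r} at gene {g!r}, sample {s!r}"
        ) from None
    if numeric.isna().any().any():
        g = numeric.index[numeric.isna().any(axis=1)][0]
        s = numeric.columns[numeric.loc[g].isna()][0]
        raise ExpressionIOError(f"{path}: missing value at gene {g!r}, sample {s!r}")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionCohort(cohort_id=cohort_id, values=numeric, platform_id=platform_id)


def write_expression_cohort(cohort: ExpressionCohort, path) -> None:
    """Write a cohort matrix as TSV; values round-trip bit-exactly."""
    df = cohort.values.copy()
    df.index.name = "gene_id"
    # repr-precision floats survive a read_csv round trip exactly
    df.to_csv(path, sep="\t", float_format=None)


def read_sample_metadata(
    path,
    diagnosis_labels: Sequence[str] = DIAGNOSIS_LABELS,
    sex_labels: Sequence[str] = SEX_LABELS,
) -> pd.DataFrame:
    """Read the sample metadata table, indexed by sample_id.

    Required columns: sample_id, cohort_id, age, sex, diagnosis, batch.
    Sex and diagnosis labels outside the declared universes are rejected,
    as are duplicate sample ids and negative ages.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise ExpressionIOError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ExpressionIOError(f"{path}: duplicate sample_id {dup!r}")
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
    if (df["age"] < 0).any():
        raise ExpressionIOError(f"{path}: negative age")
    bad_sex = set(df["sex"]) - set(sex_labels)
    if bad_sex:
        raise ExpressionIOError(f"{path}: unknown sex label(s) {sorted(bad_sex)}")
    bad_dx = set(df["diagnosis"]) - set(diagnosis_labels)
    if bad_dx:
        raise ExpressionIOError(
            f"{path}: diagnosis label(s) {sorted(bad_dx)} not in declared "
            f"universe {tuple(diagnosis_labels)}"
        )
    return df.set_index("sample_id", drop=False)


def write_sample_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_signature(path, name: str | None = None) -> DirectionalSignature:
    """Read a two-column ``gene_id<TAB>direction`` signature file.

    Directions may be spelled +1/-1/1/up/down.
    """
    pairs: list[tuple[str, int]] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ExpressionIOError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        gene, raw = fields
        key = raw.strip().lower()
        if key not in _DIRECTION_ALIASES:
            raise ExpressionIOError(f"{path}:{lineno}: bad direction {raw!r}")
        pairs.append((gene, _DIRECTION_ALIASES[key]))
    if not pairs:
        raise ExpressionIOError(f"{path}: empty signature")
    return DirectionalSignature.from_pairs(name or path.stem, pairs)


def write_signature(signature: DirectionalSignature, path) -> None:
    with open(path, "w") as fh:
        for g, d in zip(signature.genes, signature.directions):
            fh.write(f"{g}\t{d:+d}\n")


def read_gmt(path) -> list[tuple[str, frozenset[str]]]:
    """Read a GMT gene-set collection (name TAB description TAB gene ...).

    Duplicate genes within a line are deduplicated with a warning;
    duplicate set names across lines are an error.
    """
    out: list[tuple[str, frozenset[str]]] = []
    names: set[str] = set()
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ExpressionIOError(
                f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
            )
        name, _desc, *genes = fields
        if name in names:
            raise ExpressionIOError(f"{path}:{lineno}: duplicate set name {name!r}")
        names.add(name)
        if len(set(genes)) != len(genes):
            logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
        out.append((name, frozenset(genes)))
    return out


def write_gmt(sets: Iterable[tuple[str, Iterable[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_exclusion_list(path) -> frozenset[str]:
    """One gene id per line; ``#`` comments and blank lines allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return frozenset(genes)


# ---------------------------------------------------------------------------
# pools
# ---------------------------------------------------------------------------

def all_genes_pool(cohort: ExpressionCohort, name: str = "all") -> GenePool:
    """The whole platform universe as a sampling pool."""
    return GenePool(name, cohort.platform_id, cohort.gene_universe, "all")


def background_pool(
    cohort: ExpressionCohort,
    floor_quantile: float = 0.25,
    sample_fraction: float = 0.8,
    name: str = "background",
) -> GenePool:
    """Genes sitting at the detection floor ("non-expressed" probes).

    A gene is background when its intensity is at or below the
    ``floor_quantile`` quantile of the cohort's pooled intensity
    distribution in at least ``sample_fraction`` of samples.  Both knobs
    are our operationalization of "below detection" and are configurable.
    """
    if not 0 < floor_quantile < 1:
        raise ValueError("floor_quantile must lie in (0, 1)")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must lie in (0, 1]")
    v = cohort.values.to_numpy()
    threshold = np.quantile(v, floor_quantile)
    frac_below = (v <= threshold).mean(axis=1)
    mask = frac_below >= sample_fraction
    genes = frozenset(np.asarray(cohort.values.index)[mask])
    if not genes:
        raise ValueError(
            "background pool is empty; raise floor_quantile or lower sample_fraction"
        )
    return GenePool(name, cohort.platform_id, genes, "background")


def filtered_pool(
    universe: Iterable[str],
    exclusion: Iterable[str],
    platform_id: str,
    name: str = "filtered",
) -> GenePool:
    """Universe minus an exclusion list (e.g. previously published age/disease
    genes); the removed ids are recorded on the pool."""
    universe = frozenset(universe)
    exclusion = frozenset(exclusion)
    hit = universe & exclusion
    if not hit:
        logger.info("filtered_pool %r: exclusion list did not intersect universe", name)
    genes = universe - exclusion
    if not genes:
        logger.warning("filtered_pool %r: exclusion removed the entire universe", name)
    return GenePool(name, platform_id, genes, "filtered", excluded=hit)
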