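"""Per-sample directional rank scores, direction fitting, and ROC AUC.

The signature score for a sample is the difference between the mean
within-sample rank of the up-genes and the mean within-sample rank of the
down-genes, divided by the number of ranked genes G:

    score(s) = [ mean_rank_up(s) - mean_rank_down(s) ] / G

Because ranks are computed within each sample, the score is invariant to
any monotone per-sample transform of expression and is directly comparable
across cohorts and platforms without cross-cohort normalization — the
property that makes cross-cohort external validation possible.  By default
genes are ranked against the full platform; an alternative mode ranks only
within the signature genes.

AUC follows the Mann–Whitney pair formulation: the probability that a
randomly chosen case scores above a randomly chosen control, with tied
pairs credited 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import DirectionalSignature, ExpressionCohort

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-sample signature scores plus bookkeeping on platform overlap."""

    sample_ids: tuple[str, ...]
    scores: np.ndarray
    signature_name: str
    n_genes_used: int
    n_genes_missing: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.sample_ids):
            raise ValueError("scores/sample_ids length mismatch")
        if self.n_genes_used < 1:
            raise ValueError("n_genes_used must be >= 1")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.sample_ids), name=self.signature_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.sample_ids), "score": self.scores}
        )


@dataclass(frozen=True)
class AucResult:
    auc: float
    n_cases: int
    n_controls: int
    n_tied_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc {self.auc} outside [0, 1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both classes must be non-empty")


def sample_ranks(cohort: ExpressionCohort) -> pd.DataFrame:
    """Within-sample ascending ranks (ties averaged) over all platform genes.

    Each column's ranks sum to G(G+1)/2.
    """
    if cohort.n_genes < 2:
        raise ValueError("ranking requires at least 2 genes")
    return pd.DataFrame(
        cohort.ranks(), index=cohort.values.index, columns=cohort.values.columns
    )


def directional_score(
    cohort: ExpressionCohort,
    signature: DirectionalSignature,
    rank_within_signature: bool = False,
    min_overlap_warn: float = 0.5,
) -> ScoreVector:
    """Score every sample of ``cohort`` with a directional signature.

    Signature genes absent from the platform are dropped (intersect-and-
    warn: different platforms carry different gene content), counted in
    ``n_genes_missing``; a warning fires when the retained fraction falls
    below ``min_overlap_warn``.  Signatures with only up- (or only down-)
    genes are scored one-sidedly and centered at zero.
    """
    universe = cohort.gene_universe
    present = [
        (g, d) for g, d in zip(signature.genes, signature.directions) if g in universe
    ]
    n_missing = len(signature) - len(present)
    if not present:
        raise ValueError(
            f"signature {signature.name!r} shares no genes with platform "
            f"{cohort.platform_id!r}"
        )
    if len(present) < min_overlap_warn * len(signature):
        warnings.warn(
            f"signature {signature.name!r}: only {len(present)}/{len(signature)} "
            f"genes present on platform {cohort.platform_id!r}",
            stacklevel=2,
        )
    elif n_missing:
        logger.info(
            "signature %r: %d gene(s) absent from platform %r",
            signature.name, n_missing, cohort.platform_id,
        )

    genes = [g for g, _ in present]
    dirs = np.array([d for _, d in present], dtype=float)
    if rank_within_signature:
        sub = cohort.values.to_numpy()[cohort.row_indices(genes), :]
        ranks = rankdata(sub, axis=0)
        big_g = len(genes)
        rows = np.arange(big_g)
    else:
        ranks = cohort.ranks()
        big_g = cohort.n_genes
        rows = cohort.row_indices(genes)

    scores = _score_rows(ranks, rows, dirs, big_g)
    return ScoreVector(
        sample_ids=tuple(cohort.sample_ids),
        scores=scores,
        signature_name=signature.name,
        n_genes_used=len(genes),
        n_genes_missing=n_missing,
    )


def _score_rows(ranks: np.ndarray, rows: np.ndarray, dirs: np.ndarray, big_g: int) -> np.ndarray:
    """Mean-rank-difference score from a precomputed rank matrix.

    One-sided signatures are centered so a direction-free expectation
    sits at zero.
    """
    up = rows[dirs > 0]
    down = rows[dirs < 0]
    if len(up) and len(down):
        return (ranks[up].mean(axis=0) - ranks[down].mean(axis=0)) / big_g
    if len(up):
        return ranks[up].mean(axis=0) / big_g - 0.5
    return 0.5 - ranks[down].mean(axis=0) / big_g


def fit_directions(
    cohort: ExpressionCohort,
    labels: pd.Series,
    gene_set,
    name: str = "fitted",
) -> DirectionalSignature:
    """Data-driven directions: sign of the case-minus-control mean difference.

    ``labels`` is a 0/1 series indexed by sample id over (a subset of) the
    cohort's samples; the fit uses exactly those samples.  A gene with an
    exactly zero difference gets +1 (deterministic tie-break, logged).
    Gene order in the result is sorted, so a gene *set* yields a
    deterministic signature.
    """
    genes = sorted(gene_set)
    missing = [g for g in genes if g not in cohort.gene_universe]
    if missing:
        raise KeyError(f"gene(s) not on platform {cohort.platform_id!r}: {missing[:5]}")
    lab = labels.astype(int)
    case_ids = lab.index[lab == 1]
    ctl_ids = lab.index[lab == 0]
    if len(case_ids) == 0 or len(ctl_ids) == 0:
        raise ValueError("direction fitting needs both classes non-empty")
    rows = cohort.row_indices(genes)
    v = cohort.values.to_numpy()
    diff = (
        v[np.ix_(rows, cohort.column_indices(case_ids))].mean(axis=1)
        - v[np.ix_(rows, cohort.column_indices(ctl_ids))].mean(axis=1)
    )
    n_zero = int((diff == 0).sum())
    if n_zero:
        logger.info("fit_directions %r: %d zero difference(s) tie-broken to +1", name, n_zero)
    dirs = np.where(diff < 0, -1, 1)
    return DirectionalSignature(name, tuple(genes), tuple(int(d) for d in dirs))


def auc(scores, labels) -> AucResult:
    """Mann–Whitney AUC of ``scores`` against binary ``labels`` (1 = case).

    auc = [#(case,control) pairs with case > control + 0.5 * #tied] / (n1*n0);
    computed via the rank-sum identity, which is exactly the pair count.
    """
    if isinstance(scores, ScoreVector):
        scores = scores.to_series()
    if isinstance(scores, pd.Series) and isinstance(labels, pd.Series):
        scores = scores.loc[labels.index]
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    cases = s[y == 1]
    controls = s[y == 0]
    n1, n0 = len(cases), len(controls)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with an empty class")
    r = rankdata(np.concatenate([cases, controls]))
    u = r[:n1].sum() - n1 * (n1 + 1) / 2.0
    value = u / (n1 * n0)
    # cross-class tied pairs, for the record
    uc, cc = np.unique(cases, return_counts=True)
    uo, co = np.unique(controls, return_counts=True)
    common, ic, io = np.intersect1d(uc, uo, return_indices=True)
    n_tied = int((cc[ic] * co[io]).sum())
    # guard against fp drift at the boundaries
    value = min(max(value, 0.0), 1.0)
    return AucResult(auc=value, n_cases=n1, n_controls=n0, n_tied_pairs=n_tied)
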