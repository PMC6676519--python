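"""Random gene-set nulls: sampling from pools and empirical AUC distributions.

A null distribution is the set of mean AUCs obtained by evaluating many
equally sized gene-sets, sampled at random from a stated pool, under the
same validation scheme as the candidate.  When two platforms with
different gene content are in play, sampling is per-platform from that
platform's own pool; ``intersect_pools`` additionally builds the shared
pool needed when one sampled set must be evaluable on both platforms
(the mode that enables a cross-cohort significance test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionCohort, GenePool
from .validation import SchemeConfig, cross_cohort_validate, within_cohort_cv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingConfig:
    """How to draw random gene-sets: pool, set size (150 by default, the
    size of the benchmarked signature), number of sets, seed."""

    pool: GenePool
    n_sets: int
    set_size: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size < 1 or self.n_sets < 1:
            raise ValueError("set_size and n_sets must be positive")
        if self.set_size > len(self.pool):
            raise ValueError(
                f"set_size {self.set_size} exceeds pool {self.pool.name!r} "
                f"({len(self.pool)} genes)"
            )


@dataclass
class NullDistribution:
    """Mean AUCs of randomly sampled gene-sets plus sampling provenance.

    Per-set failures (e.g. a set with no genes on a test platform) are
    recorded, excluded from ``aucs`` and counted — never silently dropped.
    """

    config: SamplingConfig
    scheme: SchemeConfig
    aucs: np.ndarray
    n_failed: int = 0
    failures: tuple[tuple[int, str], ...] = ()
    gene_sets: tuple[tuple[str, ...], ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.aucs = np.asarray(self.aucs, dtype=float)
        if self.aucs.size and (self.aucs.min() < 0 or self.aucs.max() > 1):
            raise ValueError("null AUCs must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.aucs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"set_index": np.arange(len(self.aucs)), "mean_auc": self.aucs}
        )


def sample_gene_sets(config: SamplingConfig) -> list[tuple[str, ...]]:
    """Draw ``n_sets`` gene-sets of ``set_size`` distinct genes each.

    Genes are drawn uniformly without replacement within a set; sets are
    independent of each other (a gene may recur across sets).  The draw
    sequence is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.asarray(config.pool.sorted_genes())
    return [
        tuple(rng.choice(genes, size=config.set_size, replace=False))
        for _ in range(config.n_sets)
    ]


def intersect_pools(pools: Sequence[GenePool], name: str = "paired") -> GenePool:
    """Shared pool across platforms, so one sampled set is evaluable on all."""
    if not pools:
        raise ValueError("need >=1 pool")
    shared = reduce(lambda a, b: a & b, (p.gene_ids for p in pools))
    if not shared:
        raise ValueError("pools share no genes")
    return GenePool(
        name,
        "+".join(p.platform_id for p in pools),
        frozenset(shared),
        pools[0].provenance,
    )


def evaluate_null(
    sets: Sequence[Sequence[str]],
    cohorts,
    labels,
    scheme: SchemeConfig,
    keep_gene_sets: bool = False,
    config: SamplingConfig | None = None,
    progress_every: int = 0,
) -> NullDistribution:
    """Evaluate each sampled set under ``scheme`` and collect mean AUCs.

    ``cohorts``/``labels`` are a single cohort and label series for a
    within scheme, or id-keyed mappings for a cross scheme.  Per-set
    errors are recorded as failures.  Deterministic given the sampling
    and scheme seeds.
    """
    if not len(sets):
        raise ValueError("no gene-sets to evaluate")
    aucs: list[float] = []
    failures: list[tuple[int, str]] = []
    for i, gene_set in enumerate(sets):
        try:
            if scheme.mode == "within":
                res = within_cohort_cv(
                    cohorts, labels, gene_set, scheme, gene_set_name=f"null_{i:05d}"
                )
            else:
                res = cross_cohort_validate(
                    cohorts, labels, gene_set, scheme, gene_set_name=f"null_{i:05d}"
                )
            aucs.append(res.mean_auc)
        except (ValueError, KeyError) as exc:
            failures.append((i, str(exc)))
            logger.warning("null set %d failed: %s", i, exc)
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("evaluated %d/%d null sets", i + 1, len(sets))
    if config is None:
        # minimal provenance when sets were supplied directly
        pool = GenePool(
            "ad_hoc", "unknown", frozenset().union(*map(frozenset, sets)), "all"
        )
        config = SamplingConfig(pool=pool, n_sets=len(sets), set_size=len(sets[0]))
    return NullDistribution(
        config=config,
        scheme=scheme,
        aucs=np.asarray(aucs),
        n_failed=len(failures),
        failures=tuple(failures),
        gene_sets=tuple(tuple(s) for s in sets) if keep_gene_sets else None,
    )


def null_summary(null: NullDistribution | np.ndarray) -> dict:
    """Mean, sd, extrema and upper percentiles of a null AUC distribution."""
    aucs = null.aucs if isinstance(null, NullDistribution) else np.asarray(null, float)
    if aucs.size == 0:
        raise ValueError("empty null distribution")
    pct = np.percentile(aucs, [50, 90, 95, 99, 100])
    return {
        "n": int(aucs.size),
        "mean": float(aucs.mean()),
        "sd": float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        "min": float(aucs.min()),
        "max": float(aucs.max()),
        "p50": float(pct[0]),
        "p90": float(pct[1]),
        "p95": float(pct[2]),
        "p99": float(pct[3]),
        "p100": float(pct[4]),
    }
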