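"""Significance of a candidate signature: empirical rank/p against a null
of random gene-sets, parametric AUC tests, BH correction, replication.

The empirical p-value uses the add-one convention,
p = (1 + #{null >= candidate}) / (1 + n): finite resampling never yields
p = 0, and ties between candidate and null count against the candidate.
A single prespecified signature is judged by its unadjusted per-cohort p
in EVERY independent cohort (replication); Benjamini–Hochberg correction
is reserved for families of candidate sets, where thousands of ROC values
would otherwise be reported without any multiplicity control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .null_sampling import NullDistribution

_EXACT_PAIR_LIMIT = 400


@dataclass
class SignificanceResult:
    candidate_auc: float
    null_n: int
    rank: int
    empirical_p: float
    parametric_p: float | None = None
    bh_adjusted_p: float | None = None
    replicated_all_cohorts: bool | None = None

    def __post_init__(self) -> None:
        lo = 1.0 / (self.null_n + 1)
        if not lo - 1e-12 <= self.empirical_p <= 1.0 + 1e-12:
            raise ValueError(
                f"empirical p {self.empirical_p} outside [{lo}, 1]"
            )
        if not 1 <= self.rank <= self.null_n + 1:
            raise ValueError(f"rank {self.rank} outside [1, {self.null_n + 1}]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def empirical_p(candidate_auc: float, null) -> tuple[float, int]:
    """Empirical p and rank of a candidate AUC against null AUCs.

    p = (1 + #{null >= candidate}) / (1 + n); rank = 1 + #{null > candidate}
    (rank 1 = best).
    """
    aucs = null.aucs if isinstance(null, NullDistribution) else np.asarray(null, float)
    if aucs.size == 0:
        raise ValueError("empty null distribution")
    n = aucs.size
    p = (1 + int((aucs >= candidate_auc).sum())) / (1 + n)
    rank = 1 + int((aucs > candidate_auc).sum())
    return p, rank


def auc_parametric_p(scores, labels) -> float:
    """Two-sided Mann–Whitney p for score separation between classes.

    Exact enumeration of the rank-sum distribution when the instance is
    tie-free and small (n_cases * n_controls <= 400), otherwise the
    normal approximation with tie correction and continuity correction.
    Degenerate inputs (all scores identical) return p = 1 with a warning.
    """
    if isinstance(scores, pd.Series) and isinstance(labels, pd.Series):
        scores = scores.loc[labels.index]
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    cases = s[y == 1]
    controls = s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be non-empty")
    if np.ptp(s) == 0:
        warnings.warn("all scores identical; p set to 1.0", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(s)) < len(s)
    small = len(cases) * len(controls) <= _EXACT_PAIR_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = mannwhitneyu(cases, controls, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def replication_verdict(
    per_cohort_p: Mapping[str, float], alpha: float = 0.05
) -> tuple[bool, dict]:
    """True iff the candidate is significant (p < alpha) in EVERY cohort.

    Replication across independent cohorts — not performance in one — is
    the criterion a prespecified signature must meet.
    """
    if len(per_cohort_p) < 2:
        raise ValueError("replication requires >=2 independent cohorts")
    verdicts = {c: bool(p < alpha) for c, p in per_cohort_p.items()}
    report = {
        "alpha": alpha,
        "per_cohort": {c: {"p": float(p), "significant": verdicts[c]}
                       for c, p in per_cohort_p.items()},
    }
    return all(verdicts.values()), report


def summarize_candidate(
    candidate_auc: float,
    null: NullDistribution,
    parametric_p: float | None = None,
) -> SignificanceResult:
    """Bundle empirical rank/p (and optional parametric p) for one cell."""
    p, rank = empirical_p(candidate_auc, null)
    return SignificanceResult(
        candidate_auc=float(candidate_auc),
        null_n=len(null),
        rank=rank,
        empirical_p=p,
        parametric_p=parametric_p,
    )
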