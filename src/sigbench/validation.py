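"""Validation schemes: within-cohort repeated splits and cross-cohort
external validation, plus diagnosis-group selection and age/sex matching.

Within-cohort validation repeatedly splits one cohort into a training
share (directions fitted there) and a held-out share (scored and
AUC-evaluated there).  This design is prone to optimism whenever batch
structure correlates with class, since any batch-driven expression shift
is learnable from the training half and present in the test half.

Cross-cohort (external) validation fits directions once on the entire
training cohort and evaluates on fully independent cohorts; batch noise
does not travel between cohorts, so it is the stricter test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionCohort
from .scoring import AucResult, auc, directional_score, fit_directions

logger = logging.getLogger(__name__)

CASE_DEFINITIONS = ("AD_vs_CTL", "ADMCI_vs_CTL")

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SchemeConfig:
    """Configuration of one validation scheme.

    mode "within": ``split_fraction`` is the training share (0.5 and 0.75
    are the two named presets, any value in (0,1) is accepted) and
    ``n_repeats`` the number of random splits.  mode "cross": directions
    are fitted on ``train_cohort_id`` and evaluated on every cohort in
    ``test_cohort_ids``.
    """

    mode: str
    seed: int = 0
    split_fraction: float = 0.75
    n_repeats: int = 10
    train_cohort_id: str | None = None
    test_cohort_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("within", "cross"):
            raise ValueError(f"unknown scheme mode {self.mode!r}")
        if self.mode == "within":
            if not 0 < self.split_fraction < 1:
                raise ValueError("split_fraction must lie in (0, 1)")
            if self.n_repeats < 1:
                raise ValueError("n_repeats must be positive")
        else:
            if not self.train_cohort_id:
                raise ValueError("cross mode requires train_cohort_id")
            if not self.test_cohort_ids:
                raise ValueError("cross mode requires >=1 test cohort")
            if self.train_cohort_id in self.test_cohort_ids:
                raise ValueError("train cohort must be distinct from test cohorts")


@dataclass
class ValidationResult:
    """Per-unit AUCs (repeats for within mode, test cohorts for cross mode)
    and their arithmetic mean."""

    gene_set_name: str
    scheme: SchemeConfig
    per_unit_auc: tuple[tuple[str, AucResult], ...]
    mean_auc: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_unit_auc:
            raise ValueError("ValidationResult needs >=1 unit")
        self.mean_auc = float(np.mean([r.auc for _, r in self.per_unit_auc]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "unit_id": uid,
                    "auc": r.auc,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                }
                for uid, r in self.per_unit_auc
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_set_name": self.gene_set_name,
                "scheme": asdict(self.scheme),
                "mean_auc": self.mean_auc,
                "per_unit": [
                    {"unit_id": uid, **asdict(r)} for uid, r in self.per_unit_auc
                ],
            },
            indent=2,
        )


def select_diagnosis_groups(metadata: pd.DataFrame, case_definition: str) -> pd.Series:
    """Binary labels (1 = case) from diagnosis, indexed by sample_id.

    ``AD_vs_CTL`` drops MCI samples entirely; ``ADMCI_vs_CTL`` merges the
    heterogeneous MCI group into the case class.
    """
    if case_definition not in CASE_DEFINITIONS:
        raise ValueError(f"unknown case definition {case_definition!r}")
    dx = metadata["diagnosis"]
    if case_definition == "AD_vs_CTL":
        keep = dx.isin(["AD", "CTL"])
        labels = (dx[keep] == "AD").astype(int)
    else:
        keep = dx.isin(["AD", "MCI", "CTL"])
        labels = dx[keep].isin(["AD", "MCI"]).astype(int)
    labels.index = metadata.index[keep]
    labels.name = "label"
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError(f"{case_definition}: a class is empty after selection")
    return labels


def match_cases_controls(
    metadata: pd.DataFrame,
    labels: pd.Series,
    age_tolerance: float = 5.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Greedy 1:1 age matching within sex strata.

    Cases are visited in descending age; each is paired with the unused
    same-sex control minimizing the absolute age difference, accepted only
    when that difference is within ``age_tolerance`` years.  Exact-distance
    ties are broken by a seed-shuffled control order, so the output is
    deterministic given the seed.  Unmatched cases are dropped and logged.
    """
    rng = np.random.default_rng(seed)
    meta = metadata.loc[labels.index]
    pairs: list[tuple[str, str]] = []
    n_unmatched = 0
    for sex in sorted(meta["sex"].unique()):
        stratum = meta[meta["sex"] == sex]
        case_ids = [s for s in stratum.index if labels[s] == 1]
        ctl_ids = [s for s in stratum.index if labels[s] == 0]
        case_ids.sort(key=lambda s: -meta.at[s, "age"])
        order = rng.permutation(len(ctl_ids))
        # (age, shuffled tie-break key, id) for the available controls
        avail = [(meta.at[ctl_ids[i], "age"], int(k), ctl_ids[i]) for k, i in enumerate(order)]
        for cid in case_ids:
            cage = meta.at[cid, "age"]
            best = min(avail, key=lambda t: (abs(t[0] - cage), t[1])) if avail else None
            if best is not None and abs(best[0] - cage) <= age_tolerance:
                pairs.append((cid, best[2]))
                avail.remove(best)
            else:
                n_unmatched += 1
    if n_unmatched:
        logger.info("matching dropped %d unmatched case(s)", n_unmatched)
    if not pairs:
        raise ValueError("no case/control pair satisfies the matching constraints")
    return pairs


def matched_labels(pairs: list[tuple[str, str]]) -> pd.Series:
    """0/1 labels restricted to the matched samples."""
    idx = [s for pair in pairs for s in pair]
    vals = [v for _ in pairs for v in (1, 0)]
    return pd.Series(vals, index=idx, name="label")


def _stratified_split(
    case_ids: np.ndarray,
    ctl_ids: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One class-ratio-preserving split; returns
    (train_cases, train_controls, test_cases, test_controls).

    A draw leaving either side without a class is re-drawn, capped at
    100 attempts."""
    for _ in range(_MAX_REDRAWS):
        n1 = int(round(train_fraction * len(case_ids)))
        n0 = int(round(train_fraction * len(ctl_ids)))
        perm1 = rng.permutation(case_ids)
        perm0 = rng.permutation(ctl_ids)
        if 0 < n1 < len(case_ids) and 0 < n0 < len(ctl_ids):
            return perm1[:n1], perm0[:n0], perm1[n1:], perm0[n0:]
    raise ValueError(
        "could not draw a split with both classes in train and test "
        f"(fraction={train_fraction}, n_cases={len(case_ids)}, n_controls={len(ctl_ids)})"
    )


def within_cohort_cv(
    cohort: ExpressionCohort,
    labels: pd.Series,
    gene_set,
    scheme: SchemeConfig,
    gene_set_name: str = "gene_set",
) -> ValidationResult:
    """Repeated stratified-split validation inside one cohort.

    Per repeat: directions are fitted on the training share and the
    held-out share is scored and AUC-evaluated.  Fully reproducible from
    ``scheme.seed``.
    """
    if scheme.mode != "within":
        raise ValueError("within_cohort_cv requires a scheme with mode='within'")
    rng = np.random.default_rng(scheme.seed)
    lab = labels.astype(int)
    case_ids = np.asarray(lab.index[lab == 1])
    ctl_ids = np.asarray(lab.index[lab == 0])

    genes = sorted(set(gene_set))
    missing = [g for g in genes if g not in cohort.gene_universe]
    if missing:
        raise KeyError(f"gene(s) not on platform {cohort.platform_id!r}: {missing[:5]}")
    rows = cohort.row_indices(genes)
    case_cols = cohort.column_indices(case_ids)
    ctl_cols = cohort.column_indices(ctl_ids)
    v = cohort.values.to_numpy()
    ranks = cohort.ranks()
    big_g = cohort.n_genes

    units = []
    for rep in range(scheme.n_repeats):
        train_case, train_ctl, test_case, test_ctl = _stratified_split(
            case_cols, ctl_cols, scheme.split_fraction, rng
        )
        diff = (
            v[np.ix_(rows, train_case)].mean(axis=1)
            - v[np.ix_(rows, train_ctl)].mean(axis=1)
        )
        dirs = np.where(diff < 0, -1.0, 1.0)
        scores = _score_cols(ranks, rows, dirs, np.concatenate([test_case, test_ctl]), big_g)
        y = np.concatenate([np.ones(len(test_case), int), np.zeros(len(test_ctl), int)])
        units.append((f"repeat_{rep:03d}", auc(scores, y)))
    return ValidationResult(gene_set_name, scheme, tuple(units))


def _score_cols(
    ranks: np.ndarray, rows: np.ndarray, dirs: np.ndarray, cols: np.ndarray, big_g: int
) -> np.ndarray:
    """Directional mean-rank score restricted to ``cols``; matches
    scoring.directional_score for two-sided fitted signatures."""
    up = rows[dirs > 0]
    down = rows[dirs < 0]
    sub = ranks[:, cols]
    if len(up) and len(down):
        return (sub[up].mean(axis=0) - sub[down].mean(axis=0)) / big_g
    if len(up):
        return sub[up].mean(axis=0) / big_g - 0.5
    return 0.5 - sub[down].mean(axis=0) / big_g


def cross_cohort_validate(
    cohorts: Mapping[str, ExpressionCohort],
    labels_by_cohort: Mapping[str, pd.Series],
    gene_set,
    scheme: SchemeConfig,
    gene_set_name: str = "gene_set",
) -> ValidationResult:
    """External validation: fit directions on the whole training cohort,
    evaluate on each independent test cohort.

    The fitted signature travels as-is; per-sample ranks are computed
    within each test cohort, and signature genes absent from a test
    platform follow the scoring module's intersect-and-warn rule.
    """
    if scheme.mode != "cross":
        raise ValueError("cross_cohort_validate requires a scheme with mode='cross'")
    train = cohorts[scheme.train_cohort_id]
    train_genes = sorted(set(gene_set) & train.gene_universe)
    if not train_genes:
        raise ValueError("gene set shares no genes with the training platform")
    sig = fit_directions(
        train, labels_by_cohort[scheme.train_cohort_id], train_genes, name=gene_set_name
    )
    units = []
    for cid in scheme.test_cohort_ids:
        test = cohorts[cid]
        lab = labels_by_cohort[cid].astype(int)
        scores = directional_score(test, sig).to_series().loc[lab.index]
        units.append((cid, auc(scores, lab)))
    return ValidationResult(gene_set_name, scheme, tuple(units))
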