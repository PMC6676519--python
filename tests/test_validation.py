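import numpy as np
import pandas as pd
import pytest

from sigbench.simulate import CohortSpec, SimConfig, generate_cohorts, planted_signature
from sigbench.validation import (
    SchemeConfig,
    cross_cohort_validate,
    match_cases_controls,
    matched_labels,
    select_diagnosis_groups,
    within_cohort_cv,
)
from conftest import make_cohort


def _meta(rows):
    df = pd.DataFrame(
        rows, columns=["sample_id", "cohort_id", "age", "sex", "diagnosis", "batch"]
    )
    return df.set_index("sample_id", drop=False)


class TestSelectDiagnosisGroups:
    @pytest.fixture
    def meta(self):
        rows = []
        for i in range(10):
            rows.append((f"ad{i}", "c", 70, "F", "AD", "b"))
            rows.append((f"mci{i}", "c", 70, "F", "MCI", "b"))
            rows.append((f"ctl{i}", "c", 70, "F", "CTL", "b"))
        return _meta(rows)

    def test_ad_vs_ctl_drops_mci(self, meta):
        labels = select_diagnosis_groups(meta, "AD_vs_CTL")
        assert len(labels) == 20 and labels.sum() == 10
        assert not any(s.startswith("mci") for s in labels.index)

    def test_admci_merges_cases(self, meta):
        labels = select_diagnosis_groups(meta, "ADMCI_vs_CTL")
        assert len(labels) == 30 and labels.sum() == 20

    def test_no_controls_errors(self):
        meta = _meta([("s1", "c", 70, "F", "AD", "b")])
        with pytest.raises(ValueError, match="empty"):
            select_diagnosis_groups(meta, "AD_vs_CTL")


class TestMatching:
    def test_pairs_within_tolerance(self):
        meta = _meta([
            ("case_f", "c", 70, "F", "AD", "b"),
            ("case_m", "c", 80, "M", "AD", "b"),
            ("ctl_f", "c", 71, "F", "CTL", "b"),
            ("ctl_m", "c", 79, "M", "CTL", "b"),
        ])
        labels = select_diagnosis_groups(meta, "AD_vs_CTL")
        pairs = match_cases_controls(meta, labels, age_tolerance=2)
        assert sorted(pairs) == [("case_f", "ctl_f"), ("case_m", "ctl_m")]

    def test_sex_stratum_respected(self):
        meta = _meta([
            ("case_f", "c", 70, "F", "AD", "b"),
            ("ctl_m", "c", 70, "M", "CTL", "b"),
        ])
        labels = select_diagnosis_groups(meta, "AD_vs_CTL")
        with pytest.raises(ValueError, match="no case/control pair"):
            match_cases_controls(meta, labels, age_tolerance=2)

    def test_minimal_age_distance_preferred(self):
        meta = _meta([
            ("case", "c", 70, "F", "AD", "b"),
            ("ctl_far", "c", 75, "F", "CTL", "b"),
            ("ctl_near", "c", 71, "F", "CTL", "b"),
        ])
        labels = select_diagnosis_groups(meta, "AD_vs_CTL")
        pairs = match_cases_controls(meta, labels, age_tolerance=2)
        assert pairs == [("case", "ctl_near")]

    def test_matching_invariants_on_random_population(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(40):
            rows.append((f"ad{i}", "c", rng.uniform(60, 90), rng.choice(["F", "M"]), "AD", "b"))
        for i in range(60):
            rows.append((f"ctl{i}", "c", rng.uniform(55, 85), rng.choice(["F", "M"]), "CTL", "b"))
        meta = _meta(rows)
        labels = select_diagnosis_groups(meta, "AD_vs_CTL")
        pairs = match_cases_controls(meta, labels, age_tolerance=5.0, seed=3)
        controls_used = [c for _, c in pairs]
        assert len(set(controls_used)) == len(controls_used)  # no control reused
        for case, ctl in pairs:
            assert meta.at[case, "sex"] == meta.at[ctl, "sex"]
            assert abs(meta.at[case, "age"] - meta.at[ctl, "age"]) <= 5.0
        # determinism under the seed
        assert pairs == match_cases_controls(meta, labels, age_tolerance=5.0, seed=3)
        lab = matched_labels(pairs)
        assert lab.sum() == len(pairs) and len(lab) == 2 * len(pairs)


class TestWithinCohortCV:
    def _noise_cohort_and_labels(self, n=40, g=60, seed=0):
        rng = np.random.default_rng(seed)
        cohort = make_cohort(rng.normal(size=(g, n)))
        labels = pd.Series([1] * (n // 2) + [0] * (n // 2), index=cohort.sample_ids)
        return cohort, labels

    def test_perfectly_informative_gene_gives_auc_one(self):
        rng = np.random.default_rng(1)
        n = 40
        values = rng.normal(size=(20, n))
        labels = np.array([1] * 20 + [0] * 20)
        values[0] = labels * 10.0 + rng.normal(0, 0.01, n)  # planted determinant
        cohort = make_cohort(values)
        lab = pd.Series(labels, index=cohort.sample_ids)
        scheme = SchemeConfig(mode="within", split_fraction=0.5, n_repeats=8, seed=2)
        res = within_cohort_cv(cohort, lab, {"G0"}, scheme)
        assert all(r.auc == 1.0 for _, r in res.per_unit_auc)

    def test_null_labels_center_at_half(self):
        # a single gene-set's repeat-mean is data-conditional (splits of one
        # cohort are correlated), so calibration is checked over independent
        # label permutations: the grand mean sits within 3 MC SE of 0.5
        rng = np.random.default_rng(4)
        cohort = make_cohort(rng.normal(size=(100, 60)))
        means = []
        for k in range(30):
            labels = pd.Series(
                rng.permutation([1] * 30 + [0] * 30), index=cohort.sample_ids
            )
            scheme = SchemeConfig(mode="within", split_fraction=0.75,
                                  n_repeats=10, seed=100 + k)
            res = within_cohort_cv(cohort, labels, {f"G{i}" for i in range(30)}, scheme)
            means.append(res.mean_auc)
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) < 3 * se

    def test_single_repeat_single_unit(self):
        cohort, labels = self._noise_cohort_and_labels()
        scheme = SchemeConfig(mode="within", n_repeats=1, seed=0)
        res = within_cohort_cv(cohort, labels, {"G0", "G1"}, scheme)
        assert len(res.per_unit_auc) == 1
        assert res.mean_auc == res.per_unit_auc[0][1].auc

    def test_seed_reproducibility(self):
        cohort, labels = self._noise_cohort_and_labels(seed=11)
        scheme = SchemeConfig(mode="within", n_repeats=5, seed=42)
        a = within_cohort_cv(cohort, labels, {"G0", "G5", "G9"}, scheme)
        b = within_cohort_cv(cohort, labels, {"G0", "G5", "G9"}, scheme)
        assert [r.auc for _, r in a.per_unit_auc] == [r.auc for _, r in b.per_unit_auc]

    def test_degenerate_split_errors(self):
        cohort, _ = self._noise_cohort_and_labels(n=4)
        labels = pd.Series([1, 0, 0, 0], index=cohort.sample_ids)
        scheme = SchemeConfig(mode="within", split_fraction=0.9, n_repeats=2, seed=0)
        with pytest.raises(ValueError, match="split"):
            within_cohort_cv(cohort, labels, {"G0"}, scheme)


@pytest.fixture(scope="module")
def two_cohorts():
    cfg = SimConfig(
            cohorts=(
            CohortSpec("train", "p1", n_cases=40, n_controls=40, universe_size=700),
            CohortSpec("test", "p2", n_cases=40, n_controls=40, universe_size=700),
        ),
        g_total=800, n_signal=60, effect_size=2.0, noise_sd=1.0,
        n_background=100, seed=21,
    )
    data = generate_cohorts(cfg)
    cohorts = {c.cohort_id: c for c, _ in data}
    labels = {
        c.cohort_id: pd.Series(
            (m["diagnosis"] == "AD").astype(int).to_numpy(), index=m.index
        )
        for c, m in data
    }
    return cfg, cohorts, labels


class TestCrossCohortValidate:

    def test_strong_planted_effect_transfers(self, two_cohorts):
        cfg, cohorts, labels = two_cohorts
        scheme = SchemeConfig(mode="cross", train_cohort_id="train",
                              test_cohort_ids=("test",), seed=0)
        res = cross_cohort_validate(cohorts, labels, planted_signature(cfg).gene_set, scheme)
        assert res.mean_auc > 0.95

    def test_independent_labels_stay_near_half(self, two_cohorts):
        cfg, cohorts, labels = two_cohorts
        rng = np.random.default_rng(13)
        shuffled = {
            "train": labels["train"],
            "test": pd.Series(
                rng.permutation(labels["test"].to_numpy()), index=labels["test"].index
            ),
        }
        scheme = SchemeConfig(mode="cross", train_cohort_id="train",
                              test_cohort_ids=("test",), seed=0)
        res = cross_cohort_validate(cohorts, shuffled, planted_signature(cfg).gene_set, scheme)
        assert abs(res.mean_auc - 0.5) < 0.1

    def test_single_test_cohort_mean_equals_unit(self, two_cohorts):
        cfg, cohorts, labels = two_cohorts
        scheme = SchemeConfig(mode="cross", train_cohort_id="train",
                              test_cohort_ids=("test",), seed=0)
        res = cross_cohort_validate(cohorts, labels, {"GENE_000", "GENE_001"}, scheme)
        assert len(res.per_unit_auc) == 1
        assert res.mean_auc == res.per_unit_auc[0][1].auc

    def test_scheme_mode_guard(self, two_cohorts):
        cfg, cohorts, labels = two_cohorts
        with pytest.raises(ValueError, match="distinct"):
            SchemeConfig(mode="cross", train_cohort_id="train", test_cohort_ids=("train",))
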