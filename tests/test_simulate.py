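import json

import numpy as np
import pandas as pd
import pytest

from sigbench.simulate import (
    CohortSpec,
    SimConfig,
    age_gene_signature,
    background_gene_ids,
    generate_cohorts,
    planted_signature,
    write_fixture_bundle,
)
from sigbench.scoring import auc, directional_score
from sigbench.validation import SchemeConfig, cross_cohort_validate


def _small_config(**overrides):
    base = dict(
        cohorts=(
            CohortSpec("a", "p1", n_cases=30, n_controls=30, universe_size=500,
                       core_overlap=0.9),
            CohortSpec("b", "p2", n_cases=30, n_controls=30, universe_size=500,
                       core_overlap=0.9),
        ),
        g_total=600, n_signal=40, n_background=80, effect_size=0.8, seed=5,
    )
    base.update(overrides)
    return SimConfig(**base)


def _labels(meta):
    keep = meta["diagnosis"].isin(["AD", "CTL"])
    return pd.Series((meta.loc[keep, "diagnosis"] == "AD").astype(int).to_numpy(),
                     index=meta.index[keep])


class TestGenerateCohorts:
    def test_shapes_and_metadata(self):
        cfg = _small_config()
        data = generate_cohorts(cfg)
        assert len(data) == 2
        for cohort, meta in data:
            assert cohort.values.shape == (500, 60)
            assert set(meta["diagnosis"]) == {"AD", "CTL"}
            assert list(meta.index) == cohort.sample_ids

    def test_reproducible_from_seed(self):
        a = generate_cohorts(_small_config())
        b = generate_cohorts(_small_config())
        for (c1, m1), (c2, m2) in zip(a, b):
            assert np.array_equal(c1.values.to_numpy(), c2.values.to_numpy())
            assert m1.equals(m2)

    def test_platform_universes_share_core_but_differ_in_tail(self):
        cfg = _small_config()
        (ca, _), (cb, _) = generate_cohorts(cfg)
        shared = ca.gene_universe & cb.gene_universe
        assert len(shared) >= int(0.9 * 500)
        assert planted_signature(cfg).gene_set <= shared
        assert background_gene_ids(cfg) <= shared

    def test_pure_noise_config_gives_chance_auc(self):
        cfg = _small_config(effect_size=0.0, batch_sd=0.0)
        (cohort, meta), _ = generate_cohorts(cfg)
        sig = planted_signature(cfg)
        sv = directional_score(cohort, sig)
        lab = _labels(meta)
        r = auc(sv.to_series().loc[lab.index], lab)
        assert abs(r.auc - 0.5) < 0.12

    def test_mci_with_zero_mixing_looks_like_controls(self):
        cfg = _small_config(
            cohorts=(CohortSpec("a", "p1", n_cases=30, n_controls=30, n_mci=30,
                                universe_size=500, core_overlap=0.9),),
            mci_mixing=0.0, effect_size=2.0,
        )
        (cohort, meta), = generate_cohorts(cfg)
        sig = planted_signature(cfg)
        scores = directional_score(cohort, sig).to_series()
        mci = scores[meta.index[meta["diagnosis"] == "MCI"]]
        ctl = scores[meta.index[meta["diagnosis"] == "CTL"]]
        ad = scores[meta.index[meta["diagnosis"] == "AD"]]
        assert abs(mci.mean() - ctl.mean()) < 0.05
        assert ad.mean() > ctl.mean() + 0.1

    def test_noise_moments_match_config(self):
        cfg = _small_config(effect_size=0.0, batch_sd=0.0, noise_sd=1.0,
                            sd_gene_baseline=0.0)
        (cohort, _), _ = generate_cohorts(cfg)
        sig_ids = sorted(planted_signature(cfg).gene_set)
        block = cohort.values.loc[sig_ids].to_numpy()
        # per-gene sd across samples should estimate noise_sd
        sds = block.std(axis=1, ddof=1)
        assert abs(sds.mean() - 1.0) < 0.05
        bg = cohort.values.loc[sorted(background_gene_ids(cfg))].to_numpy()
        assert abs(bg.mean() - cfg.mu_background) < 0.1
        assert abs(bg.std(ddof=1) - cfg.sd_background) < 0.05

    def test_cases_older_when_shifted(self):
        cfg = _small_config(age_shift_cases=8.0)
        (_, meta), _ = generate_cohorts(cfg)
        ad = meta.loc[meta["diagnosis"] == "AD", "age"]
        ctl = meta.loc[meta["diagnosis"] == "CTL", "age"]
        assert ad.mean() - ctl.mean() > 4.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            _small_config(n_signal=400, n_background=400)
        with pytest.raises(ValueError, match="rho|\\[0, 1\\]"):
            _small_config(batch_class_rho=1.5)
        with pytest.raises(ValueError, match="core"):
            _small_config(
                cohorts=(CohortSpec("a", "p1", universe_size=200, core_overlap=0.1),)
            )


class TestCrossCohortSignalStrength:
    def test_auc_monotone_in_effect_size(self):
        aucs = []
        for d in (0.0, 0.5, 1.0, 2.0):
            cfg = _small_config(effect_size=d)
            data = generate_cohorts(cfg)
            cohorts = {c.cohort_id: c for c, _ in data}
            labels = {c.cohort_id: _labels(m) for c, m in data}
            scheme = SchemeConfig(mode="cross", train_cohort_id="a",
                                  test_cohort_ids=("b",), seed=1)
            res = cross_cohort_validate(
                cohorts, labels, planted_signature(cfg).gene_set, scheme
            )
            aucs.append(res.mean_auc)
        assert aucs == sorted(aucs)
        assert aucs[0] < 0.65 and aucs[-1] > 0.95


class TestPlantedSignature:
    def test_size_and_disjoint_from_background(self):
        cfg = _small_config()
        sig = planted_signature(cfg)
        assert len(sig) == 40
        assert not (sig.gene_set & background_gene_ids(cfg))

    def test_directions_match_generated_shift(self):
        cfg = _small_config(effect_size=3.0, noise_sd=0.3)
        (cohort, meta), _ = generate_cohorts(cfg)
        sig = planted_signature(cfg)
        lab = _labels(meta)
        v = cohort.values
        for g, d in list(zip(sig.genes, sig.directions))[:10]:
            diff = (v.loc[g, lab.index[lab == 1]].mean()
                    - v.loc[g, lab.index[lab == 0]].mean())
            assert np.sign(diff) == d

    def test_age_gene_signature_accessor(self):
        cfg = _small_config(n_age_genes=20)
        sig = age_gene_signature(cfg)
        assert len(sig) == 20
        assert not (sig.gene_set & planted_signature(cfg).gene_set)


class TestFixtureBundle:
    def test_bundle_contents_and_determinism(self, tmp_path):
        cfg = _small_config(
            cohorts=(CohortSpec("a", "p1", n_cases=10, n_controls=10,
                                universe_size=200, core_overlap=0.9),),
            g_total=250, n_signal=20, n_background=30,
        )
        m1 = write_fixture_bundle(cfg, tmp_path / "one")
        m2 = write_fixture_bundle(cfg, tmp_path / "two")
        assert set(m1["files"]) == {
            "expression_a", "metadata", "signature", "exclusion", "gene_sets"
        }
        for key in m1["files"]:
            assert m1["files"][key]["sha256"] == m2["files"][key]["sha256"]
        manifest = json.loads((tmp_path / "one" / "manifest.json").read_text())
        assert manifest["seed"] == cfg.seed

    def test_bundle_reads_back(self, tmp_path):
        from sigbench.io import (
            read_exclusion_list, read_expression_cohort, read_gmt,
            read_sample_metadata, read_signature,
        )
        cfg = _small_config(
            cohorts=(CohortSpec("a", "p1", n_cases=10, n_controls=10,
                                universe_size=200, core_overlap=0.9),),
            g_total=250, n_signal=20, n_background=30,
        )
        out = tmp_path / "bundle"
        write_fixture_bundle(cfg, out)
        cohort = read_expression_cohort(out / "expression_a.tsv", "a", "p1")
        assert cohort.values.shape == (200, 20)
        meta = read_sample_metadata(out / "metadata.tsv")
        assert len(meta) == 20
        sig = read_signature(out / "signature.tsv")
        assert sig.gene_set == planted_signature(cfg).gene_set
        excl = read_exclusion_list(out / "exclusion.txt")
        assert excl == sig.gene_set
        sets = read_gmt(out / "gene_sets.gmt")
        assert sets[0][0] == "planted" and len(sets) == 4
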