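"""Synthetic multi-cohort expression data with the structure the benchmark
probes: planted directional signal, batch effects that can confound with
class, below-detection background probes, age/sex-structured risk, an MCI
mixture group, and platforms with partially overlapping gene content.

The model is Gaussian on the log2-intensity scale (microarray-like).  For
gene g and sample s:

    y[g,s] = mu_g
           + d * dir_g * signal(s)              (signal genes only)
           + beta_g * (age_s - mean_age) / 10   (age-effect genes)
           + gamma_g * 1[s male]                (sex-effect genes)
           + b[batch(s), g]                     (all genes, incl. background)
           + eps[g,s]

signal(s) is 1 for cases, Bernoulli(mci_mixing) for MCI samples, 0 for
controls.  Batch effects b[k, g] ~ N(0, batch_sd^2) are drawn per cohort,
per batch, per gene — crucially for ALL genes, so that when case samples
concentrate in one batch (batch_class_rho > 0) even background probes
acquire an apparent class signal within that cohort; batch effects are
independent across cohorts and therefore never replicate externally.
Cases can be drawn older than controls (age_shift_cases) so that skipping
age/sex matching measurably inflates performance.

Gene-level parameters (baselines, directions, age/sex slopes) are drawn
once from the master seed and shared by every cohort; samples, batch
effects and noise are per-cohort.  Signal, background, age- and
sex-effect genes live in the shared core of every platform universe, with
cohort-specific tail genes emulating differing array content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DirectionalSignature,
    ExpressionCohort,
    write_expression_cohort,
    write_gmt,
    write_sample_metadata,
    write_signature,
)


@dataclass(frozen=True)
class CohortSpec:
    """Per-cohort sample counts and platform universe."""

    cohort_id: str
    platform_id: str
    n_cases: int = 60
    n_controls: int = 60
    n_mci: int = 0
    universe_size: int = 1800
    core_overlap: float = 0.85
    batch_class_rho: float | None = None   # overrides the config-wide value

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_mci < 0:
            raise ValueError("need >=1 case and >=1 control per cohort")
        if not 0 <= self.core_overlap <= 1:
            raise ValueError("core_overlap must lie in [0, 1]")
        if self.batch_class_rho is not None and not 0 <= self.batch_class_rho <= 1:
            raise ValueError("batch_class_rho must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls + self.n_mci


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; every stochastic element derives from
    ``seed``.  Defaults give a clearly detectable planted signal at desk
    scale: 150 signal genes at effect size 0.8 log2 units against unit
    noise, 400 background probes at the detection floor."""

    cohorts: tuple[CohortSpec, ...] = (
        CohortSpec("cohortA", "platform1"),
        CohortSpec("cohortB", "platform2"),
    )
    g_total: int = 2000
    n_signal: int = 150
    effect_size: float = 0.8           # d, log2 units
    n_background: int = 400
    mu_background: float = 4.0         # detection floor, log2
    sd_background: float = 0.25        # noise sd of background probes
    mu_expressed: float = 8.0          # mean baseline of expressed genes
    sd_gene_baseline: float = 1.0      # spread of per-gene baselines
    n_batches: int = 2
    batch_sd: float = 0.0              # tau; per-batch per-gene shift sd
    batch_class_rho: float = 0.0       # fraction of cases forced into batch 1
    age_range: tuple[float, float] = (55.0, 85.0)
    age_shift_cases: float = 0.0       # years; cases older on average
    n_age_genes: int = 0
    age_slope: float = 0.5             # log2 units per decade
    n_sex_genes: int = 0
    sex_effect: float = 0.5            # log2 shift in males
    mci_mixing: float = 0.5            # pi; P(an MCI sample carries the signal)
    noise_sd: float = 1.0              # sigma
    seed: int = 0

    def __post_init__(self) -> None:
        special = self.n_signal + self.n_background + self.n_age_genes + self.n_sex_genes
        if special > self.g_total:
            raise ValueError("signal+background+age+sex genes exceed g_total")
        for name in ("noise_sd", "sd_background", "batch_sd", "sd_gene_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("batch_class_rho", "mci_mixing"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        for spec in self.cohorts:
            if spec.universe_size > self.g_total:
                raise ValueError(
                    f"{spec.cohort_id}: universe_size exceeds g_total"
                )
            core = int(round(spec.core_overlap * spec.universe_size))
            if core < special:
                raise ValueError(
                    f"{spec.cohort_id}: platform core ({core}) cannot hold all "
                    f"signal/background/age/sex genes ({special})"
                )


@dataclass
class _GeneParams:
    gene_ids: np.ndarray
    mu: np.ndarray
    signal_idx: np.ndarray
    background_idx: np.ndarray
    age_idx: np.ndarray
    sex_idx: np.ndarray
    directions: np.ndarray      # +-1 for signal genes
    age_slopes: np.ndarray      # signed slope per age gene
    sex_effects: np.ndarray     # signed shift per sex gene


def _seed_streams(config: SimConfig) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(c) for c in ss.spawn(1 + len(config.cohorts))]


def _gene_params(config: SimConfig, rng: np.random.Generator) -> _GeneParams:
    g = config.g_total
    width = len(str(g))
    gene_ids = np.array([f"GENE_{i:0{width}d}" for i in range(g)])
    mu = config.mu_expressed + config.sd_gene_baseline * rng.standard_normal(g)
    s = config.n_signal
    b = config.n_background
    a = config.n_age_genes
    x = config.n_sex_genes
    signal_idx = np.arange(0, s)
    background_idx = np.arange(s, s + b)
    age_idx = np.arange(s + b, s + b + a)
    sex_idx = np.arange(s + b + a, s + b + a + x)
    mu[background_idx] = config.mu_background
    directions = rng.choice([-1, 1], size=s)
    age_slopes = config.age_slope * rng.choice([-1, 1], size=a)
    sex_effects = config.sex_effect * rng.choice([-1, 1], size=x)
    return _GeneParams(
        gene_ids, mu, signal_idx, background_idx, age_idx, sex_idx,
        directions, age_slopes, sex_effects,
    )


def _platform_rows(
    spec: CohortSpec, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Global row indices forming this cohort's platform universe: the
    shared core (head of the global list) plus a cohort-specific draw
    from the remaining genes."""
    core = int(round(spec.core_overlap * spec.universe_size))
    n_tail = spec.universe_size - core
    tail_pool = np.arange(core, config.g_total)
    tail = rng.choice(tail_pool, size=n_tail, replace=False) if n_tail else np.array([], int)
    return np.concatenate([np.arange(core), np.sort(tail)])


def generate_cohorts(config: SimConfig) -> list[tuple[ExpressionCohort, pd.DataFrame]]:
    """Generate each cohort's expression matrix and metadata table.

    Fully reproducible from ``config.seed``; the gene-level parameters are
    shared across cohorts so a planted signal replicates externally while
    batch noise does not.
    """
    gene_rng, *cohort_rngs = _seed_streams(config)
    params = _gene_params(config, gene_rng)
    out = []
    for spec, rng in zip(config.cohorts, cohort_rngs):
        out.append(_generate_one(spec, config, params, rng))
    return out


def _generate_one(
    spec: CohortSpec,
    config: SimConfig,
    params: _GeneParams,
    rng: np.random.Generator,
) -> tuple[ExpressionCohort, pd.DataFrame]:
    n = spec.n_samples
    diagnosis = np.array(
        ["AD"] * spec.n_cases + ["CTL"] * spec.n_controls + ["MCI"] * spec.n_mci
    )
    sample_ids = np.array([f"{spec.cohort_id}_S{i:04d}" for i in range(n)])

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    ages[diagnosis != "CTL"] += config.age_shift_cases
    sexes = rng.choice(["F", "M"], size=n)

    is_case = diagnosis == "AD"
    is_mci = diagnosis == "MCI"
    signal = is_case.astype(float)
    signal[is_mci] = (rng.random(is_mci.sum()) < config.mci_mixing).astype(float)

    # batch assignment: rho fraction of cases pinned to batch 1, everyone
    # else spread uniformly at random
    batches = rng.integers(0, config.n_batches, size=n)
    case_pos = np.flatnonzero(is_case)
    rho = spec.batch_class_rho if spec.batch_class_rho is not None else config.batch_class_rho
    n_forced = int(round(rho * len(case_pos)))
    forced = rng.choice(case_pos, size=n_forced, replace=False)
    batches[forced] = 0

    g = config.g_total
    y = params.mu[:, None] + np.zeros((g, n))
    # planted disease signal
    sig_rows = params.signal_idx
    y[sig_rows, :] += (
        config.effect_size * params.directions[:, None] * signal[None, :]
    )
    # age and sex structure (never on background probes)
    if len(params.age_idx):
        centred = (ages - ages.mean()) / 10.0
        y[params.age_idx, :] += params.age_slopes[:, None] * centred[None, :]
    if len(params.sex_idx):
        male = (sexes == "M").astype(float)
        y[params.sex_idx, :] += params.sex_effects[:, None] * male[None, :]
    # batch shifts hit every gene, background included
    if config.batch_sd > 0:
        b = rng.normal(0.0, config.batch_sd, size=(config.n_batches, g))
        y += b[batches, :].T
    # measurement noise: expressed vs floor-level probes
    noise_scale = np.full(g, config.noise_sd)
    noise_scale[params.background_idx] = config.sd_background
    y += noise_scale[:, None] * rng.standard_normal((g, n))

    rows = _platform_rows(spec, config, rng)
    values = pd.DataFrame(
        y[rows, :], index=params.gene_ids[rows], columns=sample_ids
    )
    cohort = ExpressionCohort(spec.cohort_id, values, spec.platform_id)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort_id": spec.cohort_id,
            "age": np.round(ages, 1),
            "sex": sexes,
            "diagnosis": diagnosis,
            "batch": [f"{spec.cohort_id}_batch{k}" for k in batches],
        }
    ).set_index("sample_id", drop=False)
    return cohort, meta


def planted_signature(config: SimConfig, name: str = "planted") -> DirectionalSignature:
    """Ground-truth signature: the signal genes with their true directions."""
    if config.n_signal < 1:
        raise ValueError("config has no planted signal genes")
    rng = _seed_streams(config)[0]
    params = _gene_params(config, rng)
    return DirectionalSignature(
        name,
        tuple(params.gene_ids[params.signal_idx]),
        tuple(int(d) for d in params.directions),
    )


def age_gene_signature(config: SimConfig, name: str = "age_genes") -> DirectionalSignature:
    """The planted age-effect genes, directed by the sign of their slope."""
    if config.n_age_genes < 1:
        raise ValueError("config has no age-effect genes")
    rng = _seed_streams(config)[0]
    params = _gene_params(config, rng)
    return DirectionalSignature(
        name,
        tuple(params.gene_ids[params.age_idx]),
        tuple(int(np.sign(s)) for s in params.age_slopes),
    )


def background_gene_ids(config: SimConfig) -> frozenset[str]:
    """Ids of the probes generated at the detection floor."""
    rng = _seed_streams(config)[0]
    params = _gene_params(config, rng)
    return frozenset(params.gene_ids[params.background_idx])


def write_fixture_bundle(config: SimConfig, out_dir) -> dict:
    """Write a complete on-disk bundle: expression TSV per cohort, one
    metadata TSV, the planted signature, an exclusion list of the planted
    genes (for filtered-pool runs), a GMT of planted + decoy sets, and a
    checksummed manifest.  Byte-identical across runs at a fixed seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = generate_cohorts(config)
    files: dict[str, Path] = {}
    metas = []
    for cohort, meta in data:
        p = out_dir / f"expression_{cohort.cohort_id}.tsv"
        write_expression_cohort(cohort, p)
        files[f"expression_{cohort.cohort_id}"] = p
        metas.append(meta)
    meta_path = out_dir / "metadata.tsv"
    write_sample_metadata(pd.concat(metas, axis=0), meta_path)
    files["metadata"] = meta_path

    sig = planted_signature(config)
    sig_path = out_dir / "signature.tsv"
    write_signature(sig, sig_path)
    files["signature"] = sig_path

    excl_path = out_dir / "exclusion.txt"
    excl_path.write_text(
        "# planted signal genes\n" + "\n".join(sig.genes) + "\n"
    )
    files["exclusion"] = excl_path

    decoy_rng = np.random.default_rng(np.random.SeedSequence(config.seed).generate_state(4)[-1])
    universe = [g for g in _gene_params(config, _seed_streams(config)[0]).gene_ids]
    decoys = [
        (f"decoy_{k}", decoy_rng.choice(universe, size=len(sig), replace=False))
        for k in range(3)
    ]
    gmt_path = out_dir / "gene_sets.gmt"
    write_gmt([("planted", sig.genes), *decoys], gmt_path)
    files["gene_sets"] = gmt_path

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "files": {
            key: {"path": p.name, "sha256": _sha256(p)} for key, p in files.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["cohorts"] = [asdict(c) for c in config.cohorts]
    return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
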