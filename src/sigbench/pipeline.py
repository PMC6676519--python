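"""End-to-end benchmark runs driven by a single config file.

A run evaluates one candidate directional signature against empirical
nulls of random gene-sets, cell by cell: each *arm* of the config names a
validation scheme (within-cohort splits or cross-cohort external
validation), a case definition (AD vs CTL, or AD+MCI merged vs CTL),
whether age/sex matching is applied, and the sampling pool (whole
platform, background probes, or an exclusion-filtered universe).  The
report carries, per cell, the candidate's AUCs, the null summary, and
empirical/parametric significance, plus a rigor checklist (external
validation performed, replication across cohorts, matched design, MCI
excluded, multiple testing corrected) recomputed from the cells alone.

One master seed is fanned out deterministically to every stage, so a
single integer reproduces a whole run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .io import DirectionalSignature, ExpressionCohort, GenePool
from .null_sampling import (
    NullDistribution,
    SamplingConfig,
    evaluate_null,
    intersect_pools,
    null_summary,
    sample_gene_sets,
)
from .scoring import directional_score, fit_directions
from .significance import (
    SignificanceResult,
    auc_parametric_p,
    bh_adjust,
    replication_verdict,
    summarize_candidate,
)
from .simulate import SimConfig, CohortSpec, generate_cohorts, planted_signature
from .validation import (
    SchemeConfig,
    ValidationResult,
    cross_cohort_validate,
    match_cases_controls,
    matched_labels,
    select_diagnosis_groups,
    within_cohort_cv,
)

logger = logging.getLogger(__name__)

CHECKLIST_KEYS = (
    "external_validation_done",
    "significant_in_all_test_cohorts",
    "matched_design_used",
    "mci_excluded",
    "multiple_testing_corrected",
)


@dataclass
class CellResult:
    """One (scheme, case definition, matched?, pool) cell of the benchmark."""

    name: str
    scheme: SchemeConfig
    case_definition: str
    matched: bool
    pool_name: str
    candidate: ValidationResult
    null: NullDistribution
    null_stats: dict
    significance: SignificanceResult
    involved_cohorts: tuple = ()
    per_test_cohort_p: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "name": self.name,
            "scheme": asdict(self.scheme),
            "case_definition": self.case_definition,
            "matched": self.matched,
            "pool": self.pool_name,
            "involved_cohorts": list(self.involved_cohorts),
            "candidate_mean_auc": self.candidate.mean_auc,
            "candidate_per_unit": [
                {"unit_id": u, "auc": r.auc, "n_cases": r.n_cases,
                 "n_controls": r.n_controls}
                for u, r in self.candidate.per_unit_auc
            ],
            "null": self.null_stats,
            "n_null_failed": self.null.n_failed,
            "significance": asdict(self.significance),
            "per_test_cohort_p": self.per_test_cohort_p,
        }


@dataclass
class BenchmarkReport:
    run_id: str
    config: dict
    cells: dict
    checklist: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "config": self.config,
            "cells": {name: c.summary_dict() for name, c in self.cells.items()},
            "checklist": self.checklist,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# config handling
# ---------------------------------------------------------------------------

def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, Mapping):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def sim_config_from_dict(d: Mapping, seed: int | None = None) -> SimConfig:
    d = dict(d)
    cohorts = tuple(CohortSpec(**c) for c in d.pop("cohorts", []))
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    if seed is not None:
        d["seed"] = seed
    if cohorts:
        return SimConfig(cohorts=cohorts, **d)
    return SimConfig(**d)


def _fan_out_seeds(master: int, arm_names: list[str]) -> dict:
    """Named per-stage seeds derived from one master seed."""
    n = 1 + 3 * len(arm_names)
    state = np.random.SeedSequence(master).generate_state(n) % (2**31)
    seeds = {"sim": int(state[0])}
    for i, name in enumerate(arm_names):
        seeds[f"{name}/scheme"] = int(state[1 + 3 * i])
        seeds[f"{name}/sampling"] = int(state[2 + 3 * i])
        seeds[f"{name}/matching"] = int(state[3 + 3 * i])
    return seeds


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _load_inputs(config: dict, sim_seed: int):
    """Load cohorts+metadata+signature from files, or generate from the sim
    block; returns (cohorts dict, metadata, candidate signature)."""
    if "sim" in config:
        sim = sim_config_from_dict(config["sim"], seed=sim_seed)
        data = generate_cohorts(sim)
        cohorts = {c.cohort_id: c for c, _ in data}
        metadata = pd.concat([m for _, m in data], axis=0)
        if "signature" in config.get("inputs", {}):
            candidate = sio.read_signature(config["inputs"]["signature"])
        else:
            candidate = planted_signature(sim)
        return cohorts, metadata, candidate, sim
    inputs = config.get("inputs")
    if not inputs or "signature" not in inputs:
        raise ValueError("load stage: config needs a 'sim' block or inputs with a signature")
    cohorts = {}
    for spec in inputs["cohorts"]:
        c = sio.read_expression_cohort(spec["path"], spec["cohort_id"], spec["platform_id"])
        cohorts[c.cohort_id] = c
    metadata = sio.read_sample_metadata(inputs["metadata"])
    candidate = sio.read_signature(inputs["signature"])
    return cohorts, metadata, candidate, None


def _pool_for(
    cohort: ExpressionCohort,
    kind: str,
    config: dict,
    sim: SimConfig | None,
    candidate: DirectionalSignature,
) -> GenePool:
    if kind == "all":
        return sio.all_genes_pool(cohort)
    if kind == "background":
        bg = config.get("background", {})
        return sio.background_pool(
            cohort,
            floor_quantile=bg.get("floor_quantile", 0.25),
            sample_fraction=bg.get("sample_fraction", 0.8),
        )
    if kind == "filtered":
        excl_path = config.get("inputs", {}).get("exclusion")
        if excl_path:
            exclusion = sio.read_exclusion_list(excl_path)
        else:
            # default exclusion: the candidate's own genes (the analogue of
            # removing already-published signature genes from the pool)
            exclusion = candidate.gene_set
        return sio.filtered_pool(cohort.gene_universe, exclusion, cohort.platform_id)
    raise ValueError(f"unknown pool kind {kind!r}")


def _arm_scheme(arm: dict, seed: int) -> tuple[SchemeConfig, str | None]:
    """Build the SchemeConfig; a within arm may name its cohort via the
    scheme's ``cohort_id`` key (defaults to the run's sole cohort)."""
    s = dict(arm["scheme"])
    within_cohort = s.pop("cohort_id", None)
    s.setdefault("seed", seed)
    if "test_cohort_ids" in s:
        s["test_cohort_ids"] = tuple(s["test_cohort_ids"])
    return SchemeConfig(**s), within_cohort


def _labels_for_arm(
    metadata: pd.DataFrame,
    cohort_ids: list[str],
    case_definition: str,
    matched: bool,
    age_tolerance: float,
    match_seed: int,
) -> dict:
    labels = {}
    for cid in cohort_ids:
        meta = metadata[metadata["cohort_id"] == cid]
        lab = select_diagnosis_groups(meta, case_definition)
        if matched:
            pairs = match_cases_controls(meta, lab, age_tolerance, seed=match_seed)
            lab = matched_labels(pairs)
        labels[cid] = lab
    return labels


def _run_arm(
    arm: dict,
    cohorts: dict,
    metadata: pd.DataFrame,
    candidate: DirectionalSignature,
    config: dict,
    sim: SimConfig | None,
    seeds: dict,
) -> CellResult:
    name = arm["name"]
    scheme, within_cohort = _arm_scheme(arm, seeds[f"{name}/scheme"])
    case_definition = arm.get("case_definition", "AD_vs_CTL")
    matched = bool(arm.get("matched", False))
    pool_kind = arm.get("pool", "all")
    age_tol = config.get("matching", {}).get("age_tolerance", 5.0)

    if scheme.mode == "within":
        involved = [within_cohort if within_cohort else next(iter(cohorts))]
    else:
        involved = [scheme.train_cohort_id, *scheme.test_cohort_ids]
    labels = _labels_for_arm(
        metadata, involved, case_definition, matched, age_tol, seeds[f"{name}/matching"]
    )

    pools = [_pool_for(cohorts[cid], pool_kind, config, sim, candidate) for cid in involved]
    pool = pools[0] if len(pools) == 1 else intersect_pools(pools, name=f"{pool_kind}_paired")

    set_size = arm.get("set_size") or len(candidate)
    n_sets = arm.get("n_null_sets", 200)
    sampling = SamplingConfig(
        pool=pool, n_sets=n_sets, set_size=min(set_size, len(pool)),
        seed=seeds[f"{name}/sampling"],
    )
    sets = sample_gene_sets(sampling)

    per_test_p: dict[str, float] = {}
    if scheme.mode == "within":
        cid = involved[0]
        cand_genes = sorted(candidate.gene_set & cohorts[cid].gene_universe)
        cand_res = within_cohort_cv(
            cohorts[cid], labels[cid], cand_genes, scheme, gene_set_name=candidate.name
        )
        null = evaluate_null(sets, cohorts[cid], labels[cid], scheme, config=sampling)
    else:
        cand_res = cross_cohort_validate(
            cohorts, labels, candidate.gene_set, scheme, gene_set_name=candidate.name
        )
        null = evaluate_null(sets, cohorts, labels, scheme, config=sampling)
        # per-test-cohort parametric significance of the candidate's scores
        train = cohorts[scheme.train_cohort_id]
        train_genes = sorted(candidate.gene_set & train.gene_universe)
        fitted = fit_directions(
            train, labels[scheme.train_cohort_id], train_genes, name=candidate.name
        )
        for cid in scheme.test_cohort_ids:
            lab = labels[cid]
            scores = directional_score(cohorts[cid], fitted).to_series().loc[lab.index]
            per_test_p[cid] = auc_parametric_p(scores, lab)

    stats = null_summary(null)
    sig = summarize_candidate(cand_res.mean_auc, null)
    return CellResult(
        name=name,
        scheme=scheme,
        case_definition=case_definition,
        matched=matched,
        pool_name=f"{pool_kind}:{pool.name}",
        candidate=cand_res,
        null=null,
        null_stats=stats,
        significance=sig,
        involved_cohorts=tuple(involved),
        per_test_cohort_p=per_test_p,
    )


def compute_checklist(cells: Mapping[str, CellResult], alpha: float) -> dict:
    """Rigor checklist, a pure function of the report's cells."""
    cross_cells = [c for c in cells.values() if c.scheme.mode == "cross"]
    cohort_p: dict[str, float] = {}
    for c in cross_cells:
        for cid, p in c.per_test_cohort_p.items():
            cohort_p[cid] = min(p, cohort_p.get(cid, 1.0))
    replicated = False
    if len(cohort_p) >= 2:
        replicated, _ = replication_verdict(cohort_p, alpha)
    return {
        "external_validation_done": bool(cross_cells),
        "significant_in_all_test_cohorts": replicated,
        "matched_design_used": any(c.matched for c in cells.values()),
        "mci_excluded": any(c.case_definition == "AD_vs_CTL" for c in cells.values()),
        "multiple_testing_corrected": any(
            c.significance.bh_adjusted_p is not None for c in cells.values()
        ),
    }


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def run_benchmark(config, out_dir=None, seed: int | None = None) -> BenchmarkReport:
    """Execute a full benchmark run from a config file or dict.

    Stages: load/generate cohorts -> diagnosis-group selection ->
    optional matching -> candidate evaluation per arm -> null sampling
    and evaluation per arm -> significance (empirical + BH across arms)
    -> checklist -> report.  Idempotent for a fixed config + seed.
    """
    t0 = time.time()
    config = load_config(config)
    run_id = config.get("run_id", "run")
    master = int(seed if seed is not None else config.get("seed", 0))
    arms = config.get("arms", [])
    if not arms:
        raise ValueError("config stage: no arms defined")
    arm_names = [a["name"] for a in arms]
    if len(set(arm_names)) != len(arm_names):
        raise ValueError("config stage: duplicate arm names")
    seeds = _fan_out_seeds(master, arm_names)
    alpha = config.get("alpha", 0.05)

    try:
        cohorts, metadata, candidate, sim = _load_inputs(config, seeds["sim"])
    except Exception as exc:
        raise RuntimeError(f"load stage failed: {exc}") from exc

    cells: dict[str, CellResult] = {}
    for arm in arms:
        t_arm = time.time()
        try:
            cell = _run_arm(arm, cohorts, metadata, candidate, config, sim, seeds)
        except Exception as exc:
            raise RuntimeError(f"arm {arm['name']!r} failed: {exc}") from exc
        cells[cell.name] = cell
        logger.info(
            "stage=arm name=%s wall=%.1fs n_null=%d n_failed=%d",
            cell.name, time.time() - t_arm, len(cell.null), cell.null.n_failed,
        )

    # BH across the family of cells' empirical p-values
    names = list(cells)
    adj = bh_adjust([cells[n].significance.empirical_p for n in names])
    for n, q in zip(names, adj):
        cells[n].significance.bh_adjusted_p = float(q)

    checklist = compute_checklist(cells, alpha)
    report = BenchmarkReport(
        run_id=run_id,
        config=config,
        cells=cells,
        checklist=checklist,
        provenance={
            "master_seed": master,
            "stage_seeds": seeds,
            "alpha": alpha,
            "package": "sigbench",
        },
    )
    if out_dir is not None:
        write_report(report, out_dir, wall_seconds=time.time() - t0)
    return report


def write_report(report: BenchmarkReport, out_dir, wall_seconds: float | None = None) -> None:
    """Persist the report: report.json + per-cell TSVs + checksum manifest.

    Data outputs contain no timestamps, so identical config + seed gives
    byte-identical files; wall-clock goes to run.log only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, cell in report.cells.items():
        p = out / f"cell_{name}_nulls.tsv"
        cell.null.to_frame().to_csv(p, sep="\t", index=False)
        files[p.name] = p
        p2 = out / f"cell_{name}_candidate.tsv"
        cell.candidate.to_frame().to_csv(p2, sep="\t", index=False)
        files[p2.name] = p2
    rp = out / "report.json"
    rp.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    files[rp.name] = rp
    manifest = {
        "run_id": report.run_id,
        "files": {
            name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in files.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    with open(out / "run.log", "a") as fh:
        fh.write(
            f"run_id={report.run_id} finished_at={time.strftime('%Y-%m-%dT%H:%M:%S')} "
            f"wall={wall_seconds if wall_seconds is not None else float('nan'):.1f}s\n"
        )


def load_report(report_dir) -> dict:
    """Load a persisted report directory back into a plain dict (with
    per-cell null AUC arrays re-attached)."""
    out = Path(report_dir)
    report = json.loads((out / "report.json").read_text())
    for name, cell in report["cells"].items():
        nulls = pd.read_csv(out / f"cell_{name}_nulls.tsv", sep="\t")
        cell["null_aucs"] = nulls["mean_auc"].to_numpy()
    return report


def compare_arms(report, arm_a: str, arm_b: str) -> pd.DataFrame:
    """Delta table between two arms: candidate AUC, null mean, and the
    candidate-minus-null-mean margin."""
    cells = report.cells if isinstance(report, BenchmarkReport) else None
    if cells is not None:
        if arm_a not in cells or arm_b not in cells:
            missing = arm_a if arm_a not in cells else arm_b
            raise KeyError(f"arm {missing!r} not in report")
        a, b = cells[arm_a], cells[arm_b]
        if not set(a.involved_cohorts) & set(b.involved_cohorts):
            raise ValueError(f"arms {arm_a!r} and {arm_b!r} share no cohorts")
        rows = {
            "candidate_auc": (a.candidate.mean_auc, b.candidate.mean_auc),
            "null_mean_auc": (a.null_stats["mean"], b.null_stats["mean"]),
            "margin": (
                a.candidate.mean_auc - a.null_stats["mean"],
                b.candidate.mean_auc - b.null_stats["mean"],
            ),
        }
    else:  # plain dict loaded from disk
        rc = report["cells"]
        if arm_a not in rc or arm_b not in rc:
            missing = arm_a if arm_a not in rc else arm_b
            raise KeyError(f"arm {missing!r} not in report")
        a, b = rc[arm_a], rc[arm_b]
        if not set(a["involved_cohorts"]) & set(b["involved_cohorts"]):
            raise ValueError(f"arms {arm_a!r} and {arm_b!r} share no cohorts")
        rows = {
            "candidate_auc": (a["candidate_mean_auc"], b["candidate_mean_auc"]),
            "null_mean_auc": (a["null"]["mean"], b["null"]["mean"]),
            "margin": (
                a["candidate_mean_auc"] - a["null"]["mean"],
                b["candidate_mean_auc"] - b["null"]["mean"],
            ),
        }
    return pd.DataFrame(
        {
            "metric": list(rows),
            arm_a: [v[0] for v in rows.values()],
            arm_b: [v[1] for v in rows.values()],
            "delta": [v[0] - v[1] for v in rows.values()],
        }
    )


def export_figure_table(report, cell: str) -> pd.DataFrame:
    """Plot-ready long table for one cell: every null AUC plus the flagged
    candidate row (the 'red dot')."""
    if isinstance(report, BenchmarkReport):
        if cell not in report.cells:
            raise KeyError(f"cell {cell!r} not in report")
        c = report.cells[cell]
        aucs = c.null.aucs
        cand = c.candidate.mean_auc
        cand_name = c.candidate.gene_set_name
    else:
        if cell not in report["cells"]:
            raise KeyError(f"cell {cell!r} not in report")
        c = report["cells"][cell]
        aucs = c["null_aucs"]
        cand = c["candidate_mean_auc"]
        cand_name = "candidate"
    rows = pd.DataFrame(
        {
            "set_id": [f"null_{i:05d}" for i in range(len(aucs))],
            "auc": aucs,
            "is_candidate": 0,
        }
    )
    cand_row = pd.DataFrame(
        {"set_id": [cand_name], "auc": [cand], "is_candidate": [1]}
    )
    return pd.concat([rows, cand_row], ignore_index=True)
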