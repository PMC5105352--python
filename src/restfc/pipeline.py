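"""End-to-end orchestration: simulate -> fc -> regress -> graph -> compare.

Every run writes its stage outputs into a fresh run directory (append-only)
together with a manifest of SHA-256 content hashes; the same config and
seed always reproduce identical manifests.  Stage failures abort the run
and leave a machine-readable error record.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, graph, groupstats, regression, synthetic
from .config import RunConfig
from .parcellation import ParcellationScheme

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


@dataclass
class RunResult:
    run_dir: Path
    manifest: dict


def _fresh_run_dir(base: Path, seed: int) -> Path:
    base.mkdir(parents=True, exist_ok=True)
    stamp = time.strftime("%Y%m%dT%H%M%S")
    for k in range(1000):
        candidate = base / f"run-{stamp}-seed{seed}-{k:03d}"
        if not candidate.exists():
            candidate.mkdir()
            return candidate
    raise RuntimeError("could not allocate a fresh run directory")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all five stages under one master seed; return dir + manifest."""
    run_dir = _fresh_run_dir(Path(config.out_dir), config.seed)
    manifest: dict[str, dict[str, str]] = {}
    stage = "setup"
    t0 = time.time()
    try:
        # ---- simulate -----------------------------------------------------
        stage = "simulate"
        ts_list = None
        scheme = (
            ParcellationScheme.from_csv(config.scheme_path)
            if config.scheme_path
            else ParcellationScheme.synthetic(config.n_regions)
        )
        if config.table_path:
            table = connectivity.GroupFCTable.from_csv(config.table_path)
            cohort = pd.read_csv(config.cohort_path)
        elif config.cohort_path:
            cohort = pd.read_csv(config.cohort_path)
            raise ValueError("external cohort without table_path requires time-series input")
        else:
            spec = synthetic.CohortSpec(
                n_male=config.n_male,
                n_female=config.n_female,
                age_low=config.age_low,
                age_high=config.age_high,
                n_regions=config.n_regions,
                n_timepoints=config.n_timepoints,
                seed=config.seed,
            )
            bundle = synthetic.simulate_cohort(
                spec,
                n_sex_edges=config.n_sex_edges,
                n_age_edges=config.n_age_edges,
                n_int_edges=config.n_int_edges,
                b_sex=config.b_sex,
                b_age=config.b_age,
                b_int=config.b_int,
                noise_sd=config.noise_sd,
                covariates=synthetic.default_covariates(),
                mode=config.mode,
            )
            cohort = bundle.cohort
            table = bundle.table
            ts_list = bundle.timeseries
            cohort.to_csv(run_dir / "cohort.csv", index=False)
            if bundle.effects is not None:
                bundle.effects.to_csv(run_dir / "effect_map.csv", config.n_regions)
        files = [p for p in run_dir.iterdir() if p.is_file()]
        manifest[stage] = {p.name: _sha256(p) for p in files}
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed, time.time() - t0)

        # ---- fc -----------------------------------------------------------
        stage = "fc"
        t0 = time.time()
        if ts_list is not None:
            fcs = [connectivity.compute_fc(ts.values, ts.subject_id) for ts in ts_list]
            table = connectivity.build_group_table(fcs)
        table.to_csv(run_dir / "group_fc.csv", run_dir / "edge_index.csv")
        manifest[stage] = {
            name: _sha256(run_dir / name) for name in ("group_fc.csv", "edge_index.csv")
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed, time.time() - t0)

        # ---- regress ------------------------------------------------------
        stage = "regress"
        t0 = time.time()
        report = regression.run_mass_univariate(
            table,
            cohort,
            alpha=config.alpha,
            correction=config.correction,
            alpha_remove=config.alpha_remove,
            center_age=config.center_age,
        )
        report.to_csv(run_dir / "regression_results.csv")
        _write_json(run_dir / "regression_summary.json", report.summary)
        manifest[stage] = {
            name: _sha256(run_dir / name)
            for name in ("regression_results.csv", "regression_summary.json")
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed, time.time() - t0)

        # ---- graph --------------------------------------------------------
        stage = "graph"
        t0 = time.time()
        matrices = {
            sid: table.subject_matrix(k) for k, sid in enumerate(table.subject_ids)
        }
        metrics = graph.run_density_grid(
            matrices,
            grid=config.grid(),
            spec=graph.NullEnsembleSpec(
                n_nulls=config.n_nulls, swaps_per_edge=config.swaps_per_edge
            ),
            seed=config.seed,
            use_abs=config.abs_threshold,
        )
        metrics.to_csv(run_dir / "graph_metrics.csv")
        manifest[stage] = {"graph_metrics.csv": _sha256(run_dir / "graph_metrics.csv")}
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed, time.time() - t0)

        # ---- compare ------------------------------------------------------
        stage = "compare"
        t0 = time.time()
        tables = []
        stacks = []
        for metric in groupstats.NODAL_METRICS:
            cmp_tables = groupstats.nodal_metric_comparison(
                metrics.nodal, cohort, metric, alpha=config.alpha, variant=config.t_variant
            )
            tables.append(cmp_tables.cells)
            stacks.append(cmp_tables.stacks)
        pd.concat(tables, ignore_index=True).to_csv(
            run_dir / "nodal_comparisons.csv", index=False
        )
        pd.concat(stacks, ignore_index=True).to_csv(
            run_dir / "nodal_stacks.csv", index=False
        )
        glob = pd.concat(
            [
                groupstats.global_metric_comparison(
                    metrics.global_, cohort, m, alpha=config.alpha, variant=config.t_variant
                )
                for m in groupstats.GLOBAL_METRICS
            ],
            ignore_index=True,
        )
        glob.to_csv(run_dir / "global_comparisons.csv", index=False)
        adjusted = pd.concat(
            [
                groupstats.metric_regression(metrics.global_, cohort, m)
                for m in groupstats.GLOBAL_METRICS
            ],
            ignore_index=True,
        )
        adjusted.to_csv(run_dir / "global_sex_age_regression.csv", index=False)
        summary = {
            "motion": groupstats.motion_checks(cohort, variant=config.t_variant),
            "n_significant_global_cells": int(glob["significant"].sum()),
        }
        _write_json(run_dir / "compare_summary.json", summary)
        manifest[stage] = {
            name: _sha256(run_dir / name)
            for name in (
                "nodal_comparisons.csv",
                "nodal_stacks.csv",
                "global_comparisons.csv",
                "global_sex_age_regression.csv",
                "compare_summary.json",
            )
        }
        logger.info("stage=%s seed=%d elapsed=%.2fs", stage, config.seed, time.time() - t0)
    except Exception as exc:
        _write_json(
            run_dir / "error.json",
            {"stage": stage, "error": type(exc).__name__, "message": str(exc)},
        )
        raise
    _write_json(run_dir / "manifest.json", manifest)
    return RunResult(run_dir=run_dir, manifest=manifest)
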