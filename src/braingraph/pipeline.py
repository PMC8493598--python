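"""Stage orchestration: cohort files in, statistics tables out.

Each stage reads the standard text formats written by the previous one, so
stages can be run separately or end-to-end. Every output directory gets a
``run_info.json`` sidecar with the config hash and seed provenance; result
tables are deterministic given (inputs, config, seed) and independent of
subject processing order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as gm
from . import network as net
from .config import PipelineConfig
from .errors import InputError
from .nulls import NullEnsembleSpec
from .preprocess import preprocess_subject
from .stats import full_inference
from .synthetic import simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


def _write_run_info(outdir: Path, config: PipelineConfig, stage: str, extra=None):
    info = {
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        info.update(extra)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"run_info_{stage}.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)


def _load_manifest(input_dir: Path) -> dict:
    path = input_dir / "manifest.json"
    if not path.exists():
        raise InputError(f"no manifest.json in {input_dir}")
    with open(path) as fh:
        return json.load(fh)


def run_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic cohort into ``config.input_dir``."""
    spec = config.cohort.to_spec(config.seed)
    cohort = simulate_cohort(spec)
    manifest = write_cohort(cohort, config.input_dir)
    _write_run_info(Path(config.input_dir), config, "simulate",
                    {"n_subjects": len(cohort.subjects)})
    logger.info("simulated %d subjects into %s", len(cohort.subjects),
                config.input_dir)
    return manifest


def run_prep(config: PipelineConfig) -> pd.DataFrame:
    """Clean every subject; returns the QC table (also written to disk).

    A subject whose files are missing or who fails preprocessing is excluded
    with a logged reason; the pipeline continues.
    """
    input_dir = Path(config.input_dir)
    outdir = Path(config.output_dir) / "prep"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(input_dir)
    p = config.preprocess
    qc_rows = []
    for sid in sorted(manifest["subjects"]):
        entry = manifest["subjects"][sid]
        try:
            ts = pd.read_csv(input_dir / entry["timeseries"], sep="\t")
            motion = np.loadtxt(input_dir / entry["motion"])
            nuis = pd.read_csv(input_dir / entry["nuisance"], sep="\t")
        except (OSError, ValueError) as exc:
            logger.warning("subject %s excluded: cannot read inputs (%s)", sid, exc)
            qc_rows.append({"subject_id": sid, "group": entry["group"],
                            "mean_fd": np.nan, "n_flagged": -1,
                            "excluded": True, "reason": f"unreadable input: {exc}"})
            continue
        res = preprocess_subject(
            ts.to_numpy(), motion,
            nuis["wm"].to_numpy(), nuis["csf"].to_numpy(),
            n_discard=p.n_discard, fd_threshold_mm=p.fd_threshold_mm,
            n_before=p.n_before, n_after=p.n_after,
            low_hz=p.low_hz, high_hz=p.high_hz, tr_s=p.tr_s,
            min_dof=p.min_dof,
        )
        if res.excluded:
            logger.warning("subject %s excluded: %s", sid,
                           "; ".join(res.exclusion_reasons))
        else:
            pd.DataFrame(res.timeseries, columns=ts.columns).to_csv(
                outdir / f"{sid}_clean.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
        fd_tab = pd.DataFrame({
            "volume": np.arange(res.fd.size),
            "FD": res.fd,
            "flagged": res.mask.astype(int),
        })
        fd_tab.to_csv(outdir / f"{sid}_fd.tsv", sep="\t", index=False,
                      float_format="%.6f")
        with open(outdir / f"{sid}_qc.json", "w") as fh:
            json.dump(res.qc_dict(), fh, indent=2)
        qc_rows.append({"subject_id": sid, "group": entry["group"],
                        "mean_fd": res.mean_fd, "n_flagged": res.n_flagged,
                        "excluded": res.excluded,
                        "reason": "; ".join(res.exclusion_reasons)})
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(outdir / "qc_summary.csv", index=False)
    _write_run_info(outdir, config, "prep",
                    {"n_excluded": int(qc["excluded"].sum())})
    return qc


def run_network(config: PipelineConfig) -> dict:
    """Correlation -> Fisher Z -> sparsity stack for every retained subject."""
    prep_dir = Path(config.output_dir) / "prep"
    outdir = Path(config.output_dir) / "network"
    outdir.mkdir(parents=True, exist_ok=True)
    qc = pd.read_csv(prep_dir / "qc_summary.csv")
    grid = config.network.grid()
    stacks = {}
    for sid in sorted(qc.loc[~qc["excluded"], "subject_id"]):
        ts = pd.read_csv(prep_dir / f"{sid}_clean.tsv", sep="\t")
        corr = net.correlation_matrix(ts.to_numpy(), labels=list(ts.columns))
        z = net.fisher_z(corr)
        pd.DataFrame(z, columns=ts.columns).to_csv(
            outdir / f"{sid}_zmatrix.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        stack = net.build_stack(z, grid, mode=config.network.threshold_mode)
        edges_dir = outdir / f"{sid}_edges"
        edges_dir.mkdir(exist_ok=True)
        for i, s in enumerate(stack.grid):
            np.savetxt(edges_dir / f"edges_s{s:.2f}.txt",
                       stack.edge_list(i), fmt="%d")
        stacks[sid] = stack
    with open(outdir / "stack_manifest.json", "w") as fh:
        json.dump({
            "grid": [float(s) for s in grid],
            "threshold_mode": config.network.threshold_mode,
            "subjects": sorted(stacks),
        }, fh, indent=2)
    _write_run_info(outdir, config, "network")
    return stacks


def _load_stacks(config: PipelineConfig) -> dict:
    netdir = Path(config.output_dir) / "network"
    with open(netdir / "stack_manifest.json") as fh:
        man = json.load(fh)
    grid = np.array(man["grid"])
    mode = man["threshold_mode"]
    stacks = {}
    for sid in man["subjects"]:
        z = pd.read_csv(netdir / f"{sid}_zmatrix.tsv", sep="\t").to_numpy()
        stacks[sid] = net.build_stack(z, grid, mode=mode)
    return stacks


def run_metrics(config: PipelineConfig, stacks: dict | None = None,
                include_nodal: bool = True) -> pd.DataFrame:
    """Global (+ small-world) and nodal metrics per subject; AUC table out.

    Null-ensemble seeds fan out from the master seed per subject, so results
    do not depend on the order subjects are processed.
    """
    outdir = Path(config.output_dir) / "metrics"
    outdir.mkdir(parents=True, exist_ok=True)
    if stacks is None:
        stacks = _load_stacks(config)
    null_spec = NullEnsembleSpec(
        n_null=config.nulls.n_null,
        swaps_per_edge=config.nulls.swaps_per_edge,
    )
    root = np.random.SeedSequence(config.seed)
    auc_rows = []
    for sid in sorted(stacks):
        stack = stacks[sid]
        # per-subject deterministic stream, independent of processing order
        sid_key = int.from_bytes(
            hashlib.sha256(sid.encode()).digest()[:4], "big"
        )
        child = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(sid_key,)
        )
        rng = np.random.default_rng(child)
        gdf = gm.global_metrics_for_stack(stack, null_spec=null_spec, rng=rng)
        gdf.to_csv(outdir / f"{sid}_global.tsv", sep="\t", index=False,
                   float_format="%.6f")
        ndf = None
        if include_nodal:
            ndf = gm.nodal_metrics_for_stack(stack)
            ndf.to_csv(outdir / f"{sid}_nodal.tsv", sep="\t", index=False,
                       float_format="%.6f")
        auc_rows.append({"subject_id": sid, **gm.auc_summary(gdf, ndf)})
    auc_table = pd.DataFrame(auc_rows)
    auc_table.to_csv(outdir / "auc_table.tsv", sep="\t", index=False,
                     float_format="%.6f")
    _write_run_info(outdir, config, "metrics")
    return auc_table


def run_stats(config: PipelineConfig, auc_table: pd.DataFrame | None = None):
    """Merge AUCs with covariates and run the full inference chain."""
    outdir = Path(config.output_dir) / "stats"
    outdir.mkdir(parents=True, exist_ok=True)
    if auc_table is None:
        auc_table = pd.read_csv(
            Path(config.output_dir) / "metrics" / "auc_table.tsv", sep="\t"
        )
    cov = pd.read_csv(Path(config.input_dir) / "covariates.csv")
    qc = pd.read_csv(Path(config.output_dir) / "prep" / "qc_summary.csv")
    table = (auc_table
             .merge(cov, on="subject_id")
             .merge(qc[["subject_id", "mean_fd"]], on="subject_id"))
    clinical = [c for c in config.stats.clinical if c in table.columns]
    metric_cols = [c for c in auc_table.columns if c != "subject_id"]
    results, corr = full_inference(
        table,
        clinical_cols=clinical,
        patient_groups=(list(config.stats.patient_groups)
                        if config.stats.patient_groups else None),
        q=config.stats.q,
        metric_cols=metric_cols,
        covariate_cols=config.stats.covariates,
    )
    results.omnibus.to_csv(outdir / "omnibus.tsv", sep="\t", index=False)
    results.posthoc.to_csv(outdir / "posthoc.tsv", sep="\t", index=False)
    corr.to_csv(outdir / "partial_correlations.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump({
            "significant_metrics": results.significant_metrics,
            "n_subjects": int(len(table)),
            "q": config.stats.q,
        }, fh, indent=2)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    _write_run_info(outdir, config, "stats")
    return results, corr


def run_all(config: PipelineConfig, include_nodal: bool = True):
    """simulate (if needed) -> prep -> network -> metrics -> stats."""
    config.validate()
    if not (Path(config.input_dir) / "manifest.json").exists():
        run_simulate(config)
    run_prep(config)
    stacks = run_network(config)
    auc_table = run_metrics(config, stacks, include_nodal=include_nodal)
    return run_stats(config, auc_table)
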