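"""End-to-end orchestration: simulate/read -> qc -> dmp -> dmr -> classify.

Each stage writes its tables under ``config.out_dir`` and is deterministic
given the config's seed; the run manifest records the config hash and
sha256 checksums of every written file.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (SMALL_GRID, build_triplets, finalize_and_validate,
                         iterations_to_frame, run_iterations)
from .dataset import MethylationDataset
from .dmp import call_dmps, consistency_scan, feature_enrichment, fit_dmp_model, make_subsets
from .dmr import cluster_probes, dmr_consistency_scan, dmrs_to_bed, find_bumps, permute_null
from .io import PipelineConfig, RunManifest, read_dataset, write_dataset
from .preprocessing import adjust_batch, filter_probes, pca_covariate_scan
from .synthetic import dose_response_scenario, null_scenario, simulate_dataset

log = logging.getLogger(__name__)


def _prefix_samples(ds: MethylationDataset, prefix: str) -> MethylationDataset:
    """Rename sample ids (e.g. to keep a validation cohort disjoint)."""
    mapper = {s: f"{prefix}{s}" for s in ds.beta.columns}
    samples = ds.samples.rename(index=mapper)
    samples["sample_id"] = samples.index
    return MethylationDataset(
        beta=ds.beta.rename(columns=mapper),
        manifest=ds.manifest,
        samples=samples,
        detection_p=None if ds.detection_p is None else ds.detection_p.rename(columns=mapper),
        bead_counts=None if ds.bead_counts is None else ds.bead_counts.rename(columns=mapper),
        meta=dict(ds.meta),
    )


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, **kwargs) -> None:
    df.to_csv(path, **kwargs)
    manifest.add_file(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(),
                           config_hash=config.config_hash(),
                           seed=config.seed, version=__version__)

    # ---- inputs ----------------------------------------------------------
    ds_val: Optional[MethylationDataset] = None
    if config.beta_path is not None:
        ds = read_dataset(config.beta_path, config.manifest_path,
                          config.samples_path)
    else:
        if config.spiked:
            cfg = dose_response_scenario(
                n_probes=config.n_probes, n_samples=config.n_samples,
                max_effect=config.max_effect, seed=config.seed)
            cfg_val = dose_response_scenario(
                n_probes=config.n_probes, n_samples=config.n_validation_samples,
                max_effect=config.max_effect, seed=config.seed + 10_000)
        else:
            cfg = null_scenario(n_probes=config.n_probes,
                                n_samples=config.n_samples, seed=config.seed)
            cfg_val = null_scenario(n_probes=config.n_probes,
                                    n_samples=config.n_validation_samples,
                                    seed=config.seed + 10_000)
        ds, truth = simulate_dataset(cfg)
        ds_val, _ = simulate_dataset(cfg_val)
        ds_val = _prefix_samples(ds_val, "v_")
        for p in write_dataset(ds, out, prefix="input_").values():
            manifest.add_file(p)
        _write(truth.to_frame(), out / "ground_truth.csv", manifest, index=False)

    # ---- qc --------------------------------------------------------------
    if config.run_qc:
        ds, report = filter_probes(ds, detection_p_max=config.detection_p_max,
                                   min_beads=config.min_beads,
                                   max_fail_fraction=config.max_fail_fraction)
        _write(report.to_frame(), out / "filter_report.csv", manifest, index=False)
        if config.adjust_batch_method == "standardize" \
                and ds.samples["batch"].nunique() > 1:
            ds = adjust_batch(ds)
        assoc, varexp = pca_covariate_scan(
            ds, covariates=[c for c in config.covariates
                            if c in ds.samples.columns],
            n_components=min(10, ds.n_samples - 1))
        _write(assoc, out / "pca_covariate_pvalues.csv", manifest)
        _write(varexp.to_frame(), out / "pca_variance_explained.csv", manifest)
        if ds_val is not None:
            ds_val, _ = filter_probes(ds_val,
                                      detection_p_max=config.detection_p_max,
                                      min_beads=config.min_beads,
                                      max_fail_fraction=config.max_fail_fraction)

    # ---- subsets + dmp ---------------------------------------------------
    subsets = make_subsets(ds.samples, steps=config.steps)
    called = {}
    if config.run_dmp or config.run_dmr or config.run_classify:
        fits_by_subset = {}
        for sub in subsets:
            fits = fit_dmp_model(ds, sub.low_ids, sub.high_ids,
                                 covariates=config.covariates)
            fits_by_subset[sub.label] = fits
            called[sub.label] = call_dmps(fits, p_max=config.p_max,
                                          lfc_min=config.lfc_min)
    if config.run_dmp:
        for label, tab in called.items():
            _write(tab.round(6), out / f"dmp_{label.rstrip('%')}.csv", manifest)
        cons = consistency_scan(called, subsets)
        _write(cons.round(6), out / "dmp_consistency.csv", manifest)
        full = called[subsets[0].label]
        dmp_ids = full.index[full["dmp"]]
        if len(dmp_ids):
            enr = feature_enrichment(dmp_ids, ds.manifest)
            _write(enr.round(6), out / "dmp_feature_enrichment.csv", manifest)

    # ---- dmr -------------------------------------------------------------
    if config.run_dmr:
        clusters = cluster_probes(ds.manifest, max_gap_bp=config.max_gap_bp)
        dmr_tables = {}
        for sub in subsets:
            coefs = called[sub.label]["coef"]
            bumps = find_bumps(coefs, ds.manifest, clusters=clusters,
                               smooth_window=config.smooth_window,
                               cutoff_quantile=config.cutoff_quantile)
            dmr_tables[sub.label] = bumps
            _write(bumps.round(6), out / f"dmr_{sub.label.rstrip('%')}.csv",
                   manifest, index=False)
            _write(dmrs_to_bed(bumps), out / f"dmr_{sub.label.rstrip('%')}.bed",
                   manifest, sep="\t", index=False, header=False)
        full = subsets[0]
        with_p, _null = permute_null(
            ds, full.low_ids, full.high_ids, covariates=config.covariates,
            n_perm=config.n_perm, seed=config.seed, clusters=clusters,
            observed=dmr_tables[full.label],
            smooth_window=config.smooth_window,
            cutoff_quantile=config.cutoff_quantile)
        _write(with_p.round(6), out / "dmr_full_with_perm_p.csv", manifest,
               index=False)
        cons = dmr_consistency_scan(dmr_tables, [s.label for s in subsets])
        _write(cons.round(6), out / "dmr_consistency.csv", manifest)

    # ---- classifier ------------------------------------------------------
    if config.run_classify and ds_val is not None:
        ts = build_triplets(ds.samples, low_max=config.low_max,
                            high_min=config.high_min)
        if len(ts) >= 5:
            results, ranking = run_iterations(
                ds, ts, n_iter=config.n_iter, base_seed=config.seed,
                min_probes=config.min_probes, grid=SMALL_GRID,
                cutoff_quantile=config.cutoff_quantile,
                smooth_window=config.smooth_window)
            _write(iterations_to_frame(results).round(6),
                   out / "classifier_iterations.csv", manifest, index=False)
            _write(ranking, out / "cpg_ranking.csv", manifest, index=False)
            val_lows = ds_val.samples.index[
                ds_val.samples["cdrisc_score"] <= config.low_max]
            if len(ranking) and 0 < len(val_lows) < ds_val.n_samples:
                final = finalize_and_validate(
                    ranking, ds, ts, ds_val, list(val_lows),
                    n_top_grid=config.n_top_grid, grid=SMALL_GRID,
                    seed=config.seed)
                _write(final.selection_table.round(6),
                       out / "final_model_selection.csv", manifest, index=False)
                _write(final.roc.round(6), out / "validation_roc.csv",
                       manifest, index=False)
                summary = pd.DataFrame([{
                    "n_top": final.n_top,
                    "n_features": len(final.cpgs) + 1,
                    "threshold": round(final.tuned.threshold, 6),
                    "validation_auc": round(final.validation_auc, 6),
                    "validation_sensitivity": round(final.validation_sensitivity, 6),
                    "validation_specificity": round(final.validation_specificity, 6),
                }])
                _write(summary, out / "validation_summary.csv", manifest,
                       index=False)
        else:
            manifest.warnings.append("fewer than 5 triplets; classifier skipped")

    manifest.save(out / "run_manifest.json")
    return manifest
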