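"""End-to-end experiment pipeline: simulate -> detect -> features -> analysis.

Deterministic for a fixed seed; a JSON manifest records the config hash,
package versions, seed and per-stage row counts.  Any stage failure raises a
stage-named error while earlier outputs remain on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig, dump_config
from .detect import detect_and_measure
from .errors import ImpedancyteError
from .features import (
    build_features,
    fit_size_calibration,
    transparency_column,
)
from .population import (
    OutlierRule,
    compare_all_groups,
    detect_outliers,
    scatter_export,
    summarize_groups,
    transparency_vs_size_curve,
)
from .synth import sample_population, synthesize_trace
from .trace import write_trace

logger = logging.getLogger(__name__)


class StageError(ImpedancyteError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def config_hash(cfg: ExperimentConfig) -> str:
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


def run_pipeline(
    cfg: ExperimentConfig,
    seed: int | None = None,
    output_dir: str | Path | None = None,
    write_traces: bool = True,
) -> dict:
    """Run the full experiment described by ``cfg``.

    Returns a manifest dict (also written as ``manifest.json``).  Artifacts:
    per-group trace files (HDF5) and ground-truth CSVs, pooled events and
    rejection-log CSVs, the feature table, group summaries, the binned
    transparency-vs-size curve, outlier flags, pairwise group comparisons and
    the scatter export.
    """
    seed = cfg.seed if seed is None else seed
    outdir = Path(output_dir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    system = cfg.circuit.system()
    geometry = cfg.circuit.geometry()
    mapping = cfg.circuit.mapping()
    panel = cfg.panel.panel()
    acq = cfg.acquisition.acquisition()
    params = cfg.detection.params(acq.sampling_rate, acq.transit_time)

    manifest: dict = {
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": {},
    }
    root = np.random.SeedSequence(seed)
    pop_seeds = root.spawn(max(1, len(cfg.populations)))

    all_events = []
    all_truth = []
    stage = "simulate+detect"
    try:
        for pop_cfg, pop_seed in zip(cfg.populations, pop_seeds):
            spec = pop_cfg.spec()
            sample_seed, trace_seed = pop_seed.spawn(2)
            phenotypes, outlier_mask = sample_population(
                spec, sample_seed, return_outlier_mask=True
            )
            trace, truth = synthesize_trace(
                phenotypes, acq, system, panel, geometry, mapping,
                seed=trace_seed, outlier_mask=outlier_mask,
            )
            if write_traces:
                write_trace(trace, outdir / f"trace_{pop_cfg.group}.h5")
            truth.to_csv(outdir / f"ground_truth_{pop_cfg.group}.csv", index=False)
            if len(phenotypes) == 0:
                continue
            accepted, rejections, _ = detect_and_measure(trace, params)
            accepted = accepted.assign(group=pop_cfg.group)
            rejections = rejections.assign(group=pop_cfg.group)
            all_events.append((accepted, rejections))
            all_truth.append(truth.assign(group=pop_cfg.group))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    events = (
        pd.concat([a for a, _ in all_events], ignore_index=True)
        if all_events
        else pd.DataFrame()
    )
    rejections = (
        pd.concat([r for _, r in all_events], ignore_index=True)
        if all_events
        else pd.DataFrame(columns=["event_id", "reason", "group"])
    )
    truth_df = pd.concat(all_truth, ignore_index=True) if all_truth else pd.DataFrame()
    if not events.empty:
        events["event_id"] = np.arange(len(events))
    events.to_csv(outdir / "events.csv", index=False)
    rejections.to_csv(outdir / "rejections.csv", index=False)
    manifest["stages"]["detect"] = {
        "events_accepted": int(len(events)),
        "events_rejected": int(len(rejections)),
    }

    stage = "features"
    try:
        calibration = None
        if cfg.feature.calibrate_size and not events.empty and not truth_df.empty:
            calibration = _calibrate_from_truth(
                events, truth_df, panel, acq, cfg.feature.calibration_fraction
            )
        features = build_features(
            events,
            panel,
            calibration,
            tuple(cfg.feature.transparency_freqs_hz),
        )
        features.to_csv(outdir / "features.csv", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    manifest["stages"]["features"] = {
        "rows": int(len(features)),
        "k_cal": None if calibration is None else calibration.k_cal,
    }

    stage = "population_analysis"
    try:
        if not features.empty:
            summaries = summarize_groups(features)
            summaries.to_csv(outdir / "summaries.csv", index=False)
            t_col = transparency_column(cfg.analysis.transparency_freq_hz)
            curve = transparency_vs_size_curve(
                features, cfg.analysis.n_size_bins, transparency_col=t_col
            )
            curve.to_csv(outdir / "transparency_vs_size.csv", index=False)
            rule = OutlierRule(
                size_quantile=cfg.analysis.outlier_size_quantile,
                permeability_quantile=cfg.analysis.outlier_permeability_quantile,
            )
            if len(features) >= rule.min_events:
                outliers = detect_outliers(features, rule)
                outliers.to_csv(outdir / "outliers.csv", index=False)
            else:
                outliers = None
            feature_name = cfg.analysis.compare_feature or t_col
            if features["group"].nunique() > 1:
                comparisons = compare_all_groups(features, (feature_name,), seed=seed)
                comparisons.to_csv(outdir / "comparisons.csv", index=False)
            scatter = scatter_export(features, outliers=outliers)
            scatter.to_csv(outdir / "scatter.csv", index=False)
            manifest["stages"]["population_analysis"] = {
                "groups": int(features["group"].nunique()),
                "outliers_flagged": (
                    0 if outliers is None else int(outliers["is_outlier_flag"].sum())
                ),
            }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest["row_counts_conserved"] = bool(len(features) <= len(events) or events.empty)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %s", outdir)
    return manifest


def _calibrate_from_truth(events, truth_df, panel, acq, fraction):
    """Fit the cube-law size calibration on a leading fraction of events,
    pairing measured reference amplitudes with true (microscopy-style)
    diameters via event times."""
    ref = panel.reference_index
    tol = 2.0 * acq.transit_time
    pairs_a, pairs_d = [], []
    for group, sub in events.groupby("group"):
        tru = truth_df[truth_df["group"] == group]
        true_t = tru["time_s"].to_numpy()
        true_d = tru["diameter_um"].to_numpy()
        for t, a in zip(sub["center_time_s"], sub[f"amp_rel_{ref}"]):
            j = int(np.argmin(np.abs(true_t - t)))
            if abs(true_t[j] - t) <= tol:
                pairs_a.append(a)
                pairs_d.append(true_d[j])
    n_cal = max(1, int(fraction * len(pairs_a)))
    cal, _ = fit_size_calibration(np.array(pairs_a[:n_cal]), np.array(pairs_d[:n_cal]))
    return cal
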