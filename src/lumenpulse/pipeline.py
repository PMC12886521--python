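"""Top-level pipeline: simulate -> extract -> metrics -> stats.

The on-disk layout encodes the study hierarchy directly::

    <out>/raw/<group>/<mouse>/<pa>/<timepoint>/trial_<k>.tiff (+ .meta.txt)
    <out>/traces/...                            (per-trial diameter CSVs)
    <out>/metrics/metric_table.csv              (one row per PA-timepoint)
    <out>/stats/report.txt
    <out>/manifest.json

Given a fixed seed and configuration, every file's content is
deterministic (the manifest records timestamps, but no data file does).
Any stage failure aborts with an error naming the stage and offending
file.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, save_config
from .io import (
    read_trial_stack,
    write_metric_table,
    write_trace_csv,
    write_trial_stack,
    read_trace_csv,
)
from .metrics import metrics_from_trials
from .segmentation import extract_diameter_trace
from .stats import nested_compare, summarize_by_mouse
from .synthetic import VesselGroundTruth, generate_session

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and file."""


def session_template(config: PipelineConfig) -> VesselGroundTruth:
    """Vessel template centred in the configured frame at its pixel size."""
    h, w = config.frame_shape
    return replace(
        VesselGroundTruth(),
        center_rc=((h - 1) / 2.0, (w - 1) / 2.0),
        pixel_size_um=config.pixel_size_um,
    )


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    started: str
    finished: str = ""
    stages: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _record(manifest: RunManifest, stage: str, path: Path, out_dir: Path) -> None:
    manifest.stages.setdefault(stage, []).append(str(path.relative_to(out_dir)))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full synthetic-study pipeline into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    _record(manifest, "config", save_config(config, out_dir / "config.yaml"), out_dir)

    # --- simulate ------------------------------------------------------
    design = replace(config.design, seed=config.seed)
    template = session_template(config)
    try:
        trials, truth = generate_session(
            design,
            config.protocol,
            config.noise,
            render=True,
            shape=config.frame_shape,
            template=template,
        )
    except Exception as exc:  # pragma: no cover - constructor validation
        raise PipelineError(f"stage simulate failed: {exc}") from exc
    trial_paths: dict[tuple, list[Path]] = {}
    for (group, mouse, pa, tp), trial_list in trials.items():
        for k, trial in enumerate(trial_list):
            path = out_dir / "raw" / group / mouse / pa / tp / f"trial_{k:02d}.tiff"
            write_trial_stack(
                path,
                trial.stack,
                {
                    "stim_onset_s": config.protocol.stim_onset_s,
                    "stim_duration_s": config.protocol.stim_duration_s,
                    "trial_duration_s": config.protocol.trial_duration_s,
                },
            )
            trial_paths.setdefault((group, mouse, pa, tp), []).append(path)
            _record(manifest, "simulate", path, out_dir)
    truth_path = out_dir / "raw" / "ground_truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.6f")
    _record(manifest, "simulate", truth_path, out_dir)

    # --- extract -------------------------------------------------------
    trace_paths: dict[tuple, list[Path]] = {}
    for key, paths in trial_paths.items():
        for path in paths:
            try:
                stack = read_trial_stack(path)
                trace = extract_diameter_trace(stack, config.segmentation)
            except Exception as exc:
                raise PipelineError(f"stage extract failed on {path}: {exc}") from exc
            out_path = out_dir / "traces" / path.relative_to(out_dir / "raw").with_suffix(
                ".csv"
            )
            write_trace_csv(out_path, trace)
            trace_paths.setdefault(key, []).append(out_path)
            _record(manifest, "extract", out_path, out_dir)

    # --- metrics -------------------------------------------------------
    rows = []
    for (group, mouse, pa, tp), paths in trace_paths.items():
        traces = [
            read_trace_csv(p, config.protocol.frame_rate_hz, config.pixel_size_um)
            for p in paths
        ]
        try:
            m = metrics_from_trials(traces, config.protocol)
        except Exception as exc:
            raise PipelineError(f"stage metrics failed on {pa}/{tp}: {exc}") from exc
        rows.append(
            {
                "group": group,
                "mouse_id": mouse,
                "pa_id": pa,
                "timepoint": tp,
                "basal_diameter_um": m.basal_diameter_um,
                "amplitude_pct": m.amplitude_pct,
                "t_max_s": m.t_max_s,
                "t_amp50_s": m.t_amp50_s,
                "auc_pct_s": m.auc_pct_s,
            }
        )
    metric_table = pd.DataFrame(rows).sort_values(
        ["group", "mouse_id", "pa_id", "timepoint"], kind="stable"
    )
    table_path = write_metric_table(out_dir / "metrics" / "metric_table.csv", metric_table)
    _record(manifest, "metrics", table_path, out_dir)

    # --- stats ---------------------------------------------------------
    report_lines = []
    groups = metric_table["group"].unique()
    if len(groups) >= 2:
        try:
            res = nested_compare(metric_table, config.stats_metric, list(config.stats_factors))
        except Exception as exc:
            raise PipelineError(f"stage stats failed: {exc}") from exc
        report_lines += [
            f"nested comparison of {res.metric} by {'/'.join(res.factors)}",
            f"  effect = {res.effect:.4f}  SE = {res.se:.4f}  df = {res.df:.0f}",
            f"  statistic = {res.statistic:.4f}  p = {res.p_value:.4g}",
            f"  variance components: between-mouse = {res.var_between_mouse:.4f}, "
            f"within-mouse = {res.var_within_mouse:.4f}",
        ]
        if res.pairwise is not None:
            report_lines.append(res.pairwise.to_string(index=False))
    summary = summarize_by_mouse(metric_table, config.stats_metric)
    report_lines.append("")
    report_lines.append("mouse-level summary (mean +/- SD of PAs):")
    report_lines.append(summary.to_string(index=False))
    stats_path = out_dir / "stats" / "report.txt"
    stats_path.parent.mkdir(parents=True, exist_ok=True)
    stats_path.write_text("\n".join(report_lines) + "\n")
    _record(manifest, "stats", stats_path, out_dir)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    missing = [
        p for paths in manifest.stages.values() for p in paths if not (out_dir / p).exists()
    ]
    if missing:  # pragma: no cover - defensive
        raise PipelineError(f"manifest lists missing outputs: {missing}")
    return manifest
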