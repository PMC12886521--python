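"""File formats: trial TIFFs with plain-text sidecars, trace and metric CSVs.

A trial is stored as a multi-page TIFF plus a ``<name>.meta.txt`` sidecar
of ``key = value`` lines carrying acquisition metadata (frame rate, pixel
size, stimulus timing).  Explicit overrides always win over the sidecar;
a conflict is logged as a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import DiameterTrace, ImageStack

logger = logging.getLogger("lumenpulse")

__all__ = [
    "write_trial_stack",
    "read_trial_stack",
    "read_sidecar",
    "write_trace_csv",
    "read_trace_csv",
    "write_metric_table",
    "read_metric_table",
]

SIDECAR_KEYS = (
    "frame_rate_hz",
    "pixel_size_um",
    "stim_onset_s",
    "stim_duration_s",
    "trial_duration_s",
)


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".meta.txt")


def write_trial_stack(
    path: str | Path, stack: ImageStack, extra_meta: dict | None = None
) -> Path:
    """Write a trial as multi-page TIFF with a key/value sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(stack.frames, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_size_um": stack.pixel_size_um,
        **(extra_meta or {}),
    }
    lines = [f"{k} = {v}" for k, v in meta.items()]
    _sidecar_path(path).write_text("\n".join(lines) + "\n")
    return path


def read_sidecar(tiff_path: str | Path) -> dict[str, float]:
    """Parse a trial's plain-text sidecar; missing file yields {}."""
    sidecar = _sidecar_path(Path(tiff_path))
    if not sidecar.exists():
        return {}
    meta: dict[str, float] = {}
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        try:
            meta[key.strip()] = float(value.strip())
        except ValueError:
            logger.warning("sidecar %s: unparseable line %r", sidecar, line)
    return meta


def read_trial_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a trial stack; metadata from the sidecar, overridden by arguments.

    Missing frame rate or pixel size (neither in the sidecar nor given) is
    a configuration error.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    meta = read_sidecar(path)
    resolved = {}
    for key, override in (
        ("frame_rate_hz", frame_rate_hz),
        ("pixel_size_um", pixel_size_um),
    ):
        sidecar_val = meta.get(key)
        if override is not None:
            if sidecar_val is not None and not np.isclose(sidecar_val, override):
                logger.warning(
                    "%s: override %s=%s conflicts with sidecar value %s; using override",
                    path.name, key, override, sidecar_val,
                )
            resolved[key] = override
        elif sidecar_val is not None:
            resolved[key] = sidecar_val
        else:
            raise ValueError(f"{path}: missing required metadata {key!r}")
    return ImageStack(frames, resolved["frame_rate_hz"], resolved["pixel_size_um"])


def write_trace_csv(path: str | Path, trace: DiameterTrace) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame_index": np.arange(len(trace.values_um)),
            "time_s": trace.time_axis(),
            "diameter_um": trace.values_um,
            "quality": trace.quality,
        }
    ).to_csv(path, index=False, float_format="%.6f")
    return path


def read_trace_csv(
    path: str | Path, frame_rate_hz: float, pixel_size_um: float
) -> DiameterTrace:
    df = pd.read_csv(path)
    return DiameterTrace(
        df["diameter_um"].to_numpy(), list(df["quality"]), frame_rate_hz, pixel_size_um
    )


METRIC_TABLE_COLUMNS = [
    "group",
    "mouse_id",
    "pa_id",
    "timepoint",
    "basal_diameter_um",
    "amplitude_pct",
    "t_max_s",
    "t_amp50_s",
    "auc_pct_s",
]


def write_metric_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in METRIC_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.6f")
    return path


def read_metric_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
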