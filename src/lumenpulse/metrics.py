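"""Neurovascular-coupling response metrics from diameter traces.

Each trial's trace is normalized to its own basal diameter (mean over the
pre-stimulus window, defined as 100%), the normalized traces of a
vessel's trials are averaged, and four response parameters are read off
the averaged trace over the stimulation window:

* **Amplitude** — maximum of the averaged normalized trace in the response
  window, in percent of basal;
* **t_Max** — time from stimulus onset to that maximum;
* **t_Amp50%** — time from onset to the first crossing of 50% of the
  dilation (100 + (Amplitude - 100)/2), linearly interpolated between
  frames;
* **AUC** — trapezoidal integral of (trace - 100) over the response
  window, in percent-seconds, so a null response integrates to zero.

Longitudinal effects are expressed as percent change of a metric between
timepoints; for Amplitude the dilation component (Amplitude - 100) is the
quantity compared, since the 100% floor is not part of the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimulusProtocol
from .segmentation import DiameterTrace

__all__ = [
    "NormalizedTrace",
    "NVCMetrics",
    "LongitudinalChange",
    "compute_basal",
    "normalize_trace",
    "average_trials",
    "compute_metrics",
    "percent_change",
    "metrics_from_trials",
]


@dataclass
class NormalizedTrace:
    """A diameter trace expressed as percent of its basal diameter."""

    values_pct: np.ndarray
    time_s: np.ndarray
    protocol: StimulusProtocol
    basal_mean_um: float
    basal_sd_um: float

    def __post_init__(self) -> None:
        self.values_pct = np.asarray(self.values_pct, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.values_pct.shape != self.time_s.shape:
            raise ValueError("values and times must align")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")


@dataclass(frozen=True)
class NVCMetrics:
    """The four response parameters of one vessel at one timepoint."""

    amplitude_pct: float
    t_max_s: float
    t_amp50_s: float
    auc_pct_s: float
    basal_diameter_um: float
    no_response: bool = False


@dataclass(frozen=True)
class LongitudinalChange:
    metric: str
    value_at_reference: float
    value_at_timepoint: float
    change_pct: float


def compute_basal(
    trace: DiameterTrace, protocol: StimulusProtocol, min_ok_frames: int = 3
) -> tuple[float, float]:
    """Mean and sample SD of the diameter over the basal window.

    Only ok-quality frames with ``basal_window_start_s <= t < stim_onset_s``
    contribute; flagged (interpolated) frames are excluded.  Fewer than
    ``min_ok_frames`` usable frames rejects the trace.
    """
    t = trace.time_axis()
    in_window = (t >= protocol.basal_window_start_s) & (t < protocol.stim_onset_s)
    usable = in_window & trace.ok()
    n = int(usable.sum())
    if n < min_ok_frames:
        raise ValueError(
            f"only {n} ok frames in the basal window (need >= {min_ok_frames})"
        )
    vals = trace.values_um[usable]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return float(np.mean(vals)), sd


def normalize_trace(
    trace: DiameterTrace, basal_mean_um: float, protocol: StimulusProtocol,
    basal_sd_um: float = 0.0,
) -> NormalizedTrace:
    """Express a trace as percent of basal (basal diameter = 100%)."""
    if basal_mean_um <= 0:
        raise ValueError("basal_mean_um must be positive")
    return NormalizedTrace(
        100.0 * trace.values_um / basal_mean_um,
        trace.time_axis(),
        protocol,
        basal_mean_um,
        basal_sd_um,
    )


def average_trials(traces: list[NormalizedTrace]) -> NormalizedTrace:
    """Pointwise mean of per-trial normalized traces.

    Averaging after per-trial normalization suppresses awake-imaging
    artifacts while keeping each trial's basal at 100%.
    """
    if not traces:
        raise ValueError("need at least one trace")
    first = traces[0]
    for tr in traces[1:]:
        if tr.protocol != first.protocol or len(tr.values_pct) != len(first.values_pct):
            raise ValueError("all trials must share protocol and length")
    values = np.mean([tr.values_pct for tr in traces], axis=0)
    return NormalizedTrace(
        values,
        first.time_s,
        first.protocol,
        float(np.mean([tr.basal_mean_um for tr in traces])),
        float(np.mean([tr.basal_sd_um for tr in traces])),
    )


def compute_metrics(avg: NormalizedTrace) -> NVCMetrics:
    """Read the four response parameters off an averaged normalized trace.

    The response window is closed, ``[onset, onset + stim_duration]``; ties
    at the maximum resolve to the earliest frame.  When the trace never
    exceeds 100% in the window the vessel is flagged as non-responding and
    ``t_amp50_s`` is reported equal to ``t_max_s``.
    """
    p = avg.protocol
    t = avg.time_s
    eps = 1e-9
    win = (t >= p.stim_onset_s - eps) & (t <= p.stim_onset_s + p.stim_duration_s + eps)
    if not win.any():
        raise ValueError("response window contains no frames")
    tw = t[win]
    vw = avg.values_pct[win]

    i_max = int(np.argmax(vw))  # earliest frame on ties
    amplitude = float(vw[i_max])
    t_max = float(tw[i_max] - p.stim_onset_s)
    auc = float(np.trapezoid(vw - 100.0, tw))

    if amplitude <= 100.0:
        return NVCMetrics(amplitude, t_max, t_max, auc, avg.basal_mean_um, True)

    target = 100.0 + 0.5 * (amplitude - 100.0)
    t_amp50 = t_max
    # scan from onset to the peak for the first upward crossing of target,
    # interpolating linearly between the bracketing frames
    idx_global = np.nonzero(win)[0]
    for j, gi in enumerate(idx_global[: i_max + 1]):
        if avg.values_pct[gi] >= target:
            if j == 0 or gi == 0:
                t_cross = t[gi]
            else:
                v0, v1 = avg.values_pct[gi - 1], avg.values_pct[gi]
                t0, t1 = t[gi - 1], t[gi]
                t_cross = t0 + (target - v0) / (v1 - v0) * (t1 - t0) if v1 > v0 else t1
            t_amp50 = max(0.0, float(t_cross - p.stim_onset_s))
            break
    return NVCMetrics(amplitude, t_max, min(t_amp50, t_max), auc, avg.basal_mean_um, False)


def percent_change(
    current: NVCMetrics, reference: NVCMetrics, metric: str
) -> LongitudinalChange:
    """Percent change of one metric between a timepoint and its reference.

    For ``amplitude_pct`` the compared quantity is the dilation above
    baseline (amplitude - 100); for the other metrics the raw value is
    used.  A zero reference is rejected.
    """
    def value(m: NVCMetrics) -> float:
        v = getattr(m, metric)
        return v - 100.0 if metric == "amplitude_pct" else v

    ref = value(reference)
    cur = value(current)
    if ref == 0:
        raise ZeroDivisionError(f"reference {metric} is zero; percent change undefined")
    return LongitudinalChange(metric, ref, cur, 100.0 * (cur - ref) / ref)


def metrics_from_trials(
    traces: list[DiameterTrace], protocol: StimulusProtocol
) -> NVCMetrics:
    """Convenience: per-trial basal + normalization, averaging, metrics."""
    normalized = []
    for tr in traces:
        mean, sd = compute_basal(tr, protocol)
        normalized.append(normalize_trace(tr, mean, protocol, sd))
    return compute_metrics(average_trials(normalized))
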