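"""Intrinsic optical signal (IOS) activity mapping.

Repeated-stimulation reflectance movies are turned into an activity map:
each trial's response is normalized to its own baseline per pixel
(Delta-R/R) and the per-trial maps are summed over trials.  Under red
(~630 nm) illumination an activated region absorbs more light, so the
response of interest is negative-going; the sign is always passed
explicitly rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import ImageStack

__all__ = [
    "IOSSession",
    "ActivityMap",
    "trial_response_map",
    "activity_map",
    "locate_peak_region",
]


@dataclass
class IOSSession:
    """A set of reflectance trials with shared baseline/response windows.

    Windows are half-open frame ranges ``(start, stop)``; they must be
    disjoint and lie within every trial.  The acquisition this mirrors
    used 30 trials of 1.5 s whisker stimulation with 20 s breaks.
    """

    trials: list[ImageStack]
    baseline_window: tuple[int, int]
    response_window: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("need at least one trial")
        shape = self.trials[0].frames.shape
        for tr in self.trials:
            if tr.frames.shape != shape:
                raise ValueError("all trials must share dimensions")
        b0, b1 = self.baseline_window
        r0, r1 = self.response_window
        n = shape[0]
        if not (0 <= b0 < b1 <= n and 0 <= r0 < r1 <= n):
            raise ValueError("windows must lie within the trials")
        if max(b0, r0) < min(b1, r1):
            raise ValueError("baseline and response windows must be disjoint")


@dataclass
class ActivityMap:
    """Summed baseline-normalized response over all trials."""

    map: np.ndarray
    n_trials: int


def trial_response_map(
    stack: ImageStack,
    baseline_window: tuple[int, int],
    response_window: tuple[int, int],
) -> np.ndarray:
    """Per-pixel fractional reflectance change (Delta-R/R) of one trial.

    ``(mean over response frames - mean over baseline frames) / mean over
    baseline frames``.  Pixels whose baseline mean is zero make the ratio
    undefined and reject the trial.
    """
    b0, b1 = baseline_window
    r0, r1 = response_window
    base = stack.frames[b0:b1].mean(axis=0, dtype=np.float64)
    resp = stack.frames[r0:r1].mean(axis=0, dtype=np.float64)
    n_zero = int((base == 0).sum())
    if n_zero:
        raise ValueError(f"{n_zero} pixels have zero baseline signal")
    return (resp - base) / base


def activity_map(session: IOSSession) -> ActivityMap:
    """Sum the per-trial Delta-R/R maps over all trials of a session."""
    total = np.zeros(session.trials[0].frames.shape[1:], dtype=np.float64)
    for tr in session.trials:
        total += trial_response_map(tr, session.baseline_window, session.response_window)
    return ActivityMap(total, len(session.trials))


def locate_peak_region(
    amap: np.ndarray | ActivityMap,
    sign: int = -1,
    fraction_of_peak: float = 0.5,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Threshold an activity map at a fraction of its extremum.

    ``sign = -1`` targets the most negative value (absorption increase),
    ``+1`` the most positive.  The map (flipped so the targeted extremum is
    positive) is thresholded at ``fraction_of_peak`` times the extremum;
    the largest 8-connected suprathreshold region is returned together
    with its magnitude-weighted centroid (row, col).
    """
    m = amap.map if isinstance(amap, ActivityMap) else np.asarray(amap, dtype=float)
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    if not (0 < fraction_of_peak < 1):
        raise ValueError("fraction_of_peak must be in (0, 1)")
    signed = sign * m
    peak = signed.max()
    if np.ptp(m) == 0:
        raise ValueError("activity map is constant; no peak to locate")
    if peak <= 0:
        raise ValueError("map has no extremum of the requested sign")
    supra = signed >= fraction_of_peak * peak
    labels, n = ndimage.label(supra, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(supra, labels, range(1, n + 1))
    label = int(np.argmax(sizes)) + 1
    region = labels == label
    weights = np.where(region, signed, 0.0)
    centroid = ndimage.center_of_mass(weights)
    return region, (float(centroid[0]), float(centroid[1]))
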