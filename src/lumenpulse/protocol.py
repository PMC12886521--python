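"""Stimulation-trial timing protocol.

A trial is a fixed-duration cross-section movie with a whisker-stimulation
epoch embedded in it.  The default protocol mirrors the awake-imaging
paradigm this package targets: 25 s trials sampled at 9.45 Hz, a 5 s air-puff
stimulus starting at second 10, basal (pre-stimulus) diameter measured from
second 3 to stimulus onset, and 10 trials per arteriole.

Conventions used throughout the package:

* frame ``k`` is timestamped ``t_k = k / frame_rate_hz`` (frame 0 at t = 0);
* the basal window is half-open, ``basal_window_start_s <= t < stim_onset_s``;
* the response window is closed, ``stim_onset_s <= t <= stim_onset_s +
  stim_duration_s`` (the onset frame belongs to the response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusProtocol", "DEFAULT_PROTOCOL"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of one stimulation trial.

    Parameters
    ----------
    trial_duration_s:
        Total movie duration in seconds.
    frame_rate_hz:
        Acquisition frame rate in frames/second.
    stim_onset_s:
        Time of stimulus onset from the start of acquisition, seconds.
    stim_duration_s:
        Stimulus duration, seconds.  The response window is
        ``[stim_onset_s, stim_onset_s + stim_duration_s]``.
    basal_window_start_s:
        Start of the pre-stimulus window used to define the basal (100%)
        diameter, seconds.
    n_trials:
        Number of stimulation trials acquired per arteriole.
    """

    trial_duration_s: float = 25.0
    frame_rate_hz: float = 9.45
    stim_onset_s: float = 10.0
    stim_duration_s: float = 5.0
    basal_window_start_s: float = 3.0
    n_trials: int = 10

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        if self.stim_onset_s + self.stim_duration_s > self.trial_duration_s:
            raise ValueError("stimulus window must end within the trial")
        if not (0 <= self.basal_window_start_s < self.stim_onset_s):
            raise ValueError("basal window must start before stimulus onset")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_frames < 2:
            raise ValueError("protocol implies fewer than 2 frames")

    @property
    def n_frames(self) -> int:
        """Number of frames in one trial movie."""
        return int(round(self.trial_duration_s * self.frame_rate_hz))

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def time_axis(self) -> np.ndarray:
        """Per-frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def basal_frames(self) -> np.ndarray:
        """Boolean selector for frames in the half-open basal window."""
        t = self.time_axis()
        return (t >= self.basal_window_start_s) & (t < self.stim_onset_s)

    def response_frames(self) -> np.ndarray:
        """Boolean selector for frames in the closed response window."""
        t = self.time_axis()
        # small epsilon so a frame landing exactly on the window edge
        # (up to float rounding) is included
        eps = 1e-9
        return (t >= self.stim_onset_s - eps) & (
            t <= self.stim_onset_s + self.stim_duration_s + eps
        )


DEFAULT_PROTOCOL = StimulusProtocol()
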