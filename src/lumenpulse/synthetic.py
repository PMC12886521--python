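"""Synthetic cross-section movies with known diameter dynamics.

No raw imaging data ships with this package, so benchmarking rests on a
generator that emulates what the microscope sees: a bright, roughly
elliptical lumen (plasma labelled with an intravascular dye) on a dark
parenchyma background, dilating in response to a whisker stimulus, with
frame-to-frame translation jitter and shot/read noise standing in for the
artifacts of awake imaging.  The generator also draws whole hierarchical
sessions (groups -> mice -> arterioles -> timepoints) with explicit
variance components, which is what the nested statistics are tested
against.

Every random choice flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so a session is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import DEFAULT_PROTOCOL, StimulusProtocol
from .segmentation import ImageStack

__all__ = [
    "VesselGroundTruth",
    "NoiseModel",
    "SyntheticTrial",
    "GroupSpec",
    "SessionDesign",
    "generate_diameter_timecourse",
    "render_trial",
    "draw_session_truth",
    "generate_session",
    "simulate_ios_session",
]


@dataclass(frozen=True)
class VesselGroundTruth:
    """Known geometry and dilation kinetics of one synthetic arteriole.

    The vessel is an ellipse whose minor axis is the "diameter" the
    pipeline measures (the minimum chord through an ellipse's centroid is
    its minor axis).  Dilation scales both axes by the same factor, so the
    ground-truth diameter trace fully determines the rendered shape.

    Parameters
    ----------
    basal_diameter_um:
        Resting minor-axis diameter, micrometres.
    dilation_amplitude_pct:
        Peak dilation as percent of basal (15 means the diameter peaks at
        115% of basal).
    t_max_s:
        Time from stimulus onset to peak dilation, seconds.
    rise_shape:
        ``"linear-ramp"`` (default) or ``"gamma-like"``; the kinetic form
        of the rise to peak.  ``rise_power`` shapes the gamma-like rise.
    decay_tau_s:
        Exponential time constant of the return toward basal after the
        peak, seconds.
    ellipticity:
        Major/minor axis ratio, >= 1.
    orientation_deg:
        Major-axis orientation, degrees counter-clockwise from the row
        axis.
    center_rc:
        Ellipse centre in (row, col) pixels.
    pixel_size_um:
        Micrometres per pixel of the rendered movie.
    """

    basal_diameter_um: float = 20.0
    dilation_amplitude_pct: float = 15.0
    t_max_s: float = 2.5
    rise_shape: str = "linear-ramp"
    rise_power: float = 2.0
    decay_tau_s: float = 2.0
    ellipticity: float = 1.2
    orientation_deg: float = 30.0
    center_rc: tuple[float, float] = (64.0, 64.0)
    pixel_size_um: float = 0.4

    def __post_init__(self) -> None:
        if self.basal_diameter_um <= 0:
            raise ValueError("basal_diameter_um must be positive")
        if self.dilation_amplitude_pct <= -100:
            raise ValueError("dilation_amplitude_pct must exceed -100")
        if self.t_max_s <= 0:
            raise ValueError("t_max_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.ellipticity < 1:
            raise ValueError("ellipticity must be >= 1")
        if self.rise_shape not in ("linear-ramp", "gamma-like"):
            raise ValueError(f"unknown rise_shape: {self.rise_shape!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise and motion artifacts applied after rasterization.

    ``poisson_scale`` converts intensity units to expected photon counts
    for shot noise (0 disables); ``gaussian_sd`` is additive read noise;
    ``motion_jitter_sd_px`` is the SD of the per-frame rigid translation
    that mimics residual motion of an awake, head-fixed animal.  Defaults
    give a vessel/background contrast of 0.9 with read-noise SD 0.18
    (contrast-to-noise ~5) and 1 px jitter — deliberately unflattering,
    awake-imaging-like conditions.
    """

    vessel_intensity: float = 1.0
    background_intensity: float = 0.1
    gaussian_sd: float = 0.18
    poisson_scale: float = 0.0
    motion_jitter_sd_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_intensity <= self.background_intensity:
            raise ValueError("vessel must be brighter than background")
        if self.gaussian_sd < 0 or self.motion_jitter_sd_px < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.poisson_scale < 0:
            raise ValueError("poisson_scale must be non-negative")


NOISELESS = NoiseModel(gaussian_sd=0.0, motion_jitter_sd_px=0.0)


@dataclass
class SyntheticTrial:
    """One rendered trial with its ground truth attached."""

    stack: ImageStack
    truth_trace: np.ndarray  # per-frame true minimum diameter, um
    truth: VesselGroundTruth

    def __post_init__(self) -> None:
        if len(self.truth_trace) != self.stack.n_frames:
            raise ValueError("truth_trace length must match stack frame count")


def generate_diameter_timecourse(
    truth: VesselGroundTruth, protocol: StimulusProtocol = DEFAULT_PROTOCOL
) -> np.ndarray:
    """Ground-truth per-frame diameter (um) for one trial.

    The diameter sits at basal before stimulus onset, rises monotonically
    to ``basal * (1 + amplitude/100)`` — the peak is snapped to the frame
    nearest ``onset + t_max_s`` so the true peak value is attained exactly
    on a sampled frame — and then relaxes exponentially toward basal with
    time constant ``decay_tau_s``.
    """
    if truth.t_max_s > protocol.trial_duration_s - protocol.stim_onset_s:
        raise ValueError("t_max_s falls beyond the end of the trial")
    t = protocol.time_axis()
    basal = truth.basal_diameter_um
    peak = basal * (1.0 + truth.dilation_amplitude_pct / 100.0)

    k_peak = int(np.argmin(np.abs(t - (protocol.stim_onset_s + truth.t_max_s))))
    t_peak = t[k_peak]
    onset = protocol.stim_onset_s

    d = np.full_like(t, basal)
    rising = (t > onset) & (t <= t_peak)
    if t_peak > onset:
        x = (t[rising] - onset) / (t_peak - onset)
        if truth.rise_shape == "linear-ramp":
            shape = x
        else:  # gamma-like: accelerating-then-saturating power rise
            shape = x**truth.rise_power
        d[rising] = basal + (peak - basal) * shape
    after = t > t_peak
    d[after] = basal + (peak - basal) * np.exp(-(t[after] - t_peak) / truth.decay_tau_s)
    d[k_peak] = peak
    return d


def _ellipse_coverage(
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    semi_minor_px: float,
    semi_major_px: float,
    orientation_deg: float,
    supersample: int = 8,
) -> np.ndarray:
    """Area-coverage rasterization of a filled ellipse.

    Each pixel's value is the fraction of its unit square inside the
    ellipse, estimated on a ``supersample x supersample`` sub-grid; pixel
    centers sit at integer coordinates.  Sub-pixel diameter changes
    (~0.1 px at realistic scales) therefore shift boundary-pixel coverage
    continuously.
    """
    h, w = shape
    cr, cc = center_rc
    margin = semi_major_px + 1.5
    r0 = max(0, int(np.floor(cr - margin)))
    r1 = min(h - 1, int(np.ceil(cr + margin)))
    c0 = max(0, int(np.floor(cc - margin)))
    c1 = min(w - 1, int(np.ceil(cc + margin)))

    theta = np.deg2rad(orientation_deg)
    ct, st = np.cos(theta), np.sin(theta)

    # pixel-centre pass decides fully-inside / fully-outside pixels; only
    # the boundary band (within ~1 px of the edge) is supersampled
    rr0 = np.arange(r0, r1 + 1, dtype=np.float64)
    cc0 = np.arange(c0, c1 + 1, dtype=np.float64)
    dr0 = (rr0 - cr)[:, None]
    dc0 = (cc0 - cc)[None, :]
    u0 = dr0 * ct + dc0 * st
    v0 = -dr0 * st + dc0 * ct
    f0 = (u0 / semi_major_px) ** 2 + (v0 / semi_minor_px) ** 2
    # normalized-radius margin equivalent to ~1.2 px at the minor axis
    band_half = 2.6 / semi_minor_px
    fr = np.sqrt(f0)
    cov = (fr <= 1.0).astype(np.float32)
    band = np.abs(fr - 1.0) < band_half

    if band.any():
        s = supersample
        offs = (np.arange(s) + 0.5) / s - 0.5
        br, bc = np.nonzero(band)
        dr = dr0[br, 0][:, None, None] + offs[None, :, None]
        dc = dc0[0, bc][:, None, None] + offs[None, None, :]
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        inside = (u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0
        cov[br, bc] = inside.mean(axis=(1, 2), dtype=np.float32)

    out = np.zeros(shape, dtype=np.float32)
    out[r0 : r1 + 1, c0 : c1 + 1] = cov
    return out


class GeometryError(ValueError):
    """Vessel ellipse (including jitter) would not fit inside the frame."""


def render_trial(
    trace_um: np.ndarray,
    truth: VesselGroundTruth,
    noise: NoiseModel = NOISELESS,
    protocol: StimulusProtocol = DEFAULT_PROTOCOL,
    shape: tuple[int, int] = (160, 160),
    rng: np.random.Generator | None = None,
    supersample: int = 8,
) -> SyntheticTrial:
    """Rasterize a diameter time course into a noisy movie.

    Every frame contains a filled, area-coverage anti-aliased ellipse with
    minor axis ``trace_um[t] / pixel_size_um`` pixels and major axis
    ``ellipticity`` times that, centred at ``truth.center_rc`` plus a
    per-frame Gaussian rigid translation (SD ``motion_jitter_sd_px``).
    Optional Poisson shot noise and additive Gaussian read noise are
    applied after rasterization.  Rejects geometries where any frame's
    ellipse (jitter included) would be clipped by the image border.
    """
    trace_um = np.asarray(trace_um, dtype=float)
    if len(trace_um) != protocol.n_frames:
        raise ValueError("trace length does not match protocol frame count")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    n = len(trace_um)
    jitter = (
        rng.normal(0.0, noise.motion_jitter_sd_px, size=(n, 2))
        if noise.motion_jitter_sd_px > 0
        else np.zeros((n, 2))
    )

    semi_minor = trace_um / truth.pixel_size_um / 2.0
    semi_major = semi_minor * truth.ellipticity
    centers = np.asarray(truth.center_rc) + jitter
    margin = semi_major + 1.5
    h, w = shape
    if (
        (centers[:, 0] - margin < 0).any()
        or (centers[:, 0] + margin > h - 1).any()
        or (centers[:, 1] - margin < 0).any()
        or (centers[:, 1] + margin > w - 1).any()
    ):
        raise GeometryError("vessel ellipse exceeds frame bounds (jitter included)")

    frames = np.empty((n, h, w), dtype=np.float32)
    span = noise.vessel_intensity - noise.background_intensity
    for k in range(n):
        cov = _ellipse_coverage(
            shape,
            (centers[k, 0], centers[k, 1]),
            semi_minor[k],
            semi_major[k],
            truth.orientation_deg,
            supersample,
        )
        frames[k] = noise.background_intensity + span * cov

    if noise.poisson_scale > 0:
        frames = rng.poisson(np.clip(frames, 0, None) * noise.poisson_scale).astype(
            np.float32
        ) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        frames = frames + rng.normal(0.0, noise.gaussian_sd, size=frames.shape).astype(
            np.float32
        )

    stack = ImageStack(frames, protocol.frame_rate_hz, truth.pixel_size_um)
    return SyntheticTrial(stack, trace_um, truth)


# ---------------------------------------------------------------------------
# hierarchical sessions


@dataclass(frozen=True)
class GroupSpec:
    """Per-group offsets added to the session's mean response parameters."""

    name: str
    amplitude_offset_pct: float = 0.0
    t_max_offset_s: float = 0.0


@dataclass(frozen=True)
class SessionDesign:
    """Hierarchical design of a synthetic study: groups -> mice -> PAs.

    Response parameters decompose as group mean + mouse effect + PA effect,
    with the mouse- and PA-level SDs given explicitly; the same PA keeps
    its parameters across timepoints (plus optional per-timepoint offsets
    via group specs applies only at the group level).  Defaults reflect a
    typical awake two-photon study: 8 mice per group, 2-6 arterioles per
    mouse, ~20 um basal diameters dilating ~15% with peaks ~2.5 s after
    stimulus onset.
    """

    groups: tuple[GroupSpec, ...] = (GroupSpec("control"), GroupSpec("treated"))
    n_mice_per_group: int = 8
    pas_per_mouse: tuple[int, int] = (2, 6)
    timepoints: tuple[str, ...] = ("BL",)
    mean_basal_um: float = 20.0
    sd_basal_um: float = 3.0
    mean_amplitude_pct: float = 15.0
    mouse_sd_amplitude_pct: float = 2.0
    pa_sd_amplitude_pct: float = 3.0
    mean_t_max_s: float = 2.5
    mouse_sd_t_max_s: float = 0.3
    pa_sd_t_max_s: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pas_per_mouse
        if not (1 <= lo <= hi):
            raise ValueError("pas_per_mouse must be a nondecreasing positive range")
        if hi > 6 or lo < 2:
            raise ValueError("pas_per_mouse must lie within [2, 6]")
        if self.n_mice_per_group < 1:
            raise ValueError("need at least one mouse per group")
        if min(
            self.sd_basal_um,
            self.mouse_sd_amplitude_pct,
            self.pa_sd_amplitude_pct,
            self.mouse_sd_t_max_s,
            self.pa_sd_t_max_s,
        ) < 0:
            raise ValueError("variance components must be non-negative")


def draw_session_truth(
    design: SessionDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-PA ground-truth response parameters for a whole session.

    Returns a tidy table with one row per (group, mouse, PA, timepoint) and
    columns ``basal_diameter_um``, ``dilation_amplitude_pct``, ``t_max_s``.
    Amplitude and t_max are group mean + N(0, mouse_sd^2) mouse effect +
    N(0, pa_sd^2) PA effect; draws are clipped to physically meaningful
    ranges (diameter > 1 um, amplitude > -50%, 0.2 s <= t_max within the
    stimulus analysis span).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    mouse_counter = 0
    for g in design.groups:
        for _ in range(design.n_mice_per_group):
            mouse_counter += 1
            mouse_id = f"m{mouse_counter:03d}"
            n_pa = int(rng.integers(design.pas_per_mouse[0], design.pas_per_mouse[1] + 1))
            mouse_amp = rng.normal(0.0, design.mouse_sd_amplitude_pct)
            mouse_tmax = rng.normal(0.0, design.mouse_sd_t_max_s)
            for p in range(n_pa):
                basal = max(1.0, rng.normal(design.mean_basal_um, design.sd_basal_um))
                amp = max(
                    -50.0,
                    design.mean_amplitude_pct
                    + g.amplitude_offset_pct
                    + mouse_amp
                    + rng.normal(0.0, design.pa_sd_amplitude_pct),
                )
                tmax = float(
                    np.clip(
                        design.mean_t_max_s
                        + g.t_max_offset_s
                        + mouse_tmax
                        + rng.normal(0.0, design.pa_sd_t_max_s),
                        0.2,
                        4.9,
                    )
                )
                for tp in design.timepoints:
                    rows.append(
                        {
                            "group": g.name,
                            "mouse_id": mouse_id,
                            "pa_id": f"{mouse_id}_pa{p + 1}",
                            "timepoint": tp,
                            "basal_diameter_um": basal,
                            "dilation_amplitude_pct": amp,
                            "t_max_s": tmax,
                        }
                    )
    return pd.DataFrame(rows)


def generate_session(
    design: SessionDesign,
    protocol: StimulusProtocol = DEFAULT_PROTOCOL,
    noise: NoiseModel = NoiseModel(),
    render: bool = True,
    shape: tuple[int, int] = (160, 160),
    template: VesselGroundTruth = VesselGroundTruth(),
):
    """Generate a full synthetic study session.

    Returns ``(trials, truth_table)`` where ``truth_table`` records the
    generating parameters per (group, mouse, PA, timepoint, trial) and
    ``trials`` maps ``(group, mouse_id, pa_id, timepoint)`` to the list of
    rendered :class:`SyntheticTrial` for that arteriole (empty dict when
    ``render=False``, which is how statistical calibration studies use the
    generator).  One global seed expands into independent substreams: one
    for the design draw and one per rendered trial.
    """
    root = np.random.SeedSequence(design.seed)
    design_ss, render_ss = root.spawn(2)
    truth_tbl = draw_session_truth(design, np.random.default_rng(design_ss))

    per_trial_rows = []
    trials: dict[tuple[str, str, str, str], list[SyntheticTrial]] = {}
    pa_rows = truth_tbl.to_dict("records")
    streams = render_ss.spawn(len(pa_rows) * protocol.n_trials)
    i = 0
    for row in pa_rows:
        truth = replace(
            template,
            basal_diameter_um=row["basal_diameter_um"],
            dilation_amplitude_pct=row["dilation_amplitude_pct"],
            t_max_s=row["t_max_s"],
        )
        key = (row["group"], row["mouse_id"], row["pa_id"], row["timepoint"])
        trace = generate_diameter_timecourse(truth, protocol)
        if render:
            trials[key] = []
        for trial_id in range(protocol.n_trials):
            if render:
                rng = np.random.default_rng(streams[i])
                trials[key].append(
                    render_trial(trace, truth, noise, protocol, shape, rng)
                )
            i += 1
            per_trial_rows.append({**row, "trial_id": trial_id})
    return trials, pd.DataFrame(per_trial_rows)


# ---------------------------------------------------------------------------
# intrinsic optical signal


def simulate_ios_session(
    n_trials: int = 30,
    shape: tuple[int, int] = (64, 64),
    blob_center_rc: tuple[float, float] = (40.0, 24.0),
    blob_sigma_px: float = 6.0,
    blob_dr_over_r: float = -0.02,
    baseline_frames: int = 10,
    response_frames: int = 15,
    baseline_intensity: float = 100.0,
    noise_sd: float = 4.0,
    frame_rate_hz: float = 10.0,
    seed: int = 0,
):
    """Synthetic reflectance trials with a Gaussian activation blob.

    Each trial has ``baseline_frames`` quiet frames followed by
    ``response_frames`` in which reflectance drops by ``blob_dr_over_r``
    (fractional, negative for the absorption increase seen under red
    light) with a Gaussian spatial profile; white noise of SD ``noise_sd``
    (same units as ``baseline_intensity``) is added everywhere.  Returns
    ``(stacks, baseline_window, response_window, truth_center)``.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    blob = np.exp(
        -((rr - blob_center_rc[0]) ** 2 + (cc - blob_center_rc[1]) ** 2)
        / (2 * blob_sigma_px**2)
    )
    n_frames = baseline_frames + response_frames
    stacks = []
    for _ in range(n_trials):
        frames = np.full((n_frames, h, w), baseline_intensity, dtype=np.float32)
        frames[baseline_frames:] *= 1.0 + blob_dr_over_r * blob
        frames += rng.normal(0.0, noise_sd, size=frames.shape).astype(np.float32)
        stacks.append(ImageStack(frames, frame_rate_hz, 1.0))
    return (
        stacks,
        (0, baseline_frames),
        (baseline_frames, n_frames),
        blob_center_rc,
    )
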