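"""Per-frame vessel diameter measurement from cross-section movies.

The measurement chain per frame is: percentile intensity adjustment ->
binarization (Otsu by default) -> connected-component selection with hole
filling -> minimum chord through the mask centroid, swept over orientation.
The minimum chord through the centroid of an elliptical lumen cross-section
is its minor axis, so this measures the quantity reported as the vessel
"minimum diameter".

Coordinates are (row, col), 0-based, with pixel centers at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "VesselMask",
    "DiameterTrace",
    "SegmentationParams",
    "TrialQualityError",
    "adjust_intensity",
    "binarize",
    "select_vessel_component",
    "minimum_diameter",
    "extract_diameter_trace",
]

QUALITY_OK = "ok"
QUALITY_EMPTY = "empty_mask"
QUALITY_BORDER = "border_contact"
QUALITY_OUTLIER = "outlier"


class TrialQualityError(RuntimeError):
    """Raised when too many frames of a trial fail quality checks."""


@dataclass
class ImageStack:
    """A single trial's movie: T x H x W intensities plus acquisition metadata.

    ``pixel_size_um`` is micrometres per pixel; ``frame_rate_hz`` is
    frames/second.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        t, h, w = self.frames.shape
        if t < 2 or h < 8 or w < 8:
            raise ValueError("stack too small (need T >= 2 and H, W >= 8)")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_hz and pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class VesselMask:
    """A single frame's vessel mask with its area centroid."""

    mask: np.ndarray
    centroid_rc: tuple[float, float]
    area_px: int
    touches_border: bool

    @property
    def is_empty(self) -> bool:
        return self.area_px == 0


@dataclass
class DiameterTrace:
    """Per-frame vessel diameter in physical units with quality flags.

    ``values_um[k]`` is the measured minimum diameter of frame ``k`` in
    micrometres.  Frames whose measurement failed (empty mask, border
    contact) carry values interpolated in time from neighbouring ok frames
    and a non-``ok`` quality flag; such frames are excluded from basal
    statistics downstream.
    """

    values_um: np.ndarray
    quality: list[str]
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values_um = np.asarray(self.values_um, dtype=float)
        if len(self.values_um) != len(self.quality):
            raise ValueError("values and quality flags must align")

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.values_um)) / self.frame_rate_hz

    def ok(self) -> np.ndarray:
        return np.array([q == QUALITY_OK for q in self.quality])


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the diameter-measurement chain."""

    low_pct: float = 1.0
    high_pct: float = 99.0
    threshold_method: str = "otsu"  # "otsu" or "fixed"
    fixed_threshold: float | None = None
    angular_step_deg: float = 1.0
    sample_step_px: float = 0.25
    max_flagged_fraction: float = 0.5


def adjust_intensity(frame: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linearly rescale a frame so its percentiles map onto [0, 1].

    The ``low_pct`` percentile maps to 0 and the ``high_pct`` percentile to
    1; values outside are clipped.  A constant frame maps to all zeros.
    This absorbs gain/offset differences (laser power, PMT gain, bleaching)
    so the subsequent threshold is stable across trials.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(frame, [low_pct, high_pct])
    if hi <= lo:
        return np.zeros_like(frame)
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)


def binarize(
    frame: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Threshold an adjusted frame; True marks bright (vessel) pixels.

    The default threshold is Otsu's between-class-variance optimum computed
    on the frame histogram.  A ``fixed_threshold`` overrides it.  An
    all-equal frame yields an all-False mask (flagged downstream as
    ``empty_mask``).
    """
    frame = np.asarray(frame, dtype=float)
    if method == "fixed" or fixed_threshold is not None:
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        return frame > fixed_threshold
    if method != "otsu":
        raise ValueError(f"unknown binarization method: {method!r}")
    if np.ptp(frame) == 0:
        return np.zeros(frame.shape, dtype=bool)
    thr = threshold_otsu(frame)
    return frame > thr


def select_vessel_component(
    mask: np.ndarray, prev_centroid: tuple[float, float] | None = None
) -> VesselMask:
    """Pick the vessel's connected component and compute its centroid.

    Holes are filled first (the lumen should be solid).  Among 8-connected
    components the one containing ``prev_centroid`` is chosen if given
    (nearest centroid as fallback), otherwise the largest by area; the
    previous frame's centroid serves as a tracking hint so a transient
    bright artifact cannot steal the selection.  An empty mask is returned
    as an empty :class:`VesselMask` rather than raising, so the caller can
    record a quality flag.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return VesselMask(np.zeros_like(mask), (np.nan, np.nan), 0, False)

    if prev_centroid is not None:
        r = int(round(prev_centroid[0]))
        c = int(round(prev_centroid[1]))
        label = 0
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]:
            label = labels[r, c]
        if label == 0:
            centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
            d2 = [
                (cr - prev_centroid[0]) ** 2 + (cc - prev_centroid[1]) ** 2
                for cr, cc in centroids
            ]
            label = int(np.argmin(d2)) + 1
    else:
        sizes = ndimage.sum_labels(mask, labels, range(1, n + 1))
        label = int(np.argmax(sizes)) + 1

    sel = labels == label
    # fill interior holes of the selected component only (cropped for speed)
    rows = np.nonzero(sel.any(axis=1))[0]
    cols = np.nonzero(sel.any(axis=0))[0]
    r0, r1, c0, c1 = rows[0], rows[-1], cols[0], cols[-1]
    crop = sel[r0 : r1 + 1, c0 : c1 + 1]
    sel[r0 : r1 + 1, c0 : c1 + 1] = ndimage.binary_fill_holes(crop)
    area = int(sel.sum())
    centroid = ndimage.center_of_mass(sel[r0 : r1 + 1, c0 : c1 + 1])
    touches = bool(
        sel[0, :].any() or sel[-1, :].any() or sel[:, 0].any() or sel[:, -1].any()
    )
    return VesselMask(
        sel, (float(centroid[0]) + r0, float(centroid[1]) + c0), area, touches
    )


def _smoothing_sigma(area_px: float) -> float:
    """Mask-smoothing scale for sub-pixel edge localization.

    Grows with vessel size (more boundary pixels to pool) but is capped so
    the curvature correction below stays second-order accurate.
    """
    return float(np.clip(0.125 * np.sqrt(area_px), 1.0, 2.2))


_EDGE_SHIFT_TABLE: tuple[np.ndarray, np.ndarray] | None = None


def _edge_shift(radius_of_curvature: float, sigma: float) -> float:
    """Inward shift of the 0.5 level-set of a Gaussian-smoothed disk edge.

    Smoothing a solid disk of radius R with a Gaussian of width sigma
    moves the 0.5 contour inward; to first order by sigma^2/(2R), but for
    R of a few sigma the exact radial profile of the smoothed disk
    (an integral involving the modified Bessel function I0) is inverted
    instead.  The shift for unit sigma is tabulated in x = R/sigma once
    and interpolated; by scale invariance shift(R, sigma) =
    sigma * shift(R/sigma, 1).
    """
    global _EDGE_SHIFT_TABLE
    if _EDGE_SHIFT_TABLE is None:
        from scipy import optimize, special

        def smoothed_val(d: float, rho: float) -> float:
            t = np.linspace(0.0, rho, 400)
            integrand = t * np.exp(-((t - d) ** 2) / 2.0) * special.i0e(t * d)
            return float(np.trapezoid(integrand, t))

        # below R ~ 1.6 sigma the smoothed disk peaks under 0.5 and has no
        # crossing; clamp there
        xs = np.geomspace(1.6, 60.0, 120)
        shifts = np.empty_like(xs)
        for i, x in enumerate(xs):
            f = lambda d: smoothed_val(d, x) - 0.5
            shifts[i] = x - optimize.brentq(f, max(1e-3, x - 3.0), x + 3.0, xtol=1e-5)
        _EDGE_SHIFT_TABLE = (xs, shifts)
    xs, shifts = _EDGE_SHIFT_TABLE
    x = radius_of_curvature / sigma
    if x >= xs[-1]:
        return sigma / (2.0 * x)  # first-order curvature term
    if x <= xs[0]:
        return sigma * float(shifts[0])
    return sigma * float(np.interp(x, xs, shifts))


def _bilinear_sample(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with zero outside the image (vectorized)."""
    h, w = image.shape
    padded = np.zeros((h + 2, w + 2), dtype=np.float32)
    padded[1:-1, 1:-1] = image
    r = np.clip(rows + 1.0, 0.0, h)      # stay within padded bounds
    c = np.clip(cols + 1.0, 0.0, w)
    r0 = r.astype(np.int64)
    c0 = c.astype(np.int64)
    fr = (r - r0).astype(np.float32)
    fc = (c - c0).astype(np.float32)
    flat = padded.ravel()
    idx = r0 * (w + 2) + c0
    v00 = flat[idx]
    v01 = flat[idx + 1]
    v10 = flat[idx + w + 2]
    v11 = flat[idx + w + 3]
    top = v00 + fc * (v01 - v00)
    bot = v10 + fc * (v11 - v10)
    return top + fr * (bot - top)


def _center_run_lengths(values: np.ndarray, step: float) -> np.ndarray:
    """Per-angle length of the in-mask run containing the centre sample.

    ``values`` is (n_angles, n_samples) with the centroid at the middle
    sample; each row is the bilinearly interpolated mask along one
    orientation.  Run ends are located by linear interpolation of the 0.5
    crossing between the last inside and first outside sample.
    """
    n_angles, n_samples = values.shape
    mid = n_samples // 2
    inside = values >= 0.5

    # first outside sample to each side of the centre, per angle
    right = inside[:, mid:]
    out_r = np.argmax(~right, axis=1)          # 0 if centre itself outside
    out_r[right.all(axis=1)] = right.shape[1]  # never exits: clip at end
    left = inside[:, mid::-1]
    out_l = np.argmax(~left, axis=1)
    out_l[left.all(axis=1)] = left.shape[1]

    def edge_offset(out_idx: np.ndarray, sign: int) -> np.ndarray:
        idx_in = np.clip(out_idx - 1, 0, None)
        cols_in = mid + sign * idx_in
        cols_out = np.clip(mid + sign * out_idx, 0, n_samples - 1)
        rows = np.arange(n_angles)
        v_in = values[rows, cols_in]
        v_out = values[rows, cols_out]
        denom = v_in - v_out
        frac = np.where(denom > 0, (v_in - 0.5) / np.where(denom == 0, 1, denom), 0.0)
        return np.where(out_idx > 0, (idx_in + np.clip(frac, 0, 1)) * step, 0.0)

    center_len = edge_offset(out_r, +1) + edge_offset(out_l, -1)
    return np.where(inside[:, mid], center_len, 0.0)


def _longest_run_lengths(values: np.ndarray, step: float) -> np.ndarray:
    """Per-angle length of the longest in-mask run (crescent fallback)."""
    n_angles = values.shape[0]
    inside = values >= 0.5
    longest = np.zeros(n_angles)
    for i in range(n_angles):
        row = inside[i]
        if not row.any():
            continue
        padded = np.concatenate(([False], row, [False]))
        d = np.diff(padded.astype(int))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        longest[i] = (ends - starts).max() * step
    return longest


def minimum_diameter(
    vm: VesselMask,
    angular_step_deg: float = 1.0,
    sample_step_px: float = 0.25,
    soft_mask: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Minimum chord length through the mask centroid, in pixels.

    The mask is smoothed with a small Gaussian so that boundary-pixel
    counts recover sub-pixel edge positions; orientations are swept over
    [0, 180) degrees at ``angular_step_deg`` resolution, the smoothed mask
    is sampled along each orientation at ``sample_step_px`` with bilinear
    interpolation, and the in-mask run containing the centroid is measured
    between interpolated 0.5 crossings.  The minimum over orientations is
    then compensated for the inward bias smoothing imposes on a curved
    edge, using the local curvature radius implied by the minimum and
    maximum chords (for an ellipse, a^2/b at the minor-axis endpoints).

    When ``soft_mask`` is given (the adjusted intensity image restricted
    to the selected component, values in [0, 1]), edges are localized on
    it instead of on the binary mask: boundary-pixel intensities encode
    the sub-pixel edge position that binarization quantizes away, so a
    much smaller smoothing suffices.  This is the path the per-frame
    extraction uses; the binary path serves masks without intensity
    information.

    Returns ``(diameter_px, outlier_flag)``; the flag is set when the
    centroid falls outside the mask (e.g. a crescent), in which case the
    longest in-mask run per orientation is used instead.
    """
    if vm.is_empty:
        raise ValueError("cannot measure an empty mask")
    if soft_mask is not None:
        sigma = 1.0
        mask_f = ndimage.gaussian_filter(
            np.asarray(soft_mask, dtype=np.float32), sigma
        )
    else:
        sigma = _smoothing_sigma(vm.area_px)
        mask_f = ndimage.gaussian_filter(vm.mask.astype(np.float32), sigma)
    rows, cols = np.nonzero(vm.mask)
    cr, cc = vm.centroid_rc
    # radius bound: farthest mask pixel from the centroid + smoothing tail
    r_max = float(np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2).max()) + 2.0 + 3.0 * sigma

    angles = np.deg2rad(np.arange(0.0, 180.0, angular_step_deg))
    radii = np.arange(-r_max, r_max + sample_step_px, sample_step_px)
    # centre the sample grid exactly on the centroid
    mid = len(radii) // 2
    radii = radii - radii[mid]

    rr = cr + np.cos(angles)[:, None] * radii[None, :]
    cc_ = cc + np.sin(angles)[:, None] * radii[None, :]
    values = _bilinear_sample(mask_f, rr, cc_)

    centroid_inside = bool(values[0, mid] >= 0.5)
    if centroid_inside:
        center_len = _center_run_lengths(values, sample_step_px)
        d_min = float(center_len.min())
        d_max = float(center_len.max())
        outlier = False
    else:
        longest = _longest_run_lengths(values, sample_step_px)
        valid = longest > 0
        if not valid.any():
            return 0.0, True
        d_min = float(longest[valid].min())
        d_max = float(longest[valid].max())
        outlier = True
    if d_min <= 0:
        return 0.0, True
    curv_radius = (d_max / 2.0) ** 2 / (d_min / 2.0)
    return d_min + 2.0 * _edge_shift(curv_radius, sigma), outlier


def extract_diameter_trace(
    stack: ImageStack, params: SegmentationParams | None = None
) -> DiameterTrace:
    """Measure the vessel's minimum diameter on every frame of a trial.

    Runs adjust -> binarize -> component selection -> minimum chord per
    frame, carrying the previous frame's centroid as a tracking hint, and
    converts pixels to micrometres.  Frames with an empty mask or a mask
    touching the image border are flagged and their values linearly
    interpolated in time from neighbouring ok frames.  If more than
    ``params.max_flagged_fraction`` of frames are flagged the whole trial
    is rejected with :class:`TrialQualityError`.
    """
    params = params or SegmentationParams()
    n = stack.n_frames
    values = np.full(n, np.nan)
    quality: list[str] = [QUALITY_EMPTY] * n
    prev_centroid: tuple[float, float] | None = None

    for k in range(n):
        adjusted = adjust_intensity(stack.frames[k], params.low_pct, params.high_pct)
        mask = binarize(adjusted, params.threshold_method, params.fixed_threshold)
        vm = select_vessel_component(mask, prev_centroid)
        if vm.is_empty:
            quality[k] = QUALITY_EMPTY
            continue
        prev_centroid = vm.centroid_rc
        if vm.touches_border:
            quality[k] = QUALITY_BORDER
            continue
        # sub-pixel edges come from the adjusted intensities inside the
        # selected component (slightly dilated so the intensity ramp at
        # the boundary is retained)
        region = ndimage.binary_dilation(vm.mask, iterations=3)
        soft = np.where(region, adjusted, 0.0)
        diam_px, outlier = minimum_diameter(
            vm, params.angular_step_deg, params.sample_step_px, soft_mask=soft
        )
        values[k] = diam_px * stack.pixel_size_um
        quality[k] = QUALITY_OUTLIER if outlier else QUALITY_OK

    good = np.array([q == QUALITY_OK for q in quality])
    n_flagged = int((~good).sum())
    if n_flagged > params.max_flagged_fraction * n:
        raise TrialQualityError(
            f"{n_flagged}/{n} frames failed quality checks "
            f"(limit {params.max_flagged_fraction:.0%})"
        )
    if n_flagged:
        idx = np.arange(n)
        # outlier frames have a (suspect) measured value already; empty and
        # border frames get time-interpolated values
        missing = np.isnan(values)
        if missing.any():
            values[missing] = np.interp(idx[missing], idx[~missing], values[~missing])
    return DiameterTrace(values, quality, stack.frame_rate_hz, stack.pixel_size_um)
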