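# Methods

## Scope and data model

`lumenpulse` analyzes stimulus-locked cross-section movies of penetrating
arterioles. One *trial* is a T×H×W stack with frame rate and pixel size;
an *arteriole–session* is a set of trials sharing a stimulation protocol;
a *study* is a hierarchy groups → mice → arterioles → timepoints. The
default protocol is 25 s trials at 9.45 Hz with a 5 s stimulus at second
10, basal window from second 3 to onset (half-open), response window
[10 s, 15 s] (closed — the onset frame belongs to the response), and 10
trials per arteriole. Frame *k* is timestamped *k/f*; coordinates are
(row, col), 0-based, pixel centers at integers.

## Diameter measurement

Per frame the chain is: percentile intensity adjustment (1st–99th
percentile linear stretch, clipped — robust to hot pixels and bleaching,
and it makes the measurement invariant to detector gain), binarization
(Otsu's between-class-variance threshold by default; a fixed threshold
can be supplied), connected-component selection (8-connectivity, holes
filled; the previous frame's centroid is a tracking hint, otherwise the
largest component), and the minimum chord through the component's area
centroid, swept over orientations in [0°, 180°) at 1° steps with 0.25 px
sampling along each ray. For an elliptical lumen the minimum central
chord is the minor axis, which is the quantity reported as the vessel's
minimum diameter. An alternative reading (minimal Feret diameter) gives
the same value for convex cross-sections; chord-through-centroid is the
implemented contract.

### Sub-pixel edge localization

A binary mask quantizes the vessel edge to the pixel grid, which limits
any chord reading to roughly half-pixel accuracy and, in the worst case —
an edge exactly tangent to a pixel row or column — biases the mask itself
by up to ~1 px. Two mechanisms recover sub-pixel accuracy:

* **Binary masks** (the geometry-oracle path): the mask is smoothed with
  a Gaussian whose width scales with mask area (σ = 0.125·√area, clamped
  to [1.0, 2.2] px) so that boundary-pixel counts pool into a sub-pixel
  edge estimate; chords are measured between linearly interpolated
  0.5-crossings of the smoothed mask. Smoothing shifts a curved edge
  inward, so the result is compensated using the exact radial profile of
  a Gaussian-smoothed disk (inverted from a precomputed table), with the
  local curvature radius estimated from the measured minimum and maximum
  chords (a²/b at an ellipse's minor-axis endpoints). Residual error for
  generic sub-pixel placements is ≲0.35 px; exact lattice-tangent
  alignments remain a documented limitation (the information is absent
  from the mask, not merely unexploited).

* **Intensity-weighted masks** (the movie-extraction path): boundary
  pixels of a fluorescence image carry the sub-pixel edge position in
  their partial-volume intensities. `extract_diameter_trace` therefore
  measures chords on the adjusted intensities restricted to the selected
  component (lightly smoothed, σ = 1 px, same curvature compensation).
  This reaches ~0.01 px per-frame repeatability on clean renders and is
  what makes 1-frame peak-time resolution possible at 5% dilations.

### Frame quality

Frames whose mask is empty or touches the image border are flagged and
their values linearly interpolated in time from neighbouring good frames;
flagged frames never enter basal statistics. A frame whose centroid falls
outside the mask (e.g. a crescent artifact) falls back to the longest
in-mask run and is flagged as an outlier, keeping its measured value.
A trial with more than 50% flagged frames is rejected outright. These
policies are explicit contracts rather than reconstructions of any
particular acquisition system's behaviour.

## Response metrics

Each trial is normalized to its own basal mean (basal = 100%) before
averaging — averaging raw diameters would let a large vessel dominate.
On the trial-averaged trace: Amplitude is the maximum over the closed
response window (ties → earliest frame, so t_Max is deterministic);
t_Max is the time from onset to that frame; t_Amp50% is the first
crossing of 100 + (Amplitude − 100)/2, linearly interpolated between
frames because 9.45 Hz sampling (106 ms/frame) is coarse relative to
sub-second rise times; AUC integrates (trace − 100) trapezoidally over
the window so a null response integrates to zero. t_Amp50% is referenced
to the dilation above baseline, not to 50% of the absolute normalized
value (which would precede the stimulus for any trace). A trace never
exceeding 100% in the window is returned with a no-response flag and
t_Amp50% = t_Max. Longitudinal change is 100·(current − reference)/
reference on the chosen metric, using Amplitude − 100 for amplitude.

## Synthetic benchmark

The generator renders what the microscope sees: a filled ellipse
(plasma-labelled lumen) of intensity 1.0 on a 0.1 background,
area-coverage anti-aliased (supersampled only in a boundary band, so
sub-pixel diameter changes of ~0.1 px move boundary-pixel coverage
continuously), with per-frame rigid translation jitter (default SD 1 px)
and additive Gaussian read noise (default SD 0.18, i.e. contrast-to-noise
≈ 5 — deliberately awake-imaging-like), optional Poisson shot noise.
Dilation kinetics are a linear ramp to peak followed by exponential
relaxation (τ = 2 s); the true kinetic form in vivo is unknown, so the
rise shape is pluggable (`gamma-like` power rise) and the analysis makes
no kinetic assumption. Dilation scales both axes isotropically so the
ground-truth "diameter" is exactly the minor axis. The peak is snapped to
the frame nearest onset + t_max so the true peak value is attained on a
sampled frame. Default geometry: 20 µm basal diameter, ellipticity 1.2,
0.4–0.5 µm/px (the acquisition's pixel size is configurable; these
values correspond to a zoomed two-photon field of view of ~50–80 µm).

Sessions draw per-arteriole truths as group mean + mouse effect +
arteriole effect with explicit SDs (defaults: amplitude 15% ± 2% between
mice ± 3% between arterioles; t_max 2.5 s ± 0.3/0.4 s; basal 20 ± 3 µm;
8 mice/group, 2–6 arterioles/mouse), matching the hierarchy the nested
statistics assume. One global seed expands through `SeedSequence`
spawning into independent per-trial streams, so sessions are
bit-reproducible.

What the generator does **not** emulate: wall labelling (only the lumen
is bright), red-blood-cell shadows, slow drift and focal changes,
breathing-locked motion, neighbouring vessels, or photobleaching.
Passing the benchmark therefore demonstrates correctness of the
measurement chain and its statistics under realistic noise and motion —
not robustness to every artifact of real awake imaging.

## IOS activity mapping

Each reflectance trial yields a per-pixel ΔR/R map ((response mean −
baseline mean)/baseline mean); the activity map is the sum over trials
(30 trials of 1.5 s stimulation with 20 s breaks in the emulated
paradigm). Under ~630 nm light an activated region absorbs more, so the
signal of interest is negative-going; the extremum sign is always an
explicit parameter. `locate_peak_region` thresholds |map| at a fraction
(default 0.5) of the chosen extremum and returns the largest connected
suprathreshold region with its magnitude-weighted centroid. No smoothing
is applied to the map; the response window defaults to the stimulation
period plus 1 s of hemodynamic lag and is configurable.

## Nested statistics

Arterioles are pseudo-replicates of a mouse. `nested_compare` aggregates
to one observation per mouse (the mean of its arterioles) and tests at
that level: a two-sample t-test for two groups, one-way ANOVA with
Tukey–Kramer follow-ups (studentized range at mouse-level degrees of
freedom) for more, and a two-way ANOVA on mouse means for crossed
between-mouse factors. Between- and within-mouse variance components are
estimated from the classical nested-ANOVA expected mean squares (the
unbalanced-design coefficient; negative estimates truncated at zero) and
reported with every result. This mouse-level formulation was chosen over
an iterative REML random-intercept fit because it is exactly equivalent
in balanced designs (and reduces exactly to the mouse-means t-test, a
contract the tests verify to 1e-10), is deterministic, has no
convergence failure modes at variance boundaries, and its type-I error
calibrates at the nominal level under the generator's null (verified at
1000 replicates). With unequal arteriole counts per mouse the mouse
means are mildly heteroscedastic; with equal group sizes the t-test is
robust to this, and the calibration test covers exactly that design.
Repeated-measures ANOVA with sphericity corrections is out of scope;
longitudinal contrasts are paired mouse-level comparisons via percent
change. Pearson correlations (with two-sided p from the t transform and
the least-squares line) are provided for metric–covariate associations.

## Problem sizes in tests

The validation suite measures: geometry oracles on disks (r = 5–20 px),
ellipses (b = 4–20 px, ellipticity 1–2.5, rotated) and squares, against
analytic values at ±0.5 px with a 0.1° sweep cross-check at 0.2 px; a
27-point zero-noise truth grid (basal 15–30 µm × amplitude 5–30% × t_max
1–4 s) recovered to 1 px-equivalent basal, 1 percentage-point amplitude,
1 frame t_max; 50 replicate arterioles at contrast-to-noise ≈ 5 with
1 px jitter (25 with 16 trials, 25 with 10) for the 10-trial-averaging
claim and the 1/√n peak-SD scaling over n ∈ {1, 4, 16}; 1000 null
replicates for calibration; 30-trial IOS sessions at per-trial SNR ≈ 0.5;
and two full pipeline runs for bit-level determinism. The acceptance
script re-runs a reduced version of each (its JSON output records the
sizes used).

## Known limitations

* Lattice-tangent rasterization: a vessel edge exactly aligned with the
  pixel grid biases a *binary*-mask reading by up to ~1 px; the
  intensity-weighted path used on movies does not suffer from this.
* The no-response flag uses a hard threshold (amplitude ≤ 100%); very
  small responses at high noise may flip between flagged and unflagged.
* Two-way designs are supported only for between-mouse factors; no
  random slopes, no repeated-measures covariance structure.
* The IOS module localizes a single dominant activation; overlapping
  foci of similar strength are returned as whichever region is larger.
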