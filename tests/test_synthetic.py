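"""Synthetic-trial generator: kinetics, rendering, sessions, dosing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumenpulse import (
    DEFAULT_PROTOCOL,
    StimulusProtocol,
    VesselGroundTruth,
    generate_diameter_timecourse,
    generate_session,
    render_trial,
)
from lumenpulse.dosing import DoseInputs, insulin_dose
from lumenpulse.synthetic import (
    NOISELESS,
    GeometryError,
    GroupSpec,
    NoiseModel,
    SessionDesign,
    draw_session_truth,
)


class TestDiameterTimecourse:
    def test_zero_amplitude_gives_constant_trace(self, protocol):
        truth = VesselGroundTruth(basal_diameter_um=20.0, dilation_amplitude_pct=0.0)
        trace = generate_diameter_timecourse(truth, protocol)
        assert np.allclose(trace, 20.0)

    def test_peak_value_at_frame_nearest_peak_time(self, protocol):
        truth = VesselGroundTruth(
            basal_diameter_um=20.0, dilation_amplitude_pct=15.0, t_max_s=2.5
        )
        trace = generate_diameter_timecourse(truth, protocol)
        t = protocol.time_axis()
        k = np.argmin(np.abs(t - 12.5))
        assert trace[k] == pytest.approx(23.0)
        assert trace[t < protocol.stim_onset_s].max() == pytest.approx(20.0)
        win = (t >= 10.0) & (t <= 15.0)
        assert trace[win].max() == pytest.approx(23.0)

    def test_monotone_rise_and_exponential_return(self, protocol):
        truth = VesselGroundTruth(
            dilation_amplitude_pct=20.0, t_max_s=3.0, decay_tau_s=1.5
        )
        trace = generate_diameter_timecourse(truth, protocol)
        t = protocol.time_axis()
        k_peak = int(np.argmax(trace))
        rising = trace[(t > 10.0) & (t <= t[k_peak])]
        assert np.all(np.diff(np.concatenate([[20.0], rising])) >= -1e-12)
        after = trace[k_peak:]
        assert np.all(np.diff(after) <= 1e-12)
        assert after[-1] > truth.basal_diameter_um  # decays toward, never below

    def test_gamma_like_rise_is_slower_early(self, protocol):
        lin = generate_diameter_timecourse(
            VesselGroundTruth(rise_shape="linear-ramp"), protocol
        )
        gam = generate_diameter_timecourse(
            VesselGroundTruth(rise_shape="gamma-like", rise_power=2.0), protocol
        )
        t = protocol.time_axis()
        early = (t > 10.2) & (t < 11.5)
        assert np.all(gam[early] <= lin[early])
        assert gam.max() == pytest.approx(lin.max())

    def test_peak_beyond_trial_end_rejected(self, protocol):
        with pytest.raises(ValueError, match="beyond"):
            generate_diameter_timecourse(
                VesselGroundTruth(t_max_s=20.0), protocol
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        amp=st.floats(1.0, 40.0),
        t_max=st.floats(0.3, 4.5),
        basal=st.floats(10.0, 40.0),
    )
    def test_prestimulus_always_basal_and_peak_exact(self, amp, t_max, basal):
        protocol = DEFAULT_PROTOCOL
        truth = VesselGroundTruth(
            basal_diameter_um=basal, dilation_amplitude_pct=amp, t_max_s=t_max
        )
        trace = generate_diameter_timecourse(truth, protocol)
        t = protocol.time_axis()
        assert np.allclose(trace[t <= protocol.stim_onset_s], basal)
        assert trace.max() == pytest.approx(basal * (1 + amp / 100.0), rel=1e-12)


class TestRenderTrial:
    def test_noiseless_frames_are_two_valued_outside_edge_band(self, noiseless_trial):
        frame = noiseless_trial.stack.frames[0]
        background = NOISELESS.background_intensity
        vessel = NOISELESS.vessel_intensity
        at_bg = np.isclose(frame, background).sum()
        at_vessel = np.isclose(frame, vessel).sum()
        intermediate = frame.size - at_bg - at_vessel
        # anti-aliased boundary band is a thin ring: roughly the perimeter
        minor_px = noiseless_trial.truth_trace[0] / 0.5
        assert intermediate < 4 * np.pi * minor_px
        assert at_bg > 0 and at_vessel > 0

    def test_same_seed_is_bit_identical(self, protocol):
        truth = VesselGroundTruth(center_rc=(55.5, 55.5), pixel_size_um=0.5)
        trace = generate_diameter_timecourse(truth, protocol)
        noise = NoiseModel(seed=7)
        a = render_trial(trace, truth, noise, protocol, shape=(112, 112))
        b = render_trial(trace, truth, noise, protocol, shape=(112, 112))
        assert np.array_equal(a.stack.frames, b.stack.frames)

    def test_disk_pixel_count_matches_analytic_area(self, protocol):
        # circular cross-section, minor axis 20 px: suprathreshold pixel
        # count approximates pi * r^2 within an edge-band tolerance
        truth = VesselGroundTruth(
            basal_diameter_um=10.0,
            dilation_amplitude_pct=0.0,
            ellipticity=1.0,
            center_rc=(47.63, 47.21),
            pixel_size_um=0.5,
        )
        trace = generate_diameter_timecourse(truth, protocol)
        trial = render_trial(trace, truth, NOISELESS, protocol, shape=(96, 96))
        count = (trial.stack.frames[0] > 0.55).sum()
        assert count == pytest.approx(np.pi * 10.0**2, abs=2 * np.pi * 10.0)

    def test_vessel_clipped_by_border_rejected(self, protocol):
        truth = VesselGroundTruth(center_rc=(10.0, 55.0), pixel_size_um=0.5)
        trace = generate_diameter_timecourse(truth, protocol)
        with pytest.raises(GeometryError):
            render_trial(trace, truth, NOISELESS, protocol, shape=(112, 112))

    def test_truth_trace_length_matches_stack(self, noiseless_trial):
        assert len(noiseless_trial.truth_trace) == noiseless_trial.stack.n_frames


class TestSessionGeneration:
    def test_zero_variance_two_identical_groups_share_truth(self):
        design = SessionDesign(
            groups=(GroupSpec("a"), GroupSpec("b")),
            n_mice_per_group=3,
            pas_per_mouse=(2, 2),
            sd_basal_um=0.0,
            mouse_sd_amplitude_pct=0.0,
            pa_sd_amplitude_pct=0.0,
            mouse_sd_t_max_s=0.0,
            pa_sd_t_max_s=0.0,
            seed=1,
        )
        truth = draw_session_truth(design)
        assert truth["dilation_amplitude_pct"].nunique() == 1
        assert truth["t_max_s"].nunique() == 1
        assert truth["basal_diameter_um"].nunique() == 1

    def test_group_offset_appears_exactly_in_truth_table(self):
        design = SessionDesign(
            groups=(GroupSpec("a"), GroupSpec("b", t_max_offset_s=1.0)),
            mouse_sd_t_max_s=0.0,
            pa_sd_t_max_s=0.0,
            seed=2,
        )
        truth = draw_session_truth(design)
        means = truth.groupby("group")["t_max_s"].mean()
        assert means["b"] - means["a"] == pytest.approx(1.0)

    def test_between_mouse_variance_matches_specification(self):
        # moment check: with no PA-level scatter the variance of mouse
        # means equals the stated mouse-level variance component
        design = SessionDesign(
            groups=(GroupSpec("a"),),
            n_mice_per_group=8,
            mouse_sd_amplitude_pct=2.0,
            pa_sd_amplitude_pct=0.0,
        )
        mouse_means = []
        for rep in range(250):
            t = draw_session_truth(
                SessionDesign(**{**design.__dict__, "seed": 10_000 + rep})
            )
            mouse_means.extend(t.groupby("mouse_id")["dilation_amplitude_pct"].mean())
        mouse_means = np.asarray(mouse_means)
        var = mouse_means.var(ddof=1)
        n = len(mouse_means)
        mc_se = 4.0 * np.sqrt(2.0 / (n - 1))
        assert abs(var - 4.0) < 3 * mc_se

    def test_session_determinism_and_structure(self, protocol):
        design = SessionDesign(
            groups=(GroupSpec("a"), GroupSpec("b")),
            n_mice_per_group=2,
            pas_per_mouse=(2, 3),
            seed=5,
        )
        _, t1 = generate_session(design, protocol, render=False)
        _, t2 = generate_session(design, protocol, render=False)
        assert t1.equals(t2)
        # each PA belongs to exactly one mouse; one row per trial
        assert (t1.groupby("pa_id")["mouse_id"].nunique() == 1).all()
        per_pa = t1.groupby("pa_id")["trial_id"].count()
        assert (per_pa == protocol.n_trials).all()
        pas = t1.groupby("mouse_id")["pa_id"].nunique()
        assert pas.between(2, 3).all()


class TestInsulinDose:
    @pytest.mark.parametrize(
        "weight, glucose, dose, per_kg, in_range",
        [
            (0.0, 500.0, 0.0, 0.0, False),
            (0.025, 400.0, 0.075, 3.0, True),
            (0.030, 600.0, 0.135, 4.5, False),
            (0.020, 100.0, 0.015, 0.75, False),
        ],
    )
    def test_printed_formula_and_range_flag(self, weight, glucose, dose, per_kg, in_range):
        res = insulin_dose(DoseInputs(weight, glucose))
        assert res.dose_ui == pytest.approx(dose)
        assert res.dose_ui_per_kg == pytest.approx(per_kg)
        assert res.in_range is in_range

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            DoseInputs(-0.02, 300.0)
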