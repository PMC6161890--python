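"""PAC estimators: closed forms, invariances, alignment, blind spots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pacbank as pb
from pacbank.errors import AlignmentError, DataError, ParameterError
from pacbank.metrics import PhaseAmplitudeDistribution

from conftest import RATE, SEGMENT, pair_pac


def make_pad(probs):
    probs = np.asarray(probs, dtype=float)
    j = probs.size
    return PhaseAmplitudeDistribution(
        probs, np.linspace(-np.pi, np.pi, j + 1), np.ones(j, dtype=int)
    )


class TestClosedForms:
    def test_mi_uniform_is_zero(self):
        assert pb.pac_mi(make_pad(np.full(18, 1 / 18))).value == pytest.approx(
            0.0, abs=1e-12
        )

    def test_mi_one_hot_is_one(self):
        one_hot = np.zeros(18)
        one_hot[4] = 1.0
        assert pb.pac_mi(make_pad(one_hot)).value == pytest.approx(1.0, abs=1e-12)

    def test_mi_two_equal_bins(self):
        probs = np.zeros(18)
        probs[0] = probs[1] = 0.5
        expected = 1.0 - np.log(2.0) / np.log(18.0)
        assert pb.pac_mi(make_pad(probs)).value == pytest.approx(
            expected, abs=1e-12
        )

    def test_hr_uniform_zero_and_empty_bin_one(self):
        assert pb.pac_hr(make_pad(np.full(18, 1 / 18))).value == pytest.approx(
            0.0, abs=1e-12
        )
        probs = np.full(18, 1 / 17.0)
        probs[3] = 0.0
        assert pb.pac_hr(make_pad(probs)).value == pytest.approx(1.0, abs=1e-12)

    def test_hr_direct_ratio(self):
        # p_max = 0.2, p_min = 0.05 -> HR = 1 - 0.05/0.2 = 0.75
        probs = np.array([0.2, 0.05, 0.1875, 0.1875, 0.1875, 0.1875])
        assert pb.pac_hr(make_pad(probs)).value == pytest.approx(0.75, abs=1e-12)

    def test_mvl_single_phase_is_one(self):
        phase = pb.PhaseSeries(np.full(1000, 0.7), RATE)
        amp = pb.AmplitudeSeries(np.full(1000, 3.3), RATE)
        assert pb.pac_mvl(phase, amp).value == pytest.approx(1.0, abs=1e-12)

    def test_mvl_uniform_phase_cancels(self):
        n = 9000
        phase = pb.PhaseSeries(
            np.angle(np.exp(2j * np.pi * np.arange(n) / 90.0)), RATE
        )
        amp = pb.AmplitudeSeries(np.ones(n), RATE)
        assert pb.pac_mvl(phase, amp).value < 3.0 / np.sqrt(n)


class TestPadEstimate:
    def test_uniform_phases_give_uniform_pad(self):
        n = 18000
        phase = pb.PhaseSeries(
            np.angle(np.exp(2j * np.pi * np.arange(n) / 360.0)), RATE
        )
        amp = pb.AmplitudeSeries(np.full(n, 2.0), RATE)
        pad = pb.pad_estimate(phase, amp, 18)
        assert np.allclose(pad.probabilities, 1 / 18.0, atol=2 / np.sqrt(n))

    def test_single_bin_phases_give_one_hot(self):
        # phases at a bin centre: unaffected by the half-bin dither
        width = 2 * np.pi / 18
        centre_phase = -np.pi + 3.5 * width
        phase = pb.PhaseSeries(np.full(500, centre_phase), RATE)
        amp = pb.AmplitudeSeries(np.ones(500), RATE)
        with pytest.warns(pb.DataSufficiencyWarning):
            pad = pb.pad_estimate(phase, amp, 18)
        expected = np.zeros(18)
        expected[3] = 1.0
        assert np.allclose(pad.probabilities, expected)

    def test_pad_normalization_and_errors(self):
        phase = pb.PhaseSeries(np.linspace(-3, 3, 100), RATE)
        amp = pb.AmplitudeSeries(np.abs(np.sin(np.arange(100.0))), RATE)
        pad = pb.pad_estimate(phase, amp, 18)
        assert pad.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ParameterError):
            pb.pad_estimate(phase, pb.AmplitudeSeries(np.ones(7), RATE), 18)
        with pytest.raises(DataError):
            pb.pad_estimate(phase, pb.AmplitudeSeries(np.zeros(100), RATE), 18)

    def test_generated_signal_pad_peaks_at_envelope_peak_phase(
        self, clean_signal, pair_plan
    ):
        """The envelope (P=1) peaks where sin(w t + pi) = 1, i.e. where the
        modulator sin(w t) is at -1: phase -pi/2 of its analytic signal."""
        low, high = pb.analytic_filter_segment(clean_signal, pair_plan)
        phase, amp = pb.to_phase_amplitude(low, high)
        p_up, a_up = pb.align_multirate(phase, amp)
        pad = pb.pad_estimate(p_up, a_up, 18)
        edges = pad.bin_edges
        peak_bin = int(np.argmax(pad.probabilities))
        lo, hi = edges[peak_bin], edges[peak_bin + 1]
        # modulator phase at envelope max: sin(x) = -1 -> x = -pi/2; the
        # analytic-signal angle of sin is shifted by -pi/2 -> expect -pi
        expected = np.angle(np.exp(1j * (-np.pi / 2 - np.pi / 2)))
        span = hi - lo
        assert (
            lo - span <= expected <= hi + span
            or abs(abs(expected) - np.pi) < span
        )


class TestAlignment:
    def test_identity_at_equal_rates(self):
        phase = pb.PhaseSeries(np.linspace(-3, 3, 64), 32.0)
        amp = pb.AmplitudeSeries(np.arange(64.0), 32.0)
        p, a = pb.align_multirate(phase, amp)
        assert np.array_equal(p.values, phase.values)
        assert np.array_equal(a.values, amp.values)

    def test_upsampled_ramp_matches_closed_form(self):
        f_sig, coarse, fine = 3.0, 32.0, 128.0
        n_c = 100
        phase = pb.PhaseSeries(
            np.angle(np.exp(2j * np.pi * f_sig * np.arange(n_c) / coarse)),
            coarse,
        )
        amp = pb.AmplitudeSeries(np.ones(n_c * 4), fine)
        p_up, _ = pb.align_multirate(phase, amp)
        truth = np.angle(np.exp(2j * np.pi * f_sig * np.arange(n_c * 4) / fine))
        err = np.abs(np.angle(np.exp(1j * (p_up.values - truth))))
        assert err.max() < 1e-6

    def test_non_integer_ratio_rejected(self):
        phase = pb.PhaseSeries(np.zeros(10), 32.0)
        amp = pb.AmplitudeSeries(np.ones(15), 48.0)
        with pytest.raises(AlignmentError, match="48"):
            pb.align_multirate(phase, amp)

    def test_carrier_detrending_handles_near_nyquist_phase(self):
        """A 16 Hz band at a 32 Hz decimated rate sits at Nyquist; the
        carrier-aware unwrap must still reconstruct the fine-grid ramp."""
        n_c, k = 128, 32
        coarse_rate = 32.0
        phase_vals = np.angle(
            np.exp(2j * np.pi * 16.0 * np.arange(n_c) / coarse_rate - 0.5j)
        )
        phase = pb.PhaseSeries(phase_vals, coarse_rate, centre=15.0)
        amp = pb.AmplitudeSeries(np.ones(n_c * k), coarse_rate * k)
        p_up, _ = pb.align_multirate(phase, amp)
        truth = np.angle(
            np.exp(2j * np.pi * 16.0 * np.arange(n_c * k) / (coarse_rate * k) - 0.5j)
        )
        err = np.abs(np.angle(np.exp(1j * (p_up.values[:-k] - truth[:-k]))))
        assert err.max() < 1e-9


class TestPipelineProperties:
    def test_mi_nondecreasing_in_coupling_strength(self, pair_plan):
        values = []
        for p in np.linspace(0.0, 1.0, 11):
            sig = pb.generate_pac_signal(pb.GeneratorParams(pac_level=float(p)))
            values.append(pair_pac(sig, pair_plan, "mi"))
        assert all(np.diff(values) >= -1e-12)

    def test_phase_rotation_invariance(self):
        rng = np.random.default_rng(5)
        phi = rng.uniform(-np.pi, np.pi, 5000)
        amp_vals = rng.gamma(2.0, 1.0, 5000)
        amp = pb.AmplitudeSeries(amp_vals, RATE)
        for shift in (0.3, 1.7, -2.2):
            rotated = np.angle(np.exp(1j * (phi + shift)))
            base_pad = pb.pad_estimate(pb.PhaseSeries(phi, RATE), amp, 18)
            rot_pad = pb.pad_estimate(pb.PhaseSeries(rotated, RATE), amp, 18)
            # MVL norm is exactly rotation-invariant
            v0 = pb.pac_mvl(pb.PhaseSeries(phi, RATE), amp).value
            v1 = pb.pac_mvl(pb.PhaseSeries(rotated, RATE), amp).value
            assert v0 == pytest.approx(v1, abs=1e-12)
            # binned metrics are invariant up to bin re-alignment
            assert pb.pac_mi(base_pad).value == pytest.approx(
                pb.pac_mi(rot_pad).value, abs=0.02
            )

    def test_multirate_mi_matches_full_rate(self, noisy_signal):
        kwargs = dict(phase_bandwidth=5.0, amp_bandwidth=150.0)
        plan_dec = pb.plan_filterbank([16.0], [130.0], RATE, SEGMENT, **kwargs)
        plan_full = pb.plan_filterbank(
            [16.0], [130.0], RATE, SEGMENT, decimate=False, **kwargs
        )
        v_dec = pair_pac(noisy_signal, plan_dec, "mi")
        v_full = pair_pac(noisy_signal, plan_full, "mi")
        assert abs(v_dec - v_full) / v_full < 0.02

    def test_mvl_blind_to_opposed_bimodal_coupling_but_mi_is_not(self):
        """Two envelope modes at opposite phases cancel the mean vector."""
        n = np.arange(SEGMENT)
        w_p = 2 * np.pi * 16.0 / RATE
        w_a = 2 * np.pi * 130.0 / RATE
        env = np.exp(2.0 * np.cos(2 * w_p * n))
        env = 0.5 * env / env.max()
        sig = pb.RawSignal(np.sin(w_p * n) + env * np.sin(w_a * n), RATE)
        plan = pb.plan_filterbank(
            [16.0], [130.0], RATE, SEGMENT,
            phase_bandwidth=5.0, amp_bandwidth=150.0,
        )
        mvl = pair_pac(sig, plan, "mvl")
        mi = pair_pac(sig, plan, "mi")
        assert mvl < 0.05
        assert mi > 0.1

    def test_plv_locked_and_generated(self, clean_signal, pair_plan):
        low, high = pb.analytic_filter_segment(clean_signal, pair_plan)
        phase, amp = pb.to_phase_amplitude(low, high)
        assert pb.pac_plv(low, amp).value > 0.9
        # identical phase series -> PLV exactly 1
        n = 2048
        phi = np.angle(np.exp(2j * np.pi * 16 * np.arange(n) / 1024.0))
        dphi = phi - phi
        assert np.abs(np.mean(np.exp(1j * dphi))) == pytest.approx(1.0)

    def test_plv_independent_phases_near_zero(self):
        rng = np.random.default_rng(9)
        n = 20000
        dphi = rng.uniform(-np.pi, np.pi, n)
        assert np.abs(np.mean(np.exp(1j * dphi))) < 3.0 / np.sqrt(n)


class TestRangeInvariant:
    @given(
        data=st.data(),
        n=st.integers(min_value=50, max_value=400),
        method=st.sampled_from(["mi", "hr", "mvl"]),
    )
    @settings(max_examples=40, deadline=None)
    def test_estimators_bounded_on_arbitrary_input(self, data, n, method):
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-np.pi, np.pi, n)
        amp_vals = rng.gamma(1.5, 2.0, n) + 1e-9
        phase = pb.PhaseSeries(phi, RATE)
        amp = pb.AmplitudeSeries(amp_vals, RATE)
        if method == "mvl":
            value = pb.pac_mvl(phase, amp).value
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pad = pb.pad_estimate(phase, amp, 18)
            value = (pb.pac_mi(pad) if method == "mi" else pb.pac_hr(pad)).value
        assert 0.0 <= value <= 1.0
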