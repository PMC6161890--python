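"""Filter bank: prototype design, planning, analytic filtering, oracle."""

import numpy as np
import pytest

import pacbank as pb
import pacbank.filterbank as fb
from pacbank.errors import PlanningError, SegmentLengthError

RATE = 16384.0
SEGMENT = 2**16


def band_response_on_grid(band, segment_length):
    """Full original-grid magnitude response of a planned band (one-sided)."""
    resp = np.zeros(segment_length)
    bins = (band.centre_bin + band.offsets) % segment_length
    resp[bins] = band.gains / 2.0
    return resp


class TestPrototype:
    def test_fir_passband_gain_unity_at_centre(self):
        spec = pb.PrototypeFilterSpec("fir_linear_phase", 8000, 5.0, 32.0)
        resp = pb.design_prototype(spec, 128)
        assert resp[0] == pytest.approx(1.0, rel=0.01)

    def test_fir_stopband_at_four_bandwidths(self):
        plan = pb.plan_filterbank(
            [100.0], [500.0], RATE, SEGMENT,
            phase_bandwidth=10.0, amp_bandwidth=100.0,
        )
        band = plan.phase_bands[0]
        resp = band_response_on_grid(band, SEGMENT)
        idx = int(round((band.centre + 4 * band.bandwidth) * SEGMENT / RATE))
        assert resp[idx] < 1e-3

    def test_butterworth_half_power_at_band_edge(self):
        spec = pb.PrototypeFilterSpec("iir_butterworth", 5, 5.0, 32.0)
        resp = pb.design_prototype(spec, 4096)
        freqs = np.abs(np.fft.fftfreq(4096, d=1.0 / 32.0))
        edge = np.argmin(np.abs(freqs - 2.5))
        assert resp[edge] == pytest.approx(1.0 / np.sqrt(2.0), rel=0.01)


class TestPlanning:
    def test_decimation_factor_for_ten_hz_band(self):
        plan = pb.plan_filterbank(
            [100.0], [500.0], RATE, SEGMENT,
            phase_bandwidth=10.0, amp_bandwidth=100.0,
        )
        band = plan.phase_bands[0]
        assert band.decim_factor == 256
        assert band.decimated_rate == 64.0
        assert band.decimated_rate >= 4 * band.bandwidth

    def test_band_count_is_m_plus_n(self, grid_plan):
        assert len(grid_plan.phase_bands) == 15
        assert len(grid_plan.amp_bands) == 15
        assert grid_plan.n_bands == 30

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(PlanningError):
            pb.plan_filterbank(
                [16.0], [8150.0], RATE, SEGMENT,
                phase_bandwidth=5.0, amp_bandwidth=200.0,
            )

    def test_integer_rate_ratio_guaranteed(self, grid_plan):
        for amp in grid_plan.amp_bands:
            for phase in grid_plan.phase_bands:
                ratio = amp.decimated_rate / phase.decimated_rate
                assert ratio == int(ratio) >= 1

    def test_plan_serializes_deterministically(self):
        mk = lambda: pb.plan_filterbank(
            [16.0], [130.0], RATE, SEGMENT,
            phase_bandwidth=5.0, amp_bandwidth=150.0,
        )
        assert mk().to_json() == mk().to_json()


class TestAnalyticFiltering:
    def test_in_band_tone_has_unit_envelope_and_centre_frequency(self):
        n = np.arange(SEGMENT)
        tone = pb.RawSignal(np.cos(2 * np.pi * 16.0 * n / RATE), RATE)
        plan = pb.plan_filterbank(
            [16.0], [130.0], RATE, SEGMENT,
            phase_bandwidth=5.0, amp_bandwidth=150.0,
        )
        out = pb.analytic_filter_segment(tone, plan)[0]
        interior = out.interior()
        assert np.allclose(np.abs(interior), 1.0, atol=0.02)
        dphi = np.diff(np.unwrap(np.angle(interior) - np.angle(interior)[0]
                                 - 2 * np.pi * 16.0 / out.rate
                                 * np.arange(interior.size)))
        inst_freq = 16.0 + np.median(dphi) * out.rate / (2 * np.pi)
        assert inst_freq == pytest.approx(16.0, abs=0.05)

    def test_out_of_band_energy_suppressed(self):
        n = np.arange(SEGMENT)
        tone = pb.RawSignal(np.cos(2 * np.pi * 300.0 * n / RATE), RATE)
        plan = pb.plan_filterbank(
            [16.0], [130.0], RATE, SEGMENT,
            phase_bandwidth=5.0, amp_bandwidth=40.0,
        )
        for out in pb.analytic_filter_segment(tone, plan):
            assert np.abs(out.interior()).max() < 1e-3

    def test_single_fft_per_segment(self, grid_plan, noisy_signal):
        before = fb.FFT_CALLS
        pb.analytic_filter_segment(noisy_signal, grid_plan)
        assert fb.FFT_CALLS - before == 1

    def test_linearity(self, pair_plan):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(SEGMENT)
        y = rng.standard_normal(SEGMENT)
        combined = pb.analytic_filter_segment(2.0 * x - 3.0 * y, pair_plan)
        fx = pb.analytic_filter_segment(x, pair_plan)
        fy = pb.analytic_filter_segment(y, pair_plan)
        for c, a, b in zip(combined, fx, fy):
            expected = 2.0 * a.samples - 3.0 * b.samples
            scale = np.abs(expected).max()
            assert np.allclose(c.samples, expected, atol=1e-9 * max(scale, 1))

    def test_segment_length_mismatch_rejected(self, pair_plan):
        with pytest.raises(SegmentLengthError):
            pb.analytic_filter_segment(np.zeros(1000), pair_plan)

    def test_envelope_invariant_under_decimation(self):
        params = dict(phase_bandwidth=5.0, amp_bandwidth=150.0)
        plan_dec = pb.plan_filterbank([16.0], [130.0], RATE, SEGMENT, **params)
        plan_full = pb.plan_filterbank(
            [16.0], [130.0], RATE, SEGMENT, decimate=False, **params
        )
        sig = pb.generate_pac_signal(pb.GeneratorParams(pac_level=1.0))
        high_dec = pb.analytic_filter_segment(sig, plan_dec)[1]
        high_full = pb.analytic_filter_segment(sig, plan_full)[1]
        env_dec = np.abs(high_dec.interior())
        env_full = np.abs(high_full.samples[:: plan_dec.amp_bands[0].decim_factor])
        b = high_dec.burn_in
        env_full = env_full[b: len(high_dec) - b]
        rel = np.abs(env_dec - env_full) / env_full.max()
        assert rel.max() < 0.01

    def test_zero_phase_no_envelope_delay(self):
        """An AM tone's envelope peak positions survive filtering unshifted."""
        n = np.arange(SEGMENT)
        env = 1.0 + 0.8 * np.sin(2 * np.pi * 4.0 * n / RATE)
        x = pb.RawSignal(env * np.cos(2 * np.pi * 130.0 * n / RATE), RATE)
        plan = pb.plan_filterbank(
            [16.0], [130.0], RATE, SEGMENT,
            phase_bandwidth=5.0, amp_bandwidth=40.0,
        )
        out = pb.analytic_filter_segment(x, plan)[1]
        m = plan.amp_bands[0].decim_factor
        b = out.burn_in
        got = np.abs(out.samples)[b:-b]
        expected = env[::m][b:-b]
        lags = np.arange(-4, 5)
        scores = [
            np.corrcoef(got[4 + lag: got.size - 4 + lag],
                        expected[4: -4])[0, 1]
            for lag in lags
        ]
        assert lags[int(np.argmax(scores))] == 0


class TestOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_frequency_domain_matches_time_domain_pipeline(self, seed):
        """Single-FFT band extraction vs convolution + Hilbert + decimation."""
        rng = np.random.default_rng(seed)
        x = pb.RawSignal(rng.standard_normal(SEGMENT), RATE)
        plan = pb.plan_filterbank(
            [15.0, 45.0], [130.0], RATE, SEGMENT,
            phase_bandwidth=5.0, amp_bandwidth=150.0,
        )
        fast = pb.analytic_filter_segment(x, plan)
        for band, out in zip(plan.bands, fast):
            ref = pb.reference_time_domain_filter(x, plan, band)
            k = band.retained_bins
            lo, hi = k // 10, k - k // 10
            err = np.sqrt(np.mean(np.abs(out.samples[lo:hi] - ref.samples[lo:hi]) ** 2))
            rms = np.sqrt(np.mean(np.abs(ref.samples[lo:hi]) ** 2))
            assert err / rms < 1e-6

    def test_oracle_zero_input_zero_output(self, pair_plan):
        zero = np.zeros(SEGMENT)
        out = pb.reference_time_domain_filter(
            zero, pair_plan, pair_plan.phase_bands[0]
        )
        assert np.allclose(out.samples, 0.0)

    def test_oracle_unit_envelope_for_in_band_tone(self, pair_plan):
        n = np.arange(SEGMENT)
        tone = np.cos(2 * np.pi * 16.0 * n / RATE)
        out = pb.reference_time_domain_filter(
            tone, pair_plan, pair_plan.phase_bands[0]
        )
        k = out.samples.size
        assert np.allclose(np.abs(out.samples[k // 8: -k // 8]), 1.0, atol=0.02)
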