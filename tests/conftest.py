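import numpy as np
import pytest

import pacbank as pb

RATE = 16384.0
SEGMENT = 2**16  # 4 s at 16384 Hz


@pytest.fixture(scope="session")
def standard_params():
    """The canonical simulation: 16 Hz modulator, 130 Hz carrier, full coupling."""
    return pb.GeneratorParams(
        f_phase=16.0, f_amp=130.0, f_mod=16.0, pac_level=1.0,
        rate=RATE, duration=4.0,
    )


@pytest.fixture(scope="session")
def clean_signal(standard_params):
    return pb.generate_pac_signal(standard_params)


@pytest.fixture(scope="session")
def noisy_signal(clean_signal):
    return pb.add_noise_at_snr(clean_signal, pb.NoiseSpec("white", 10.0, 0))


@pytest.fixture(scope="session")
def grid_plan():
    """15x15 sensitivity-grid filter bank plan, designed once per session."""
    phase_c, amp_c = pb.sensitivity_grid()
    return pb.plan_filterbank(list(phase_c), list(amp_c), RATE, SEGMENT)


@pytest.fixture(scope="session")
def pair_plan():
    """Single 16/130 Hz band-pair plan with the standard wide amplitude band."""
    return pb.plan_filterbank(
        [16.0], [130.0], RATE, SEGMENT,
        phase_bandwidth=5.0, amp_bandwidth=150.0,
    )


def pair_pac(signal, plan, method="mi", n_bins=18):
    """Single band-pair PAC through the standard pipeline."""
    low, high = pb.analytic_filter_segment(signal, plan)
    phase, amp = pb.to_phase_amplitude(low, high)
    if method == "plv":
        return pb.pac_plv(low, amp).value
    p_up, a_up = pb.align_multirate(phase, amp)
    if method == "mvl":
        return pb.pac_mvl(p_up, a_up).value
    pad = pb.pad_estimate(p_up, a_up, n_bins)
    return (pb.pac_mi(pad) if method == "mi" else pb.pac_hr(pad)).value
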