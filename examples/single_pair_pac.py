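"""Quantify coupling for one band pair with all four estimators.

The signal couples a 16 Hz phase to a 130 Hz amplitude; every estimator
should report strong coupling on the coupled signal and near zero on the
uncoupled control.
"""

import pacbank as pb

RATE, SEGMENT = 16384.0, 2**16

plan = pb.plan_filterbank(
    [16.0], [130.0], RATE, SEGMENT,
    phase_bandwidth=5.0, amp_bandwidth=150.0,
)


def all_methods(signal):
    low, high = pb.analytic_filter_segment(signal, plan)
    phase, amp = pb.to_phase_amplitude(low, high)
    p_up, a_up = pb.align_multirate(phase, amp)
    pad = pb.pad_estimate(p_up, a_up, n_bins=18)
    return {
        "mi": pb.pac_mi(pad).value,
        "hr": pb.pac_hr(pad).value,
        "mvl": pb.pac_mvl(p_up, a_up).value,
        "plv": pb.pac_plv(low, amp).value,
    }


for label, p in [("coupled (P=1)", 1.0), ("uncoupled (P=0)", 0.0)]:
    sig = pb.add_noise_at_snr(
        pb.generate_pac_signal(pb.GeneratorParams(pac_level=p)),
        pb.NoiseSpec("white", 10.0, seed=0),
    )
    values = all_methods(sig)
    print(label, {k: round(v, 4) for k, v in values.items()})

print("MI/HR/MVL/PLV all live in [0, 1]; MI is the noise-tolerant default.")
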