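"""Synthetic phase-amplitude-coupled test signals, noise, and artefacts.

The generator produces the canonical two-component PAC test signal

    x(n) = x_p(n) + x_a(n)
    x_p(n) = sin(w_p n)
    x_a(n) = A_a(n) sin(w_a n)

where the amplitude envelope ``A_a`` of the fast component is modulated at
the slow frequency.  With the sinusoidal envelope shape,

    A_a(n) = (P sin(w_am n + pi) + 2 - P) / 4,

so the coupling strength ``P`` in [0, 1] moves the envelope between a
constant 1/2 (no coupling) and full-depth modulation over [0, 1/2].  The
burst shape instead convolves a Gaussian kernel with an impulse train of
period 1/F_am; the coupling strength blends the burst envelope with the
uncoupled constant so that P keeps its meaning across shapes.

White (measurement) and pink (1/f biological background) noise can be
added at a prescribed SNR, defined as the ratio of oscillatory amplitude
(unity for the slow component of the standard generator) to the noise
standard deviation.  Clipping and short broadband spike bursts emulate the
two artefact families typical of intraoperative microelectrode recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .signals import RawSignal

__all__ = [
    "GeneratorParams",
    "NoiseSpec",
    "generate_pac_signal",
    "generate_transient_pac",
    "modulation_envelope",
    "make_noise",
    "add_noise_at_snr",
    "clip_signal",
    "inject_spike_artefacts",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the two-component PAC signal generator.

    Attributes
    ----------
    f_phase:
        Frequency of the slow, phase-giving component (Hz).
    f_amp:
        Carrier frequency of the fast, amplitude-modulated component (Hz).
    f_mod:
        Modulation frequency of the fast component's envelope (Hz);
        normally equal to ``f_phase``.
    pac_level:
        Coupling strength P in [0, 1].
    rate:
        Sampling rate in Hz; must exceed twice ``f_amp``.
    duration:
        Signal length in seconds.
    envelope_shape:
        ``"sinusoidal"`` or ``"burst"``.
    burst_sigma:
        Gaussian burst width in samples (burst shape only).
    seed:
        Base seed, recorded for provenance; the noiseless generator is
        deterministic, the seed matters once noise is added downstream.
    """

    f_phase: float = 16.0
    f_amp: float = 130.0
    f_mod: float = 16.0
    pac_level: float = 1.0
    rate: float = 16384.0
    duration: float = 4.0
    envelope_shape: str = "sinusoidal"
    burst_sigma: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pac_level <= 1.0:
            raise ParameterError(f"pac_level must be in [0, 1], got {self.pac_level}")
        if not self.f_phase > 0:
            raise ParameterError(f"f_phase must be positive, got {self.f_phase}")
        if not self.f_amp > self.f_phase:
            raise ParameterError(
                f"f_amp ({self.f_amp}) must exceed f_phase ({self.f_phase})"
            )
        if not self.f_mod > 0:
            raise ParameterError(f"f_mod must be positive, got {self.f_mod}")
        if not self.rate > 2 * self.f_amp:
            raise ParameterError(
                f"rate ({self.rate}) must exceed 2*f_amp ({2 * self.f_amp})"
            )
        if not self.duration > 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if self.envelope_shape not in ("sinusoidal", "burst"):
            raise ParameterError(
                f"envelope_shape must be 'sinusoidal' or 'burst', got "
                f"{self.envelope_shape!r}"
            )
        if self.envelope_shape == "burst" and not self.burst_sigma > 0:
            raise ParameterError(
                f"burst_sigma must be positive, got {self.burst_sigma}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise description: kind, SNR, and seed."""

    kind: str = "white"      # "white" | "pink"
    snr: float = 10.0        # oscillatory amplitude / noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "pink"):
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if not self.snr > 0:
            raise ParameterError(f"snr must be positive, got {self.snr}")


def modulation_envelope(params: GeneratorParams) -> np.ndarray:
    """Amplitude envelope ``A_a(n)`` of the fast component.

    Sinusoidal shape: ``(P sin(w_am n + pi) + 2 - P) / 4``, bounded in
    [0, 1/2] with mean ``(2 - P)/4`` for every P.  Burst shape: a Gaussian
    of width ``burst_sigma`` samples convolved with an impulse train of
    period ``rate / f_mod`` samples, peak-normalized to 1/2 and blended
    with the uncoupled constant 1/2 by the coupling strength P.
    """
    n = np.arange(params.n_samples)
    p = params.pac_level
    if params.envelope_shape == "sinusoidal":
        w_am = 2.0 * np.pi * params.f_mod / params.rate
        return 0.25 * (p * np.sin(w_am * n + np.pi) + 2.0 - p)

    # burst: Gaussian kernel (mean 0 relative to each impulse) * impulse train
    sigma = params.burst_sigma
    period = params.rate / params.f_mod          # samples per burst
    train = np.zeros(params.n_samples)
    ticks = np.round(np.arange(0.0, params.n_samples, period)).astype(int)
    train[ticks[ticks < params.n_samples]] = 1.0
    half = int(math.ceil(4.0 * sigma))
    k = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (k / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    bursts = np.convolve(train, kernel, mode="same")
    peak = bursts.max()
    if peak > 0:
        bursts = 0.5 * bursts / peak
    return p * bursts + (1.0 - p) * 0.5


def generate_pac_signal(params: GeneratorParams) -> RawSignal:
    """Generate the noiseless two-component PAC signal x(n)."""
    n = np.arange(params.n_samples)
    w_p = 2.0 * np.pi * params.f_phase / params.rate
    w_a = 2.0 * np.pi * params.f_amp / params.rate
    x = np.sin(w_p * n) + modulation_envelope(params) * np.sin(w_a * n)
    return RawSignal(x, params.rate, label="pac")


def generate_transient_pac(
    params: GeneratorParams, active: tuple[float, float]
) -> RawSignal:
    """PAC signal whose coupling is switched on only during ``active``.

    Outside the ``(t_start, t_stop)`` window (seconds) the envelope is the
    uncoupled constant (P = 0); inside it follows ``params``.  The slow
    component and fast carrier run continuously, so only the modulation is
    transient -- the synthetic analogue of coupling that appears for a few
    seconds in a longer recording.
    """
    t0, t1 = active
    if not 0.0 <= t0 < t1 <= params.duration:
        raise ParameterError(
            f"active window {active} must lie within [0, {params.duration}] s"
        )
    n = np.arange(params.n_samples)
    env_on = modulation_envelope(params)
    env_off = modulation_envelope(replace(params, pac_level=0.0))
    gate = (n >= round(t0 * params.rate)) & (n < round(t1 * params.rate))
    env = np.where(gate, env_on, env_off)
    w_p = 2.0 * np.pi * params.f_phase / params.rate
    w_a = 2.0 * np.pi * params.f_amp / params.rate
    x = np.sin(w_p * n) + env * np.sin(w_a * n)
    return RawSignal(x, params.rate, label="pac-transient")


def make_noise(n_samples: int, spec: NoiseSpec, rate: float) -> RawSignal:
    """Unit-scale noise of the requested colour.

    White noise is i.i.d. zero-mean unit-variance Gaussian.  Pink noise is
    synthesized in the frequency domain with power spectral density
    proportional to 1/f (amplitude ~ f^-1/2, DC bin zeroed) and seeded
    random phases, then scaled to exactly unit sample standard deviation.
    """
    if n_samples < 2:
        raise ParameterError(f"n_samples must be >= 2, got {n_samples}")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white":
        x = rng.standard_normal(n_samples)
    else:  # pink
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
        mag = np.zeros_like(freqs)
        mag[1:] = freqs[1:] ** -0.5
        phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
        spectrum = mag * np.exp(1j * phases)
        spectrum[0] = 0.0
        if n_samples % 2 == 0:
            spectrum[-1] = np.abs(spectrum[-1])  # Nyquist bin must be real
        x = np.fft.irfft(spectrum, n=n_samples)
        x = x / x.std()
    return RawSignal(x, rate, label=f"{spec.kind}-noise")


def add_noise_at_snr(
    signal: RawSignal, spec: NoiseSpec, oscillatory_amplitude: float = 1.0
) -> RawSignal:
    """Add noise so that its sd equals ``oscillatory_amplitude / snr``.

    The SNR convention is amplitude-to-sd: the reference amplitude is that
    of the slow oscillatory component, 1.0 for the standard generator, and
    can be overridden for other signals.
    """
    noise = make_noise(len(signal), spec, signal.rate)
    scale = oscillatory_amplitude / spec.snr
    return RawSignal(
        signal.samples + scale * noise.samples, signal.rate, label=signal.label
    )


def clip_signal(signal: RawSignal, limit: float) -> tuple[RawSignal, int]:
    """Hard-limit samples to [-limit, +limit].

    Returns the clipped signal together with the number of samples that
    were altered.
    """
    if not limit > 0:
        raise ParameterError(f"limit must be positive, got {limit}")
    clipped = np.clip(signal.samples, -limit, limit)
    n_clipped = int(np.count_nonzero(clipped != signal.samples))
    return RawSignal(clipped, signal.rate, label=signal.label), n_clipped


def inject_spike_artefacts(
    signal: RawSignal,
    onsets: list[float],
    burst_duration: float,
    amplitude: float,
    seed: int = 0,
    taper: float = 0.010,
) -> RawSignal:
    """Add short broadband spike bursts at the given onset times.

    Each burst is zero-mean Gaussian noise scaled to ``amplitude`` times
    the signal's standard deviation, with cosine on/off tapers of ``taper``
    seconds, mimicking mechanical transients (e.g. tremor shaking the lead
    wire).  Samples outside the burst intervals are untouched.
    """
    if not burst_duration > 0:
        raise ParameterError(
            f"burst_duration must be positive, got {burst_duration}"
        )
    n_burst = int(round(burst_duration * signal.rate))
    out = signal.samples.copy()
    rng = np.random.default_rng(seed)
    sd = signal.samples.std()
    for onset in onsets:
        i0 = int(round(onset * signal.rate))
        if i0 < 0 or i0 + n_burst > len(signal):
            raise ParameterError(
                f"burst at {onset} s (+{burst_duration} s) exceeds the "
                f"{signal.duration:.3f} s signal"
            )
        burst = rng.standard_normal(n_burst) * amplitude * sd
        n_taper = min(int(round(taper * signal.rate)), n_burst // 2)
        if n_taper > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_taper) / n_taper))
            burst[:n_taper] *= ramp
            burst[-n_taper:] *= ramp[::-1]
        out[i0: i0 + n_burst] += burst
    return RawSignal(out, signal.rate, label=signal.label)
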