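# Methods

## Signal model

The synthetic generator produces `x(n) = x_p(n) + x_a(n)` with
`x_p(n) = sin(ω_p n)` and `x_a(n) = A_a(n)·sin(ω_a n)`, where
`ω_i = 2π F_i / F_s`. With the sinusoidal envelope shape,

    A_a(n) = (P·sin(ω_am n + π) + 2 − P) / 4,

so the coupling strength P ∈ [0, 1] interpolates between a constant
envelope of 1/2 (no coupling) and full-depth modulation over [0, 1/2].
The envelope mean is `(2 − P)/4` for every P, so mean fast-band power is
not confounded with coupling strength. Defaults follow the simulation
conditions used throughout: F_p = F_am = 16 Hz, F_a = 130 Hz,
F_s = 16384 Hz, 4 s duration (chosen to match the sliding-window length;
the analysis windows are 4 s, so simulated segments are too).

The burst envelope convolves a Gaussian of width σ (samples, default 100)
with an impulse train of period F_s/F_am. Two choices the model leaves
open are fixed here: the Gaussian is centred on the impulses (μ = 0), and
each burst is peak-normalized to 1/2 so the burst and sinusoidal shapes
have commensurate modulation depth; P blends the burst train with the
uncoupled constant 1/2 so its meaning is shape-independent.

Noise kinds: white (i.i.d. zero-mean unit-variance Gaussian) and pink
(1/f power spectral density, i.e. amplitude ∝ f^(−1/2), DC bin zeroed,
seeded random phases, scaled to exactly unit sample standard deviation).
SNR is defined as oscillatory amplitude over noise standard deviation; the
reference amplitude is that of the slow component (1.0 for the standard
generator) and is overridable for other signals. Artefact models:
hard clipping to ±limit, and 0.5 s broadband spike bursts (zero-mean
Gaussian scaled to a multiple of the signal sd, 10 ms cosine tapers),
mimicking hardware saturation and mechanical transients in intraoperative
recordings.

What the generator does *not* emulate: realistic spiking statistics,
non-sinusoidal slow rhythms, nonstationary spectra, or volume-conducted
mixtures. Passing tests demonstrates correct recovery of additive
sinusoid-plus-noise coupling, not performance on arbitrary clinical data.

## Filter bank

A segment of length L (power of two; 65536 = 4 s at 16384 Hz by default)
is transformed once. Per band, the K = L/M bins centred on the band's
centre bin are extracted, doubled (analytic one-siding), multiplied by the
sampled zero-phase prototype response, and inverse-transformed at length
K; multiplying by the band's carrier (at the binned centre frequency, so
the reconstruction is exact for on-grid centres) restores absolute phase.
Bins at or below 0 Hz, or at or above the original Nyquist, are zeroed to
preserve analyticity — relevant for low phase bands, whose retained window
(±2 bandwidths around the centre) can reach below 0 Hz.

Decimation factors are powers of two, the largest with decimated rate
≥ 4×bandwidth (one FFT-bin tolerance). Power-of-two rates make every
amplitude-band rate an integer multiple of every phase-band rate, which
the multirate pairing requires; the planner verifies this and reports the
feasible bandwidth range when it fails.

The prototype lowpass (default: 8000-tap linear-phase FIR, windowed-sinc
with a Blackman-Harris window; alternatively a 5th-order Butterworth
sampled as a zero-phase magnitude response for offline use) is designed at
the band's *decimated* rate — the rate at which the architecture applies
it — and its DTFT is sampled exactly on the K-bin grid by alias-folding
the kernel. At a 32 Hz decimated rate, 8000 taps give a transition band of
a few hundredths of a Hz, so adjacent 5 Hz-wide phase bands genuinely
separate: a tone 6 Hz outside a band's passband is attenuated into the
noise floor rather than passed at partial gain. (Designed at the original
rate instead, the same tap count yields an ~8 Hz transition; neighbouring
phase bands then carry attenuated copies of a strong modulator coherently,
and comodulogram peak localization degrades to a tie between adjacent
rows. This is the single most consequential design choice in the package.)
When a band is extracted without decimation, the response is still the one
designed at the band's reference decimated rate, so decimated and
full-rate outputs of the same band are samples of the same underlying
filtered signal.

Zero-phase realization multiplies by |H| once; a `squared_response` toggle
gives |H|², the literal forward–backward equivalent. Burn-in is flagged as
one eighth of the decimated segment per edge (0.5 s of a 4 s window) —
the near-brickwall band edge rings like a sinc whose tails fall below the
percent level beyond that — and all estimators drop burn-in symmetrically,
using the larger of the pair's burn-in durations.

Default bandwidths: phase bands tile (bandwidth = grid spacing); amplitude
bands default to twice the largest phase centre so the modulation
sidebands of any pairing stay inside the band, clipped per band when that
default would cross 0 Hz or Nyquist (an explicitly requested bandwidth is
validated, not clipped).

A time-domain oracle (`reference_time_domain_filter`) re-derives each band
by zero-phase convolution with the band's symmetric kernel (circular
boundary handling via wrap padding), a Hilbert transform, and plain
decimation; the test suite requires agreement with the single-FFT path to
1e-6 relative RMS (observed: ~1e-13).

## Estimators and alignment

Phase upsampling removes the known carrier ramp before unwrapping,
interpolates the slowly varying baseband phase linearly (zero-order hold
optional), and restores the ramp on the fine grid. This matters because a
decimated band's content can sit at or above the decimated Nyquist
frequency (a 16 Hz tone in a band sampled at 32 Hz), where unwrapping the
raw phase is ill-posed.

The PAD uses J = 18 bins (20°, the standard choice in the MI literature;
configurable), bin j covering [−π + j·2π/J, −π + (j+1)·2π/J) with the last
bin closed at π. Empty bins contribute zero with a warning (escalated when
more than J/4 bins are empty). Bin assignment is dithered by a
deterministic golden-ratio sequence spanning half a bin width: phases
reconstructed from a decimated band lie on a comb of
(amplitude rate / modulation frequency) distinct values when the signal is
periodic, and hard-edged binning of that comb biases bin means by a few
percent relative — enough to violate the 2% decimated-vs-full-rate
consistency contract, since the full-rate comb is 16× finer. Dithered
quantization is the standard remedy; it is applied identically on every
path and costs a sub-percent smoothing of genuine modulation
(`dither=False` restores hard edges). A related resolution limit remains:
with very narrow amplitude bands the decimated rate can drop below
2·J samples per modulation cycle, at which point an 18-bin PAD is
under-resolved regardless of binning; the default wide amplitude bands
keep ≥ 64 samples per cycle for a 16 Hz modulator.

MI uses the 0·ln 0 := 0 convention and is clipped at 0 against rounding.
MVL normalizes by the per-window maximum amplitude (the definition is
written per-signal; a global maximum would couple windows). For PLV, the
envelope's phase is obtained by band-filtering A(n) at the low band's
centre and bandwidth, at the envelope's own rate, with the same
reference-rate prototype; one eighth of the series is dropped per edge
against the circular ringing of that secondary filter.

## Comodulogram and blob detection

`compute_comodulogram` filters once (M+N bands) and evaluates the chosen
method per pair; any cell equals the standalone two-band computation
exactly. Blob detection thresholds at a fraction (default 0.5) of the
matrix maximum, labels suprathreshold pixels by 8-connectivity, and
reports per blob the maximum pixel (the "centre" — deterministic on a
grid), the mean value, and the value-weighted centroid; blobs sort by
mean value. The default analysis grid is 15 phase centres (5–75 Hz step 5,
bandwidth 5 Hz) × 15 amplitude centres (60–200 Hz step 10); a broader
20 × 15 survey grid (4–50 Hz × 60–250 Hz) is also provided. With wide
amplitude bands every band containing the carrier sees the same envelope,
so blobs extend along the amplitude axis and the phase coordinate of the
blob centre is the reproducible quantity.

## Streaming

The engine validates the configuration, plans the filter bank once, and
keeps a ring buffer of at most one window. Windows are right-aligned to
the newest sample and emitted when complete (causal); a 16 s stream with
4 s windows and 250 ms steps yields floor((16−4)/0.25)+1 = 49 emissions.
(The often-quoted "95% overlap" for these settings is arithmetically
93.75%; the window and step lengths are taken as the definition.) Each
window is processed by the same function the offline path uses, so
per-window results are bit-identical to offline computation on the same
slice and independent of chunking. No window taper is applied by default.
For transient-coupling localization, a window is counted as overlapping
the active interval only beyond the per-edge burn-in (0.5 s): a sliver
overlap lies entirely inside the trimmed edge and cannot register.

## Sensitivity sweep

Signals are simulated `reps` (default 4) times at each coupling level
(default 10 values, 0→1) × SNR level (default 10 values, 10→1). The blob
mask is fixed once from the rep-averaged comodulogram of the strongest
condition (max P, max SNR) — a per-condition blob would be undefined at
P = 0 — and the mean MI over the mask is each condition's readout.
Readouts are rep-averaged first, then min-max normalized against the
reference-SNR column (the reference column spans exactly [0, 1]; other
columns may leave it). Seeds follow the ladder
`base + 1000·i_P + 100·j_SNR + rep` and are logged in the result, making
the whole sweep a pure function of its spec.

## Known limitations

- The blob detector is threshold-based and intended for simulated
  signals; it is too noise-sensitive for unscreened clinical data.
- IIR prototypes are realized only as sampled zero-phase magnitude
  responses (offline mode); there is no streaming IIR convolution.
- Off-grid band centres are snapped to the nearest FFT bin for carrier
  restoration; grids should be chosen on the bin grid (all defaults are).
- MI's independence from the phase-band amplitude means a band containing
  only a coherent leak of a strong modulator can still score; the sharp
  decimated-rate prototypes suppress this across grid neighbours, but
  extremely fine grids (spacing well below the achievable transition
  width) would reintroduce ties.
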