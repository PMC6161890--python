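"""Sensitivity-analysis harness: coupling x noise sweep with blob-mask
readout and reference-SNR normalization.

Signals are simulated ``reps`` times at each coupling level P and each
noise level (SNR); a comodulogram is computed for every simulation.  The
blob mask is fixed once, from the rep-averaged comodulogram of the
strongest condition (max P, max SNR) -- a per-condition blob would be
undefined at P = 0 -- and the mean PAC over that mask is the readout for
every condition.  Rep-averaged readouts are min-max normalized to the
range of values observed at the reference SNR.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .comodulogram import compute_comodulogram, detect_blobs, sensitivity_grid
from .errors import DataError, ParameterError
from .filterbank import plan_filterbank
from .simulate import GeneratorParams, NoiseSpec, add_noise_at_snr, generate_pac_signal

__all__ = [
    "SweepSpec",
    "SweepResult",
    "sensitivity_sweep",
    "normalize_against_reference",
    "condition_seed",
]


@dataclass(frozen=True)
class SweepSpec:
    """Sweep protocol: coupling levels x SNR levels x repetitions."""

    pac_levels: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 10), 6))
    snr_levels: tuple[float, ...] = tuple(np.round(np.linspace(10.0, 1.0, 10), 6))
    reps: int = 4
    f_phase: float = 16.0
    f_amp: float = 130.0
    f_mod: float = 16.0
    rate: float = 16384.0
    duration: float = 4.0
    noise_kind: str = "white"
    method: str = "mi"
    n_bins: int = 18
    threshold_fraction: float = 0.5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ParameterError(f"reps must be >= 1, got {self.reps}")
        if not self.pac_levels or not self.snr_levels:
            raise ParameterError("pac_levels and snr_levels must be non-empty")
        if any(s <= 0 for s in self.snr_levels):
            raise ParameterError("all SNR levels must be positive")


@dataclass
class SweepResult:
    """Raw, rep-averaged, and normalized sweep readouts with provenance."""

    spec: SweepSpec
    raw: np.ndarray            # |P| x |SNR| x reps blob-mask mean PAC
    rep_averaged: np.ndarray   # |P| x |SNR|
    normalized: np.ndarray     # |P| x |SNR|, min-max vs the reference SNR
    blob_mask: np.ndarray      # boolean M x N grid mask
    seeds: np.ndarray          # |P| x |SNR| x reps seeds used
    phase_centres: np.ndarray
    amp_centres: np.ndarray
    reference_snr: float

    def to_json(self) -> str:
        payload = {
            "spec": asdict(self.spec),
            "raw": self.raw.tolist(),
            "rep_averaged": self.rep_averaged.tolist(),
            "normalized": self.normalized.tolist(),
            "blob_mask": self.blob_mask.astype(int).tolist(),
            "seeds": self.seeds.tolist(),
            "phase_centres": self.phase_centres.tolist(),
            "amp_centres": self.amp_centres.tolist(),
            "reference_snr": self.reference_snr,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SweepResult":
        raw = json.loads(text)
        spec_raw = raw["spec"]
        for key in ("pac_levels", "snr_levels"):
            spec_raw[key] = tuple(spec_raw[key])
        return cls(
            spec=SweepSpec(**spec_raw),
            raw=np.array(raw["raw"]),
            rep_averaged=np.array(raw["rep_averaged"]),
            normalized=np.array(raw["normalized"]),
            blob_mask=np.array(raw["blob_mask"], dtype=bool),
            seeds=np.array(raw["seeds"]),
            phase_centres=np.array(raw["phase_centres"]),
            amp_centres=np.array(raw["amp_centres"]),
            reference_snr=float(raw["reference_snr"]),
        )


def condition_seed(spec: SweepSpec, i_pac: int, j_snr: int, rep: int) -> int:
    """Seed ladder: base + 1000*i + 100*j + rep (logged per simulation)."""
    return int(spec.base_seed + 1000 * i_pac + 100 * j_snr + rep)


def _simulate_condition(
    spec: SweepSpec, pac_level: float, snr: float, seed: int
):
    params = GeneratorParams(
        f_phase=spec.f_phase,
        f_amp=spec.f_amp,
        f_mod=spec.f_mod,
        pac_level=pac_level,
        rate=spec.rate,
        duration=spec.duration,
        seed=seed,
    )
    clean = generate_pac_signal(params)
    return add_noise_at_snr(clean, NoiseSpec(spec.noise_kind, snr, seed))


def sensitivity_sweep(spec: SweepSpec) -> SweepResult:
    """Run the full sweep; a pure function of the spec (incl. base seed)."""
    phase_centres, amp_centres = sensitivity_grid()
    n_samples = int(round(spec.duration * spec.rate))
    plan = plan_filterbank(
        list(phase_centres), list(amp_centres), spec.rate, n_samples
    )
    n_p, n_s, reps = len(spec.pac_levels), len(spec.snr_levels), spec.reps
    i_ref = int(np.argmax(spec.pac_levels))
    j_ref = int(np.argmax(spec.snr_levels))

    matrices = np.zeros((n_p, n_s, reps, len(phase_centres), len(amp_centres)))
    seeds = np.zeros((n_p, n_s, reps), dtype=int)
    for i, p in enumerate(spec.pac_levels):
        for j, snr in enumerate(spec.snr_levels):
            for r in range(reps):
                seed = condition_seed(spec, i, j, r)
                seeds[i, j, r] = seed
                sig = _simulate_condition(spec, p, snr, seed)
                comod = compute_comodulogram(
                    sig, plan, method=spec.method, n_bins=spec.n_bins
                )
                matrices[i, j, r] = comod.values

    # blob mask from the strongest condition's rep-averaged comodulogram
    from .comodulogram import Comodulogram

    ref = Comodulogram(
        phase_centres, amp_centres, matrices[i_ref, j_ref].mean(axis=0),
        method=spec.method,
    )
    blobs = detect_blobs(ref, spec.threshold_fraction)
    if not blobs:
        raise DataError(
            "no blob found in the reference (max P, max SNR) condition; "
            "the signal or grid is misconfigured"
        )
    mask = np.zeros((len(phase_centres), len(amp_centres)), dtype=bool)
    for i0, j0 in blobs[0].members:
        mask[i0, j0] = True

    raw = matrices[..., mask].mean(axis=-1)          # |P| x |SNR| x reps
    rep_avg = raw.mean(axis=-1)
    normalized = normalize_against_reference(
        rep_avg, list(spec.snr_levels), spec.snr_levels[j_ref]
    )
    return SweepResult(
        spec=spec,
        raw=raw,
        rep_averaged=rep_avg,
        normalized=normalized,
        blob_mask=mask,
        seeds=seeds,
        phase_centres=phase_centres,
        amp_centres=amp_centres,
        reference_snr=spec.snr_levels[j_ref],
    )


def normalize_against_reference(
    rep_averaged: np.ndarray, snr_levels: list[float], reference_snr: float
) -> np.ndarray:
    """Min-max normalize against the values observed at the reference SNR.

    ``v' = (v - min_ref) / (max_ref - min_ref)`` with min/max taken over
    the rep-averaged column at the reference SNR; the reference column maps
    onto exactly [0, 1], other columns may fall outside.
    """
    rep_averaged = np.asarray(rep_averaged, dtype=float)
    snr_levels = list(snr_levels)
    matches = [
        j for j, s in enumerate(snr_levels) if abs(s - reference_snr) < 1e-9
    ]
    if not matches:
        raise ParameterError(
            f"reference SNR {reference_snr} is not among the sweep levels "
            f"{snr_levels}"
        )
    ref_col = rep_averaged[:, matches[0]]
    lo, hi = ref_col.min(), ref_col.max()
    if hi - lo <= 0:
        raise ParameterError(
            "degenerate reference column: all values equal, cannot normalize"
        )
    return (rep_averaged - lo) / (hi - lo)
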