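"""Comodulograms (PAC over a frequency-pair grid) and blob detection.

A comodulogram evaluates one PAC method for every pairing of M
phase-frequency centres with N amplitude-frequency centres.  The raw
segment is filtered only M + N times (one analytic band per centre, all
from a single FFT); every one of the M*N cells then reuses the banded
signals.  Blob detection thresholds the matrix at a fraction of its
maximum and groups suprathreshold pixels by 8-connectivity; the blob
centre (its maximum pixel) marks the main contributing frequency pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .filterbank import FilterBankPlan, analytic_filter_segment, plan_filterbank
from .metrics import (
    align_multirate,
    pac_hr,
    pac_mi,
    pac_mvl,
    pac_plv,
    pad_estimate,
    to_phase_amplitude,
)
from .signals import RawSignal

__all__ = [
    "Comodulogram",
    "Blob",
    "compute_comodulogram",
    "detect_blobs",
    "sensitivity_grid",
    "broadband_grid",
]


def sensitivity_grid() -> tuple[np.ndarray, np.ndarray]:
    """15x15 grid: phase centres 5-75 Hz step 5, amplitude 60-200 Hz step 10."""
    return np.arange(5.0, 76.0, 5.0), np.arange(60.0, 201.0, 10.0)


def broadband_grid() -> tuple[np.ndarray, np.ndarray]:
    """Survey grid: 20 phase centres over 4-50 Hz, 15 amplitude centres over
    60-250 Hz (snapped to a 0.25 Hz design grid)."""
    phase = np.round(np.linspace(4.0, 50.0, 20) * 4) / 4
    amp = np.round(np.linspace(60.0, 250.0, 15) * 4) / 4
    return phase, amp


@dataclass
class Comodulogram:
    """M x N matrix of PAC magnitudes over (phase centre, amp centre) pairs."""

    phase_centres: np.ndarray
    amp_centres: np.ndarray
    values: np.ndarray
    method: str = "mi"
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.phase_centres = np.asarray(self.phase_centres, dtype=float)
        self.amp_centres = np.asarray(self.amp_centres, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.phase_centres.size, self.amp_centres.size):
            raise ParameterError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.phase_centres.size} x {self.amp_centres.size})"
            )
        if np.any(np.diff(self.phase_centres) <= 0) or np.any(
            np.diff(self.amp_centres) <= 0
        ):
            raise ParameterError("grid centres must be strictly increasing")

    def argmax_pair(self) -> tuple[float, float]:
        """(phase Hz, amp Hz) of the matrix maximum."""
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.phase_centres[i]), float(self.amp_centres[j])


@dataclass
class Blob:
    """One connected suprathreshold pixel group of a comodulogram."""

    members: list[tuple[int, int]]          # (phase index, amp index) pixels
    centre: tuple[float, float]             # grid Hz of the maximum pixel
    centre_index: tuple[int, int]
    mean_value: float
    centroid: tuple[float, float]           # value-weighted centroid, Hz


def compute_comodulogram(
    segment: RawSignal,
    plan: FilterBankPlan,
    method: str = "mi",
    n_bins: int = 18,
    window: tuple[float, float] | None = None,
) -> Comodulogram:
    """PAC for every phase-band x amplitude-band pair of the plan.

    Runs the analytic filter bank once (M + N band filterings from a single
    FFT) and evaluates the requested method for each pair on the
    burn-trimmed, rate-aligned series.
    """
    if method not in ("mi", "hr", "mvl", "plv"):
        raise ParameterError(f"unknown PAC method {method!r}")
    bands = analytic_filter_segment(segment, plan)
    n_phase = len(plan.phase_bands)
    lows, highs = bands[:n_phase], bands[n_phase:]
    values = np.zeros((len(lows), len(highs)))
    for i, low in enumerate(lows):
        for j, high in enumerate(highs):
            phase, amp = to_phase_amplitude(low, high)
            if method == "plv":
                values[i, j] = pac_plv(low, amp).value
            elif method == "mvl":
                p_up, a_up = align_multirate(phase, amp)
                values[i, j] = pac_mvl(p_up, a_up).value
            else:
                p_up, a_up = align_multirate(phase, amp)
                pad = pad_estimate(p_up, a_up, n_bins)
                est = pac_mi(pad) if method == "mi" else pac_hr(pad)
                values[i, j] = est.value
    return Comodulogram(
        phase_centres=np.array([b.centre for b in plan.phase_bands]),
        amp_centres=np.array([b.centre for b in plan.amp_bands]),
        values=values,
        method=method,
        window=window,
    )


def comodulogram_for_signal(
    segment: RawSignal,
    phase_centres: np.ndarray | list[float] | None = None,
    amp_centres: np.ndarray | list[float] | None = None,
    method: str = "mi",
    n_bins: int = 18,
    **plan_kwargs,
) -> Comodulogram:
    """Convenience wrapper: plan the filter bank for this segment and run it."""
    if phase_centres is None or amp_centres is None:
        phase_centres, amp_centres = sensitivity_grid()
    plan = plan_filterbank(
        list(phase_centres), list(amp_centres), segment.rate, len(segment),
        **plan_kwargs,
    )
    return compute_comodulogram(segment, plan, method=method, n_bins=n_bins)


def detect_blobs(
    comod: Comodulogram, threshold_fraction: float = 0.5
) -> list[Blob]:
    """Threshold blob detection with 8-connectivity.

    The threshold is ``threshold_fraction`` times the matrix maximum;
    suprathreshold pixels are grouped into connected components.  Each blob
    reports its maximum pixel (the blob centre), its mean value, and its
    value-weighted centroid.  Blobs are sorted by mean value, descending.
    An all-zero matrix yields no blobs.
    """
    if not 0 < threshold_fraction <= 1:
        raise ParameterError(
            f"threshold_fraction must be in (0, 1], got {threshold_fraction}"
        )
    v = comod.values
    peak = v.max()
    if peak <= 0:
        return []
    mask = v >= threshold_fraction * peak
    labels, n_labels = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    blobs: list[Blob] = []
    for lab in range(1, n_labels + 1):
        members = [tuple(p) for p in np.argwhere(labels == lab)]
        sub = np.array([v[p] for p in members])
        best = members[int(np.argmax(sub))]
        weights = sub / sub.sum()
        centroid_phase = float(
            np.sum(weights * np.array([comod.phase_centres[p[0]] for p in members]))
        )
        centroid_amp = float(
            np.sum(weights * np.array([comod.amp_centres[p[1]] for p in members]))
        )
        blobs.append(
            Blob(
                members=members,
                centre=(
                    float(comod.phase_centres[best[0]]),
                    float(comod.amp_centres[best[1]]),
                ),
                centre_index=(int(best[0]), int(best[1])),
                mean_value=float(sub.mean()),
                centroid=(centroid_phase, centroid_amp),
            )
        )
    blobs.sort(key=lambda b: b.mean_value, reverse=True)
    return blobs
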