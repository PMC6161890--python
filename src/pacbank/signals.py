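"""Basic in-memory signal containers.

Everything in the package starts from a :class:`RawSignal` (real samples at
a known rate) and flows through :class:`AnalyticSignal` objects: complex,
band-limited, decimated, and tagged with the band geometry that produced
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError


@dataclass
class RawSignal:
    """A real-valued, uniformly sampled time series.

    Parameters
    ----------
    samples:
        1-D array of finite real values (arbitrary units).
    rate:
        Sampling rate in Hz, strictly positive.
    label:
        Optional channel label.
    """

    samples: np.ndarray
    rate: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not self.rate > 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            bad = np.flatnonzero(~np.isfinite(self.samples))
            raise DataError(
                f"samples contain {bad.size} non-finite values "
                f"(first offending indices: {bad[:10].tolist()})"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate


@dataclass
class AnalyticSignal:
    """Complex band-limited samples at a (possibly) decimated rate.

    ``samples[m]`` is the analytic signal of one band evaluated at original
    time instant ``m * decim_factor / original_rate``.  The first and last
    ``burn_in`` samples carry filter edge transients and are excluded from
    PAC estimation by default.
    """

    samples: np.ndarray
    rate: float          # decimated sampling rate, Hz
    centre: float        # band centre frequency, Hz
    bandwidth: float     # band width, Hz
    burn_in: int = 0     # edge samples to discard at each end
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("analytic samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    def interior(self) -> np.ndarray:
        """Samples with the burn-in trimmed from both ends."""
        b = self.burn_in
        return self.samples[b: self.samples.size - b] if b else self.samples


@dataclass
class PhaseSeries:
    """Instantaneous phase values in (-pi, pi] at a known rate."""

    values: np.ndarray
    rate: float
    centre: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class AmplitudeSeries:
    """Nonnegative instantaneous amplitude values at a known rate."""

    values: np.ndarray
    rate: float
    centre: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size
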