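"""Realtime sliding-window PAC engine.

Windows of fixed length slide over the incoming stream with a small step
(e.g. 4 s windows every 250 ms).  All filter design happens once at engine
creation; pushing samples performs only FFT filtering and PAC
quantification.  Emissions are a pure function of the stream content:
pushing the same samples in different chunk sizes yields bit-identical
results.  Windows are right-aligned to the newest sample and emitted as
soon as they complete (causal); the buffer never holds more than one
window of samples.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .comodulogram import Comodulogram, compute_comodulogram
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

__all__ = ["StreamConfig", "StreamingEngine", "create_engine", "push_samples"]


@dataclass(frozen=True)
class StreamConfig:
    """Sliding-window analysis description.

    ``emit`` selects per-window output: a single band-pair PAC estimate
    (``"pac"``) or a full comodulogram (``"comodulogram"``).
    """

    window_length: float                 # seconds
    step: float                          # seconds
    rate: float                          # Hz
    emit: str = "pac"                    # "pac" | "comodulogram"
    method: str = "mi"
    n_bins: int = 18
    phase_band: tuple[float, float] = (16.0, 8.0)     # (centre, bandwidth) Hz
    amp_band: tuple[float, float] | None = None       # (centre, bandwidth) Hz
    phase_centres: tuple[float, ...] | None = None    # comodulogram grids
    amp_centres: tuple[float, ...] | None = None
    prototype_kind: str = "fir_linear_phase"
    taps_or_order: int | None = None

    def __post_init__(self) -> None:
        if not self.window_length > self.step > 0:
            raise ParameterError(
                f"need window_length > step > 0, got "
                f"{self.window_length} s / {self.step} s"
            )
        if self.emit not in ("pac", "comodulogram"):
            raise ParameterError(f"unknown emit kind {self.emit!r}")
        n = self.window_length * self.rate
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"window_length * rate must be an integer sample count, got {n}"
            )
        s = self.step * self.rate
        if abs(s - round(s)) > 1e-9:
            raise ParameterError(
                f"step * rate must be an integer sample count, got {s}"
            )

    @property
    def window_samples(self) -> int:
        return int(round(self.window_length * self.rate))

    @property
    def step_samples(self) -> int:
        return int(round(self.step * self.rate))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StreamConfig":
        raw = json.loads(text)
        for key in ("phase_band", "amp_band", "phase_centres", "amp_centres"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class StreamingEngine:
    """One-time initialized sliding-window PAC engine.

    All band plans and prototype responses are computed in ``__init__``;
    :meth:`push` only filters and quantifies.  State is a ring buffer of at
    most one window plus two counters.
    """

    def __init__(self, config: StreamConfig):
        self.config = config
        w = config.window_samples
        if config.emit == "comodulogram":
            phase_centres = list(config.phase_centres or (5, 10, 15, 20, 25))
            amp_centres = list(config.amp_centres or (80, 100, 120, 140))
        else:
            if config.amp_band is None:
                raise ParameterError("emit='pac' requires amp_band")
            phase_centres = [config.phase_band[0]]
            amp_centres = [config.amp_band[0]]
        kwargs: dict = {
            "prototype_kind": config.prototype_kind,
            "taps_or_order": config.taps_or_order,
        }
        if config.emit == "pac":
            kwargs["phase_bandwidth"] = config.phase_band[1]
            kwargs["amp_bandwidth"] = config.amp_band[1]
        self.plan: FilterBankPlan = plan_filterbank(
            phase_centres, amp_centres, config.rate, w, **kwargs
        )
        max_burn = max(
            b.burn_in * b.decim_factor for b in self.plan.bands
        )
        if w < 2 * max_burn + 4:
            raise ParameterError(
                f"window of {w} samples is shorter than twice the filter "
                f"burn-in ({max_burn} samples per edge)"
            )
        self._ring = np.zeros(w)
        self._total = 0               # samples consumed so far
        self._next_start = 0          # start index of the next window

    # -- streaming ---------------------------------------------------------

    def push(self, chunk: RawSignal | np.ndarray) -> list:
        """Consume samples; return results for every window completed."""
        if isinstance(chunk, RawSignal):
            if chunk.rate != self.config.rate:
                raise ParameterError(
                    f"chunk rate {chunk.rate} Hz differs from engine rate "
                    f"{self.config.rate} Hz"
                )
            data = chunk.samples
        else:
            data = np.asarray(chunk, dtype=float)
        w = self.config.window_samples
        step = self.config.step_samples
        results = []
        pos = 0
        while pos < data.size:
            boundary = self._next_start + w
            take = min(data.size - pos, max(1, boundary - self._total))
            self._append(data[pos: pos + take])
            pos += take
            while self._total >= self._next_start + w:
                results.append(self._emit_window())
                self._next_start += step
        return results

    def _append(self, data: np.ndarray) -> None:
        w = self._ring.size
        if data.size >= w:
            self._ring[:] = data[-w:]
        else:
            idx = (self._total + np.arange(data.size)) % w
            self._ring[idx] = data
        self._total += data.size

    def _window_samples_array(self) -> np.ndarray:
        w = self._ring.size
        start = self._next_start
        idx = (start + np.arange(w)) % w
        return self._ring[idx]

    def _emit_window(self):
        w = self.config.window_samples
        start = self._next_start
        span = (start / self.config.rate, (start + w) / self.config.rate)
        x = self._window_samples_array()
        return compute_window(x, self.plan, self.config, span)

    @property
    def samples_consumed(self) -> int:
        return self._total


def compute_window(
    x: np.ndarray,
    plan: FilterBankPlan,
    config: StreamConfig,
    span: tuple[float, float] | None = None,
):
    """Offline computation for one window; the engine calls exactly this."""
    if config.emit == "comodulogram":
        return compute_comodulogram(
            RawSignal(x, config.rate), plan, method=config.method,
            n_bins=config.n_bins, window=span,
        )
    bands = analytic_filter_segment(x, plan)
    low, high = bands[0], bands[1]
    phase, amp = to_phase_amplitude(low, high)
    if config.method == "plv":
        est = pac_plv(low, amp)
    elif config.method == "mvl":
        p_up, a_up = align_multirate(phase, amp)
        est = pac_mvl(p_up, a_up)
    else:
        p_up, a_up = align_multirate(phase, amp)
        pad = pad_estimate(p_up, a_up, config.n_bins)
        est = pac_mi(pad) if config.method == "mi" else pac_hr(pad)
    est.phase_band = (low.centre, low.bandwidth)
    est.amp_band = (high.centre, high.bandwidth)
    est.window = span
    return est


def create_engine(config: StreamConfig) -> StreamingEngine:
    """Build a fully initialized engine (all plans precomputed)."""
    return StreamingEngine(config)


def push_samples(engine: StreamingEngine, chunk: RawSignal | np.ndarray) -> list:
    """Feed samples to the engine; returns newly completed window results."""
    return engine.push(chunk)
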