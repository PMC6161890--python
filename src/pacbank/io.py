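"""Reading signals (CSV, MAT v5, HDF5) and writing results (CSV, JSON).

CSV signal convention: an optional leading comment line ``# rate_hz=...``,
then one header row and one column per channel.  HDF5 stores the samples
in ``/signal`` with a ``rate_hz`` attribute.  MAT v5 files are read with
scipy; the rate is taken from a scalar variable named ``rate``, ``fs`` or
``rate_hz`` when present, else from the ``rate`` argument.
"""

from __future__ import annotations

import hashlib
import json
from importlib import metadata
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as sio

from .comodulogram import Comodulogram
from .errors import DataError, ParameterError
from .metrics import PACEstimate
from .signals import RawSignal
from .sweep import SweepResult

__all__ = [
    "read_signal",
    "write_signal",
    "write_results",
    "read_comodulogram_csv",
]

_RATE_VARS = ("rate", "fs", "rate_hz", "sampling_rate")


def _version() -> str:
    try:
        return metadata.version("pacbank")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _validate_samples(samples: np.ndarray, source: str) -> np.ndarray:
    samples = np.asarray(samples, dtype=float).squeeze()
    if samples.ndim != 1:
        raise DataError(f"{source}: expected a single channel vector")
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        raise DataError(
            f"{source}: {bad.size} non-finite samples at indices "
            f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
        )
    return samples


def read_signal(
    path: str | Path,
    fmt: str | None = None,
    rate: float | None = None,
    channel: str | None = None,
) -> RawSignal:
    """Load a single-channel signal from CSV, MAT v5, or HDF5."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {
            ".csv": "csv", ".mat": "mat", ".h5": "hdf5", ".hdf5": "hdf5",
        }.get(ext)
        if fmt is None:
            raise DataError(
                f"cannot infer format from extension {ext!r}; pass fmt="
            )
    if fmt == "csv":
        return _read_csv(path, rate, channel)
    if fmt == "mat":
        return _read_mat(path, rate, channel)
    if fmt == "hdf5":
        return _read_hdf5(path, rate, channel)
    raise ParameterError(f"unknown format {fmt!r}")


def _read_csv(path: Path, rate: float | None, channel: str | None) -> RawSignal:
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first.lstrip("#").replace(",", " ").split():
            if token.startswith("rate_hz="):
                rate = float(token.split("=", 1)[1])
    frame = pd.read_csv(path, skiprows=skip)
    if rate is None:
        raise DataError(
            f"{path}: no '# rate_hz=...' header found; pass rate="
        )
    col = channel if channel is not None else frame.columns[0]
    if col not in frame.columns:
        raise DataError(f"{path}: no column named {col!r}")
    values = pd.to_numeric(frame[col], errors="coerce").to_numpy()
    return RawSignal(_validate_samples(values, str(path)), rate, label=str(col))


def _read_mat(path: Path, rate: float | None, channel: str | None) -> RawSignal:
    data = sio.loadmat(path)
    arrays = {
        k: v for k, v in data.items()
        if not k.startswith("__") and isinstance(v, np.ndarray)
    }
    if rate is None:
        for name in _RATE_VARS:
            if name in arrays and arrays[name].size == 1:
                rate = float(arrays[name].ravel()[0])
                break
    if rate is None:
        raise DataError(f"{path}: no rate variable found; pass rate=")
    if channel is not None:
        if channel not in arrays:
            raise DataError(f"{path}: no variable named {channel!r}")
        vec = arrays[channel]
    else:
        candidates = [
            (k, v) for k, v in arrays.items()
            if v.size > 1 and k not in _RATE_VARS
        ]
        if not candidates:
            raise DataError(f"{path}: no vector variable found")
        vec = candidates[0][1]
        channel = candidates[0][0]
    return RawSignal(_validate_samples(vec, str(path)), rate, label=channel)


def _read_hdf5(path: Path, rate: float | None, channel: str | None) -> RawSignal:
    with h5py.File(path, "r") as fh:
        name = channel or "signal"
        if name not in fh:
            raise DataError(f"{path}: no dataset named {name!r}")
        dset = fh[name]
        if rate is None:
            rate = dset.attrs.get("rate_hz")
            if rate is None:
                raise DataError(
                    f"{path}: dataset {name!r} has no rate_hz attribute; "
                    "pass rate="
                )
        values = np.asarray(dset[...])
    return RawSignal(_validate_samples(values, str(path)), float(rate), label=name)


def write_signal(signal: RawSignal, path: str | Path, fmt: str | None = None) -> Path:
    """Write a signal as CSV (with rate header) or HDF5."""
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if fmt == "csv":
        label = signal.label or "signal"
        with open(path, "w") as fh:
            fh.write(f"# rate_hz={signal.rate}\n")
            fh.write(f"{label}\n")
            np.savetxt(fh, signal.samples, fmt="%.12g")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("signal", data=signal.samples)
            dset.attrs["rate_hz"] = signal.rate
    else:
        raise ParameterError(f"unknown signal format {fmt!r}")
    return path


def _plan_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def write_results(
    result, path: str | Path, fmt: str = "json", provenance: dict | None = None
) -> Path:
    """Write PAC estimates, a comodulogram, or a sweep result to disk.

    JSON output embeds provenance (software version plus whatever the
    caller supplies: seeds, grids, plan hash) and round-trips bit-exactly.
    """
    path = Path(path)
    meta = {"pacbank_version": _version()}
    if provenance:
        meta.update(provenance)

    if isinstance(result, Comodulogram):
        if fmt == "csv":
            frame = pd.DataFrame(
                result.values,
                index=pd.Index(result.phase_centres, name="phase_hz"),
                columns=result.amp_centres,
            )
            frame.to_csv(path)
        else:
            payload = {
                "kind": "comodulogram",
                "method": result.method,
                "phase_centres": result.phase_centres.tolist(),
                "amp_centres": result.amp_centres.tolist(),
                "values": result.values.tolist(),
                "window": result.window,
                "provenance": meta,
            }
            path.write_text(json.dumps(payload, sort_keys=True))
    elif isinstance(result, SweepResult):
        if fmt != "json":
            raise ParameterError("sweep results are written as JSON")
        payload = json.loads(result.to_json())
        payload["provenance"] = meta
        path.write_text(json.dumps(payload, sort_keys=True))
    elif isinstance(result, list) and all(
        isinstance(r, PACEstimate) for r in result
    ):
        rows = [
            {
                "window_start": (r.window or (None, None))[0],
                "window_end": (r.window or (None, None))[1],
                "method": r.method,
                "phase_hz": (r.phase_band or (None, None))[0],
                "amp_hz": (r.amp_band or (None, None))[0],
                "value": r.value,
            }
            for r in result
        ]
        if fmt == "csv":
            pd.DataFrame(rows).to_csv(path, index=False)
        else:
            path.write_text(
                json.dumps({"estimates": rows, "provenance": meta}, sort_keys=True)
            )
    else:
        raise ParameterError(
            f"cannot serialize result of type {type(result).__name__}"
        )
    return path


def read_comodulogram_csv(path: str | Path) -> Comodulogram:
    """Read back a comodulogram written by :func:`write_results` (CSV)."""
    frame = pd.read_csv(path, index_col=0)
    return Comodulogram(
        phase_centres=frame.index.to_numpy(dtype=float),
        amp_centres=np.array([float(c) for c in frame.columns]),
        values=frame.to_numpy(dtype=float),
    )
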