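"""Reading and writing recordings, cohort tables and analysis reports.

The canonical interchange format is plain CSV (columns ``time_s``,
``ecg_mv``, ``ppg_au``; comma separated, ``.`` decimal, UTF-8, mandatory
header).  Subject metadata travels in ``#``-prefixed JSON comment lines
above the header so a recording survives a round trip through a single
text file.  An optional EDF exporter/importer is provided for
interoperability with polysomnography tooling; EDF stores samples as
16-bit integers, so the round trip is exact only up to the documented
quantization step ``(physical_max - physical_min) / (dig_max - dig_min)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import FormatError

SCHEMA_VERSION = "1.0"

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "write_report",
    "read_report",
    "edf_quantization_step",
    "SCHEMA_VERSION",
]


@dataclass
class Recording:
    """Two synchronized sampled channels (ECG in mV, PPG in arbitrary units).

    Both channels share one uniform time base starting at t = 0.
    """

    subject_id: str
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.ecg.shape != self.ppg.shape or self.ecg.ndim != 1:
            raise FormatError(
                f"channel length mismatch: ecg has {self.ecg.shape}, "
                f"ppg has {self.ppg.shape}"
            )
        if np.isnan(self.ecg).any() or np.isnan(self.ppg).any():
            raise FormatError("missing samples (NaN) are not allowed in a Recording")

    @property
    def n_samples(self) -> int:
        return self.ecg.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    header = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        **rec.meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pulsebp-recording " + json.dumps(header, sort_keys=True) + "\n")
        fh.write("time_s,ecg_mv,ppg_au\n")
        t = rec.time
        for i in range(rec.n_samples):
            fh.write(f"{t[i]:.6f},{rec.ecg[i]:.17g},{rec.ppg[i]:.17g}\n")
    return path


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    meta: dict[str, Any] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# pulsebp-recording"):
        try:
            meta = json.loads(first.split(None, 2)[2])
        except (json.JSONDecodeError, IndexError) as exc:
            raise FormatError(f"unparseable recording header in {path}") from exc
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"time_s", "ecg_mv", "ppg_au"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path} is missing required columns {sorted(required - set(df.columns))}"
        )
    if df[["ecg_mv", "ppg_au"]].isna().any().any():
        raise FormatError(f"{path}: channel length mismatch or missing samples")
    fs = meta.pop("fs", None)
    if fs is None:
        # fall back to the median time step
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        if not np.isfinite(dt) or dt <= 0:
            raise FormatError(f"{path}: cannot determine sampling rate")
        fs = 1.0 / dt
    try:
        fs = float(fs)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: unparseable sampling rate {fs!r}") from exc
    subject_id = str(meta.pop("subject_id", path.stem))
    meta.pop("schema_version", None)
    return Recording(
        subject_id=subject_id,
        fs=fs,
        ecg=df["ecg_mv"].to_numpy(),
        ppg=df["ppg_au"].to_numpy(),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# EDF (minimal single-record codec, 16-bit)
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: Any, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_limits(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1.0
    # widen, then store exactly as written (8 ASCII chars); the written
    # limits must enclose the data or clipping would exceed the
    # quantization step
    margin = 1e-3 * (hi - lo) + 1e-5 * max(abs(lo), abs(hi))
    for _ in range(8):
        lo_w = float(f"{lo - margin:.6g}"[:8])
        hi_w = float(f"{hi + margin:.6g}"[:8])
        if lo_w <= lo and hi_w >= hi and hi_w > lo_w:
            return lo_w, hi_w
        margin *= 4
    return lo - 1.0, hi + 1.0


def edf_quantization_step(x: np.ndarray) -> float:
    """Worst-case per-sample error bound of the 16-bit EDF round trip."""
    lo, hi = _phys_limits(np.asarray(x, dtype=float))
    return (hi - lo) / (_DIG_MAX - _DIG_MIN)


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write an EDF file with one data record holding the full channels."""
    path = Path(path)
    channels = [("ECG I", "mV", rec.ecg), ("PPG", "au", rec.ppg)]
    ns = len(channels)
    header_bytes = 256 + 256 * ns
    duration = rec.n_samples / rec.fs
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(f"subject {rec.subject_id}", 80))
        fh.write(_ascii(f"pulsebp fs={rec.fs:g}", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(1, 8))                    # one data record
        fh.write(_ascii(f"{duration:.6g}", 8))
        fh.write(_ascii(ns, 4))
        limits = [_phys_limits(x) for _, _, x in channels]
        for (label, _, _), _lim in zip(channels, limits):
            fh.write(_ascii(label, 16))
        for _ in channels:
            fh.write(_ascii("", 80))              # transducer
        for (_, dim, _) in channels:
            fh.write(_ascii(dim, 8))
        for lo, _hi in limits:
            fh.write(_ascii(f"{lo:.6g}", 8))
        for _lo, hi in limits:
            fh.write(_ascii(f"{hi:.6g}", 8))
        for _ in channels:
            fh.write(_ascii(_DIG_MIN, 8))
        for _ in channels:
            fh.write(_ascii(_DIG_MAX, 8))
        for _ in channels:
            fh.write(_ascii("", 80))              # prefiltering
        for _ in channels:
            fh.write(_ascii(rec.n_samples, 8))
        for _ in channels:
            fh.write(_ascii("", 32))
        for (_, _, x), (lo, hi) in zip(channels, limits):
            scale = (hi - lo) / (_DIG_MAX - _DIG_MIN)
            dig = np.round((x - lo) / scale + _DIG_MIN)
            dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(dig.tobytes())
    return path


def read_recording_edf(path: str | Path) -> Recording:
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        recording_field = head[88:168].decode("ascii", "replace").strip()
        duration = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)
        labels = [sig[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = 16 * ns + 80 * ns + 8 * ns
        pmin = [float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        pmax = [float(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dmin = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns
        dmax = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        off += 8 * ns + 80 * ns
        nsamp = [int(sig[off + 8 * i: off + 8 * (i + 1)]) for i in range(ns)]
        data = {}
        for i in range(ns):
            raw = fh.read(2 * nsamp[i])
            dig = np.frombuffer(raw, dtype="<i2").astype(float)
            scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
            data[labels[i]] = (dig - dmin[i]) * scale + pmin[i]
    fs = None
    for token in recording_field.split():
        if token.startswith("fs="):
            fs = float(token[3:])
    if fs is None:
        fs = nsamp[0] / duration
    subject = head[8:88].decode("ascii").strip()
    if subject.startswith("subject "):
        subject = subject[len("subject "):]
    try:
        ecg, ppg = data["ECG I"], data["PPG"]
    except KeyError as exc:
        raise FormatError(f"{path}: expected 'ECG I' and 'PPG' channels") from exc
    return Recording(subject_id=subject, fs=fs, ecg=ecg, ppg=ppg)


# ---------------------------------------------------------------------------
# front doors
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path, format: str = "csv") -> Path:
    if format == "csv":
        return write_recording_csv(rec, path)
    if format == "edf":
        return write_recording_edf(rec, path)
    raise FormatError(f"unknown recording format {format!r} (use 'csv' or 'edf')")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return read_recording_csv(path)
    if format == "edf":
        return read_recording_edf(path)
    raise FormatError(f"unknown recording format {format!r} (use 'csv' or 'edf')")


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------

def _jsonable(obj: Any, trail: str) -> Any:
    """Convert to JSON-serializable form; NaN becomes null with a warning."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name), f"{trail}.{f.name}")
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, f"{trail}.{k}") for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, f"{trail}[{i}]") for i, v in enumerate(obj)]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v, f"{trail}[{i}]") for i, v in enumerate(obj.tolist())]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        warnings.warn(
            f"non-finite value at {trail} serialized as null", stacklevel=3
        )
        return None
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"), trail)
    raise FormatError(f"report field {trail} of type {type(obj).__name__} "
                      "is not serializable")


def write_report(report: Any, path: str | Path, csv_path: str | Path | None = None,
                 ) -> Path:
    """Serialize an evaluation report to versioned JSON (and optionally CSV).

    The JSON is written with sorted keys so that identical reports are
    byte-identical files.  An empty report (zero subjects) is a contract
    violation, not an empty file.
    """
    path = Path(path)
    payload = _jsonable(report, "report")
    if not isinstance(payload, dict):
        raise FormatError("report must serialize to a JSON object")
    n = payload.get("n", None)
    if n == 0:
        raise FormatError("refusing to write a report for 0 subjects")
    payload.setdefault("schema_version", SCHEMA_VERSION)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1, allow_nan=False)
        fh.write("\n")
    if csv_path is not None:
        flat = _flatten(payload)
        pd.DataFrame(
            {"field": list(flat), "value": list(flat.values())}
        ).to_csv(csv_path, index=False)
    return path


def _flatten(d: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if isinstance(d, dict):
        for k, v in d.items():
            out.update(_flatten(v, f"{prefix}{k}."))
    elif isinstance(d, list):
        for i, v in enumerate(d):
            out.update(_flatten(v, f"{prefix}{i}."))
    else:
        out[prefix.rstrip(".")] = d
    return out


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
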