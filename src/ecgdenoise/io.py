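"""Record readers/writers: CSV with sampling-rate header, plain-text
annotation files, and a minimal read-only WFDB parser.

CSV dialect: comma-separated, UTF-8, '.' decimal, one comment line
``# fs_hz=<rate>`` followed by a ``time_s,ecg_mv`` header.  Values are
written with 17 significant digits so a round trip is lossless.

The WFDB support is a minimal parser for header (.hea) files and signal
files in formats 16 (16-bit little-endian) and 212 (packed 12-bit), enough
to read ambulatory arrhythmia-database records for the optional real-data
experiments; a format-16 writer exists so the test suite can build
fixtures.  It is not a general WFDB implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError


@dataclass(frozen=True)
class RecordFile:
    samples: np.ndarray
    fs: float
    annotations: np.ndarray | None = None


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------


def write_record(samples: np.ndarray, fs: float, path: str | Path) -> None:
    """Write a record as CSV; lossless at full double precision."""
    if fs <= 0:
        raise ParameterError("fs must be positive")
    samples = np.asarray(samples, dtype=float)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={float(fs)!r}\n")
        fh.write("time_s,ecg_mv\n")
        for i, v in enumerate(samples):
            fh.write(f"{i / fs!r},{float(v)!r}\n")


def read_record(path: str | Path) -> RecordFile:
    """Read a CSV record written by :func:`write_record` (or compatible)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fs = None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                fs = float(first.split("=", 1)[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:1: malformed fs header {first!r}") from exc
            skip = 1
        else:
            skip = 0
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path}: CSV parse failure: {exc}") from exc
    if "ecg_mv" not in df.columns or "time_s" not in df.columns:
        raise FormatError(f"{path}: expected columns time_s,ecg_mv, got {list(df.columns)}")
    for col in ("time_s", "ecg_mv"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col}, data row {row}"
            )
    samples = df["ecg_mv"].to_numpy(dtype=float)
    if fs is None:
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    ann_path = annotation_path(path)
    annotations = read_annotations(ann_path) if ann_path.exists() else None
    return RecordFile(samples=samples, fs=fs, annotations=annotations)


def annotation_path(record_path: str | Path) -> Path:
    return Path(record_path).with_suffix(".rpeaks.txt")


def write_annotations(indices: np.ndarray, path: str | Path) -> None:
    """One R-peak sample index per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for idx in np.asarray(indices, dtype=int):
            fh.write(f"{idx}\n")


def read_annotations(path: str | Path) -> np.ndarray:
    path = Path(path)
    out = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append(int(line))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: not an integer: {line!r}") from exc
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# minimal WFDB (read formats 16 and 212; write 16 for fixtures)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _WfdbSignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    description: str


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    rec_fields = lines[0].split()
    if len(rec_fields) < 3:
        raise FormatError(f"{hea_path}:1: record line needs name, n_sig, fs")
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0])
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else None
    specs = []
    for lineno, line in enumerate(lines[1 : 1 + n_sig], 2):
        f = line.split()
        if len(f) < 2:
            raise FormatError(f"{hea_path}:{lineno}: malformed signal line")
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = f[2] if len(f) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain, baseline = gain_str.split("(")
            baseline = int(baseline.rstrip(")"))
        else:
            gain, baseline = gain_str, 0
        specs.append(
            _WfdbSignalSpec(
                file_name=f[0],
                fmt=fmt,
                gain=float(gain) or 200.0,
                baseline=baseline,
                description=" ".join(f[8:]) if len(f) > 8 else f"sig{lineno - 2}",
            )
        )
    return n_sig, fs, n_samples, specs


def _decode_212(raw: bytes, n_samples_total: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_triplets = len(b) // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    out = np.empty(n_triplets * 2, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    return out[:n_samples_total]


def read_wfdb(record_path: str | Path, channel: int = 0) -> RecordFile:
    """Read one channel of a WFDB record given the path without extension."""
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"{hea}: no such header file")
    n_sig, fs, n_samples, specs = _parse_header(hea)
    if not 0 <= channel < n_sig:
        raise ParameterError(f"channel {channel} out of range for {n_sig} signals")
    spec = specs[channel]
    dat = record_path.parent / spec.file_name
    if not dat.exists():
        raise FormatError(f"{dat}: no such signal file")
    raw = dat.read_bytes()
    # channels sharing one .dat file are interleaved sample-by-sample
    sharing = [i for i, s in enumerate(specs) if s.file_name == spec.file_name]
    n_shared = len(sharing)
    pos = sharing.index(channel)
    if spec.fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif spec.fmt == 212:
        total = n_samples * n_shared if n_samples else (len(raw) // 3) * 2
        flat = _decode_212(raw, total)
    else:
        raise FormatError(f"{dat}: unsupported WFDB format {spec.fmt}")
    sig = flat[pos::n_shared]
    if n_samples is not None:
        sig = sig[:n_samples]
    physical = (sig - spec.baseline) / spec.gain
    return RecordFile(samples=physical.astype(float), fs=fs)


def write_wfdb_fixture(
    samples: np.ndarray, fs: float, record_path: str | Path, gain: float = 200.0
) -> None:
    """Write a single-channel format-16 WFDB record (test fixtures only)."""
    record_path = Path(record_path)
    samples = np.asarray(samples, dtype=float)
    digital = np.round(samples * gain).astype("<i2")
    name = record_path.name
    record_path.with_suffix(".hea").write_text(
        f"{name} 1 {fs:g} {len(samples)}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 ECG\n",
        encoding="utf-8",
    )
    (record_path.parent / f"{name}.dat").write_bytes(digital.tobytes())
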