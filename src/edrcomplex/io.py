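"""Plain-text I/O: ECG traces, beat series, rate traces and cohort tables.

Everything is CSV/JSON so records round-trip through version control and
spreadsheets.  ECG ground-truth annotations (synthetic records) travel in a
JSON sidecar next to the trace file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECGRecord, RPeakSeries, RateTrace
from .errors import SchemaError

__all__ = [
    "read_ecg_csv",
    "write_ecg_csv",
    "write_rpeaks_csv",
    "read_rpeaks_csv",
    "write_rate_trace_csv",
    "read_rate_trace_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = (
    "patient_id",
    "group",
    "etiology",
    "frequency_theta",
    "apg",
    "reactivity",
    "apen",
)
_VALID_GROUPS = {"UWS", "MCS", "EMCS"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".annotations.json")


def write_ecg_csv(ecg: ECGRecord, path: str | Path) -> Path:
    """Write an ECG as a two-column CSV (time_s, mv); annotations to a sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": ecg.times, "mv": ecg.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    if ecg.annotations is not None:
        _sidecar(path).write_text(
            json.dumps({"rpeak_times_s": list(map(float, ecg.annotations))})
        )
    return path


def read_ecg_csv(path: str | Path) -> ECGRecord:
    """Read a (time_s, mv) CSV; the sampling rate is inferred from the grid."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "mv"):
        if col not in df.columns:
            raise SchemaError(f"ECG CSV {path} is missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    # the writer stores time at microsecond precision; allow that rounding
    if len(dt) == 0 or np.ptp(dt) > 2.5e-6:
        raise SchemaError(f"ECG CSV {path}: time column is not a uniform grid")
    fs = (len(t) - 1) / float(t[-1] - t[0])
    if abs(fs - round(fs)) < 1e-3:  # written grids are integer-rate
        fs = float(round(fs))
    annotations = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        annotations = np.asarray(
            json.loads(sidecar.read_text())["rpeak_times_s"], dtype=float
        )
    return ECGRecord(samples=df["mv"].to_numpy(dtype=float), fs=fs, annotations=annotations)


def write_rpeaks_csv(rpeaks: RPeakSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": rpeaks.times, "flag": rpeaks.flags}).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_rpeaks_csv(path: str | Path) -> RPeakSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "flag"):
        if col not in df.columns:
            raise SchemaError(f"R-peak CSV {path} is missing column {col!r}")
    return RPeakSeries(
        times=df["time_s"].to_numpy(dtype=float),
        flags=df["flag"].to_numpy(dtype=object),
    )


def write_rate_trace_csv(
    rate: RateTrace, path: str | Path, params: dict | None = None
) -> Path:
    """Rate trace as CSV; fs_resample and processing parameters in a header comment."""
    path = Path(path)
    header = {"fs_resample": rate.fs_resample, **(params or {})}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        pd.DataFrame({"time_s": rate.times, "rate_bpm": rate.rate}).to_csv(
            fh, index=False, float_format="%.6f"
        )
    return path


def read_rate_trace_csv(path: str | Path) -> tuple[RateTrace, dict]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise SchemaError(f"rate-trace CSV {path} lacks the parameter header line")
        params = json.loads(first.lstrip("# ").strip())
        df = pd.read_csv(fh)
    trace = RateTrace(
        times=df["time_s"].to_numpy(dtype=float),
        rate=df["rate_bpm"].to_numpy(dtype=float),
        fs_resample=float(params["fs_resample"]),
    )
    return trace, params


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path, require_apen: bool = True) -> pd.DataFrame:
    """Read and validate a cohort table.

    Raises :class:`SchemaError` naming the offending column on any violation:
    missing column, unknown group label, non-binary descriptor, or
    non-numeric ApEn (blank ApEn allowed with ``require_apen=False`` for
    to-be-computed cohorts).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = [c for c in COHORT_COLUMNS if require_apen or c != "apen"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"cohort table {path} is missing column {col!r}")
    bad_groups = set(df["group"].astype(str)) - _VALID_GROUPS
    if bad_groups:
        raise SchemaError(
            f"cohort table {path}: column 'group' has invalid labels {sorted(bad_groups)}"
        )
    for col in ("frequency_theta", "apg", "reactivity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not set(vals.unique()) <= {0, 1}:
            raise SchemaError(
                f"cohort table {path}: column {col!r} must be binary 0/1"
            )
        df[col] = vals.astype(int)
    if "apen" in df.columns:
        apen = pd.to_numeric(df["apen"], errors="coerce")
        if require_apen and apen.isna().any():
            raise SchemaError(
                f"cohort table {path}: column 'apen' has missing or non-numeric values"
            )
        df["apen"] = apen
    df["group"] = pd.Categorical(
        df["group"].astype(str), categories=["UWS", "MCS", "EMCS"], ordered=True
    )
    return df
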