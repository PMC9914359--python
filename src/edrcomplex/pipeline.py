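"""End-to-end orchestration: config, per-record processing, cohort analysis.

:func:`process_record` turns one ECG into a clean rate trace, EDR signal and
ApEn value.  :func:`run_analysis` runs a whole study: generate (or load) a
cohort, compute ApEn where needed, and emit the descriptive, factorial and
model-comparison reports plus a provenance log, all as text files in the
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ecg import ECGRecord, correct_ectopic, detect_rpeaks, instantaneous_rate
from .edr import approximate_entropy, estimate_resp_rate, extract_edr
from .errors import EDRComplexError, InvalidArgumentError
from .io import read_cohort_csv, read_ecg_csv, write_cohort_csv
from .report import descriptive_report, factorial_report, models_report
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "process_record", "run_analysis"]

log = logging.getLogger("edrcomplex")

MODES = ("synthetic-feature", "synthetic-signal", "user-data")


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable run configuration (provenance travels with outputs)."""

    mode: str = "synthetic-feature"
    cohort_path: str | None = None  # user-data mode
    seed: int = 0
    out_dir: str = "edrcomplex_run"
    # processing parameters
    fs_resample: float = 4.0
    passband: tuple[float, float] = (0.1, 0.4)
    m: int = 2
    r_factor: float = 0.2
    ectopic_tolerance: float = 0.3
    detect_lowpass_hz: float | None = 5.0
    # synthetic-signal parameters
    record_duration: float = 600.0
    group_sizes: tuple[int, int, int] = (42, 61, 99)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidArgumentError(f"mode must be one of {MODES}; got {self.mode!r}")
        if self.mode == "user-data" and not self.cohort_path:
            raise InvalidArgumentError("user-data mode requires cohort_path")
        if not (0 < self.passband[0] < self.passband[1] < self.fs_resample / 2):
            raise InvalidArgumentError("passband must lie inside (0, fs_resample/2)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def process_record(
    ecg: ECGRecord,
    fs_resample: float = 4.0,
    passband: tuple[float, float] = (0.1, 0.4),
    ectopic_tolerance: float = 0.3,
    m: int = 2,
    r_factor: float = 0.2,
    detect_lowpass_hz: float | None = 5.0,
) -> dict:
    """Run one ECG through the full analysis path.

    Returns a dict with the corrected beat series, rate trace, EDR signal,
    the estimated respiratory rate (Hz) and the ApEn result.
    """
    rpeaks = detect_rpeaks(ecg, lowpass_cutoff=detect_lowpass_hz)
    corrected = correct_ectopic(rpeaks, tolerance=ectopic_tolerance)
    rate = instantaneous_rate(corrected, fs_resample=fs_resample)
    edr = extract_edr(rate, passband=passband)
    resp_rate = estimate_resp_rate(edr)
    apen = approximate_entropy(edr.values, m=m, r_factor=r_factor)
    return {
        "rpeaks": corrected,
        "rate": rate,
        "edr": edr,
        "resp_rate_hz": resp_rate,
        "apen": apen,
    }


def _stage(name: str, out_dir: Path):
    """Context manager: stage timing/logging and FAILED-marker bookkeeping."""

    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise EDRComplexError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, dt)

    return _Stage()


def run_analysis(config: RunConfig) -> dict:
    """Run the full study per `config`; write reports; return them in-memory.

    Outputs in ``config.out_dir``: ``cohort.csv`` (with computed ApEn),
    ``descriptive_report.json``, ``factorial_report.json``,
    ``models_report.json``, ``run_log.json``.  Any stage failure leaves a
    ``FAILED`` marker file naming the stage; partial outputs are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "FAILED"
    if marker.exists():
        marker.unlink()
    t_start = time.perf_counter()

    with _stage("cohort", out_dir):
        if config.mode == "user-data":
            cohort = read_cohort_csv(config.cohort_path, require_apen=False)
            if cohort["apen"].isna().any() if "apen" in cohort.columns else True:
                cohort = _compute_missing_apen(cohort, config)
        else:
            spec = CohortSpec(seed=config.seed, group_sizes=config.group_sizes)
            mode = "feature" if config.mode == "synthetic-feature" else "signal"
            cohort = generate_cohort(spec, mode=mode, duration=config.record_duration)
        write_cohort_csv(cohort, out_dir / "cohort.csv")

    reports: dict[str, dict] = {}
    with _stage("descriptive", out_dir):
        reports["descriptive"] = descriptive_report(cohort)
    with _stage("factorial", out_dir):
        reports["factorial"] = factorial_report(cohort)
    with _stage("models", out_dir):
        reports["models"] = models_report(cohort)

    run_log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients": int(len(cohort)),
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    reports["run_log"] = run_log
    for name, payload in reports.items():
        (out_dir / f"{name if name.endswith('log') else name + '_report'}.json").write_text(
            json.dumps(payload, indent=2, default=_json_default) + "\n"
        )
    return {"cohort": cohort, **reports}


def _compute_missing_apen(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Fill blank ApEn values by processing each patient's referenced ECG."""
    if "ecg_path" not in cohort.columns:
        raise InvalidArgumentError(
            "cohort has missing ApEn values but no 'ecg_path' column to compute them from"
        )
    cohort = cohort.copy()
    if "apen" not in cohort.columns:
        cohort["apen"] = np.nan
    for idx, row in cohort.iterrows():
        if pd.notna(row["apen"]):
            continue
        ecg = read_ecg_csv(row["ecg_path"])
        result = process_record(
            ecg,
            fs_resample=config.fs_resample,
            passband=config.passband,
            ectopic_tolerance=config.ectopic_tolerance,
            m=config.m,
            r_factor=config.r_factor,
            detect_lowpass_hz=config.detect_lowpass_hz,
        )
        cohort.loc[idx, "apen"] = result["apen"].value
    return cohort


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
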