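"""Synthetic ECG cohorts with controllable respiratory complexity.

Real recordings from the study population are not redistributable, so this
module generates data with the statistical structure the analysis assumes:

* a respiratory-rate process whose regularity is controlled by one knob
  (the AR(1) fluctuation sd) — :func:`simulate_resp_rate_trace`;
* an R-peak train carrying respiratory sinus arrhythmia, generated by
  integral pulse frequency modulation (IPFM): a beat fires each time the
  integral of the instantaneous rate crosses an integer —
  :func:`simulate_rpeak_train`;
* ectopic-beat corruption (premature and missed beats) with a perturbation
  log for the correction stage's tests — :func:`inject_ectopic_beats`;
* a rendered single-lead ECG waveform (sum-of-Gaussians P-QRS-T template)
  with ground-truth peak annotations — :func:`render_ecg`;
* full cohorts whose per-class approximate-entropy distributions, EEG
  descriptor prevalences and etiology mixes default to the published
  three-group cohort (42 unresponsive-wakefulness, 61 minimally-conscious,
  99 emerged patients) — :func:`generate_cohort`.

Cohorts come in two modes: *feature-level* (ApEn drawn directly from a
log-normal matched to each class's median/IQR) and *signal-level* (per
patient, a modulation sd is chosen through a simulated calibration curve so
the measured pipeline ApEn lands near the class target, and the actual ECG
is generated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .ecg import (
    ECGRecord,
    RPeakSeries,
    correct_ectopic,
    instantaneous_rate,
)
from .edr import approximate_entropy, extract_edr
from .errors import CalibrationError, InvalidArgumentError

__all__ = [
    "RespRateProcess",
    "RSAParams",
    "CohortSpec",
    "RespRateTrace",
    "simulate_resp_rate_trace",
    "simulate_rpeak_train",
    "inject_ectopic_beats",
    "render_ecg",
    "generate_cohort",
    "pipeline_apen",
    "build_apen_calibration",
    "fit_lognormal_to_median_iqr",
    "GROUPS",
    "ETIOLOGIES",
]

GROUPS = ("UWS", "MCS", "EMCS")
ETIOLOGIES = ("traumatic", "anoxic", "ischemic", "hemorrhagic")

RATE_CLIP = (0.05, 0.45)  # Hz; respiratory rate kept strictly positive and
# inside a physiologically plausible band around the 0.1-0.4 Hz passband


@dataclass(frozen=True)
class RespRateProcess:
    """Stochastic respiratory-rate process: base rate plus AR(1) fluctuation.

    `modulation_sd` is the *stationary* standard deviation of the
    fluctuation (Hz); `ar_coefficient` sets its correlation time.  Larger
    `modulation_sd` produces a less regular breathing rhythm and hence a
    higher downstream approximate entropy.
    """

    base_rate: float = 0.25
    modulation_sd: float = 0.02
    ar_coefficient: float = 0.995
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.1 < self.base_rate < 0.4):
            raise InvalidArgumentError(
                f"base_rate must lie in (0.1, 0.4) Hz; got {self.base_rate}"
            )
        if self.modulation_sd < 0:
            raise InvalidArgumentError("modulation_sd must be >= 0")
        if not (0 <= self.ar_coefficient < 1):
            raise InvalidArgumentError("ar_coefficient must be in [0, 1)")


@dataclass(frozen=True)
class RSAParams:
    """Heart-rate parameters: mean rate, RSA depth, jitter, ectopic rate."""

    mean_hr: float = 75.0  # beats/min
    rsa_depth: float = 5.0  # beats/min
    hr_jitter_sd: float = 0.0  # beats/min
    ectopic_rate: float = 0.0  # events/min

    def __post_init__(self) -> None:
        if self.mean_hr <= 0:
            raise InvalidArgumentError("mean_hr must be positive")
        if self.rsa_depth < 0:
            raise InvalidArgumentError("rsa_depth must be >= 0")
        if self.rsa_depth >= self.mean_hr:
            raise InvalidArgumentError("rsa_depth must be < mean_hr")
        if self.hr_jitter_sd < 0 or self.ectopic_rate < 0:
            raise InvalidArgumentError("noise rates must be >= 0")


@dataclass
class RespRateTrace:
    """Uniformly sampled instantaneous respiratory rate (Hz)."""

    times: np.ndarray
    rate_hz: np.ndarray
    fs: float


def simulate_resp_rate_trace(
    process: RespRateProcess, duration: float, fs_out: float = 8.0
) -> RespRateTrace:
    """Simulate r(t) = base_rate + AR(1) fluctuation, clipped to (0.05, 0.45) Hz.

    The AR(1) innovation variance is scaled so the stationary sd of the
    fluctuation equals ``process.modulation_sd`` regardless of
    ``ar_coefficient``; the initial state is drawn from the stationary
    distribution, so the trace is stationary from the first sample.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if fs_out < 1:
        raise InvalidArgumentError("fs_out must be >= 1 Hz")
    rng = np.random.default_rng(process.seed)
    n = int(round(duration * fs_out)) + 1
    phi = process.ar_coefficient
    sd = process.modulation_sd
    x = np.zeros(n)
    if sd > 0:
        innov_sd = sd * math.sqrt(1 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        x[0] = rng.normal(0.0, sd)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
    rate = np.clip(process.base_rate + x, *RATE_CLIP)
    times = np.arange(n) / fs_out
    return RespRateTrace(times=times, rate_hz=rate, fs=fs_out)


def simulate_rpeak_train(
    rsa: RSAParams,
    resp: RespRateTrace,
    duration: float,
    seed: int = 0,
) -> RPeakSeries:
    """Generate R-peak times by integral pulse frequency modulation.

    The instantaneous heart rate (beats/min) is

        hr(t) = mean_hr + rsa_depth * sin(2*pi * integral of resp rate) + jitter

    and a beat fires whenever the integral of hr(t)/60 crosses the next
    integer.  Crossing times are located by linear interpolation on the
    respiratory grid, so beat count equals floor(integral of rate) up to the
    boundary beat.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = np.random.default_rng(seed)
    mask = resp.times <= duration + 1.0 / resp.fs
    t = resp.times[mask]
    r = resp.rate_hz[mask]
    resp_phase = cumulative_trapezoid(r, t, initial=0.0)  # cycles
    hr = rsa.mean_hr + rsa.rsa_depth * np.sin(2 * np.pi * resp_phase)
    if rsa.hr_jitter_sd > 0:
        hr = hr + rng.normal(0.0, rsa.hr_jitter_sd, size=len(hr))
    if np.any(hr <= 0):
        raise InvalidArgumentError(
            "parameters imply a non-positive instantaneous heart rate"
        )
    beat_phase = cumulative_trapezoid(hr / 60.0, t, initial=0.0)  # beats
    n_beats = int(np.floor(beat_phase[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    # beat_phase is strictly increasing (hr > 0): invert by interpolation
    beat_times = np.interp(targets, beat_phase, t)
    beat_times = beat_times[beat_times <= duration]
    return RPeakSeries(times=beat_times, duration=duration)


@dataclass
class EctopicLog:
    """Record of injected perturbations, for correction-stage assertions."""

    kinds: list[str] = field(default_factory=list)  # "premature" | "missed"
    times: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.kinds)


def inject_ectopic_beats(
    rpeaks: RPeakSeries, rate: float, seed: int = 0
) -> tuple[RPeakSeries, EctopicLog]:
    """Corrupt a beat train with premature (split) and missed (merged) beats.

    The number of perturbations is Poisson with mean ``rate`` events/min over
    the record duration; each is a premature beat (an extra beat inserted at
    ~40% of a randomly chosen interval) or a missed beat (an interior beat
    deleted), with equal probability.  Returns the corrupted train and a log
    of what was done.
    """
    if rate < 0:
        raise InvalidArgumentError("ectopic rate must be >= 0")
    log = EctopicLog()
    if rate == 0 or len(rpeaks) < 5:
        return RPeakSeries(
            times=rpeaks.times.copy(), flags=rpeaks.flags.copy(), duration=rpeaks.duration
        ), log
    rng = np.random.default_rng(seed)
    duration_min = (rpeaks.times[-1] - rpeaks.times[0]) / 60.0
    n_events = rng.poisson(rate * duration_min)
    times = list(rpeaks.times)
    for _ in range(n_events):
        if len(times) < 5:
            break
        kind = "premature" if rng.random() < 0.5 else "missed"
        if kind == "premature":
            i = int(rng.integers(1, len(times) - 1))
            new_t = times[i] + 0.4 * (times[i + 1] - times[i])
            times.insert(i + 1, new_t)
            log.kinds.append("premature")
            log.times.append(new_t)
        else:
            i = int(rng.integers(2, len(times) - 2))
            log.kinds.append("missed")
            log.times.append(times[i])
            del times[i]
    return RPeakSeries(times=np.asarray(times), duration=rpeaks.duration), log


# sum-of-Gaussians beat template: (offset s, amplitude mV, width s)
_BEAT_TEMPLATE = (
    (-0.20, 0.10, 0.030),  # P
    (-0.035, -0.12, 0.010),  # Q
    (0.0, 1.00, 0.012),  # R
    (0.035, -0.15, 0.010),  # S
    (0.25, 0.25, 0.045),  # T
)


def render_ecg(
    rpeaks: RPeakSeries,
    fs: float = 128.0,
    noise_sd: float = 0.0,
    baseline_wander_mv: float = 0.0,
    baseline_wander_hz: float = 0.3,
    seed: int = 0,
) -> ECGRecord:
    """Render an ECG waveform by stamping a P-QRS-T template at each beat.

    The waveform is a flat baseline plus, per beat, a fixed sum-of-Gaussians
    template centred on the beat time, plus optional white noise and slow
    sinusoidal baseline wander.  Ground-truth beat times are stored as
    annotations for detector validation.
    """
    if fs < 64:
        raise InvalidArgumentError(
            f"fs must be >= 64 Hz to represent the QRS complex; got {fs}"
        )
    duration = rpeaks.duration if rpeaks.duration else float(rpeaks.times[-1]) + 1.0
    n = int(round(duration * fs))
    samples = np.zeros(n)
    half_w = 0.45  # s; template support around each beat
    for t_beat in rpeaks.times:
        lo = max(0, int(math.floor((t_beat - half_w) * fs)))
        hi = min(n, int(math.ceil((t_beat + half_w) * fs)) + 1)
        if hi <= lo:
            continue
        t_rel = np.arange(lo, hi) / fs - t_beat
        for offset, amp, width in _BEAT_TEMPLATE:
            samples[lo:hi] += amp * np.exp(-0.5 * ((t_rel - offset) / width) ** 2)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    if baseline_wander_mv > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        samples = samples + baseline_wander_mv * np.sin(
            2 * np.pi * baseline_wander_hz * t + phase
        )
    return ECGRecord(samples=samples, fs=fs, annotations=rpeaks.times.copy())


# ---------------------------------------------------------------------------
# cohort generation


def _etiology_mix_default() -> dict[str, tuple[float, ...]]:
    # per-class distribution over (traumatic, anoxic, ischemic, hemorrhagic),
    # from the published per-group etiology counts
    counts = {
        "UWS": (8, 7, 6, 21),
        "MCS": (20, 1, 9, 31),
        "EMCS": (44, 5, 19, 31),
    }
    return {g: tuple(c / sum(v) for c in v) for g, v in counts.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative spec; defaults reproduce the published cohort.

    ``group_complexity_targets`` maps each ordered class to its target
    (median, IQR) of approximate entropy; ``descriptor_prevalences`` maps
    each binary EEG descriptor to per-class presence probabilities;
    ``etiology_mix`` maps each class to a categorical distribution over
    injury etiologies.
    """

    group_sizes: tuple[int, int, int] = (42, 61, 99)
    group_complexity_targets: tuple[tuple[float, float], ...] = (
        (0.97, 0.22),  # UWS median [IQR]
        (1.11, 0.34),  # MCS
        (1.10, 0.28),  # EMCS
    )
    descriptor_prevalences: tuple[tuple[float, float, float], ...] = (
        (4 / 42, 14 / 61, 49 / 99),  # frequency_theta
        (8 / 42, 16 / 61, 39 / 99),  # apg
        (9 / 42, 24 / 61, 52 / 99),  # reactivity
    )
    etiology_mix: tuple[tuple[float, ...], ...] = tuple(
        _etiology_mix_default()[g] for g in GROUPS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.group_sizes):
            raise InvalidArgumentError("group sizes must be positive")
        for row in self.descriptor_prevalences:
            if any(not (0 <= p <= 1) for p in row):
                raise InvalidArgumentError("prevalences must be in [0, 1]")
        for row in self.etiology_mix:
            if abs(sum(row) - 1.0) > 1e-9:
                raise InvalidArgumentError("etiology mix rows must sum to 1")


DESCRIPTORS = ("frequency_theta", "apg", "reactivity")

_Z75 = 0.674489750196082  # 75th-percentile standard-normal quantile


def fit_lognormal_to_median_iqr(
    median: float, iqr: float, loc: float = 0.0
) -> tuple[float, float, float]:
    """Parameters (mu, sigma, loc) of a shifted log-normal with given median/IQR.

    For X = loc + exp(mu + sigma*Z):  median = loc + e^mu and
    IQR = 2 e^mu sinh(z75*sigma), so sigma has the closed form
    asinh(IQR / (2 e^mu)) / z75.
    """
    scale = median - loc
    if scale <= 0:
        raise InvalidArgumentError("median must exceed the location shift")
    if iqr <= 0:
        raise InvalidArgumentError("IQR must be positive")
    mu = math.log(scale)
    sigma = math.asinh(iqr / (2 * scale)) / _Z75
    return mu, sigma, loc


def _draw_class_apen(
    rng: np.random.Generator, n: int, median: float, iqr: float, loc: float = 0.0
) -> np.ndarray:
    mu, sigma, loc = fit_lognormal_to_median_iqr(median, iqr, loc)
    return loc + rng.lognormal(mean=mu, sigma=sigma, size=n)


def pipeline_apen(
    modulation_sd: float,
    seed: int,
    duration: float = 600.0,
    base_rate: float = 0.25,
    ar_coefficient: float = 0.995,
    rsa: RSAParams | None = None,
    fs_resample: float = 4.0,
    m: int = 2,
    r_factor: float = 0.2,
) -> float:
    """Approximate entropy measured through the beat-level pipeline.

    Simulates the respiratory-rate process and the IPFM beat train, then runs
    the analysis path (ectopic correction, rate resampling, respiratory
    band-pass, ApEn).  Used by the signal-mode calibration and by the
    monotonicity checks; ECG rendering/detection is bypassed here because it
    recovers the beat times near-exactly on clean records and would only add
    cost.
    """
    proc = RespRateProcess(
        base_rate=base_rate,
        modulation_sd=modulation_sd,
        ar_coefficient=ar_coefficient,
        seed=seed,
    )
    resp = simulate_resp_rate_trace(proc, duration=duration, fs_out=8.0)
    rsa = rsa or RSAParams(mean_hr=75.0, rsa_depth=5.0, hr_jitter_sd=0.5)
    rpeaks = simulate_rpeak_train(rsa, resp, duration=duration, seed=seed + 1)
    rpeaks = correct_ectopic(rpeaks)
    rate = instantaneous_rate(rpeaks, fs_resample=fs_resample)
    edr = extract_edr(rate)
    return approximate_entropy(edr.values, m=m, r_factor=r_factor).value


_CALIBRATION_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def build_apen_calibration(
    sd_grid: tuple[float, ...] = (0.002, 0.005, 0.01, 0.02, 0.04, 0.08),
    n_seeds: int = 5,
    duration: float = 600.0,
    seed: int = 0,
    **pipeline_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Median pipeline-ApEn as a function of respiratory modulation sd.

    Built by simulation (there is no closed form linking the AR(1) sd to the
    entropy of the band-passed rate trace) and cached per configuration.
    Returns (sd_grid, median_apen); the curve is empirically increasing,
    which the test suite asserts.
    """
    key = (sd_grid, n_seeds, duration, seed, tuple(sorted(pipeline_kwargs.items())))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    medians = []
    for j, sd in enumerate(sd_grid):
        vals = [
            pipeline_apen(sd, seed=seed + 1000 * j + k, duration=duration, **pipeline_kwargs)
            for k in range(n_seeds)
        ]
        medians.append(float(np.median(vals)))
    out = (np.asarray(sd_grid, dtype=float), np.asarray(medians))
    _CALIBRATION_CACHE[key] = out
    return out


def _invert_calibration(
    target: float, sd_grid: np.ndarray, apen_grid: np.ndarray
) -> float:
    # enforce monotonicity before inversion; simulation noise can produce
    # tiny local dips
    apen_mono = np.maximum.accumulate(apen_grid)
    lo, hi = apen_mono[0], apen_mono[-1]
    if not (lo <= target <= hi):
        raise CalibrationError(
            f"target ApEn {target:.3f} outside the attainable range "
            f"[{lo:.3f}, {hi:.3f}] for this configuration"
        )
    return float(np.interp(target, apen_mono, sd_grid))


def generate_cohort(
    spec: CohortSpec,
    mode: str = "feature",
    duration: float = 600.0,
    calibration: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Generate a cohort table (and, in signal mode, measure ApEn end-to-end).

    Parameters
    ----------
    mode : {"feature", "signal"}
        ``feature``: ApEn drawn per class from a log-normal matched to the
        class target median/IQR.  ``signal``: per patient, the class target
        draw is mapped through the simulated calibration curve to a
        respiratory modulation sd, the beat train is generated and the
        pipeline ApEn actually measured.
    duration : float
        Record length (s) for signal mode.
    calibration : optional
        Precomputed (sd_grid, apen_grid) from :func:`build_apen_calibration`.

    Returns
    -------
    DataFrame with columns patient_id, group, etiology, frequency_theta,
    apg, reactivity, apen (and modulation_sd in signal mode).  Group labels
    are ordered UWS < MCS < EMCS.
    """
    if mode not in ("feature", "signal"):
        raise InvalidArgumentError(f"unknown cohort mode {mode!r}")
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    if mode == "signal" and calibration is None:
        calibration = build_apen_calibration(seed=spec.seed, duration=duration)
    pid = 0
    for g_idx, group in enumerate(GROUPS):
        n = spec.group_sizes[g_idx]
        med, iqr = spec.group_complexity_targets[g_idx]
        targets = _draw_class_apen(rng, n, med, iqr)
        for i in range(n):
            row: dict = {"patient_id": f"P{pid:04d}", "group": group}
            row["etiology"] = ETIOLOGIES[
                rng.choice(len(ETIOLOGIES), p=spec.etiology_mix[g_idx])
            ]
            for d_idx, desc in enumerate(DESCRIPTORS):
                p = spec.descriptor_prevalences[d_idx][g_idx]
                row[desc] = int(rng.random() < p)
            if mode == "feature":
                row["apen"] = float(targets[i])
            else:
                sd = _invert_calibration(
                    float(np.clip(targets[i], calibration[1][0], calibration[1][-1])),
                    *calibration,
                )
                row["modulation_sd"] = sd
                row["apen"] = pipeline_apen(
                    sd, seed=int(rng.integers(2**31 - 1)), duration=duration
                )
            rows.append(row)
            pid += 1
    df = pd.DataFrame(rows)
    df["group"] = pd.Categorical(df["group"], categories=list(GROUPS), ordered=True)
    return df
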