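"""ECG-derived respiration (EDR) and its approximate entropy (ApEn).

Respiratory sinus arrhythmia imprints the breathing rhythm on the
instantaneous heart rate; band-passing the rate trace in the respiratory band
(0.1-0.4 Hz) therefore yields a respiratory surrogate waveform without any
dedicated respiration sensor.  The regularity of that waveform is summarised
by approximate entropy:

    ApEn(m, r, N) = phi^m(r) - phi^{m+1}(r)

where phi^m(r) is the average natural log of the fraction of m-length
template pairs whose Chebyshev distance is at most r.  Self-matches are
included (the classic formulation), so every C_i is positive and the result
is well defined; a constant series gives exactly 0.  With the tolerance tied
to the series standard deviation (r = r_factor * sd) the statistic is
invariant under affine rescaling of the input.

Two implementations are provided: a vectorised production routine
(:func:`approximate_entropy`) and a deliberately literal nested-loop
reference (:func:`apen_bruteforce_oracle`) used to pin down the former in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .ecg import RateTrace
from .errors import DegenerateSeriesError, InvalidArgumentError, TooShortError

__all__ = [
    "EDRSignal",
    "ApENParams",
    "ApENResult",
    "extract_edr",
    "estimate_resp_rate",
    "approximate_entropy",
    "apen_bruteforce_oracle",
    "apen_sensitivity_grid",
]

DEFAULT_PASSBAND = (0.1, 0.4)


@dataclass
class EDRSignal:
    """Band-limited respiratory surrogate derived from the heart-rate trace."""

    times: np.ndarray
    values: np.ndarray
    fs: float
    passband: tuple[float, float] = DEFAULT_PASSBAND

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise InvalidArgumentError("times and values must be equal length")

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.fs if len(self.values) else 0.0


@dataclass(frozen=True)
class ApENParams:
    """Approximate-entropy parameters: embedding length m, tolerance, length N."""

    m: int
    r_factor: float | None
    r_absolute: float
    n: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidArgumentError("m must be >= 1")
        if self.n <= self.m + 1:
            raise TooShortError(f"need N > m+1; got N={self.n}, m={self.m}")
        if self.r_absolute < 0:
            raise InvalidArgumentError("tolerance r must be non-negative")


@dataclass(frozen=True)
class ApENResult:
    """ApEn value with its parameters and the intermediate phi averages."""

    value: float
    params: ApENParams
    phi_m: float
    phi_m1: float
    degenerate: bool = False


def extract_edr(
    rate: RateTrace,
    passband: tuple[float, float] = DEFAULT_PASSBAND,
    order: int = 2,
    trim: float = 10.0,
) -> EDRSignal:
    """Band-pass the mean-removed rate trace into the respiratory band.

    A zero-phase second-order Butterworth band-pass (default 0.1-0.4 Hz) is
    applied to the mean-removed instantaneous heart rate; the first and last
    `trim` seconds are dropped to discard filter transients.

    Raises
    ------
    TooShortError
        If fewer than 60 s of signal remain after trimming.
    """
    lo, hi = passband
    nyq = rate.fs_resample / 2
    if not (0 < lo < hi < nyq):
        raise InvalidArgumentError(
            f"passband must satisfy 0 < lo < hi < fs/2={nyq}; got {passband}"
        )
    x = rate.rate - np.mean(rate.rate)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate.fs_resample, output="sos")
    y = sps.sosfiltfilt(sos, x)
    n_trim = int(round(trim * rate.fs_resample))
    if len(y) - 2 * n_trim < 60 * rate.fs_resample:
        raise TooShortError(
            "less than 60 s of EDR signal remains after transient trimming"
        )
    sl = slice(n_trim, len(y) - n_trim if n_trim else None)
    values = y[sl]
    # residual DC from filter edge transients; the EDR is zero-mean by design
    values = values - values.mean()
    return EDRSignal(
        times=rate.times[sl], values=values, fs=rate.fs_resample, passband=(lo, hi)
    )


def estimate_resp_rate(edr: EDRSignal) -> float:
    """Dominant respiratory frequency (Hz): periodogram peak within the passband.

    Raises
    ------
    DegenerateSeriesError
        If the signal is identically zero (no spectral peak).
    """
    if np.allclose(edr.values, 0):
        raise DegenerateSeriesError("all-zero EDR signal: no rate estimate")
    freqs, pxx = sps.periodogram(edr.values, fs=edr.fs, detrend="constant")
    lo, hi = edr.passband
    band = (freqs >= lo) & (freqs <= hi)
    if not np.any(band) or np.max(pxx[band]) <= 0:
        raise DegenerateSeriesError("no spectral power inside the passband")
    return float(freqs[band][np.argmax(pxx[band])])


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """phi^m(r): mean over i of ln( #{j : d(S_i,S_j) <= r} / (N-m+1) ).

    Chebyshev distance over m-length templates; self-matches included.
    Vectorised over template pairs; memory is kept bounded by chunking the
    outer index.
    """
    n = len(x)
    n_templates = n - m + 1
    # templates as a strided (n_templates, m) view
    templ = np.lib.stride_tricks.sliding_window_view(x, m)
    counts = np.empty(n_templates, dtype=np.int64)
    chunk = max(1, int(4e7) // (n_templates * m))  # ~300 MB worst case
    for start in range(0, n_templates, chunk):
        stop = min(start + chunk, n_templates)
        d = np.abs(templ[start:stop, None, :] - templ[None, :, :]).max(axis=2)
        counts[start:stop] = np.count_nonzero(d <= r, axis=1)
    c = counts / n_templates
    return float(np.mean(np.log(c)))


def approximate_entropy(
    series: Sequence[float] | np.ndarray,
    m: int = 2,
    r_factor: float | None = 0.2,
    r_absolute: float | None = None,
) -> ApENResult:
    """Approximate entropy of a numeric series.

    The tolerance is ``r = r_factor * sd(series)`` by default; pass
    `r_absolute` (and ``r_factor=None``) for an absolute tolerance.

    A zero-variance series with a relative tolerance is degenerate: the
    result is 0 with ``degenerate=True`` rather than an error, since a
    constant signal is maximally regular by any reading.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("series must be one-dimensional")
    n = len(x)
    if n <= m + 1:
        raise TooShortError(f"need N > m+1; got N={n}, m={m}")
    if (r_factor is None) == (r_absolute is None):
        raise InvalidArgumentError("specify exactly one of r_factor, r_absolute")
    if r_absolute is None:
        sd = float(np.std(x))
        if sd == 0:
            params = ApENParams(m=m, r_factor=r_factor, r_absolute=0.0, n=n)
            return ApENResult(
                value=0.0, params=params, phi_m=0.0, phi_m1=0.0, degenerate=True
            )
        r = r_factor * sd
    else:
        r = float(r_absolute)
    params = ApENParams(m=m, r_factor=r_factor, r_absolute=r, n=n)
    phi_m = _phi(x, m, r)
    phi_m1 = _phi(x, m + 1, r)
    return ApENResult(value=phi_m - phi_m1, params=params, phi_m=phi_m, phi_m1=phi_m1)


def apen_bruteforce_oracle(
    series: Sequence[float], m: int, r_absolute: float
) -> float:
    """Literal nested-loop ApEn reference (test use; N <= 2000).

    Transcribes the definition with explicit loops and no vectorisation:
    for each template pair the Chebyshev distance is a max over m scalar
    differences, counts include the self-match, and
    ApEn = phi^m - phi^{m+1}.
    """
    x = [float(v) for v in series]
    n = len(x)
    if n > 2000:
        raise InvalidArgumentError("oracle is for small test series (N <= 2000)")
    if n <= m + 1:
        raise TooShortError(f"need N > m+1; got N={n}, m={m}")

    import math

    def phi(mm: int) -> float:
        n_templates = n - mm + 1
        total = 0.0
        for i in range(n_templates):
            count = 0
            for j in range(n_templates):
                d = 0.0
                for k in range(mm):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                if d <= r_absolute:
                    count += 1
            total += math.log(count / n_templates)
        return total / n_templates

    return phi(m) - phi(m + 1)


def apen_sensitivity_grid(
    series: Sequence[float] | np.ndarray,
    m_values: Sequence[int] = (1, 2, 3),
    r_factors: Sequence[float] = (0.1, 0.15, 0.2, 0.25),
) -> dict[tuple[int, float], float]:
    """ApEn over a small (m, r_factor) grid, for parameter-sensitivity checks."""
    return {
        (m, rf): approximate_entropy(series, m=m, r_factor=rf).value
        for m in m_values
        for rf in r_factors
    }
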