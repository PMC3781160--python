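"""Long-range-correlation metrics for stride-interval series.

Two complementary indices distinguish white noise, Brownian noise and
long-range-correlated series:

* **DFA** (detrended fluctuation analysis).  The mean-subtracted intervals
  are integrated to a profile ``y``; for each window size ``n`` the profile
  is split into non-overlapping windows from the series start, a least
  squares line is fitted in every window, and ``F(n)`` is the RMS residual
  over the covered samples.  The scaling exponent ``alpha`` is the slope of
  the least-squares line relating ``log F(n)`` to ``log n``: 0.5 for white
  noise, 1.5 for Brownian noise, between 0.5 and 1 for long-range
  correlations.  Window sizes run from 4 to half the series length with
  0.1 increments of ``log10 n``.

* **Spectral exponent**.  ``S(f)`` is the squared amplitude of the Fourier
  spectrum of the mean-subtracted series, ``f`` the inverse stride number;
  the regression slope of ``log S`` on ``log f`` is 0 for white noise, -1
  for 1/f noise, -2 for Brownian noise.  ``beta`` is -1 times the slope.
  The fit range depends on the series length (0.01–0.3 strides^-1 for
  500-stride series, 1/600–0.3 for 3,000, 2e-5–0.3 for 100,000).

Shuffled (Theiler) surrogates destroy temporal order while preserving the
value distribution exactly, isolating sequential structure as the origin of
any scaling.  Significance is assessed at the 5% level with t-tests
(one-sample against a reference constant, paired against per-run
surrogates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import DegenerateSeriesError
from .series import StrideSeries

__all__ = [
    "DFAResult", "SpectrumResult", "StatTestResult",
    "integrated_profile", "dfa_window_grid", "dfa_fluctuation", "dfa_alpha",
    "power_spectrum", "spectral_beta", "spectral_fit_range",
    "shuffle_surrogate", "cov_percent", "exponent_tests",
]

ArrayLike = Union[StrideSeries, np.ndarray, Sequence[float]]

SIGNIFICANCE_LEVEL = 0.05

#: Published spectral fit ranges keyed by series length (strides^-1).
_SPECTRAL_RANGES = {
    500: (0.01, 0.3),
    3000: (1.0 / 600.0, 0.3),
    100000: (2e-5, 0.3),
}
#: Low-frequency diagnostic sub-range for 100,000-stride series.
SPECTRAL_RANGE_100K_LOWF = (2e-5, 0.01)


def _values(intervals: ArrayLike) -> np.ndarray:
    if isinstance(intervals, StrideSeries):
        return intervals.intervals
    return np.asarray(intervals, dtype=np.float64)


@dataclass(frozen=True)
class DFAResult:
    n_values: np.ndarray
    F_values: np.ndarray
    alpha: float
    fit_range: Tuple[float, float]


@dataclass(frozen=True)
class SpectrumResult:
    f_values: np.ndarray
    S_values: np.ndarray
    beta: float
    fit_range: Optional[Tuple[float, float]] = None


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    p_value: float
    significant: bool


def integrated_profile(intervals: ArrayLike) -> np.ndarray:
    """Cumulative sum of mean-subtracted intervals; ends at zero exactly."""
    x = _values(intervals)
    if x.size < 2:
        raise ValueError("need at least two intervals")
    return np.cumsum(x - x.mean())


def dfa_window_grid(N: int, n_min: int = 4) -> np.ndarray:
    """Window sizes ``round(10^x)`` for ``x`` from ``log10(4)`` to
    ``log10(N/2)`` in 0.1 increments, deduplicated and clipped to
    ``[4, N/2]``."""
    if N < 2 * n_min:
        raise ValueError(f"series too short for DFA (need N >= {2 * n_min})")
    exponents = np.arange(math.log10(n_min), math.log10(N / 2) + 1e-12, 0.1)
    ns = np.unique(np.round(10.0 ** exponents).astype(int))
    return ns[(ns >= n_min) & (ns <= N // 2)]


def dfa_fluctuation(y: np.ndarray, n: int) -> float:
    """RMS fluctuation of the profile about per-window least-squares lines.

    Windows of length ``n`` partition the profile from the start; trailing
    samples that do not fill a window are discarded.
    """
    y = np.asarray(y, dtype=np.float64)
    N = y.size
    if not 4 <= n <= N // 2:
        raise ValueError("window size must satisfy 4 <= n <= N/2")
    m = N // n
    seg = y[:m * n].reshape(m, n)
    t = np.arange(n, dtype=np.float64)
    tc = t - t.mean()
    slope = seg @ tc / (tc @ tc)
    resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * tc
    return float(np.sqrt(np.mean(resid ** 2)))


def dfa_alpha(intervals: ArrayLike, grid: Optional[np.ndarray] = None,
              fit_range: Optional[Tuple[float, float]] = None) -> DFAResult:
    """DFA scaling exponent over a window grid.

    ``fit_range = (n_lo, n_hi)`` restricts the log-log fit to a sub-range of
    the grid (used for the large-window diagnostic on very long series)
    while ``F(n)`` is still reported on the full grid.
    """
    x = _values(intervals)
    if np.ptp(x) == 0.0:
        raise DegenerateSeriesError("alpha undefined for a constant series")
    y = integrated_profile(x)
    if grid is None:
        grid = dfa_window_grid(x.size)
    grid = np.asarray(grid, dtype=int)
    F = np.array([dfa_fluctuation(y, int(n)) for n in grid])
    lo, hi = (grid.min(), grid.max()) if fit_range is None else fit_range
    sel = (grid >= lo) & (grid <= hi) & (F > 0.0)
    if (F[(grid >= lo) & (grid <= hi)] <= 0.0).any():
        import warnings
        warnings.warn("zero fluctuation windows excluded from the alpha fit")
    if sel.sum() < 2:
        raise DegenerateSeriesError("fewer than two usable window sizes")
    slope, _ = np.polyfit(np.log10(grid[sel]), np.log10(F[sel]), 1)
    return DFAResult(n_values=grid, F_values=F, alpha=float(slope),
                     fit_range=(float(lo), float(hi)))


def power_spectrum(intervals: ArrayLike) -> SpectrumResult:
    """One-sided power spectrum of the mean-subtracted series.

    ``S(f) = |X(f)|^2`` from the discrete Fourier transform at
    ``f = j/N`` cycles per stride, ``j = 1 .. floor(N/2)``; no taper is
    applied.  ``beta`` is left unfitted (nan) — see :func:`spectral_beta`.
    """
    x = _values(intervals)
    if x.size < 16:
        raise ValueError("need at least 16 intervals for a spectrum")
    N = x.size
    X = np.fft.rfft(x - x.mean())
    S = np.abs(X[1:N // 2 + 1]) ** 2
    f = np.arange(1, N // 2 + 1) / N
    return SpectrumResult(f_values=f, S_values=S, beta=math.nan)


def spectral_fit_range(N: int) -> Tuple[float, float]:
    """Published frequency fit range for a series of length ``N``.

    Exact lengths 500 / 3,000 / 100,000 use the printed ranges; other
    lengths fall back to ``[5/N, 0.3]`` (five cycles across the series, the
    same rule the printed 500- and 3,000-stride ranges follow).
    """
    if N in _SPECTRAL_RANGES:
        return _SPECTRAL_RANGES[N]
    return (5.0 / N, 0.3)


def spectral_beta(spec: SpectrumResult,
                  f_range: Tuple[float, float]) -> float:
    """``beta = -1 x`` the OLS slope of ``log10 S`` on ``log10 f`` in range."""
    f_min, f_max = f_range
    sel = (spec.f_values >= f_min) & (spec.f_values <= f_max) \
        & (spec.S_values > 0.0)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 usable frequencies in the fit range")
    slope, _ = np.polyfit(np.log10(spec.f_values[sel]),
                          np.log10(spec.S_values[sel]), 1)
    return float(-slope)


def shuffle_surrogate(intervals: ArrayLike, seed: int):
    """Theiler surrogate: a uniformly random permutation of the intervals.

    The value multiset is preserved bitwise (mean, SD and COV are exactly
    unchanged); only temporal order — and with it any genuine long-range
    correlation — is destroyed.
    """
    rng = np.random.default_rng(seed)
    if isinstance(intervals, StrideSeries):
        shuffled = rng.permutation(intervals.intervals)
        return StrideSeries(intervals=shuffled, seed=seed,
                            params=intervals.params,
                            kind=(intervals.kind + "_shuffled").lstrip("_"),
                            complete=intervals.complete)
    return rng.permutation(_values(intervals))


def cov_percent(intervals: ArrayLike, of: str = "intervals") -> float:
    """Coefficient of variation, ``100 * SD / mean`` (%).

    ``of="cadence"`` applies the same statistic to instantaneous cadence
    (reciprocal intervals) instead of the intervals themselves.
    """
    x = _values(intervals)
    if of == "cadence":
        x = 1.0 / x
    elif of != "intervals":
        raise ValueError("of must be 'intervals' or 'cadence'")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean must be strictly positive")
    if x.size < 2:
        raise ValueError("need at least two values")
    return float(100.0 * x.std(ddof=1) / mean)


def exponent_tests(sample: Sequence[float],
                   reference: Union[float, Sequence[float]]) -> StatTestResult:
    """Two-sided t-test of ensemble exponents at the 5% level.

    A scalar ``reference`` gives a one-sample test against that constant; an
    array (e.g. per-run shuffled counterparts) gives a paired test.
    """
    sample = np.asarray(sample, dtype=np.float64)
    if sample.size < 2:
        raise ValueError("need at least two exponents")
    if np.isscalar(reference) or np.ndim(reference) == 0:
        if sample.std(ddof=1) == 0.0:
            if sample[0] == reference:
                return StatTestResult(0.0, 1.0, False)
            raise DegenerateSeriesError(
                "zero-variance sample differs from the reference constant")
        res = stats.ttest_1samp(sample, float(reference))
    else:
        reference = np.asarray(reference, dtype=np.float64)
        if reference.shape != sample.shape:
            raise ValueError("paired reference must match the sample shape")
        diff = sample - reference
        if diff.std(ddof=1) == 0.0:
            if np.all(diff == 0.0):
                return StatTestResult(0.0, 1.0, False)
            raise DegenerateSeriesError("zero-variance paired differences")
        res = stats.ttest_rel(sample, reference)
    p = float(res.pvalue)
    return StatTestResult(float(res.statistic), p, p < SIGNIFICANCE_LEVEL)
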