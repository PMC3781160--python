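"""Benchmark stride-interval generators: white and Brownian extremes.

These are the calibration end points of the exponent estimators.  White
noise (iid Gaussian intervals, mean 1.23 s, SD 0.0369 s — matching the
published human mean stride interval and its 3% COV) is the zero-memory
extreme (alpha = 0.5, beta = 0); a cumulative sum of Gaussian increments is
the never-forgetting, marginal-stability extreme (alpha = 1.5, beta = 2).
"""

from __future__ import annotations

import numpy as np

from .params import NoiseSpec
from .series import StrideSeries

__all__ = ["white_noise_intervals", "brownian_intervals",
           "BROWNIAN_INCREMENT_SD"]

#: Default increment SD (s) for the Brownian benchmark: chosen so the COV of
#: a 500-sample path is about 3%, mirroring the rolling-disk calibration
#: (a random walk of N steps has RMS sample SD ~ sd*sqrt(N/6), so
#: 0.0369 s / sqrt(500/6) ~ 0.004 s).
BROWNIAN_INCREMENT_SD = 0.004


def white_noise_intervals(spec: NoiseSpec) -> StrideSeries:
    """iid N(mean, sd^2) stride intervals."""
    if spec.kind != "white":
        raise ValueError("spec.kind must be 'white'")
    rng = np.random.default_rng(spec.seed)
    x = rng.normal(spec.mean, spec.sd, size=spec.n)
    return StrideSeries(intervals=x, seed=spec.seed, params=spec.to_dict(),
                        kind="white_noise")


def brownian_intervals(spec: NoiseSpec) -> StrideSeries:
    """Cumulative sum of iid N(0, sd^2) increments added to ``mean``."""
    if spec.kind != "brownian":
        raise ValueError("spec.kind must be 'brownian'")
    rng = np.random.default_rng(spec.seed)
    x = spec.mean + np.cumsum(rng.normal(0.0, spec.sd, size=spec.n))
    return StrideSeries(intervals=x, seed=spec.seed, params=spec.to_dict(),
                        kind="brownian")
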