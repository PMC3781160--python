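"""Calibration and the replication experiment matrix.

Calibration fixes the two free constants per leg angle exactly the way the
study conditions define them: the nominal ankle constant ``k0`` is chosen so
the deterministic limit cycle walks at the average human speed (1.35 m/s),
and the actuation variance ``sigma^2`` so the stride-interval COV of noisy
500-stride walks matches the human 3%.  The rolling-disk force SD is
calibrated the same way on cycle durations.

``run_experiment`` then reproduces the published ensemble design: ``n_runs``
independent simulations of one case (walker at pi/12 or pi/6, rolling disk,
or white noise), per-run DFA alpha, spectral beta and COV, shuffled-surrogate
counterparts, and the 5%-level tests against the white-noise constants and
against the paired surrogates.

Seed scheme (documented in every output): run ``i`` uses
``base_seed + i``; its shuffle surrogate uses ``run_seed + SHUFFLE_OFFSET``;
calibration seed ``j`` is ``base_seed + CALIBRATION_OFFSET + j``.  All
derived seeds stay below 2**31.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, GaitFailureError
from .lrc import (cov_percent, dfa_alpha, dfa_window_grid, exponent_tests,
                  power_spectrum, shuffle_surrogate, spectral_beta,
                  spectral_fit_range)
from .params import DiskParams, NoiseSpec, WalkerParams
from .rolling_disk import simulate_disk
from .synthetic import BROWNIAN_INCREMENT_SD, brownian_intervals, white_noise_intervals
from .walker import average_speed, simulate_walk

__all__ = [
    "ExperimentConfig", "RunSummary", "CASES",
    "calibrate_k0", "calibrate_sigma", "calibrate_disk_noise",
    "calibrated_walker", "run_experiment", "load_config",
    "TARGET_SPEED", "TARGET_COV",
]

logger = logging.getLogger("stridewalk")

TARGET_SPEED = 1.35  # m/s, average speed of normal human walking
TARGET_COV = 3.0     # %, stride-interval COV of normal human walking

CALIBRATION_OFFSET = 100_000
SHUFFLE_OFFSET = 500_000

CASES = ("walker_pi12", "walker_pi6", "rolling_disk", "white_noise", "brownian")

_CASE_THETA0 = {"walker_pi12": math.pi / 12, "walker_pi6": math.pi / 6}

#: Default k0 search brackets (N*m/rad) by case; expanded automatically if
#: the speed target is not bracketed.
_K0_BRACKETS = {"walker_pi12": (20.0, 500.0), "walker_pi6": (200.0, 8000.0)}


@dataclass
class ExperimentConfig:
    """One cell of the experiment matrix (case x series length)."""

    case: str
    n_strides: int
    n_runs: int = 20
    base_seed: int = 0
    theta0: Optional[float] = None
    k0: Optional[float] = None
    sigma2: Optional[float] = None
    force_sd: Optional[float] = None
    f_range: Optional[Tuple[float, float]] = None
    extended_windows: bool = False  # fit alpha over n >= 1000 as well
    cov_of: str = "intervals"       # or "cadence"
    n_calibration_seeds: int = 5

    def __post_init__(self):
        if self.case not in CASES:
            raise ValueError(f"case must be one of {CASES}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_strides < 8:
            raise ValueError("n_strides must be >= 8")
        if self.theta0 is None:
            self.theta0 = _CASE_THETA0.get(self.case)


@dataclass
class RunSummary:
    """Per-run exponents plus ensemble statistics and significance tests."""

    config: ExperimentConfig
    rows: pd.DataFrame
    tests: dict
    n_failed: int = 0
    calibration: dict = field(default_factory=dict)

    @property
    def mean_alpha(self) -> float:
        return float(self.rows["alpha"].mean())

    @property
    def mean_beta(self) -> float:
        return float(self.rows["beta"].mean())

    @property
    def mean_cov(self) -> float:
        return float(self.rows["cov_percent"].mean())

    def summary(self) -> dict:
        r = self.rows
        out = {"case": self.config.case, "n_strides": self.config.n_strides,
               "n_runs": len(r), "n_failed": self.n_failed}
        for col in ("alpha", "beta", "cov_percent",
                    "alpha_shuffled", "beta_shuffled"):
            out[f"{col}_mean"] = float(r[col].mean())
            out[f"{col}_sd"] = float(r[col].std(ddof=1)) if len(r) > 1 else 0.0
        out["tests"] = {
            name: {"statistic": t.statistic, "p_value": t.p_value,
                   "significant": t.significant}
            for name, t in self.tests.items()}
        out["calibration"] = self.calibration
        return out

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, index=False, float_format="%.17g")
        return path


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _deterministic_speed(params: WalkerParams, n_strides: int = 1) -> float:
    try:
        series = simulate_walk(params, n_strides, noisy=False)
    except GaitFailureError:
        return math.nan
    return average_speed(series, params)


def calibrate_k0(params: WalkerParams, target_speed: float = TARGET_SPEED,
                 bracket: Optional[Tuple[float, float]] = None,
                 tol: float = 1e-3) -> float:
    """Nominal ankle constant matching the deterministic limit-cycle speed.

    Bisection (Brent) on the deterministic average speed; a walker that
    falls at small ``k0`` counts as arbitrarily slow, which keeps the
    residual sign-definite on the lower bracket edge.
    """
    if bracket is None:
        bracket = _K0_BRACKETS.get(
            "walker_pi12" if params.theta0 < math.pi / 8 else "walker_pi6")

    def residual(k0: float) -> float:
        v = _deterministic_speed(
            WalkerParams(**{**params.to_dict(), "k0": k0, "sigma2": 0.0}))
        return (v - target_speed) if math.isfinite(v) else -10.0 * target_speed

    lo, hi = bracket
    for _ in range(12):
        if residual(hi) > 0:
            break
        hi *= 2.0
    else:
        raise CalibrationError("speed target not bracketed from above")
    for _ in range(12):
        if residual(lo) < 0:
            break
        lo *= 0.5
    else:
        raise CalibrationError("speed target not bracketed from below")
    k0 = brentq(residual, lo, hi, xtol=1e-8 * hi, rtol=1e-12)
    speed = residual(k0) + target_speed
    if abs(speed - target_speed) > tol:
        raise CalibrationError(
            f"calibrated speed {speed:.5f} misses target by more than {tol}")
    return float(k0)


def _calibration_seeds(base_seed: int, n: int) -> list:
    return [base_seed + CALIBRATION_OFFSET + j for j in range(n)]


def calibrate_sigma(params: WalkerParams, target_cov: float = TARGET_COV,
                    n_strides: int = 500,
                    seeds: Sequence[int] = (100000, 100001, 100002,
                                            100003, 100004),
                    tol: float = 0.1, cov_of: str = "intervals") -> float:
    """Actuation-noise SD matching the mean stride-interval COV (percent).

    Root-finds on the mean COV over the fixed calibration seed set; the
    target is the published 3% of normal human walking.  Gait failures
    during the search shrink the admissible bracket and are logged.
    """
    if params.k0 <= 0:
        raise ValueError("calibrate k0 first")

    def mean_cov(sigma: float) -> float:
        if sigma == 0.0:
            return 0.0
        covs = []
        noisy = params.with_noise(sigma ** 2)
        for s in seeds:
            try:
                series = simulate_walk(noisy, n_strides, seed=s)
            except GaitFailureError:
                logger.warning("gait failure at sigma=%.4g (seed %d); "
                               "shrinking bracket", sigma, s)
                return math.inf
            covs.append(cov_percent(series, of=cov_of))
        return float(np.mean(covs))

    lo, hi = 1e-4 * params.k0, 0.05 * params.k0
    c = mean_cov(hi)
    for _ in range(30):
        if math.isinf(c):       # fell: back off toward the failure boundary
            hi *= 0.7
        elif c < target_cov:    # too quiet: push the bracket up
            hi *= 2.0
        else:
            break
        c = mean_cov(hi)
    if not c >= target_cov:
        raise CalibrationError(
            "COV target unreachable below the gait-failure boundary")
    sigma = brentq(lambda s: mean_cov(s) - target_cov, lo, hi,
                   xtol=1e-4 * params.k0)
    achieved = mean_cov(sigma)
    if abs(achieved - target_cov) > tol:
        raise CalibrationError(
            f"calibrated COV {achieved:.3f}% misses {target_cov}% by > {tol}")
    return float(sigma)


def calibrate_disk_noise(disk: DiskParams, target_cov: float = TARGET_COV,
                         n_cycles: int = 500,
                         seeds: Sequence[int] = (100000, 100001, 100002,
                                                 100003, 100004),
                         tol: float = 0.1) -> float:
    """Half-cycle force SD matching the disk's 500-cycle duration COV."""
    def mean_cov(fsd: float) -> float:
        if fsd == 0.0:
            return 0.0
        covs = []
        p = DiskParams(m=disk.m, radius=disk.radius, v0=disk.v0, force_sd=fsd)
        for s in seeds:
            try:
                series = simulate_disk(p, n_cycles, seed=s)
            except GaitFailureError:
                return math.inf
            covs.append(cov_percent(series))
        return float(np.mean(covs))

    hi = 0.05 * disk.m * disk.v0  # well below the stall scale
    while math.isinf(mean_cov(hi)):
        hi *= 0.5
    while mean_cov(hi) < target_cov:
        hi *= 2.0
        if math.isinf(mean_cov(hi)):
            raise CalibrationError("COV target unreachable before stall")
    fsd = brentq(lambda s: mean_cov(s) - target_cov, 1e-6, hi, xtol=1e-5)
    achieved = mean_cov(fsd)
    if abs(achieved - target_cov) > tol:
        raise CalibrationError(
            f"calibrated COV {achieved:.3f}% misses {target_cov}% by > {tol}")
    return float(fsd)


def calibrated_walker(theta0: float, base_seed: int = 0,
                      n_calibration_seeds: int = 5) -> WalkerParams:
    """Fully calibrated walker: k0 to 1.35 m/s, sigma to 3% COV at 500 strides."""
    k0 = calibrate_k0(WalkerParams(theta0=theta0, k0=100.0))
    params = WalkerParams(theta0=theta0, k0=k0)
    sigma = calibrate_sigma(
        params, seeds=_calibration_seeds(base_seed, n_calibration_seeds))
    return params.with_noise(sigma ** 2)


# ---------------------------------------------------------------------------
# experiment matrix
# ---------------------------------------------------------------------------

def _simulate_case(config: ExperimentConfig, seed: int):
    case = config.case
    if case in ("walker_pi12", "walker_pi6"):
        params = WalkerParams(theta0=config.theta0, k0=config.k0,
                              sigma2=config.sigma2)
        return simulate_walk(params, config.n_strides, seed=seed)
    if case == "rolling_disk":
        disk = DiskParams(force_sd=config.force_sd)
        return simulate_disk(disk, config.n_strides, seed=seed)
    if case == "white_noise":
        return white_noise_intervals(
            NoiseSpec(kind="white", n=config.n_strides, seed=seed))
    return brownian_intervals(
        NoiseSpec(kind="brownian", n=config.n_strides, seed=seed,
                  sd=BROWNIAN_INCREMENT_SD))


def _ensure_calibrated(config: ExperimentConfig) -> dict:
    """Fill missing calibrated constants in-place; returns what was done."""
    done = {}
    if config.case in ("walker_pi12", "walker_pi6"):
        if config.k0 is None:
            config.k0 = calibrate_k0(
                WalkerParams(theta0=config.theta0, k0=100.0))
            done["k0"] = config.k0
        if config.sigma2 is None:
            sigma = calibrate_sigma(
                WalkerParams(theta0=config.theta0, k0=config.k0),
                seeds=_calibration_seeds(config.base_seed,
                                         config.n_calibration_seeds),
                cov_of=config.cov_of)
            config.sigma2 = sigma ** 2
            done["sigma"] = sigma
    elif config.case == "rolling_disk" and config.force_sd is None:
        config.force_sd = calibrate_disk_noise(
            DiskParams(),
            seeds=_calibration_seeds(config.base_seed,
                                     config.n_calibration_seeds))
        done["force_sd"] = config.force_sd
    return done


def run_experiment(config: ExperimentConfig) -> RunSummary:
    """Run one ensemble cell: simulate, analyze, shuffle, test.

    Per run: DFA alpha over the standard window grid (plus the n >= 1000
    sub-range fit when ``extended_windows``), spectral beta over the
    length-appropriate frequency range, the COV, and alpha/beta of the
    run's shuffled surrogate.  Failed runs are logged and excluded, with
    the count reported.
    """
    calibration = _ensure_calibrated(config)
    N = config.n_strides
    grid = dfa_window_grid(N)
    f_range = config.f_range or spectral_fit_range(N)

    records = []
    n_failed = 0
    for i in range(config.n_runs):
        seed = config.base_seed + i
        try:
            series = _simulate_case(config, seed)
        except GaitFailureError as exc:
            logger.warning("run %d (seed %d) failed: %s", i, seed, exc)
            n_failed += 1
            continue
        surrogate = shuffle_surrogate(series, seed + SHUFFLE_OFFSET)
        rec = {"run": i, "seed": seed,
               "alpha": dfa_alpha(series, grid).alpha,
               "beta": spectral_beta(power_spectrum(series), f_range),
               "cov_percent": cov_percent(series, of=config.cov_of),
               "alpha_shuffled": dfa_alpha(surrogate, grid).alpha,
               "beta_shuffled": spectral_beta(power_spectrum(surrogate),
                                              f_range)}
        if config.extended_windows:
            rec["alpha_extended"] = dfa_alpha(
                series, grid, fit_range=(1000, N // 2)).alpha
        records.append(rec)
    rows = pd.DataFrame.from_records(records)
    if len(rows) < 2:
        raise CalibrationError("fewer than two successful runs")

    tests = {
        "alpha_vs_white": exponent_tests(rows["alpha"], 0.5),
        "beta_vs_white": exponent_tests(rows["beta"], 0.0),
        "alpha_vs_shuffled": exponent_tests(rows["alpha"],
                                            rows["alpha_shuffled"]),
        "beta_vs_shuffled": exponent_tests(rows["beta"],
                                           rows["beta_shuffled"]),
        "cov_vs_target": exponent_tests(rows["cov_percent"], TARGET_COV),
    }
    return RunSummary(config=config, rows=rows, tests=tests,
                      n_failed=n_failed, calibration=calibration)


def load_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML key-value file."""
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "f_range" in data and data["f_range"] is not None:
        data["f_range"] = tuple(data["f_range"])
    return ExperimentConfig(**data)
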