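"""Step-to-step return map, fixed point and Floquet multiplier.

Work-energy bookkeeping over one step makes the map exactly affine in the
energy-like state ``x = Omega^2`` (squared post-collision angular speed of
the stance leg):

    x_{i+1} = cos^2(2*theta0) * (x_i + k_i * (mu - psi0)^2 / (m L^2))

The ankle spring releases its full pre-load ``(1/2) k (mu - psi0)^2`` during
double stance, gravity does zero net work over the step (the hip height is
``L cos(theta0)`` at both ends), and the collision scales speed by
``cos(2*theta0)`` — hence kinetic energy, and the map's slope, by
``cos^2(2*theta0)``.  For ``theta0`` in (0, pi/4) the slope is strictly
inside (0, 1): the map is monotone and affine, has a unique fixed point,
admits no period-two orbit, and its single Floquet multiplier is the slope
itself.  The simulator provides an independent empirical check of all of
this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InfeasibleStateError, GeometryError
from .params import WalkerParams

__all__ = [
    "ReturnMapModel", "analytic_step_map", "fixed_point",
    "floquet_multiplier", "floquet_numerical", "perturbation_decay",
    "empirical_step_map", "min_feasible_x",
]


@dataclass(frozen=True)
class ReturnMapModel:
    """Affine step-to-step map ``x' = slope * x + offset``.

    The state convention is recorded explicitly: ``x`` is the squared
    post-collision angular speed (rad/s)^2, an energy-like variable (kinetic
    energy is ``m L^2 x / 2``).  ``sqrt(fixed_point)`` recovers the rad/s
    parameterization.
    """

    slope: float
    offset: float
    params: Optional[WalkerParams] = None
    convention: str = "omega_squared"

    def __post_init__(self):
        if not 0.0 < self.slope < 1.0:
            raise ValueError("slope must lie in (0, 1) for a stable gait")
        if self.offset <= 0:
            raise ValueError("offset must be positive (the spring does work)")

    @classmethod
    def from_params(cls, params: WalkerParams,
                    k: Optional[float] = None) -> "ReturnMapModel":
        k = params.k0 if k is None else k
        slope = params.floquet
        return cls(slope=slope, offset=slope * k * params.energy_gain,
                   params=params)

    @property
    def fixed_point(self) -> float:
        return self.offset / (1.0 - self.slope)

    def __call__(self, x: float) -> float:
        return analytic_step_map(x, self)


def min_feasible_x(params: WalkerParams, k: Optional[float] = None,
                   n_grid: int = 2001) -> float:
    """Smallest post-collision ``x`` that carries the walker over the step.

    Along the step, energy conservation gives ``thetadot^2(theta) = x +
    D(theta)`` where ``D`` collects the gravity term and the spring energy
    released so far; the step completes iff the minimum of ``x + D`` stays
    positive (otherwise the walker stalls and falls backward).
    """
    from .walker import psi_of_theta  # local import avoids a module cycle
    k = params.k0 if k is None else k
    theta_s = params.theta_release
    two_g_over_L = 2.0 * params.g / params.L
    mL2 = params.m * params.L ** 2
    cos_t0 = math.cos(params.theta0)
    full = k * params.spring_travel ** 2 / mL2

    worst = np.inf
    # double stance: partial spring release
    for theta in np.linspace(params.theta0, theta_s, n_grid):
        psi = psi_of_theta(theta, params)
        released = (params.spring_travel ** 2
                    - (params.mu - psi) ** 2) * k / mL2
        d = two_g_over_L * (cos_t0 - math.cos(theta)) + released
        worst = min(worst, d)
    # single stance: full release
    for theta in np.linspace(theta_s, -params.theta0, n_grid):
        d = two_g_over_L * (cos_t0 - math.cos(theta)) + full
        worst = min(worst, d)
    return max(0.0, -worst)


def analytic_step_map(x: float, model: ReturnMapModel) -> float:
    """Apply the affine step-to-step map to the state ``x = Omega^2``."""
    if x < 0:
        raise InfeasibleStateError("x must be >= 0")
    if model.params is not None and x < min_feasible_x(model.params):
        raise InfeasibleStateError(
            f"x={x:.6g} is below the minimum energy to complete a step")
    return model.slope * x + model.offset


def fixed_point(model: ReturnMapModel) -> float:
    """Unique fixed point of the map; iteration converges to it monotonically."""
    return model.fixed_point


def floquet_multiplier(params: WalkerParams) -> float:
    """Closed-form Floquet multiplier ``cos^2(2*theta0)`` of the limit cycle.

    The only eigenvalue of the linearized return map: 0.25 at
    ``theta0 = pi/6``, 0.75 at ``pi/12``, approaching 1 (marginal
    stability) as ``theta0 -> 0``.
    """
    if not 0.0 < params.theta0 < math.pi / 4:
        raise ValueError("theta0 must lie in (0, pi/4)")
    return params.floquet


def floquet_numerical(params: WalkerParams, rel_offset: float = 1e-2) -> float:
    """Finite-difference slope of the simulated return map at its fixed point.

    Central differences with a relative state offset (default 1e-2) around
    ``x*``; agrees with the closed form to well under 1e-4.
    """
    model = ReturnMapModel.from_params(params)
    x_star = model.fixed_point
    dx = rel_offset * x_star
    pairs = empirical_step_map(params, [x_star - dx, x_star + dx])
    (x_lo, y_lo), (x_hi, y_hi) = pairs
    return (y_hi - y_lo) / (x_hi - x_lo)


def perturbation_decay(multiplier: float, n_steps: int) -> float:
    """Residual fraction of a unit perturbation after ``n_steps`` steps."""
    if not 0.0 <= multiplier <= 1.0:
        raise ValueError("multiplier must lie in [0, 1]")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    return multiplier ** n_steps


def empirical_step_map(params: WalkerParams, grid: Sequence[float],
                       k: Optional[float] = None):
    """Return map sampled from full hybrid-step simulations at sigma^2 = 0.

    For each ``x`` on the grid, one step (collision + double + single
    stance) is integrated from ``Omega = sqrt(x)`` and the successor
    ``x' = (cos(2 theta0) * omega_pre)^2`` recorded.  Infeasible states map
    to ``nan`` (flagged, excluded from fits).
    """
    from .walker import post_collision_state, integrate_step
    from .errors import GaitFailureError
    k = params.k0 if k is None else k
    pairs = []
    for x in grid:
        if x < 0:
            pairs.append((x, math.nan))
            continue
        init = post_collision_state(math.sqrt(x), params)
        try:
            _, omega_pre = integrate_step(init, k, params)
        except GaitFailureError:
            pairs.append((x, math.nan))
            continue
        pairs.append((x, (params.collision_factor * omega_pre) ** 2))
    return pairs
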