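"""Event-driven hybrid simulation of the one-degree-of-freedom walker.

Model
-----
A point mass ``m`` at the hip moves in the sagittal plane on rigid massless
legs of length ``L``.  Each step is the hybrid sequence

1. *heel-strike collision*: the hip velocity is redirected by the inter-leg
   angle ``2*theta0`` and its magnitude reduced by ``cos(2*theta0)`` (angular
   momentum about the new contact);
2. *double stance*: the model is an actuated four-bar linkage — trailing-foot
   pivot to trailing ankle (length ``l``), trailing leg (``L``), leading leg
   (``L``), with the leading ankle hinged on the ground.  The trailing ankle
   carries a pre-loaded torsional spring ``T = k*(mu - psi)`` (``psi`` is the
   interior ankle angle, positive towards plantar flexion) that is released
   at double-stance onset and pushes until ``psi = mu``, where the torque —
   and with it double stance — ends;
3. *single stance*: an inverted pendulum hinged at the stance ankle,
   ``thetaddot = (g/L) * sin(theta)``, until the hip angle reaches
   ``-theta0`` and the next collision follows.

Sign convention: ``theta`` is the stance-leg angle from the vertical through
the stance ankle, positive when the hip is *behind* it.  A step starts at
``theta = +theta0`` with ``thetadot < 0`` and ends at ``theta = -theta0``;
that end value at the collision matches the event the hybrid sequence is
defined by.

Stochasticity enters once per step: ``k`` is drawn iid from
``N(k0, sigma2)`` (non-positive draws are rejected and resampled — at the
calibrated noise level this is astronomically rare).  Because both the hip
(in either phase) and the leading leg rotate about the fixed leading ankle,
the whole step reduces to a scalar second-order ODE in ``theta``; the
four-bar enters through the closed-form ``psi(theta)`` alone.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _core
from .errors import (GaitFailureError, GeometryError, PhaseViolationError)
from .params import WalkerParams
from .series import StrideSeries

__all__ = [
    "Phase", "HybridState", "StepRecord",
    "ankle_torque", "collision_map",
    "psi_of_theta", "theta_of_psi", "dpsi_dtheta", "d2psi_dtheta2",
    "double_stance_derivatives", "single_stance_derivatives",
    "post_collision_state", "integrate_step", "simulate_walk",
    "average_speed", "draw_spring_constants",
]


class Phase(enum.Enum):
    DOUBLE_STANCE = "double_stance"
    SINGLE_STANCE = "single_stance"


@dataclass
class HybridState:
    """Phase label plus the active generalized coordinate.

    In double stance the coordinate is the trailing ankle angle ``psi``;
    in single stance it is the stance-leg angle ``theta``.
    """

    phase: Phase
    q: float
    qdot: float
    t: float = 0.0


@dataclass(frozen=True)
class StepRecord:
    """Durations and boundary speeds of one completed step."""

    duration: float
    ds_duration: float
    ss_duration: float
    k_sample: float
    omega_post: float  # post-collision angular speed entering this step

    def __post_init__(self):
        if self.duration <= 0 or self.k_sample <= 0:
            raise ValueError("duration and k_sample must be positive")


# ---------------------------------------------------------------------------
# four-bar geometry
# ---------------------------------------------------------------------------

def psi_of_theta(theta: float, params: WalkerParams) -> float:
    """Interior trailing-ankle angle as a function of the stance-leg angle.

    Closed form from the triangle (pivot, trailing ankle, hip):
    ``cos psi = (l^2 - c1^2 + 2 L c1 sin theta) / (2 l L)`` with
    ``c1`` the fixed pivot-to-leading-ankle ground link.
    """
    c1 = params.ground_link
    c = (params.l ** 2 - c1 ** 2 + 2.0 * params.L * c1 * math.sin(theta)) \
        / (2.0 * params.l * params.L)
    if not -1.0 <= c <= 1.0:
        raise GeometryError(f"four-bar cannot close at theta={theta:.4f}")
    return math.acos(c)


def theta_of_psi(psi: float, params: WalkerParams) -> float:
    """Inverse of :func:`psi_of_theta` on the step's monotone branch."""
    c1 = params.ground_link
    arg = (2.0 * params.l * params.L * math.cos(psi)
           + c1 ** 2 - params.l ** 2) / (2.0 * params.L * c1)
    if not -1.0 <= arg <= 1.0:
        raise GeometryError(f"no stance-leg angle realizes psi={psi:.4f}")
    return math.asin(arg)


def dpsi_dtheta(theta: float, params: WalkerParams) -> float:
    """Four-bar transmission ratio dpsi/dtheta (negative along the step)."""
    psi = psi_of_theta(theta, params)
    s = math.sin(psi)
    if abs(s) < 1e-6:
        raise GeometryError("singular linkage: pivot, ankle and hip collinear")
    return -params.ground_link * math.cos(theta) / (params.l * s)


def d2psi_dtheta2(theta: float, params: WalkerParams) -> float:
    psi = psi_of_theta(theta, params)
    s = math.sin(psi)
    if abs(s) < 1e-6:
        raise GeometryError("singular linkage: pivot, ankle and hip collinear")
    j = dpsi_dtheta(theta, params)
    c1 = params.ground_link
    return c1 * (math.sin(theta) * s
                 + math.cos(theta) * math.cos(psi) * j) / (params.l * s * s)


# ---------------------------------------------------------------------------
# constitutive pieces
# ---------------------------------------------------------------------------

def ankle_torque(psi: float, k: float, params: WalkerParams) -> float:
    """Plantar ankle torque ``T = k * (mu - psi)`` of the released spring.

    Zero at ``psi = mu`` (double stance ends there); positive for
    ``psi < mu``.  A ``psi`` beyond ``mu`` is a phase violation: the foot can
    only push while the torque is positive.
    """
    if k < 0:
        raise ValueError("spring constant k must be >= 0")
    if psi > params.mu:
        raise PhaseViolationError(
            f"psi={psi:.4f} exceeds mu={params.mu:.4f}: double stance "
            "should already have ended")
    return k * (params.mu - psi)


def collision_map(omega_pre: float, params: WalkerParams) -> float:
    """Heel-strike reduction of the stance-leg angular speed.

    The hip velocity is redirected by ``2*theta0`` and scaled by
    ``cos(2*theta0)``; kinetic energy therefore scales by ``cos^2(2*theta0)``
    — the model's single Floquet multiplier.
    """
    if omega_pre < 0:
        raise ValueError("omega_pre must be >= 0")
    return omega_pre * params.collision_factor


def single_stance_derivatives(state: HybridState, params: WalkerParams):
    """Inverted-pendulum rates ``(thetadot, (g/L) sin theta)``."""
    if state.phase is not Phase.SINGLE_STANCE:
        raise PhaseViolationError("state is not in single stance")
    return state.qdot, (params.g / params.L) * math.sin(state.q)


def double_stance_derivatives(state: HybridState, k: float,
                              params: WalkerParams):
    """Four-bar rates ``(psidot, psiddot)`` for the double-stance DOF.

    The hip rotates about the fixed leading ankle, so the dynamics in the
    leg angle are ``m L^2 thetaddot = m g L sin theta + T(psi) dpsi/dtheta``;
    the psi-rates follow by the chain rule through the closed-loop
    constraint.
    """
    if state.phase is not Phase.DOUBLE_STANCE:
        raise PhaseViolationError("state is not in double stance")
    psi, psidot = state.q, state.qdot
    if psi > params.mu:
        raise PhaseViolationError(
            f"psi={psi:.4f} > mu: double stance already over")
    theta = theta_of_psi(psi, params)
    j = dpsi_dtheta(theta, params)
    thetadot = psidot / j
    torque = ankle_torque(psi, k, params)
    thetaddot = (params.g / params.L) * math.sin(theta) \
        + torque * j / (params.m * params.L ** 2)
    psiddot = j * thetaddot + d2psi_dtheta2(theta, params) * thetadot ** 2
    return psidot, psiddot


# ---------------------------------------------------------------------------
# step and walk integration
# ---------------------------------------------------------------------------

def post_collision_state(omega_post: float, params: WalkerParams) -> HybridState:
    """Double-stance state just after a collision with stance speed ``omega_post``."""
    j0 = dpsi_dtheta(params.theta0, params)
    return HybridState(Phase.DOUBLE_STANCE, params.psi0, j0 * (-omega_post), 0.0)


def integrate_step(init: HybridState, k: float, params: WalkerParams):
    """Integrate one full step from a post-collision double-stance state.

    Fixed-step RK4 at ``params.h`` with the two events (``psi = mu`` and
    ``theta = -theta0``) bisected to 1e-10 s.  Returns ``(StepRecord,
    omega_pre_next)``: the pre-collision angular speed feeds
    :func:`collision_map` for the next step.
    """
    if k <= 0:
        raise ValueError("spring constant k must be strictly positive")
    if init.phase is not Phase.DOUBLE_STANCE:
        raise PhaseViolationError("integrate_step expects a double-stance state")
    theta = theta_of_psi(init.q, params)
    thetadot = init.qdot / dpsi_dtheta(theta, params)
    t_ds, t, omega_pre, status = _core.step_core(
        theta, thetadot, k,
        params.m, params.L, params.l, params.g, params.mu,
        params.theta0, params.h, params.theta_release)
    if status == _core.STATUS_FELL:
        raise GaitFailureError(
            f"walker fell backward after {t:.4f}s (thetadot reached zero "
            "before heel strike)")
    if status == _core.STATUS_TIMEOUT:
        raise GaitFailureError(f"no heel strike within {_core.T_MAX}s")
    rec = StepRecord(duration=t, ds_duration=t_ds, ss_duration=t - t_ds,
                     k_sample=k, omega_post=-thetadot)
    return rec, omega_pre


def draw_spring_constants(params: WalkerParams, n_steps: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-step spring constants: iid N(k0, sigma2), non-positive draws resampled."""
    ks = rng.normal(params.k0, params.sigma, size=n_steps)
    while (ks <= 0).any():
        bad = ks <= 0
        ks[bad] = rng.normal(params.k0, params.sigma, size=int(bad.sum()))
    return ks


def simulate_walk(params: WalkerParams, n_strides: int, seed: int = 0,
                  noisy: bool = True, discard: int = 0) -> StrideSeries:
    """Walk ``2*n_strides`` steps from the deterministic fixed point.

    Stride ``i`` is the sum of step ``2i`` and step ``2i+1`` durations.  With
    ``noisy=False`` (or ``sigma2 = 0``) every stride equals the limit-cycle
    period.  A fall raises :class:`GaitFailureError` with the completed
    strides attached as a partial, flagged series.

    Parameters
    ----------
    discard : int
        Strides dropped from the front of the returned series (no burn-in by
        default: the walk starts exactly on the deterministic limit cycle).
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    from .return_map import ReturnMapModel  # deferred: avoids module cycle

    n_steps = 2 * (n_strides + discard)
    if noisy and params.sigma2 > 0:
        rng = np.random.default_rng(seed)
        ks = draw_spring_constants(params, n_steps, rng)
    else:
        ks = np.full(n_steps, params.k0)
    omega_star = math.sqrt(ReturnMapModel.from_params(params).fixed_point)
    durations, ds_durations, omega_posts, n_done, status = _core.walk_core(
        omega_star, ks,
        params.m, params.L, params.l, params.g, params.mu,
        params.theta0, params.h, params.theta_release)
    meta = dict(params.to_dict())
    if status != _core.STATUS_OK:
        n_ok = (n_done // 2) - discard
        partial = StrideSeries(
            intervals=(durations[0:2 * max(n_ok, 0):2]
                       + durations[1:2 * max(n_ok, 0):2]),
            seed=seed if noisy else None, params=meta, kind="walker",
            complete=False, failed_at=n_done // 2)
        raise GaitFailureError(
            f"gait failure at stride {n_done // 2}", stride_index=n_done // 2,
            partial=partial)
    strides = durations[0::2] + durations[1::2]
    return StrideSeries(intervals=strides[discard:],
                        seed=seed if noisy else None,
                        params=meta, kind="walker")


def average_speed(series: StrideSeries, params: WalkerParams) -> float:
    """Mean forward speed: strides times stride length over total time."""
    if series.n == 0:
        raise ValueError("series is empty")
    return series.n * params.stride_length / series.total_time
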