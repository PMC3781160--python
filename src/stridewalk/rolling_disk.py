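"""Rolling-disk limit of the walker: marginal stability, Brownian intervals.

As ``theta0 -> 0`` the rimless-wheel picture of the walker becomes a rolling
disk of radius ``L`` carrying the mass at its center with zero moment of
inertia, and the ankle actuation converges to zero.  Stochasticity is a
horizontal force on the center, constant within the first half of each
rolling cycle (0 to pi radians — the double-stance share of the gait cycle)
and zero for the second half, drawn iid N(0, force_sd^2) per cycle.  The
"stride interval" is the time to recover orientation by rotating 2*pi.

With zero moment of inertia the kinematics are closed form: uniform
acceleration ``F/m`` over the forced arc, then constant speed.  The
post-cycle velocity performs a driftless random walk — the Floquet
multiplier is 1, no perturbation is ever forgotten — so cycle durations
approach Brownian noise (DFA alpha -> 1.5, spectral slope -> -2).
"""

from __future__ import annotations

import math

import numpy as np

from .errors import GaitFailureError
from .params import DiskParams
from .series import StrideSeries

__all__ = ["nominal_velocity", "disk_cycle", "simulate_disk"]


def nominal_velocity(period: float, radius: float) -> float:
    """Rim speed ``2*pi*radius/period`` giving the disk the nominal cycle period."""
    if period <= 0:
        raise ValueError("period must be strictly positive")
    if radius <= 0:
        raise ValueError("radius must be strictly positive")
    return 2.0 * math.pi * radius / period


def disk_cycle(v_in: float, force: float, params: DiskParams):
    """One 2*pi rolling cycle under a half-cycle force.

    Phase 1 (0 -> pi rad): constant acceleration ``force/m`` over arc length
    ``pi*radius``; phase 2 (pi -> 2*pi rad): momentum conserved, constant
    speed.  Returns ``(duration, v_out)``.
    """
    if v_in <= 0:
        raise ValueError("v_in must be strictly positive")
    arc = math.pi * params.radius
    a = force / params.m
    disc = v_in * v_in + 2.0 * a * arc
    if disc <= 0.0:
        raise GaitFailureError(
            "disk stalls before rolling pi radians (force too negative)")
    # cancellation-stable root of arc = v_in*t + a*t^2/2 (exact for a = 0)
    t1 = 2.0 * arc / (v_in + math.sqrt(disc))
    v_out = v_in + a * t1
    if v_out <= 0:
        raise GaitFailureError("disk stalls at the end of the forced arc")
    t2 = arc / v_out
    return t1 + t2, v_out


def simulate_disk(params: DiskParams, n_cycles: int, seed: int = 0) -> StrideSeries:
    """Iterate :func:`disk_cycle` with iid N(0, force_sd^2) half-cycle forces.

    The velocity sequence is a martingale-like random walk (zero-mean
    forcing); a stall raises :class:`GaitFailureError` with the completed
    cycles attached as a flagged partial series.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    forces = rng.normal(0.0, params.force_sd, size=n_cycles)
    durations = np.empty(n_cycles)
    v = params.v0
    meta = dict(params.to_dict())
    for i in range(n_cycles):
        try:
            durations[i], v = disk_cycle(v, forces[i], params)
        except GaitFailureError:
            partial = StrideSeries(intervals=durations[:i], seed=seed,
                                   params=meta, kind="rolling_disk",
                                   complete=False, failed_at=i)
            raise GaitFailureError(f"disk stalled at cycle {i}",
                                   stride_index=i, partial=partial)
    return StrideSeries(intervals=durations, seed=seed, params=meta,
                        kind="rolling_disk")
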