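"""Parameter containers for the walker, the rolling-disk limit and benchmarks.

The walker is a point mass on rigid massless legs.  Each step is the hybrid
sequence heel-strike collision -> actuated four-bar double stance -> inverted
pendulum single stance.  ``WalkerParams`` collects the physical constants
(morphology, gravity, ankle spring) together with the numerical step size of
the fixed-grid integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

from .errors import GeometryError

__all__ = ["WalkerParams", "DiskParams", "NoiseSpec", "TABLE_MORPHOLOGY"]

#: Morphological constants shared by both leg-angle configurations:
#: mass (kg), leg length (m), foot length (m), gravity (m/s^2) and the
#: maximal plantar flexion angle of the ankle (rad).
TABLE_MORPHOLOGY = {"m": 80.0, "L": 1.0, "l": 0.2, "g": 9.81, "mu": 2.576}


@dataclass(frozen=True)
class WalkerParams:
    """Physical and numerical constants of the one-degree-of-freedom walker.

    Parameters
    ----------
    m : float
        Point mass at the hip (kg).
    L : float
        Leg length, hip to ankle (m).
    l : float
        Foot length, ankle to ground pivot (m).
    g : float
        Gravitational acceleration (m/s^2).
    mu : float
        Maximal plantar flexion angle of the ankle (rad).  The trailing
        ankle torque is ``k * (mu - psi)`` and double stance ends exactly
        when ``psi`` reaches ``mu``.
    theta0 : float
        Half inter-leg angle at heel strike (rad).  Solely determines the
        orbital stability: the single Floquet multiplier is ``cos^2(2*theta0)``.
    k0 : float
        Nominal ankle spring constant (N*m/rad), mean of the per-step draw.
    sigma2 : float
        Variance of the per-step spring constant (units of k^2).  Zero gives
        the deterministic limit cycle.
    h : float
        Fixed step size of the Runge-Kutta integrator (s).
    """

    theta0: float
    k0: float
    sigma2: float = 0.0
    m: float = TABLE_MORPHOLOGY["m"]
    L: float = TABLE_MORPHOLOGY["L"]
    l: float = TABLE_MORPHOLOGY["l"]
    g: float = TABLE_MORPHOLOGY["g"]
    mu: float = TABLE_MORPHOLOGY["mu"]
    h: float = 1e-4

    def __post_init__(self):
        for name in ("m", "L", "l", "g", "k0", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not 0.0 < self.theta0 < math.pi / 4:
            raise ValueError("theta0 must lie in (0, pi/4)")
        if not 0.0 < self.mu < math.pi:
            raise ValueError("mu must lie in (0, pi)")

    # -- derived geometry ---------------------------------------------------

    @property
    def sigma(self) -> float:
        """Standard deviation of the per-step spring constant."""
        return math.sqrt(self.sigma2)

    @property
    def psi0(self) -> float:
        """Ankle angle at double-stance onset: pi/2 + theta0.

        The trailing foot pivots about its ground contact a distance ``l``
        behind the ankle; with the legs at +/- theta0 this places the interior
        ankle angle at pi/2 + theta0 when the spring is released.
        """
        return math.pi / 2 + self.theta0

    @property
    def spring_travel(self) -> float:
        """Plantar flexion travel mu - psi0 of the pre-loaded spring (rad)."""
        return self.mu - self.psi0

    @property
    def ground_link(self) -> float:
        """Distance from the trailing-foot pivot to the leading ankle (m)."""
        return 2.0 * self.L * math.sin(self.theta0) + self.l

    @property
    def theta_release(self) -> float:
        """Stance-leg angle at which psi reaches mu and double stance ends."""
        c1 = self.ground_link
        arg = (c1 * c1 - self.l * self.l
               + 2.0 * self.l * self.L * math.cos(self.mu)) / (2.0 * self.L * c1)
        if not -1.0 <= arg <= 1.0:
            raise GeometryError("release angle psi = mu is unreachable")
        theta_s = math.asin(arg)
        if not -self.theta0 < theta_s < self.theta0:
            raise GeometryError(
                f"release angle {theta_s:.4f} rad lies outside the step "
                f"(+/-{self.theta0:.4f} rad); no valid hybrid gait")
        return theta_s

    @property
    def collision_factor(self) -> float:
        """Speed-reduction factor cos(2*theta0) of the heel-strike collision."""
        return math.cos(2.0 * self.theta0)

    @property
    def floquet(self) -> float:
        """The single Floquet multiplier cos^2(2*theta0) of the limit cycle."""
        return self.collision_factor ** 2

    @property
    def stride_length(self) -> float:
        """Distance travelled per stride (two steps): 4*L*sin(theta0) (m)."""
        return 4.0 * self.L * math.sin(self.theta0)

    @property
    def energy_gain(self) -> float:
        """Squared-angular-speed gain per step: k*(mu-psi0)^2 / (m*L^2) per unit k."""
        return self.spring_travel ** 2 / (self.m * self.L ** 2)

    def with_noise(self, sigma2: float) -> "WalkerParams":
        return replace(self, sigma2=sigma2)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WalkerParams":
        return cls(**d)


@dataclass(frozen=True)
class DiskParams:
    """Constants of the rolling-disk limit (theta0 -> 0) of the walker.

    A disk of radius ``radius`` with all mass ``m`` at the center (zero
    moment of inertia) rolls without slipping.  A stochastic horizontal
    force of zero mean and standard deviation ``force_sd`` acts on the
    center while the disk rolls through the first pi radians of each cycle
    and vanishes for the second half, mirroring the double-stance-only
    actuation of the walker.
    """

    m: float = 80.0
    radius: float = 1.0
    v0: float = 2.0 * math.pi / 1.23
    force_sd: float = 0.0

    def __post_init__(self):
        for name in ("m", "radius", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.force_sd < 0:
            raise ValueError("force_sd must be >= 0")

    @property
    def nominal_period(self) -> float:
        """Cycle duration 2*pi*radius/v0 of the unforced disk (s)."""
        return 2.0 * math.pi * self.radius / self.v0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of a benchmark stride-interval series.

    ``white`` draws iid Gaussian intervals N(mean, sd^2); ``brownian`` adds a
    cumulative sum of iid N(0, sd^2) increments to ``mean``, producing the
    marginal-stability (Brownian) benchmark.
    """

    kind: str
    n: int
    seed: int
    mean: float = 1.23
    sd: float = 0.0369
    _KINDS = ("white", "brownian")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if not k.startswith("_")}
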