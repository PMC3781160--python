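"""Independent oracles used to cross-check the simulator and the DFA code.

Everything here deliberately avoids the code paths it validates: step
durations come from energy-conservation quadrature instead of the RK4
event integrator, the double-stance hip trajectory from a Cartesian
constraint-projection (DAE) integration instead of the reduced scalar ODE,
and the DFA fluctuation from a naive per-window polyfit loop instead of the
vectorized implementation.
"""

import math

import numpy as np
from scipy.integrate import quad

from stridewalk import WalkerParams
from stridewalk.walker import psi_of_theta


# ---------------------------------------------------------------------------
# energy-quadrature step oracle
# ---------------------------------------------------------------------------

def thetadot_sq(theta: float, x: float, k: float, p: WalkerParams) -> float:
    """Squared leg angular speed from energy conservation at angle theta."""
    mL2 = p.m * p.L ** 2
    grav = 2.0 * p.g / p.L * (math.cos(p.theta0) - math.cos(theta))
    if theta >= p.theta_release:  # double stance: partial spring release
        psi = psi_of_theta(theta, p)
        released = k * (p.spring_travel ** 2 - (p.mu - psi) ** 2) / mL2
    else:  # single stance: full pre-load released
        released = k * p.spring_travel ** 2 / mL2
    return x + grav + released


def quad_step_durations(x: float, k: float, p: WalkerParams):
    """(t_ds, t_total, omega_pre) by quadrature of dtheta/|thetadot|."""
    theta_s = p.theta_release

    def inv_speed(theta):
        return 1.0 / math.sqrt(thetadot_sq(theta, x, k, p))

    t_ds, _ = quad(inv_speed, theta_s, p.theta0, epsabs=1e-13, epsrel=1e-12)
    t_ss, _ = quad(inv_speed, -p.theta0, theta_s, epsabs=1e-13, epsrel=1e-12)
    omega_pre = math.sqrt(thetadot_sq(-p.theta0, x, k, p))
    return t_ds, t_ds + t_ss, omega_pre


# ---------------------------------------------------------------------------
# Cartesian constraint-projection (DAE) oracle for double stance
# ---------------------------------------------------------------------------

def dae_hip_trajectory(x: float, k: float, p: WalkerParams, t_end: float,
                       h: float = 1e-5):
    """Hip positions on [0, t_end] from projected Cartesian dynamics.

    The hip is a point mass on the circle |r| = L about the leading ankle
    (origin).  Gravity acts directly; the ankle-spring generalized force
    Q_theta = T(psi) * dpsi/dtheta is applied along the tangent.  After each
    RK4 step, position and velocity are projected back onto the constraint.
    Returns (times, positions[n,2]).
    """
    from stridewalk.walker import dpsi_dtheta, ankle_torque

    mL2_inv = 1.0 / (p.m * p.L)

    def accel(r, v):
        theta = math.atan2(-r[0], r[1])
        tang = np.array([-math.cos(theta), -math.sin(theta)])  # d(hip)/dtheta / L
        q_theta = ankle_torque(psi_of_theta(theta, p), k, p) \
            * dpsi_dtheta(theta, p)
        f = np.array([0.0, -p.g]) + (q_theta * mL2_inv) * tang
        # project out the radial component (ideal constraint force)
        rhat = r / np.linalg.norm(r)
        f_t = f - (f @ rhat) * rhat
        # centripetal term keeps |r| constant
        return f_t - (v @ v) / (r @ r) * r

    theta0 = p.theta0
    r = np.array([-p.L * math.sin(theta0), p.L * math.cos(theta0)])
    omega = math.sqrt(x)
    # thetadot = -omega; hip velocity = thetadot * L * tangent_hat
    v = (-omega * p.L) * np.array([-math.cos(theta0), -math.sin(theta0)])

    n = int(round(t_end / h))
    times = np.arange(n + 1) * h
    out = np.empty((n + 1, 2))
    out[0] = r
    for i in range(n):
        k1r, k1v = v, accel(r, v)
        k2r, k2v = v + 0.5 * h * k1v, accel(r + 0.5 * h * k1r, v + 0.5 * h * k1v)
        k3r, k3v = v + 0.5 * h * k2v, accel(r + 0.5 * h * k2r, v + 0.5 * h * k2v)
        k4r, k4v = v + h * k3v, accel(r + h * k3r, v + h * k3v)
        r = r + h * (k1r + 2 * k2r + 2 * k3r + k4r) / 6.0
        v = v + h * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
        # projection onto the constraint manifold
        r = r * (p.L / np.linalg.norm(r))
        rhat = r / p.L
        v = v - (v @ rhat) * rhat
        out[i + 1] = r
    return times, out


# ---------------------------------------------------------------------------
# brute-force DFA fluctuation oracle
# ---------------------------------------------------------------------------

def naive_dfa_fluctuation(y: np.ndarray, n: int) -> float:
    """Per-window polyfit loop; RMS residual over covered samples."""
    y = np.asarray(y, dtype=float)
    m = len(y) // n
    sq = 0.0
    t = np.arange(n, dtype=float)
    for w in range(m):
        seg = y[w * n:(w + 1) * n]
        coef = np.polyfit(t, seg, 1)
        fit = np.polyval(coef, t)
        sq += np.sum((seg - fit) ** 2)
    return math.sqrt(sq / (m * n))
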