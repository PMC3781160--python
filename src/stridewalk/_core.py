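"""Jitted fixed-step integrator for the hybrid walker step.

Everything here works in the stance-leg angle theta (positive when the hip is
behind the vertical through the stance ankle; theta runs from +theta0 just
after the collision down to -theta0 at the next heel strike).  The four-bar
double stance enters only through the ankle angle psi(theta) and its
derivative, both closed-form:

    cos psi = (l^2 - c1^2 + 2 L c1 sin theta) / (2 l L),   c1 = 2 L sin theta0 + l
    dpsi/dtheta = -c1 cos theta / (l sin psi)

Integration is classical Runge-Kutta 4 on the fixed grid h; phase-transition
events (psi = mu, then theta = -theta0) are localized by bisecting the length
of a single partial RK4 step until the event time is bracketed to 1e-10 s.

Status codes returned by the step integrator:
    0  step completed
    1  fell backward (thetadot reached zero before heel strike)
    2  timed out (no event within T_MAX seconds)
"""

import numpy as np
from numba import njit

T_MAX = 30.0  # hard cap on a single step duration (s)
EVENT_TOL = 1e-10  # event localization tolerance (s)

STATUS_OK = 0
STATUS_FELL = 1
STATUS_TIMEOUT = 2


@njit(cache=True)
def psi_of_theta(theta, L, l, c1):
    c = (l * l - c1 * c1 + 2.0 * L * c1 * np.sin(theta)) / (2.0 * l * L)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c)


@njit(cache=True)
def _accel_ds(theta, k, m, L, l, g, mu, c1):
    psi = psi_of_theta(theta, L, l, c1)
    dpsi = -c1 * np.cos(theta) / (l * np.sin(psi))
    return (g / L) * np.sin(theta) + k * (mu - psi) * dpsi / (m * L * L)


@njit(cache=True)
def _rk4_ds(theta, thetadot, tau, k, m, L, l, g, mu, c1):
    k1v = _accel_ds(theta, k, m, L, l, g, mu, c1)
    th2 = theta + 0.5 * tau * thetadot
    k2v = _accel_ds(th2, k, m, L, l, g, mu, c1)
    v2 = thetadot + 0.5 * tau * k1v
    th3 = theta + 0.5 * tau * v2
    k3v = _accel_ds(th3, k, m, L, l, g, mu, c1)
    v3 = thetadot + 0.5 * tau * k2v
    th4 = theta + tau * v3
    k4v = _accel_ds(th4, k, m, L, l, g, mu, c1)
    theta_new = theta + tau * (thetadot + 2.0 * v2 + 2.0 * v3 + (thetadot + tau * k3v)) / 6.0
    thetadot_new = thetadot + tau * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
    return theta_new, thetadot_new


@njit(cache=True)
def _rk4_ss(theta, thetadot, tau, L, g):
    gl = g / L
    k1v = gl * np.sin(theta)
    th2 = theta + 0.5 * tau * thetadot
    k2v = gl * np.sin(th2)
    v2 = thetadot + 0.5 * tau * k1v
    th3 = theta + 0.5 * tau * v2
    k3v = gl * np.sin(th3)
    v3 = thetadot + 0.5 * tau * k2v
    th4 = theta + tau * v3
    k4v = gl * np.sin(th4)
    theta_new = theta + tau * (thetadot + 2.0 * v2 + 2.0 * v3 + (thetadot + tau * k3v)) / 6.0
    thetadot_new = thetadot + tau * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
    return theta_new, thetadot_new


@njit(cache=True)
def step_core(theta, thetadot, k, m, L, l, g, mu, theta0, h, theta_s):
    """Integrate one step from a double-stance state.

    Returns (t_ds, t_total, omega_pre, status): the double-stance duration,
    the step duration, and the pre-collision stance-leg angular speed.
    """
    c1 = 2.0 * L * np.sin(theta0) + l
    t = 0.0
    # --- double stance: until psi = mu, i.e. theta = theta_s (theta falls) ---
    while True:
        th2, td2 = _rk4_ds(theta, thetadot, h, k, m, L, l, g, mu, c1)
        if th2 <= theta_s:
            lo = 0.0
            hi = h
            while hi - lo > EVENT_TOL:
                mid = 0.5 * (lo + hi)
                thm, _ = _rk4_ds(theta, thetadot, mid, k, m, L, l, g, mu, c1)
                if thm <= theta_s:
                    hi = mid
                else:
                    lo = mid
            tau = 0.5 * (lo + hi)
            theta, thetadot = _rk4_ds(theta, thetadot, tau, k, m, L, l, g, mu, c1)
            t += tau
            break
        if td2 >= 0.0:
            return t, t, 0.0, STATUS_FELL
        theta, thetadot = th2, td2
        t += h
        if t > T_MAX:
            return t, t, 0.0, STATUS_TIMEOUT
    t_ds = t
    # --- single stance: inverted pendulum until theta = -theta0 ---
    while True:
        th2, td2 = _rk4_ss(theta, thetadot, h, L, g)
        if th2 <= -theta0:
            lo = 0.0
            hi = h
            while hi - lo > EVENT_TOL:
                mid = 0.5 * (lo + hi)
                thm, _ = _rk4_ss(theta, thetadot, mid, L, g)
                if thm <= -theta0:
                    hi = mid
                else:
                    lo = mid
            tau = 0.5 * (lo + hi)
            theta, thetadot = _rk4_ss(theta, thetadot, tau, L, g)
            t += tau
            break
        if td2 >= 0.0:
            return t_ds, t, 0.0, STATUS_FELL
        theta, thetadot = th2, td2
        t += h
        if t > T_MAX:
            return t_ds, t, 0.0, STATUS_TIMEOUT
    return t_ds, t, -thetadot, STATUS_OK


@njit(cache=True)
def walk_core(omega0, ks, m, L, l, g, mu, theta0, h, theta_s):
    """Chain steps through the heel-strike collision.

    omega0 is the post-collision angular speed entering the first step and
    ks the per-step spring constants.  Returns (durations, ds_durations,
    omega_posts, n_done, status); on failure n_done counts completed steps.
    """
    n = ks.shape[0]
    durations = np.empty(n)
    ds_durations = np.empty(n)
    omega_posts = np.empty(n)
    cf = np.cos(2.0 * theta0)
    om = omega0
    for i in range(n):
        omega_posts[i] = om
        t_ds, t, om_pre, status = step_core(
            theta0, -om, ks[i], m, L, l, g, mu, theta0, h, theta_s)
        if status != STATUS_OK:
            return durations, ds_durations, omega_posts, i, status
        durations[i] = t
        ds_durations[i] = t_ds
        om = cf * om_pre
    return durations, ds_durations, omega_posts, n, STATUS_OK
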