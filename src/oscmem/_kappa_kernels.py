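"""Numba-accelerated fixed-step integration of the reduced kappa dynamics.

These kernels integrate

    tau dk_i/dt = -k_i + (1/N) n^(i)T tanh(x) + alpha_i A sin(theta) + tonic_i
    x(k, theta) = m^(1) k1 + m^(2) k2 + I_perp v(theta) + base
    v(theta)    = A / sqrt((w tau)^2 + 1) * sin(theta - arctan(w tau))

with theta = theta0 + w t, using RK4 (or Euler) at a fixed step.  If numba is
unavailable the same code runs as plain Python (slow but correct).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except Exception:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True)
def _rhs(k1, k2, theta, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl):
    N = m.shape[0]
    v = A * vg * np.sin(theta - vl)
    u = A * np.sin(theta)
    acc1 = 0.0
    acc2 = 0.0
    for j in range(N):
        xj = m[j, 0] * k1 + m[j, 1] * k2 + Iperp[j] * v + base[j]
        t = np.tanh(xj)
        acc1 += n[j, 0] * t
        acc2 += n[j, 1] * t
    dk1 = (-k1 + acc1 / N + alpha[0] * u + tonic[0]) / tau
    dk2 = (-k2 + acc2 / N + alpha[1] * u + tonic[1]) / tau
    return dk1, dk2


@njit(cache=True)
def map_batch(kappas, theta0, n_steps, h, omega, tau, m, n, Iperp, base, alpha, tonic, A, use_rk4):
    """Advance K initial kappa points through n_steps of the flow."""
    K = kappas.shape[0]
    out = kappas.copy()
    vg = 1.0 / np.sqrt((omega * tau) ** 2 + 1.0)
    vl = np.arctan(omega * tau)
    for i in range(K):
        k1 = out[i, 0]
        k2 = out[i, 1]
        for s in range(n_steps):
            th = theta0 + omega * s * h
            if use_rk4:
                a1, a2 = _rhs(k1, k2, th, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
                b1, b2 = _rhs(k1 + 0.5 * h * a1, k2 + 0.5 * h * a2, th + 0.5 * omega * h,
                              m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
                c1, c2 = _rhs(k1 + 0.5 * h * b1, k2 + 0.5 * h * b2, th + 0.5 * omega * h,
                              m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
                d1, d2 = _rhs(k1 + h * c1, k2 + h * c2, th + omega * h,
                              m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
                k1 += h * (a1 + 2 * b1 + 2 * c1 + d1) / 6.0
                k2 += h * (a2 + 2 * b2 + 2 * c2 + d2) / 6.0
            else:
                a1, a2 = _rhs(k1, k2, th, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
                k1 += h * a1
                k2 += h * a2
        out[i, 0] = k1
        out[i, 1] = k2
    return out


@njit(cache=True)
def orbit(kappa, theta0, n_steps, h, omega, tau, m, n, Iperp, base, alpha, tonic, A, use_rk4):
    """Trajectory (n_steps + 1, 2) of one kappa initial condition."""
    traj = np.empty((n_steps + 1, 2))
    traj[0, 0] = kappa[0]
    traj[0, 1] = kappa[1]
    vg = 1.0 / np.sqrt((omega * tau) ** 2 + 1.0)
    vl = np.arctan(omega * tau)
    k1 = kappa[0]
    k2 = kappa[1]
    for s in range(n_steps):
        th = theta0 + omega * s * h
        if use_rk4:
            a1, a2 = _rhs(k1, k2, th, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            b1, b2 = _rhs(k1 + 0.5 * h * a1, k2 + 0.5 * h * a2, th + 0.5 * omega * h,
                          m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            c1, c2 = _rhs(k1 + 0.5 * h * b1, k2 + 0.5 * h * b2, th + 0.5 * omega * h,
                          m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            d1, d2 = _rhs(k1 + h * c1, k2 + h * c2, th + omega * h,
                          m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            k1 += h * (a1 + 2 * b1 + 2 * c1 + d1) / 6.0
            k2 += h * (a2 + 2 * b2 + 2 * c2 + d2) / 6.0
        else:
            a1, a2 = _rhs(k1, k2, th, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            k1 += h * a1
            k2 += h * a2
        traj[s + 1, 0] = k1
        traj[s + 1, 1] = k2
    return traj


@njit(cache=True)
def _jac(k1, k2, theta, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl):
    """Jacobian of the kappa field: (1/tau)(-I + (1/N) n^T diag(1 - tanh^2 x) m)."""
    N = m.shape[0]
    v = A * vg * np.sin(theta - vl)
    a11 = 0.0
    a12 = 0.0
    a21 = 0.0
    a22 = 0.0
    for j in range(N):
        xj = m[j, 0] * k1 + m[j, 1] * k2 + Iperp[j] * v + base[j]
        t = np.tanh(xj)
        sech2 = 1.0 - t * t
        a11 += n[j, 0] * sech2 * m[j, 0]
        a12 += n[j, 0] * sech2 * m[j, 1]
        a21 += n[j, 1] * sech2 * m[j, 0]
        a22 += n[j, 1] * sech2 * m[j, 1]
    inv = 1.0 / (N * tau)
    return (
        (a11 * inv - 1.0 / tau),
        a12 * inv,
        a21 * inv,
        (a22 * inv - 1.0 / tau),
    )


@njit(cache=True)
def map_with_monodromy(kappa, theta0, n_steps, h, omega, tau, m, n, Iperp, base, alpha, tonic, A, use_rk4):
    """Integrate the flow and the variational equation dM/dt = DF M, M(0) = I.

    Returns (kappa_final (2,), M (2, 2)).
    """
    vg = 1.0 / np.sqrt((omega * tau) ** 2 + 1.0)
    vl = np.arctan(omega * tau)
    k1 = kappa[0]
    k2 = kappa[1]
    M = np.eye(2)
    y = np.empty(6)
    for s in range(n_steps):
        th = theta0 + omega * s * h
        y[0] = k1
        y[1] = k2
        y[2] = M[0, 0]
        y[3] = M[0, 1]
        y[4] = M[1, 0]
        y[5] = M[1, 1]
        if use_rk4:
            f1 = _joint_rhs(y, th, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            f2 = _joint_rhs(y + 0.5 * h * f1, th + 0.5 * omega * h, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            f3 = _joint_rhs(y + 0.5 * h * f2, th + 0.5 * omega * h, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            f4 = _joint_rhs(y + h * f3, th + omega * h, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
            y = y + h * (f1 + 2 * f2 + 2 * f3 + f4) / 6.0
        else:
            y = y + h * _joint_rhs(y, th, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
        k1 = y[0]
        k2 = y[1]
        M[0, 0] = y[2]
        M[0, 1] = y[3]
        M[1, 0] = y[4]
        M[1, 1] = y[5]
    out = np.empty(2)
    out[0] = k1
    out[1] = k2
    return out, M


@njit(cache=True)
def _joint_rhs(y, theta, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl):
    dk1, dk2 = _rhs(y[0], y[1], theta, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
    j11, j12, j21, j22 = _jac(y[0], y[1], theta, m, n, Iperp, base, alpha, tonic, A, omega, tau, vg, vl)
    out = np.empty(6)
    out[0] = dk1
    out[1] = dk2
    out[2] = j11 * y[2] + j12 * y[4]
    out[3] = j11 * y[3] + j12 * y[5]
    out[4] = j21 * y[2] + j22 * y[4]
    out[5] = j21 * y[3] + j22 * y[5]
    return out
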