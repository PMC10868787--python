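"""Reduced kappa dynamics: limit cycles, Floquet stability and locking scans.

A rank-2 network driven by u(theta) = A sin(theta) reduces to a 3-D
autonomous system on (kappa1, kappa2, theta).  This module locates limit
cycles as fixed points of the Poincare return map on the section theta = 0,
computes their Floquet multipliers from the variational (monodromy)
equation, and scans stimulus amplitude and reference amplitude/frequency for
bifurcations and m:n locking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from . import _kappa_kernels as _kk
from .rnn_core import LowRankRNN, canonicalize, decompose_along_m

__all__ = [
    "TorusPoint",
    "PoincareFixedPoint",
    "FieldBase",
    "KappaField",
    "poincare_map",
    "find_fixed_points",
    "floquet_multipliers",
    "stimulus_bifurcation",
    "freq_amp_scan",
    "torus_embed",
    "coding_metrics",
    "pca_basis_fullrank",
]


@dataclass
class TorusPoint:
    kappa1: float
    kappa2: float
    theta: float

    def __post_init__(self) -> None:
        self.theta = float(np.mod(self.theta, 2 * np.pi))


@dataclass
class PoincareFixedPoint:
    """A limit cycle, represented as a fixed point of the section map."""

    kappa_star: np.ndarray  # (2,) on the section theta = 0
    period_n: int  # reference periods per return
    winding_m: int  # internal cycles per return
    multipliers: np.ndarray  # 2 complex Floquet multipliers
    residual: float

    @property
    def stable(self) -> bool:
        return bool(np.max(np.abs(self.multipliers)) < 1.0)

    @property
    def max_multiplier(self) -> float:
        return float(np.max(np.abs(self.multipliers)))

    @property
    def phase(self) -> float:
        """Internal phase atan2(kappa2, kappa1) on the section."""
        return float(np.arctan2(self.kappa_star[1], self.kappa_star[0]))


class FieldBase:
    """Protocol + generic fixed-step integrators for a kappa field.

    Subclasses provide ``rhs_batch(kappas (K,2), theta) -> (K,2)`` plus the
    attributes ``omega`` (rad/ms), ``h`` (ms) and ``use_rk4``; they may
    override the heavy entry points with faster kernels.
    """

    omega: float
    h: float
    use_rk4: bool = True

    def rhs_batch(self, kappas: np.ndarray, theta: float) -> np.ndarray:
        raise NotImplementedError

    def rhs(self, kappa, theta: float) -> np.ndarray:
        return self.rhs_batch(np.asarray(kappa, float)[None, :], theta)[0]

    def jac(self, kappa, theta: float, eps: float = 1e-6) -> np.ndarray:
        """Field Jacobian d(dkappa/dt)/dkappa; central differences by default."""
        J = np.empty((2, 2))
        for j in range(2):
            dp = np.array(kappa, float)
            dm = np.array(kappa, float)
            dp[j] += eps
            dm[j] -= eps
            J[:, j] = (self.rhs(dp, theta) - self.rhs(dm, theta)) / (2 * eps)
        return J

    # -- period bookkeeping ------------------------------------------------
    def period_ms(self) -> float:
        return 2 * np.pi / self.omega

    def _steps(self, n_periods: int) -> tuple[int, float]:
        T = n_periods * self.period_ms()
        n = max(1, int(round(T / self.h)))
        return n, T / n  # adjusted step so the map lands exactly on theta=0

    # -- generic integrators ----------------------------------------------
    def map_batch(self, kappas: np.ndarray, n_periods: int = 1, theta0: float = 0.0) -> np.ndarray:
        n, h = self._steps(n_periods)
        k = np.array(kappas, float)
        for s in range(n):
            th = theta0 + self.omega * s * h
            if self.use_rk4:
                a = self.rhs_batch(k, th)
                b = self.rhs_batch(k + 0.5 * h * a, th + 0.5 * self.omega * h)
                c = self.rhs_batch(k + 0.5 * h * b, th + 0.5 * self.omega * h)
                d = self.rhs_batch(k + h * c, th + self.omega * h)
                k = k + h * (a + 2 * b + 2 * c + d) / 6.0
            else:
                k = k + h * self.rhs_batch(k, th)
        if not np.all(np.isfinite(k)):
            raise FloatingPointError("non-finite kappa state during integration")
        return k

    def orbit(self, kappa, n_periods: int = 1, theta0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Returns (thetas (S+1,), kappa trajectory (S+1, 2))."""
        n, h = self._steps(n_periods)
        traj = np.empty((n + 1, 2))
        traj[0] = kappa
        k = np.array(kappa, float)[None, :]
        for s in range(n):
            th = theta0 + self.omega * s * h
            if self.use_rk4:
                a = self.rhs_batch(k, th)
                b = self.rhs_batch(k + 0.5 * h * a, th + 0.5 * self.omega * h)
                c = self.rhs_batch(k + 0.5 * h * b, th + 0.5 * self.omega * h)
                d = self.rhs_batch(k + h * c, th + self.omega * h)
                k = k + h * (a + 2 * b + 2 * c + d) / 6.0
            else:
                k = k + h * self.rhs_batch(k, th)
            traj[s + 1] = k[0]
        thetas = theta0 + self.omega * np.arange(n + 1) * (self.period_ms() * n_periods / n)
        return thetas, traj

    def map_with_monodromy(self, kappa, n_periods: int = 1, theta0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Integrate flow + variational equation dM/dt = DF M, M(0) = I."""
        n, h = self._steps(n_periods)
        k = np.array(kappa, float)
        M = np.eye(2)

        def joint_rhs(y, th):
            kk, MM = y[:2], y[2:].reshape(2, 2)
            J = self.jac(kk, th)
            return np.concatenate([self.rhs(kk, th), (J @ MM).ravel()])

        y = np.concatenate([k, M.ravel()])
        for s in range(n):
            th = theta0 + self.omega * s * h
            if self.use_rk4:
                a = joint_rhs(y, th)
                b = joint_rhs(y + 0.5 * h * a, th + 0.5 * self.omega * h)
                c = joint_rhs(y + 0.5 * h * b, th + 0.5 * self.omega * h)
                d = joint_rhs(y + h * c, th + self.omega * h)
                y = y + h * (a + 2 * b + 2 * c + d) / 6.0
            else:
                y = y + h * joint_rhs(y, th)
        return y[:2], y[2:].reshape(2, 2)

    def replaced(self, **kw) -> "FieldBase":
        return replace(self, **kw)


@dataclass
class KappaField(FieldBase):
    """RNN-backed kappa field (canonicalized rank-2 network under sine drive).

    ``base`` is the theta-independent part of x coming from tonically applied
    stimuli (their m-orthogonal component, already at steady state), and
    ``tonic`` their direct contribution to the kappa drive.
    """

    m: np.ndarray  # (N, 2) orthogonal basis
    n: np.ndarray  # (N, 2)
    I_perp: np.ndarray  # (N,)
    alphas: np.ndarray  # (2,)
    tau: float
    A: float = 1.0
    omega: float = 2 * np.pi * 8.0 / 1000.0  # rad/ms
    h: float = 0.5
    use_rk4: bool = True
    base: np.ndarray | None = None
    tonic: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))
    I_stim_perp: np.ndarray | None = None  # (N, S)
    betas: np.ndarray | None = None  # (2, S)

    def __post_init__(self) -> None:
        if self.base is None:
            self.base = np.zeros(self.m.shape[0])

    @classmethod
    def from_rnn(
        cls,
        rnn: LowRankRNN,
        A: float = 1.0,
        freq_hz: float = 8.0,
        h: float = 0.5,
        use_rk4: bool = True,
    ) -> "KappaField":
        can, alphas, I_perp = canonicalize(rnn)
        S = can.n_stimuli
        betas = np.empty((2, S))
        I_stim_perp = np.empty((can.N, S))
        for j in range(S):
            betas[:, j], I_stim_perp[:, j] = decompose_along_m(can, can.I_stim[:, j])
        return cls(
            m=can.m,
            n=can.n,
            I_perp=I_perp,
            alphas=alphas,
            tau=can.tau,
            A=A,
            omega=2 * np.pi * freq_hz / 1000.0,
            h=h,
            use_rk4=use_rk4,
            I_stim_perp=I_stim_perp,
            betas=betas,
        )

    def with_stimulus(self, stim_id: int, s: float) -> "KappaField":
        """Fold a tonic stimulus (at its steady-state filtered value) into the field."""
        if self.I_stim_perp is None:
            raise ValueError("field was built without stimulus decomposition")
        return replace(
            self,
            base=self.I_stim_perp[:, stim_id] * s,
            tonic=self.betas[:, stim_id] * s,
        )

    # -- direct evaluation -------------------------------------------------
    def v_of(self, theta) -> np.ndarray:
        wt = self.omega * self.tau
        return self.A / np.sqrt(wt**2 + 1.0) * np.sin(np.asarray(theta) - np.arctan(wt))

    def x_of(self, kappa, theta: float) -> np.ndarray:
        """Full network state for a torus point (transients discarded)."""
        k = np.asarray(kappa, float)
        return self.m[:, 0] * k[0] + self.m[:, 1] * k[1] + self.I_perp * self.v_of(theta) + self.base

    def rhs_batch(self, kappas: np.ndarray, theta: float) -> np.ndarray:
        k = np.atleast_2d(kappas)
        x = k @ self.m.T + (self.I_perp * self.v_of(theta) + self.base)[None, :]
        rec = np.tanh(x) @ self.n / self.m.shape[0]
        drive = rec + self.alphas[None, :] * (self.A * np.sin(theta)) + self.tonic[None, :]
        return (-k + drive) / self.tau

    def jac(self, kappa, theta: float, eps: float = 0.0) -> np.ndarray:
        x = self.x_of(kappa, theta)
        sech2 = 1.0 - np.tanh(x) ** 2
        N = self.m.shape[0]
        return (self.n.T @ (sech2[:, None] * self.m) / N - np.eye(2)) / self.tau

    # -- numba fast paths --------------------------------------------------
    def _kernel_args(self, n_periods: int):
        n, h = self._steps(n_periods)
        return (
            n,
            h,
            self.omega,
            self.tau,
            np.ascontiguousarray(self.m),
            np.ascontiguousarray(self.n),
            np.ascontiguousarray(self.I_perp),
            np.ascontiguousarray(self.base),
            np.ascontiguousarray(self.alphas),
            np.ascontiguousarray(self.tonic),
            self.A,
            self.use_rk4,
        )

    def map_batch(self, kappas: np.ndarray, n_periods: int = 1, theta0: float = 0.0) -> np.ndarray:
        n, h, *rest = self._kernel_args(n_periods)
        out = _kk.map_batch(np.atleast_2d(np.array(kappas, float)), theta0, n, h, *rest[:-1], rest[-1])
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite kappa state during integration")
        return out

    def orbit(self, kappa, n_periods: int = 1, theta0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        n, h, *rest = self._kernel_args(n_periods)
        traj = _kk.orbit(np.array(kappa, float), theta0, n, h, *rest[:-1], rest[-1])
        thetas = theta0 + self.omega * np.arange(n + 1) * h
        return thetas, traj

    def map_with_monodromy(self, kappa, n_periods: int = 1, theta0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        n, h, *rest = self._kernel_args(n_periods)
        return _kk.map_with_monodromy(np.array(kappa, float), theta0, n, h, *rest[:-1], rest[-1])


# ---------------------------------------------------------------------------
# Poincare machinery (generic over fields)
# ---------------------------------------------------------------------------


def poincare_map(field: FieldBase, kappa, n_periods: int = 1) -> np.ndarray:
    """Return map on the section theta = 0 (mod 2 pi)."""
    k = np.asarray(kappa, float)
    single = k.ndim == 1
    out = field.map_batch(np.atleast_2d(k), n_periods=n_periods)
    return out[0] if single else out


def winding_number(field: FieldBase, kappa_star, n_periods: int = 1) -> int:
    """Internal cycles per return, from the unwrapped orbit angle."""
    _, traj = field.orbit(kappa_star, n_periods=n_periods)
    r = np.hypot(traj[:, 0], traj[:, 1])
    if np.median(r) < 1e-8:
        return 0
    ang = np.unwrap(np.arctan2(traj[:, 1], traj[:, 0]))
    return int(np.round((ang[-1] - ang[0]) / (2 * np.pi)))


def floquet_multipliers(field: FieldBase, kappa_star, n_periods: int = 1) -> np.ndarray:
    """Floquet multipliers: eigenvalues of the monodromy matrix M(T)."""
    _, M = field.map_with_monodromy(kappa_star, n_periods=n_periods)
    return np.linalg.eigvals(M)


def _newton_polish(field: FieldBase, kappa0, n_periods: int, tol: float, max_iter: int = 40):
    """Damped Newton on P(kappa) - kappa; returns (kappa, M, residual) or None."""
    k = np.array(kappa0, float)
    kp, M = field.map_with_monodromy(k, n_periods=n_periods)
    F = kp - k
    res = float(np.linalg.norm(F))
    for _ in range(max_iter):
        if res < tol:
            return k, M, res
        Amat = M - np.eye(2)
        try:
            delta = np.linalg.solve(Amat, -F)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(Amat, -F, rcond=None)[0]
        if not np.all(np.isfinite(delta)):
            return None
        step = 1.0
        for _ in range(8):
            trial = k + step * delta
            try:
                kp_t, M_t = field.map_with_monodromy(trial, n_periods=n_periods)
            except FloatingPointError:
                step *= 0.5
                continue
            F_t = kp_t - trial
            res_t = float(np.linalg.norm(F_t))
            if res_t < res or res < tol:
                k, M, F, res = trial, M_t, F_t, res_t
                break
            step *= 0.5
        else:
            return None
    return (k, M, res) if res < tol else None


def default_seed_grid(scale: float = 2.0, n_rings: int = 2, n_angles: int = 8) -> np.ndarray:
    """Origin plus rings of initial kappa conditions."""
    pts = [np.zeros(2)]
    for r in np.linspace(scale / n_rings, scale, n_rings):
        for a in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
            pts.append(np.array([r * np.cos(a), r * np.sin(a)]))
    return np.array(pts)


def estimate_orbit_scale(field: FieldBase, n_settle: int = 12, floor: float = 0.05) -> float:
    """Typical attractor radius, from settling a few probe points forward.

    Used to place seed grids at the right scale: trained networks can have
    orbit radii orders of magnitude apart depending on their weight scale.
    """
    probes = np.array([[0.3, 0.0], [0.0, 1.0], [-2.0, 0.0], [0.7, -0.7]])
    try:
        settled = field.map_batch(probes, n_periods=n_settle)
    except FloatingPointError:
        return 1.0
    r = np.hypot(settled[:, 0], settled[:, 1])
    return float(max(np.median(r), floor))


def find_fixed_points(
    field: FieldBase,
    seed_grid: np.ndarray | None = None,
    tol: float = 1e-9,
    n_periods: int = 1,
    merge_tol: float = 1e-3,
    presettle: int = 8,
) -> list[PoincareFixedPoint]:
    """Locate fixed points of the n_periods-return map via Newton iteration.

    Seeds are first settled by forward iteration of the map (which pulls them
    toward stable cycles), then polished with a damped Newton using the
    monodromy-matrix Jacobian.  Duplicates are merged by distance.
    """
    if seed_grid is None:
        scale = estimate_orbit_scale(field)
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        seeds = [np.zeros(2)]
        for rr in (0.7 * scale, scale, 1.3 * scale):
            seeds += [np.array([rr * np.cos(a), rr * np.sin(a)]) for a in angles]
        seeds = np.array(seeds)
    else:
        seeds = np.atleast_2d(seed_grid)
    if presettle > 0:
        try:
            settled = field.map_batch(seeds, n_periods=n_periods * presettle)
            # cluster settled points so Newton runs once per candidate attractor
            reps: list[np.ndarray] = []
            for p in settled:
                if not any(np.linalg.norm(p - q) < 10 * merge_tol for q in reps):
                    reps.append(p)
            seeds = np.array(reps)
        except FloatingPointError:
            pass
    found: list[PoincareFixedPoint] = []
    for seed in seeds:
        try:
            sol = _newton_polish(field, seed, n_periods, tol)
        except FloatingPointError:
            continue
        if sol is None:
            continue
        k, M, res = sol
        if any(np.linalg.norm(k - fp.kappa_star) < merge_tol for fp in found):
            continue
        lam = np.linalg.eigvals(M)
        found.append(
            PoincareFixedPoint(
                kappa_star=k,
                period_n=n_periods,
                winding_m=winding_number(field, k, n_periods),
                multipliers=lam,
                residual=res,
            )
        )
    found.sort(key=lambda fp: fp.phase)
    return found


def stimulus_bifurcation(
    field: KappaField,
    stim_id: int,
    amplitudes: np.ndarray,
    tol: float = 1e-9,
) -> tuple[pd.DataFrame, float]:
    """Track both no-stimulus cycles under increasing tonic stimulus amplitude.

    Returns a tidy table (amplitude, cycle, max multiplier norm, stable,
    n_stable) and the critical amplitude where the disfavored cycle's max
    multiplier norm crosses 1 (linear interpolation; NaN if no crossing).
    """
    amplitudes = np.asarray(amplitudes, float)
    stable_base = [fp for fp in find_fixed_points(field, tol=tol) if fp.stable]
    if len(stable_base) < 2:
        raise ValueError("need two stable no-stimulus cycles to run the stimulus sweep")
    merge_tol = 1e-3
    branches: dict[int, np.ndarray | None] = {
        0: stable_base[0].kappa_star.copy(),
        1: stable_base[1].kappa_star.copy(),
    }
    rows = []
    per_cycle_max: dict[int, list[tuple[float, float]]] = {0: [], 1: []}
    for s in amplitudes:
        f_s = field.with_stimulus(stim_id, float(s))
        pts: dict[int, tuple[np.ndarray, float] | None] = {}
        moved: dict[int, float] = {}
        for b in (0, 1):
            if branches[b] is None:
                pts[b] = None
                continue
            prev = branches[b].copy()
            sol = _newton_polish(f_s, prev, 1, tol)
            if sol is None:
                branches[b] = None
                pts[b] = None
                continue
            k, M, _ = sol
            pts[b] = (k, float(np.abs(np.linalg.eigvals(M)).max()))
            moved[b] = float(np.linalg.norm(k - prev))
            branches[b] = k
        # a branch whose Newton iterate jumped onto the other branch's cycle
        # has vanished (saddle-node fold crossed between grid points)
        if pts[0] is not None and pts[1] is not None and s > amplitudes[0]:
            if np.linalg.norm(pts[0][0] - pts[1][0]) < 10 * merge_tol:
                drop = 0 if moved.get(0, 0.0) > moved.get(1, 0.0) else 1
                pts[drop] = None
                branches[drop] = None
        n_stable = sum(1 for p in pts.values() if p is not None and p[1] < 1.0)
        for b in (0, 1):
            if pts[b] is None:
                rows.append(
                    {"amplitude": s, "cycle": b, "max_multiplier": np.nan, "stable": False, "n_stable": n_stable}
                )
                per_cycle_max[b].append((s, np.nan))
            else:
                k, lam = pts[b]
                rows.append(
                    {"amplitude": s, "cycle": b, "max_multiplier": lam, "stable": lam < 1.0, "n_stable": n_stable}
                )
                per_cycle_max[b].append((s, lam))
    table = pd.DataFrame(rows)
    # critical amplitude: |lambda| = 1 crossing of the disfavored cycle, or the
    # amplitude at which its branch vanished (saddle-node fold)
    crit = np.nan
    for b in (0, 1):
        arr = np.array(per_cycle_max[b], float)
        lam = arr[:, 1]
        for i in range(len(lam) - 1):
            if np.isfinite(lam[i]) and lam[i] < 1.0:
                if not np.isfinite(lam[i + 1]):
                    c = arr[i + 1, 0]  # fold in (s_i, s_{i+1}]
                elif lam[i + 1] >= 1.0:
                    c = arr[i, 0] + (1.0 - lam[i]) / (lam[i + 1] - lam[i]) * (arr[i + 1, 0] - arr[i, 0])
                else:
                    continue
                crit = c if np.isnan(crit) else min(crit, c)
                break
    return table, float(crit)


def _attractors_of_map(
    field: FieldBase,
    max_n: int = 4,
    n_ics: int = 12,
    scale: float | None = None,
    max_iter: int = 50,
    conv_tol: float = 2e-5,
    merge_tol: float = 1e-2,
    stagnation_window: int = 15,
):
    """Forward-iterate the section map and cluster period-<=max_n attractors.

    Returns a list of dicts {points, period_n, winding_m}.
    """
    if scale is None:
        scale = estimate_orbit_scale(field)
    angles = np.linspace(0, 2 * np.pi, n_ics, endpoint=False)
    k = np.stack([scale * np.cos(angles), scale * np.sin(angles)], axis=1)
    k = np.vstack([k, 0.5 * k, np.zeros((1, 2))])
    n_total = k.shape[0]
    active = np.arange(n_total)
    hist = np.full((max_iter + 1, n_total, 2), np.nan)
    hist[0] = k
    last_row = np.zeros(n_total, int)
    mind_log: dict[int, list[float]] = {i: [] for i in range(n_total)}
    for it in range(max_iter):
        if active.size == 0:
            break
        k_act = field.map_batch(hist[it][active], n_periods=1)
        hist[it + 1, active] = k_act
        last_row[active] = it + 1
        if it >= 2 * max_n and it % 3 == 0:
            # retire trajectories that already closed onto a period-<=max_n orbit
            still = []
            for i in active:
                dists = [
                    np.linalg.norm(hist[it + 1, i] - hist[it + 1 - p, i])
                    for p in range(1, max_n + 1)
                ]
                mind_log[i].append(min(dists))
                if min(dists) >= conv_tol:
                    still.append(i)
            active = np.array(still, int)
            # quasiperiodic cells never contract: abandon when no active
            # trajectory has shrunk its closure distance over the window
            n_checks = stagnation_window // 3
            if active.size and all(
                len(mind_log[i]) > n_checks
                and mind_log[i][-1] > 0.5 * mind_log[i][-1 - n_checks]
                for i in active
            ):
                break
    attractors = []
    for i in range(n_total):
        row = last_row[i]
        if row <= max_n:
            continue
        period = None
        for p in range(1, max_n + 1):
            if np.linalg.norm(hist[row, i] - hist[row - p, i]) < 10 * conv_tol:
                period = p
                break
        if period is None:
            continue
        pts = hist[row - period + 1 : row + 1, i, :]
        is_new = True
        for att in attractors:
            if att["period_n"] == period:
                d = min(
                    np.linalg.norm(a - b) for a in att["points"] for b in pts
                )
                if d < merge_tol:
                    is_new = False
                    break
        if is_new:
            attractors.append({"points": pts, "period_n": period})
    for att in attractors:
        att["winding_m"] = winding_number(field, att["points"][-1], n_periods=att["period_n"])
    return attractors


def freq_amp_scan(
    field: FieldBase,
    amp_grid: np.ndarray,
    freq_grid_hz: np.ndarray,
    max_n: int = 4,
    n_ics: int = 8,
    scale: float | None = None,
) -> pd.DataFrame:
    """Stability map over reference amplitude and frequency.

    Per grid cell, counts attracting period-n orbits (n <= max_n) of the
    section map with their winding numbers and labels the cell
    {bistable 1:1 | bistable m:n | monostable | none | other}.  The m:n tag
    is the raw (winding : period) of the orbit — not reduced to lowest
    terms, since a period-2 orbit with winding 2 is dynamically distinct
    from a fixed point with winding 1.
    """
    rows = []
    for A in np.asarray(amp_grid, float):
        for f in np.asarray(freq_grid_hz, float):
            omega = 2 * np.pi * f / 1000.0
            # fixed steps-per-period keeps per-cell cost uniform across the grid
            h_cell = float(np.clip((2 * np.pi / omega) / 64.0, 0.5, 8.0))
            fld = field.replaced(A=A, omega=omega, h=h_cell)
            try:
                atts = _attractors_of_map(fld, max_n=max_n, n_ics=n_ics, scale=scale)
            except FloatingPointError:
                atts = []
            n_att = len(atts)
            if n_att == 0:
                label = "none"
            elif n_att == 1:
                label = "monostable"
            elif n_att == 2:
                ratios = {(att["winding_m"], att["period_n"]) for att in atts}
                if len(ratios) == 1:
                    m_, n_ = next(iter(ratios))
                    label = f"bistable {m_}:{n_}"
                else:
                    label = "other"
            else:
                label = "other"
            best = max(atts, key=lambda a: a["period_n"], default=None)
            rows.append(
                {
                    "amplitude": A,
                    "freq_hz": f,
                    "n_stable": n_att,
                    "winding_m": best["winding_m"] if best else 0,
                    "period_n": best["period_n"] if best else 0,
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Geometry and coding metrics
# ---------------------------------------------------------------------------


def torus_embed(points: np.ndarray, r_tilde: float) -> np.ndarray:
    """Embed (kappa1, kappa2, theta) rows into 3-D torus coordinates.

    (x, y, z) = (cos(theta) (r - k1), sin(theta) (r - k1), k2).  The map is
    injective when r_tilde exceeds every kappa1 in the data.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if r_tilde <= np.max(pts[:, 0]):
        warnings.warn("r_tilde <= max kappa1: torus embedding may self-intersect")
    k1, k2, th = pts[:, 0], pts[:, 1], pts[:, 2]
    return np.stack([np.cos(th) * (r_tilde - k1), np.sin(th) * (r_tilde - k1), k2], axis=1)


def coding_metrics(
    rnn: LowRankRNN,
    trial_pairs: list,
    h: float | None = None,
    min_cycles: float = 2.0,
) -> tuple[float, float]:
    """Mean per-unit |rate difference| and |phase difference| across conditions.

    For each (stimulus-a trial, stimulus-b trial) pair, rates tanh(x) are
    taken over the post-stimulus window; per unit the conditions are compared
    by normalized time-mean rate and by circular phase at the reference
    frequency.  Returns the unit means, averaged over pairs.
    """
    from .rnn_core import simulate

    rate_metrics, phase_metrics = [], []
    for ta, tb in trial_pairs:
        vals = {}
        for tag, tr in (("a", ta), ("b", tb)):
            x, _ = simulate(rnn, tr, h=h)
            w = tr.mask
            theta = tr.theta[w]
            if theta.size < 2:
                raise ValueError("empty steady-state window")
            cycles = (np.unwrap(theta)[-1] - np.unwrap(theta)[0]) / (2 * np.pi)
            if cycles < min_cycles:
                raise ValueError("steady-state window shorter than required cycles")
            rates = np.tanh(x[w])  # (Tw, N)
            vals[tag] = {
                "mean": rates.mean(axis=0),
                "z": (rates * np.exp(-1j * theta)[:, None]).mean(axis=0),
                "amp": np.abs(rates).max(axis=0),
            }
        norm = np.maximum(np.maximum(vals["a"]["amp"], vals["b"]["amp"]), 1e-9)
        rate_metrics.append(np.mean(np.abs(vals["a"]["mean"] - vals["b"]["mean"]) / norm))
        dphi = np.angle(vals["a"]["z"] * np.conj(vals["b"]["z"]))
        phase_metrics.append(np.mean(np.abs(dphi)))
    return float(np.mean(rate_metrics)), float(np.mean(phase_metrics))


def pca_basis_fullrank(
    rnn: LowRankRNN, trajectories: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """PCA basis of the recurrent drive of a (full-rank) network.

    Stacks states from the given trajectories (each (T, N)), computes the
    first two left singular vectors of J tanh(X), orthogonalizes I_osc
    against them, and reports the r^2 of reconstructing X in the 3-D basis.
    """
    X = np.concatenate(trajectories, axis=0).T  # (N, sum T)
    D = rnn.J_matrix() @ np.tanh(X)
    if np.linalg.matrix_rank(D, tol=1e-8) < 2:
        warnings.warn("recurrent drive matrix is rank deficient")
    U, _, _ = np.linalg.svd(D, full_matrices=False)
    u1, u2 = U[:, 0], U[:, 1]
    Ip = rnn.I_osc - u1 * (u1 @ rnn.I_osc) - u2 * (u2 @ rnn.I_osc)
    Ip = Ip / np.linalg.norm(Ip)
    Q = np.stack([u1, u2, Ip], axis=1)
    Xhat = Q @ (Q.T @ X)
    r2 = 1.0 - np.sum((X - Xhat) ** 2) / np.sum(X**2)
    return u1, u2, Ip, float(r2)
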