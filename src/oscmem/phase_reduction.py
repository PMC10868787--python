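"""Two-oscillator reduction: coupling-function extraction and phase model.

On the converged orbit the internal state is approximated by a constant
radius r in the kappa plane, leaving a phase phi = atan2(kappa2, kappa1).
The pair (theta, phi) then evolves as

    dtheta/dt = omega,   dphi/dt = omega + g(phi, theta)

with g extracted directly from the kappa field: dphi/dt is the tangential
component of dkappa/dt on the radius-r circle, divided by r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .dynamics_analysis import FieldBase, find_fixed_points

__all__ = [
    "CouplingGrid",
    "extract_coupling",
    "simulate_phase_model",
    "census_attractors",
    "compare_phase_to_full",
    "coupling_under_stimulus",
]


@dataclass
class CouplingGrid:
    """g(theta, phi) sampled on a uniform periodic grid (rad/ms)."""

    theta_grid: np.ndarray  # (n_theta,) in [0, 2pi)
    phi_grid: np.ndarray  # (n_phi,)
    g_values: np.ndarray  # (n_theta, n_phi)
    omega: float  # rad/ms
    r: float
    stimulus_state: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("radius must be positive")
        if self.g_values.shape != (self.theta_grid.size, self.phi_grid.size):
            raise ValueError("g_values shape mismatch")

    def __call__(self, theta, phi):
        """Periodic bilinear interpolation of g."""
        nt, np_ = self.theta_grid.size, self.phi_grid.size
        dt = 2 * np.pi / nt
        dp = 2 * np.pi / np_
        th = np.mod(np.asarray(theta, float), 2 * np.pi) / dt
        ph = np.mod(np.asarray(phi, float), 2 * np.pi) / dp
        i0 = np.floor(th).astype(int) % nt
        j0 = np.floor(ph).astype(int) % np_
        i1 = (i0 + 1) % nt
        j1 = (j0 + 1) % np_
        ft = th - np.floor(th)
        fp = ph - np.floor(ph)
        G = self.g_values
        return (
            G[i0, j0] * (1 - ft) * (1 - fp)
            + G[i1, j0] * ft * (1 - fp)
            + G[i0, j1] * (1 - ft) * fp
            + G[i1, j1] * ft * fp
        )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("coupling")
            g.create_dataset("theta_grid", data=self.theta_grid)
            g.create_dataset("phi_grid", data=self.phi_grid)
            g.create_dataset("g_values", data=self.g_values)
            g.attrs["omega"] = self.omega
            g.attrs["r"] = self.r

    @classmethod
    def load_hdf5(cls, path) -> "CouplingGrid":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["coupling"]
            return cls(
                g["theta_grid"][()],
                g["phi_grid"][()],
                g["g_values"][()],
                float(g.attrs["omega"]),
                float(g.attrs["r"]),
            )


def mean_cycle_radius(field: FieldBase, fixed_points=None) -> float:
    """Mean orbit radius over the stable limit cycles of the field."""
    if fixed_points is None:
        fixed_points = find_fixed_points(field)
    stable = [fp for fp in fixed_points if fp.stable]
    if not stable:
        raise ValueError("no stable cycles found; cannot define a radius")
    radii = []
    for fp in stable:
        _, traj = field.orbit(fp.kappa_star, n_periods=fp.period_n)
        radii.append(np.hypot(traj[:, 0], traj[:, 1]).mean())
    return float(np.mean(radii))


def extract_coupling(
    field: FieldBase,
    r: float | None = None,
    n_theta: int = 64,
    n_phi: int = 64,
) -> CouplingGrid:
    """Extract g(theta, phi) from a kappa field at constant radius r.

    r defaults to the mean orbit radius over the field's stable cycles.  On
    each grid point, dphi/dt is the tangential component of the kappa flow on
    the radius-r circle and g = dphi/dt - omega.
    """
    if r is None:
        r = mean_cycle_radius(field)
    if r <= 0:
        raise ValueError("radius must be positive")
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    phis = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    kappas = np.stack([r * np.cos(phis), r * np.sin(phis)], axis=1)
    G = np.empty((n_theta, n_phi))
    for i, th in enumerate(thetas):
        dk = field.rhs_batch(kappas, th)
        dphi = (kappas[:, 0] * dk[:, 1] - kappas[:, 1] * dk[:, 0]) / r**2
        G[i] = dphi - field.omega
    stim = {}
    tonic = getattr(field, "tonic", None)
    if tonic is not None:
        stim["tonic"] = np.asarray(tonic).tolist()
    return CouplingGrid(thetas, phis, G, field.omega, r, stimulus_state=stim)


def simulate_phase_model(
    coupling: CouplingGrid,
    theta0: float = 0.0,
    phi0: float = 0.0,
    duration_ms: float | None = None,
    n_cycles: int | None = None,
    h: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate theta' = omega, phi' = omega + g(phi, theta) with RK4.

    Returns (t, theta, phi) with theta exactly linear and phi unwrapped.
    """
    w = coupling.omega
    if duration_ms is None:
        duration_ms = (n_cycles or 20) * 2 * np.pi / w
    n = int(round(duration_ms / h))
    t = np.arange(n + 1) * h
    theta = theta0 + w * t
    phi0 = np.asarray(phi0, float)
    single = phi0.ndim == 0
    p = np.atleast_1d(phi0).astype(float).copy()
    phi = np.empty((n + 1,) + p.shape)
    phi[0] = p
    for k in range(n):
        th = theta[k]
        a = w + coupling(th, p)
        b = w + coupling(th + 0.5 * w * h, p + 0.5 * h * a)
        c = w + coupling(th + 0.5 * w * h, p + 0.5 * h * b)
        d = w + coupling(th + w * h, p + h * c)
        p = p + h * (a + 2 * b + 2 * c + d) / 6.0
        phi[k + 1] = p
    if single:
        return t, theta, phi[:, 0]
    return t, theta, phi


def _circ_dist(a, b):
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))


def census_attractors(
    coupling: CouplingGrid,
    n_init: int = 16,
    n_cycles: int = 80,
    lock_tol: float = 1e-3,
    cluster_tol: float = 0.15,
) -> list[float]:
    """Distinct locked phase differences of the phase model.

    Simulates from a ring of initial phi; a trajectory is "locked" when the
    per-cycle change of phi - theta stays below ``lock_tol`` rad for 5
    consecutive reference cycles.  Locked end states are clustered by
    circular distance.  Returns the sorted locked values of (phi - theta)
    mod 2 pi.
    """
    T = 2 * np.pi / coupling.omega
    phi0s = np.linspace(0, 2 * np.pi, n_init, endpoint=False)
    t, theta, phi = simulate_phase_model(coupling, 0.0, phi0s, duration_ms=n_cycles * T)
    idx = np.clip(np.searchsorted(t, np.arange(1, n_cycles + 1) * T), 0, len(t) - 1)
    psi_all = phi[idx] - theta[idx][:, None]  # (n_cycles, n_init)
    locked = []
    for j in range(n_init):
        dpsi = np.abs(np.diff(psi_all[:, j]))
        if dpsi.size >= 5 and np.all(dpsi[-5:] < lock_tol):
            locked.append(np.mod(psi_all[-1, j], 2 * np.pi))
    clusters: list[list[float]] = []
    for v in locked:
        for cl in clusters:
            cmean = np.angle(np.mean(np.exp(1j * np.array(cl))))
            if _circ_dist(v, cmean) < cluster_tol:
                cl.append(v)
                break
        else:
            clusters.append([v])
    return sorted(float(np.mod(np.angle(np.mean(np.exp(1j * np.array(cl)))), 2 * np.pi)) for cl in clusters)


def compare_phase_to_full(
    field: FieldBase,
    coupling: CouplingGrid,
    inits: np.ndarray | None = None,
    n_cycles: int = 60,
    lock_tol: float = 1e-3,
) -> dict:
    """Locked-phase agreement between the phase model and the full kappa flow.

    Both systems start from a ring of initial phases (the field on the
    radius-r circle) and run for ``n_cycles`` reference periods.  Converged
    end states are clustered into attractors for each system; the headline
    numbers are the attractor counts and the maximal circular distance
    between matched locked phases.  Per-init discrepancies are also reported
    for initial conditions whose two trajectories landed in the same
    attractor (inits near basin boundaries legitimately diverge).
    """
    if inits is None:
        inits = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    inits = np.atleast_1d(inits)
    T = 2 * np.pi / field.omega
    k = np.stack([coupling.r * np.cos(inits), coupling.r * np.sin(inits)], axis=1)
    sections = [k]
    for _ in range(n_cycles):
        k = field.map_batch(k, n_periods=1)
        sections.append(k.copy())
    sec = np.array(sections)  # (n_cycles + 1, K, 2)
    phi_full = np.arctan2(sec[:, :, 1], sec[:, :, 0])  # (n_cycles + 1, K)
    t, theta, phi = simulate_phase_model(coupling, 0.0, inits, duration_ms=n_cycles * T)
    idx = np.clip(np.searchsorted(t, np.arange(n_cycles + 1) * T), 0, len(t) - 1)
    psi_model = phi[idx] - theta[idx][:, None]

    def _cluster(vals):
        clusters: list[list[float]] = []
        for v in vals:
            for cl in clusters:
                if _circ_dist(v, np.angle(np.mean(np.exp(1j * np.array(cl))))) < 0.3:
                    cl.append(v)
                    break
            else:
                clusters.append([v])
        return [float(np.angle(np.mean(np.exp(1j * np.array(cl))))) for cl in clusters]

    full_end, model_end, per_init, skipped = [], [], [], 0
    for j in range(inits.size):
        dfull = _circ_dist(phi_full[-5:, j], phi_full[-6:-1, j])
        dmodel = np.abs(np.diff(psi_model[:, j]))[-5:]
        if np.any(dfull > lock_tol) or np.any(dmodel > lock_tol):
            skipped += 1
            continue
        full_end.append(float(phi_full[-1, j]))
        model_end.append(float(psi_model[-1, j]))
        d = float(_circ_dist(phi_full[-1, j], psi_model[-1, j]))
        if d < 0.5 * np.pi:  # same basin
            per_init.append(d)
    if skipped:
        warnings.warn(f"{skipped} non-convergent initial conditions excluded")
    if not full_end:
        raise ValueError("no convergent trajectories to compare")
    full_att = _cluster(full_end)
    model_att = _cluster(model_end)
    att_dist = max(
        min(_circ_dist(a, b) for b in model_att) for a in full_att
    ) if model_att else np.inf
    return {
        "full_attractors": sorted(np.mod(full_att, 2 * np.pi)),
        "model_attractors": sorted(np.mod(model_att, 2 * np.pi)),
        "n_full": len(full_att),
        "n_model": len(model_att),
        "max": float(att_dist),
        "per_init": per_init,
        "basin_agreement": len(per_init) / max(len(full_end), 1),
        "n_excluded": skipped,
    }


def coupling_under_stimulus(
    field,
    stim_id: int,
    s: float,
    r: float | None = None,
    n_theta: int = 64,
    n_phi: int = 64,
    **census_kw,
) -> tuple[CouplingGrid, list[float]]:
    """Coupling function with a tonic stimulus folded in + attractor census."""
    if r is None:
        r = mean_cycle_radius(field)
    f_s = field.with_stimulus(stim_id, s)
    coupling = extract_coupling(f_s, r=r, n_theta=n_theta, n_phi=n_phi)
    coupling.stimulus_state = {"stim_id": stim_id, "s": s}
    return coupling, census_attractors(coupling, **census_kw)
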