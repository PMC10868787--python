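"""Gaussian-mixture connectivity: mean-field dynamics, designed reduced
models, finite-size sampling and mixture fitting.

Per-unit weight vectors (inputs, n's, m's, readout) are treated as draws
from a mixture of L zero-mean Gaussians.  In the large-N limit the kappa
dynamics close on themselves: each component contributes a linear drive
through its covariances, multiplied by a scalar gain E[tanh'(Delta z)] that
collapses to 1/sqrt(1 + (pi/2) Delta^2) under the erf approximation of tanh.
The per-component Delta^2 is the variance of the unit input, i.e. the full
quadratic form of the loading vector in the component covariance (this
reduces to the diagonal sum when cross-covariances vanish).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .dynamics_analysis import FieldBase
from .rnn_core import LowRankRNN

__all__ = [
    "gain",
    "gain_exact",
    "MixtureConnectivity",
    "MeanFieldState",
    "meanfield_rhs",
    "meanfield_readout",
    "MeanFieldKappaField",
    "flow_1d",
    "sample_network",
    "design_two_stim",
    "design_four_stim",
    "design_rate_coding_rank1",
    "design_phase_precession",
    "fit_mixture",
]


def gain(delta_sq):
    """Population gain 1/sqrt(1 + (pi/2) Delta^2) = E[tanh'(Delta z)] (erf approx)."""
    delta_sq = np.asarray(delta_sq, float)
    if np.any(delta_sq < 0):
        raise ValueError("delta_sq must be non-negative")
    out = 1.0 / np.sqrt(1.0 + (np.pi / 2.0) * delta_sq)
    return float(out) if out.ndim == 0 else out


_QZ = np.linspace(-8.0, 8.0, 481)
_QW = np.exp(-_QZ**2 / 2.0) / np.sqrt(2.0 * np.pi)
_QW = _QW * (_QZ[1] - _QZ[0])


def gain_exact(delta_sq):
    """E[tanh'(Delta z)], z ~ N(0,1), by dense Gaussian quadrature.

    The closed form :func:`gain` carries the erf substitution's ~2% bias at
    moderate Delta; finite-size comparisons can use this exact version.
    """
    delta_sq = np.asarray(delta_sq, float)
    if np.any(delta_sq < 0):
        raise ValueError("delta_sq must be non-negative")
    d = np.sqrt(delta_sq)[..., None]
    vals = (1.0 - np.tanh(d * _QZ) ** 2) @ _QW
    return float(vals) if vals.ndim == 0 else vals


@dataclass
class MixtureConnectivity:
    """Mixture of L zero-mean Gaussians over the joint per-unit weight vector.

    ``names`` orders the joint vector, e.g. (I_osc, I_s1, I_s2, n1, n2, m1,
    m2, w); ``covs`` is (L, d, d); ``weights`` are component proportions.
    """

    names: list
    weights: np.ndarray
    covs: np.ndarray
    labels: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.covs = np.asarray(self.covs, float)
        if not np.all(self.weights > 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be positive and sum to 1")
        d = len(self.names)
        if self.covs.shape != (self.L, d, d):
            raise ValueError("covs must have shape (L, d, d)")
        for l in range(self.L):
            if np.linalg.eigvalsh(self.covs[l]).min() < -1e-8:
                raise ValueError(f"component {l} covariance is not PSD")
        if not self.labels:
            self.labels = [f"pop{l + 1}" for l in range(self.L)]

    @property
    def L(self) -> int:
        return self.weights.size

    @property
    def rank(self) -> int:
        return sum(1 for nm in self.names if nm.startswith("m"))

    @property
    def input_names(self) -> list:
        return [nm for nm in self.names if nm.startswith("I_")]

    def idx(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def empty(cls, L: int, rank: int, input_names: list, labels=None) -> "MixtureConnectivity":
        names = list(input_names) + [f"n{i+1}" for i in range(rank)] + [f"m{i+1}" for i in range(rank)] + ["w"]
        covs = np.array([np.eye(len(names)) * 1e-12 for _ in range(L)])
        return cls(names, np.full(L, 1.0 / L), covs, labels=list(labels) if labels else [])

    def set(self, l: int, a: str, b: str, value: float) -> None:
        i, j = self.idx(a), self.idx(b)
        self.covs[l, i, j] = value
        self.covs[l, j, i] = value

    def get(self, l: int, a: str, b: str) -> float:
        return float(self.covs[l, self.idx(a), self.idx(b)])

    def validate(self) -> None:
        for l in range(self.L):
            ev = np.linalg.eigvalsh(self.covs[l])
            if ev.min() < -1e-8:
                raise ValueError(f"component {l} covariance not PSD (min eig {ev.min():.3g})")

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "weights": self.weights.tolist(),
            "covs": self.covs.tolist(),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureConnectivity":
        return cls(d["names"], np.array(d["weights"]), np.array(d["covs"]), list(d.get("labels", [])))

    def save_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f)

    @classmethod
    def load_yaml(cls, path) -> "MixtureConnectivity":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class MeanFieldState:
    """Instantaneous mean-field coordinates: kappa, filtered inputs, stimuli."""

    kappa: np.ndarray
    inputs: dict


def _load_indices(mix: MixtureConnectivity):
    """Indices of x-loading variables (m's then inputs) and of the n targets."""
    R = mix.rank
    load = [mix.idx(f"m{i+1}") for i in range(R)] + [mix.idx(nm) for nm in mix.input_names]
    targets = [mix.idx(f"n{i+1}") for i in range(R)]
    return np.array(load), np.array(targets)


def meanfield_rhs(mix: MixtureConnectivity, kappa, inputs: dict, tau: float = 20.0) -> np.ndarray:
    """tau-scaled mean-field drift d(kappa)/dt for arbitrary rank.

    ``inputs`` maps every input variable name to its current (filtered)
    value.  Per component l the drive on kappa_i is
    (sum_b c_b sigma_{b, n_i}^(l)) * gain(Delta_l^2) with c the loading
    vector (kappa for m's, input values for inputs) and
    Delta_l^2 = c^T Sigma_l c.
    """
    kappa = np.atleast_1d(np.asarray(kappa, float))
    R = mix.rank
    if kappa.size != R:
        raise ValueError(f"kappa must have {R} entries")
    load, targets = _load_indices(mix)
    c = np.concatenate([kappa, [float(inputs[nm]) for nm in mix.input_names]])
    drive = np.zeros(R)
    for l in range(mix.L):
        Sig = mix.covs[l][np.ix_(load, load)]
        delta2 = float(c @ Sig @ c)
        cross = mix.covs[l][np.ix_(load, targets)]
        drive += mix.weights[l] * (c @ cross) * gain(delta2)
    return (-kappa + drive) / tau


def meanfield_readout(
    mix: MixtureConnectivity, kappa, inputs: dict, mode: str = "linear_out"
) -> float:
    """Mean-field readout (1/N) w.x or (1/N) w.tanh(x)."""
    kappa = np.atleast_1d(np.asarray(kappa, float))
    load, _ = _load_indices(mix)
    iw = mix.idx("w")
    c = np.concatenate([kappa, [float(inputs[nm]) for nm in mix.input_names]])
    out = 0.0
    for l in range(mix.L):
        cov_w = mix.covs[l][load, iw]
        term = float(c @ cov_w)
        if mode == "tanh_out":
            Sig = mix.covs[l][np.ix_(load, load)]
            term *= gain(float(c @ Sig @ c))
        out += mix.weights[l] * term
    return out


def input_values(mix: MixtureConnectivity, A: float, omega: float, tau: float, theta, stim_values: dict) -> dict:
    """Filtered input values at phase theta.

    Oscillatory channels carry the tau-filtered reference (gain
    1/sqrt((w tau)^2+1), lag arctan(w tau)); 'I_osca'/'I_oscb' are the
    sin/cos channels of a two-channel reference.  Tonic stimuli are passed
    through at their steady-state values.
    """
    wt = omega * tau
    vg = A / np.sqrt(wt**2 + 1.0)
    lag = np.arctan(wt)
    vals = {}
    for nm in mix.input_names:
        if nm in ("I_osc", "I_osca"):
            vals[nm] = vg * np.sin(theta - lag)
        elif nm == "I_oscb":
            vals[nm] = vg * np.cos(theta - lag)
        else:
            vals[nm] = stim_values.get(nm, 0.0)
    return vals


@dataclass
class MeanFieldKappaField(FieldBase):
    """Rank-2 mean-field kappa dynamics as a Poincare-analysable field."""

    mix: MixtureConnectivity
    A: float = 1.0
    omega: float = 2 * np.pi * 8.0 / 1000.0
    tau: float = 20.0
    h: float = 0.5
    use_rk4: bool = True
    stim_values: dict = dc_field(default_factory=dict)
    gain_mode: str = "erf"  # "erf" (closed form) or "exact" (quadrature)

    def __post_init__(self) -> None:
        if self.mix.rank != 2:
            raise ValueError("MeanFieldKappaField requires a rank-2 mixture")
        if self.gain_mode not in ("erf", "exact"):
            raise ValueError("gain_mode must be 'erf' or 'exact'")
        self._load, self._targets = _load_indices(self.mix)

    def _gain(self, delta_sq):
        return gain(delta_sq) if self.gain_mode == "erf" else gain_exact(delta_sq)

    def _gain_prime(self, delta_sq):
        """d gain / d delta_sq."""
        if self.gain_mode == "erf":
            g = gain(delta_sq)
            return -(np.pi / 4.0) * g**3
        eps = 1e-6 + 1e-3 * delta_sq
        return (gain_exact(delta_sq + eps) - gain_exact(np.maximum(delta_sq - eps, 0.0))) / (
            eps + np.minimum(delta_sq, eps)
        )

    def with_stimulus(self, stim_name, s: float) -> "MeanFieldKappaField":
        if isinstance(stim_name, int):
            stim_name = f"I_s{stim_name + 1}"
        vals = dict(self.stim_values)
        vals[stim_name] = float(s)
        return replace(self, stim_values=vals)

    def rhs_batch(self, kappas: np.ndarray, theta: float) -> np.ndarray:
        k = np.atleast_2d(np.asarray(kappas, float))
        vals = input_values(self.mix, self.A, self.omega, self.tau, theta, self.stim_values)
        inp = np.array([vals[nm] for nm in self.mix.input_names])
        c = np.concatenate([k, np.broadcast_to(inp, (k.shape[0], inp.size))], axis=1)
        drive = np.zeros((k.shape[0], 2))
        mix = self.mix
        for l in range(mix.L):
            Sig = mix.covs[l][np.ix_(self._load, self._load)]
            delta2 = np.einsum("ka,ab,kb->k", c, Sig, c)
            cross = mix.covs[l][np.ix_(self._load, self._targets)]
            drive += mix.weights[l] * (c @ cross) * self._gain(np.maximum(delta2, 0.0))[:, None]
        return (-k + drive) / self.tau

    def jac(self, kappa, theta: float, eps: float = 0.0) -> np.ndarray:
        """Analytic field Jacobian d(dkappa/dt)/dkappa."""
        kappa = np.asarray(kappa, float)
        vals = input_values(self.mix, self.A, self.omega, self.tau, theta, self.stim_values)
        inp = np.array([vals[nm] for nm in self.mix.input_names])
        c = np.concatenate([kappa, inp])
        J = -np.eye(2)
        mix = self.mix
        for l in range(mix.L):
            Sig = mix.covs[l][np.ix_(self._load, self._load)]
            cross = mix.covs[l][np.ix_(self._load, self._targets)]
            delta2 = max(float(c @ Sig @ c), 0.0)
            g = self._gain(delta2)
            gprime = self._gain_prime(delta2)
            drive = c @ cross  # (2,)
            dd2 = 2.0 * (Sig @ c)[:2]  # d delta2 / d kappa
            J += mix.weights[l] * (cross[:2, :].T * g + np.outer(drive, dd2) * gprime)
        return J / self.tau

    def phi_contributions(self, kappa, theta: float) -> np.ndarray:
        """Per-population tau*dphi/dt terms (their sum is the total)."""
        kappa = np.asarray(kappa, float)
        r2 = kappa @ kappa
        vals = input_values(self.mix, self.A, self.omega, self.tau, theta, self.stim_values)
        inp = np.array([vals[nm] for nm in self.mix.input_names])
        c = np.concatenate([kappa, inp])
        out = np.empty(self.mix.L)
        for l in range(self.mix.L):
            Sig = self.mix.covs[l][np.ix_(self._load, self._load)]
            cross = self.mix.covs[l][np.ix_(self._load, self._targets)]
            d = self.mix.weights[l] * (c @ cross) * self._gain(max(float(c @ Sig @ c), 0.0))
            out[l] = (kappa[0] * d[1] - kappa[1] * d[0]) / r2
        return out

    def population_gains(self, kappa, theta: float) -> np.ndarray:
        kappa = np.asarray(kappa, float)
        vals = input_values(self.mix, self.A, self.omega, self.tau, theta, self.stim_values)
        inp = np.array([vals[nm] for nm in self.mix.input_names])
        c = np.concatenate([kappa, inp])
        out = np.empty(self.mix.L)
        for l in range(self.mix.L):
            Sig = self.mix.covs[l][np.ix_(self._load, self._load)]
            out[l] = self._gain(max(float(c @ Sig @ c), 0.0))
        return out

    def readout(self, kappa, theta: float, mode: str = "linear_out") -> float:
        vals = input_values(self.mix, self.A, self.omega, self.tau, theta, self.stim_values)
        return meanfield_readout(self.mix, kappa, vals, mode=mode)


def flow_1d(
    mix: MixtureConnectivity,
    kappa_grid: np.ndarray,
    stim_values: dict | None = None,
    A: float = 1.0,
    omega: float = 2 * np.pi * 8.0 / 1000.0,
    tau: float = 20.0,
    n_theta: int = 32,
) -> np.ndarray:
    """Theta-averaged 1-D mean-field flow d(kappa)/dt for rank-1 mixtures."""
    if mix.rank != 1:
        raise ValueError("flow_1d requires a rank-1 mixture")
    kappa_grid = np.asarray(kappa_grid, float)
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    out = np.zeros_like(kappa_grid)
    for th in thetas:
        vals = input_values(mix, A, omega, tau, th, stim_values or {})
        for i, kap in enumerate(kappa_grid):
            out[i] += meanfield_rhs(mix, [kap], vals, tau=tau)[0]
    return out / n_theta


def stable_zeros_1d(kappa_grid: np.ndarray, flow: np.ndarray) -> list[float]:
    """Stable zero crossings (flow goes + -> -) located by linear interpolation."""
    zeros = []
    for i in range(len(flow) - 1):
        if flow[i] > 0 >= flow[i + 1]:
            t = flow[i] / (flow[i] - flow[i + 1])
            zeros.append(float(kappa_grid[i] + t * (kappa_grid[i + 1] - kappa_grid[i])))
    return zeros


# ---------------------------------------------------------------------------
# Finite-size sampling
# ---------------------------------------------------------------------------


def sample_network(mix: MixtureConnectivity, N: int, seed: int = 0, tau: float = 20.0) -> LowRankRNN:
    """Draw an N-unit network from the mixture (deterministic block allocation).

    Component sizes are the rounded cumulative shares of N; units within a
    block are i.i.d. from that component's Gaussian.
    """
    if N * mix.weights.min() < 10:
        raise ValueError("smallest component would have fewer than 10 units")
    rng = np.random.default_rng(seed)
    bounds = np.round(np.cumsum(mix.weights) * N).astype(int)
    bounds = np.concatenate([[0], bounds])
    bounds[-1] = N
    d = len(mix.names)
    Y = np.empty((N, d))
    for l in range(mix.L):
        lo, hi = bounds[l], bounds[l + 1]
        vals, vecs = np.linalg.eigh(mix.covs[l])
        Lc = vecs * np.sqrt(np.clip(vals, 0.0, None))
        Y[lo:hi] = rng.standard_normal((hi - lo, d)) @ Lc.T
    col = {nm: Y[:, i] for i, nm in enumerate(mix.names)}
    R = mix.rank
    m = np.stack([col[f"m{i+1}"] for i in range(R)], axis=1)
    n = np.stack([col[f"n{i+1}"] for i in range(R)], axis=1)
    osc_names = [nm for nm in mix.input_names if nm.startswith("I_osc")]
    stim_names = [nm for nm in mix.input_names if not nm.startswith("I_osc")]
    I_osc = col[osc_names[0]]
    I_osc2 = col[osc_names[1]] if len(osc_names) > 1 else None
    if stim_names:
        I_stim = np.stack([col[nm] for nm in stim_names], axis=1)
    else:
        I_stim = np.zeros((N, 1))
    return LowRankRNN(
        m=m, n=n, I_osc=I_osc, I_stim=I_stim, w=col["w"], tau=tau, I_osc2=I_osc2
    )


# ---------------------------------------------------------------------------
# Designed reduced models
# ---------------------------------------------------------------------------


def _oscillator_covariances(
    mix: MixtureConnectivity,
    l: int,
    weight: float,
    freq_hz: float,
    tau: float,
    radius: float,
    sigma_m: float,
    n_var_margin: float = 1.6,
) -> None:
    """Fill component l with a self-oscillating skew-symmetric structure.

    The pair structure sigma_{m1n1} = sigma_{m2n2} = rho,
    sigma_{m1n2} = -sigma_{m2n1} = eta produces a rotation of the kappa plane;
    rho is chosen so the radial fixed point sits at ``radius`` and eta so the
    angular velocity there equals 2 pi freq_hz.
    """
    omega = 2 * np.pi * freq_hz / 1000.0
    g1 = gain(sigma_m**2 * radius**2)
    rho = 1.0 / (weight * g1)
    eta = omega * tau / (weight * g1)
    for v in ("m1", "m2"):
        mix.set(l, v, v, sigma_m**2)
    n_var = n_var_margin * (rho**2 + eta**2) / sigma_m**2
    for v in ("n1", "n2"):
        mix.set(l, v, v, n_var)
    mix.set(l, "m1", "n1", rho)
    mix.set(l, "m2", "n2", rho)
    mix.set(l, "m1", "n2", eta)
    mix.set(l, "m2", "n1", -eta)


def _inflate_n_variance(mix: MixtureConnectivity, l: int, margin: float = 1.3) -> None:
    """Raise the n-variances of component l until its covariance is PSD.

    The n entries never load the unit input x, so inflating them changes
    nothing in the mean-field drive; it only licenses the requested
    cross-covariances.
    """
    names = [f"n{i+1}" for i in range(mix.rank)]
    for _ in range(60):
        if np.linalg.eigvalsh(mix.covs[l]).min() > 1e-9:
            break
        for nm in names:
            cur = max(mix.get(l, nm, nm), 1.0)
            mix.set(l, nm, nm, cur * margin)


def _calibrate_oscillator(
    mix: MixtureConnectivity,
    omega: float,
    tau: float = 20.0,
    h: float = 1.0,
    max_iter: int = 5,
    lock_tol: float = 0.01,
    stim_values: dict | None = None,
) -> None:
    """Nudge the oscillator's rotation entries until the full model 1:1 locks.

    The coupling populations shift the radial balance, which detunes the
    oscillator's self-consistent angular velocity; this loop measures the
    residual per-cycle phase drift of the full mean-field model and rescales
    the skew entries (m1-n2 / m2-n1 of component 0) to cancel it.
    Deterministic: fixed probe initial conditions, no randomness.
    """
    T = 2 * np.pi / omega
    probes = np.array(
        [[1.2, 0], [0, 1.2], [-1.2, 0], [0, -1.2], [0.85, 0.85], [-0.85, 0.85]]
    )
    for _ in range(max_iter):
        fld = MeanFieldKappaField(mix, omega=omega, tau=tau, h=h, stim_values=stim_values or {})
        k = probes.copy()
        for _ in range(40):
            k = fld.map_batch(k, n_periods=1)
        psi = np.arctan2(k[:, 1], k[:, 0])
        k2 = fld.map_batch(k, n_periods=1)
        drift = np.angle(np.exp(1j * (np.arctan2(k2[:, 1], k2[:, 0]) - psi)))
        if np.max(np.abs(drift)) < lock_tol:
            return
        scale = 1.0 - np.mean(drift) / (T * omega)
        mix.set(0, "m1", "n2", mix.get(0, "m1", "n2") * scale)
        mix.set(0, "m2", "n1", mix.get(0, "m2", "n1") * scale)


def design_two_stim(
    freq_hz: float = 8.0,
    tau: float = 20.0,
    radius: float = 1.0,
    osc_weight: float = 0.5,
    osc_sigma_m: float = 2.0,
    beta: float = 3.0,
    gamma: float = 10.0,
    sigma_I: float = 4.0,
    sigma_stim: float = 8.0,
    coupling_sigma_m: float = 0.9,
    lock_rotation: float = 0.6,
    readout_rotation: float = 2.664826,
    readout_amp: float = 0.782243,
    w_var: float = 16.0,
    calibrate: bool = True,
) -> MixtureConnectivity:
    """Three-population model: one oscillator + two coupling populations.

    Population 1 autonomously oscillates near the reference frequency and is
    unconnected to any input.  Populations 2 and 3 couple the internal phase
    to the reference through sigma_{I_osc n} patterns of opposite sign (their
    sin(phi) terms cancel without stimulus, leaving cos(2 phi) terms that
    lock two states ~pi apart) and are saturated by stimulus a and b
    respectively.  The readout covariances rotate the locked internal phase
    to the task's target offsets.
    """
    mix = MixtureConnectivity.empty(
        3, 2, ["I_osc", "I_s1", "I_s2"], labels=["oscillator", "coupling_a", "coupling_b"]
    )
    w_rest = (1.0 - osc_weight) / 2.0
    mix.weights = np.array([osc_weight, w_rest, w_rest])
    _oscillator_covariances(mix, 0, osc_weight, freq_hz, tau, radius, osc_sigma_m)
    mix.set(0, "w", "w", w_var)
    for l, (stim, sgn) in enumerate([("I_s1", +1.0), ("I_s2", -1.0)], start=1):
        for v in ("m1", "m2"):
            mix.set(l, v, v, coupling_sigma_m**2)
        mix.set(l, "I_osc", "I_osc", sigma_I**2)
        mix.set(l, stim, stim, sigma_stim**2)
        # cos(2 phi - 2 lock_rotation) generator: rotating the locked pair so
        # the no-stimulus attractors coincide with the tonic-stimulus ones
        mix.set(l, "m1", "n2", beta * np.cos(2 * lock_rotation))
        mix.set(l, "m2", "n1", beta * np.cos(2 * lock_rotation))
        mix.set(l, "m1", "n1", -beta * np.sin(2 * lock_rotation))
        mix.set(l, "m2", "n2", beta * np.sin(2 * lock_rotation))
        # sin(phi + pi/4) * v(theta) terms, opposite signs across populations
        mix.set(l, "I_osc", "n1", sgn * gamma)
        mix.set(l, "I_osc", "n2", -sgn * gamma)
        n_var = 1.6 * (beta**2 / coupling_sigma_m**2 + gamma**2 / sigma_I**2)
        mix.set(l, "n1", "n1", n_var)
        mix.set(l, "n2", "n2", n_var)
        mix.set(l, "w", "w", w_var)
    # readout: r = kappa . (c1, c2); rotation aligns the a-attractor with the
    # task target sin(theta - 0.2 pi)
    c1 = readout_amp / radius * np.cos(readout_rotation)
    c2 = readout_amp / radius * np.sin(readout_rotation)
    # place the readout covariance on the oscillator population (scaled by
    # its weight so the total matches)
    mix.set(0, "m1", "w", c1 / osc_weight)
    mix.set(0, "m2", "w", c2 / osc_weight)
    mix.validate()
    if calibrate:
        _calibrate_oscillator(mix, 2 * np.pi * freq_hz / 1000.0, tau)
        mix.validate()
    return mix


def design_four_stim(
    freq_hz: float = 8.0,
    tau: float = 20.0,
    radius: float = 1.0,
    osc_weight: float = 0.4,
    osc_sigma_m: float = 1.4,
    beta: float = 3.0,
    gamma: float = 2.0,
    sigma_I: float = 2.0,
    sigma_stim: float = 6.0,
    coupling_sigma_m: float = 1.1,
    aniso: float = 0.75,
    w_var: float = 16.0,
    calibrate: bool = True,
) -> MixtureConnectivity:
    """Five-population model storing four stimuli in four locked phases.

    Four coupling populations are quarter-turn rotated copies of each other
    (sin(phi + c_k) input patterns with c_k spaced pi/2 apart and m-covariance
    anisotropy axes rotated along with them).  Their first-harmonic terms
    cancel without stimulus; the rotation-equivariant residue carries
    cos(4 phi)-type terms that lock four states.  Each stimulus saturates all
    coupling populations except one, whose surviving sin term selects the
    corresponding phase.
    """
    mix = MixtureConnectivity.empty(
        5,
        2,
        ["I_osc", "I_s1", "I_s2", "I_s3", "I_s4"],
        labels=["oscillator"] + [f"coupling_{k}" for k in range(1, 5)],
    )
    wc = (1.0 - osc_weight) / 4.0
    mix.weights = np.array([osc_weight] + [wc] * 4)
    _oscillator_covariances(mix, 0, osc_weight, freq_hz, tau, radius, osc_sigma_m)
    mix.set(0, "w", "w", w_var)
    for k in range(4):
        l = k + 1
        ck = k * np.pi / 2.0
        # sin(phi + c_k) v(theta): sigma_{I n1} = -S cos c_k, sigma_{I n2} = S sin c_k
        mix.set(l, "I_osc", "n1", -gamma * np.cos(ck))
        mix.set(l, "I_osc", "n2", gamma * np.sin(ck))
        mix.set(l, "I_osc", "I_osc", sigma_I**2)
        # anisotropic m covariance rotated with the population
        s2 = coupling_sigma_m**2
        b = aniso * s2
        # quadratic form s2 + b cos(2 phi - 2 gamma_k), gamma_k = c_k / 1 (mod pi)
        g2 = ck  # axis angle
        mix.set(l, "m1", "m1", s2 + b * np.cos(2 * g2))
        mix.set(l, "m2", "m2", s2 - b * np.cos(2 * g2))
        mix.set(l, "m1", "m2", b * np.sin(2 * g2))
        # cos(2 phi) generator, sign alternating with the quarter turns
        sgn = 1.0 if k % 2 == 0 else -1.0
        mix.set(l, "m1", "n2", sgn * beta)
        mix.set(l, "m2", "n1", sgn * beta)
        # stimulus j saturates every coupling population except j
        for j in range(4):
            if j != k:
                mix.set(l, f"I_s{j+1}", f"I_s{j+1}", sigma_stim**2)
        n_var = 2.0 * (beta**2 / s2 + gamma**2 / sigma_I**2)
        mix.set(l, "n1", "n1", n_var)
        mix.set(l, "n2", "n2", n_var)
        mix.set(l, "w", "w", w_var)
        _inflate_n_variance(mix, l)
    mix.validate()
    if calibrate:
        _calibrate_oscillator(mix, 2 * np.pi * freq_hz / 1000.0, tau)
        mix.validate()
    return mix


def design_rate_coding_rank1(
    osc_weight: float = 0.5,
    sigma_m_fp0: float = 6.0,
    sigma_m_pm: float = 0.6,
    mn_fp0: float = -3.2,
    mn_pm: float = 4.5,
    sigma_I: float = 1.0,
    sigma_stim: float = 6.0,
    stim_push: float = 2.0,
    wI_in: float = 3.5,
    wI_anti: float = -2.0,
    w_var: float = 16.0,
) -> MixtureConnectivity:
    """Rank-1 rate-coding model (two populations, tanh readout).

    Population 1 stabilizes the fixed point at kappa = 0 (negative m-n
    coupling, large sigma_m so it saturates away from 0) and produces an
    in-phase output (positive I_osc-w covariance).  Population 2 sustains the
    two fixed points at +-kappa* (positive coupling, small sigma_m) and
    produces the anti-phase output.  Stimulus 1 saturates population 2
    (steering to 0); stimulus 2 saturates population 1 and pushes kappa away
    from 0 through a stimulus-n covariance.
    """
    mix = MixtureConnectivity.empty(
        2, 1, ["I_osc", "I_s1", "I_s2"], labels=["inphase_fp0", "antiphase_fppm"]
    )
    mix.weights = np.array([osc_weight, 1.0 - osc_weight])
    # population 1: fixed point at 0, in-phase readout
    mix.set(0, "m1", "m1", sigma_m_fp0**2)
    mix.set(0, "m1", "n1", mn_fp0)
    mix.set(0, "n1", "n1", 2.0 * mn_fp0**2 / sigma_m_fp0**2 + 4.0)
    mix.set(0, "I_osc", "I_osc", sigma_I**2)
    mix.set(0, "I_osc", "w", wI_in)
    mix.set(0, "I_s2", "I_s2", sigma_stim**2)  # stimulus b saturates pop 1
    mix.set(0, "w", "w", w_var)
    _inflate_n_variance(mix, 0)
    # population 2: fixed points at +-kappa*, anti-phase readout
    mix.set(1, "m1", "m1", sigma_m_pm**2)
    mix.set(1, "m1", "n1", mn_pm)
    mix.set(1, "n1", "n1", 2.0 * mn_pm**2 / sigma_m_pm**2 + 4.0)
    mix.set(1, "I_osc", "I_osc", sigma_I**2)
    mix.set(1, "I_osc", "w", wI_anti)
    mix.set(1, "I_s1", "I_s1", sigma_stim**2)  # stimulus a saturates pop 2
    mix.set(1, "I_s2", "I_s2", 1.0)  # licenses the push covariance below
    mix.set(1, "I_s2", "n1", stim_push)  # stimulus b pushes kappa off 0
    mix.set(1, "w", "w", w_var)
    _inflate_n_variance(mix, 1)
    mix.validate()
    return mix


def design_phase_precession(
    freq_hz: float = 8.0,
    tau: float = 20.0,
    radius: float = 1.0,
    osc_weight: float = 0.5,
    osc_sigma_m: float = 1.4,
    q: float = 2.2,
    sigma_I: float = 1.2,
    sigma_stim: float = 12.0,
    coupling_sigma_m: float = 0.9,
    w_var: float = 16.0,
) -> MixtureConnectivity:
    """Continuous phase shift driven by a position-like input s in [0, 1).

    The reference enters as sin(theta), cos(theta) on channels I_osca/I_oscb
    and the position as sin(pi s / 2), cos(pi s / 2) on I_s1/I_s2.
    Population 2 implements a sin(theta - phi) coupling and is saturated by
    the I_s2 channel (strong at s = 0); population 3 implements
    cos(theta - phi) and is saturated by I_s1 (strong at s = 1).  Sweeping s
    therefore rotates the locked phase difference continuously by a quarter
    period.
    """
    mix = MixtureConnectivity.empty(
        3,
        2,
        ["I_osca", "I_oscb", "I_s1", "I_s2"],
        labels=["oscillator", "coupling_sin", "coupling_cos"],
    )
    w_rest = (1.0 - osc_weight) / 2.0
    mix.weights = np.array([osc_weight, w_rest, w_rest])
    _oscillator_covariances(mix, 0, osc_weight, freq_hz, tau, radius, osc_sigma_m)
    mix.set(0, "w", "w", w_var)
    for l, pattern in ((1, "sin"), (2, "cos")):
        mix.set(l, "I_osca", "I_osca", sigma_I**2)
        mix.set(l, "I_oscb", "I_oscb", sigma_I**2)
        for v in ("m1", "m2"):
            mix.set(l, v, v, coupling_sigma_m**2)
        if pattern == "sin":
            # v_a cos(phi) - v_b sin(phi) -> sin(theta' - phi)
            mix.set(l, "I_osca", "n2", q)
            mix.set(l, "I_oscb", "n1", q)
            mix.set(l, "I_s2", "I_s2", sigma_stim**2)
        else:
            # v_b cos(phi) + v_a sin(phi) -> cos(theta' - phi)
            mix.set(l, "I_oscb", "n2", q)
            mix.set(l, "I_osca", "n1", -q)
            mix.set(l, "I_s1", "I_s1", sigma_stim**2)
        n_var = 2.5 * q**2 / sigma_I**2
        mix.set(l, "n1", "n1", n_var)
        mix.set(l, "n2", "n2", n_var)
        mix.set(l, "w", "w", w_var)
    mix.validate()
    return mix


def precession_inputs(s: float) -> dict:
    """Position s in [0, 1) encoded on the two stimulus channels."""
    return {"I_s1": np.sin(np.pi * s / 2.0), "I_s2": np.cos(np.pi * s / 2.0)}


# ---------------------------------------------------------------------------
# Mixture fitting (variational GMM) and resampling evaluation
# ---------------------------------------------------------------------------


def connectivity_matrix(rnn: LowRankRNN) -> tuple[np.ndarray, list]:
    """Stack per-unit weight vectors (N, d) with their variable names."""
    cols, names = [], []
    osc_names = ["I_osc"] if rnn.I_osc2 is None else ["I_osca", "I_oscb"]
    cols.append(rnn.I_osc)
    names.append(osc_names[0])
    if rnn.I_osc2 is not None:
        cols.append(rnn.I_osc2)
        names.append("I_oscb")
    for j in range(rnn.n_stimuli):
        cols.append(rnn.I_stim[:, j])
        names.append(f"I_s{j+1}")
    R = rnn.m.shape[1]
    for i in range(R):
        cols.append(rnn.n[:, i])
        names.append(f"n{i+1}")
    for i in range(R):
        cols.append(rnn.m[:, i])
        names.append(f"m{i+1}")
    cols.append(rnn.w)
    names.append("w")
    return np.stack(cols, axis=1), names


def fit_mixture(
    rnn: LowRankRNN,
    L_range=range(1, 8),
    seed: int = 0,
    n_resample: int = 30,
    eval_trials: list | None = None,
    h: float = 2.0,
    max_restarts: int = 5,
) -> dict:
    """Variational Gaussian-mixture fits to the connectivity + resampling loss.

    For each L, fits a Bayesian GMM (zero-mean prior with precision 1e6) to
    the per-unit weight vectors, then resamples ``n_resample`` networks of
    the same size and evaluates their task loss on ``eval_trials`` (if
    given).  Returns {L: {"mixture", "losses", "model_loss"}}.
    """
    from sklearn.mixture import BayesianGaussianMixture

    from .rnn_core import batch_loss

    X, names = connectivity_matrix(rnn)
    N, d = X.shape
    results = {}
    model_loss = batch_loss(rnn, eval_trials, h) if eval_trials else None
    for L in L_range:
        fitted = None
        for attempt in range(max_restarts):
            gm = BayesianGaussianMixture(
                n_components=L,
                covariance_type="full",
                mean_precision_prior=1e6,
                mean_prior=np.zeros(d),
                max_iter=500,
                random_state=seed + 97 * attempt,
            )
            gm.fit(X)
            if np.all(gm.weights_ > 1.0 / (20.0 * L) / 10.0):
                fitted = gm
                break
            fitted = gm
        weights = np.clip(fitted.weights_, 1e-9, None)
        weights = weights / weights.sum()
        mix = MixtureConnectivity(
            names, weights, fitted.covariances_, labels=[f"fit{l}" for l in range(L)]
        )
        losses = []
        if eval_trials:
            rng = np.random.default_rng(seed + 1)
            for rsi in range(n_resample):
                comp = rng.choice(L, size=N, p=weights)
                Y = np.empty((N, d))
                for l in range(L):
                    idx = np.where(comp == l)[0]
                    if idx.size == 0:
                        continue
                    vals, vecs = np.linalg.eigh(fitted.covariances_[l])
                    Lc = vecs * np.sqrt(np.clip(vals, 0.0, None))
                    Y[idx] = fitted.means_[l] + rng.standard_normal((idx.size, d)) @ Lc.T
                net = _network_from_matrix(Y, names, rnn)
                try:
                    losses.append(batch_loss(net, eval_trials, h))
                except Exception:
                    losses.append(np.inf)
        results[L] = {"mixture": mix, "losses": np.array(losses), "model_loss": model_loss}
    return results


def _network_from_matrix(Y: np.ndarray, names: list, template: LowRankRNN) -> LowRankRNN:
    col = {nm: Y[:, i] for i, nm in enumerate(names)}
    R = template.m.shape[1]
    m = np.stack([col[f"m{i+1}"] for i in range(R)], axis=1)
    n = np.stack([col[f"n{i+1}"] for i in range(R)], axis=1)
    I_osc = col.get("I_osc", col.get("I_osca"))
    I_osc2 = col.get("I_oscb") if template.I_osc2 is not None else None
    I_stim = np.stack([col[f"I_s{j+1}"] for j in range(template.n_stimuli)], axis=1)
    return LowRankRNN(
        m=m,
        n=n,
        I_osc=I_osc,
        I_stim=I_stim,
        w=col["w"],
        readout_scale=template.readout_scale,
        tau=template.tau,
        readout_mode=template.readout_mode,
        I_osc2=I_osc2,
    )
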