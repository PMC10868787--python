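"""Low-rank rate networks: definition, integration, initialization and training.

The recurrent weight matrix is either a rank-R outer-product sum
J = (1/N) sum_i m^(i) n^(i)T (never materialized during simulation) or a
dense matrix for full-rank experiments.  Training is backpropagation through
the unrolled Euler-Maruyama update with an Adam optimizer, both implemented
directly on NumPy arrays so the package has no deep-learning framework
dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .task_generator import Trial

__all__ = [
    "LowRankRNN",
    "InitSpec",
    "TrainConfig",
    "IntegrationError",
    "init",
    "simulate",
    "simulate_batch",
    "loss",
    "regularizer",
    "train",
    "canonicalize",
]


class IntegrationError(RuntimeError):
    """Raised when the network state becomes non-finite during integration."""


@dataclass
class LowRankRNN:
    """All parameters of the rate network.

    ``m``/``n`` hold the rank-R connectivity vectors as (N, R) arrays;
    full-rank networks set them to ``None`` and carry a dense ``J``.
    Times are in ms throughout (tau defaults to 20 ms).
    """

    m: np.ndarray | None
    n: np.ndarray | None
    I_osc: np.ndarray
    I_stim: np.ndarray  # (N, n_stimuli)
    w: np.ndarray
    readout_scale: float = 1.0
    tau: float = 20.0
    sigma_noise: float = 0.0
    readout_mode: str = "linear_out"  # or "tanh_out"
    J_dense: np.ndarray | None = None
    # Multi-channel oscillatory input (e.g. sin/cos pairs); optional.
    I_osc2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.readout_mode not in ("linear_out", "tanh_out"):
            raise ValueError("readout_mode must be linear_out or tanh_out")
        self.I_osc = np.asarray(self.I_osc, float).ravel()
        self.w = np.asarray(self.w, float).ravel()
        self.I_stim = np.atleast_2d(np.asarray(self.I_stim, float))
        if self.I_stim.shape[0] != self.N:
            self.I_stim = self.I_stim.T

    @property
    def N(self) -> int:
        return self.I_osc.size

    @property
    def rank(self) -> int | str:
        return "full" if self.m is None else self.m.shape[1]

    @property
    def n_stimuli(self) -> int:
        return self.I_stim.shape[1]

    def J_matrix(self) -> np.ndarray:
        """Dense recurrent matrix (reconstructed exactly for low rank)."""
        if self.m is None:
            return self.J_dense
        return (self.m @ self.n.T) / self.N

    def copy(self) -> "LowRankRNN":
        return replace(
            self,
            m=None if self.m is None else self.m.copy(),
            n=None if self.n is None else self.n.copy(),
            I_osc=self.I_osc.copy(),
            I_stim=self.I_stim.copy(),
            w=self.w.copy(),
            J_dense=None if self.J_dense is None else self.J_dense.copy(),
            I_osc2=None if self.I_osc2 is None else self.I_osc2.copy(),
        )

    def readout(self, x: np.ndarray) -> np.ndarray:
        """Readout r from state(s) x (..., N)."""
        z = np.tanh(x) if self.readout_mode == "tanh_out" else x
        return (self.readout_scale / self.N) * (z @ self.w)

    # -- persistence -------------------------------------------------------
    def save_hdf5(self, path, meta: dict | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("rnn")
            for name in ("m", "n", "I_osc", "I_stim", "w", "J_dense", "I_osc2"):
                val = getattr(self, name)
                if val is not None:
                    g.create_dataset(name, data=val)
            g.attrs["readout_scale"] = self.readout_scale
            g.attrs["tau"] = self.tau
            g.attrs["sigma_noise"] = self.sigma_noise
            g.attrs["readout_mode"] = self.readout_mode
            for k, v in (meta or {}).items():
                g.attrs[f"meta_{k}"] = v

    @classmethod
    def load_hdf5(cls, path) -> "LowRankRNN":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["rnn"]
            get = lambda k: g[k][()] if k in g else None
            return cls(
                m=get("m"),
                n=get("n"),
                I_osc=g["I_osc"][()],
                I_stim=g["I_stim"][()],
                w=g["w"][()],
                readout_scale=float(g.attrs["readout_scale"]),
                tau=float(g.attrs["tau"]),
                sigma_noise=float(g.attrs["sigma_noise"]),
                readout_mode=str(g.attrs["readout_mode"]),
                J_dense=get("J_dense"),
                I_osc2=get("I_osc2"),
            )


@dataclass
class InitSpec:
    """Joint-Gaussian initialization of the per-unit weight vector.

    Default: identity covariance over (m1, m2, n1, n2, I_osc, I_stim...,)
    except cov(m1, n1) = cov(m2, n2) = 0.6 and var(w) = 16.  ``oscillatory``
    mode instead couples the m/n pairs so that J starts with a complex
    conjugate eigenvalue pair with real part > 1.  ``fullrank`` draws a dense
    J with entries N(0, g^2/N).
    """

    mode: str = "default"  # default | oscillatory | fullrank
    rank: int = 2
    n_stimuli: int = 2
    mn_cov: float = 0.6
    w_var: float = 16.0
    g: float = 0.6  # full-rank gain
    osc_real: float = 1.2  # oscillatory mode: Re(lambda) of the J spectrum
    osc_imag: float = 1.0
    osc_var: float = 2.0  # m/n variance in oscillatory mode (PSD needs var >= |lambda|)

    def covariance(self) -> tuple[np.ndarray, list[str]]:
        """Covariance matrix over the joint per-unit vector + variable names."""
        R, S = self.rank, self.n_stimuli
        names = [f"m{i+1}" for i in range(R)] + [f"n{i+1}" for i in range(R)]
        names += ["I_osc"] + [f"I_s{i+1}" for i in range(S)] + ["w"]
        d = len(names)
        C = np.eye(d)
        C[names.index("w"), names.index("w")] = self.w_var
        if self.mode == "oscillatory":
            if R < 2:
                raise ValueError("oscillatory initialization needs rank >= 2")
            # n^T m / N = [[a, b], [-b, a]] -> eigenvalues a +- i b
            a, b = self.osc_real, self.osc_imag
            if self.osc_var < np.hypot(a, b):
                raise ValueError("osc_var too small for a PSD covariance")
            for nm in ("m1", "m2", "n1", "n2"):
                C[names.index(nm), names.index(nm)] = self.osc_var
            C[names.index("m1"), names.index("n1")] = a
            C[names.index("m2"), names.index("n2")] = a
            C[names.index("m1"), names.index("n2")] = -b
            C[names.index("m2"), names.index("n1")] = b
        else:
            for i in range(min(R, 2)):
                C[names.index(f"m{i+1}"), names.index(f"n{i+1}")] = self.mn_cov
        C = np.triu(C) + np.triu(C, 1).T
        return C, names


def init(N: int, spec: InitSpec | None = None, seed: int = 0) -> LowRankRNN:
    """Draw a network with jointly Gaussian per-unit weights."""
    spec = spec or InitSpec()
    rng = np.random.default_rng(seed)
    if spec.mode == "fullrank":
        J = rng.normal(0.0, spec.g / np.sqrt(N), size=(N, N))
        I_osc = rng.normal(size=N)
        I_stim = rng.normal(size=(N, spec.n_stimuli))
        w = rng.normal(0.0, np.sqrt(spec.w_var), size=N)
        return LowRankRNN(None, None, I_osc, I_stim, w, J_dense=J)
    C, names = spec.covariance()
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-10:
        raise ValueError("initialization covariance is not PSD")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    Y = rng.standard_normal((N, len(C))) @ L.T
    col = {nm: Y[:, i] for i, nm in enumerate(names)}
    m = np.stack([col[f"m{i+1}"] for i in range(spec.rank)], axis=1)
    n = np.stack([col[f"n{i+1}"] for i in range(spec.rank)], axis=1)
    I_stim = np.stack([col[f"I_s{i+1}"] for i in range(spec.n_stimuli)], axis=1)
    return LowRankRNN(m, n, col["I_osc"], I_stim, col["w"])


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _drive(rnn: LowRankRNN, phi: np.ndarray) -> np.ndarray:
    """Recurrent drive J tanh(x) for phi = tanh(x), batched (..., N)."""
    if rnn.m is None:
        return phi @ rnn.J_dense.T
    return (phi @ rnn.n) @ rnn.m.T / rnn.N


def simulate_batch(
    rnn: LowRankRNN,
    u: np.ndarray,  # (B, T) or (B, T, n_osc) for multi-channel reference
    stimuli: np.ndarray,  # (B, T, S)
    h: float,
    noise_seed: int | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of a batch of trials.

    x_{k+1} = (1 - h/tau) x_k + (h/tau)(J tanh x_k + I_osc u_k + I_stim s_k)
              + sqrt(h/tau) eps,  eps ~ N(0, 2 sigma_noise^2) i.i.d.

    Returns (x_traj (T, B, N), readout (T, B)); x_traj[0] = x0 (zeros by
    default) and inputs at step k produce x_traj[k+1].
    """
    B, T = u.shape[0], u.shape[1]
    N = rnn.N
    a = h / rnn.tau
    x = np.zeros((B, N)) if x0 is None else np.array(x0, float).reshape(B, N)
    xs = np.empty((T, B, N))
    xs[0] = x
    rng = np.random.default_rng(noise_seed) if rnn.sigma_noise > 0 else None
    noise_sd = np.sqrt(2.0 * a) * rnn.sigma_noise
    multi_osc = u.ndim == 3
    for k in range(T - 1):
        phi = np.tanh(x)
        if multi_osc:
            osc = u[:, k, 0:1] * rnn.I_osc[None, :]
            if rnn.I_osc2 is not None:
                osc = osc + u[:, k, 1:2] * rnn.I_osc2[None, :]
        else:
            osc = u[:, k, None] * rnn.I_osc[None, :]
        inp = osc + stimuli[:, k, :] @ rnn.I_stim.T
        x = (1.0 - a) * x + a * (_drive(rnn, phi) + inp)
        if rng is not None:
            x = x + noise_sd * rng.standard_normal((B, N))
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite state at step {k + 1}")
        xs[k + 1] = x
    return xs, rnn.readout(xs)


def simulate(
    rnn: LowRankRNN,
    trial: Trial,
    h: float | None = None,
    noise_seed: int | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a single trial; returns (x (T, N), readout (T,))."""
    h = trial.h_ms if h is None else h
    xs, r = simulate_batch(
        rnn,
        trial.u[None, :],
        trial.stimuli[None, :, :],
        h,
        noise_seed=noise_seed,
        x0=None if x0 is None else x0[None, :],
    )
    return xs[:, 0, :], r[:, 0]


# ---------------------------------------------------------------------------
# Loss / regularizer
# ---------------------------------------------------------------------------


def loss(r: np.ndarray, trial: Trial) -> float:
    """Mean squared error over the masked (post-stimulus) samples."""
    if not trial.mask.any():
        raise ValueError("trial has an empty loss mask")
    d = r[trial.mask] - trial.target[trial.mask]
    return float(np.mean(d * d))


def regularizer(x: np.ndarray, trial: Trial) -> float:
    """(1/N) sum_i (time-mean of x_i over the masked region)^2."""
    if not trial.mask.any():
        raise ValueError("trial has an empty loss mask")
    xbar = x[trial.mask].mean(axis=0)
    return float(np.mean(xbar * xbar))


@dataclass
class TrainConfig:
    """Optimization settings (Adam + backprop through time)."""

    epochs: int = 50
    batch: int = 128
    lr: float = 0.01
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    h_train: float = 2.0
    regularize_rates: bool = False
    reg_weight: float = 1.0
    train_inputs: bool = True
    train_recurrent: bool = True
    train_readout_scale: bool = True

    def __post_init__(self) -> None:
        if self.h_train <= 0:
            raise ValueError("h_train must be positive")


def _stack_trials(trials: list[Trial]):
    u = np.stack([t.u for t in trials])
    s = np.stack([t.stimuli for t in trials])
    tgt = np.stack([t.target for t in trials])
    mask = np.stack([t.mask for t in trials])
    return u, s, tgt, mask


def batch_loss(rnn: LowRankRNN, trials: list[Trial], h: float, noise_seed=None) -> float:
    """Mean per-trial masked MSE over a list of trials (forward only)."""
    u, s, tgt, mask = _stack_trials(trials)
    _, r = simulate_batch(rnn, u, s, h, noise_seed=noise_seed)
    r = r.T  # (B, T)
    per = ((r - tgt) ** 2 * mask).sum(axis=1) / mask.sum(axis=1)
    return float(per.mean())


def _forward_backward(
    rnn: LowRankRNN,
    u: np.ndarray,
    s: np.ndarray,
    tgt: np.ndarray,
    mask: np.ndarray,
    h: float,
    cfg: TrainConfig,
    noise_seed=None,
):
    """Loss + gradients w.r.t. (m, n | J), I_osc, I_stim, readout_scale.

    Hand-written adjoint of the unrolled Euler-Maruyama update; the noise
    realization is treated as a constant (standard pathwise gradient).
    """
    B, T = u.shape
    N = rnn.N
    a = h / rnn.tau
    c = rnn.readout_scale
    low_rank = rnn.m is not None

    xs, r = simulate_batch(rnn, u, s, h, noise_seed=noise_seed)
    r = r.T  # (B, T)
    m_counts = mask.sum(axis=1)  # (B,)
    err = (r - tgt) * mask
    per_loss = (err**2).sum(axis=1) / m_counts
    total = float(per_loss.mean())
    # dL/dr_k
    e = 2.0 * err / (B * m_counts[:, None])  # (B, T)

    # Regularizer on the time-mean of x over the masked region.
    reg_val = 0.0
    if cfg.regularize_rates:
        xbar = np.einsum("bt,tbn->bn", mask / m_counts[:, None], xs)
        reg_val = cfg.reg_weight * float(np.mean((xbar**2).sum(axis=1)) / N)
        dreg_dxbar = cfg.reg_weight * 2.0 * xbar / (B * N)  # (B, N)
        total_loss = total + reg_val
    else:
        total_loss = total

    grad = {
        "m": np.zeros_like(rnn.m) if low_rank else None,
        "n": np.zeros_like(rnn.n) if low_rank else None,
        "J": None if low_rank else np.zeros_like(rnn.J_dense),
        "I_osc": np.zeros(N),
        "I_stim": np.zeros_like(rnn.I_stim),
        "readout_scale": 0.0,
    }

    w_over_N = rnn.w / N
    g_next = np.zeros((B, N))  # dL/dx_{k+1}
    for k in range(T - 1, -1, -1):
        xk = xs[k]
        phik = np.tanh(xk)
        # direct readout contribution at step k
        if rnn.readout_mode == "linear_out":
            direct = (e[:, k, None] * c) * w_over_N[None, :]
            grad["readout_scale"] += float(np.sum(e[:, k] * (xk @ w_over_N)))
        else:
            direct = (e[:, k, None] * c) * w_over_N[None, :] * (1.0 - phik**2)
            grad["readout_scale"] += float(np.sum(e[:, k] * (phik @ w_over_N)))
        if cfg.regularize_rates:
            direct = direct + dreg_dxbar * (mask[:, k] / m_counts)[:, None]
        if k == T - 1:
            g_next = direct
            continue
        # parameter gradients from the k -> k+1 transition
        if low_rank:
            sk = phik @ rnn.n  # (B, R)
            pk = g_next @ rnn.m  # (B, R)
            grad["m"] += (a / N) * (g_next.T @ sk)
            grad["n"] += (a / N) * (phik.T @ pk)
        else:
            grad["J"] += a * (g_next.T @ phik)
        grad["I_osc"] += a * (g_next.T @ u[:, k])
        grad["I_stim"] += a * (g_next.T @ s[:, k, :])
        # adjoint recursion
        if low_rank:
            back = (pk @ rnn.n.T) / N
        else:
            back = g_next @ rnn.J_dense
        g_next = direct + (1.0 - a) * g_next + a * (1.0 - phik**2) * back
    return total_loss, total, reg_val, grad


class _Adam:
    def __init__(self, shapes: dict, lr: float, betas, eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.mom = {k: np.zeros(s) if s != () else 0.0 for k, s in shapes.items()}
        self.vel = {k: np.zeros(s) if s != () else 0.0 for k, s in shapes.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if g is None or k not in params:
                continue
            self.mom[k] = self.b1 * self.mom[k] + (1 - self.b1) * g
            self.vel[k] = self.b2 * self.vel[k] + (1 - self.b2) * np.square(g)
            mhat = self.mom[k] / (1 - self.b1**self.t)
            vhat = self.vel[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    rnn: LowRankRNN,
    train_trials: list[Trial],
    cfg: TrainConfig | None = None,
    seed: int = 0,
    val_trials: list[Trial] | None = None,
    verbose: bool = False,
) -> tuple[LowRankRNN, dict]:
    """Train in place on batches of trials; returns (rnn, history).

    Trained parameters: connectivity vectors (or dense J), all input weight
    vectors, and the scalar multiplying the frozen readout weights w.
    History holds per-epoch train/validation loss curves.
    """
    cfg = cfg or TrainConfig()
    rnn = rnn.copy()
    rng = np.random.default_rng(seed)
    low_rank = rnn.m is not None

    params: dict[str, np.ndarray | float] = {}
    if cfg.train_recurrent:
        if low_rank:
            params["m"], params["n"] = rnn.m, rnn.n
        else:
            params["J"] = rnn.J_dense
    if cfg.train_inputs:
        params["I_osc"], params["I_stim"] = rnn.I_osc, rnn.I_stim
    shapes = {k: np.shape(v) for k, v in params.items()}
    if cfg.train_readout_scale:
        shapes["readout_scale"] = ()
    opt = _Adam(shapes, cfg.lr, cfg.betas, cfg.eps)

    history = {"train_loss": [], "val_loss": [], "reg": []}
    n_trials = len(train_trials)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_trials)
        ep_losses, ep_regs = [], []
        for start in range(0, n_trials, cfg.batch):
            idx = order[start : start + cfg.batch]
            batch = [train_trials[i] for i in idx]
            u, s, tgt, mask = _stack_trials(batch)
            noise_seed = int(rng.integers(2**31)) if rnn.sigma_noise > 0 else None
            total, mse, reg, grads = _forward_backward(
                rnn, u, s, tgt, mask, cfg.h_train, cfg, noise_seed
            )
            if not np.isfinite(total):
                raise IntegrationError(f"divergent loss at epoch {epoch}")
            scal = {"readout_scale": rnn.readout_scale}
            # arrays update in place; the scalar needs special handling
            opt_grads = {k: v for k, v in grads.items() if k in shapes}
            arr_grads = {k: v for k, v in opt_grads.items() if k != "readout_scale"}
            opt.step(params, arr_grads)
            if cfg.train_readout_scale:
                opt.step(scal, {"readout_scale": opt_grads["readout_scale"]})
                rnn.readout_scale = float(scal["readout_scale"])
            ep_losses.append(mse)
            ep_regs.append(reg)
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["reg"].append(float(np.mean(ep_regs)))
        if val_trials:
            history["val_loss"].append(batch_loss(rnn, val_trials, cfg.h_train))
        if verbose:
            v = history["val_loss"][-1] if val_trials else float("nan")
            print(f"epoch {epoch + 1}/{cfg.epochs}  train {history['train_loss'][-1]:.4f}  val {v:.4f}")
    return rnn, history


# ---------------------------------------------------------------------------
# Canonical form
# ---------------------------------------------------------------------------


def canonicalize(rnn: LowRankRNN) -> tuple[LowRankRNN, np.ndarray, np.ndarray]:
    """Orthogonalize the m-vectors via SVD of J (J itself is unchanged).

    Returns (rnn', alphas, I_perp) with
    I_osc = I_perp + sum_i m'^(i) alpha_i  and  m'^(i)T I_perp = 0.
    The (m2, n2) pair's sign is chosen so the linearized kappa rotation at the
    origin is counter-clockwise, fixing the orientation convention used by the
    phase reduction.
    """
    if rnn.m is None or rnn.m.shape[1] < 2:
        raise ValueError("canonicalize requires an explicit rank >= 2 factorization")
    N = rnn.N
    J = rnn.J_matrix()
    R = rnn.m.shape[1]
    U, S, Vt = np.linalg.svd(J)
    if S[R - 1] < 1e-12 * S[0]:
        import warnings

        warnings.warn("J is rank deficient; canonical factors may be ill-conditioned")
    m_new = U[:, :R] * np.sqrt(N * S[:R])
    n_new = Vt[:R].T * np.sqrt(N * S[:R])
    # orientation: ensure n2.m1/N - n1.m2/N rotation is counter-clockwise
    B21 = n_new[:, 1] @ m_new[:, 0] / N
    B12 = n_new[:, 0] @ m_new[:, 1] / N
    if B21 - B12 < 0:
        m_new[:, 1] *= -1
        n_new[:, 1] *= -1
    out = rnn.copy()
    out.m, out.n = m_new, n_new
    alphas = (m_new.T @ rnn.I_osc) / np.sum(m_new * m_new, axis=0)
    I_perp = rnn.I_osc - m_new @ alphas
    return out, alphas, I_perp


def decompose_along_m(rnn: LowRankRNN, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split any N-vector into m-parallel coefficients and the orthogonal rest."""
    coeff = (rnn.m.T @ vec) / np.sum(rnn.m * rnn.m, axis=0)
    return coeff, vec - rnn.m @ coeff
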