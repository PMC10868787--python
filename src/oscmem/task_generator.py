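"""Phase-coding working-memory trials.

A trial presents one transient stimulus pulse on top of a reference
oscillation; after stimulus offset the desired readout is a unit sinusoid
locked to the reference phase at a stimulus-specific offset
(target = sin(theta - offset)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_signals import ReferenceSignal

__all__ = ["TaskConfig", "Trial", "make_trial", "make_trial_multi", "split_segments"]

# "offset by phi0" means target = sin(theta - phi0); offsets stored positive.
TWO_STIM_OFFSETS = (0.2 * np.pi, 1.2 * np.pi)
FOUR_STIM_OFFSETS = (0.2 * np.pi, 0.7 * np.pi, 1.4 * np.pi, 1.7 * np.pi)


@dataclass
class TaskConfig:
    """Trial-construction parameters (times in seconds, phases in radians)."""

    T_trial: float = 0.8
    onset_range: tuple[float, float] = (0.125, 0.25)
    dur_range: tuple[float, float] = (0.125, 0.175)
    amplitude: float = 1.0
    phase_offsets: tuple[float, ...] = TWO_STIM_OFFSETS
    h_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.onset_range[1] + self.dur_range[1] > self.T_trial:
            raise ValueError("stimulus window does not fit in the trial")
        offs = np.mod(np.asarray(self.phase_offsets), 2 * np.pi)
        if len(np.unique(np.round(offs, 9))) != len(offs):
            raise ValueError("phase offsets must be distinct mod 2pi")

    @property
    def n_stimuli(self) -> int:
        return len(self.phase_offsets)

    @property
    def n_steps(self) -> int:
        return int(round(self.T_trial * 1000.0 / self.h_ms))

    def to_dict(self) -> dict:
        return {
            "T_trial": self.T_trial,
            "onset_range": list(self.onset_range),
            "dur_range": list(self.dur_range),
            "amplitude": self.amplitude,
            "phase_offsets": [float(p) for p in self.phase_offsets],
            "h_ms": self.h_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        for key in ("onset_range", "dur_range", "phase_offsets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Trial:
    """One task trial sampled on the integration grid."""

    u: np.ndarray  # (T,)
    theta: np.ndarray  # (T,) rad
    stimuli: np.ndarray  # (T, n_stim)
    target: np.ndarray  # (T,)
    mask: np.ndarray  # (T,) bool, True from stimulus offset onward
    stim_id: int
    t_stim_on: float  # ms
    t_stim_off: float  # ms
    h_ms: float = 2.0

    @property
    def n_steps(self) -> int:
        return self.u.size


def make_trial(
    ref: ReferenceSignal, stim_id: int, cfg: TaskConfig, seed: int = 0, start_index: int | None = None
) -> Trial:
    """Build one trial from a reference signal.

    Stimulus onset ~ U(onset_range) and duration ~ U(dur_range), rounded down
    to the integration grid; the stimulus is a rectangular pulse of
    ``cfg.amplitude`` on channel ``stim_id``; the target is
    sin(theta - offset) wherever the loss mask is on (t >= stimulus offset).
    If the reference is longer than the trial, a random trial-length window is
    cut (``start_index`` overrides for reproducible alignment).
    """
    if stim_id >= cfg.n_stimuli:
        raise ValueError("stim_id out of range")
    rng = np.random.default_rng(seed)
    n = cfg.n_steps
    fs_expected = 1000.0 / cfg.h_ms
    if abs(ref.sample_rate - fs_expected) > 1e-9:
        raise ValueError(
            f"reference sampled at {ref.sample_rate} Hz; trial grid needs {fs_expected} Hz"
        )
    if ref.n_samples < n:
        raise ValueError("reference signal shorter than the trial")
    if start_index is None:
        start_index = int(rng.integers(ref.n_samples - n + 1))
    u = ref.u[start_index : start_index + n].copy()
    theta = ref.theta[start_index : start_index + n].copy()

    onset_s = rng.uniform(*cfg.onset_range)
    dur_s = rng.uniform(*cfg.dur_range)
    i_on = int(onset_s * 1000.0 / cfg.h_ms)
    i_off = i_on + int(dur_s * 1000.0 / cfg.h_ms)

    stimuli = np.zeros((n, cfg.n_stimuli))
    stimuli[i_on:i_off, stim_id] = cfg.amplitude
    mask = np.zeros(n, dtype=bool)
    mask[i_off:] = True
    target = np.zeros(n)
    target[mask] = np.sin(theta[mask] - cfg.phase_offsets[stim_id])
    return Trial(
        u=u,
        theta=theta,
        stimuli=stimuli,
        target=target,
        mask=mask,
        stim_id=stim_id,
        t_stim_on=i_on * cfg.h_ms,
        t_stim_off=i_off * cfg.h_ms,
        h_ms=cfg.h_ms,
    )


def make_trial_multi(ref: ReferenceSignal, stim_id: int, cfg4: TaskConfig | None = None, seed: int = 0) -> Trial:
    """Four-stimulus variant: offsets 0.2pi, 0.7pi, 1.4pi, 1.7pi."""
    if cfg4 is None:
        cfg4 = TaskConfig(phase_offsets=FOUR_STIM_OFFSETS)
    if cfg4.n_stimuli != 4:
        raise ValueError("multi-stimulus config must define 4 offsets")
    return make_trial(ref, stim_id, cfg4, seed=seed)


def split_segments(segments: list, frac_train: float = 0.9, seed: int = 0) -> tuple[list, list]:
    """Seeded shuffle-split of reference segments into train/validation."""
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to split")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(segments))
    n_train = int(round(frac_train * len(segments)))
    n_train = min(max(n_train, 1), len(segments) - 1)
    train = [segments[i] for i in idx[:n_train]]
    val = [segments[i] for i in idx[n_train:]]
    return train, val


def save_trials_hdf5(trials: list[Trial], path) -> None:
    """Store a batch of trials as HDF5 groups (u, theta, stimuli, target, mask)."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, tr in enumerate(trials):
            g = f.create_group(f"trial_{i:05d}")
            for name in ("u", "theta", "stimuli", "target", "mask"):
                g.create_dataset(name, data=getattr(tr, name))
            g.attrs["stim_id"] = tr.stim_id
            g.attrs["t_stim_on"] = tr.t_stim_on
            g.attrs["t_stim_off"] = tr.t_stim_off
            g.attrs["h_ms"] = tr.h_ms


def load_trials_hdf5(path) -> list[Trial]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(
                Trial(
                    u=g["u"][()],
                    theta=g["theta"][()],
                    stimuli=g["stimuli"][()],
                    target=g["target"][()],
                    mask=g["mask"][()].astype(bool),
                    stim_id=int(g.attrs["stim_id"]),
                    t_stim_on=float(g.attrs["t_stim_on"]),
                    t_stim_off=float(g.attrs["t_stim_off"]),
                    h_ms=float(g.attrs["h_ms"]),
                )
            )
    return out


def save_config_yaml(cfg: TaskConfig, path) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f)


def load_config_yaml(path) -> TaskConfig:
    import yaml

    with open(path) as f:
        return TaskConfig.from_dict(yaml.safe_load(f))


def make_trial_batch(
    segments: list, cfg: TaskConfig, n_trials: int, seed: int = 0
) -> list[Trial]:
    """Round-robin over segments with cycling stimulus identity."""
    rng = np.random.default_rng(seed)
    trials = []
    for k in range(n_trials):
        ref = segments[k % len(segments)]
        stim_id = k % cfg.n_stimuli
        trials.append(make_trial(ref, stim_id, cfg, seed=int(rng.integers(2**31))))
    return trials
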