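"""Synthetic theta-band reference oscillations and the LFP-style preprocessing chain.

The package never requires real recordings: :func:`generate_synthetic_lfp`
produces a narrowband stochastic oscillation with slow amplitude/frequency
drift whose statistics stand in for a filtered hippocampal LFP.  Real
multichannel arrays can be pushed through the same chain
(:func:`preprocess` -> :func:`segment_trials` -> :func:`extract_phase`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "ReferenceSignal",
    "generate_synthetic_lfp",
    "preprocess",
    "extract_phase",
    "segment_trials",
    "pure_sine",
]

SINE_RMS = 1.0 / np.sqrt(2.0)


@dataclass
class RawRecording:
    """Multichannel raw signal, channels x samples."""

    samples: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def save_npz(self, path) -> None:
        np.savez(path, lfp=self.samples, sample_rate=self.sample_rate)

    @classmethod
    def load_npz(cls, path) -> "RawRecording":
        d = np.load(path)
        return cls(d["lfp"], float(d["sample_rate"]))

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("lfp", data=self.samples)
            ds.attrs["sample_rate"] = self.sample_rate

    @classmethod
    def load_hdf5(cls, path) -> "RawRecording":
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["lfp"]
            return cls(ds[()], float(ds.attrs["sample_rate"]))


@dataclass
class ReferenceSignal:
    """Normalized 1-D reference oscillation with an instantaneous-phase track.

    ``u`` is dimensionless (RMS comparable to a unit-amplitude sine for
    synthetic/preprocessed sources), ``theta`` is wrapped to [0, 2pi).
    """

    u: np.ndarray
    theta: np.ndarray
    sample_rate: float
    dominant_freq: float
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).ravel()
        self.theta = np.mod(np.asarray(self.theta, dtype=float).ravel(), 2 * np.pi)
        if self.u.shape != self.theta.shape:
            raise ValueError("u and theta must have equal length")

    @property
    def n_samples(self) -> int:
        return self.u.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def save_hdf5(self, path, group: str = "reference") -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group(group)
            g.create_dataset("u", data=self.u)
            g.create_dataset("theta", data=self.theta)
            g.attrs["sample_rate"] = self.sample_rate
            g.attrs["dominant_freq"] = self.dominant_freq
            g.attrs["source"] = self.source

    @classmethod
    def load_hdf5(cls, path, group: str = "reference") -> "ReferenceSignal":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[group]
            return cls(
                g["u"][()],
                g["theta"][()],
                float(g.attrs["sample_rate"]),
                float(g.attrs["dominant_freq"]),
                str(g.attrs["source"]),
            )


def _ou_path(n: int, dt: float, tau: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, mean 0, stationary SD ``sd``."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
    if sd == 0:
        x[:] = 0.0
        return x
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, 1.0, size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * eps[i - 1]
    return x


def generate_synthetic_lfp(
    duration_s: float,
    sample_rate: float = 1250.0,
    band_low_hz: float = 7.0,
    band_high_hz: float = 9.0,
    amp_drift_sd: float = 0.2,
    freq_drift_sd: float = 0.3,
    seed: int = 0,
    n_channels: int = 1,
    drift_tau_s: float = 2.0,
    noise_floor: float = 0.05,
    scale: float = 100.0,
) -> RawRecording:
    """Narrowband stochastic oscillation with slow amplitude and frequency drift.

    The carrier is a sinusoid whose instantaneous frequency wanders inside
    [band_low_hz, band_high_hz] (OU-modulated, clipped by a smooth squashing)
    and whose amplitude is log-OU modulated.  Channels share the hidden phase
    but carry independent additive broadband noise.  The hidden phase track is
    stored in ``meta['true_phase']`` so downstream phase extraction can be
    validated against ground truth.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not (0 < band_low_hz < band_high_hz < sample_rate / 2):
        raise ValueError("need 0 < band_low < band_high < Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    dt = 1.0 / sample_rate
    tau = drift_tau_s

    f0 = 0.5 * (band_low_hz + band_high_hz)
    half_bw = 0.5 * (band_high_hz - band_low_hz)
    zf = _ou_path(n, dt, tau, freq_drift_sd, rng)
    freq = f0 + half_bw * np.tanh(zf)  # stays strictly inside the band

    za = _ou_path(n, dt, tau, amp_drift_sd, rng)
    amp = np.exp(za)

    phase = 2 * np.pi * np.cumsum(freq) * dt
    carrier = amp * np.sin(phase)

    chans = np.empty((n_channels, n))
    for c in range(n_channels):
        noise = rng.normal(0.0, noise_floor, size=n) if noise_floor > 0 else 0.0
        gain = 1.0 + (0.1 * rng.normal() if n_channels > 1 else 0.0)
        chans[c] = scale * (gain * carrier + noise)
    return RawRecording(chans, sample_rate, meta={"true_phase": phase, "true_freq": freq})


def design_highpass(n_taps: int, cutoff_hz: float, sample_rate: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR high-pass taps."""
    return sps.firwin(n_taps, cutoff_hz, window="hamming", pass_zero=False, fs=sample_rate)


def preprocess(
    raw: RawRecording,
    target_rate: float = 500.0,
    highpass_hz: float = 7.0,
    n_taps: int = 511,
) -> RawRecording:
    """Resample, FIR-high-pass and normalize a recording channel-wise.

    Steps: polyphase resampling to ``target_rate``; linear-phase FIR high-pass
    (Hamming window, ``n_taps`` taps) applied with symmetric delay
    compensation; channel-wise division by sqrt(2) times the channel SD,
    which gives each channel the RMS of a unit-amplitude sine (1/sqrt(2)).
    """
    from fractions import Fraction

    frac = Fraction(target_rate / raw.sample_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    x = sps.resample_poly(raw.samples, up, down, axis=1)
    if x.shape[1] <= n_taps:
        raise ValueError("signal shorter than the FIR filter; record longer data")
    taps = design_highpass(n_taps, highpass_hz, target_rate)
    # 'same' convolution centres the linear-phase kernel: zero group delay.
    y = np.stack([np.convolve(ch, taps, mode="same") for ch in x])
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    y = y / (np.sqrt(2.0) * sd)
    meta = dict(raw.meta)
    if "true_phase" in meta:
        idx = np.round(np.arange(y.shape[1]) * raw.sample_rate / target_rate).astype(int)
        idx = np.clip(idx, 0, len(meta["true_phase"]) - 1)
        meta["true_phase"] = np.asarray(meta["true_phase"])[idx]
    meta["preprocessed"] = True
    return RawRecording(y, target_rate, meta=meta)


def morlet_power_phase(
    u: np.ndarray, sample_rate: float, freq_hz: float, cycles: float = 7.0
) -> tuple[np.ndarray, float]:
    """Complex Morlet convolution at one frequency -> (analytic phase, mean power)."""
    sigma_t = cycles / (2 * np.pi * freq_hz)
    half = int(np.ceil(4 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    wavelet = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    wavelet /= np.abs(wavelet).sum()
    analytic = np.convolve(u, wavelet, mode="same")
    return np.angle(analytic), float(np.mean(np.abs(analytic) ** 2))


def extract_phase(
    u: np.ndarray,
    sample_rate: float,
    freq_lo: float = 7.0,
    freq_hi: float = 9.0,
    freq_step: float = 0.2,
    cycles: float = 7.0,
    discard_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Instantaneous phase of a 1-D signal via complex Morlet wavelets.

    Scans the frequency grid ``freq_lo..freq_hi`` (inclusive, step
    ``freq_step``), keeps the phase at the frequency with maximal mean power
    over the whole chunk, and discards the first ``discard_s`` seconds to
    avoid convolution edge effects.

    Returns ``(u_kept, theta, dominant_freq)`` with ``theta`` wrapped to
    [0, 2pi) and aligned sample-by-sample with ``u_kept``.
    """
    u = np.asarray(u, dtype=float).ravel()
    freqs = np.arange(freq_lo, freq_hi + freq_step / 2, freq_step)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    n_skip = int(round(discard_s * sample_rate))
    if u.size <= n_skip:
        raise ValueError("signal shorter than the discard window")
    best_phase, best_power, best_f = None, -np.inf, freqs[0]
    for f in freqs:
        ph, pw = morlet_power_phase(u, sample_rate, f, cycles)
        if pw > best_power:
            best_phase, best_power, best_f = ph, pw, f
    # analytic angle is relative to cosine; shift so that u ~ sin(theta),
    # matching the pure-sine convention used everywhere else
    theta = np.mod(best_phase[n_skip:] + np.pi / 2.0, 2 * np.pi)
    return u[n_skip:], theta, float(best_f)


def segment_trials(
    recording: RawRecording,
    segment_s: float = 4.0,
    artifact_thresh: float = 4.0,
    seed: int = 0,
    freq_lo: float = 7.0,
    freq_hi: float = 9.0,
    freq_step: float = 0.2,
    cycles: float = 7.0,
    discard_s: float = 1.0,
) -> list[ReferenceSignal]:
    """Cut a preprocessed recording into per-trial reference signals.

    Non-overlapping ``segment_s`` chunks; one uniformly chosen channel per
    chunk; chunks whose max |u| exceeds ``artifact_thresh`` are dropped; each
    surviving chunk gets a Morlet phase track (first ``discard_s`` seconds of
    every chunk removed).
    """
    rng = np.random.default_rng(seed)
    fs = recording.sample_rate
    seg_len = int(round(segment_s * fs))
    n_segs = recording.n_samples // seg_len
    out: list[ReferenceSignal] = []
    for k in range(n_segs):
        ch = int(rng.integers(recording.n_channels))
        chunk = recording.samples[ch, k * seg_len : (k + 1) * seg_len]
        if np.max(np.abs(chunk)) > artifact_thresh:
            continue
        u, theta, fdom = extract_phase(
            chunk, fs, freq_lo, freq_hi, freq_step, cycles, discard_s
        )
        out.append(ReferenceSignal(u, theta, fs, fdom, source="preprocessed"))
    return out


def pure_sine(
    freq_hz: float,
    amplitude: float = 1.0,
    phase0: float = 0.0,
    duration_s: float = 1.0,
    sample_rate: float = 500.0,
) -> ReferenceSignal:
    """Pure sinusoid reference with an exact phase track."""
    if freq_hz >= sample_rate / 2:
        raise ValueError("frequency above Nyquist")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    theta = phase0 + 2 * np.pi * freq_hz * t
    return ReferenceSignal(
        amplitude * np.sin(theta), theta, sample_rate, freq_hz, source="pure_sine"
    )


def synthetic_reference_segments(
    n_trials: int,
    seed: int = 0,
    sample_rate: float = 500.0,
    segment_s: float = 4.0,
    **lfp_kwargs,
) -> list[ReferenceSignal]:
    """End-to-end convenience: synthetic LFP -> preprocess -> segments.

    Generates enough raw signal so that at least ``n_trials`` artifact-free
    segments come out, then truncates to exactly ``n_trials``.
    """
    segs: list[ReferenceSignal] = []
    round_i = 0
    while len(segs) < n_trials and round_i < 8:
        dur = segment_s * max(4, int(np.ceil(1.3 * (n_trials - len(segs)))))
        raw = generate_synthetic_lfp(dur, seed=seed + 1000 * round_i, **lfp_kwargs)
        pre = preprocess(raw, target_rate=sample_rate)
        segs.extend(segment_trials(pre, segment_s=segment_s, seed=seed + round_i))
        round_i += 1
    return segs[:n_trials]
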