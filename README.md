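# oscmem

Phase-coded working memory in oscillator-driven low-rank recurrent networks:
training, reverse engineering, and mean-field reduction — in pure scientific
Python (NumPy/SciPy + numba kernels; no deep-learning framework).

A rank-2 rate network receives a theta-band reference oscillation and brief
stimulus pulses, and must produce an output oscillation whose phase offset
relative to the reference stores the stimulus identity. The package

- generates **synthetic theta-like reference signals** (OU-modulated
  amplitude/frequency on a narrowband carrier) and implements the
  LFP-style preprocessing chain (polyphase resampling, Hamming-window FIR
  high-pass, RMS normalization, complex-Morlet phase extraction, artifact
  rejection, per-trial segmentation) so real multichannel recordings can be
  dropped in (`reference_signals`);
- builds the **two- and four-stimulus working-memory task**
  (`task_generator`);
- defines, initializes and **trains the low-rank RNN** with hand-written
  backprop-through-time and Adam on NumPy arrays (`rnn_core`);
- reduces the driven network to a 3-D autonomous system on
  (kappa1, kappa2, theta) and analyses it with **Poincaré maps, Floquet
  multipliers (variational/monodromy equation), stimulus bifurcation sweeps
  and amplitude–frequency locking scans** (`dynamics_analysis`);
- rewrites the dynamics as **two phase-coupled oscillators**, extracting the
  coupling function g(theta, phi) on a grid and validating the reduced phase
  model against the full network (`phase_reduction`);
- implements the **Gaussian-mixture mean-field theory** (closed-form gain
  `1/sqrt(1 + (pi/2) Delta^2)`), hand-designed reduced models (3-population
  two-stimulus, 5-population four-stimulus, rank-1 rate-coding,
  phase-precession), finite-size sampling, and variational mixture fitting
  to trained connectivity (`meanfield_models`).

## CLI

```bash
oscmem generate-data --seed 1 --out run/      # synthetic reference segments
oscmem train         --seed 1 --out run/      # BPTT training -> checkpoint.h5
oscmem stability     --out run/               # limit cycles + Floquet + bifurcation
oscmem scan          --out run/               # amplitude/frequency locking map
oscmem reduce        --out run/               # coupling function + phase model
oscmem meanfield --model two_stim --out run/  # designed mixture + sampled net
oscmem fit-mixture   --out run/               # GMM fit to trained connectivity
oscmem report        --out run/               # PNG figures from artifacts
```

All stages accept `--config cfg.yaml` (see `oscmem.cli_io.DEFAULT_CONFIG`
for the schema) and write a manifest (config hash, seeds, version) next to
their artifacts; reruns with the same config and seed are bit-identical.

## Layout

```
src/oscmem/
  reference_signals.py   synthetic theta references + preprocessing chain
  task_generator.py      phase-coding trials, train/validation splits
  rnn_core.py            low-rank RNN, NumPy BPTT + Adam, canonical form
  dynamics_analysis.py   kappa fields, Poincaré/Floquet, bifurcation scans
  _kappa_kernels.py      numba fixed-step integrators (RK4/Euler + monodromy)
  phase_reduction.py     coupling-function extraction, two-phase model
  meanfield_models.py    Gaussian-mixture mean field, designed models, fits
  cli_io.py              CLI, YAML config, manifests, report figures
```
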