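# modemix

Dynamic functional networks in multivariate time series, modelled as a
**time-varying linear mixture of modes** rather than a sequence of mutually
exclusive states.

Electrophysiological recordings (MEG/EEG source time courses and comparable
multichannel signals) switch between large-scale spatial patterns on
sub-second time scales. The standard tool, a hidden Markov model (HMM),
assumes exactly one state generates the data at each instant and has a memory
of a single time step. `modemix` implements a generative model that drops
both assumptions:

```
x_t ~ N(m_t, C_t),      m_t = Σ_j α_jt µ_j,      C_t = Σ_j α_jt D_j
α_t = softmax(θ_t / τ)
θ_t | θ_1:t-1 ~ N(µ_θt, σ²_θt),   (µ_θt, σ_θt) = heads(LSTM(θ_1:t-1))
```

Each *mode* j is a static spatial pattern (mean µ_j, covariance D_j). The
simplex-valued mixing coefficients α_t let modes co-activate, and their
recurrent prior (a unidirectional LSTM, the *model RNN*) gives the latent
dynamics a long memory. Inference is amortised variational Bayes: a
bidirectional LSTM (the *inference RNN*) maps each data window to a Gaussian
posterior over the logits θ_t, trained by minimising the variational free
energy F = −LL + KL with single reparameterized posterior samples, KL
annealing and Adam. Covariances are Cholesky-parameterised (softplus + ε
diagonal) so they stay positive definite; the softmax temperature τ is
trainable and controls how mixed or exclusive the modes are.

The package also ships:

- `modemix.simulate` — the validation simulators: a hidden semi-Markov model
  (gamma lifetimes, no self-transitions) and a soft mixture driven by
  sine-wave logits, both with multivariate-normal emissions;
- `modemix.prepare` — time-delay embedding, PCA and standardisation for real
  recordings;
- `modemix.baseline_hmm` — a Gaussian-observation HMM baseline (Baum–Welch,
  Viterbi, generative sampling);
- `modemix.posthoc` — trace-weighted mixing coefficients, GMM activation
  detection, lifetime/interval/occupancy statistics, mode matching, dice,
  affine-invariant Riemannian distances, mixing-course PSDs, regression
  spectra and sign-flip max-statistic evoked-response tests;
- `modemix.runner` — the two end-to-end simulation studies.

All numerics (including the LSTM training) run on a small in-repo
reverse-mode autodiff core over NumPy; no deep-learning framework is
required.

## Worked example

```python
from modemix import StudyConfig, run_simulation1

report = run_simulation1(StudyConfig(study="simulation1", seed=1))
print(report["dice_mixture"], report["dice_hmm"])
# 0.9969140625 0.99765625
print(report["sampled_lifetimes_mixture"])
# {'ks_gamma': 0.176, 'ks_geometric': 0.198, ..., 'ks_gamma_truth': 0.154}
print(report["sampled_lifetimes_hmm"])
# {'ks_gamma': 0.014, 'ks_geometric': 0.014, ..., 'ks_gamma_truth': 0.288}
```

This simulates 25,600 samples of 11-channel data from a 3-state hidden
semi-Markov model whose state lifetimes are gamma distributed (shape 5,
scale 10 — mean 50 samples), then trains the mixture model and the baseline
HMM on it. Both models recover the hidden state course almost perfectly
(dice ≥ 0.99 against ground truth after Hungarian matching). The difference
appears in the *generative* direction: a long sample from the trained mixture
model has a lifetime distribution closer to a gamma law than to a geometric
one (`ks_gamma < ks_geometric`, and `ks_gamma_truth < ks_geometric` against
the true gamma), i.e. the recurrent prior learnt long-range temporal
structure — whereas the sampled HMM lifetimes are geometric by construction
(`ks_geometric` ≈ 0.01 but `ks_gamma_truth` ≈ 0.29).

The second study (`run_simulation2`) simulates genuinely co-activating modes
(sine-wave logits through a softmax) and compares how well each model
reconstructs the time-varying covariance C_t: the mixture model's mean
affine-invariant Riemannian distance to the ground-truth C_t is smaller than
the HMM's, whose mutually exclusive states cannot represent a blend.

A thin CLI wraps the same functions:

```bash
modemix simulate --kind hsmm --seed 1 --out data.h5
modemix train --data data.h5 --out run/
modemix hmm --data data.h5 --n-states 3 --out hmm/
modemix study simulation1 --seed 1 --out study/
```

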