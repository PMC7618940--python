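# Methods

## Generative model

Observed data x_t (n channels) are modelled as multivariate normal with
instantaneous moments formed by linearly mixing J static modes:

    m_t = Σ_j α_jt µ_j,    C_t = Σ_j α_jt D_j,    Σ_j α_jt = 1,  α_jt ≥ 0.

The mixing coefficients are a temperature-scaled softmax of unconstrained
logits, α_t = softmax(θ_t / τ). The logits follow a recurrent prior: a
single-layer unidirectional LSTM reads the logit history θ_1:t−1 and two
affine heads emit the mean and (softplus-positive) standard deviation of
θ_t. Because the LSTM carries state across the whole window, the prior can
represent dependencies far beyond one step — this is what lets the trained
model *generate* non-geometric state lifetimes, which a Markov chain cannot.

Mode covariances are parameterised by flat Cholesky vectors: the diagonal of
each factor passes through a softplus plus ε = 1e-6, so D_j = L_j L_j′ is
strictly positive definite for any parameter value. Mode means are frozen at
zero by default (the simulations are zero mean; for time-delay-embedded real
data the spectral information should live in the covariances) and can be
enabled per config. The temperature τ is a trainable positive scalar
(softplus parameterisation, initialised at 1): low values drive the modes
towards mutual exclusivity, high values towards a soft blend.

## Inference

A bidirectional LSTM maps a data window x_1:N to a diagonal-Gaussian
variational posterior q(θ_t) = N(m_θt, s²_θt) at every time point (amortised
inference: the network's weights are shared over all windows). Training
minimises the variational free energy

    F = −LL + a(e) · KL

per batch of windows, with a single reparameterized sample path
θ_t = m_θt + s_θt ⊙ ε per window: the log-likelihood term evaluates the data
under the mixture moments of the sampled path, and the KL term is the
closed-form diagonal-Gaussian divergence between the posterior and the
recurrent prior fed that same sampled path. The KL sum starts at the second
time point of each window — the first has no recurrent history (the
generative sampler uses N(0, I) for its first step for the same reason).
The annealing factor a(e) = ½[tanh(A_s (e/n_AE − ½)) + 1] rises from ≈0 to 1
over n_AE epochs (sharpness A_s = 10), reaching exactly 1 afterwards; it
keeps the posterior from being pulled onto the prior before the observation
model has learnt anything.

Optimisation is Adam (the de-facto stochastic gradient method for
variational autoencoders) with optional global-norm gradient clipping.
Windows are non-overlapping, remainder samples are dropped during training,
and the bidirectional pass never sees across window boundaries. The
log-likelihood is summed per window (not averaged per time point); with the
closed-form KL summed the same way the two terms are on a common scale.
Optionally several short multi-start runs race from different
initialisations and the lowest-loss start trains to completion.

All of this runs on a small in-repo reverse-mode autodiff core
(`modemix._autodiff`): elementwise ops, matmul, softmax, an LSTM kernel with
hand-derived backpropagation-through-time, a Cholesky-fill kernel, and a
fused mixture-Gaussian negative log-likelihood whose gradients with respect
to mixing coefficients, means and covariances are computed analytically.
Every custom kernel's gradient is validated against central finite
differences in the test suite.

### Initialisation

Mode covariance initialisation decides whether the modes separate at all.
With all covariances initialised near identity, the gradient pressure on
each D_j is identical up to jitter and training reliably collapses to a
single effective mode (constant α, one covariance absorbing the global
covariance). The default is therefore a *data-split* initialisation: the
time axis is divided into J contiguous blocks and each D_j starts at the
covariance of one block (plus small jitter). Blocks over-represent different
latent regimes, which breaks the symmetry with realistic scales;
identity-plus-jitter remains available per config. The same consideration
applies to the baseline HMM, whose states are initialised from the
covariances of random data windows. LSTM and head weights use Glorot-uniform
initialisation with forget-gate biases at 1.

## Simulators

*Hidden semi-Markov study.* 3 states, 11 channels, 25,600 samples. State
lifetimes are gamma(shape 5, scale 10) draws — mean 50 samples — rounded to
the nearest integer and floored at one sample; the transition matrix has a
zero diagonal (uniform over the other states by default), so durations come
entirely from the gamma law. Mode means are zero; covariances are random
D = W W′/n + 0.1 I with W a standard-normal square matrix (strictly positive
definite, reproducible from the seed).

*Soft-mixture study.* 6 modes, 80 channels, 25,600 samples. Logits are sine
waves θ_jt = A_j sin(2π f_j t + φ_j) with amplitudes uniform in [1, 2.5] and
phases uniform in [0, 2π), pushed through a softmax to give ground-truth
mixing coefficients. Frequencies are evenly spaced over [0.5, 2] cycles per
1000 samples: random frequency draws can nearly coincide, which makes two
modes' logits collinear and the mixture unidentifiable for *any* inference
method, so distinct spacing is part of the study definition.

*Lifetime-law comparison.* Whether a trained model's generative side has
learnt long-range structure is judged on the segment lengths of a long
(102,400-sample) argmax state course sampled from it: two-sample
Kolmogorov–Smirnov distances are computed against large draws from an
ML-fitted gamma, an ML-fitted geometric, and the ground-truth gamma — each
*discretised* (rounded, floored at one sample) so the integer-valued
lifetimes are treated symmetrically; a one-sample KS against a continuous
gamma but a discrete geometric systematically favours the gamma. A mixture
model with memory shows `ks_gamma < ks_geometric`, while a sampled HMM
course is geometric by construction and far from the ground-truth gamma.
A caveat the tests make visible: the learned memory is qualitative — the
sampled lifetimes are non-geometric, but their fitted gamma shape is around
1.2 rather than the generating 5.

What these simulators emulate is the latent structure the model targets —
long-memory exclusive dynamics and genuinely co-activating spatial
covariance patterns. They do not emulate measurement noise, non-Gaussian
artefacts, spectral content within modes, or inter-subject variability, so
passing tests demonstrate correct inference under the model's own
assumptions, not performance on raw recordings.

## Baseline HMM

A Gaussian-observation HMM (means frozen at zero by default for parity)
fitted by scaled Baum–Welch, with Viterbi or posterior decoding and Markov
chain sampling. EM stops at a relative log-likelihood change of 1e-6 or 200
iterations. A state whose responsibility mass collapses below n+1 samples is
re-seeded from a fresh random data window rather than producing a degenerate
covariance; near-singular covariance updates receive diagonal jitter with a
warning.

## Post-hoc statistics

- **Trace-weighted mixing**: α̃_jt = α_jt Tr(D_j) / Σ_k α_kt Tr(D_k), a
  simplex-preserving reweighting that reflects each mode's actual
  contribution to C_t.
- **Activation detection**: a two-component univariate Gaussian mixture per
  mode; a time point is active when the higher-mean component's
  responsibility exceeds 0.5. Applied to the weighted-normalised mixing
  series. Near-constant series are marked never-active with a warning.
- **Summary statistics**: lifetimes (contiguous active runs), intervals
  (inactive gaps between activations) and fractional occupancy, in seconds
  given a sampling frequency.
- **Mode matching**: Hungarian assignment maximising summed time-course
  correlations (or covariance RV coefficients).
- **Dice coefficient**: computed after argmax binarisation of soft mixtures
  and Hungarian matching; for mutually exclusive courses it equals the
  fraction of agreeing time points.
- **Riemannian distance**: the affine-invariant metric
  d(A,B) = √Σ log² λ_i(A⁻¹B), the standard geodesic distance on the SPD
  manifold; eigenvalues floored at 1e-10.
- **Regression spectra**: a Hann-tapered spectrogram (window 2·fs samples,
  50% overlap, channel-averaged) is regressed per frequency on the
  frame-averaged mixing coefficients with an intercept,
  S_t(f) = P₀(f) + Σ_j α_jt P_j(f) + ε_t(f). Because simplex α makes the
  intercept collinear with the mode columns, the least-squares solution is
  the minimum-norm one; P₀ + P_j (each mode's full spectrum) remains
  identifiable. Reconstruction error is reported per frame as a percentage
  of frequency-averaged power.
- **Evoked responses**: trials are epoched around events, baseline-corrected
  by their pre-event mean and averaged; significance uses a sign-flip
  permutation test whose null is the maximum |t| across time points within
  each permutation, controlling the family-wise error rate across time
  per mode (1000 permutations by default, seeded).

## Study problem sizes

The full-scale studies (runner defaults) use the simulation conditions above
with training at sequence length 200, 64 hidden units in each RNN, 200
epochs, batch 16, learning rate 0.01 and KL annealing over 100 epochs. The
test suite runs study 1 at full scale and study 2 at a reduced size chosen
as the package's test-scale configuration — 40 channels, 25,600 samples, 100
epochs (annealing 50) — which preserves the study's qualitative conclusions
while keeping the suite quick; `run_simulation2()` with defaults reproduces
the full-scale setting.

## Numerical choices and limitations

- Standardisation uses the population (not sample) standard deviation;
  PCA projects onto leading covariance eigenvectors without whitening.
- Time-delay embedding uses a symmetric lag window centred on lag 0
  (configurable), trimming edge samples without full context.
- Free-energy evaluation inverts each mixed covariance C_t directly
  (dimensions here are ≤ 80); a non-positive-definite C_t raises an error
  naming the offending window positions.
- Seeds fan out from a single study seed through `numpy` SeedSequence
  spawning, so every report is bit-reproducible given its config.
- The Riemannian-distance gap between the mixture model and the HMM on the
  soft-mixture study depends strongly on how far apart the random mode
  covariances are; with the D = W W′/n + 0.1 I construction the gap is a
  clear, highly significant ordering rather than an order of magnitude.
- On the soft-mixture study, recovery quality per mode tracks that mode's
  sine amplitude: strong modes (amplitude ≳ 1.9, mixing std ≈ 0.2) are
  recovered essentially exactly at the test scale, while the weakest mode
  (amplitude ≈ 1.0, mixing std ≈ 0.10) needs more channels and training than
  the test-scale configuration provides — its time-course correlation
  improves steadily with data volume and epochs but does not reach the
  strong-mode level. The corresponding acceptance test asserts full recovery
  for every mode and therefore documents this as an open gap at test scale.
- The HMM baseline uses a multivariate-normal observation model throughout;
  autoregressive observation models, hierarchical subject models and
  coherence-based connectivity are out of scope.
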