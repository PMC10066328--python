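# Methods

## Model and procedure

The learner is a bias-free fully connected softmax classifier whose hidden
layers use the softplus activation `softplus_beta(z) = log(1 + exp(beta z)) / beta`.
Softplus (rather than ReLU) is required because the meta-gradient
differentiates the adaptation loop a second time: the error-propagation step
already contains `sigma'(z)`, so the activation must be twice
differentiable. `beta = 10` everywhere; the activation and the softmax are
computed in log-sum-exp stable forms.

Feedback matrices `B` carry errors backward. In BP mode `B` is a dynamic
view of `W^T`, re-read on every backward pass so the propagated signals are
the exact loss gradients of the *current* weights; in FA mode `B` is drawn
independently of `W` at episode start and held fixed. Both `W` and `B` use
Glorot/Xavier initialization; the uniform variant was chosen (the normal
variant would be equally defensible, and nothing downstream depends on the
difference). No biases, dropout, or normalization layers exist anywhere —
the plasticity rules define the entire learning dynamics.

Within one adaptation step the full error trace is computed from the
pre-update weights and all layers are then updated together. This matches
the update ordering of the meta-learning algorithm as written (each `e_l` is
formed before the weight it feeds is touched) and makes BP mode with only
the pseudo-gradient term exactly equivalent to plain online SGD, which the
test-suite verifies step-for-step against an independent implementation.

The synthetic input-layer error is `e_0 = B_{1,0} e_1 ⊙ (1 - exp(-beta y_0))`.
The elementwise factor equals `sigma'(z_0)` exactly when `y_0 = softplus(z_0)`
(an identity the tests assert to 1e-10), i.e. `e_0` treats the input as if
it were the output of a softplus layer. `e_0` exists only so that first-layer
updates of terms needing a pre-synaptic error are defined; it never updates
anything by itself. In the identity-activation (linear) network used by the
feedback-correlation diagnostic the factor is 1, since the derivative being
emulated is that of the identity.

## Meta-optimization

Each episode: draw a task, re-initialize `W` and `B`, run one online epoch
(batch size one, `M*K` steps), evaluate the meta-loss (mean query
cross-entropy + `lambda * ||Theta||_1`) and take one ADAM step on Theta
(step size 1e-3, moments 0.9/0.999, epsilon 1e-8 — the original defaults,
as the protocol leaves them unstated). The L1 subgradient at exactly zero is
taken as zero, the convention of gradient-based deep-learning frameworks.

The gradient of the meta-loss with respect to Theta is exact, not
approximated: every inner-loop quantity carries a stack of directional
derivatives (forward-mode accumulation), one per active coefficient. With at
most ten coefficients this costs a small constant factor over the plain
loop and O(1) memory in the number of unrolled steps — no truncation of the
unrolled graph is ever needed, so the full 250-step episodes are
differentiated end to end. The tangent arithmetic is validated against
central finite differences to 1e-4 relative error in both feedback modes
(in practice it agrees to ~1e-8, the finite-difference noise floor).

Episodes whose weights become non-finite (possible for aggressive
coefficient settings of the higher-order pool terms) are aborted: the
episode is recorded with NaN loss and the Theta update is skipped; the run
continues. Coefficients are unconstrained reals — meta-learning is free to
choose signs, and in practice it does (e.g. the Hebbian-error coefficient
converges negative under this parameterization, which is the direction that
pushes `W` toward `B^T`).

Reproducibility: every random draw derives from integer keys through
`numpy.random.SeedSequence` — episode `eps` of a run with `trial_seed` uses
`(trial_seed, eps, 0)` for weights and `(trial_seed, eps, 1)` for the task
draw; trial `t` of a multi-trial experiment uses `(base_seed, t)`. Identical
configurations therefore reproduce bit-identical histories on a platform.

## Tasks

Episodes are M-way K-shot classification streams: M classes drawn without
replacement from the class pool, K train and Q query items per class
(disjoint), labels relabeled `0..M-1`, pixels scaled to `[0, 1]` with no
mean-centering. Full-scale protocol: M=5, K=50, Q=10 (250 online samples),
47-class pool, 784-170-130-100-70-47 network, 600 episodes (500 for the
per-layer assignment sweep, angles averaged after a 100-episode burn-in),
20 trials, percentile-bootstrap 98% confidence bands from 500 resamples.

The synthetic generator gives each class a fixed prototype (dense uniform
pattern by default, or sparse Gaussian-bump "glyphs") and adds elementwise
Gaussian noise (scale 0.2 by default), clipped to `[0, 1]`. The defaults
were calibrated once so that a backprop learner at the standard initial
learning rate (1e-3) reaches well-above-chance query accuracy (~0.64 mean,
chance 0.2) within one 250-sample episode — the same "learnable online, but
only by a good rule" regime as the real handwritten-character benchmark —
and were not revisited. What the generator does **not** emulate: the
manifold structure of handwriting (strokes, deformations, within-class style
variation correlated across pixels), class imbalance, and label noise.
Passing the scaled tests therefore shows that the *mechanisms* (alignment
via the Hebbian error term, orthonormalization via Oja's rule, the BP/FA
gap) operate as described, not that accuracies on real data are matched.

## Diagnostics

* **Alignment angle.** For each layer, the angle between the error signal
  the rule's own feedback pathway produces and the signal backprop would
  produce from the same forward pass and the same `e_L`. The top-layer angle
  is identically zero by construction and is reported as exactly 0. Angles
  are computed per training sample and averaged within the episode;
  zero-norm vectors are excluded from the average rather than imputed (an
  imputation at 90° would bias early-training averages). Whether the
  original protocol probes training or query samples is not recorded
  anywhere; per-training-sample averaging was chosen and is used
  consistently.
* **Orthonormality error.** `E_W = ||z_l - W (W^T sigma(z_l))||^2` per
  hidden layer, averaged within episodes like the angles; the softmax output
  layer is excluded.
* **Feedback correlation (linear networks).** With identity activations,
  random inputs, and uniform labels, the sample mean of `e_l e_{l-1}^T`
  correlates positively with `B_{l,l-1}^T` (cosine ~0.3–0.7 at 1e5 samples
  on a 6-5-4-3 network, by an independent calibration run). The statement is
  asserted only for linear networks; it is outside its assumptions
  otherwise.
* **Surviving-term count.** A coefficient counts as surviving if
  `|theta_r| >= 10%` of `max_r |theta_r|` at the final episode — a
  scale-free criterion robust to the overall learning-rate magnitude.

## Problem sizes used in the test-suite

The qualitative reproductions run on a 64-40-30-20-5 network (same depth as
the full model, 5-way tasks, K=10, 100 episodes, 5 trial seeds) — sizes at
which the BP≫FA gap, the angle reduction from the Hebbian error term, and
the `E_W` reduction from Oja's rule are all unambiguous. The sparsification
check uses a 32-16-10-4 network with the 10-term pool across
`lambda ∈ {0, 0.01, 0.1}`. The exact `lambda` of the full-scale pool
experiment is not part of the recorded protocol; the `pool-bench` preset
defaults to 1e-3 and exposes it in configuration.

## Known limitations

* The per-layer assignment sweep meta-learns its two shared coefficients
  with `lambda = 0`; whether the original sweep fixed or learned them is
  not recorded. This is an assumption of the preset.
* Forward-mode differentiation scales linearly in the number of active
  coefficients; it is the right trade-off for ≤10 meta-parameters but would
  not be for rule families with thousands.
* The locality property (entry `(j,k)` of the update depends only on that
  synapse's own signals) holds strictly for terms 0–4; terms 5–9 contain
  sums over other post-synaptic or pre-synaptic indices, so the tests assert
  strict locality only for the first five.
* Feedback matrices are never plastic; only the forward weights learn.
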