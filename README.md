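# metaplast

Meta-learning of interpretable synaptic plasticity rules for deep networks
trained through fixed random feedback pathways.

## The problem

Backpropagation updates a weight `W_{l-1,l}` with an error signal carried by
the transpose of the downstream forward weights — a "weight transport" that
biological circuits cannot perform. Random feedback alignment replaces
`W^T` with fixed random feedback matrices `B`, which is biologically
plausible but learns poorly in deep networks fed an online stream of few
samples. This package implements a meta-learning framework that *discovers*
plasticity rules closing that gap, and the diagnostic instruments that make
the discovered rules interpretable.

## The model

A bias-free fully connected classifier (softplus hidden layers with
smoothness `beta = 10`, softmax output):

    z_l = W_{l-1,l} y_{l-1},      y_l = softplus_beta(z_l)

Teaching signals start from `e_L = dL/dz_L` (cross-entropy) and flow through
feedback matrices:

    e_{l-1} = B_{l,l-1} e_l ⊙ sigma'(z_{l-1})

with `B = W^T` (backprop, "BP") or fixed random `B` (feedback alignment,
"FA"). A synthetic input-layer error `e_0 = B_{1,0} e_1 ⊙ (1 - exp(-beta y_0))`
extends the recursion one step past the input.

Weight updates are a linear combination of ten candidate plasticity terms
built only from signals local to each synapse (pre/post activations `y`,
pre/post errors `e`, and the current weight):

    W ← W + Σ_r θ_r F^r(y_pre, y_post, e_pre, e_post, W)

The pool includes the pseudo-gradient term `F^0 = -e_l y_{l-1}^T`, a Hebbian
error term `F^2 = -e_l e_{l-1}^T`, Oja's subspace rule
`F^9 = y_l y_{l-1}^T - (y_l y_l^T) W`, and seven further candidates
(see `metaplast.plasticity`).

**Meta-learning (outer loop).** Each episode draws a fresh M-way task
(K train + Q query samples per class), re-initializes all weights, trains
online (batch size one, single epoch) with the current rule, and evaluates
the meta-loss on the query set:

    L_meta(Θ) = CE(f_W(X_query), Y_query) + λ ||Θ||_1

One ADAM step per episode descends the *exact* gradient of `L_meta` with
respect to Θ, obtained by differentiating through the entire unrolled
adaptation loop (implemented as forward-mode differentiation over the ≤10
coefficients; the activation is differentiated twice in the process). The L1
penalty drives superfluous coefficients to zero, so the surviving terms form
a small, interpretable rule.

**Diagnostics.** Per layer: the alignment angle `alpha_l` between a rule's
teaching signal and the true backprop gradient signal, and the
orthonormality error `E_W = ||z_l - W (W^T sigma(z_l))||^2`, a proximity
measure to the Oja fixed point `W W^T = I`.

## Worked example

All experiments run on a built-in synthetic task generator (a pool of ≥20
image classes with prototype-plus-noise structure), so nothing is
downloaded. The scaled presets use a 5-layer 64-40-30-20-5 network, 5-way
episodes with 50 online training samples, and 100 meta-optimization
episodes:

```bash
metaplast meta-train --preset bp-scaled  --trials 3 --seed 0 --out runs/bp
metaplast meta-train --preset fa-scaled  --trials 3 --seed 0 --out runs/fa
metaplast meta-train --preset oja-scaled --trials 3 --seed 0 --out runs/oja
```

printed (final-episode meta-accuracy, mean over 3 trials):

    final meta-accuracy (mean over 3 trial(s)): 0.627   # backprop
    final meta-accuracy (mean over 3 trial(s)): 0.240   # feedback alignment
    final meta-accuracy (mean over 3 trial(s)): 0.207   # FA + Oja term

Backprop trains well online while feedback alignment stays near chance
(0.2) at this episode budget — the gap the discovered rules are meant to
close. The per-episode CSV written for each trial shows *how* a rule works;
for the Oja run (`runs/oja/trial_000.csv`):

    episode  meta_accuracy  theta_0  theta_9  alpha_3    EW_2    EW_3
          0           0.02   0.0010   0.0000  87.5539  9.8970  2.9713
         50           0.18   0.0087  -0.0073  85.4784  1.9622  0.6547
         99           0.16   0.0114  -0.0077  92.1700  1.2190  0.5532

Meta-learning grows the learning rate `theta_0` and recruits the Oja
coefficient `theta_9`; the orthonormality error `EW` of the compression
layers falls by an order of magnitude while the alignment angle `alpha_3`
stays near 90° — Oja's rule helps by improving the forward features, not by
aligning the backward signals. The Hebbian-error preset (`ehebb-scaled`)
shows the complementary signature: `alpha` falls while `EW` does not.

The full-scale presets (`bp-bench`, `fa-bench`, `pool-bench`, `ehebb-bench`,
`oja-bench`, `bio-bench`) use the 784-170-130-100-70-47 architecture with
K=50/Q=10 episodes for 600 episodes; pass `--data-dir` with IDX-format
image/label files to run them on a real 47-class handwritten-character
dataset instead of the synthetic source.

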