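# Methods

## The adversarial model

The generator treats frame synthesis as sequence generation: a latent
vector z of length 1000 (default `uniform01`, i.e. U[0,1] per entry; a
`gaussian` option exists because both conventions are common for this
model family) is consumed one scalar per time step by a stack of two
peephole LSTM layers with 128 units.  The recurrent cell implements

    i_t = σ(W_ix x_t + W_ih h_{t−1} + w_ic ∘ c_{t−1} + b_i)
    f_t = σ(W_fx x_t + W_fh h_{t−1} + w_fc ∘ c_{t−1} + b_f)
    o_t = σ(W_ox x_t + W_oh h_{t−1} + w_oc ∘ c_{t−1} + b_o)
    c_t = f_t ∘ c_{t−1} + i_t ∘ tanh(W_cx x_t + W_ch h_{t−1} + b_c)
    h_t = o_t ∘ tanh(c_t)

with elementwise (diagonal) peephole weights initialized to zero and the
forget bias to one; all gates read the *previous* cell state, including the
output gate.  States are zeroed at the start of every sequence; no
statefulness across batches.  The (1000 × 128) output sequence is flattened,
mapped by a fully connected layer to width 1000, reshaped, and mapped by a
second fully connected layer to the 500-sample frame, squashed by tanh.
Batch normalization sits before each activation (leaky-ReLU, slope 1e-4)
and dropout 0.5 after it, between layers only — not inside the recurrent
connections.

The critic compresses a 500-sample frame with a 256-unit dense layer, then
four convolutions (filters 8/16/32/64, kernel 3, stride 2, pad 1) that
halve the length 256 → 128 → 64 → 32 → 16, each followed by batch
normalization, leaky-ReLU (slope 1e-4) and dropout 0.5, and a dense head to
one score.  Under the `bce` loss the head ends in a sigmoid (a
probability); under `wgan`/`wgan_gp` the head is linear — a bounded critic
caps the Wasserstein gradient, so the training loop switches a sigmoid spec
to linear automatically.  Batch normalization in the critic is kept for
fidelity to the architecture this package implements even though WGAN-GP
practice often omits it; `CriticSpec(batchnorm=False)` is the ablation
switch.

### Losses and schedule

`wgan_gp` (default): critic minimizes mean D(fake) − mean D(real) + GP,
generator minimizes −mean D(fake).  The gradient penalty is
λ·mean[(‖∇_x̂ D(x̂)‖₂ − 1)²] with λ = 10, evaluated at per-sample uniform
interpolates x̂ = ε·real + (1−ε)·fake (`gp_mode="interpolate"`); the
`"fake"` mode evaluates the penalty at the generated batch instead, for
comparison with formulations that write the expectation over the generator
distribution.  A constant 1e-16 inside the norm's square root keeps the
derivative finite when the gradient vanishes; it biases the penalty by less
than 1e-6 of λ.  `bce` uses cross-entropy with real labelled 1, fake 0,
and log-clipping at 1e-7.

Training alternates exactly five critic steps per generator step (counted
in optimizer steps, with the counter carrying across epochs so the ratio is
exact globally).  Real batches are drawn without replacement within an
epoch and reshuffled per epoch from the run seed; an epoch is one pass over
the training frames.  Adam uses lr 1e-3 and betas (0.5, 0.9) — the
conventional GAN endpoints of the commonly searched range — and the
learning rate at epoch e is lr·0.5^⌊e/50⌋.  Training aborts with a
diagnostic if any loss is non-finite for three consecutive steps.  One
`LossRecord` (epoch-averaged critic loss, generator loss, penalty term,
learning rate) is emitted per epoch; the recorded critic loss includes the
penalty term, which is also reported separately.

### The differentiation engine

All networks run on a small reverse-mode autodiff engine
(`eeggan.autodiff`) whose vector-Jacobian products are themselves built
from engine primitives, so gradients can be differentiated again; the
penalty's parameter gradient (a second derivative through ∇_x D) is exact,
not approximated.  Unit tests verify every layer's gradient and the
double-backprop path against central finite differences.  Float64
throughout; piecewise-linear activations use their almost-everywhere
derivative.

## Preprocessing

NaNs in a raw recording are replaced by the minimum of the valid samples of
that recording (keeps the amplitude range intact; idempotent).  Framing is
contiguous and non-overlapping with the trailing remainder discarded.
Normalization is a pooled z-score — one global mean and one *population*
standard deviation over every entry of the frame matrix — stored for exact
inversion; per-frame normalization is deliberately not used.  The
train/test split draws a seeded permutation and rounds the train count
half-up; the smaller part always comes from the front of the permutation,
so fractions f and 1−f with the same seed produce the same partition with
roles swapped.  CSV input is one signal per row, optional header, empty
cells or any spelling of "nan" as missing; NPY input is 1-D or 2-D.

## Synthetic surrogate frames

Each frame is one random-phase sinusoid per rhythm band — frequency uniform
in the band, amplitude √(2·power) so the sinusoid's expected power equals
the configured relative power — plus 1/f^α noise synthesized by
random-phase spectral shaping (α = 1 by default), and a per-frame amplitude
jitter (relative std 0.1) emulating slow gain drift.  Defaults: bands
delta 0.5–4 Hz (power 1.0), theta 4–8 (0.8), alpha 8–13 (1.2), beta 13–30
(0.6) — alpha-dominant as in resting EEG — and a noise floor of 0.5
relative power, chosen so the broadband background is visible but the
oscillations dominate.  The generator emulates the *spectral* character of
EEG only: no event structure, no cross-channel covariance, no artifacts,
no non-stationarity beyond the jitter.  Tests passing on these frames
therefore validate the machinery (shapes, losses, schedules, metrics,
benchmark bookkeeping) and qualitative training behaviour, not
physiological fidelity.

## Similarity metrics

RMSE and DTW operate on raw amplitude sequences; DTW uses absolute point
distance, the symmetric step pattern, accumulating first row/column and no
band constraint.  The discrete Fréchet distance is computed on planar
curves (sample index, amplitude) by the standard dynamic program — the
min-over-couplings of the max pointwise distance.  A formulation that
takes the minimum over a coupling's distances is sometimes printed for
this quantity, but it is not a curve metric (it is zero whenever the
curves cross); the standard definition matching the metric's stated intent
is implemented instead, as a deliberate correction.  Set-level reports
average over index-matched pairs (`paired_mean`, default) or score each
generated frame against its nearest real frame per metric
(`nearest_real_mean`); reports name the aggregation used.  The spectrogram
helper normalizes each windowed segment's one-sided periodogram so its sum
equals the segment's mean squared (windowed) amplitude — Parseval's
convention, asserted in tests.

## Compressed-sensing benchmark

The sparse binary measurement matrix has exactly `ones_per_column` ones
per column (default 4 — a common sparse-binary sensing density; the source
description does not fix one), with rows drawn from a balanced pool so row
weights stay near-uniform; the M = N, one-per-column case is then an exact
permutation, which the inverse-sanity checks exploit.  The pseudoinverse
is precomputed with `numpy.linalg.pinv`.

CS-ResNet: a 16-filter kernel-3 stem, two residual blocks of six dilated
convolutions (filters 32/64/128/64/32/16, kernels 7/7/5/5/3/3, dilation 2,
ELU, "same" padding), a single-filter kernel-3 head convolution and a
dense output layer.  Two design choices are this package's own: the dense
output layer is zero-initialized and a global residual connection adds the
lifted input to the refinement, so the untrained network *is* the
pseudoinverse-lift baseline and training can only improve on it.  Without
the global skip the refiner must first relearn the identity, and at desk
scale it never catches the lift (measured PRD above 100% versus ~49% for
the lift alone at CR 90%).  The reconstructor trains under MSE with Adam
(lr 1e-3, betas 0.9/0.999, batch 64, epochs configurable; defaults are
desk-scale).  The `plain_cnn` architecture — the same stack without any
skip — is a synthetic stand-in comparison network, not a faithful copy of
any published baseline.

The augmentation benchmark trains one reconstructor per (CR, fraction)
cell on the real training frames plus the first f% of the generated pool,
and reports mean test PRD.  Improvement deltas are baseline minus
augmented, *truncated* (not rounded) to two decimals — the convention the
bundled reference grids follow (e.g. 3.7965 → 3.79).  `eeggan.reference`
bundles the published PRD grids for a CNN and a CS-ResNet reconstructor at
CR 10–90% and fractions 0–100%, and recomputes every stated improvement
range from the raw cells; all eight range statements reproduce exactly
under the truncation convention.

## Desk-scale problem sizes

The full-size configuration (500-sample frames, 1000-step LSTM, 1000
epochs, 29k-frame corpora) is the method's intended deployment; the test
suite and acceptance script run reduced sizes chosen once as this
package's demo scale (`eeggan.presets`): 100-sample frames, 100-step LSTM
with 16 units, 320 single-band frames, 150 epochs for adversarial smoke
runs; a CS-ResNet with 8-filter stem and 16/32/64/32/16/8 blocks on
length-100 signals, 10 epochs, for the benchmark.  Stochastic properties
(loss contraction, augmentation direction) are asserted by majority over
three seeds.

## Known limitations

- The tanh output bounds generated amplitudes to (−1, 1), while
  pooled-normalized oscillatory frames exceed ±1; matching the real pooled
  std of 1.0 requires near-saturated outputs.  At the reduced smoke scale
  (150 generator updates) the generated pooled std reaches ≈ 0.37–0.53
  across seeds — moving toward but not always within a factor of two of
  the real value; the corresponding drift test documents this gap.
- Similarity values at desk scale are not comparable to full-scale
  published figures; only directions and contracts are.
- Batch statistics in the critic couple samples within a batch; the
  penalty is computed with the critic in training mode, so the penalty's
  batch-statistic dependence is differentiated through rather than frozen.
- The CLI's GDF/real-data path is limited to whatever arrays the caller
  produces; no artifact rejection or filtering is provided (acquisition
  hardware concerns, not method steps).
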