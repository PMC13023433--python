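# Methods

This note documents the models and procedures implemented in `mibci`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## The decoding model

A trial is a matrix `X ∈ R^{C×T}` of C EEG channels by T samples (default
22 × 1000: four seconds at 250 Hz). The decoder is a three-stage hybrid:

1. **Spatial–spectral encoder.** Four 1-D convolution blocks
   (conv → batch-norm → ReLU → max-pool → dropout) with channel widths
   22→32→64→128→128 and kernel 5 (≈20 ms, matched to sensorimotor rhythm
   periods). Convolutions are stride-1 with length-preserving (half-kernel)
   padding; *all* temporal reduction comes from the pool of size 2 with
   floor division. This is the only reading under which a 1000-sample trial
   maps to the feature length T′ = ⌊⌊⌊⌊1000/2⌋/2⌋/2⌋/2⌋ = 62 that the rest
   of the architecture (and its parameter budget) presumes.
2. **Temporal encoder.** A two-layer bidirectional LSTM with d_h = 128
   hidden units per direction over the T′ feature frames. Forward and
   backward states are concatenated per frame: `h_t = [→h_t; ←h_t] ∈ R^{2d_h}`.
   Each gate block carries two bias vectors (input-side and hidden-side).
3. **Patch Transformer.** The T′ × 2d_h sequence is cut into
   N = ⌊(T′−p)/s⌋+1 overlapping patches (p = 24 frames, stride s = 12, so
   N = 4), each flattened time-major, affinely projected to d = 128
   dimensions (`z_i = W_e · vec(P_i) + b_e`), layer-normalized, and summed
   with non-learned sinusoidal positional encodings. L = 2 pre-norm encoder
   layers with h = 4 attention heads (d_k = d/h, scaled by 1/√d_k), a GELU
   feed-forward of width 2d = 256, residual connections, and one final
   normalization are followed by mean pooling over tokens and a two-layer
   head (d→d, GELU, d→n_classes) with softmax.

### Parameter accounting

`count_parameters` gives closed-form per-component counts under exactly the
conventions above; for the default configuration:

| component | parameters |
|---|---|
| spatial–spectral encoder | 137,696 |
| temporal encoder (BiLSTM) | 659,456 |
| patch embedding | 786,816 |
| transformer encoder | 265,216 |
| classification head | 17,028 |
| **total** | **1,866,212** |

A test asserts that these closed forms equal the element counts of the
actually allocated parameter arrays for arbitrary configurations.

Conventions that the totals pin down: conv bias *and* batch-norm
scale/shift per block; two bias vectors per LSTM gate block per direction;
tokenizer = projection + bias + one layer norm (positional encodings are
parameter-free); feed-forward width 2d rather than the more common 4d; two
layer norms per encoder layer plus one final; head = two affine maps. The
head nonlinearity does not affect counts; GELU is used and recorded as a
config flag. Where prose-level descriptions of the architecture conflict
with its hyperparameter table (d_h 64 vs 128, 2 vs 4 heads, p/s 10/8 vs
24/12), the table values are used: they are the only set consistent with
the component parameter budget.

`estimate_macs` counts multiplies only (convolution, recurrence,
projections, attention score/value products, feed-forward, head);
normalizations, activations and softmax are excluded. The default
configuration totals ≈0.074 GMAC per trial. This estimate is the
deterministic latency surrogate used in architecture search; it is an
accounting convention, not a hardware measurement.

## Automatic differentiation

The network, its training, and the meta-learning engine run on a small
tape-based reverse-mode autodiff over numpy arrays (`mibci._autodiff`).
Every vector–Jacobian product is itself written in differentiable
primitives, so gradients can be differentiated again; second-order
meta-gradients fall out of the same machinery. Gradient correctness is
tested against central finite differences for every primitive and for the
composed network, and linear operators (unfold/fold, gather/scatter) are
tested via the adjoint identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩.

## Preprocessing

The conditioning chain mirrors standard motor-imagery practice: zero-phase
4th-order Butterworth band-pass (4–40 Hz) on continuous data, optional
50 Hz IIR notch, polyphase resampling to 250 Hz, epoching around cue
events with baseline correction, ±100 µV amplitude rejection (strict
inequality at the boundary, applied after filtering, in the order the
chain runs), joint-probability rejection, per-trial per-channel z-scoring,
and channel selection. All operations are pure and carry provenance
history.

The joint-probability criterion is stated in the literature without a
formula; here it is made concrete as: per channel, an empirical density
over all trials pooled (histogram, Freedman–Diaconis bins clamped to
[10, 200]); per trial, the statistic −mean log p̂ of its samples averaged
over channels; single-pass rejection of trials above mean + 3 SD. On
i.i.d. Gaussian trials this flags ≲5%; a planted 10× amplitude outlier is
flagged reliably.

Baseline correction subtracts the pre-cue mean when the epoch window
starts before the cue and the whole-trial mean otherwise (the zero-start
window leaves no pre-cue segment; recorded as a config flag).

## Synthetic ERD benchmark

Real benchmark recordings are optional external inputs; the bundled
generator produces data realizing the assumptions the decoder targets:

* 22-channel 10–20-style montage, 250 Hz, 4-s trials, four classes
  (left hand, right hand, feet, tongue), balanced, multi-subject.
* Four source groups — left-central, right-central, midline-central,
  fronto-central — project band-limited mu (8–13 Hz) and beta (14–30 Hz)
  rhythms through per-subject topographies (group channel weights,
  unit-normalized). Channel-group membership is configuration, not code.
* **ERD:** after 0.5 s of pre-cue rest, the class-targeted source's rhythm
  amplitude is multiplied by (1 − erd_depth) with a 100 ms raised-cosine
  ramp. Left-hand imagery targets the right-central source, right-hand the
  left-central, feet the midline, tongue the fronto-central group. Power
  therefore drops by ≈(1 − erd_depth)²; with the default depth 0.4 the
  post/pre band-power ratio at the targeted channels is ≈0.36 plus the
  in-band noise floor (measured ≈0.5 at 0 dB SNR). Ratios are estimated by
  pooling power across trials before dividing — per-trial ratios of short
  pre-cue estimates are heavy-tailed and biased upward.
* Background noise is spatially correlated 1/f (spectrally shaped, fitted
  log-log slope within ±0.2 of the configured exponent over 1–40 Hz),
  scaled to a configured SNR (default 0 dB against total rhythm power).
* Inter-subject variability: multiplicative rhythm gains
  (SD 0.15) and topography jitter (SD 0.1) per subject.
* Everything is deterministic in (master seed, subject, class, trial) via
  SHA-256 seed fan-out, so datasets are bit-reproducible and adding a
  pipeline stage never shifts another stage's randomness.

What the generator does **not** emulate: ocular/muscle artifacts,
inter-session non-stationarity, volume-conduction mixing beyond fixed
topographies, or realistic class overlap (the class–source assignment is
exact). Passing tests on this benchmark demonstrates that the pipeline's
machinery is correct and that the decoder can exploit ERD structure; it
does not predict accuracy on real recordings.

## Training and evaluation

Supervised training: cross-entropy, AdamW (decoupled weight decay 1e−2 on
matrix-shaped parameters; bias and normalization vectors exempt), batch 32,
gradient-norm clipping at 1.0, linear warm-up over 10 epochs to lr 3e−4,
plateau decay ×0.5 after patience/2 non-improving validation epochs, early
stopping after 10 (validation *loss* is monitored; the choice between loss
and accuracy was open and loss is the stabler signal at small validation
sizes). The best-validation checkpoint is returned.

Protocols: **within-subject** (stratified 50/50 split per subject,
emulating a two-session recording; validation is carved from the training
half), **LOSO** (the held-out subject contributes nothing to training or
validation), and **fine-tuning** (LOSO pretraining, then a few
calibration trials per class from the held-out subject; support and test
are disjoint). Every protocol asserts pairwise disjointness of its index
sets. Statistics on matched per-subject scores: two-sided paired t-test,
two-sided Wilcoxon signed-rank (zeros dropped, exact p for n ≤ 12),
Cohen's d with pooled SD — conventions chosen where the methodology
leaves them unstated. "Independent runs" are realized as seeds derived
deterministically from a master seed.

### Desk-scale presets

The default architecture and regimen target GPU-scale experiments on real
data. For CPU-scale runs on the synthetic benchmark the package provides
presets, used by the test suite and the acceptance script:

* `desk_scale_config()` — same three-stage architecture with narrow conv
  blocks (8→16→16→16), pool size 3 (T′ = 12), one 16-unit BiLSTM layer,
  4-frame patches with 50% overlap, one 2-head encoder layer at d = 32,
  light dropout (0.1); ≈27k parameters.
* `desk_scale_train_config()` — lr 2e−3, 3-epoch warm-up, batch 16,
  30 epochs: with ~100 trials per fit there are only a few dozen updates,
  so the full-scale schedule (3e−4 with a 10-epoch warm-up) cannot leave
  the warm-up phase before the budget ends.
* `desk_scale_meta_config()` — inner lr 0.05 (five inner steps at the
  full-scale 0.01 move a small well-fit network imperceptibly), outer
  AdamW at 1e−3, first-order by default for speed.

With these presets, within-subject decoding on 3 subjects × 40 trials per
class at ERD depth 0.6 reaches ≈0.9 mean accuracy (chance 0.25) in
30 epochs on one CPU, and LOSO accuracy falls at or below the
within-subject mean on average across runs (at this data scale single
splits can invert the ordering, since LOSO folds see more training
trials, and individual LOSO folds vary widely; comparisons therefore
average a few runs).

## Meta-learning

Each subject is a task: a support set (k trials per class) and a query set
(the rest). The inner loop takes `steps` full-batch gradient steps on the
support cross-entropy from shared initialization θ (θ is never mutated;
batch-norm uses support batch statistics during adaptation); the outer
objective is the query loss at the adapted parameters summed over a
meta-batch of 4 tasks. The second-order path differentiates through the
inner trajectory and is the default in the `meta_step` operation; the
first-order approximation stops gradients at the adapted parameters. Both
are verified against hand-derived closed forms on scalar quadratic tasks,
and their meta-gradients agree in the α→0 limit at the theoretically
expected linear rate.

`meta_train` runs a supervised warm start (20 epochs on the pooled
meta-training subjects; switch-over rather than interleaving, the simpler
of the two unstated options) and then episodic meta-optimization. The
outer update is plain SGD on the meta-batch-averaged, norm-clipped
meta-gradient, matching the θ ← θ − β∇ semantics of the `meta_step`
operation. Two desk-scale findings are baked into the defaults: an
adaptive (Adam-style) outer optimizer renormalizes a *saturated* meta
objective's near-zero gradients into a destructive parameter random walk,
and the first-order approximation systematically erodes the warm-started
solution where the exact second-order gradient preserves it. Eval-mode
normalization statistics are re-estimated after the episodic phase, and
few-shot evaluation recalibrates them on the support set (the calibration
trials are available at deployment, and the inner loop itself adapts
under support statistics). Adaptation touches all parameters (no
head-only variant). Meta-training subjects are audited to be disjoint
from held-out subjects.

## Architecture search

Five genes — d_h ∈ {64,128,256}, L ∈ {1,2,3}, h ∈ {2,4,6}, p ∈ {16,20,24}
with s = p/2, d ∈ {64,128,256} — give 3⁵ = 243 raw combinations.
A genome whose embedding dimension is not divisible by its head count is
repaired by resampling the head gene; since none of {64,128,256} divides
by 6, h = 6 is unreachable and the effective space has 162 points, small
enough for exhaustive enumeration to serve as the global Pareto oracle in
tests. Objectives: proxy-training error (1 − accuracy after a short fit
on an 80% subject split with early stopping), the MAC latency surrogate,
and the parameter count. Survival is NSGA-II (fast non-dominated sort +
crowding distance, binary tournament, elitist μ+λ merge); the weighted
scalar λ·(error, latency, params) = (0.6, 0.3, 0.1) with min–max
normalization over the search-space bounds is computed for logging and
tie-breaking only — how the scalar loss and the multi-objective ranking
interact is unstated in the source methodology, and rank+crowding is the
defining NSGA-II behavior. Evaluations are cached per genome; the
returned front is the nondominated set over everything evaluated.
Front-0 of the fast sort is tested to equal a brute-force O(n²) dominance
filter on random objective clouds, and the scaled search (population 20,
10 generations) recovers the exhaustive Pareto set of the enumerable
space under an analytic convex error surrogate.

## Numerical and degenerate-input choices

* Patch flattening is time-major within a patch (arbitrary but fixed).
* Softmax/log-softmax subtract the row maximum; layer norm uses ε = 1e−5;
  batch norm ε = 1e−5 (batch statistics are used whenever running ones
  are uninitialized). Eval-mode statistics are re-estimated exactly over
  the training set after every epoch and after episodic meta-phases: a
  momentum-style moving average lags badly when an epoch is only a
  handful of small batches, which corrupts validation losses and
  checkpoint selection.
* Floor division at every pooling stage; a configuration whose temporal
  length collapses below the patch size is rejected at construction.
* Amplitude rejection uses strict ">" at the threshold ("exceeding").
* Wilcoxon with all-zero differences raises (the statistic is undefined);
  the paired t-test on identical samples returns (0, 1).
* Zero-variance channels make z-scoring raise an error naming trial and
  channel rather than emitting NaNs.
* LSTM forget-gate input-side bias initializes to 1; other biases to 0;
  weights are Glorot-uniform per named RNG stream.

## Known limitations

* The autodiff engine favors clarity over throughput; wall-clock budgets
  are met by the desk-scale presets, not by kernel efficiency.
* FLOPs/bytes-level figures (model file size, hardware latency) are out
  of scope; the MAC surrogate is the only compute proxy.
* The generator's class structure is deliberately clean; robustness to
  artifacts and non-stationarity is untested by design.
* EDF reading requires the optional `mne` dependency; GDF is not wired.
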