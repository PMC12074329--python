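# Methods

## Problem

Antepartum cardiotocography (CTG) records two channels — fetal heart rate
(FHR, bpm) and uterine tone (TOCO, 0–100) — and clinicians read them for
signs of fetal compromise. Visual interpretation is unreliable, and the
rule-based computerised systems in clinical use are built to confirm
well-being rather than to detect adverse outcomes. This package implements
a patch-based, channel-independent transformer that classifies a
standardised one-hour CTG window (L = 960 samples per channel, one sample
per 3.75 s) as adverse vs. normal pregnancy outcome, together with the
full study pipeline around it: preprocessing, cohort balancing, training
with AUC-based early stopping, a temporal pretrain/finetune protocol,
hyperparameter search, and ROC operating-point evaluation.

## Model

Per channel `x ∈ R^L` with validity mask `m`:

1. **Instance normalisation.** `x̃ = (x − μ)/(σ + ε)` with `μ, σ`
   (population SD) computed over *observed* samples only, `ε = 1e−8`.
   Unobserved positions are set to 0 after normalisation, so their stored
   values can never reach the network: mask invariance is exact, not
   approximate. A constant channel maps to all zeros via the ε-guard.
2. **Patching.** Patches `p_j = x̃[jS : jS+P]`, `j = 0…N−1`, with
   `N = ⌊(L−P)/S⌋ + 1`. A patch is *valid* iff at least 50% of its samples
   were observed (this threshold is the package's choice; it keeps patches
   with minor dropouts while discarding mostly-interpolated ones).
3. **Embedding.** `e_j = W_P p_j + W_pos[j]`, with `W_P ∈ R^{P×d}` and a
   *learned* positional table `W_pos ∈ R^{N×d}` (initialised N(0, 0.02²)),
   one per channel — consistent with strict channel independence.
4. **Encoder.** `n_layers` blocks of multi-head self-attention
   (`softmax(QKᵀ/√d_k)V`, `d_k = d/heads`) and a two-layer feed-forward
   network, each wrapped in a residual connection followed by layer
   normalisation (post-norm). Invalid patches receive additive −1e9
   attention scores as keys, so valid tokens never attend to them; invalid
   tokens are excluded from pooling, so whatever they compute is inert.
5. **Head.** Masked global average pooling over valid tokens per channel;
   the two pooled vectors are concatenated (FHR first, classifier input
   2·d) and a dense layer + sigmoid yields the adverse-outcome
   probability. Training minimises mean binary cross-entropy, computed
   from logits via the softplus form for numerical stability; reported
   probabilities are clamped to [1e−7, 1−1e−7].

Dropout placements: rate `dropout` after patch embedding and inside the
FFN, `attn_dropout` on attention weights, `fc_dropout` on the aggregated
vector before the head. These are the standard placements for the three
advertised rates.

An optional learnable 1-D convolution (odd kernel, same padding,
identity-initialised) can be enabled between normalisation and patching
(`smooth_kernel`); it is off by default. It exists because a tuned kernel
size appears among the operating hyperparameters without an architectural
role being stated anywhere; an identity-initialised input smoother is the
least-committal interpretation and changes nothing unless trained.

Default (tuned) configuration: 6 layers, 4 heads, d_model 512, d_ff 128,
dropout 0.1 / fc 0.4 / attn 0.2, P = S = 16 (60 non-overlapping patches),
ReLU, batch 48, learning rate 1e−4.

### Implementation note

The network, its gradients and Adam are implemented directly on numpy via
a small reverse-mode autodiff engine shipped with the package
(`ctgformer.autodiff`). Everything runs in float64 on a single CPU thread;
gradient rules are verified against central finite differences in the test
suite. The estimator (`PatchTransformerClassifier`) follows the
scikit-learn fit/predict contract, so it composes with `clone`, pipelines
and model selection.

## Preprocessing pipeline

* **Cleaning.** Observed FHR is clipped into [50, 250] bpm, TOCO into
  [0, 100]; the raw missing sentinel (−1) passes through. Clipping (rather
  than marking missing) is the least destructive reading of
  range-adjustment; the alternative is available via
  `clean_channels(..., out_of_range="missing")`.
* **Unit scaling.** FHR ↦ (x−50)/200, TOCO ↦ x/100. From here on,
  missingness is an explicit boolean mask; masked positions hold 0.0.
* **Quality filter.** A trace is excluded iff strictly more than 30% of
  its samples, pooled over both channels, are missing. Whether the 30%
  rule should be per channel is genuinely open; pooled is the default and
  the threshold is a parameter.
* **Windowing.** Non-overlapping 960-step windows are cut from the *end*
  of the trace backwards, so window 0 is always the delivery-proximal
  hour (anchoring is the package's choice; it privileges the clinically
  most relevant segment). A leading remainder is kept as one left-padded,
  mask-false-padded window iff it has ≥ 480 observed steps; otherwise it
  is dropped. Every observed sample therefore lands in exactly one window
  or the (small) dropped tail.
* **Matching.** Propensity scores come from a logistic regression of the
  label on standardised covariates; greedy 1:1 nearest-neighbour matching
  on the logit, without replacement, cases processed in descending
  propensity, optional caliper. Balance is audited with the standardised
  mean difference `|μ₁−μ₀| / √((s₁²+s₀²)/2)` per covariate, before and
  after; the conventional SMD < 0.10 threshold sets the balance flag.
* **Splitting.** 80–20, stratified by label, train size exactly
  `⌊0.8·N⌋` with largest-remainder allocation across strata;
  deterministic under a seed. (20,589 ids → 16,471 / 4,118.)

## Training

Adam (default moments) on mean BCE; after each epoch the validation AUC
(rank-statistic form) is computed and training halts when it has not
*strictly* improved for `patience` = 10 consecutive epochs (ties count
against patience, no minimum delta) or at `max_epochs` (50 standard, 60
per search trial). The returned parameters are always from the best-AUC
epoch. The temporal protocol trains from scratch on cases recorded 3–7
days before delivery, then finetunes — all parameters updated, no
freezing — on the within-2-days subset with its own early stopping.
Validation AUC is computed per window; an optional max-over-windows
per-trace aggregation exists but is not the default.

The hyperparameter harness samples from the tuned grids (layers 3–6,
heads {4,8,16,32}, d_model {64…640}, d_ff {128…640}, dropouts [0.1, 0.5],
learning rate {1e−6…1e−3}, batch {16,32,48,64}, P {4,8,16,32},
S {4,8,16}, activation {ReLU, GELU, ELU}) through a pluggable sampler
callable; draws violating `d_model % heads == 0` or giving head width < 2
are resampled before any training. A seeded uniform random sampler is
provided; a Bayesian optimiser can be slotted in through the same
interface. Failed trials are recorded in the trial table, not fatal.

## Evaluation

Decision rule: positive iff score ≥ threshold, everywhere (including the
default 0.5 rule). The empirical ROC enumerates distinct scores plus an
above-maximum sentinel; AUC is the trapezoidal area and is asserted (in
tests) equal to the tie-corrected Mann–Whitney pairwise probability.
Operating points: default (0.5); Youden `J = sens + spec − 1` maximiser
with ties broken toward the *higher* threshold (fewer false alarms);
highest threshold with sensitivity ≥ target; lowest threshold with
specificity ≥ target (targets default 0.90, configurable — no numeric
definition of "high" exists, so it is a parameter). Zero-denominator
metrics are NaN, never silently 0. The temporal sweep evaluates controls
plus cases within d days of delivery for d = 1…7, flagging (not dropping)
single-class subsets.

## Synthetic data generator

The generator emulates the statistical structure the classifier relies
on, not fetal physiology. One trace = baseline (trace-level offset plus a
slow bounded wander, kept within ±2.9 baseline-SD so event-free traces
respect a 3σ envelope) + band-limited short-term variability (SD
`stv_amplitude`, default 5 bpm) + Poisson accelerations (~+15 bpm, ~15 s,
default 8/h) + decelerations (~−22 bpm, coupled to a contraction with
probability 0.3, plus spontaneous ones at 2/h) + smooth contraction bumps
on TOCO (6/h). Per-trace log-normal jitter (SD 0.2) keeps cohorts
non-degenerate. The adverse class multiplies variability and the
acceleration rate by `adverse_effect` (< 1) and divides the deceleration
rate by it — flatter, deceleration-heavy traces. Missingness is bursty:
`round(rate·T/burst_len)` bursts of `burst_len` samples placed in jittered
blocks, independently per channel, so the realised missing fraction
tracks the rate within a few percent. Cohort metadata draws
days-to-delivery uniformly on [1, 7] and four covariates (gestational
age, maternal age, BMI, parity) deliberately shifted for the adverse
class so that propensity matching has real confounding to remove.

What passing tests show — and do not show: the pipeline is exercised
end-to-end on data with the right *shape* (two bounded channels, masks,
bursty dropouts, class-conditional event structure, confounded
covariates), and the architecture demonstrably learns such signals to
high AUC. Nothing here certifies performance on real CTG archives, whose
artefacts (sensor loss correlated with movement, device changes, rhythm
pathologies) the generator does not model.

## Problem sizes and numerical choices

Tests and the acceptance script run deliberately compact configurations —
d_model 16–64, 1–2 layers, cohorts of a few hundred traces — chosen so the
whole suite completes in minutes on one CPU while still training past
AUC 0.9 on separable synthetic cohorts. Float64 throughout; instance-norm
ε 1e−8, layer-norm ε 1e−5, probability clamp 1e−7, attention mask −1e9.
All indices are 0-based with half-open patch intervals. Degenerate inputs
raise typed errors: all-missing channel, no valid patch in a channel,
single-class validation or prediction sets, zero pooled variance in an
SMD, unreachable operating-point targets.

## Known limitations

* Real-data performance claims are out of scope; no real CTG data ships
  with or is required by the package.
* The greedy matcher is O(cases × controls) and not optimal-assignment
  matching; adequate at cohort scales here.
* The Bayesian search sampler is an interface, not an implementation;
  only random search is built in.
* Single-threaded CPU training bounds practical model sizes well below
  the full tuned configuration at dataset scale; the architecture code is
  identical at all sizes.
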