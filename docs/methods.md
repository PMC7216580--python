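# Methods

## Data model

A methylome dataset is a samples × CpG-sites matrix of beta values — the
fraction of methylated signal at a CpG, bounded in [0, 1] — plus a
categorical cancer-type label per sample. `BetaMatrix` stores values as
float64 with NaN marking missing entries and enforces the range and
ID-uniqueness invariants at construction; I/O is lossless (full
double-precision round trips, no clipping). The canonical in-memory
orientation is samples-as-rows; readers transpose on the way in so the
rest of the package never has to guess.

## Preprocessing

Array data carries missing values that bias a generative model trained on
it. Four steps run in order:

1. **Drop all-missing CpGs.** A site with no observation anywhere carries
   no information.
2. **Chunk CpGs** into consecutive blocks (default 10,000). Outlier and
   imputation decisions are then chunk-local, so a sample that failed in
   one genomic region still contributes to others.
3. **Remove outlier samples per chunk** by the Tukey rule on per-sample
   missing-value counts: a sample goes if its count exceeds
   Q3 + 1.5 · IQR. The fence is one-sided — low missingness is a virtue,
   not a defect — and quantiles use linear interpolation between order
   statistics (the "type 7" convention), both fixed so the rule is
   testable against an independent implementation. The whisker (1.5) is
   the canonical constant and is configurable.
4. **Median-impute** each remaining missing entry with its CpG's observed
   within-chunk median, pooled across all retained samples. Per-condition
   (stratified) imputation exists behind `stratify_imputation=True` but is
   off by default: pooling is the simpler convention and the imputed
   fraction after steps 1–3 is small.

The pipeline is idempotent, never alters an observed value, and logs every
removal and imputation in a `PreprocessReport`.

## The conditional VAE

Latent variables z have the standard-normal prior N(0, I). The decoder
defines p(x | z, y) through hidden layers mirroring the encoder and a
sigmoid output, which keeps every generated beta value strictly inside
(0, 1). The encoder maps the concatenation (x ⊕ y) to the posterior mean
and log-variance; the decoder receives (z ⊕ y). One-hot concatenation is
the conventional conditioning mechanism; the prior is kept independent of
y (the conventional CVAE simplification).

Training minimizes the negative conditional ELBO

    recon(x, x̂) + KL[N(μ, diag e^logvar) ‖ N(0, I)],

with the KL term in closed form, −½ Σ(1 + logvar − μ² − e^logvar), checked
against numerical quadrature in the tests. The default reconstruction term
is elementwise binary cross-entropy treating beta values as probabilities
(targets clipped to [1e-6, 1−1e-6]; computed stably from logits), which
pairs naturally with the sigmoid output; summed squared error is available
via `reconstruction_loss="mse"`. The KL weight is fixed at 1 (no
annealing).

**Architecture defaults**: encoder 500 → 250 (ELU, then tanh), 125 latent
dimensions, decoder 250 → 500 with the activation order reversed. The
activation placement is configurable since only the pair of nonlinearities
is canonical, not their order. Weights are fan-in-scaled Gaussian,
biases zero. **Optimization**: Adam (β₁ = 0.9, β₂ = 0.999), learning rate
1e-3, 10,000 epochs, minibatch 100 by default.

One independent model is trained per 10,000-CpG chunk and generated chunk
outputs are concatenated; nothing ties parameters across chunks, which is
the simplest reading of chunk-wise training and keeps memory bounded. The
consequence — no cross-chunk correlation in generated data beyond what the
condition induces — is shared with the beta benchmark (which is fully
per-CpG independent) and does not affect per-type classification.

The network is implemented directly in NumPy: dense layers with explicit
forward/backward passes and a hand-rolled Adam step. At the package's
problem sizes (chunks of ≤ 10⁴ CpGs, hundreds of samples) this is fast,
dependency-free, and — because every random draw (init, shuffling,
reparameterization noise, generation) flows from one `SeedSequence` —
bit-reproducible: identical seeds give identical weights and identical
generated matrices, before and after a serialization round trip.

## The beta benchmark

For each (CpG, cancer type) cell the observed values (clipped to
[1e-6, 1−1e-6], since exact 0/1 occur in array data and degenerate the
moments) give method-of-moments estimates

    α = m (m(1−m)/v − 1),   β = (1−m) (m(1−m)/v − 1),

with m the sample mean and v the sample variance (ddof = 1). MoM is
closed-form — essential at ~10⁷ cells — and self-verifying: the fitted
distribution's analytic mean and variance reproduce m and v exactly, which
the tests assert to floating precision. Maximum likelihood is available
via `method="mle"`. Cells that cannot be fitted (fewer than `min_n = 3`
observations, zero variance, or v ≥ m(1−m)) receive the mean-preserving
fallback Beta(m·κ, (1−m)·κ) with κ = 1000 — a narrow distribution at the
right location — and are flagged `fallback_used`. Sampling draws each cell
independently.

## Synthetic ground truth

The generator emulates the input the tool expects: per-(CpG, condition)
beta-distributed values with condition-dependent means. Parameters are
built mean-first (α = m·c, β = (1−m)·c with concentration c = α+β drawn
from `concentration_range`, default 10–50 — typical of the moderate
dispersion of array betas), so the separation between condition means is
directly controllable. At an *informative* CpG the conditions receive a
random permutation of equally spaced mean levels `start + j·Δ` with
Δ = `mean_separation`, making **every pair** of conditions separated by at
least Δ there; a spec is rejected as infeasible when the level span cannot
fit inside [0.02, 0.98]. Uninformative CpGs share identical parameters
across conditions. Missingness injection adds uniform
missing-completely-at-random entries, designated high-missingness outlier
samples, and optional all-missing CpGs — exactly the three defects the
preprocessing steps target — and returns the exact mask for oracle tests.

Default study conditions used throughout the tests and the acceptance
script: 4 conditions × 200 CpGs × 150 samples/condition with mean
separation 0.3 for the separated fixture (trained with the reduced CVAE
config 64/32 hidden, 16 latent, batch 50, 500 epochs); 25 fixtures of
≤ 50 samples × 200 CpGs with 2% missingness, 1–2 outlier samples at 60%
and one dead CpG for the preprocessing oracle; 4 conditions × 100 CpGs ×
500 samples/condition for parameter recovery; 4 × 100 × 80 for the null
control. These sizes make the whole suite run in well under a minute per
heavy step while leaving wide margins on every check.

What the synthetic data does **not** emulate: co-methylation blocks and
genomic CpG spacing, probe-chemistry artefacts (type I/II probe shifts),
batch effects, and cross-CpG correlation beyond the condition effect.
Passing tests therefore demonstrate that the machinery is correct and that
the CVAE can learn and steer condition-dependent beta distributions — not
that it reproduces every higher-order property of real 450K data.

## Evaluation protocol

`split_data` makes a stratified 70/30 split (per-condition proportions
within one sample of the target). `train_classifiers` fits DT, GaussianNB,
RF, KNN and SVM with library defaults and fixed seeds — defaults maximize
comparability since no hyperparameters are canonical here. Per-condition
scores for AUC come from `predict_proba` where available and from the
one-vs-rest `decision_function` for the SVM; AUC is the rank statistic
with midrank ties, checked against an exhaustive pair-counting oracle.
`compare_generators` re-draws both the split and the generation in every
repetition (flags `redraw_split` / `redraw_generation` pin either), which
is the more conservative reading of "repeated" evaluation; the choice is
recorded in the report. A 3-D t-SNE embedding of real plus generated
samples, tagged by source and condition, is available as a visual
diagnostic.

## Numerical choices and degenerate inputs

- Beta values within 1e-9 of [0, 1] are accepted and clamped at parse
  time; anything further out is a validation error naming the cell.
- Cross-entropy targets and benchmark fits clip to [1e-6, 1−1e-6];
  benchmark samples are clipped to [1e-12, 1−1e-12] to keep the open
  interval when tiny shape parameters round a draw to 0 or 1.
- With IQR = 0 the outlier fence equals Q3, so any sample with more
  missing values than the (typical) count is removed — the rule's honest
  limit behaviour; an error is raised if a step would empty a chunk.
- Empty matrices, zero-sample generation requests and remainder-only
  chunks are all defined rather than errors.

## Known limitations

- The null-control check (identical generating parameters across
  conditions → chance accuracy) uses a binomial test that assumes
  independent trials. Samples generated by a *trained* CVAE within one
  condition share whatever spurious condition effect the decoder picked
  up from noise, so their correctness indicators are positively
  correlated and the accuracy is overdispersed relative to the binomial:
  across many seeds the test rejects somewhat more often than the nominal
  1%. The benchmark arm, whose cells are fitted independently, is much
  closer to nominal.
- One model per chunk means no learned correlation between CpGs in
  different chunks.
- Training cost at the full default scale (10,000 epochs on hundreds of
  10,000-CpG chunks) is substantial; the NumPy implementation is intended
  for the chunk sizes and sample counts of array cohorts, not for
  GPU-scale sweeps.
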