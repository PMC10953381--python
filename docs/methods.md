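# Methods

## The analysis model

`loadsense` treats load-stress biomarker discovery as a supervised
feature-selection problem on a normalized multi-study expression compendium.
The pipeline assumes:

- expression values arrive on a log scale (log-TPM), with no missing values;
- every study contributes at least one reference (control) sample, or an
  explicit fallback list of "least perturbed" samples is supplied;
- the load-stress label is binary and never applies to reference samples;
- between-study variation is predominantly an additive per-study, per-gene
  offset, which reference subtraction removes.

Normalization subtracts, per study, the arithmetic mean (on the log scale)
of the study's reference samples from every sample of that study.  The
operation is idempotent and commutes with row/column permutations; after it,
a value of 0 means "expressed like the study's control".

## Synthetic compendium generator

The generator produces the statistical structure the analysis assumes, with
a known ground truth, so every downstream stage is testable offline:

```
X(g, s) = baseline(g) + batch(study(s), g)
          + effect_size · 1[g planted ∧ s load-stress] + N(0, noise_sd)
```

- `baseline(g) ~ N(6, 2)` log2 units, a typical log-TPM location spread.
- `batch(study, g) ~ N(0, batch_sd)`, default `batch_sd = 1.0` — strong
  enough that a classifier can identify the study from raw values, which is
  exactly why reference normalization has to matter.
- `noise_sd = 0.5` log2 units of iid per-observation noise; the default
  planted `effect_size = 2.0` is four noise standard deviations.
- Defaults sketch the scale of the real compendium the analysis targets:
  10 equal-size studies × 25 samples = 250 samples with 82 load-stress
  samples.  (The real collection has 251 profiles; with the equal-study-size
  contract 251 is prime and unreachable, so 250 is the closest realization
  while the 82 load-stress count is kept exactly.)
- Load-stress labels are assigned **round-robin across studies** over the
  non-reference samples.  This deliberately decouples the class from the
  study offsets: with no planted effect, raw (un-normalized) data predicts
  the study far above chance but predicts load stress only at chance.
- Counts are `round(2^X · library_factor)` with per-sample library factors
  log-normal around 1 (σ = 0.2) — integer input for count-based contrasts
  without modelling full negative-binomial dispersion.
- Gene sets partition the gene universe into equal blocks, plus one set
  holding exactly the planted genes, so set-level indices respond to the
  planted signal and percentage indices over the collection sum to 1.
- The iModulon model is a truncated SVD of the *noise-free*, gene-centered
  signal; because the signal has rank ≤ n_studies + 1, the default
  12-component model reproduces it exactly and the declared residual
  (`truth["decomposition_tolerance"]`) is just the extremal centered noise.
- Growth rates for load-stress samples follow
  `base_rate − slope · (mean planted-gene deviation) + N(0, 0.05)`, defaults
  `base_rate = 0.9 h⁻¹`, `slope = 0.15`, clipped at 0.05 h⁻¹, so stronger
  biomarker induction co-occurs with slower growth and a negative
  expression/growth correlation is plantable.
- Each logical component (baseline, batch, noise, library, growth, sets)
  draws from its own stream spawned from the master seed: adding or
  resizing one component never perturbs another's draws, and identical
  configs are byte-identical.

What the generator does **not** emulate: operon/regulatory structure,
mean–variance coupling of counts, bimodal or heavy-tailed expression, class
imbalance across studies, or ICA-style mixing beyond the linear M·A
contract.  Passing tests therefore demonstrate correctness of the machinery
and recoverability of additive planted signals — not performance on real
compendia, where effect shapes are richer.

## Differential expression stand-in

Per-gene contrasts use Welch's unequal-variance t-test on the log2 scale
(counts are transformed with `log2(count + 1)` first; the pseudocount is
recorded in the table metadata).  This is a deliberate stand-in for a
negative-binomial GLM: dispersion modelling belongs to dedicated
differential-expression packages, and `load_deg_table` accepts their output
(gene_id, lfc, p_adj) so real-data runs reuse published results.  Genes with
zero variance in both groups get p = 1 when the means agree and p = 0
otherwise.  The DEG rule is `|lfc| > 1` and adjusted `p < 0.05`; whether the
cut applies to adjusted or raw p is configurable (`adjusted=True` by
default).  Overrepresentation uses the one-sided hypergeometric tail with
Bonferroni correction across the sets tested (α = 0.01); Benjamini–Hochberg
is available as a config switch because "Bonferroni" and "false discovery
rate" name different error controls and reasonable users may want either.

## Activity indices

The percentage index divides by the DEG count, so it is undefined — reported
as NaN and serialized as an empty cell, never 0 — when a condition has no
DEGs.  The same convention applies to intensity indices with empty overlap:
0 is a meaningful "no net change" and must stay distinguishable.  iModulon
intensity is a difference of mean activities between condition and reference
samples (activities already live on a log-derived scale).  The reporting
view keeps sets whose percentage index in the load-stress condition exceeds
0.3; applying the threshold to other conditions is a config option.

## Feature elimination

Both eliminators consume the classifier's own importances: Gini importances
for the random forest, absolute coefficients for the linear SVM.  The SVM is
fit on mean-centered features, which keeps its decision function intact
while forcing a constant (information-free) feature's coefficient to exactly
zero under the L2 penalty.  Importance ties rank by ascending feature index
(stable sort) so runs are reproducible.

Default hyperparameters, recorded in output metadata: random forest with
100 trees; linear-kernel SVM with C = 1.  The desk-scale test and
acceptance configurations use 30-tree forests — the recovery problems there
have 100 features and 60 samples, where 30 trees already give stable
importances at a third of the cost.

RGIFE specifics:

- "No negative effect" means `trial f1 ≥ reference f1` with **zero
  tolerance** (an optional tolerance knob exists, default 0); on acceptance
  the reference becomes the trial's f1, the ranking is recomputed, the block
  size is re-derived as `max(1, floor(0.25 · n))`, and the failure counter
  resets.
- Within an epoch (between acceptances at a fixed block size) the ranking
  stays frozen and blocks are consecutive chunks of it, least important
  first; a block is never allowed to remove every remaining feature.
- CV folds are re-drawn from the run seed at every trial rather than frozen,
  avoiding overfitting a single partition; every fold seed is recorded in
  the JSON-lines trace.
- Termination: after five consecutive failures, or when every block of the
  epoch has been tried, the block size divides by 4 (floor, min 1); at block
  size 1 the failure counter deliberately **carries across epoch restarts**,
  so a feature set smaller than the failure cap cannot cycle forever — the
  run always ends after five consecutive failed single-feature trials (or
  when one feature remains).  A defensive `max_trials` cap (20 000) guards
  against pathological configurations.

Because acceptance requires no degradation, the trace-final reference f1 is
never below the initial full-set f1, and block sizes between acceptances
form a non-increasing sequence ending at 1 — both are asserted from traces
in the tests.

## Panel prioritization

Occurrence counts identical unordered gene sets pooled across models and
runs (per-model provenance is kept in `model_names`).  Outer evaluation is
stratified 10-fold CV on the selected genes only, reported as mean ± sd over
folds; the shortlist keeps panels with `f1 > 0.98` and `margin > 0.1`,
sorted by margin, then f1, then gene ids.  The margin threshold default is
0.1; both thresholds are explicit arguments, never hard-coded deeper in.

**Margin sign rule.**  A sample pair counts positive only when *every* panel
gene's difference has the same non-zero sign as the class-mean difference
for that gene (strict agreement).  A literal product-of-signs form — under
which an even number of per-gene disagreements would still count positive —
is available behind `sign_rule="product"`, but strict agreement is the
default because the statistic's purpose is to flag any pair that interleaves
the classes.

**Margin is an extreme-value statistic.**  Its sign is decided by the single
worst of `|I| · |J|` pairs.  Under the generator's Gaussian noise, a pair's
per-gene difference flips sign with probability
`Φ(−effect / (noise_sd · √2))`, so a positive margin requires that flip
probability to be small against the number of pairs: at the default desk
scale (20 × 40 pairs, effect four noise sd) the expected number of flipped
pairs is ≈ 3.7 and the margin is usually negative, while at 6 × 24 pairs and
effect six noise sd it is positive with large headroom.  Real biomarkers
separate bimodally rather than by a mean shift with Gaussian tails, which is
why published panels attain positive margins at hundreds of pairs.  Tests of
the "planted panel has positive margin" property therefore use the latter
regime; the margin *computation* is oracle-checked by exhaustive enumeration
everywhere.

## Numerical choices and degenerate inputs

- BH adjustment delegates to the standard step-up implementation; inputs
  outside [0, 1] are rejected.
- Fisher p-values come from the hypergeometric survival function; tests
  verify them against exact integer-arithmetic tail sums for every table
  with background ≤ 60.
- Stratified folds require `n_folds ≤ minority class count`; violations
  abort with the counts.  f1 uses `zero_division=0`.
- Growth correlations with constant expression or constant growth return
  NaN with a reason code instead of raising.
- Pipeline stages never mutate inputs; a failing stage writes a `FAILED`
  marker naming itself and retains completed outputs.

## Problem sizes used by the test and acceptance runs

Desk-scale study conditions: 100 genes, 4 studies × 15 samples (2 references
each), 20 load-stress samples, 2 planted genes at effect 2.0 (= 4 ×
noise_sd 0.5).  Recovery is measured over 20 independently generated
compendia (RGIFE-RF must keep both planted genes in ≥ 80%); the null arm
uses 10 effect-0 compendia against a 200-shuffle permutation band.  The
acceptance script runs the same conditions with a scaled ensemble (RFE sizes
2–3 × 2 repetitions, RGIFE × 2, both classifiers) and a 5-compendium
recovery arm.

## Known limitations

- The Welch stand-in is less powerful than a count GLM at low counts; use
  externally computed DEG tables for real data.
- RGIFE with zero tolerance stops early on easy problems (reference f1
  saturates at 1 and any dip is a failure), so returned panels can be much
  larger than the minimal discriminative set; the ensemble's size-retention
  filter (2–6 genes) is what surfaces minimal panels.
- The ensemble's outer CV evaluates panels on the same data used for
  elimination; with small sample counts this is optimistic.  The module
  separates inner elimination from outer evaluation explicitly so a nested
  scheme can be layered on.
- Margin values are comparable only within a fixed normalization and scale,
  and, being extreme-value statistics, are noisy at large sample counts.
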