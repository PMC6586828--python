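# Methods

This note documents the statistical model behind `exclusig`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make the
pipeline deterministic.

## Data model

All protein abundances live on a log2 scale: NPX (the PEA relative
unit) for multiplex panels, log2 pg/ml for calibrated custom assays.
Outcome groups form a closed vocabulary — `benign`, `borderline`,
`stageI_II`, `stageIII_IV`. A binary *decision* codes benign (or the
earlier stage) as 0 and cancer (or the later stage) as 1; borderline
samples are carried through preprocessing and scored by final models
but are excluded from every training comparison and every cut-off
determination.

Preprocessing conventions:

* **LOD replacement.** Values below the per-assay lower limit of
  detection are replaced by the LOD itself (`max(x, lod)`); the
  operation is idempotent and never decreases a value.
* **Panel merging.** Proteins are unioned across panels, samples
  intersected (the analysis requires complete cases). A protein assayed
  on several panels is kept from the first panel providing it, with a
  warning — the manifest carries no dynamic-range information on which
  a better rule could be based.
* **Replicate averaging.** Replicate concentrations are averaged on
  the linear scale and then log2-transformed. If *all* replicates fall
  below (above) the detection limits, no mean is formed; the lower
  (upper) limit value is substituted. The upper limit is handled
  symmetrically to the LOD and flagged, since assays saturate at both
  ends.
* **Standard-curve calibration.** A piecewise log-log linear curve
  through the mean response at each non-blank calibrator level; sample
  responses are inverted through it, and responses outside the
  calibrated [low, high] range are clamped and flagged. Non-monotone
  calibrator means abort the plate — they indicate corruption, not
  noise. The true response family of a commercial assay is unknown;
  piecewise log-log linearity is the weakest monotone assumption that
  is exact for log-linear assays and needs no parametric fit.

## Core discovery

Stability selection over `n_splits` (default 50) stratified 50/50
splits. Per split, an elastic-net linear regression of the decision on
all available proteins (mixing α = 0.9, i.e. mostly lasso with a small
ridge component to spread weight over correlated proteins) is fitted on
the training half with the penalty chosen by 10-fold cross-validation.
Splits are stratified by outcome — at the cohort sizes involved
(~40–100 per class), unstratified halves regularly produce degenerate
folds.

**Penalty rule.** Coefficients are extracted at the largest penalty
within one standard error of the CV minimum (`penalty_rule="one_se"`).
At the CV minimum the elastic net retains many small noise
coefficients consistently enough that pure-null proteins can exceed
the 70% inclusion threshold, inflating cores past their size bounds;
the one-SE penalty restores the selectivity the 70% rule presumes, and
is also the default coefficient-extraction rule of the R package this
class of analysis is usually built on. The CV-minimum rule remains
available as `penalty_rule="cv_min"`.

A protein is "present" in a split model iff its coefficient is non-zero
at the selected penalty. The core is the set of proteins present in at
least `inclusion_threshold` (default 0.70) of splits. Core performance
is the best-point sensitivity/specificity of an *unpenalized* OLS refit
on each training half, scored on the test half, averaged over the same
splits used for selection — the same operating point later reported as
"BP", so acceptance thresholds and reported performance are comparable.

**Stage presets** (comparison → size range, sens-only / joint
threshold): benign vs I–II → 2–6, 0.8 / 0.6; benign vs III–IV → 2–5,
0.8 / 0.7; benign vs I–IV → 2–6, 0.8 / 0.7. Early-stage disease is the
hardest to separate, hence the laxer joint threshold. `StageConfig`
accepts a lower bound of 1 so that degenerate single-protein cores can
be studied, but the presets keep the 2-protein minimum.

**Exclusion search.** Depth-first; every accepted core of size N
spawns N children, each adding one core protein to the branch's
exclusion set (monotone down the tree, so any two cores from different
branches differ in ≥ 1 protein). Branches terminate on no-core, a
constraint violation, or > `max_exclusions` (default 20) exclusions.
Children are visited in order of decreasing selection frequency of the
excluded protein (ties lexicographic), duplicate (core, exclusion-set)
states are reported once, and each node's randomness is seeded from the
master seed plus the sorted exclusion set — so the accepted set is
invariant to traversal order and bit-reproducible under a fixed seed.

## Forward extension

Only the outcome is residualized: after OLS of the decision on the
selected proteins, the candidate maximizing squared Pearson correlation
with the residual is added, then the outcome is re-residualized on the
full selected set. Candidates are used raw — this is deliberate and
differs from classical forward stagewise regression, where candidates
are also orthogonalized against the selected set; with correlated
proteins the two variants can pick different orders. Gains are
fractions of *remaining* variance; addition stops at gain ≤ `min_gain`
(default 0.01) or 20 proteins total (a hard cap). Ties in the argmax
break lexicographically by protein id. A `force_include` list supports
manually curated additions (markers with prior evidence) before greedy
selection starts.

The practical-panel filter keeps proteins whose assays tolerate ≥ 7.5
mg/ml hemolysate and need a predilution weaker than 1:2025 (a protein
requiring exactly 1:2025 is removed); proteins with missing annotation
are excluded conservatively with a warning.

## Evaluation

ROC curves enumerate every distinct score threshold plus a +∞ sentinel;
a sample is positive when score ≥ threshold. AUC is the Mann–Whitney
probability with ties counted ½. Operating points:

* **BP** minimizes √((1−sens)² + (1−spec)²); ties break toward higher
  sensitivity, then higher threshold (a clinical-triage bias: when two
  points are equally far from perfection, prefer finding the cancer).
* **FSE/FSP** maximize the unconstrained metric subject to the other
  being ≥ a level (0.93 for replication evaluation, 0.98 for final
  cut-offs; both configurable). An unattainable level returns the point
  with the maximal constrained metric, flagged rather than raised.

Replication-style evaluation refits the fixed protein set by OLS on
repeated stratified 50/50 splits (coefficients cannot transfer across
laboratory runs on the relative NPX scale), standardizing predictors
with training-half statistics only, and reports mean and SD of each
metric over repeats; PPV/NPV are computed at the BP threshold. Models
are ranked by mean of (BPse, BPsp), ties by AUC then smaller size.
Group-score contrasts use two-sample rank-sum tests with a Bonferroni
threshold α/(number of pairs) — e.g. 0.05/6 ≈ 8.3 × 10⁻³ — using the
exact null distribution when both groups are ≤ 25 and tie-free.

## Final-model fixation

Stratified 50/50 train/validation split (per-stratum counts differ by
≤ 1). Ridge regression (the pure-ℓ₂ limit of the elastic net — at this
stage the panel is fixed, so shrinkage without selection is wanted)
over a 100-point log-spaced penalty path, 5-fold stratified CV, penalty
at the one-SE rule; the per-fold path is computed in closed form via
SVD. Train vs validation AUC is compared with an **unpaired** DeLong
test (the two halves are disjoint samples, so the placement covariance
term is zero by design); the paired variant is implemented for
same-sample score comparisons. When the AUCs do not differ, the model
is refitted on all coded samples with the same scheme, scores are
mapped through f(x) = eˣ/(eˣ+1), and the three cut-offs are determined
on the full defining cohort. The model card (proteins, coefficients on
the log2 scale, intercept, link, cut-offs, fold/seed metadata) is
self-contained JSON; prediction refuses samples with missing features
rather than imputing.

## Synthetic cohorts

The generator emulates what the analysis assumes about PEA cohorts:

* unit-variance log2 abundances in equicorrelated blocks of
  `block_size` (default 5, ρ = 0.5) — signal proteins occupy leading
  positions so correlated null "proxies" arise in their blocks;
* additive per-group mean shifts on signal proteins, in SD units
  (defaults: benign 0, borderline 0.5, stage I–II 1.0, stage III–IV
  1.5 — monotone in stage, matching the universal observation that
  late-stage disease separates more strongly; the magnitudes are a
  modeling choice, not estimates from any cohort);
* per-protein LOD at a quantile (default 0.05) of the benign-group
  distribution, with left-censoring at the LOD — the LOD is a property
  of the assay, so it is anchored to the reference group, not to each
  sample set;
* ages truncated-normal in [18, 100] with group means/SDs defaulting to
  an adnexal-mass clinic profile (≈ 58–64 ± 12–17 years);
* group sizes defaulting to a discovery-style cohort (90 benign / 42
  early / 37 late).

Under the generator the two classes are homoscedastic Gaussians, so the
best achievable AUC is Φ(√(δᵀΣ⁻¹δ + (Δage/σ)²)/√2), which
`optimal_auc` computes exactly (ignoring the mild age truncation and
assuming a shared age SD). This is the oracle the final-model pipeline
is checked against.

The generator does **not** emulate: plate effects or inter-plate
normalization (delegated upstream), heavy-tailed or skewed abundance
distributions, assay-specific noise heteroscedasticity, missing
samples, or correlation between age and protein levels. Tests passing
on this generator therefore demonstrate correctness of the machinery
and calibration under the assumed model, not performance on real
cohorts — in particular, the headline performance of any real panel
cannot be reproduced without the original study data.

Custom-assay plates are simulated as monotone log-linear responses
(log2 response = a + b·log2 conc, b ∈ [0.8, 1.2]) with Gaussian log2
noise, blank calibrators responding at a background floor, calibrators
always in triplicate, and samples in 2–3 replicates.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
under it; per-node seeds in the exclusion search and per-split CV seeds
are derived through `numpy.random.SeedSequence`. The bundled tests and
the acceptance script run the pipeline at reduced but statistically
adequate sizes — stability selection at 8–20 splits instead of 50,
cohorts of 100–200 per group, 10–20 generator seeds per property —
chosen so each check's Monte-Carlo error is small against its assertion
margin. The defaults in the library remain the full-size settings
(50 splits, 50 repeats, 10-fold CV).

## Known limitations

* Core discovery at the one-SE penalty is conservative; very weak
  signals (< ~1 SD at n ≈ 200/group) may yield no core where the
  CV-minimum rule would find one (at the price of noise cores).
* The search cost grows with the number of accepted cores (each spawns
  its size in branches); the `max_exclusions` budget, not visit-order
  heuristics, is the effective bound.
* `evaluate_model_replication` drops repeats where an operating-point
  level is unattainable from that metric's summary (NaN-aware means),
  which slightly biases FSE/FSP summaries on tiny cohorts.
* The DeLong normal approximation is unreliable below ~20 samples per
  class; the paired bootstrap cross-check in the tests bounds the
  discrepancy at n = 20.
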