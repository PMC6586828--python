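# exclusig

Discovery of **mutually exclusive plasma-protein biomarker signatures**
for case/control classification, built around the proximity extension
assay (PEA) data model used in ovarian-cancer diagnostics: log2-scale
NPX abundances with per-assay lower limits of detection (LOD), multi-
panel cohorts, and custom multiplex assays calibrated to absolute
concentrations.

The package is aimed at computational biologists developing multivariate
protein panels who want the full pipeline — discovery, replication-style
evaluation, and fixation of a deployable classifier — as tested,
seed-deterministic library code, exercised end-to-end on synthetic
cohorts with planted ground truth.

## The method

Exhaustive panel searches are infeasible (choosing 4 of 1000 proteins
already gives > 4 × 10¹⁰ panels), and correlated biomarkers make
univariate ranking misleading. The pipeline instead works in two stages:

**1. Cores by stability selection.** The discovery cohort is split
50/50 into training/test halves, repeatedly (default 50 times). On each
training half an elastic-net linear model of the 0/1 decision *y*
(benign = 0, cancer = 1) is fitted,

  min_β ‖y − β₀ − Xβ‖²/(2n) + λ[α‖β‖₁ + (1−α)‖β‖₂²/2],  α = 0.9,

with λ chosen by 10-fold cross-validation (one-SE rule). Proteins with
non-zero coefficients in ≥ 70% of splits form a **core**; its held-out
sensitivity/specificity is the best-point ROC performance of an
unpenalized refit averaged over the same splits. A core is accepted if
its size and sens/spec meet stage-specific constraints (e.g. size 2–5
and sens ≥ 0.8, or sens & spec ≥ 0.7, for benign vs stage III–IV).
**Mutual exclusivity** comes from a recursive exclusion search: each
accepted core of size N spawns N branches, each permanently withholding
one more core protein from the candidate pool, until no acceptable core
remains or more than 20 proteins have been excluded.

**2. Signatures by forward extension.** Each core is grown by stepwise
forward selection on *residual* explained variance: the decision is
residualized on the selected proteins by OLS, and the candidate with the
largest squared correlation with the residual is added — stopping when
the best gain is ≤ 1% of the remaining variance or the model reaches 20
proteins.

Signatures are evaluated replication-style (repeated 50/50 split, OLS
refit of the fixed protein set, metrics on the held-out half): AUC,
PPV/NPV, and sens/spec at three ROC operating points — **BP** (closest
point to perfect classification), **FSE** (max specificity subject to
sensitivity ≥ 0.93) and **FSP** (the mirror image).

A chosen panel is finally **fixed** on absolute-concentration data:
stratified train/validation split, 5-fold cross-validated ridge fit with
the penalty at the one-standard-error rule, a DeLong test that train and
validation AUCs do not differ, refit on all samples, and logistic-link
scores f(x) = eˣ/(eˣ+1) with three clinical cut-offs (BP, and FSE/FSP at
a 0.98 floor).

A synthetic-data module generates PEA-like cohorts (block-correlated
log2 abundances, stage-dependent planted effects, LOD left-censoring,
truncated-normal ages) and calibrator-based custom-assay plates, so
every stage is testable against known ground truth, including the
analytically optimal AUC Φ(√(δᵀΣ⁻¹δ)/√2).

## Worked example

`examples/05_fix_final_model.py` fixes an 11-protein + age panel on a
synthetic cohort (106 benign, 25 stage I–II, 65 stage III–IV) and
prints:

```
panel: 11 proteins + age
train AUC      0.893
validation AUC 0.866
DeLong p       0.60  (> 0.05: no overfitting signal, refit on all samples)
analytic optimum for this generator: 0.899

clinical cut-offs on the (0,1) score scale:
  BP  0.6199  sens 0.78 spec 0.81
  FSE 0.5549  sens 0.99 spec 0.19
  FSP 0.6500  sens 0.44 spec 0.98
```

Train and validation AUCs agree (DeLong p = 0.60), so the refit on the
full cohort is justified; both sit close to the best any classifier
could do on this generator (0.899). The FSE cut-off buys near-perfect
sensitivity at the cost of specificity — the triage setting — while FSP
does the opposite, the screening setting. The other examples cover
cohort simulation, core discovery, forward extension with the
practical-assay filter (hemolysate tolerance ≥ 7.5 mg/ml, dilution
< 1:2025), and custom-assay calibration.

A thin CLI mirrors the library:

```sh
exclusig simulate --config cohort.yaml --out data/ --seed 1
exclusig discover --matrix data/matrix.tsv --meta data/metadata.tsv \
    --comparison benign_vs_III_IV --out cores.json
exclusig extend --cores cores.json --matrix data/matrix.tsv \
    --meta data/metadata.tsv --comparison benign_vs_III_IV --out models.json
exclusig evaluate --models models.json ... --out eval.json
exclusig finalize --matrix conc.tsv --meta meta.tsv --proteins P1,...,P11 --out model.json
exclusig predict --model model.json --matrix new.tsv --out scores.tsv
```

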