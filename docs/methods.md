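# Methods

`flavoromics` implements a complete two-group volatile-flavor comparison
for GC-MS peak tables: area normalization, odor-activity scoring, flavor
networks, and a two-track importance fusion that screens signature
differential flavor compounds. This note records the models, the
conventions chosen where the field leaves them open, and the limits of
what the synthetic tests demonstrate.

## Relative content and group profiles

A peak table holds raw peak areas for each replicate injection (sample)
and identified compound; a compound absent from a sample is stored as 0.
Relative content is the classic area-normalization statistic

    C(s, c) = 100 · area(s, c) / Σ_c' area(s, c')   [percent],

so every sample row sums to exactly 100%. Group profiles report the
arithmetic mean ± standard deviation over replicates, with the sample SD
(n−1 denominator) — the usual convention for n = 4 analytical replicates.
A single-replicate group reports SD 0 with a warning. A compound is
*detected* in a group iff its mean content is > 0; dashes in published
tables load as 0.

Because contents are compositional (closed to 100%), per-replicate
normalization and normalization of pooled areas give slightly different
group means; this package normalizes per replicate and then averages,
which treats every injection as an equally weighted observation.

Compound identity joins across tables use the canonicalized name (trim,
collapse whitespace, case-fold) with CAS as a tiebreaker; two records
with the same name but conflicting CAS raise an error rather than merge
silently.

The presence-pattern classifier (labels I–IV from the two group means
against a "high" threshold, default 3%) is a convenience summary for
heat-map-style grouping and carries no inferential weight.

## OAV and ROAV

The odor activity value divides content by the compound's water odor
threshold T (mg/kg): `OAV = C / T`. Within each group, the relative odor
activity value rescales to the group's most odor-active compound:

    ROAV_i = 100 · OAV_i / OAV_max,

so ROAV ∈ [0, 100] and exactly one compound per group attains 100 (ties
aside). Compounds with ROAV ≥ 1 are *key flavor contributors*; 0 < ROAV
< 1 marks *flavor modifiers*. ROAV is computed from group-mean contents
(one ROAV per group), matching how key-flavor tables are published.
Compounds without a threshold entry are flagged `no_threshold` and
excluded from the ranking, never silently dropped. Values below 0.1
display as "<0.1" in reports; full precision is kept internally.

ROAV is scale-invariant: multiplying all contents in a group by k > 0
changes nothing, so the statistic is immune to total-signal differences
between groups.

## Flavor network

Key compounds and their odor descriptors form a bipartite graph: one
edge per (compound, descriptor) with weight equal to the compound's
ROAV; a descriptor node's weight is the sum of incident ROAVs, so
descriptor weights conserve the total compound ROAV mass counted with
descriptor multiplicity. Descriptors are free text, canonicalized
case-insensitively and deduplicated; no synonym merging is attempted. A
key compound without descriptors stays as an isolated node with a
warning. Export formats are an edge-list CSV and GraphML.

## OPLS-DA

For a two-class response coded −1/+1, orthogonal projections to latent
structures splits the scaled predictor matrix into one Y-predictive
component and `n_ortho` Y-orthogonal components that are deflated from X
before the predictive fit. With a single response column the PLS weight
has the closed form w ∝ X'y (NIPALS converges in one step), so the fit
is fully deterministic — no initialization or convergence issues arise.
Each orthogonal component is the part of the X-loading orthogonal to w,
Trygg–Wold style; predictive and orthogonal scores are exactly
orthogonal by construction.

Conventions:

- **Scaling**: unit variance with mean centering (the chemometrics
  default for discriminant models); Pareto and no scaling are available.
  Zero-variance columns are dropped and recorded.
- **n_ortho**: default 1 for two-class problems.
- **VIP**: `vip_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)` with
  the sum over the predictive plus orthogonal components weighted by the
  response sum of squares each explains ("total" mode; orthogonal
  components explain almost none, so this differs little from the
  predictive-only mode, which is available as a switch). The
  normalization Σ vip² = p (mean squared VIP = 1 over retained columns)
  holds exactly.
- **Cross-validation**: Q² = 1 − PRESS/TSS with stratified venetian-blind
  folds — samples of each class dealt to folds in input order, staggered
  by cumulative class size, 7 folds by default; deterministic, and
  `n_folds = n` degenerates to leave-one-out. Folds whose training set
  would lose a class are skipped with a warning.
- **Permutation test**: labels are permuted, the model refit and
  cross-validated, and R²Y/Q² regressed by ordinary least squares on
  |corr(permuted, original)| including the observed model at correlation
  1; intercepts are read at correlation 0. Draws equivalent to the
  observed split (identity or label swap, |corr| = 1) are rejected as
  redundant with the observed point — without this, tiny balanced
  designs (70 distinct splits at 4+4) would frequently redraw the
  observed labeling and no model could ever beat "every" permutation.

**Small-sample Q² calibration.** At the design point of the synthetic
tests (4 replicates per group, 12 compounds) the null distribution of Q²
is strongly negative on average (mean ≈ −1.7) but retains a positive
tail: across 1000 signal-free runs, Q² ≤ 0 in ~82%. This is genuine
small-sample behavior of cross-validated discriminant models, not a
defect of the estimator — with 8 samples and 12 variables, chance
correlation occasionally survives cross-validation. Consequently a
positive Q² alone is weak evidence at this size; the permutation test is
the appropriate check.

## Random-forest Gini importance

Mean decrease in impurity from a scikit-learn random forest (500 trees,
sqrt(p) features per split, bootstrap, fixed seed). The raw importance
is the average of per-tree *unnormalized* impurity decreases, reported
alongside a sum-to-1 normalized column; ranks break ties by compound
name. A fixed seed gives bit-identical importances.

Seeded forests are *not* exactly equivariant under column permutation:
the per-tree RNG stream binds to column positions, and with n = 8 many
features induce identical best partitions, with ties broken by feature
visit order. Equivariance holds statistically (mean importances over 40
seeds agree within ~9% between column layouts) and at the level of
ranks for clearly separated variables.

## Fusion score and signature screen

VIP and Gini are placed on a common scale by min–max normalization,
`x_nom = (x − min)/(max − min)` over the compounds being screened (all
tied extremes map to 0 or 1; an all-equal column is an error since the
map divides by zero), and averaged:

    X_A = (VIP_nom + Gini_nom) / 2.

A compound is a *signature differential flavor component* when **both**
VIP ≥ 1 (raw VIP, inclusive cut) and X_A > 0.5 (exclusive cut).
Screening uses full precision; 2-decimal rounding is display-only. The
screen operates by default on the union of the per-group key-flavor sets
(the compounds that qualify for a ROAV table), configurable to all
compounds.

**Q² gate in the pipeline.** When VIP and Gini are fitted from replicate
data, `run_pipeline` suppresses the signature list unless the OPLS-DA
model cross-validates (Q² > 0, configurable). Min–max normalization
guarantees some compound reaches x_vnom = 1, so an ungated screen
reports "signatures" even on pure noise; gating on model validity is the
analogue of validating the discriminant model before interpreting its
loadings. The gate does not apply when VIP/Gini are supplied as an
external (published) table.

## Synthetic data generator

Raw areas are drawn log-normally per compound × replicate with
`E[area]` equal to a configured per-group linear mean (0 = absent;
`log_sigma = 0` gives the noiseless limit exactly); planted discriminant
compounds have their mean multiplied by a fold change > 1 in a
designated group, per compound. Defaults: 2 groups × 4 replicates.

- **paper** preset: 61 compounds with presence masks and mean contents
  matched to the packaged published table; per-compound log-sigma is
  back-computed from the published CVs (up to ~0.9). Only the 12
  published thresholds are emitted.
- **strong-signal** preset: 12 compounds; 8 background compounds with a
  skewed abundance profile and 4 planted minor discriminants (~1% base
  share) at a 6-fold effect, two elevated in each group with
  mass-balanced base areas. The bidirectional, mass-balanced design
  keeps group totals equal so that closure (rows summing to 100%) leaves
  the background uninformative — a one-sided design would make every
  background compound coherently informative through renormalization.
  The 6-fold effect is conservative relative to real signature
  compounds, which are often group-exclusive (infinite fold change).
- **null** preset: the same table with no planted effect.

What the generator does *not* emulate: retention-time drift, co-elution,
detector saturation, missingness from detection limits, or correlated
compound families from shared biosynthesis. Passing tests therefore
demonstrate the statistical machinery under clean log-normal noise with
known ground truth, not robustness to real chromatographic artifacts.

The generator matches *expected* proportions; per-replicate closure
makes realized group means approximate (the convergence test tracks the
lognormal-mean standard error, which grows with the compound's CV).

## Problem sizes in tests

Monte-Carlo test sizes follow the study design they emulate: 4 replicates
per group and 12 compounds throughout; 50-seed runs for screen recovery,
100-seed runs for rank recovery and null calibration, 1000 runs (offline,
recorded here) to pin the null Q² tail at 81.6% non-positive.

## Known limitations

- Exact published OPLS-DA summaries (R²X, R²Y, Q²) and VIP/Gini
  magnitudes for the packaged study are not reproducible from printed
  tables because replicate-level data were not published; the printed
  VIP/Gini columns ship as inputs to the fusion stage instead, and the
  statistical machinery is validated on synthetic ground truth.
- Odor thresholds are matrix-specific; the packaged table transcribes
  water thresholds and the package does not attempt to estimate or
  harmonize thresholds.
- Descriptor matching is exact after canonicalization; "floral" and
  "flower" remain distinct nodes, as in the source tables.
- Two-class designs only; multi-class OPLS-DA is out of scope.
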