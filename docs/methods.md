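# Methods

This note records the models, parameter choices, and numerical conventions
behind `fieldspot`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and input handling

Mutation tables use 1-based genomic positions; regions and panels use
0-based half-open BED intervals. All conversion is isolated in
`fieldspot.io`; a 1-based position *p* lies in BED interval `[s, e)` iff
`s < p ≤ e`. Chromosome names are normalized at ingest (leading `chr`
stripped) so mixed conventions interoperate. Only single-nucleotide
substitutions are analyzed: indels, multi-base substitutions and rows with
identical ref/alt are dropped at read time with a logged count. Duplicate
records are kept by default — merged multi-source catalogs can differ in
their deduplication conventions, so dropping exact duplicates is an
explicit opt-in (`MutationCatalog.deduplicated`). Catalogs carry an
optional explicit sample roster so samples with zero mutations still count
toward per-sample averages; `restrict_to_regions` preserves the roster.

## Window placement

Placement is a greedy maximal-capture search. Candidates are anchored at
each distinct position of a not-yet-captured record (window
`[p, p + w − 1]`, default *w* = 100 bp); at each step the candidate
capturing the most remaining records is selected, with deterministic
tie-breaks (lexicographically smallest chromosome, then smallest start).
Anchoring at *uncaptured* positions is essential: it makes the procedure
reproducible and capture-disjoint (every record attributed to exactly one
window, so capture counts sum to the catalog size). Selected windows can
still overlap *spatially* in rare configurations (an uncaptured position
just left of an earlier window); panel disjointness is therefore defined as
capture-disjointness. Windows never straddle chromosomes but may extend
past exon ends — the segments are genomic, not exon-clipped.

Greedy selection is not globally optimal. Empirically it matches the
brute-force best-capture-at-budget-*k* solution in ≈ 98% of random small
catalogs and, for the small budgets a panel designer uses (*k* ≤ 3 in our
checks), never captures fewer mutations than the *k* most-mutated fixed
tiles. At large budgets near full coverage the greedy and tiling orderings
can interleave, so no dominance is claimed there.

Panels keep the top `ceil(q·N)` ranked windows (*q* = 0.10 default);
ceiling guarantees a non-empty panel for any *q* > 0. Panel overlap uses a
≥ 1 bp intersection criterion and reports shared counts per side
separately, since window overlap between two panels need not be one-to-one.

## Hotspot refinement

The per-sample count matrix (samples × panel windows) feeds a single
one-way fixed-effects ANOVA with window as the factor. All-equal matrices
return the `F = 0, p = 1` convention. If the window factor is significant
at α (default 0.05), all-pairs Tukey–Kramer HSD is computed with the pooled
MSE and the studentized-range distribution (*k* groups, *N − k* error df).
A window is a hotspot when it beats — greater mean and adjusted *p* < α —
strictly more than a `majority` fraction (default 0.5) of the windows
ranked below it; the lowest-ranked window has no comparators and is never a
hotspot.

Numerical conventions: the hotspot decision compares the studentized-range
statistic against the cached critical value `ppf(1 − α, k, df)` (identical
to thresholding the adjusted p-value, and far cheaper in simulations);
exact adjusted p-values are available from `tukey_pairwise_p` and agree
with an independent implementation to 1e-6. Zero pooled within-window
variance raises a `DegenerateDataError` rather than emitting undefined
p-values. Tukey HSD on count data ignores non-normality; it is retained as
the method of record, with a max-statistic permutation alternative
(`method="permutation"`, 999 permutations by default) for sensitivity
analysis. The ANOVA/Tukey comparison is run within the supplied candidate
panel (not the full ranked list) — the panel is the set of windows actually
competing for sequencing space.

## Burden statistics

Window frequencies are per-sample normalized (captured mutations divided by
cohort size) before correlation, because cohort sizes in realistic designs
differ severalfold and raw counts would confound size with burden; raw
counts remain available. Pearson's r uses the two-sided t-transform p-value
with n − 2 df and refuses constant vectors rather than returning a silent
zero. Cohort comparisons default to the unpaired Wilcoxon rank-sum test
(cohorts are independent); the paired signed-rank variant is used for
window-wise paired vectors (e.g. the same samples' hotspot vs cold-spot
burden). The rank-sum test is exact when both samples have ≤ 25
observations and the pooled data is tie-free, otherwise tie-corrected
normal approximation. Fold changes are ratios of mean per-sample counts
("average mutations per sample"); a zero denominator is reported as an
infinite fold, not dropped. Cold-spot panels tile the footprint at the
panel width, drop tiles intersecting the hotspot panel, and keep the
`size` least-mutated tiles (ties by chromosome, then start).

## Risk classification

Features: hotspot-panel burden (raw per-sample count inside the panel),
age in years, a male indicator, and smoking one-hot indicators for
*current* and *former* with never-smoker as reference plus a missingness
indicator. Rows missing age or sex are dropped with a logged count. The
split is 70/30, stratified by label (the realistic cohorts are ~2:1
imbalanced, and unstratified splits destabilize small-test AUC), with
`floor(0.7·n)` per label and full determinism given the seed.

Models (hyperparameters pinned for reproducibility, ecosystem-typical):
L2 logistic regression with the penalty chosen by 5-fold CV on the training
split; a one-hidden-layer neural network (5 logistic units, seeded
initialization); a 500-tree random forest with √p features per split.
Numeric features are standardized using training statistics only.
Non-convergence is reported on the `ModelReport`, never raised.

ROC/AUC is computed in-package from midranks, which equals pairwise
concordance with ties counted ½ exactly (property-tested against brute
force on all instances ≤ 20 samples). Importance is permutation-based on
the held-out test set (mean drop in test AUC over 20 seeded permutations
per feature) rather than impurity-based: it is model-honest and comparable
across feature scales.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with full ground
truth:

- **Footprint**: 25 genes × 4 exons × 400 bp (~40 kb over 5 synthetic
  chromosomes; a few hundred background candidate windows) laid out
  arithmetically — the shape, not the scale, of a real targeted panel
  (~0.92 Mb). All desk-scale experiments use this footprint.
- **Hotspots**: 10 disjoint 100-bp windows placed uniformly inside distinct
  exons. Positions within a hotspot are uniform — the analysis operates at
  window resolution, so site-level recurrence is out of scope.
- **Burden**: per-sample totals are negative binomial (default mean 20,
  dispersion 2; variance = μ + μ²/2) — real cohorts mix targeted-panel and
  exome burdens with heavy overdispersion, so Poisson would be too tight.
- **Hotspot weight**: each mutation lands in a hotspot with probability
  `hotspot_weight` (default 0.3), choosing the hotspot by a
  Dirichlet-distributed weight vector (concentration 5), else uniformly
  over the **whole** footprint — hotspot windows also receive their
  width-share of background, so weight 0 reduces exactly to a uniform
  catalog.
- **Cohort structure**: a per-cohort multiplier scales both the burden mean
  and the hotspot weight. Passing one cohort's weight vector to another
  produces correlated cohorts; passing a disjoint hotspot set (planted
  under another seed) produces cohorts with fully independent hotspot
  structure — the null for the correlation contrast.
- **Clinical covariates**: age ~ Normal(mean per label, sd) truncated to
  [30, 95]; sex a fair coin; smoking categorical per label.

All randomness flows from a single integer seed through tagged
sub-streams (CRC-derived), so any cohort is reproducible in isolation;
files written by the CLI embed a config hash in a header comment.

The **risk scenario** (`risk_scenario_config`) fixes the high/low-risk
study: low-risk normal tissue with burden mean 4 and hotspot weight 0.03,
high-risk tissue with a 3× multiplier on both, donors 70 ± 5 vs 60 ± 5
years old, and smoking more prevalent in the high-risk group; cohort sizes
default to 233 high / 483 low. The burden baseline is deliberately small:
normal urothelium carries few somatic SNVs inside tumor hotspots, and the
dominant epidemiological signal is age — which is why age tops the
importance ranking while hotspot burden adds the margin that lifts the
random forest above the risk-factors-only model.

### What the synthetic experiments do and do not show

Passing recovery tests show the pipeline's statistics behave as designed
under the generative model: windows with genuinely elevated per-sample
rates are found (recall and precision ≥ 0.9 at the default signal
strength), exchangeable counts are almost never flagged, correlated
weight vectors are detected as correlated and independent structure as
uncorrelated, and burden-plus-covariates classification reaches the
expected discrimination. They do **not** show robustness to features of
real data the generator omits: trinucleotide-context mutation spectra and
signature structure, sequencing-platform and depth differences between
cohorts, calling-pipeline artifacts, copy-number variation, indels, or
site-level recurrence within hotspots. Conclusions about real cohorts
require the real catalogs.

## Problem sizes and runtimes

Desk-scale experiment sizes were chosen so the whole validation suite runs
in minutes on one CPU while keeping every statistical contrast
well-powered: 200-sample discovery cohorts (10 seeds) for recovery,
1000 null / 200 spiked 20-window panels for calibration, 150-sample cohort
pairs for correlation, a 126-sample validation cohort for the cold-spot
contrast, and 716 samples for the risk models.

## Known limitations

- The greedy placement is order-dependent by design; a different tie-break
  convention yields a different (equally valid) panel.
- Tukey HSD assumes homoscedastic, roughly normal group observations;
  per-sample window counts are small counts, so the adjusted p-values are
  approximate (the permutation mode exists for this reason).
- `panel_overlap` counts shared windows per side under a ≥ 1 bp criterion;
  other reciprocal-overlap conventions will give different shared/unique
  accounting when overlaps are not one-to-one.
- Burden features are raw counts; no normalization for per-sample
  sequencing footprint is applied before modeling.
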