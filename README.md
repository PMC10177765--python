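# fieldspot

Somatic mutation catalogs from tumors concentrate in short genomic hotspots,
and histologically normal tissue from high-risk patients carries measurable
mutation burden in those same hotspots (field cancerization). `fieldspot` is
a library for building and exploiting hotspot panels from such catalogs:

1. **Discovery** — place fixed-width (default 100 bp) mutation-capture
   windows over a tumor cohort's SNV catalog, rank them by capture count,
   and keep the top fraction (default 10%) as a candidate panel.
2. **Refinement** — keep only windows that capture *significantly* more
   mutations than most windows ranked below them (one-way ANOVA across
   windows, then all-pairs Tukey HSD).
3. **Burden statistics** — per-sample-normalized window frequencies,
   Pearson correlation of burden profiles between cohorts, Wilcoxon
   rank-sum/signed-rank comparisons, per-window fold changes, and
   equal-sized cold-spot control panels.
4. **Risk classification** — per-sample hotspot burden combined with
   personal risk factors (age, sex, smoking), a stratified 70/30 split, and
   logistic-regression / neural-network / random-forest classifiers scored
   with an exact rank-based ROC/AUC and held-out permutation importance.
5. **Synthetic cohorts** — a fully seeded generator with planted hotspots
   and ground truth, so every step above can be validated by parameter
   recovery.

It is aimed at researchers designing targeted sequencing panels for early
cancer-risk assessment, or analyzing mutation burden in normal tissue.

## The statistics in brief

*Placement.* Candidate windows of width *w* are anchored at each distinct
position *p* of a not-yet-captured mutation, spanning `[p, p + w - 1]`.
Greedily select the candidate capturing the most remaining records (ties:
smallest chromosome, then leftmost start) until every record is captured
exactly once. For a window budget *k*, the top-*k* windows dominate the *k*
best fixed tiles of the same width.

*Refinement.* For a candidate panel of *k* windows over *n* samples, treat
each window as a group with the per-sample counts as observations. After a
one-way ANOVA gate (window factor significant at α), compute all-pairs
Tukey–Kramer HSD with pooled MSE and the studentized-range distribution
(*k* groups, *N − k* error df). Window *i* is a **hotspot** iff

> #{ j ranked below i : p̃(i, j) < α and mean(i) > mean(j) } / #{ j below i } > ½

*Burden.* Window frequency = captured mutations / n_samples (zero-mutation
samples counted). Correlations use Pearson's r with the t-transform p-value;
cohort comparisons use the Wilcoxon rank-sum (exact when both n ≤ 25 and
tie-free), paired vectors the signed-rank test.

*Classification.* AUC is computed from midranks — exactly the probability a
random positive outscores a random negative with ties counted ½.
Random-forest importance is the mean drop in held-out AUC over 20 seeded
permutations of each feature column.

## Worked example

```python
import fieldspot as fs

cfg = fs.SimulationConfig(seed=7)                      # 10 planted hotspots
catalog, truth = fs.generate_cohort(cfg, "tumor", 200) # ~20 SNVs/sample
ranked = fs.rank_windows(fs.place_windows(catalog))
panel = fs.top_fraction_panel(ranked, q=0.10, name="tumor10")
hotspots = fs.refine_panel(catalog, panel, alpha=0.05, majority=0.5)
```

Running `python examples/02_refine_hotspots.py` (this exact pipeline)
prints:

```
ANOVA gate: F = 67.2, p = 0
8 hotspots kept out of 46 candidates:
window             gene      rank frac beaten  hotspot
3:38158-38257      GENE013      1        1.00  yes
4:23792-23891      GENE009      2        0.95  yes
...
recovered 8/10 planted hotspots
```

i.e. the window ranked first beats 100% of lower-ranked windows at the
Tukey-adjusted 5% level, the panel of 46 candidates collapses to 8
hotspots, and 8 of the 10 planted hotspots are recovered (the remaining two
drew small Dirichlet weights). `examples/03_compare_cohorts.py` and
`examples/04_risk_classification.py` walk through the burden statistics
(e.g. hotspot vs cold-spot burden 6.29 vs 0.35 mutations/sample, Wilcoxon
p = 3.4e-24) and the risk models (random-forest test AUC 0.915 with age the
top importance).

Each pipeline stage is also exposed as a thin CLI:

```sh
fieldspot simulate --cohorts "tumor:200" --out-dir sim
fieldspot discover --mutations sim/tumor.tsv --regions sim/footprint.bed \
    --out-panel panel.bed
fieldspot refine --mutations sim/tumor.tsv --panel panel.bed \
    --out-hotspots hotspots.bed --out-report report.tsv
```

Input formats are plain text: tab-delimited mutation tables (`simple-tsv`
or MAF-like columns), BED for regions and panels, CSV for clinical tables.

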