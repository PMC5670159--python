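# Methods

## The measurement model

Every trait enters the pipeline as a microtiter-plate absorbance.  Three
measurement families are distinguished by the assay table:

* **OD-based assays** (stress resistance, antibiotic resistance, growth on
  the 14 carbon sources, and the LB growth reference itself, all read at
  600 nm): signal is proportional to cell density, so the negative control
  (medium without culture) is subtracted and the result divided by the
  strain's LB stationary-phase OD₆₀₀.  The ratio is the trait — growth under
  the stressor relative to unstressed growth.
* **Dye-based supernatant assays** (exoprotease at 440 nm, biofilm crystal
  violet at 590 nm): blank-corrected absorbance is used directly and is not
  divided by growth, because the signal comes from the supernatant or the
  adherent film, not the planktonic density.
* **Curve-calibrated assays** (CAS siderophore at 630 nm, Salkowski IAA at
  535 nm): absorbance maps to a concentration through a fitted standard
  curve, so no blank is subtracted — the curve, measured in the same
  reaction mixture, anchors the zero point, and subtracting a medium control
  would double-correct.  The CAS mixture starts at 0.015 mM FeCl₃; iron
  chelated by secreted siderophores is removed from the dye complex, so the
  siderophore proxy is consumed Fe = 0.015 − inferred remaining, clipped to
  [0, 0.015] mM.  IAA standards span 10⁻⁶–10⁻⁴ M and are fitted on log₁₀
  concentration; inferred concentrations are reported in µM.

Both standard curves are ordinary least-squares lines.  Nothing in the
assays' range suggests saturation, and a linear Beer–Lambert response is the
minimal model; four-parameter logistic fitting is deliberately out of scope.
Inversions outside the fitted standard range are flagged (debug log), not
rejected, since screening of unknowns against a fixed curve cannot
guarantee containment.

## Normalization chain and its order

`assemble_trait_matrix` applies: blank correction → calibration → growth
normalization → metabolic standardization → abundance weighting, recording
each step in the matrix's provenance log.  Weighting is last so that every
weighted value is a rescaling of an already-normalized trait.  Relative
abundance is the strain's colony count divided by the summed counts of its
treatment (stage × plant × compartment); fitness and PGP traits are
weighted, metabolic profiles are not (they feed the niche breadth instead).

**Metabolic standardization scope.** "Divide by the maximum across all
carbon sources" is ambiguous between a per-isolate and a global maximum.
The per-isolate maximum is the default because niche breadth is a
per-isolate quantity — Σᵢ xᵢ/max(x) then measures how evenly a strain uses
substrates relative to its best one, on a fixed 0–14 scale with the maximum
achieved by a perfectly even profile.  A `scope="global"` switch preserves
between-strain magnitude differences instead.  An all-zero profile yields
breadth 0 rather than a division error.

**No-growth guard.** A strain whose LB reference OD falls below 0.05 AU
(configurable) never grew; dividing by it would manufacture huge trait
values, so the pipeline raises a named error instead.

## Diversity statistics

Functional diversity of a group is the arithmetic mean of all pairwise
Bray–Curtis distances among its strains' trait vectors, computed on the
weighted matrix by default (a flag selects the unweighted normalized
matrix; the choice is recorded in the provenance log and manifest).  Groups
with fewer than two strains are undefined and render as `N.A.`.
Bray–Curtis on two all-zero vectors raises an error rather than returning
0: a silent zero would hide degenerate normalization upstream.

Group comparisons use Kruskal–Wallis on the pooled pairwise distances,
followed by the all-pairs Nemenyi test: mean-rank differences referred to
the studentized range distribution with infinite degrees of freedom,
tie-corrected — the convention of the standard R implementation.  **The
pairwise distances are not independent observations**: two distances sharing
a strain are positively correlated.  The procedure is applied to them
anyway because that is how the field uses it, but the consequence is
quantified in the test suite: on null data (20 isolates, stage grouping)
the Kruskal–Wallis rejection rate at α = 0.05 is ≈0.22, not 0.05.  The
quadratic-trend F-test, whose observations are independent strains,
calibrates nominally (≈0.05–0.06) under the same null.  p-values from the
distance-based Kruskal–Wallis should therefore be read as descriptive
ranking evidence, not calibrated error rates.

The Nemenyi approximation itself is asymptotic: at 5 observations per group
it deviates from the exact permutation distribution by up to ~0.03; at 10
per group agreement is within ~0.003 (checked against a 10⁵-permutation
oracle).

## Trend, ANOVA and ordination choices

* Stage age is **numeric** in trait regressions (years) and **categorical**
  in the CFU ANOVA/Tukey — the two roles it plays in the design.
* Trait trends use degree-2 polynomials by default; the reported shapes
  (hump, U) are quadratic-like, and the classification reads the fitted
  parabola: hump iff curvature < 0 and the vertex −b/(2c) lies inside
  [5, 105] years; monotone classes by the derivative's sign over the
  domain; `flat` when the overall F-test is not significant at 0.05.  No
  cross-trait multiplicity correction is applied by default.
* The CFU ANOVA uses sequential (type-I) sums of squares, the convention of
  the reference environment; the design is balanced, where type I and II
  coincide.  Normality (Shapiro–Wilk per group) and variance homogeneity
  (Fligner–Killeen) are reported as advisories; the pipeline proceeds
  regardless.
* Spearman's ρ uses average ranks; its p-value is exact (full enumeration
  of rank permutations) for n ≤ 9 and the t approximation above.
* Z-scores use the sample (n−1) standard deviation; constant traits map to
  zero columns.  The high/low split is average-linkage agglomerative
  clustering on Euclidean distance over the category's Z-scored columns,
  cut at k = 2; "high" is the cluster with the larger grand mean.  k = 2 is
  fixed in the pipeline because the profile view is a binary split; general
  k is available only through scipy directly.
* PCA operates on ln(1+x)-transformed, column-centered, **unscaled** values
  via SVD.  The offset δ = 1 keeps the transform defined at the exact zeros
  abundance weighting produces; a half-minimum-positive policy was
  considered and rejected because it makes the transform data-dependent
  across runs.  Component signs are fixed deterministically (largest
  loading positive).

## The synthetic-study generator

The generator emulates the screening campaign's design: 5 stages × 3
plots × 2 plant species × 2 compartments, ≤32 morphotype colonies per
treatment sample, strain colony counts from a Dirichlet(1)–multinomial,
CFU from its own quadratic stage model, and per-trait quadratic stage
responses with plant/compartment offsets.  Its central engineering choice:
it writes **raw plate absorbances**, produced by pushing each strain's true
trait value backwards through the normalization chain (× LB OD, + blank,
standard-curve forward transform), so the analysis pipeline's forward pass
is exercised in full and recovers the truth exactly when noise is zero.

Noise is multiplicative lognormal at two levels, matching nonnegative plate
reads whose error grows with signal:

| parameter | default | meaning |
|---|---|---|
| `noise_sd` | 0.15 | plate measurement error (log scale) |
| `strain_sd` | 0.45 | strain-to-strain trait heterogeneity within a treatment |
| `lb_od_sd` | 0.10 | spread of LB stationary-phase OD around 1.2 |
| `cfu_model.noise_sd` | 0.15 | residual sd of log₁₀ CFU |

`strain_sd = 0.45` was set so that the generated quadratic stage trends
have coefficients of determination around 0.4, the upper end of the
magnitudes such screens report; smaller values make trends unrealistically
clean, larger ones bury them.  Trait shapes default to: salinity resistance
and siderophore production peaking at the 35-year stage, antibiotic
resistance peaking at 65 years, osmotic stress in a shallow U, remaining
traits stage-flat, and stage-varying substrate baselines for the 14 carbon
sources so niche breadths differ between strains.

Named fixtures: `tiny` (8 isolates, 2 stages — smoke runs), `paper_like`
(fixed strain plan totalling 59 strains over the 20 treatments, the
screening scale), `null` (20 single-strain treatments, every stage, plant
and compartment effect zeroed — type-I calibration), and `hump35` (6
strains per treatment with the salinity vertex planted at 35 years —
parameter recovery; at default noise the fitted vertex lands within ±10
years in ≥90 % of seeded runs).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: phylogenetic correlation among strains (strains
are exchangeable within a treatment), plate-position and edge effects,
assay-specific saturation or hook effects, cross-plot heterogeneity within
a stage beyond random plot assignment, and any taxon–trait association.
Recovery results demonstrate that the pipeline is a faithful inverse of the
stated measurement model, not that the model captures every property of a
wet-lab screen.

## Numerical and degenerate-input conventions

TSVs are UTF-8, tab-separated, `.` decimal, floats at 17 significant
digits (12 for derived outputs), giving byte-identical reruns under a fixed
seed and ≤1e-12 numeric round trips.  Blank wells use the literal isolate
id `BLANK`.  Missing raw readings are an assembly error, never NaN
propagation.  Zero CFU values are replaced by half the detection limit
(default 1) before the log transform.  Replicates are averaged wherever
more than one exists; at least one is required.  Kruskal–Wallis on fully
constant data returns H = 0, p = 1 rather than an error.

## Problem sizes used in the checks

The automated checks run at deliberately modest scale: 1000 null datasets
of 20 isolates for type-I calibration, 100 seeds of the 120-isolate
`hump35` fixture for vertex recovery, 100 seeds at the 59-strain scale for
diversity-ranking recovery, and a 10⁵-permutation oracle for the Nemenyi
comparison.  These sizes give Monte-Carlo standard errors comfortably
below the decision margins involved.
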