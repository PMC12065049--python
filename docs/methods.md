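# Methods

## Scope and data model

The package evaluates plot-scale sampling error for the three core
transect methods used by standardized monitoring programs. The reference
("full") design is the one used on 1-ha National Wind Erosion Research
Network-style plots: three 100-m transects radiating from the plot
center at 60° spacing, line-point intercept (LPI) pins every 0.25 m
(1200 per plot), vegetation height points every 2 m (150 per plot), and
continuous canopy-gap intercept with a 5-cm minimum gap. Transects are
modeled as directed spokes with along-transect positions in integer
centimeters, 0 at the plot center; integer positions make interval
thinning exact (all reduced intervals are multiples of the 25-cm and
200-cm base spacings) and eliminate floating-point ambiguity at class
and truncation boundaries. A "sampling event" is one dated visit at
which all three methods are run; repeated events within a plot are the
nested replicates of the agreement analysis.

Four indicator families are computed per plot-event: total foliar cover
(percent of pins intercepting at least one plant layer, live or dead),
species count (distinct plant codes over all layers), canopy gap class
cover (percent of sampled transect length in gaps of 5–24, 25–50,
51–100, 101–200 and >200 cm, membership by integer gap length), and mean
vegetation height. Which layer codes count as "plant" is configuration
(`NonPlantCodeSet`), because code dialects differ across programs; the
default set covers the no-hit marker, litter, soil, rock, bedrock, duff,
moss, lichen and water codes.

Two conventions were genuinely open and are resolved as follows:

* **Mean height excludes plantless points** rather than imputing zeros:
  the indicator is the mean height of rooted plants, not of points. A
  program that wants point-mean-with-zeros can impute before ingest.
* **A pin intercepting only non-plant codes** counts in the cover
  denominator but not the numerator.

## Subsampling designs

A `Scenario` is (number of transects, transect length, LPI interval,
height interval). Applying one composes three reductions, in an order
that provably commutes for the deterministic steps:

1. **Transect omission** — a uniformly random subset, one seeded draw per
   (plot, event, transect design) shared by all three methods. Sharing
   mimics a crew laying out fewer physical transects; the alternative
   (independent subsets per method) would understate between-method
   correlation in the differences.
2. **Truncation** — positions beyond the cut are dropped; gaps are
   *clipped* at the boundary (the field protocol terminates a gap at the
   transect end) and clipped fragments shorter than 5 cm are discarded;
   layout lengths are updated so gap denominators use the walked length.
3. **Thinning** — pins/heights whose position is not a multiple of the
   new interval are dropped. Gap intercept is continuous and is never
   thinned.

The full-design scenario is an exact identity on the indicators, which
the pipeline emits as a self-check row (bias 0, half-width 0). The
difference sign convention is d = full − subsample, so positive bias
means the reduced design underestimates; species-count differences are
non-negative by construction (a subset of pins can only detect a subset
of species).

The default grid crosses one to three transects with 25/50/100-m
lengths, LPI intervals 0.25/0.5/1/2 m, and height intervals 2/4/8/16/20 m.
The height grid follows the published results table; the engine accepts
any multiple of 2 m.

## Nested limits of agreement

Differences are modeled as d_ij = μ + b_i + e_ij with plot effects
b_i ~ N(0, σ_b²) and event residuals e_ij ~ N(0, σ_e²). Estimation is
one-way random-effects ANOVA on the (generally unbalanced) plot
structure:

* bias μ̂ = unweighted mean of plot means (plots are the inferential
  subjects, so they are equally weighted under imbalance);
  CI μ̂ ± t_{k−1}·sd(plot means)/√k;
* σ̂_e² = pooled within-plot variance (df N−k);
* σ̂_b² = var(plot means) − c·σ̂_e², with c = (Σ 1/n_i)/k, truncated at 0;
* agreement half-width = z_{(1+L)/2}·√(σ̂_b²+σ̂_e²); limits = μ̂ ± half-width.

The confidence level and the agreement proportion are governed by one
`level` knob (0.95 or 0.80), matching how the acceptance criteria are
stated for this analysis.

**MOVER bounds.** Uncertainty in the limits is expressed by composing a
bias bound with a variance bound via the MOVER square-root rule, e.g.
upper bound = limit_hi + √((μ_hi−μ̂)² + z²(σ_hi−σ̂)²). The variance bound
is modified-large-sample (MLS): the plot-mean variance (df k−1) and the
residual variance (df N−k) enter as chi-square components with
coefficients (1, 1−c). Both component bounds are taken **one-sided at
the analysis level**, so the reported upper MOVER bound is an upper
level-confidence bound for the true upper agreement limit (and
symmetrically for the lower). This is the construction certified by the
Monte-Carlo coverage test: at k = 13 plots with 5–20 events each, the
measured one-sided coverage is 0.788 at the 80% level and 0.948 at the
95% level (4000 replicates; the test tolerance is ±2 points). Degenerate
inputs are handled explicitly: identical differences collapse every
bound to the bias; a single difference per plot degrades to the
classical unreplicated Bland–Altman limits (total variance = variance of
the k differences, one chi-square component).

Normality of the differences is reported (Shapiro–Wilk per indicator ×
design) but never gates the analysis; constant difference sets are
reported as degenerate rather than tested.

**Acceptance criteria.** A design passes for an indicator when the bias
CI contains zero and max(|mover_hi−bias|, |bias−mover_lo|) is within the
family threshold: 5 percentage points (cover, gap classes), 5 cm
(height), 2 species (species count). Thresholds mirror standard
field-crew calibration limits and are configurable.

## Design selection

Effort is ordered lexicographically: total transect length first, then
number of measurements. Walking and laying out transect dominates field
cost, and this ordering reproduces the published headline choices (e.g.
2 × 100 m at 0.5 m preferred over 2 × 100 m at 0.25 m and over
3 × 100 m at 1 m for total foliar cover at 95%). Because crews may weigh
the axes differently, all Pareto-minimal passing designs on (total
length, measurement count) are reported as ranked alternates; the
published 80% ties for cover (1 × 100 m at 0.25 m vs 3 × 50 m at 0.5 m)
appear exactly as such a Pareto tie. The reference design itself is
excluded from candidacy. `published.py` carries the transcribed pass
flags of the published scenario screening for the LPI indicators, so the
headline recommendations are reproducible without the field data.

## Synthetic studies

The simulator generates the study structure the analysis assumes, not a
calibrated ecosystem:

* **Canopies** are disks placed by a Thomas cluster process (Poisson
  parents, Poisson(μ_c) offspring displaced by an isotropic Gaussian
  σ_c). Clustering is the default because pin-drop bias depends on the
  relation between pin spacing, plant size and cluster size; a plain
  Poisson field is available as `generate_poisson_map` for closed-form
  checks. Defaults: μ_c = 8 offspring, σ_c = 300 cm, lognormal radii
  (median 30 cm, log-sd 0.4) — shrub-scale patches a few meters across.
* **The vegetation field spans the full transect reach** (half-width
  100 m plus a 5-m root buffer), not just the nominal 1-ha square, so
  the spokes never run off the vegetated area and the field is
  stationary along their whole length.
* **Cover gradient**: 13 plots by default with target cover log-spaced
  in density from 2% (playa-like) to 98% (closed canopy), times a
  lognormal plot effect (σ_plot = 0.2). Targets are *realized* cover:
  the density needed for a target is obtained from the exact
  point-coverage probability of the Thomas disk model,
  P(uncovered) = exp(−λ_p·I) with
  I = ∫(1−e^{−μ_c q(s)})·2πs ds, where q(s) is the probability that one
  offspring disk of a parent at distance s covers the point (a
  noncentral-χ² tail, Gauss–Hermite-averaged over the radius law). The
  naive Boolean inversion 1−exp(−λπE[r²]) would overshoot: clustered
  plants overlap within clusters and cover less area per plant.
* **Events**: 5–12 per plot; each event re-draws positions, radii and
  heights for a fraction σ_event = 0.15 of the base map's plants,
  creating the within-plot repeat-measures correlation the nested model
  partitions. σ_event = 0 yields identical events.
* **Sampling is exact**: a pin intercepts every disk covering its
  coordinates (layers recorded tallest-first, one per species); gaps are
  the maximal uncovered intervals ≥ 5 cm, recorded in integer cm (ends
  rounded inward); height points record the tallest intercepting canopy.
* **Determinism**: one master seed spawns independent per-plot streams;
  the pipeline spawns per-(plot, event, transect design) streams keyed
  by stable CRC-32 hashes, so adding scenarios never perturbs existing
  draws and identical configurations reproduce outputs byte-for-byte.

What the simulator does **not** emulate: real species assemblages and
phenology, seasonal within-plot trends (events are exchangeable
replicates, as the nested model assumes), observer error, elliptical or
layered canopies, and spatial autocorrelation structures beyond
two-level clustering. Passing tests therefore demonstrate that the
estimators and the pipeline behave correctly under the variance
structure the analysis assumes — not that any particular real ecosystem
meets a given acceptance criterion.

## Problem sizes and numerical choices

The test suite and acceptance script use scaled study sizes chosen to
exercise every code path with comfortable Monte-Carlo margins: 6–8 plots
× 3–4 events for pipeline and trend checks (20 seeds for the
monotonicity tests), 4000 replicates for MOVER coverage, 30–50 plots for
the Boolean-model check. Variance components are truncated at zero;
MOVER bounds are clamped to enclose the limits; Gauss–Hermite quadrature
uses 24 nodes and the coverage integral an 800-point trapezoid on
[0, 6σ_c + r_max]. Results tables round-trip CSV at six decimals.

## Known limitations

* The MOVER construction is asymptotic in k; with very few plots
  (k ≤ 4) the outer bounds are wide and their coverage is not certified.
* Bias weighting treats plots equally; precision-weighted alternatives
  would change results under strong imbalance.
* The acceptance thresholds are absolute (percentage points, cm,
  species); proportional or log-scale agreement is out of scope.
* Real-data ingest expects the documented four-CSV layout; mapping from
  program-specific schemas is left to the user.
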