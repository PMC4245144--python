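# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where the design was genuinely open,
and what the synthetic-data validation does and does not establish.

## Plotless density estimation

**Data model.** Each sampling date yields *n* sample points (default
72 = 12 transects × 6 points, 0.30 m apart) with a point-to-nearest-open-
flower distance, and for each found flower a flower-to-nearest-neighbour
distance. Both searches stop at the field limit *r*<sub>max</sub> = 0.15 m;
failures are censored. Under complete spatial randomness (CSR) with
intensity λ (flowers m⁻²), the searched area to the nearest object is
exponential: P(d > r) = exp(−λπr²).

**Truncation.** A per-date truncation radius *R* is the 70th percentile
(linear interpolation between order statistics) of the uncensored point
distances, so that roughly 30% of the longest point distances are
excluded from the squared-distance sum. Excluded and censored searches
still contribute their searched disc πR². The interpolation rule is
stated because quantile conventions can move *R* by up to one distance
gap. Truncation is selected on point distances only and shared by both
estimators; applying it to neighbour distances as well was considered and
rejected because the neighbour set is already selection-filtered.

**Point estimator.** The censored-exponential MLE

  D_P = m / (π (Σᵢ dᵢ² + (n − m) R²)),

with m the uncensored point distances ≤ R. Its small-sample bias is
multiplicative ≈ m/(m−1), under 2% at the standard layout.

**Neighbour estimator and the empty-lens correction.** The flower whose
neighbour is sought was located as the nearest flower to a sample point
at distance *d*; the disc of radius *d* around that point is therefore
known to be empty, and for small search radii about half of the
neighbour's search disc lies inside it. Ignoring this overlap inflates
neighbour distances and biases the naive truncated estimator low by
roughly one third *even under CSR*. The estimator therefore uses
effective searched areas

  A(r; d) = πr² − lens(r, d),

where lens(·) is the circle-overlap area of the radius-*r* disc centred
on the flower and the empty radius-*d* disc on whose boundary the flower
sits (closed form; equals πd² once r ≥ 2d). The Poisson MLE is then
D_N = m₂ / Σⱼ A(min(rⱼ, R); dⱼ), censored searches contributing A(R; dⱼ).

**Clustering correction.** The corrected point density is the geometric
mean D_C = √(D_P · D_N). On clustered patterns point distances oversample
the gaps between clumps (D_P biased low) while neighbour distances are
dominated by within-clump spacing (D_N biased high); the multiplicative
biases partially cancel. D_C equals both inputs when they agree and lies
between them otherwise.

**Uncertainty.** Percentile bootstrap (default B = 1000) resampling
sample points as units, each carrying its attached neighbour observation;
the truncation radius is re-selected on every resample. The standard
error is backed out of the interval as SE = (CI_hi − CI_lo)/(2t) with t
the two-sided critical value at the interval's level and n − 1 degrees of
freedom (71 at the standard layout). Degenerate resamples with no
detections evaluate to zero density rather than failing.

**Validated behaviour** (all computed by `floralres.validation`, asserted
in the test suite at the sizes given):

* CSR, λ ∈ {50, 200, 500} m⁻², 72 points, 500 replicates: relative bias
  of D_P, D_N and D_C each within ±5% (measured ≲2%).
* Bootstrap 95% intervals on CSR (λ = 200, 200 replicates, B = 400):
  empirical coverage ≈ 93–96%, inside the 88–99% acceptance band.
* Thomas-clustered patterns at the plant-clump defaults below:
  E[D_P] ≤ E[D_C] ≤ E[D_N] and |bias(D_C)| < min(|bias(D_P)|, |bias(D_N)|)
  (measured ≈ −77%, +170%, −23%).

**Validated regime and known limitation.** The clustered validation uses
a Thomas process with 1 parent m⁻², 50 mean offspring and 0.10 m Gaussian
scatter — one flowering plant per m² carrying ~50 open flowers clumped on
its cyme, i.e. distinct dense clumps separated by bare ground, which is
the within-plot structure the correction is designed for. When clusters
overlap heavily (scatter comparable to inter-plant spacing) the pattern's
local density contrast fades: D_N approaches truth while hard field-limit
censoring still drags D_P down, both biases become negative, and the
geometric mean can no longer out-perform the better single estimator.
Absolute accuracy on strongly clustered patterns is modest (here ≈ −23%);
the correction narrows, not eliminates, the clustering error. Because the
legacy software used on the original field data is unpublished, observed
field densities can only be reproduced structurally, not numerically.

## Season integrals

All areas under curves use the trapezoid rule on the observed day grid,
with no extrapolation beyond the first or last observation: %t from
percent cover, pvt from the total visitation rate (counts divided by
observers × minutes), ∑f ha⁻¹ from the flower-density curve. Visitation
intensity is pvt/%t (undefined and flagged at zero %t). Relative
comparisons are plain ratios, 100·a/b — the "X% higher" phrasing in field
reports corresponds to this ratio reading, and summaries round it to
whole percent. Replicate plots are averaged onto their common date grid
before integration (treatment-mean curves); by linearity of the trapezoid
rule this equals averaging per-replicate integrals, and a test asserts
it. Honey-bee share per observation is the honey-bee rate over the total
rate (undefined on insect-free days, which contribute zero to both
integrals of the season aggregate).

Reporting precision in summary tables: %t and pvt to whole units,
intensity to two decimals, ∑f to two significant figures in 10⁹ units,
sucrose and money to whole kg/$.

## Nectar energetics

Nectar volume is column length over capillary length times capillary
capacity (1, 5 or 10 µL). Sucrose concentration uses the standard
refractometry quadratic c(C) = 0.00226 + 0.00937 C + 0.0000585 C²
mg µL⁻¹ (C in °Brix, valid 0–85), so mass (µg) = 1000·v·c(C); this
reproduces the classic soybean benchmark (0.01 µL at 36.2 °Bx ≈ 4 µg,
"about 5 µg per flower" at one significant figure). Daily per-flower
production is the sum of the three 2-h interval means (0900–1100,
1200–1400, 1500–1700), pooled as an unweighted mean over all flowers and
sampling dates. Hectare-season sucrose is ∑f ha⁻¹ × µg d⁻¹ × 10⁻⁹ kg µg⁻¹.
Hive support divides by a colony's annual sugar requirement (100–200 kg)
and rounds half-up to whole hives. The model deliberately assumes
constant per-flower production across anthesis and full collection of the
nectar flow; both assumptions overstate deliverable support and are the
reason hive counts are reported as a potential, not a forecast. No
secretion-rate dynamics or flower-density feedback on secretion is
modelled, and pollen is out of scope.

## Economics

Gross return = yield × contract price ($5.30 kg⁻¹ default); net return
assumes the commodity net:gross ratio (0.32); break-even yield against a
commodity net return N is N/ratio/price. Planting-class yields are
unweighted means over site-years. Dollar and kg figures round to whole
units for reporting, which matches every published check value except
one internally inconsistent gross-return figure in the source trial's
earliest year (excluded from checks).

## Synthetic field generator

The generator produces the study conditions the estimators assume, with
these defaults (chosen once, from the trial's reported magnitudes):

* **Spatial**: plots 3.1 × 12.2 m; CSR patterns for null-model recovery;
  Thomas patterns (Poisson parents, Poisson offspring counts, isotropic
  Gaussian scatter, offspring outside the plot dropped, nominal density
  recorded before that edge loss) for clustering. Transects lie parallel
  to the plot's long axis at uniformly random positions fully inside the
  plot (placement was not recorded in the field protocol; rows run the
  long way, so ropes do too). No toroidal wrap-around — censored searches
  carry the field limit as their searched radius, exactly as in the field.
* **Season curves**: a scaled beta density over the anthesis window
  (concentration k = 4), zero at first flower and harvest, mode exactly at
  the peak-day offset; defaults 45 d to first flower, 55 d anthesis, peak
  cover 40% at day 17, peak density 3×10⁷ flowers ha⁻¹ (integrating to
  ≈10⁹ flowers ha⁻¹ season⁻¹), peak visitation 35 insects min⁻¹
  observer⁻¹, honey-bee share 0.5. Any unimodal family satisfying these
  constraints would serve; the beta was chosen for its exact mode control.
* **Noise**: multiplicative mean-one lognormal (CV 0.15) for cover and
  density — positive-valued visual scores; Poisson counts split
  multinomially across the six insect categories (non-honey-bee weights
  0.20/0.10/0.40/0.05/0.25 for bumble bee/other bee/fly/butterfly/other,
  flies prominent as in field shoulders) for visitation. `noise_cv = 0`
  yields the exact noise-free curves, which the round-trip tests exploit.
* **Nectar**: interval means (180, 280, 175) µg per 2 h — midday peak,
  summing to the measured 635 µg d⁻¹ — at 30 °Bx, capillaries 64 mm long,
  column lengths back-computed so the standard arithmetic recovers the
  intended mass; the smallest capillary holding the volume is used.

What passing on synthetic data shows: the estimators recover known
densities under their stated spatial models, the integral metrics are
exact quadrature, and the pipeline is deterministic under seeding. What
it does not show: real flower patterns need not be Thomas processes
(plants vary in size, rows impose anisotropy), visual cover scores can be
observer-biased rather than mean-one noisy, and real nectar production
varies with weather and flower age. Field accuracy claims therefore rest
on the structure of the estimators, not on these simulations.

## Numerical conventions and degenerate inputs

Quantiles interpolate linearly between order statistics. Integrals
require ≥ 2 strictly increasing days and reject duplicates. A sample with
no detections estimates zero density with a warning rather than failing;
a fully censored sample raises an estimation error (distinct CLI exit
code 3; schema violations exit 2). Row-level schema violations drop the
row and log row and column; missing columns are structural errors. Seeds
propagate through `numpy.random.SeedSequence.spawn`, making every stage
independently reproducible; identical configs and seeds produce
byte-identical output files (fixed CSV float formats). Pipeline problem
sizes (weekly density dates, 72 points per date, B = 400 bootstrap in the
pipeline default, 300–500 Monte-Carlo replicates in the validation
studies) were sized to keep the estimators' Monte-Carlo error well below
the tolerances they are tested against.
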