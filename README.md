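# floralres

Quantifies what a flowering oilseed crop offers pollinators, and what it
offers the grower. Built for quantitative pollination ecologists and
agronomists evaluating alternative crops such as oilseed echium
(*Echium plantagineum* L.): dense, long-flowering stands whose value lies
both in seed revenue and in season-long floral resources for honey bees
and wild pollinators.

The package chains four stages:

1. **Plotless flower-density estimation** (`floralres.density`). Field
   crews record, at sample points along transect ropes, the distance to
   the nearest open flower and from that flower to its nearest neighbour,
   both censored at a 0.15 m field limit. Under complete spatial
   randomness the squared distances are exponential,
   P(d > r) = exp(−λπr²), and each estimator is the censored-exponential
   maximum-likelihood estimate of λ with truncation radius *R* chosen to
   exclude ~30% of the longest point distances:

       D_P = m / (π (Σᵢ dᵢ² + (n − m) R²))

   The neighbour estimator additionally discounts the part of each search
   disc already known to be empty from the point search (an overlap-lens
   area correction). The **corrected point density** is the geometric
   mean D_C = √(D_P · D_N), which cancels the opposite-signed biases the
   two distance sets acquire on clustered patterns. Confidence limits
   come from a percentile bootstrap over sample points; the standard
   error is SE = (CI_high − CI_low) / (2t).
2. **Season integrals** (`floralres.phenology`). Trapezoidal areas under
   the observed curves: flower coverage time %t (percent·days),
   pollinator visitation time pvt (insects·min⁻¹·observer⁻¹·days),
   visitation intensity pvt %t⁻¹, and the cumulative flower sum
   ∑f ha⁻¹.
3. **Nectar energetics** (`floralres.nectar`). Microcapillary volumes
   (column length / capillary length × capacity) and °Brix readings give
   sucrose mass via the standard quadratic concentration curve; the three
   2-h interval means sum to daily per-flower sucrose, which scales by
   ∑f ha⁻¹ to kg of sucrose per hectare-season and, against a colony's
   100–200 kg yr⁻¹ sugar need, to a supportable-hive range.
4. **Economics** (`floralres.economics`). Gross returns (yield × contract
   price), net returns via the commodity net:gross ratio, and break-even
   yields against commodity reference net returns.

A synthetic-field simulator (`floralres.synthetic_field`) generates all
five record types — Poisson (CSR) and Thomas-clustered flower patterns,
transect distance samples, unimodal cover/density/visitation seasons, and
nectar records — with known ground truth, so every estimator is validated
by parameter recovery (`floralres.validation`). Published summary values
from a three-year Minnesota sowing-date trial ship in
`floralres.datasets` as worked-example inputs.

## Worked example

Run the whole seeded chain — simulate a season per sowing treatment,
re-estimate flower density from 72-point distance samples on weekly
dates, integrate, convert to sucrose and hives, and price the yields:

```sh
$ floralres pipeline --seed 1 --out demo/
 year planting_time  coverage_time  pvt  intensity  flower_sum_billion  sucrose_kg_ha  honeybee_pct  hives_min  hives_max  seed_yield_kg_ha  gross_return_usd_ha
 2013         early           1107  839       0.76                 0.6            370            50          2          4               430                 2279
 2013           mid           1112  953       0.86                 1.1            679            52          3          7               387                 2051
 2013          late            842 1120       1.33                 0.6            372            50          2          4               258                 1367
```

Reading the early-sown row: flowers covered an integrated 1107
percent·days of ground (%t); pollinator walks accumulated 839
insect-minutes-rate·days (pvt), i.e. 0.76 insects per unit of flower
area-time; the crop produced 0.6 billion flowers ha⁻¹ over anthesis,
worth 370 kg of nectar sucrose per hectare — enough sugar to sustain 2–4
honey-bee colonies for a year — while 430 kg ha⁻¹ of seed grossed
$2279 ha⁻¹ at the $5.30 kg⁻¹ contract price. Note the late sowing's
higher intensity (1.33 vs 0.76): fewer flower-days but proportionally
more insects per flower, the signature pattern of late-sown stands.

The same stages are available piecemeal (`floralres simulate`,
`density`, `phenology`, `nectar`, `econ`, `report`) on the documented CSV
schemas, and as plain library calls:

```python
from floralres import estimate_density, hives_supported, season_sucrose_per_ha
from floralres.validation import sample_csr

est = estimate_density(sample_csr(200.0, seed=1), n_boot=1000, seed=1)
print(f"{est.per_ha:.3g} flowers/ha (95% CI {est.ci_low:.3g}-{est.ci_high:.3g})")
print(hives_supported(season_sucrose_per_ha(1.01e9, 635.0)))   # -> (3, 6)
```

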