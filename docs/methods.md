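# Methods

## Scoring model

The assessment converts land cover into ecosystem-services potential
(ESP) with a lookup matrix: each of the 27 Urban Atlas LULC classes has
a relative score in [5, 100] for six services (I1 biodiversity
integrity, P1 drinking water, R1 flood protection, R2 air quality, R3
water purification, C1 recreation & tourism). The approach assumes that
potential is a property of the land-cover class alone — two forest
patches score identically regardless of condition, connectivity or
management — which is what makes pan-regional comparisons from a single
harmonized LULC product possible, and is also the model's main
simplification.

The bundled matrix is a **synthetic reconstruction**. The original
adapted matrix is distributed only as supplementary data of its study;
the file shipped here reproduces every anchor printed in the main text
— forests I1 = 70, arable 30, continuous fabric 5; the open-spaces
class (33000) averaging 22 over six services with min 10 / max 50;
exactly 18 of 27 classes at the floor score 5 for drinking water; the
global minimum 5; forests/wetlands/water ranked highest overall;
fast-transit roads and ports lowest for biodiversity — and fills the
remaining cells with plausible values in the Burkhard-matrix tradition.
Analyses that depend on individual non-anchored cells should load the
original matrix instead (`load_matrix` accepts any complete CSV).

Two matrix-construction helpers encode how a coarse-nomenclature matrix
is downscaled to the Urban Atlas classes:

* `distribute_subclass_scores(parent, n, lower, upper)` splits one
  parent score over density-ordered subclasses. Only two constraints are
  inherent to the method — the group mean must equal the parent and the
  values must stay inside the bounds set by the neighbouring artificial
  and natural classes — so the spacing is a package choice: equal steps
  symmetric about the parent, default step 10 score points, shrunk to
  fit the bounds. Symmetry makes mean preservation exact without any
  rebalancing pass.
* `merge_class_scores` averages several source-class scores into one
  target class (used when several water/wetland source classes collapse
  into the single Urban Atlas class).

## Geometry and areas

All geometric computation is planar and assumes a projected equal-area
CRS in metres (the Urban Atlas native LAEA family); areas are
`shapely` polygon areas / 10⁴ ha. There is no reprojection machinery —
inputs in geographic coordinates must be projected upstream. Supported
formats are GeoJSON (geometry) and CSV attribute tables (geometry-free);
the minimum mapping unit is not enforced on input.

Area resolution is governed by a policy: `geometry-first` (default)
trusts the polygon and logs disagreements beyond 1% with an area
attribute; `attribute-first` supports tabular workflows where the
attribute is authoritative.

Scoping to the urban core uses `split` mode by default: a
boundary-straddling patch is partitioned geometrically and its
attribute area allocated by the geometric fraction, so total area is
conserved exactly. `centroid` mode assigns patches whole, for workflows
without reliable geometry. The metropolitan level is always the union
of both scopes. Whether real straddling patches should be split or
assigned whole is not observable from the change products alone; both
modes are provided and the choice is recorded in the run configuration.

`derive_change` prefers a geometric overlay (intersections of
differing-class regions, via an STRtree) and falls back to an id-join
(full-patch class flips) for tabular mosaics. A supplied change product
takes precedence over self-derived change in the CLI pipeline, since
the upstream product encodes the producer's own change mapping.

## Indicators

Equations as in the README. Numerical conventions:

* Both un-normalized totals (score·ha) and A_tot-normalized densities
  are first-class outputs for ESPcum and ESPDcum; worked-example
  bookkeeping uses totals, cross-city comparison uses densities.
* ESPDmean is the plain mean of area-free per-patch changes; an
  `area_weighted` flag yields the mean of per-patch change totals
  (ESPD_p·A_p) instead, matching the alternative bookkeeping some
  summary tables use.
* Records whose two classes share a score contribute 0 to ESPD and are
  counted in `n_changed` but not `n_nonzero` (the count of alterations
  that actually moved the indicator).
* `change_intensity` reports m² of natural→artificial conversion per ha
  of study area; the class grouping (artificial = 1xxxx, natural/
  semi-natural/agricultural = 2xxxx–5xxxx) is a configurable table.
* Degenerate inputs: an empty change set is a valid no-change case for
  ESPDcum (0) but leaves ESPDmean/ESPDch.i undefined (reported missing,
  never 0); empty mosaics are errors.
* Conservation: ESPcum(new) − ESPcum(old) equals ESPDcum of the derived
  change set. This holds to float precision and is enforced in tests at
  1e-6 relative.

## Trends and correlations

Trend classification compares ESPDcum (density variant by default)
between two consecutive periods: accelerating iff d2 − d1 < −ε, slowing
iff > +ε, stable inside the band. ε defaults to 0 because the published
two-colour presentation admits no third class; it is configurable for
noisy inputs. The aggregate statistic is
100·(Σd2 − Σd1)/|Σd1| — positive when the combined deterioration
shrank. Cities missing a period are excluded and logged rather than
imputed.

Correlations are plain Pearson coefficients on pairwise-complete
city observations (panels differ per factor across data sources), with
two-sided p-values from the t transform reported but never used to
filter, and no multiple-testing adjustment — matching how such
screening analyses report raw r.

## Synthetic scenarios

The generator emulates the structure of the real inputs, not their
cartography:

* **Mosaics** — patch classes drawn from a class-weight census
  (defaults: agriculture ~24%, forest 20%, artificial ~27% of patches,
  the typical composition of a functional urban area), areas lognormal
  (μ=1, σ=1 in log-ha, median ≈ 2.7 ha — patch areas in such products
  are heavy-tailed). Grid layout tiles vertical strips of proportional
  width in a 1 km band with a rectangular core covering `core_fraction`
  (default 0.25) of the area; this is deliberately schematic, chosen
  because strip/rectangle intersections have analytic areas that make
  split scoping exactly checkable.
* **Transitions** — donors (arable, pastures, herbaceous, complex
  cultivation, forests) convert to extraction/dump sites (25%),
  construction (20%), industry (18%), dense discontinuous fabric (12%)
  and other artificial sinks, so default scenarios are
  decline-dominated in every service — qualitatively the urbanization
  pressure the indicators were designed to detect, with no claim to
  real magnitudes. The per-period selection probability is calibrated
  so the expected transformed share of total area equals
  `change_fraction` (default 0.05 per six-year period) exactly,
  accounting for partial-patch conversions (probability 0.3, uniform
  fraction 0.25–0.75). Change records are emitted alongside the new
  mosaic and are exactly consistent with it.
* **Covariates** — for a target correlation ρ, the standardized
  indicator z is mixed with fresh Gaussian noise as ρ·z + √(1−ρ²)·ε and
  affine-mapped to a plausible scale per covariate (e.g. latitude
  50 ± 8°, expansion ratio 5 ± 3%). The planted ρ is stored in a
  ground-truth manifest; recovery is checked within 3 standard errors
  on the Fisher-z scale.

All randomness derives from one seed through per-operation
`SeedSequence` spawn keys, so generators are pure functions of their
specs and adding a call never perturbs other draws.

What passing synthetic tests does **not** show: realism of urban
morphology (no fragmentation structure, no contiguity), realistic class
adjacency, minimum-mapping-unit effects, or the data-quality issues of
real products (topology errors, nomenclature drift between epochs).

## Problem sizes

Default test and acceptance runs use mosaics of ≤ 1000 patches,
100-seed conservation sweeps at ≤ 50 patches, and 500-city covariate
panels — sizes at which every stochastic check is stable at the 3·SE
level while the full suite stays fast.

## Known limitations

* No reprojection: equal-area projected input is a precondition.
* GeoJSON/CSV only; container formats (GeoPackage, Shapefile) are not
  read.
* Scores are class-level constants; no within-class condition
  modifiers, no uncertainty propagation on matrix scores.
* The coastal vs. inland water-class averaging is frozen into whichever
  matrix file is loaded; there is one 50000 water class at runtime.
* `derive_change` id-join detects only whole-patch flips; partial
  transformations require geometry (or a supplied change product).
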