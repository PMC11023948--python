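# espdyn

Ecosystem-services-potential (ESP) scoring and change dynamics for
land-use/land-cover (LULC) patch mosaics.

Metropolitan regions lose ecosystem services mainly through land
conversion: forests, pastures and other natural surfaces turning into
construction sites, industry and urban fabric. `espdyn` implements the
expert-matrix assessment workflow used to monitor that loss across
functional urban areas: it scores polygon patch mosaics (Urban Atlas
conventions: 27 LULC classes, epochs six years apart, change layers in
between) against a 27-class × 6-service expert matrix, computes
area-weighted ESP indicators at urban-core and metropolitan scope,
classifies multi-period decline trends, and correlates the dynamics
with socio-economic and environmental covariates. It is aimed at
landscape ecologists and urban planners comparing cities, and ships a
synthetic-scenario generator so the whole pipeline is testable without
any external download.

## The model

An expert matrix assigns each LULC class *c* a relative potential score
*S(c, e)* ∈ [5, 100] for each of six ecosystem services *e*:
biodiversity integrity (I1), drinking water (P1), flood protection
(R1), air quality (R2), water purification (R3) and recreation &
tourism (C1). For a mosaic of patches *p* with areas *A_p* (ha) and a
change set of transformed patches, the indicators are

- ESPcum = Σ S(c_p, e)·A_p, optionally / A_tot (density form, in [5, 100]);
- ESPD_p = S(c_new, e) − S(c_old, e), the per-patch change;
- ESPDcum = Σ ESPD_p·A_p, optionally / A_tot;
- ESPDmean = Σ ESPD_p / n over the n altered patches;
- ESPDch.i = Σ ESPD_p·A_p / A_tot.ch, the area-weighted mean over the
  altered surface A_tot.ch only.

Negative change values mean deterioration. Comparing ESPDcum across two
consecutive periods classifies a city as *accelerating* (later decline
stronger) or *slowing*; Pearson correlations relate indicator dynamics
to covariates such as the urban expansion ratio.

The bundled default matrix (`src/espdyn/data/expert_matrix_synthetic.csv`)
is a synthetic reconstruction of the adapted expert matrix: it satisfies
all published anchor facts (see its module docstring) but is not the
original elicited dataset; any matrix in the same CSV layout is a
drop-in replacement via `load_matrix`.

## Worked example

The classic three-patch teaching mosaic: 20 ha, with 12 ha forests
(31000), 5 ha arable (21000), 3 ha continuous urban fabric (11100) in
2012; by 2018, 3 ha of forest became arable and 2 ha became fabric.

```sh
espdyn synth --preset table1 --out scn
espdyn compute -c cfg.yaml -o out    # cfg.yaml lists the two epochs + boundaries
```

The I1 (biodiversity) rows of `out/indicators.csv`:

```
       scope service  espcum_old_total  espcum_total  espdcum_total  espdcum_density  espdmean  espd_chi  n_changed
       urban      I1             225.0          95.0         -130.0       -21.666667     -65.0     -65.0          1
metropolitan      I1            1005.0         755.0         -250.0       -12.500000     -52.5     -50.0          2
```

At the metropolitan level the cumulative potential drops from 1005 to
755 score·ha; the change set alone reproduces the same −250 (the
boolean-difference equivalence), i.e. −12.5 per hectare of study area.
The mean loss per altered patch is −52.5 score points and the
area-weighted loss over the 5 transformed hectares is −50. Within the
6 ha urban core only the 2 ha forest→fabric conversion applies, hence
the single change record at −65.

The same computations are available as library calls
(`espdyn.esp_cum`, `espdyn.espd_cum`, …), and `espdyn trends` /
`espdyn correlate` cover the multi-period and covariate analyses.

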