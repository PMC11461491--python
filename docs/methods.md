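# Methods

## Zone grid

The epithelial thickness (ET) map is modelled as 41 zones on a 7-mm
disc: one central disc plus five concentric annuli, each divided into
eight octant sectors labelled by anatomical direction (S, SN, N, NI, I,
TI, T, TS; `TI` is the inferior-temporal octant).  This is the unique
regular ring/octant decomposition summing to 41 zones and consistent
with the paracentral zone names `cI` and `cTI`.  Ring boundaries default
to a 0.7-mm central disc plus five equal-width annuli out to 3.5 mm
(0.7, 1.26, 1.82, 2.38, 2.94, 3.5 mm); the radii are configurable and
affect only rendering and the synthetic-data geometry, never the
difference statistics.

Two zones are adjacent iff they share a boundary arc (adjacent rings,
same sector; the central disc borders all eight paracentral zones) or a
radial segment (same ring, angularly adjacent sectors).  Corner contact
is not adjacency; an `edge+corner` mode is available for exploring the
alternative reading of "neighbouring zones".  Degrees are therefore 8
(centre), 4 (rings 1–4) and 3 (ring 5).

Left-eye maps are mirrored across the vertical meridian
(N↔T, SN↔TS, NI↔TI) before analysis so that "temporal" denotes the same
anatomical direction in both eyes.  Mirroring is an involution, and all
derived parameters are invariant under the OD/OS encoding of the same
anatomy (property-tested).

## Parameters

Per zone, the inter-zonal ET difference is the mean absolute contrast
with its neighbours; the localized parameter averages the `cI` and
`cTI` values and the global parameter averages all 41.  Baseline
comparators computed on the zonal values themselves: mean, SD (sample
convention, n−1; configurable), minimum, maximum, and inferior−superior
(mean of the five I-octant zones minus mean of the five S-octant zones
— the comparator's exact zone set is not standardised, so the full
octants are used and the definition is config-exposed).

## Statistics

* **ROC**: empirical curve over all distinct thresholds; AUC by the
  trapezoid rule, which equals the Mann–Whitney concordance probability
  with tied pairs counted ½ (property-tested against pair
  enumeration).  95% CIs by the DeLong midrank estimator (cross-checked
  against R `pROC::ci.auc(method="delong")`), normal-theory on the AUC
  scale and clipped to [0, 1]; a stratified-bootstrap percentile CI is
  available behind a flag.  Scores where *lower* values indicate
  disease are handled by negation.
* **Zone selection**: per-zone ROC (higher difference = disease) over
  the 41 zones; the k = 2 largest AUCs are selected.  AUC ties — which
  saturate at 1.0 on noise-free cohorts — are broken by the difference
  of group medians of the zone's values, then by grid order, keeping
  selection deterministic while letting noise-free cone recovery
  succeed.
* **Cut-offs**: candidate thresholds are midpoints between adjacent
  distinct observed scores; the decision rule is score ≥ cut-off ⇒
  positive.  The screening cut-off is the largest threshold with
  sensitivity ≥ 95% (maximising specificity under that floor); the
  confirmation cut-off is the smallest threshold with specificity ≥
  95%.  When the two floor-satisfying regions overlap (strong
  discriminators or lax targets), the raw values cross; the pair is
  then reported in ascending order, in which case each cut-off
  satisfies both floors.  Unattainable floors leave the cut-off absent
  with a warning.
* **Group comparisons**: two-sided Mann–Whitney U, exact by full
  enumeration when both samples have ≤ 8 observations and no ties,
  otherwise the normal approximation with tie and continuity
  correction.  The four prespecified validation comparisons (two
  parameters × two keratoconus groups vs healthy) use the
  Bonferroni-adjusted per-comparison level 0.05/4 = 0.0125; the
  development-stage per-zone screen is intentionally uncorrected.
* **Correlation**: Spearman with midrank ties.
* **Repeatability**: per-eye sample SD of the quantity across repeated
  measurements; cohorts are summarised by the median and IQR of those
  SDs (IQR by linear interpolation, R type 7; a type-6/HAVERAGE switch
  is provided since SPSS uses it) and additionally by the pooled
  root-mean-square SD.  With only 3 repeats the *median* per-eye SD is
  a biased-low estimate of the underlying noise SD (the median of
  σ·√(χ²₂/2) is ≈ 0.83 σ), so calibration checks against a configured
  noise level use the pooled SD, which is consistent.

## Validation-stage conventions

Per-eye parameter values are the mean of the parameter over the
repeated measurements (not the parameter of the mean map); the maximum
absolute difference between the two orders of operation is computed and
carried in the report config for transparency.  The same averaging is
applied to the baseline comparators.  Baseline ROC directions are fixed
a priori: SD and maximum ET higher-is-disease; mean, minimum and
inferior−superior lower-is-disease (keratoconic thinning is
inferior-temporal and focal).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes;
defaults encode the study conditions.

* **Healthy surface**: a 53-µm baseline with the normal, eyelid-related
  superior and temporal thinning.  The thinning is a radial ramp
  starting at the paracentral boundary (1.26 mm) and anchored so the
  S−I and T−N offsets reach 5.9 µm and 1.3 µm at the 3-mm reference
  radius; central and paracentral zones stay level.  The flat centre is
  deliberate: any vertical gradient at the paracentral ring creates a
  baseline contrast at `cI` that a shallow cone first *cancels*, which
  would make the severity response non-monotone — with the ramp, the
  localized parameter is strictly non-decreasing in severity at zero
  noise (tested).
* **Cone**: a raised-cosine depression (half-width 0.9 mm) centred by
  default midway between the `cI` and `cTI` zone centres, with depth =
  severity (µm), surrounded by a raised-cosine annular thickening
  (radius 1.6 mm, half-width 0.7 mm, peak 0.2 × depth).  Severity 0
  reproduces the healthy model exactly under the same random stream.
* **Noise**: an N(0, 1.5²) per-eye level offset shared by an eye's
  repeats, plus independent N(0, 0.6²) zonal measurement noise per
  measurement — 0.6 µm matching the reported zonal repeatability scale.
  Spatial noise correlation of real maps is *not* modelled; passing
  tests therefore demonstrate the pipeline's behaviour under
  independent zonal noise, not under device-specific artefact
  structure.
* **Groups and severities**: healthy severity 0; tomographically
  normal fellow eyes Uniform(0.5, 2.5) µm; significant keratoconus
  Uniform(4, 12) µm (validation) — the BAD-D coupling (affine in
  severity, noise SD 0.3, truncated to the group-defining ranges
  ≥ 2.69 / < 1.65) then reproduces the reported BAD-D medians of ≈ 6.4
  (keratoconus) and ≈ 1.0 (healthy).  The development cohort uses
  Uniform(1.5, 12) because its bilateral-ectasia inclusion rule
  (fellow-eye BAD-D ≥ 1.65) admits milder disease than the validation
  "significant" definition.  Belin ABCD values are coupled to severity
  for the significant group and fixed at stage 0 for the others; the
  indices are consumed only by the correlation analyses.
* **Calibration targets**: healthy inter-zonal differences ≈ 1 µm and
  zonal noise 0.6 µm.  Group medians are *not* hard-coded; the ordered
  medians the pipeline reports (≈ 0.7 / 1.0 / 3.9 µm localized) emerge
  from the severity distributions.
* **Randomness**: one root seed spawns an independent stream per eye,
  so cohorts are reproducible eye-by-eye under any group-size change.

Under these defaults the noise-free cone is recovered (`select_top_zones`
returns the seeded pair for every paracentral placement); with the
default 0.6-µm noise the development stage selects exactly {cI, cTI} in
roughly 85% of seeds, with near-ties going to immediately neighbouring
zones — mirroring the fact that zone selection on a real finite cohort
is itself a noisy estimate.

## Problem sizes

The default study sizes are the study's own: development 86 + 40 eyes
at one measurement, validation 21 + 21 + 21 eyes at three repeats.  The
cross-cohort ordering check in `scripts/acceptance.py` uses 50
independent validation-size cohorts; the test suite's ordering property
uses 100.  Repeatability calibration uses 200 eyes × 3 repeats.

## Known limitations

* Zonal noise is spatially independent; real maps show correlated
  segmentation artefacts (flagged above).
* The device's true zone shapes/radii and the authors' exact adjacency
  reading are not public; the declared layout is a reconstruction, with
  the corner-adjacency alternative exposed as a switch.
* The generator models neither dry-eye/contact-lens confounders nor
  longitudinal progression, and the tomography indices are a minimal
  coupling sufficient for correlation tests, not a tomography model.
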