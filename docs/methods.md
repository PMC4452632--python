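# Methods

This note documents the models behind `sirtsim`, the choices made where the
design was genuinely open, and what the synthetic studies do and do not show
about real tissue.

## Dosimetry

The absorbed dose uses the *local deposition* model: every β decay deposits
its mean energy (Ē = 0.934 MeV) in the tissue element where the microsphere
lodged, and the source decays completely in place (T½ = 64 h), giving
D = c₀·Ē·T½/ln 2 for an activity concentration c₀ referenced to
administration time. Cross-fire between tissue elements is ignored; the mean
and maximum β ranges (2.5 / 11 mm) are carried as nuclide metadata only.
Convolving the simulated activity maps with a β dose-point kernel is an
explicit non-goal.

BED uses the standard permanent-implant expression for an exponentially
decaying source with mono-exponential repair,
BED = D·[1 + λ/(μ+λ)·D/(α/β)]. Two presets are fixed: normal liver
(α/β = 2.5 Gy, repair half-time 2.5 h) and tumour (α/β = 10 Gy, 1.5 h). The
repair half-times are not free parameters of convenience: together with the
dose formula they reproduce all eight published (dose, BED) worked pairs
(22→29, 31→45, 33→49, 52→93 Gy normal; 59→67, 100→123, 125→161, 150→202 Gy
tumour) to nearest-integer rounding, which is the validation that these are
the intended constants. Activity concentrations measured at a later time
(default 216 h, the surgery day) are decay-corrected back to administration.

## Liver lattice

Normal parenchyma is a lattice of hexagonal-prism lobules (circumradius
0.6 mm, length 1.5 mm) stacked in axial layers with aligned columns. Portal
tracts sit at the hexagon corners; deduplicating shared corners leaves two
tracts per lobule in the bulk. The nominal lobule mass of 2 mg converts a
target tissue mass into a lobule count and gives the anatomical rule of
about one portal tract per milligram (the package asserts ±10 % at ≥1 g;
below that, boundary corners dominate). Note that the quoted hexagon
geometry encloses ≈1.40 mm³, so nominal mass and geometric volume disagree
by ≈1.4×; this is inherited from the source anatomy figures. The package
resolves it by using the nominal mass *only* for lobule counting and tract
density, and geometric volume × density (default 1 mg/mm³) for every
concentration, biopsy-mass and dose computation, so that biopsy-level and
compartment-level concentrations share one convention.

A tumour compartment is the ball of lobules nearest a configurable centre,
relabelled `tumour`. Its tract lattice is retained; tumour microarchitecture
is instead represented by the chaotic deposition mode.

## Cluster-size law

Microspheres arrive in clusters that each occupy a single trapping site.
The spheres-per-location law is a mixture: probability `p_single` = 0.64 of
an isolated single, otherwise a truncated power-law tail on 2…59 spheres.
The tail exponent (1.753) is root-found so the overall mean location size is
3.3 spheres. These two moments are the calibration targets; with them fixed,
the power-law tail also predicts 9 % of locations in clusters of ≥8 spheres
carrying 54 % of all spheres (observed values: 7 % and 53 %), which is why
the power law is the default over a truncated geometric tail (13 % / 53 %).
A requested sphere total is hit exactly by truncating the last cluster, so
sphere-count conservation holds identically through the pipeline.

Per-sphere activities are drawn from a triangular distribution on
(40, 70) Bq with mode 40, the unique triangular law on that support with the
nominal mean of 50 Bq (a uniform draw would have mean 55). Diameters are
lognormal with mean 30 μm, clipped to the manufacturing range (20, 60) μm.

## Structured (normal-tissue) deposition

Each cluster is assigned to one portal tract with probability proportional
to: a base intensity field × an optional linear gradient × a tumour
enrichment factor. The enrichment factor is normalised against the realised
per-compartment weight totals so that the *expected* tumour-to-normal
concentration ratio equals the configured TNC exactly, independent of tract
density differences between compartments.

The base intensity field represents repetitive regional heterogeneity: a
lognormal field with unit mean on cubic cells ("basic elements") of
configurable size. Defaults are element CV 2.0 on 1.6 mm cells. Spheres of a
cluster are jittered uniformly within 100 μm of the tract point.

When the number of clusters does not exceed the number of tracts, tracts are
sampled without replacement (weighted Gumbel top-k), so no two clusters
share a tract and isolated singles are guaranteed ≥200 μm from any other
sphere (adjacent corners are 600 μm apart). At therapeutic densities there
are several clusters per tract; sampling is then with replacement and
co-resident clusters merge into one microscopy "location". This is the
model's main departure from reality: real portal tracts are spatially
extended structures that can host several resolvable locations, so
microscopy statistics at full therapeutic density are biased toward large
merged locations. Parameter-recovery experiments therefore use sparse,
tract-exclusive depositions (see below).

## Chaotic (tumour) deposition

Tumour tissue is modelled as a doubly stochastic process that ignores the
tract lattice: a uniform background modulated by a large-scale linear drift
along the slab axis (density ∝ 1 + g·ẑ, default g = 0.95, random sign),
plus scattered spherical foci (lognormal radii, median 5 mm) that attract
`patchiness`/(1+`patchiness`) of the clusters (default 0.3, i.e. a minor
focal component). With zero patchiness and zero drift the mode reduces to
complete spatial randomness.

The drift term is essential to the intended phenomenology: any purely focal
structure smaller than the largest biopsy is partially averaged by large
punches and produces a *decreasing* CV-vs-mass trend, i.e. it masquerades as
repetitive heterogeneity. A box-scale systematic variation contributes equal
relative variance at every biopsy size and is what makes the tumour CV
sequence trendless — the same mechanism (systematic concentration gradients)
that the interpretive rules for trendless CVs invoke.

## Virtual biopsies

Punches are axis-aligned cylinders (default diameter set {3, 4, 6, 8} mm);
membership is by sphere-centre inclusion with closed boundaries (spheres are
≤60 μm, negligible against punch dimensions). Mass is πr²·t·ρ. Measured
activity is the administered-time activity decayed to the measurement time.
Random plans place non-overlapping punches uniformly (rejection sampling,
largest punches first in the shipped plans); infeasible placements return a
partial plan with a warning count rather than failing. Mass strata default
to the small/medium/large bounds 6–14 / 15–39 / 40–91 mg; per-stratum mean
concentration is the ratio of totals Σ activity / Σ mass, not the mean of
ratios.

## Heterogeneity statistics and pattern classification

CV uses the (n−1)-denominator sample standard deviation over the mean, and
SK is the adjusted Fisher–Pearson standardised moment coefficient with the
same s — the standard definition of the named statistic (equal to
`scipy.stats.skew(..., bias=False)`; this equivalence is asserted in the
tests). The classifier works on the ordered per-stratum CVs:

* not strictly decreasing → `chaotic_unstructured`;
* strictly decreasing with total relative drop ≥ 30 % → `repetitive`
  (with an `element_larger_than_biopsies` evidence flag when the fall has
  not plateaued at the largest masses, i.e. last-step drop ≥ 15 %);
* strictly decreasing, drop < 15 %, all CV < 0.3 →
  `element_smaller_than_biopsies`;
* any weaker monotone trend → `chaotic_unstructured`.

The 30/15/0.3 thresholds are package choices (configurable); the source
rules are qualitative. A monotone trend short of "strong" with large CVs is
deliberately classified as trendless: the interpretive dichotomy is strong
trend vs no usable trend, and the published normal-tissue (strong trend) and
tumour / wide-strata (trendless) verdicts are reproduced under these
defaults.

## Microscopy

Serial sections (default 10 × 20 μm) are cut from the top of a biopsy;
sphere→section assignment is axial binning. Locations are single-linkage
clusters with the 200 μm isolation distance doubling as the linkage radius —
one threshold, consistent with the span of the largest portal tract (so two
singles cannot share a tract). Coordinates are in-section (x, y) plus the
section-centre offset, mimicking what aligning adjacent sections
reconstructs; no registration-error model is applied by default. The
sectioned volume fraction is tracked explicitly so that count-based
concentration estimates can be compared with whole-biopsy detector
measurements; individual stacks scatter around the detector value, which is
how a ~28 % single-sample discrepancy between the two estimates arises as
ordinary subsampling noise.

## Calibrated study conditions

Two bench-scale study designs are bundled and used by the acceptance tests:

**Repetitive (normal-tissue) study** — 32 g lattice (12 mm deep), sphere
density 85 Bq per volumetric mg, element field CV 2.0 at 1.6 mm, and a
fixed-mass sampling plan of 30 punches per stratum at 7.1 / 33.9 / 90.5 mg
(inside the default stratum bounds). Under these conditions the per-stratum
CVs average ≈1.5 / 0.9 / 0.6 with positive SK everywhere, and the joint
event "CV strictly decreasing and SK > 0 in all strata" holds in ≈95 % of
seeds (measured over 150 calibration seeds).

The sphere density is roughly a tenth of the measured therapeutic
concentrations. This is a deliberate study-size choice: at full density the
biopsy counts are so large that the compound-sampling contribution to
skewness vanishes, and the sample SK of ~30 biopsies in the largest stratum
is no longer reliably positive. The scaled-down density preserves every
qualitative feature under study (trend direction, trend strength,
positive skew) at bench-scale runtimes. The patient-like presets
(`pt1_like`, `pt2_like`) instead use the measured concentrations (620 and
1,040 Bq/mg) so the dosimetry block reproduces the published dose/BED/TNC
worked numbers; their trend verdicts are correspondingly less stable.

**Chaotic (tumour) study** — 16 g block (12 mm deep), tumour-like density
4,300 Bq per volumetric mg, drift 0.95, patchiness 0.3, sampled with the
published tumour design (13–14 biopsies per stratum, wide within-stratum
mass spread from thickness ranges). The chaotic label is returned in ≈90 %
of calibration seeds.

**Parameter recovery** — sparse deposition (1,800 clusters on a 2,000 mg,
single-layer lattice with ~2,100 tracts, tract-exclusive) punched with six
8 mm × 0.6 mm biopsies sectioned over their full thickness (30 × 20 μm), so
locations are observed without merging or axial truncation. The singles
fraction `p_single` is then an unbiased binomial estimate; a 95 % percentile
bootstrap over pooled locations covers the generator value in ≥90 % of
replicates.

## Numerical and API choices

* All randomness flows from a single top-level seed via `SeedSequence`
  spawning; identical config + seed reproduces byte-identical output tables.
* Closed boundaries everywhere (region membership, mass-group bounds);
  spheres exactly on a section boundary go to the upper section.
* Degenerate inputs are rejected with the parameter named (negative
  concentrations, non-positive α/β or repair time, zero-mass samples,
  overlapping mass strata); undersized strata yield NaN CV/SK flags in
  summaries rather than errors.
* Study configs are pydantic-validated with unknown keys rejected; every
  report embeds the resolved config, its SHA-256, the stage seeds and the
  package version.

## Known limitations

* No cross-fire dosimetry: reported doses are mean compartment doses under
  local deposition, not voxel dose distributions.
* Point-like portal tracts merge co-resident clusters at therapeutic
  densities (see above), so absolute microscopy statistics are only
  comparable to published counts in sparse regimes.
* The lobule lattice has aligned columns (no inter-layer offset) and no
  periportal/centrilobular substructure; vascular-tree hemodynamics and
  embolisation feedback are not modelled.
* Biopsy placement is uniform-random non-overlapping, an assumption; real
  punch placement on slices was likely opportunistic.
* Passing trend tests on the synthetic tissue demonstrates internal
  consistency of generator + statistics, not that real livers have lognormal
  1.6 mm elements; the element field is a minimal stand-in for whatever
  produces the observed CV magnitudes.
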