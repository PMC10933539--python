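# Methods

## Scope and model of the data

The package treats one segmented, leaf-off tree point cloud (metres, z-up)
as the unit of analysis.  Upstream steps that produce such clouds —
multi-scan co-registration, plot-level segmentation, leaf–wood separation —
are out of scope; the estimators assume their input is already a single
tree's woody points.  All heights used in slicing are measured relative to
the cloud's lowest point, and slice intervals are half-open `[low, high)`
so boundary points are assigned deterministically.

## Stem diameters

**DBH** and **DTB** come from horizontal cross-sections (1.2–1.4 m and
4.0–4.5 m) flattened to the x–y plane.  The fitted circle is the
*geometric* (orthogonal-distance) least-squares circle: minimise
Σᵢ(dᵢ − r)² with dᵢ the point-to-centre distance.  It is initialised from
the Kåsa algebraic fit (a linear least-squares problem) and refined by
Gauss–Newton with analytic Jacobian and Levenberg damping, stopping when
the parameter step falls below 10⁻⁹ m–10⁻¹⁰ m or after 100 iterations.
The algebraic fit is retained in the API as an independent cross-check:
by construction the geometric objective never exceeds the algebraic
starting point, and the test suite asserts this over randomised sections.
Sections need ≥ 20 points (an explicit guard against meaningless fits;
the threshold is a package choice, not a measurement standard).

Monte-Carlo behaviour, frozen into tests: on a full circle of 500 points
with 1 cm isotropic noise the radius is recovered within 5 mm; on a
semicircular arc (a heavily occluded stem) with 5 mm noise, within 2%.

**fDBH** is the equivalent-area diameter 2·√(A/π) of the breast-height
section's convex hull.  The hull is used exactly (the α → 0 limit of an
alpha shape); introducing a concave alpha-shape boundary would add an
unstated tuning parameter for little benefit on near-convex stem sections.

## Crown volume and crown base

Crown volume is the volume of the 3-D convex hull of all points at or
above the crown base.  The crown base is user-supplied or detected as the
lowest 0.5 m slab whose horizontal spread (95th percentile of distance to
the slab centroid) exceeds 1.5× the DTB-slice radius.  The factor 1.5 and
the percentile are deliberate, overridable choices: conifer stems taper,
so any slab whose spread clearly exceeds the stem radius marks branch
material.  Whether the stem below the crown should be excluded from the
hull is ambiguous in general; including it changes the hull negligibly for
deep-crowned conifers and is what the implementation does.

## Woody volume: the slice-stack estimator

Full cylinder-graph QSM reconstruction is intentionally not reimplemented.
The estimator here cuts the cloud into 0.5 m slabs, isolates the stem in
each slab, fits the geometric circle, and integrates conical frusta
through the fitted (height, radius) knots, closing the stack with a basal
frustum linearly extrapolated to the ground and an apical cone to the
treetop.  Externally computed volumes (e.g. from a QSM tool) can be
supplied through the metrics CSV instead.

Stem isolation per slab: points are linked into planar connected
components at a radius of 2.2× the median nearest-neighbour spacing of the
basal metre (adapting to scan density); among components large enough to
fit, the one whose nearest member is closest to the running stem centre
wins.  The circle fit is trimmed — up to three rounds discarding residuals
beyond 3 robust standard deviations — because branch junctions contribute
high-leverage outliers.  A slab fit is rejected (and bridged by the
neighbouring knots) if its RMS residual exceeds 8 cm, or its radius jumps
above 1.4× the previous slab's + 5 cm, or exceeds the tree height; stems
do not double in radius over half a metre, so such fits are contamination.
If fewer than 60% of slabs yield a fit the estimator refuses with the
empty slabs listed, rather than extrapolating through the gaps.

Branch wood is added as a multiplier of stem volume, default 0.15.  This
is calibrated once against the synthetic generator, whose branch cylinders
contribute exactly 15% of trunk volume in closed form, and frozen; on real
clouds of other species it is the first parameter to revisit.

The whole fit is repeated 10 times (uniform slab-phase offset in
[0, 0.5 m), 90% random subsample, seeded) and the mean and SD over repeats
are reported, mirroring the mean/SD-of-10-models convention of optimised
QSM processing.  Accuracy on analytic solids: within 1% on a noiseless
cone; within 5% of total (trunk + branch) truth on full synthetic trees
with flare, branches, crown and noise.

## Biomass, carbon and growth rates

AGB = V·ρ with ρ = 0.34 Mg m⁻³, a mid-range value for giant-sequoia wood
(published components span ~0.2 for bark to ~0.45 for branch wood; the
single value is a deliberate simplification, so AGB inherits its
uncertainty while volumes do not).  Carbon = AGB × CF with CF = 0.54,
reported for *S. giganteum* and among the highest measured for North
American species.  Both constants are parameters (`GrowthParams`),
validated to plausible ranges (ρ ∈ (0.2, 0.6), CF ∈ (0.4, 0.6)).

Annual rates divide by the age from the planting record: H/age (m yr⁻¹),
100·DBH/age (cm yr⁻¹), 1000·AGB/age (kg yr⁻¹), carbon = AGB rate × CF.
The constant-growth assumption is strong — growth varies with age and the
sample only contains survivors — so the rates are lifetime means, not
current increments.  Site summaries report both the rate of the cohort
mean metric over the mean age and the mean of per-tree rates; the two
differ whenever ages vary within a cohort, and neither is privileged.
Between-group comparisons use Welch's two-sided t-test (variances of
accumulation rates differ strongly between sites, so the pooled-variance
variant would be wrong more often than not).  Reported rates round to
2 d.p. for m yr⁻¹ and cm yr⁻¹ and 1 d.p. for kg yr⁻¹.

## Allometry

The registry stores the five published models with their coefficients
exactly as printed and a declared input set and output (stem volume in m³
or AGB in Mg).  Volume-returning models are converted to AGB with a
per-model density, default 0.34.  A known limitation: the native
calibration units of the US models (notably Parks and Jenkins) are not
re-derived here; coefficients are applied to metre/Mg inputs as declared,
so their absolute predictions on synthetic trees carry that convention
with them.  Evaluation regresses predicted on observed AGB by OLS and
reports gradient, intercept, slope standard error, r² and RMSE.

The four UK forms are two-parameter power laws fitted in arithmetic space
(scipy least-squares, Levenberg–Marquardt; initialisation a = ȳ/x̄,
b = 1; tolerances 10⁻¹²).  Arithmetic-space fitting avoids the
back-transform bias correction a log-log regression would need.  Fit
quality is summarised by r² (1 − SS_res/SS_tot), RMSE, and bias = mean of
(predicted − observed)/observed × 100 (mean relative error; alternative
definitions can be computed from the stored data).  Uncertainty comes
from a parametric bootstrap: resample y from the fitted curve plus
Gaussian residuals (sd = residual sd of the fit), refit, and summarise
per-abscissa refit predictions as min/max and 2.5/97.5 percentiles
(the band definition of a bootstrap plot is not standardised; both are
provided).  Failed refits are counted, not silently dropped.

## The synthetic generator

The generator is the package's reference-data substitute and defines the
conditions under which the estimators are validated.

*Trunk*: a surface of revolution — constant radius r_b below breast
height, taper r_b·((H−h)/(H−1.3))^t above it, plus a buttress flare
B·(1−h/F)² vanishing at the flare height F.  r_b is solved so the total
diameter at 1.3 m equals the requested DBH.  Trunk volume is the exact
integral of π r(h)² (the flare–taper cross term expands into pure powers
of H−h), cross-checked against numerical quadrature in the tests.

*Branches*: explicit cylinders in the crown whose summed volume is a fixed
fraction (default 15%) of trunk volume, keeping total woody truth
analytic; branch reach is capped so tips stay inside the crown envelope.
*Crown*: surface plus sparse interior samples of a conoid, paraboloid or
prolate spheroid (volumes πR²L/3, πR²L/2, 2πR²L/3).  Sensor effects:
per-coordinate Gaussian noise (default 5 mm, commensurate with survey-grade
terrestrial scanners) and removal of an azimuthal stem sector for
occlusion.  There is no beam-divergence/footprint simulation, no
range-dependent density, no leaf points and no registration error —
passing tests therefore demonstrate estimator correctness on clean
single-tree geometry, not robustness to every field artefact.

The bundled three-site study mirrors a UK survey's structure: a wet-site
avenue of 40 trees planted 1863 (mean H 44.3 m, DBH 1.80 m), a dry-site
avenue of 34 planted 1870 (24.5 m, 1.12 m), and a mixed-age garden with
10 old (≈1900) and 13 young (1989) trees; per-tree sizes jitter by 10%
(Gaussian factors, truncated at ±2.5 sd).  Heights, diameters and ages
follow the surveyed means; volumes then follow from the chosen taper
(t = 1) rather than being matched to any published volume figure.  Crown
bases are kept above ~4.8 m even at the lower jitter extreme so the
4.0–4.5 m DTB slice always measures stem, which is the regime the DTB
definition exists for.  Sampling defaults for the study (8 cm trunk point
spacing, half-size cohorts in the acceptance script) keep a full run in
CPU-minutes; single-tree fixtures in the tests use finer spacing.

## Numerical and degeneracy conventions

- Collinear or coincident section points fail the circle fit explicitly.
- Clouds under 100 points are refused by the diameter estimators but still
  yield a height.
- A cloud whose slice cannot reach 20 points raises an error carrying the
  count; missing metrics propagate as `None` plus a reason in a per-tree
  error ledger — never imputed.
- All randomness (generator, volume repeats, bootstrap, pipeline) flows
  from explicit integer seeds; reruns are bit-identical, which the tests
  assert end to end.
- Identical degenerate groups in the Welch test (zero variance, equal
  means) return statistic 0, p = 1 instead of NaN.

## Known limitations

- The slice-stack volume assumes a single dominant stem; forked or
  strongly leaning trees would need per-axis stacking (lean is supported
  in the generator but the estimator is validated on near-vertical stems).
- No hollow-stem or bark-fraction modelling: volumes are over-bark solids.
- The branch multiplier is a single global calibration, not per-tree.
- Published-model unit conventions, as noted above, are declared rather
  than re-derived from their original calibrations.
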