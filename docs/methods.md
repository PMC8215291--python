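# Methods

## Scope and model

`atriaflow` post-processes wall data of a left-atrial (LA) hemodynamic
analysis; it assumes the flow problem is already solved. Its inputs are
a triangulated wall surface, an LGE-like intensity source, and the wall
shear stress (WSS) vector τ(t) per wall point over one cardiac cycle.
Everything downstream — fibrosis labels, the four shear metrics, burden
fractions, region statistics — is deterministic given those inputs.

The four metrics use the canonical literature forms:
TAWSS = (1/T)∫‖τ‖dt, OSI = ½(1 − ‖∫τ dt‖/∫‖τ‖dt),
ECAP = OSI/TAWSS, RRT = [(1 − 2·OSI)·TAWSS]⁻¹. ECAP is defined as
OSI over TAWSS (not the reciprocal): only that orientation amplifies
regions of low shear and high oscillation, which is the quantity's
purpose. RRT is algebraically the reciprocal magnitude of the time-mean
WSS vector; the identity is exercised in tests.

## Quadrature

Cycle integrals use the trapezoidal rule with periodic closure: the
frames sample one full cycle, so the segment from the last frame back to
the first (wrapped by T) is included and the weights sum exactly to T.
Non-uniform frame times are supported; the default is 92 uniform frames
over T = 0.92 s (0.01 s output resolution). At 92 frames the quadrature
reproduces the closed-form TAWSS of a zero-offset sinusoid (2A/π) to
about 4 × 10⁻⁴ relative and the OSI of a fully reversing series to
round-off.

Degenerate conventions, all flagged with counts in reports: OSI := 0
where the shear vanishes over the whole cycle; ECAP is NaN (excluded
from means) where TAWSS = 0; RRT is capped (default 10⁹ Pa⁻¹) where
(1 − 2·OSI)·TAWSS ≤ 10⁻¹². OSI is clipped to [0, 0.5] against
round-off; the bound itself is a Cauchy–Schwarz consequence and is
property-tested. Input vectors are trusted to be tangential; an optional
config switch projects out the wall-normal component.

## Fibrosis mapping

Wall intensity is the maximum nearest-voxel sample along the
inward-facing vertex normal, at steps of half the smallest voxel spacing
(so no traversed voxel is skipped) down to a depth of 2.5 mm — one slice
thickness of the emulated 1.25 × 1.25 × 2.5 mm imaging geometry. The
traversal depth is this package's explicit choice: the wall thickness
crossed by the projection is not standardised, so it is a config
parameter. The maximum (not an interpolated profile) matches the intent
of capturing any enhancing tissue through the wall.

IIR = intensity / blood-pool mean; the blood-pool mean is an input
scalar because blood-pool segmentation is out of scope and the synthetic
generator emits the true value. Classification is strictly greater than
the threshold (default 1.22): IIR exactly at threshold is non-fibrotic.
Vertices with no in-bounds sample are excluded from both regions and
from all statistics, with logged counts.

Burden weighting defaults to area (vertex area = ⅓ of incident triangle
areas — exactly conservative, which burden ratios need; Voronoi/mixed
weights would buy curvature accuracy burden fractions do not use).
Count weighting is available because region statistics operate on data
points.

## Registration

Continuous fields transfer by closest-point projection onto the source
triangulation with linear barycentric interpolation — exact for linear
fields on planar patches, bounded by the source range everywhere.
Labels transfer by nearest source vertex, ties to the lowest index;
interpolating a binary label is meaningless. The accelerated search
(k-d tree over triangle centroids with a circumradius-bounded ball-query
second pass) is contractually equivalent to the brute-force scan, which
the tests enforce on small meshes. Target vertices farther than 5 mm
from the source surface (e.g. vessel extensions absent from the
segmentation) keep their nearest value but are counted as extrapolated.

## Statistics

Per region, normality is checked with a one-sample Kolmogorov–Smirnov
test of the z-scored values against the standard normal (no Lilliefors
correction — the plain one-sample usage). If either region rejects at
α = 0.05 the regions are compared with a two-sided Mann–Whitney U test
(scipy's exact method at small tie-free n, normal approximation with tie
correction otherwise); otherwise Welch's t-test. At realistic wall
point counts (10⁴–10⁵) the KS test essentially always rejects, so the
rank test is the de-facto default; the t-path matters for small
synthetic inputs. Descriptives are mean ± SE (sd/√n, sample sd). No
multiple-testing correction is applied across the four metrics; reports
say so implicitly by carrying raw p-values.

Aberrant burden thresholds ECAP at (1 + δ) × its wall mean with
δ = 0.10, i.e. "10 % above average". The alternative reading
(0.10 × mean) would flag nearly the entire wall and is inconsistent
with observed aberrant areas of order 10–20 %; δ is configurable. The
quantity is invariant to positive rescaling of ECAP, so raw and
normalized fields give the same burden.

Cohort aggregation averages per-case region means (normalized values
for TAWSS/ECAP/RRT, raw OSI) rather than pooling points across cases,
and compares regions across cases with a paired test chosen by the same
normality rule (Wilcoxon signed-rank / paired t). Per-case reports emit
both raw and normalized region means, since either could be wanted
downstream. The burden regression is plain OLS with R² = 1 − SSres/SStot
(defined as 0 for constant y; constant x is an error).

## Synthetic data

The generator defines the desk-scale study conditions; its defaults are
fixed, not tuning knobs.

- **Chamber**: a Fibonacci lattice on a 45 × 35 × 25 mm semi-axis
  ellipsoid (≈165 ml, a dilated atrium) triangulated by its convex
  hull. This hits any vertex count exactly — icosphere subdivision
  quantizes counts (642/2562/10242) and cannot meet a 5,000-point
  target — and is watertight by construction. Default 5,000 vertices
  (clinical meshes run 20,000–50,000; the desk scale keeps the suite
  fast while leaving the statistics overwhelmingly powered). A smooth
  radial bulge can emulate an appendage.
- **Fibrosis**: patches grow as equal-radius balls around seeded
  centers until the area burden is as close as possible to target
  (default 15 %, 3 patches; clinical burdens span roughly 6–25 %).
  Achieved burden is returned and lands within ±1 percentage point at
  these mesh resolutions.
- **Image**: grid at 1.25 × 1.25 × 2.5 mm filled with the blood-pool
  mean (100); voxels on each vertex's inward wall ray are stamped with
  contrast 1.5 × for fibrotic wall, 1 × otherwise, nearest stamping
  vertex winning shared voxels; Gaussian noise (default SD 2) last.
  The imperfection of the forward-inverse round trip is pure
  voxelization at patch boundaries; noise-free recovery agreement is
  ≥ 95 % (typically ≈ 99 %).
- **WSS**: per vertex τ(t) = A·w(t)·ê with A = 0.8 Pa, ê a
  deterministic azimuthal tangent, and w a positive two-harmonic
  pulsatile waveform. Fibrotic vertices get A × 0.7 and the waveform
  shifted down by its 0.25-quantile, so a quarter of the cycle reverses
  — lower TAWSS, higher OSI, hence higher ECAP and RRT, the pattern the
  pipeline must detect. Isotropic Gaussian noise (SD 0.04 Pa) per frame
  and component. Ground truth records the noise-free per-region
  TAWSS/OSI from the waveform itself.

What the generator does **not** emulate: real flow physics (no
Navier–Stokes solution — effects are injected into the shear field
directly), anatomical pulmonary veins / mitral valve and their local
flow structures, spatially correlated image noise, wall motion, or
inter-patient anatomical variability. Passing recovery tests therefore
demonstrates that the measurement and statistics pipeline is correct
and powered under controlled effects, not that real atria exhibit those
effects.

An analytic oracle supplies closed-form TAWSS/OSI for offset sinusoids
(piecewise integration of |c + A sin|), used to validate the quadrature
independently of it.

## Reproducibility and problem sizes

Every stochastic generator takes an integer seed (sub-stages of a case
derive independent streams from it); pipeline runs contain no
randomness, and report JSON is byte-identical across reruns. The test
suite runs at 400–5,000-vertex meshes; the 20-replicate recovery check
uses 5,000 points per case, the scale at which per-case significance
saturates. Reports embed the resolved config, package version and all
flagged-point counts so the effective n of every test is auditable.

## Known limitations

- Closed, star-shaped-ish chambers are assumed where orientation is
  resolved against the centroid; pass an interior reference point for
  anything else.
- The VTP reader/writer covers ascii PolyData with point/cell scalars
  and 3-vectors — the subset this pipeline emits — not the full VTK XML
  spec (no binary/appended encodings, no strips).
- Nearest-voxel sampling (no interpolation) is deliberate for the
  max-through-wall projection but makes wall intensities sensitive to
  sub-voxel mesh placement at boundaries.
- The exact Mann–Whitney enumeration lives in the test suite as an
  oracle; the library delegates to scipy's implementation.
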