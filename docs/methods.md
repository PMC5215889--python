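# Methods

`meshacc` measures the *practical accuracy* of an optical facial scanner:
how far a scan of a real, possibly deformed face deviates from a
high-accuracy reference surface of the same face. This note records the
model behind each stage, the parameters that matter, the numerical choices,
and what the synthetic phantoms do and do not establish.

## The 3D error

Two registered surfaces are compared by sampling every vertex `P_i` of the
reference mesh and finding its exact nearest point `P_i'` on the test
surface (point-to-surface, not vertex-to-vertex — the two meshes typically
differ in density by a factor of 3–5, and vertex pairing would bias
distances upward). With `X_i = ||P_i − P_i'||`, pairs with `X_i` beyond the
exclusion band (default **5 mm**) are dropped, and the *3D error* is

    RMS = sqrt( Σ X_i² / N )

over the `N` retained pairs. The same ±5 mm band clips the deviation color
map: black marks excluded vertices, green zero error, blue negative and
yellow→red positive deviations (piecewise linear in `d / 5 mm`). Deviations
are always sampled from the reference onto the test surface; the reverse
direction is an explicit argument swap, never an implicit average.

Signed distances take the sign of `(P_i − P_i') · n̂(P_i')`, where `n̂` is
the angle-weighted pseudo-normal of the test surface at the matched point
(face normal in a triangle interior, area-free average of the two adjacent
face normals on an edge, angle-weighted normal at a vertex). Commercial
packages do not document their sign convention; ours is stated and tested
instead. The sign never affects the RMS (squares).

### Exact accelerated search

Nearest points are found exactly, not approximately. A KD-tree over
triangle centroids yields, per query, an upper bound (the exact distance to
the nearest centroid's triangle); every triangle whose centroid lies within
that bound plus the largest centroid-to-corner radius is then scanned with
a vectorized closed-form point-to-triangle solver. Any triangle containing
the true optimum must have its centroid inside that ball, so the
accelerated result equals an exhaustive all-triangle scan (verified to
1e-9 mm in the tests). Ties between equidistant triangles break to the
lowest triangle index.

## Registration

Alignment is rigid only — scale would hide exactly the error being
measured — and proceeds in two stages:

1. **Landmark pre-alignment.** Nine corresponding anatomical landmarks
   (default: exocanthion L/R, endocanthion L/R, pronasale, subnasale,
   cheilion L/R, pogonion — configurable) are solved in closed form by the
   cross-covariance SVD construction with reflection correction. Exact at
   machine precision for noise-free correspondences; requires ≥ 3
   non-collinear points.
2. **ICP refinement.** Floating vertices (all of them up to a 50 000 cap,
   then a seeded uniform subsample) are matched to exact nearest points on
   the fixed surface; pairs beyond the **10 mm** rejection threshold are
   discarded (boundary and hair-like outliers must not steer convergence;
   this threshold is distinct from the 5 mm analysis band); the closed-form
   rigid update is applied. Iteration stops when the relative change of the
   RMS objective falls below **1e-6** or after **100** iterations —
   tolerances far below the 0.01 mm reporting precision. Replicated
   simulation studies use a documented fast preset (6 iterations, 1e-3)
   because alignment quality saturates within a few iterations at phantom
   resolutions.

The objective trace is non-increasing on clean inputs (the classical ICP
argument); with aggressive rejection-set churn on pathological data,
single-step upticks are theoretically possible and would be visible in the
trace.

## Trimming and facial thirds

The clinical procedure trims all of a patient's scans "in the same
boundary" to discard hair, ears and nostrils; the original boundary is a
manual curve and unrecoverable. The reproducible surrogate is (a) a
config-driven set of clip planes applied identically to every mesh, then
(b) a mutual-overlap mask: a vertex survives only if it lies within
**10 mm** of every other mesh's surface; triangles touching a dropped
vertex are removed.

The face is divided by two planes normal to the vertical axis of the
natural head position (NHP) frame, through glabella and subnasale: upper /
middle / lower thirds. NHP is a clinical posture; computationally a
surrogate frame is derived from landmarks (X = inter-exocanthion direction,
Y = glabella−subnasale direction orthogonalized against X, Z = X×Y, origin
at subnasale), or an explicit frame may be supplied. Triangles straddling a
cutting plane are split exactly at the edge–plane intersections, so the
three parts' areas sum to the whole (1e-6 relative, tested) and a part's
RMS does not depend on how the input happened to be triangulated. Vertices
exactly on a plane belong to the part above it (closed-below convention).

## Statistical battery

Per case the pipeline yields eight RMS values — scanner (A, B) × region
(global, upper, middle, lower). The battery runs, in order: per-group K-S
normality (Lilliefors-corrected by default, since the population moments
are estimated; the uncorrected variant is a flag), group means and sample
SDs (n−1), a per-scanner one-way ANOVA across the three thirds with a
Levene test (center = mean, configurable) gating the post hoc — Tukey's HSD
under equal variances, Dunnett's T3 otherwise — and four paired two-sided
t-tests comparing the scanners per region. α = 0.05 throughout; all tests
two-sided. A zero-variance paired design raises an error rather than
silently reporting p = 1.

Dunnett's T3 uses Welch pairwise t statistics with Satterthwaite degrees of
freedom; the multiplicity adjustment evaluates the studentized maximum
modulus under independence, `p_adj = 1 − (2·F_t(|t|; ν) − 1)^k` with `k`
the number of comparisons. Against tabulated SMM quantiles this numerical
construction is accurate to about 1e-4, which is far below any decision
boundary the battery faces.

## Synthetic phantoms and simulated scanners

No scan data ships with the package. A phantom is a height field over a
curved (paraboloid) base with smooth Gaussian bumps for the nose (16 mm),
brow (5 mm), lips (3.5 mm) and chin (6 mm) over a 140 × 170 mm patch, so
every landmark has an exact analytic position. An optional deformity adds a
broad collapse plus a sharp crease in a chosen third (default lower),
emulating the collapse/deflection of jaw deformities.

A scanner model applies, in order: undercut dropout (region removal),
decimation (deterministic grid vertex clustering with a bisection on the
cell size; it honors the triangle-count contract to within ~10–20%, and any
standard decimator could be substituted), Gaussian noise along vertex
normals (the depth-error model of triangulation scanners — noise is *not*
isotropic), uniform Laplacian smoothing (the optical low-pass), and an
unknown rigid displacement. Ground-truth displacements and noise levels are
recorded per scan, enabling registration-recovery and noise-floor audits.

Virtual-study defaults emulate the clinical design: 10 cases, one
low-noise full-resolution reference scan (σ = 0.05 mm, cf. a 0.059 mm
line-laser arm) and two test scanners (σ = 0.4 mm, 2 smoothing passes,
landmark jitter 0.5 mm, displacement ≤ 8°/8 mm) that differ in decimation
target (6000 vs 4000 triangles of an ~18k-triangle truth, mirroring the
60k/40k-of-200k ratio of the emulated devices). Each case draws a lower
face deformity of 3–8 mm and ±20% feature-amplitude jitter. Two presets
fix the replicated-study conditions: `null_study_config` (identical test
scanners, no deformity, 20×20 grids) for type-I-error calibration, and
`deformity_study_config` (4–8 mm deformity plus a dropout band below the
lower lip, 32×32 grids) for the region-ordering power check.

### What the phantoms do not show

* **Between-case variance is too small.** Real patients differ in
  expression, skin texture, coverage and cooperation; phantom cases differ
  only in drawn shape parameters and noise realizations. Simulated
  per-group SDs (~0.01 mm) are therefore an order of magnitude below
  clinically reported ones, and paired tests resolve tiny systematic
  differences — the default study's two scanners, which differ only in
  resolution, are distinguishable (p ≈ 0) even though comparable real
  devices were not. Calibration claims use the null preset, where the
  scanners are exactly exchangeable.
* **Noise-floor checks need vertex-coincident sampling.** The noise-floor
  acceptance band (measured RMS within 10% of an injected σ = 0.3 mm) holds
  on a patch whose spacing (5 mm) is large against σ; at fine spacing the
  closest-point distance to a jagged noisy surface is biased low by the
  local surface tilt. Pipeline RMS values on dense meshes therefore mix
  noise with interpolation bias, exactly as real scanner evaluations do.
* Deformity magnitude is a free parameter; no mapping to a clinical
  severity scale is claimed.

## Degenerate inputs and numerical conventions

* Degenerate (zero-area) triangles are permitted in closest-point queries
  (they collapse to segments/points exactly) and reported — not repaired —
  by mesh validation.
* Plane splitting snaps |signed distance| ≤ 1e-9 mm to the plane to avoid
  sliver triangles; slivers that still collapse to a repeated index are
  dropped (area loss below 1e-12 of any real triangle).
* STL files store an unindexed triangle soup; the reader merges
  exactly-coincident corners in first-occurrence order to recover
  connectivity. Binary STL is float32 by format definition, so round-trips
  are exact only to float32 resolution; OBJ, ASCII STL and PLY (written as
  doubles) round-trip below 1e-6 mm.
* Problem sizes in tests and replicated studies (20×20–48×48 phantom
  grids, 500 null replicates, 100 power replicates) were chosen as the
  smallest designs whose conclusions are stable under reseeding.
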