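# Methods

## The measurement problem

A saccular intracranial aneurysm imaged with retrospectively ECG-gated
4D-CTA yields one segmented vascular volume per cardiac phase (20 phases,
0–95 % of the R-R interval). Wall motion over the cycle is millimetric at
most and often sub-voxel, so every dynamic quantity in this package is
paired with an explicit uncertainty gate: a measurement counts as biology
only when it exceeds both a resolution floor and a noise-derived
threshold. Sub-threshold findings are reported as *not demonstrable above
uncertainty*, never as biologically absent.

## Pipeline

### Segmentation and sac isolation

Grey-valued volumes are thresholded at a fixed 180 HU (the contrast
bolus-tracking threshold); binary masks are smoothed with a 3×3×3 box
moving average and linearly refined 5× per axis (the `refine` parameter;
tests and examples use 2× on a 0.4 mm grid, which resolves the same
sub-voxel thresholds at lower cost). The wall surface is the 0.5
isosurface of the smoothed occupancy — the midpoint of a binary field
under linear smoothing — extracted by marching cubes in world
millimetres.

The centerline is a 3-D thinning skeleton with a 26-connectivity graph;
endpoints have degree 1, junctions degree ≥ 3. The *sac point* is the
skeleton point with maximal inscribed-sphere radius (distance-transform
value); skeleton points inside that maximal inscribed sphere are sac
points, the rest branch-centerline points, and branches are the connected
non-sac runs that reach an endpoint. The neck plane is built from
centerline-to-surface projections: each branch's points are projected
onto the surface toward the sac point, and per branch the projected point
nearest the neck junction becomes a cut point. Two branches give a plane
through both cut points whose normal is the perpendicular from the
cut-point line to the dome apex (the vertex of maximal extent along the
neck-to-sac direction — a frame-independent "highest point"); three or
more branches give the plane through the three cut points nearest the
neck. The sac is sliced off at this plane and closed with a planar
centroid-fan cap (exact for divergence-theorem volumes even on mildly
non-convex neck loops); the two halves must conserve the original volume
to 0.5 %.

Displacement mapping matches each reference-phase vertex to its nearest
vertex on every other phase mesh: d_i(t) = ‖v(t)_i − r_i‖, non-negative
by construction and zero at the reference phase (phase 0, the
conventional gating origin). Nearest-vertex matching is exact for motion
smaller than half the mesh edge length and a lower bound beyond that; no
regularised registration is attempted because none is defined for this
measurement.

### Morphology

Direct parameters are measured on the capped sac mesh (volumes via the
divergence theorem, areas from the triangulation) and on the neck
polygon. The neck polygon is the sac's own planar opening (the section of
the capped sac just above its cap): sectioning the sac+parent surface at
the neck plane instead can merge the neck loop with a long sliver where
the nearly-tangent plane grazes the parent vessel, inflating N_max; the
two definitions agree on clean geometry (hemisphere oracle) and the
sac-opening form is robust, so it is the default.

Ratio indices use the standard definitions: AR = H_max/N_max,
SR = H_max/parent diameter, UI = 1 − V_sac/V_hull,
NSI = 1 − (36π)^{1/3}·V^{2/3}/S, BF = W_max/N_max,
CP = 1/2 − h*/H. W_max and h* come from slicing the sac at 40 evenly
spaced heights parallel to the neck plane (including height 0, so a
hemisphere yields h* = 0 and CP = 1/2). NSI is referenced to a sphere
(NSI = 0 for a closed sphere, which satisfies S³ = 36πV²) so that convex,
round sacs score zero on both shape indices; `nsi_reference="hemisphere"`
selects the Raghavan-style (18π)^{1/3} constant, which is zero for a
hemispherical dome measured without its base. The parent diameter for SR
is twice the mean inscribed-sphere radius of branch-centerline points
within 3·N_max of the neck, or can be supplied directly.

### Dynamics

*Size change* between two examinations is significant when
|V̄₂ − V̄₁| > 2·√(SD₁² + SD₂²), with phase-wise means and sample SDs
(n−1) over the 20 phases — i.e. the change must exceed twice the combined
phase-to-phase measurement variability.

*Noise estimation.* σ_noise = MAD(d_i)/(0.6745·√2) where d_i are the
inter-phase first differences of the volume curve. The MAD (about the
median of d) is robust to the harmonic signal riding on the differences;
0.6745 converts MAD to a Gaussian SD and √2 undoes the variance doubling
of first differences. A literal /2 divisor (a published variant of the
same estimator) is available as `divisor="literal"`.

*GVP.* Amplitude is the raw peak-to-peak range of the volume curve — no
denoising is applied — and the flag requires amplitude > 3 mm³ (the
volume-resolution floor, `volume_floor`) **and** > 3σ_noise
(`sigma_multiple`). Both thresholds are configuration values, never
hidden constants.

*SWP.* Per-vertex amplitude is max_t d_i(t). Vertices above 0.3 mm are
grouped by mesh-edge connectivity; region area uses barycentric lumping
(one third of incident triangle areas per vertex, exact on uniform
meshes). Regions below 5 mm² are dropped; the kept fraction of the sac
surface classifies the result (none < 5 %, focal 5–20 %, heterogeneous
≥ 20 %).

*Qualification and decomposition.* A signal qualifies when ΔX > 0 and
SNR = ΔX/σ_noise ≥ `min_snr` (default 3; the threshold is not fixed by
any published value and is deliberately configurable). A noise-free
signal with zero-median differences reports SNR = +∞. The first-harmonic
fit X(t) = μ + a·sin(2πt/n) + b·cos(2πt/n) is ordinary least squares on
an orthogonal design (equally spaced phases over one cycle), so
√(a²+b²) equals the first Fourier coefficient magnitude and
fit + residuals reconstruct the input to machine precision. Residual MAD
summarises non-periodic content.

*Deformability.* Repeatability pairs give the Bland–Altman bias, limits
of agreement, and MDC = 1.96·SD(differences) (MDC95). Residual MAD counts
as deformability only when it exceeds max(MDC, noise floor); unqualified
signals raise a *not-evaluable* status rather than returning false, so
exclusion by reliability criteria is distinguishable from a negative
finding.

### Statistics

All cohort analyses are exact-small-sample methods: the two-sided Fisher
p sums hypergeometric probabilities of tables no more probable than the
observed one; the conditional odds ratio is the noncentral-hypergeometric
MLE (E_ψ[a | margins] = a) with a CI from inverting one-sided exact
conditional tests at α/2 per side, boundary tables yielding 0/∞ points
with one-sided intervals; risk-difference CIs use the Newcombe hybrid
score (a Wald interval cannot reproduce sensible intervals with zero
cells); Hedges' g applies the J = 1 − 3/(4·df − 1) small-sample
correction with the standard normal-approximation CI. Spearman ρ uses
average ranks with exact permutation p below n = 10; Mann–Whitney U uses
tie-aware exact enumeration up to a combined n of 12. No multiplicity
adjustment is applied — the analyses are exploratory by design, and
effect sizes with intervals carry the interpretation.

## Synthetic phantoms: what they do and do not emulate

The phantom is a sphere (sac) on a cylinder (parent vessel), voxelised
per phase on a lattice-aligned grid. It emulates the *geometry* of a
gated acquisition: periodic global radial pulsation, focal raised-cosine
patches (single, multiple, or counter-phase pairs — the latter produce
shape change with near-zero net volume change, dissociating SWP from
GVP), Gaussian jitter of the segmented boundary, a second branch
configuration (Y junction) for the three-point neck rule, and repeated
measurement pairs. Ground truth is analytic: sphere and spherical-cap
volumes, cap areas 2πr²(1 − cos θ), and quadrature sac volumes per phase.

It does **not** emulate CT physics — no reconstruction noise texture,
beam hardening, contrast-bolus dynamics, ECG irregularity, or patient
motion. Passing tests therefore demonstrate that the analysis chain is
correct and conservative under controlled geometry and boundary noise;
they do not certify performance on scanner data, where segmentation bias
and phase-dependent artefacts add failure modes the phantom cannot
produce.

Defaults mirror the study conditions: 20 phases, 3 mm sac on a 1.5 mm
parent vessel, 0.25 mm isotropic default spacing (finer than the 0.5 mm
in-plane acquisition so sub-voxel thresholds are testable; tests use
0.4 mm for speed), boundary noise 0–0.05 mm.

## Numerical choices

- Grids are snapped to the world lattice (origin a multiple of the
  spacing). Off-lattice grids voxelise symmetric shapes into even-width
  ribbons that 3-D thinning retracts into half-missing centerlines.
- Marching cubes output is used as-is: its vertices are already shared,
  and re-welding collapses the degenerate slivers it emits at on-grid
  crossings into non-manifold edges.
- Slicing duplicates vertices along the cut line; coincident vertices are
  welded (exact-tolerance union-find) before boundary loops are walked
  and capped.
- Ray-mesh projection uses exhaustive vectorised Möller–Trumbore
  (batched per ray), with branch centerlines subsampled to ≤ 120 rays.
- Index invariances: all six ratio indices are invariant to uniform
  scaling to 1e-6 relative; under rotation they agree to ~1e-3 because
  plane sections re-discretise on the rotated triangulation.

## Known limitations

- **The 3σ rule does not filter pure noise for a range statistic.** The
  GVP amplitude is the peak-to-peak range of 20 samples; for i.i.d.
  Gaussian noise that range averages ≈ 3.7σ, so "range > 3σ_noise" alone
  flags ~80 % of pure-noise series (measured 80.1 % over 10 000 seeded
  series; the acceptance suite documents this as a failing contract
  rather than hiding it). In practice the 3 mm³ resolution floor is the
  binding criterion; the 3σ rule only suppresses noise when σ_noise is
  large relative to the floor.
- **Box smoothing contracts convex surfaces.** The 0.5-isosurface after
  3×3×3 smoothing underestimates voxel-count volume by ≈ 2 % at 0.25 mm
  spacing (≈ 5 % at 0.4 mm); comparisons against voxel oracles carry this
  bias. Neck-cut volumes still agree with the constructive-geometry
  oracle within 5 %.
- **Nearest-vertex displacement is a lower bound** once motion exceeds
  half the mesh edge length, and drifts toward point-to-surface distance
  on dense meshes; tangential wall motion is invisible to it. This is
  inherent to the always-positive magnitude definition, not an artefact.
- The SNR qualification threshold and the deformability noise floor have
  no published numeric values; defaults (3, and 0 — i.e. MDC-only
  gating) are explicit configuration.
- Manual segmentation correction is out of scope: inputs the automatic
  chain cannot process raise stage-labelled errors instead.
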