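# Methods

This note documents the models, numerical choices and limitations behind
`curvemark`, in the spirit of a statistical-software methods appendix.
Everything quantitative stated here is computed by the test suite or the
acceptance script; nothing is quoted from elsewhere.

## Surface curvature and the shape index

At each mesh vertex a local frame is taken from the vertex normal (area-
weighted face-winding normal; consistently wound meshes give outward
normals, and a global flip flag exists for inward-wound meshes). The
neighbourhood is the Euclidean ball of radius 10 mm by default — an
anatomically motivated scale: small enough to resolve the alar and lip
ridges, large enough to average scanner noise. At least 6 neighbours are
required (5 fitted coefficients); sparser vertices are flagged invalid,
never zero-filled.

The height of the neighbourhood over the tangent plane is fitted by least
squares as

    z = e·x + f·y + ½(a·x² + 2b·xy + c·y²).

The linear terms absorb error in the estimated normal; no constant term is
included because the fitted vertex is the frame origin. Principal
curvatures are the eigenvalues of the shape operator I⁻¹·II with
I = [[1+e², ef], [ef, 1+f²]] and II = [[a, b], [b, c]]/√(1+e²+f²), not the
raw a, c — this makes the estimate first-order robust to frame tilt. The
generalized eigenvectors, pushed through the surface parameterisation,
give 3D principal directions orthogonal to each other and to the fitted
normal.

Sign convention: curvature is the second derivative of height along the
*outward* normal, so convex features have κ < 0 and shape index S → +1
(cap), concave features κ > 0 and S → −1 (cup). On a sampled 50 mm sphere
the fit recovers κ = −1/50 with ≈ 0.5 % mean error at 5 mm vertex spacing
(the residual is the truncation bias of a quadric over a curved patch; it
shrinks as the neighbourhood shrinks with mesh density, which the
convergence test verifies over three densities).

The shape index uses the umbilic limit convention (−1 both positive, +1
both negative). Vertices with both |κ| < 10⁻⁴ mm⁻¹ (radius of curvature
above 10 m) are flagged planar rather than classified — S is numerically
meaningless there. Categories follow the nine-band eighths partition of
[−1, 1] (cup, trough, rut, saddle rut, saddle, saddle ridge, ridge, dome,
cap), half-open on the left with the cap band closed; the bands and their
colours are configuration, not constants.

## Ridge and rut curves

A ridge point must (i) have S in the ridge band, default [3/8, 1] — the
band deliberately includes the dome/cap end so crests on rounded anatomy
such as the nasal dorsum are not dropped; (ii) be sufficiently
*anisotropic*, |κ₁−κ₂|/max(|κ₁|,|κ₂|) ≥ 0.05, because at umbilic points
(a sphere) no feature direction exists and suppression degenerates to
numerical noise; and (iii) be a strict local maximum, among one-ring
neighbours transverse to the feature direction, of the S-weighted
curvedness |S|·√((κ₁²+κ₂²)/2). The weighting matters: on an extruded
(cylindrical) crest the shape index is *constant* across the whole convex
flank, so shape index alone cannot localise the crest, while the
transverse bending rate peaks exactly on it. The feature direction is the
principal direction of the curvature smaller in magnitude (a crest bends
strongly across itself, weakly along itself).

Flagged points are linked by greedy nearest-neighbour chaining with a link
radius of 3× the median edge length and a 60° direction gate, growing both
ways from a seed; ties go to the stronger, then lower-indexed vertex for
determinism, and traces shorter than 5 points are discarded as noise.
Where two anatomical curves cross, the superposition locally turns the
surface into a dome and the ridge signature genuinely vanishes — this is
anatomy, not a defect — so either a wider link radius bridges the gap or
the curve is *continued*: a walk in small steps (half the median edge
length) projected back onto the surface by exact point-triangle closest-
point queries, in the last direction, toward a target point, or to the
closest point on another curve. The walk is a surface path, not an exact
geodesic; at facial curvature scales the difference is far below the mesh
resolution. Eyelid curves are edges of the palpebral fissure, not
curvature features, and are accepted only as user-supplied polylines.

## Curve smoothing and curvature profiles

Each coordinate of a traced polyline is smoothed as a function of chord
length with cubic B-splines on *uniform* (unclamped) knots and a second-
order difference penalty on the coefficients. Uniform knots keep the
penalty null space exactly the linear functions, so straight data are
reproduced for machine precision at any penalty. The penalty weight is
solved by root-finding so the trace of the smoother matrix equals the
requested effective degrees of freedom (default 8) within 0.01; because
the smoother depends only on the parameterisation, one weight serves all
three coordinates and the fit is exactly equivariant under rigid motions.
The fitted curve is re-parameterised to its own arc length through a dense
monotone table; derivatives with respect to arc length use the chain rule
(u′ = 1/|r_u|, u″ = −(r_u·r_uu)/|r_u|⁴).

The bending rate κ(s) = |r′×r″|/|r′|³ is evaluated on a uniform 512-point
arc-length grid (convergence-checked against 2048 on the circle; the
profile is unchanged to plotting precision). It is non-negative by
construction, re-parameterisation invariant, reduces to the planar
curvature magnitude for planar curves (checked to 1e-9), and reproduces
1/r on the circle and a/(a²+b²) on the helix.

Peak search excludes 5 % of arc length at each end (spline boundary
derivatives are unreliable) and can be restricted to a named half of the
curve for qualifiers such as "at the nasal root end"; curve tracing
direction conventions (mid-line superior→inferior, lateral medial→lateral)
are documented in the catalog. Exact ties resolve to the smaller arc
length with a warning, since the definitions presuppose a dominant peak;
the dominance ratio (peak over second-highest interior local maximum) is
reported as the QC metric, and a flat alar peak (dominance < 1.2) reports
alare coincident with alare crest. Crossings are closest-approach
midpoints — traced polylines rarely intersect exactly — found by dense
sampling plus exact segment-segment refinement, flagged beyond a 2 mm
tolerance.

## Registration and the variance-components model

Repeat annotations of one image share that image's coordinate frame, so
GPA is applied to the averages of the repeat pairs and each pair's
translation/rotation/scale is applied to both members, preserving within-
pair differences up to the pair's common scale factor. GPA itself is the
standard alternation (centre, scale to unit centroid size, rotate to the
mean by the Kabsch solution, re-estimate the mean) iterated to 1e-10; its
objective is non-increasing by construction and the test suite checks
this. After unit-size alignment the collection is rescaled once by the
mean centroid size of the raw pair averages, so fitted standard deviations
keep their millimetre meaning (unit-size coordinates would make all
variance components dimensionless shape units). A final rotation places
the mean exocanthion axis along +x and the subnasale→nasion direction in
the x–y plane (+y), making x/y/z readable as left-right/bottom-top/
back-front and fixing the rotational gauge; with that step the whole
pipeline is exactly invariant to any common rigid motion of the raw data
and covariant under a common rescaling.

The model for one landmark coordinate is

    v_ijklm = μ + o_i + s_j + d_jk + c_jkl + r_ijklm,

with independent centred Gaussian effects: observer (crossed), subject,
day-within-subject, capture-within-day, and the per-record repeat effect.
Day and capture effects are properties of the imaged face and are shared
by every observer of the same image; the repeat effect is each observer's
own re-annotation error and plays the role of the residual. (With the
repeat effect shared across observers instead, the crossed design's
covariance is singular — the observer-by-image interaction lies in no
effect's column space — and the Gaussian likelihood is ill-posed; the
per-record reading is the one under which ML is defined.)

Fitting is by maximum likelihood over log-variances (non-negativity by
construction), from a Henderson-style method-of-moments start plus random
restarts, with L-BFGS-B. For balanced full-factorial designs the
covariance matrix lies in the algebra spanned by Kronecker products of
identity and all-ones factors, so it is diagonalised exactly by
mean/contrast tensor projections: the log-likelihood becomes a sum over at
most 2⁵ strata of m·log λ + SS/λ with closed-form eigenvalues, each
evaluation O(n). A 32 000-record fit takes ~0.3 s. The balanced path is
verified, stratum by stratum, against an independent dense multivariate-
normal likelihood, and the optimiser against a brute-force 5-D likelihood
lattice on a tiny instance. Unbalanced data (≤ 4000 records) use the dense
likelihood directly. Variances converging to the floor are reported as 0
with a boundary flag; levels with a single unit (e.g. one day) are
inestimable and fixed at 0 with the same flag. REML is available but ML is
the default, which is also why the ML repeat SD differs from the ANOVA
mean-square estimator by a small degrees-of-freedom factor (the agreement
test allows 5 %).

Summaries average raw SDs (not variances) over landmarks and dimensions;
the combined per-identification reproducibility is
√(3·(σ_o²+σ_d²+σ_c²+σ_r²)), excluding the subject level (anatomy, not
error) and treating dimensions as independent. Per-landmark sphere radii
apply the same combination to each landmark's own per-dimension fits.

## Synthetic phantoms

The phantom module is first-class, tested code. Surfaces: the exact
quadric patch, the icosphere, the extruded Gaussian ridge
z = h·exp(−x²/2w²) (defaults h = 5 mm, w = 3 mm — a crest of realistic
facial sharpness whose analytic shape index on the crest is exactly ½),
and the composite of two orthogonal Gaussian ridges whose crest lines
cross at a known point. Analytic κ₁, κ₂ and S come from the closed-form
Monge-patch formulas at the noise-free vertex positions; optional Gaussian
noise displaces vertices along the analytic normal. Curves: circle, helix
and tangent arc-chains with piecewise-constant 1/R profiles. Grid spacing
defaults to 1 mm, the order of a stereophotogrammetry mesh resolution.

The hierarchical simulator draws each random effect once per index at the
stated SDs and sums them per the model; the study-design preset is 2
observers per definition group × 4 subjects × 2 days × 2 captures × 2
repeats (64 records per group), and the published per-level SDs
(curvature group 0.361/1.645/0.288/0.103/0.562 mm; orientation group
0.553/1.670/0.323/0.086/0.587 mm) are available as simulation truths. A
confirmation preset (10 observers per group, 5 subjects, 2 images,
gnathion plus four registration landmarks) mirrors the follow-up design.
Optionally every image is wrapped in a random similarity transform
(rotation ≤ 10°, scale 0.97–1.03, translation ≤ 20 mm) — small enough for
GPA to converge, large enough that registration is actually exercised.
All randomness flows through explicit seeds; no global state.

What the phantoms do *not* emulate: real scanner artefacts (holes,
stippling on flat regions, texture-dependent noise), non-Gaussian observer
behaviour, facial expression change, and the soft, low-anisotropy ridges
of real chins and brows. Passing phantom tests therefore demonstrates
correctness of the geometry and statistics, not field performance on
arbitrary faces; fully automatic seeding of all sixteen curves on real
data is explicitly out of scope.

## Problem sizes and determinism

The test suite runs phantoms at a few hundred to a few thousand vertices
and fits at up to ~10⁴ records; the acceptance script simulates and refits
32 000 records per target, sizes chosen so the closed-form likelihood path
is exercised at full study scale while the whole suite stays interactive.
With 100 observers the sampling SD of the fitted observer-level SD is ≈ 7 %
relative (a χ²₉₉ width), so the 10 % recovery checks are expected to pass
for most seeds but are intrinsically stochastic. Greedy linking, tie
rules and seed-driven generators make every pipeline output reproducible
bit-for-bit from its inputs and seed.
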