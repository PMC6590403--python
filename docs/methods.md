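# Methods

## Model

Two point sets are registered: a fixed set **P** (M points) and a moving set
**Q** (N points), each point a 4-vector (x, y, z, a) of Cartesian mm
coordinates plus a non-negative integer *form attribute*. Attribute 0 marks
unlabeled background; nonzero values name anatomical feature classes (in the
intended application: the individual suture arms of the Lambda fissure and
the protuberantia occipitalis externa, outlined coarsely by the operator on
both datasets).

**Binary matching.** The weighted 4-D distance
√(‖p − q‖² + w·(a_p − a_q)²) with a very large w (default 10⁹) reduces to the
Euclidean distance for equal attributes and is effectively infinite
otherwise, so the closest-point search rejects cross-class pairs outright.
The production path implements this exactly as one KD-tree per feature class
(the w → ∞ limit), which avoids the floating-point swamping of the spatial
term that a literal 4-D search with w = 10⁹ would suffer; the literal
finite-w exhaustive search is retained (`matching.brute_force_closest`) and
the test suite asserts the two agree pairwise to 10⁻⁹ on random clouds.
Nearest-neighbor ties are broken toward the lowest fixed index in both paths.
Moving points with attribute 0 do not participate in matching or energy; they
are carried through transforms for visualization and TRE only.

**Energy.** With dₙ the closest same-class distance of moving point n, each
point contributes the Gaussian scale-space potential Uₙ = 1 − exp(−dₙ²/σ²)
and the registration energy is E_σ = Σ Uₙ ∈ [0, N]. For dₙ ≤ 0.1 σ the
energy is within 1% of the quadratic spring energy Σ dₙ²/σ² (unit spring
constant), so near alignment the unitless residual approximates a squared
metric in mm. The aperture default σ = 10 sets the spatial scale at which
mismatches saturate; larger σ widens and smooths the landscape at the cost of
a flatter minimum.

**Vector field analysis.** Holding the correspondence fixed at the current
pose, the potential gradient at each attributed moving point is analytic:
∇Uₙ = (2/σ²)·exp(−dₙ²/σ²)·(qₙ − p*). The negative gradients are forces of
attraction Fₙ. The curl of this scattered vector field is estimated per point
by a weighted least-squares affine fit F(x) ≈ F₀ + J(x − xᵢ) over the k = 12
nearest field samples (Gaussian distance weights, bandwidth = mean neighbor
distance), reading the curl off the antisymmetric part of J. The estimator is
exact on affine fields; on rank-deficient neighborhoods (e.g. points along a
straight suture segment) it raises an error and the driver retries with a
doubled neighborhood, falling back to the attributed centroid as pivot if
geometry never permits a fit. The *vortex* — the sample of minimal curl
magnitude, ties broken by smaller force then lower index — is taken as the
instant center of rotation (ICR). The search is restricted to samples whose
force magnitude is at least 10⁻³ of the maximum: where the potential has
saturated the field vanishes numerically and its curl is zero only because
there is no field there, not because the point is a rotation center.

## Optimization

Six parameters are optimized: rotations (Φ, Θ, Ψ) in degrees about the x, y,
z axes — composed extrinsically, R = R_z(Ψ)·R_y(Θ)·R_x(Φ), the convention
used everywhere including transform JSON files — applied about a pivot, plus
a translation in mm. The VFA method pivots at the ICR; the Gaussian-fields
(GF) baseline pivots at the coordinate origin and replaces binary matching
with a soft 4-D nearest-neighbor search over all fixed points,
√(‖Δq‖² + w_gf·Δa²) with w_gf = σ² by default (attributes matter at the
scale of one aperture). Degenerate Euler configurations need no special
handling: transforms are built from parameters, never decomposed, except in
`inverse`/`compose` plumbing where any valid decomposition yields the
identical point map.

**Quasi-Newton core.** A standard BFGS inverse-Hessian iteration with Armijo
backtracking line search (unit initial step, shrink 0.5, slope constant
10⁻⁴, at most 30 halvings), terminating on gradient ∞-norm < 10⁻⁶, accepted
decrease < 10⁻⁹, or 500 iterations. The accepted-step objective sequence is
non-increasing by construction and the best visited point is returned.

**Log-domain objective.** The optimizer minimizes
f = −log Σₙ exp(−dₙ²/σ²), a strictly monotone transform of E_σ = N − e^(−f)
with identical minimizers, basins and stationary points. Rationale: when all
dₙ ≫ σ the Gaussian terms fall below the floating-point resolution of
E_σ ≈ N (and underflow entirely beyond dₙ ≈ 266 mm at σ = 10), making
decreases of E_σ invisible to any line search; the log-domain form keeps full
relative precision at arbitrary distance, and its gradient is a
softmax-weighted combination of the same per-point analytic gradients.
Reported residuals and energy traces are always E_σ (the final residual is
recomputed in full precision at the final pose).

**Driver.** The correspondence is recomputed at every objective evaluation
(line-search probes included); gradients freeze it at the evaluation pose.
The ICR is computed once before optimization (configurable periodic refresh).
Descent proceeds in outer rounds that re-center the parameterization at the
current pose with a fresh Hessian; when a round converges without improving,
the VFA driver *steps out*: it evaluates the energy at the 60 icosahedral
rotations about the (re-detected) ICR with the attributed mass center of the
moving cloud mapped onto the fixed one — the decoupling of rotation from
translation that the pivoted parameterization is built around — runs a
bounded trial descent from the few most promising poses, and commits the
excursion only if it ends strictly below the departure energy, so the
accepted energy trace remains non-increasing. The step-out stage belongs to
the field-analysis assistance and is disabled for the GF baseline by default
(it is a config switch), which preserves the original formulation's limited
convergence basin. There is no randomness anywhere in the optimizer; all
stochastic choices live in the experiment drivers and generators under
explicit seeds.

## Synthetic study data

`make_phantom` emulates a CT-segmented occiput at desk scale: ~5000
quasi-uniform points (Fibonacci lattice) on a hemisphere of radius 90 mm
whose radius is perturbed by a smooth seeded lobe field of ±5 mm amplitude
(breaking all rotational symmetries), centered off the coordinate origin at
(20, −15, 35) mm — imaging frames do not place the anatomy at the origin, and
an origin pivot is only distinguishable from an ICR pivot when the two
differ. Three suture-like arms (120 points each, classes 1–3) radiate from a
"Lambda" junction near the apex along geodesic-like arcs with unequal
azimuths, unequal lengths (82°, 70°, 76°) and a transverse sinusoidal wiggle;
the wiggle matters: a plain great-circle arc maps onto itself under a
half-turn about its midpoint, which manufactures flip local minima real
sutures do not have. A compact 60-point blob (class 4) stands in for the
protuberance. The arm/blob layout was set so the attributed mass center falls
within 0.25·radius of the cloud centroid — features evenly distributed with
respect to the principal axes are a stated operating condition of the method.

`simulate_amode_scan` emulates the mechanically positioned single-beam
acquisition: rays from the shell center on an inclusive polar grid,
Φ ∈ [0°, 360°], Θ ∈ [−60°, 60°], 1° resolution (361 × 121 nodes); each ray
hits the surface point nearest in angle (within a 0.75° cone; misses are
counted, not fatal), takes its radius plus Gaussian radial noise
(default 0.3 mm — an assumption about the ranging sensor, not a measured
value), inherits its form attribute, and a 30% random dropout models signal
loss through tissue. The device's crankshaft kinematics are not modeled — Θ
is sampled directly, since registration consumes only the resulting cloud —
and no acoustic physics (impedances, speed-of-sound interfaces) is simulated.
What passing tests on these data show is that the pipeline recovers rigid
misalignments of feature-labeled surfaces under realistic noise, truncation
(the scan window covers only part of the arms) and dropout; they cannot
certify segmentation quality, operator labeling variability, acoustic
artifacts, or tracking errors of a real acquisition chain.

## Evaluation protocols

* **TRE**: Euclidean error at labeled target points after registration; the
  synthetic target set sits on the anterior rim of the phantom (opposite the
  scanned pole) to expose the lever-arm effect. The real anatomical target
  list is not reproducible, so this is a documented stand-in.
* **Distance map**: per-fixed-point nearest distance to the registered
  moving cloud, raw and clamped to [0.3, 1.5] mm for color mapping; written
  as PLY scalars for external viewers.
* **Basin sweeps**: initial rotations in 5° steps over ±180° about each
  principal axis through the moving centroid; a run counts as converged when
  its residual is within 10% of the best residual of the sweep (sweep plots
  show raw residuals; set comparisons need a binary call).
* **Energy surfaces**: E_σ on a 10° grid over each pair of rotation angles,
  other parameters zero, pivot at the moving centroid; the grid spans
  [0°, 360°) — including 360° would duplicate the 0° row and make the global
  minimum trivially non-unique.

## Problem sizes and defaults

The shipped experiments use the generator defaults: 5000 + 420 phantom
points (420 attributed, 4 classes — the same order as the ~400 attributed
model points the method is designed around), scans of ~1000 attributed
points after dropout, 20 displacement replicates for self-registration, and
full ±180° sweeps at 5°. These sizes were chosen so the complete suite runs
on a single CPU in minutes while every qualitative regime (saturated start,
flip minima, noisy partial overlap) is exercised.

## Known limitations

* Global convergence is empirical, not guaranteed: the step-out stage probes
  a fixed 60-rotation cover of SO(3) (covering radius ≈ 37°), so a global
  basin narrower than that could be missed on feature geometries much less
  favorable than the design conditions.
* The curl of a gradient field vanishes identically in the continuum; the
  nonzero curls analyzed here arise from correspondence switching and
  discretization. The estimator is therefore a heuristic whose value is the
  pivot it selects, not a physical field property.
* The GF baseline implements the original formulation's *behavior* (soft
  additive attribute distance, origin pivot, no field-analysis assistance);
  its soft attribute weight is under-specified in the literature and is a
  configurable default here (σ²).
* Only rigid transforms; no affine or deformable extension, no quaternion
  parameterization in the public contract.
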