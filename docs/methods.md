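# Methods

This note records the models, numerical choices and design decisions
behind `taluscam`, in the order the pipeline uses them.

## Measurement protocol

**Cylinder fit.** The talocrural axis is modelled by the cylinder
minimising Σᵢ (dᵢ − r)², where dᵢ is the orthogonal distance of facet
vertex i to the axis; the fit is unconstrained by the surface. The
objective is parameterised by an axis point, two direction angles and
the radius and solved with Levenberg–Marquardt-style least squares
(`scipy.optimize.least_squares`, tolerances 1e-14). Partial arcs
(< 180°) make the objective locally multimodal, so the solver starts
from each principal axis of the selected points (with an algebraic Kasa
circle fit in the normal plane supplying centre and radius) and falls
back on up to 10 random-direction restarts, keeping the best converged
optimum. On noiseless 120° sectors the radius is recovered to < 1e-6 mm;
on noisy data the fit agrees with an independent multi-start
direction-search oracle to < 1e-4 mm.

**Landmarking.** Principal curvatures are estimated per vertex by
fitting a full quadric (linear + quadratic terms) over neighbours within
3× the mean edge length — a radius that gives stable fits at
scan-resolution meshing — and reading the shape operator from the
first/second fundamental forms. In `saddle` mode the landmark is the
vertex with k₁ > 0 > k₂ maximising |k₁k₂| (most saddle-like); when no
such vertex exists the groove is convex and a dedicated error signals
it, mirroring the one known convex-groove specimen; `convex_max` mode
then returns the largest-mean-curvature vertex. A manual vertex-id
override reproduces the original hand-placed workflow. This replaces a
view-dependent manual step with a view-independent geometric criterion;
rigid motions change the measured index by < 1e-6 and uniform scaling
leaves it unchanged (the index is dimensionless).

**Units** are millimetres throughout; meshes in other units are rescaled
at measurement time (`scale=` / `--units-scale`). The natural log of the
index is stored alongside the raw value (NaN when the index is ≤ 0);
default analyses use the raw index and a flag selects the log form,
since which analyses used the transform is not otherwise determined.

## Cam model

The sagittal cross-section is a base circle of the talocrural radius
plus a raised-cosine lobe of height `rise = (PTS index − 1) × radius`,
centred posteriorly (default 140°, full width 70°). Two modelling
decisions matter:

1. **The body is convex-by-construction**: r(φ) = R + max(0, rise)·bump(φ).
   A groove sunk inside the base circle cannot push a taut tendon, so
   negative rises leave the body — and hence the path length — exactly
   that of the circle. A literal polar dent would instead let the taut
   string bridge the dent with a chord and produce a spurious ~1e-2 mm
   excursion.
2. **Both tendon endpoints are fixed in the world frame by default**, so
   the computed excursion is the *cam-attributable* length change: a
   circular cam is rotation-invariant and yields exactly zero. Rotating
   the insertion with the foot (`rotate_insertion=True`) adds the
   ordinary moment-arm payout (~R·θ, about 6 mm over ±60° at R = 3 mm)
   that every ankle tendon has regardless of the shelf, which would
   swamp the cam signal.

The taut string is the shortest path avoiding the discretised body
(default 4096 boundary segments): the straight segment when unblocked,
otherwise the shorter boundary chain of the convex hull of the endpoints
and the outline — equivalent to a visibility-graph geodesic for a single
convex obstacle, and verified against one in the tests. Discretisation
keeps the zero-rise excursion below 1e-6 of the base radius. The default
tendon geometry (origin 10 radii proximal, insertion 3 radii distal,
both 0.6 radii posterior so the string wraps the posterior side) is
configurable; absolute path lengths are artefacts of that geometry, and
only ordinal claims — more rise, more excursion; peak in dorsiflexion —
are treated as conclusions.

## Trees and transforms

Trees are `dendropy` objects; internal nodes get stable preorder labels
(`n0`, `n1`, …) on load. Pagel transforms act on node depths over a
fixed topology: δ raises depth-normalised node heights to a power
(δ < 1 concentrates change near the root), κ raises each branch length
to a power (κ = 0 is purely speciational), λ scales internal branches
while preserving tip heights (λ = 0 is a star tree). Because all three
are depth maps, likelihood code computes transformed covariances
directly from a precomputed MRCA-index matrix without cloning trees —
bit-identical to transforming the tree and rebuilding the covariance,
and ~20× faster inside MCMC. Polytomies are retained (the covariance
formulation needs no bifurcation); zero-length branches are kept with a
warning, and a 1e-10 ridge is added only if the covariance fails its
Cholesky factorisation.

## BM-family inference

The random-walk model is a multivariate normal with mean `root` (plus
`trend × tip height` under the directional model, which is rejected on
ultrametric trees where the trend is unidentifiable) and covariance
σ² × shared-path-length matrix of the transformed tree. Root/trend are
profiled by GLS and σ² in closed form, leaving a bounded 1-D search over
the scaling value (δ, κ ∈ [0, 3], λ ∈ [0, 1]).

**Priors** (all configurable): root ~ Normal(trait mean, (10 × SD)²);
σ² ~ half-Cauchy scaled by the ML Brownian rate of the data; scaling
uniform on its bounds; trend ~ Normal(0, (10 × SD / tree depth)²).

**MCMC** is component-wise random-walk Metropolis on (root, log σ²,
scaling, [trend]) with step-size adaptation toward 30% acceptance during
burn-in, seeded and bit-reproducible.

**Stepping stone.** Powers follow the Beta(0.3, 1) quantile schedule
β_k = (k/K)^(1/0.3); each stone is sampled by MH initialised from the
previous stone's final state, and the log marginal likelihood is the sum
of per-stone log-mean-exponential importance ratios. Two independent
replicate runs are built in; their difference is the convergence
diagnostic, and the reported log ML is their mean. On a conjugate
normal–normal toy, 64 stones × 2000 generations land within 0.1 of the
analytic marginal. Log Bayes factors use the 2·Δlog ML convention with
positive evidence above 2. Paper-scale settings (1000 stones × 10,000
generations; 20M-generation reconstruction runs) remain valid arguments;
the shipped studies use the scaled-down settings above, which the
replicate diagnostic shows are converged at these problem sizes.

**Ancestral states.** For each posterior draw the tree is scaled by the
drawn Pagel value and the conditional normal of each requested node
given the tips (GLS reconstruction) is sampled once; two independent
runs are pooled and summarised by mean and 95% HPD (`arviz.hdi`). Nodes
can be named by label or as named clades (tip lists → MRCA). Passing a
fixed parameter set instead of a chain returns the exact plug-in
conditional mean and central interval with no Monte Carlo error; at the
tips the reconstruction degenerates to the observed values.

## Multi-regime OU and the stepwise search

A regime painting maps shifts to nodes; a shift colours the branch
subtending its node and all descendants until overridden. The likelihood
is multivariate normal with path-weighted optima means (root pinned at
the basal regime's optimum, so the α → 0 single-regime limit is Brownian
motion) and the fixed-root OU covariance, valid on non-ultrametric
trees. Optima are profiled by GLS at each α, σ² in closed form, and α is
searched on a log grid within [1e-8, 50/tree-depth]; boundary hits are
flagged, not hidden. **Profiled optima are box-constrained** to the
observed trait range widened by one range on each side (bounded LS on
the whitened system): unconstrained optima diverge when a shift's design
weight vanishes (a short branch at small α), which both produces
meaningless optima for a bounded ratio trait and creates spurious
stepwise gains. AICc uses parameter count 2 + number of distinct optima.

**Forward phase.** Greedy addition of the single best shift under the
classic accept-any-AICc-improvement rule builds the model path, but the
*returned* model is chosen along that path by a selection-adjusted
criterion: AICc + 2 ln(b) per shift, b the number of candidate branches.
The correction is the standard Bonferroni-style account of choosing each
shift location among b candidates — without it, the best spurious shift
on null data gains ≈ 2 ln(b) ≈ 9.7 (64 tips) against a penalty of ≈ 2.4,
and the search adds shifts to essentially every dataset, the documented
overfitting of stepwise-AIC regime detection. Exploration continues a
few steps past the current best (patience 3), which lets the path pass
through locally weak single-shift models on the way to a strong
multi-shift one; a relocation polish then hill-climbs each shift to
neighbouring branches at fixed model size. `aic_threshold=0` restores
the classic behaviour. The search is deterministic.

**Backward phase.** Regime pairs are greedily merged while plain AICc
improves (merging is nested simplification, so no selection correction
applies); no-op shifts left by merges are dropped. Shifts still sharing
an optimum afterwards are the convergent classes. Measured at the study
conditions (64 tips, two root-separated clades of 6–16 tips shifted from
0.7 to a shared 1.6, α = 8, σ² = 0.5 — a phylogenetic half-life under 3%
of tree depth, i.e. strong attraction), the search recovers a modal
shift count of 2, localises both shifts to within one node in 12/20
seeds, merges the convergent clades in 14/20, and adds no shift on null
data in 20/20.

**Genus consolidation** collapses species tips to one per genus
(configurable exceptions stay at species level), with genus values as
specimen-count-weighted means of species means by default — "weighted by
species representation" is ambiguous, so unweighted means are a flag.

## Synthetic data: what it does and does not emulate

The talus generator produces the two measured structures — a cylindrical
trochlear sector and a posterior quadric saddle patch with prescribed
principal curvatures — at known radius, shelf offset and saddle
location, with optional Gaussian vertex noise applied along normals
(mimicking scan roughness without breaking topology) after region tags
are recorded. It does not attempt anatomically realistic talar shape,
connected patch topology, or CT artefacts; passing the geometric tests
shows the protocol recovers known geometry at scan-like resolution and
noise, not that segmentation of real scans is solved. Trees are
pure-birth with optional fossil tips made by truncating pendant branches
by a uniform fraction (the simplest non-ultrametric generator). Trait
simulators use exact branchwise transitions (Gaussian increments for BM,
the closed-form OU transition per branch), so simulated distributions
are exact, not Euler approximations. The regime-recovery studies place
their two shifted clades so that the root separates them; without that,
a single deeper shift plus a carve-out is statistically indistinguishable
from the truth (measured < 1.5 AICc apart) and localisation is not a
meaningful target.

## Problem sizes and determinism

The shipped studies use 128-tip trees for root-recovery (20 simulations,
2000-generation chains), 64-tip trees for regime detection (20 seeds),
64 stones × 2000 generations for the stepping-stone check, and
0.1 mm-resolution meshes (~3200 vertices) for geometry — sizes at which
every stochastic check is stable across seeds while a full run of the
test suite and the acceptance script completes in minutes. All samplers
and generators take explicit integer seeds; the pipeline derives
per-stage seeds from one master seed and records them, with input and
output hashes, in its manifest. Known limitations: the cam model is 2-D
(no talar medial rotation during dorsiflexion, no 3-D tendon wrapping,
no muscle force or length–tension modelling); measurement-error variance
is not propagated into the OU fits; and δ is weakly identified on
pure-birth trees, where its ML estimator is strongly right-skewed even
though the likelihood surface is correct — interval summaries (HPDs)
remain calibrated.
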