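# Methods

`craniofit` implements a fully automatic statistical pipeline for
craniofacial reconstruction: three statistical models — a volumetric
(tetrahedral) skull model, a surface head model, and a dense per-vertex
statistic of facial soft-tissue thickness (FSTT) — are built from
corresponding skull/skin surfaces, and an unknown skull is turned into a
plausible head by fitting the skull model, attaching thickness as a union
of spheres, and fitting the head model to that sphere model.  This note
documents the model equations as implemented, the numerical choices, the
synthetic test bed, and the known limitations.

## Template fitting

### Volumetric skull registration

The skull template is a tetrahedral mesh with vertex positions `S` and
tetrahedra `T`.  Fitting to an extracted skull surface minimizes

    E(S) = E_fit(S) + lambda_reg * E_reg(S_prev, S)

where `E_fit` is the weighted mean of squared distances between template
vertices and their corresponding target points (weights `w_c`; the inner
skull shell gets weight 0.5 by default, the outer shell 1.0), and `E_reg`
penalizes the change of every tetrahedron's volume relative to the current
rest state `S_prev`.  The public `ereg_volume` returns the plain sum of
squared volume changes; inside the solver the per-tet change is divided by
the rest volume and averaged, which makes `lambda_reg` scale-invariant
(units mm^2).  Since tet volumes are trilinear in the vertices, each inner
iteration linearizes the volume residuals (Gauss-Newton) and solves the
sparse normal equations with a Levenberg-Marquardt damping of 1e-5 times
the largest diagonal entry; a step-halving line search guarantees the
energy never increases within an inner iteration.  The damping matters:
the volume energy is invariant under volume-preserving shear, and without
it vertices that currently have no correspondence can drift arbitrarily
along that null space.

The stiffness schedule runs six levels with `lambda_0 = 10 x E_fit` at
entry and geometric decay x0.2; the rest state `S_prev` is advanced to the
current state whenever `lambda_reg` drops.  Correspondences are recomputed
at every level:

* level 0 — hierarchical piecewise ICP: the template is partitioned by an
  octree (depth 2; parts under 10 vertices merge into their parent), each
  part is aligned by its own similarity transform, and each vertex takes
  the closest target point of its part-aligned position.  The parts refine
  from the identity (the template is coarsely aligned by precondition; a
  global ICP would drag a complete template onto a partial target), and a
  part whose ICP shifts its centroid by more than 6% of the template
  diagonal — a part whose data is missing — falls back to the identity;
* middle levels — closest-point correspondences from *all* template
  vertices, pruned by distance and normal deviation.  A curvature-gated
  vertex-to-vertex strategy (vertices above the 70th |H| percentile) is
  implemented and selectable, but it is not the default: on the smooth,
  feature-poor synthetic anatomy the gate leaves large regions without
  constraints while the material softens, which lets those regions freeze
  more than 2 mm away once the tight late-stage pruning begins.  On real
  skulls, whose curvature field is rich, the gated strategy is the natural
  choice; schedules are fully configurable.
* final levels — the two-way search: target vertices are matched to
  template vertices (pruned by distance and normal deviation), then those
  template vertices are matched back to target *surface points*, pruned by
  normal deviation only.  This suppresses tangential drift and ignores
  unmatched scan artifacts.

Pruning distances default to (20, 15, 10, 8, 4, 2) mm over the six levels
— generous while the template is far, and exactly the 2 mm evaluation
threshold at the end.  The normal-deviation gate is 60 degrees.  Two
further gates protect fits to *partial* targets (cropped scans):
correspondences whose displacement is tangential to the template normal
(pull angle above 75 degrees) are dropped — they arise when a cut boundary
steals matches from the adjacent unobserved region — and matches whose
target point lies within two median edge lengths of the target mesh's open
boundary are discarded outright.  The boundary filter is what actually
stops the creeping collapse of an unobserved calvaria onto the cut rim;
the same filter masks boundary points out of the model-based alignment
stage of reconstruction.  On closed targets all three gates are inactive
or near-inactive.

After the last level a *release step* removes accumulated parametrization
distortion: the best similarity transform from the undeformed template to
the fitted state through sparse points of interest (the ten named
landmarks plus every 20th vertex) is factored out, the residual
displacements at the points of interest are interpolated over the whole
template by one stiff bi-harmonic (squared graph-Laplacian) solve, and a
single soft re-attachment pass from this released rest state restores
surface contact.

### Surface head registration

The head template is a triangle mesh fitted with the same two-stage
scheme, but the regularizer is a bending energy on rotation-compensated
per-edge Laplacians:

    E_reg = (1 / sum_e A_e) * sum_e A_e || L_e(h) - R_e L_e(h_prev) ||^2

`A_e` is one third of the summed areas of the up-to-two incident triangles
(this partitions the total surface area over the edges), and `L_e` is the
uniform-weight second difference over the edge diamond,
`h_k + h_l - h_i - h_j` for an interior edge `(i, j)` with opposite
vertices `(k, l)` (boundary edges use `h_k - (h_i + h_j)/2`).  A
cotangent-weighted variant was considered and rejected: cotangent weights
degenerate on the skinny triangles that decimation and marching cubes
produce, while the uniform stencil has the same invariances — translation
invariance, exact rotation compensation through the per-edge best-fit
rotation `R_e` (Kabsch on the centered diamond vertices), and strict
positivity under pure scaling.  Minimization alternates a local step
(recompute `R_e`) with a global sparse linear solve per coordinate; the
system matrix is factorized once per level.  Correspondences run from scan
points to closest template surface points (barycentric constraints),
pruned by distance and normal deviation, optionally extended by landmark
pairs at 10x weight.

The weighted RMS error over surviving correspondences (2 mm pruning, as in
the fitting) is the reported fit quality.

## Statistical models

All three models are linear (PCA) models `x(w) = mean + U w` built by thin
SVD of the centered training matrix, with component variances
`sigma_k^2 = s_k^2 / (n - 1)`.  The skull model keeps all p-1 components;
the head model is capped at d = 30; the FSTT model keeps all r-1.  Model
fitting to partial observations solves the Tikhonov-regularized normal
equations with penalty `(lambda_tik / d) * sum_k (w_k / sigma_k)^2`
(lambda_tik = 1e-4 for head fitting, 1e-3 for skull fitting) and is exact
against a dense ridge solver.  Alignment and shape are optimized
alternately: closed-form weighted similarity (Umeyama, proper rotation
enforced) against current correspondences, then weights on the
back-transformed targets, until the objective stalls.

`ShapeModel.fit` returns a `ShapeFitResult` carrying weights, transform,
residual RMS and a `summary()` table, in the spirit of statistical
modelling packages; the registration pipeline itself remains functional
since its artifacts are meshes, not parameter estimates.

## FSTT statistic and sphere model

FSTT at a skull vertex is the shortest unsigned distance to the skin
surface — deliberately directionless, avoiding unstable normal estimates.
Vertices of the fitted template farther than 2 mm from the *extracted*
(possibly partial) skull carry no data there and are masked out.  The
per-vertex mean/std/count statistic uses the population (divide-by-N) std
by default; a flag selects the sample convention.  The thickness PCA model
is built over vertices valid in all subjects (no imputation by default).
For reconstruction, vertices supported by fewer than half the subjects
(the cropped-calvaria region in clinical data) are excluded from the
sphere model.

The sphere model places one sphere per active fitted-skull vertex with
radius equal to the chosen FSTT value and samples each sphere with a
64-point Fibonacci spiral (deterministic, quasi-uniform).  Because the
thickness is the shortest distance, the true skin surface is tangent to
each sphere from outside; the envelope of the union therefore approximates
the skin to within the sphere sampling spacing.

## Reconstruction

1. **Skull fitting.**  Optional global alignment (below), then alternating
   similarity/PCA fitting of the skull model (lambda_tik = 1e-3, distance
   pruning so partial remains do not drag unobserved regions), then
   non-rigid refinement of the synthesized skull with the volumetric
   energy.  Unobserved regions (e.g. a missing calvaria) stay on the
   statistical prior and the output is always a complete skull.
2. **Thickness attachment.**  The sphere model is built from the mean
   statistic, from a thickness-model instance, or from an explicit vector
   (validation mode).
3. **Landmark projection.**  Each of the ten named skull landmarks moves
   outward along its surface normal by the local radius and snaps to the
   nearest sphere sample — deterministic, radius-consistent, and exact in
   the concentric-sphere case.
4. **Head fitting.**  Landmark-only similarity + PCA initialization (the
   weights are clipped to +-2 sigma — ten landmarks cannot determine a
   full weight vector, and an unclipped Tikhonov solve interpolates them
   with implausible weights), then
   the non-rigid surface fit against the sphere samples with the
   outside-weight rule `w = 1 + 1e8 * ||h - q|| / B` for points on the
   outer side of the current template surface (`B` = bounding-box
   diagonal), recomputed from current normals every correspondence round.
   Distance/normal pruning is disabled for sphere targets — interior
   samples are legitimate, just five orders of magnitude less influential.

Head variants over a thickness-weight grid (sigma multiples, typically
{-2, 0, 2} per leading component) rebuild the partial sphere model and
refit the head per grid point; everything is deterministic given the
configuration seed.

**Plausible thickness projection.**  Reconstruction "with the subject's
best thickness representable by the model" projects the measured FSTT onto
the thickness model.  The projection uses only the leading components
covering 90% of the model variance, Tikhonov regularization
(lambda_tik = 1e-4), and clips weights to +-2 sigma.  Trailing sample-PCA
components estimated from a ten-subject population are dominated by noise;
including them makes the projected field spatially rough, and the
outside-weight rule then amplifies every locally overshooting sphere into
an outward bias of the fitted surface.  The +-2 sigma clip mirrors the
sigma range of the variant grids.

## Global alignment

`coarse_align` matches local Darboux-angle histograms (a simplified
fast-point-feature scheme) between downsampled clouds and estimates a
similarity transform by RANSAC over 3-point samples; the top candidates
are ICP-polished and scored by a trimmed RMS (45% quantile, robust to
half-missing targets).  Because local feature histograms carry almost no
information on near-spherical geometry — which includes this package's
synthetic anatomy — the result is always cross-checked against a
multi-start trimmed ICP over a rotation grid (42 directions x 4 rolls,
rigid steps), and the better-scoring pose wins.  On shapes with weak
asymmetry the absolute pose may remain ambiguous under heavy cropping even
when the surfaces coincide; the contract is therefore closest-point RMS
(inside the convergence basin of the subsequent ICP), not pose recovery.

## Synthetic anatomy

The test bed replaces a clinical CT database.  The skull template is a
tetrahedralized shell between two offset copies of a "skull-like" base
shape: an icosphere (outer radius 75 mm, shell 6 mm) with three smooth
radial indentations (two orbit-like, one jaw-like) that provide curvature
variation and break the sphere's symmetry.  Prisms between the shells are
split into three tetrahedra each with the classic smallest-vertex-index
diagonal rule, which keeps the decomposition conforming across prisms.
The head template is the same surface pushed outward by a nominal 5 mm
soft-tissue layer.  Ten named landmarks (nasion, menton, and bilateral
mid-supraorbitale, porion, ciliare lateralis/medialis) plus 70 facial
landmarks sit at fixed vertex indices shared by skull and head.

Subjects are generated by (a) low-rank smooth radial deformation modes
(low-order polynomial profiles in the vertex direction; default three
modes with 4 / 2.5 / 1.5 mm amplitudes), identical for both shells, and
(b) a strictly positive smooth thickness field (base 5 mm plus up to four
Gaussian bumps on the sphere, per-bump amplitude drawn with 1 mm scale),
applied radially to the deformed outer shell and lightly smoothed.  The
stored ground-truth FSTT is the *exact* distance from each generated skull
vertex to the final discrete skin mesh, so mesh-discretization effects
cancel when comparing measured to true thickness.  All generators are pure
functions of their parameters and a seed.

Voxelization rasterizes air/soft-tissue/bone as -1000 / +40 / +1000 HU
(straddling the -200 and 600 extraction iso-levels) by exact ray-triangle
classification, which is valid because every generated surface is
star-shaped about the subject centre.

What the synthetic anatomy does *not* reproduce: real cranial topology
(orbits and nasal aperture as holes, the mandible as a separate bone),
imaging noise and metal artifacts, the rich curvature field of real bone,
and demographic structure.  Consequently, passing tests demonstrate the
correctness and stability of the algorithms, not clinical accuracy; in
particular the curvature-gated correspondence strategy cannot show its
strength here, and global alignment leans on the rotation-grid search.

## Study-scale evaluation

The acceptance script and the study-scale tests use subdivision-3
templates (642 vertices per shell, 3840 tets; 642-vertex head) and a
ten-subject population — sizes chosen so the whole evaluation runs in a
few minutes while the fits are comfortably converged.  Reported
quantities: the mean facial-region skull-fitting error, the average
weighted head-fitting RMS under 2 mm pruning, and the held-out
reconstruction RMSE when the sphere model carries the subject's true
thickness, along with the strict error ordering
true < PCA-projected < mean thickness.

## Known limitations

* The volumetric energy does not resist volume-preserving shear; the
  damping and the release step control it, but per-vertex correspondence
  drift of a few millimetres can remain on feature-poor shapes (surface
  accuracy is unaffected).
* The feature-matching path of the global alignment is ineffective on
  near-spherical clouds; the rotation-grid fallback covers this at extra
  cost (~1 s on study-size clouds).
* The FSTT model assumes a common validity support across subjects;
  heavily fragmented masks would shrink the modelled vertex set.
* Decimation uses plain quadric edge collapse without topology or aspect
  safeguards beyond a normal-flip check.
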