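# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cervkin`, in the order the measurement chain runs.

## Signed point-to-surface distance

For a moving model with vertices *p<sub>i</sub>* and a target triangulated
surface, the distance field is d<sub>i</sub> = s<sub>i</sub> ·
min<sub>T</sub> ‖p<sub>i</sub> − c<sub>T</sub>(p<sub>i</sub>)‖, where
c<sub>T</sub> is the exact closest point on facet *T* (face interior, edge
or vertex) and the sign s<sub>i</sub> is +1 when the vertex lies on the
outward-normal side of the nearest facet, −1 behind it. The sign convention
(positive = outside the target surface) is a package definition; it assumes
consistently outward-wound targets, which the reader and the generator
guarantee.

Queries are accelerated with two KD-trees (scipy `cKDTree`): one over
on-surface samples (vertices plus face centroids) supplies an upper bound
*u* on the true distance; every facet whose centroid lies within
*u* + r<sub>max</sub> (r<sub>max</sub> = largest facet circumradius) is then
scanned with a vectorised exact point-triangle routine. Because the
candidate set provably contains every facet attaining the minimum and the
per-facet arithmetic is identical, the accelerated result equals the
exhaustive per-facet scan bit for bit; ties between facets are broken
toward the lowest face index in both paths. `method="bruteforce"` runs the
exhaustive scan directly and is used as the oracle in tests.

## Deviation statistics

A registered pair is summarised by: mean signed distance; the largest
positive and most negative distances; standard deviations of the positive
and negative subsets separately (an empty subset reports 0); mean |d|
("mean absolute deviation"); RMS of d ("mean deviation"); and angular
equivalents of the two extremes. These definitions are fixed and
self-consistent: mean |d| ≤ RMS ≤ max |d| holds for any field. The angular
equivalent uses the small-angle estimate θ = (e / h) rad for a linear
deviation *e* over a characteristic dimension *h*; *h* defaults to the
tabulated per-level vertebral height (11.9 mm for C5), so sub-0.06 mm mean
deviations correspond to ≈ 0.1–0.3° of angular uncertainty.

## Registration

ICP alternates (a) closest-point correspondence of every moving vertex to
the target *surface* and (b) the closed-form least-squares rigid update
(Kabsch via SVD, solved fresh from the original vertices each iteration so
the rotation is orthonormal to machine precision at every step). The
objective reported per iteration is the RMS correspondence distance.
Minimising the *sum of squared* distances is what admits the closed-form
update; a plain sum of distances (L1) has no such solution. With
least-squares updates the objective trace is mathematically non-increasing,
and the tests assert it on every run.

Stopping: relative objective decrease < 1e-6 (configurable), an absolute
floor of 1e-9 mm (exact alignment up to round-off; far below any physical
scale), or 200 iterations — exhaustion returns `converged=False` rather
than raising, so one bad posture cannot lose a session. There is no
randomness anywhere in ICP; optional distance-percentile trimming exists
for robustness experiments and is off by default because the models are
same-subject, same-bone.

Initialisation: `centroid` translates centroids onto each other;
`centroid+principal_axes` (default) additionally aligns vertex-covariance
eigenvectors, resolving the four-fold axis-sign ambiguity by scoring each
proper-rotation candidate with the RMS surface distance on a deterministic
~400-vertex subsample. A rank-deficient or repeated-eigenvalue covariance
(e.g. coplanar vertices) falls back to centroid mode with a warning.

Direction of registration follows the measurement design: the neutral
model moves onto each end-position target, and in model-accuracy validation
the independent (CT-like) copy moves onto the reference.

## Anatomic frames

Frames are built from four explicit landmarks; automatic detection is out
of scope (the generator emits its landmarks analytically). Orthonormalisation
order is fixed: x = unit(left − right) is primary; y is the superior
direction Gram-Schmidt-orthogonalised against x; z = x × y. The origin is
the posterior-inferior body point projected onto the mid-sagittal plane
(through the left/right midpoint, normal x). Building the frame once on the
neutral model and carrying it through registration transforms means
landmark placement error cancels within a subject: it offsets every posture
identically and drops out of motion-from-neutral results.

## 6-DOF decomposition

The upper frame expressed in the subjacent frame gives translation
R<sub>l</sub><sup>T</sup>(o<sub>u</sub> − o<sub>l</sub>) (reported in the
lower vertebra's anatomic directions) and rotation
R<sub>l</sub><sup>T</sup>R<sub>u</sub>. The default mode references each
end-position pose to the neutral pose, D = P<sub>neutral</sub><sup>−1</sup>
P<sub>posture</sub>, so the neutral posture is identically zero.

Euler sequence: intrinsic y–x–z (axial rotation, then flexion–extension,
then lateral bending), configurable among all six proper sequences. The
choice is a convention, not a claim: cross-sequence differences are second
order in the angles (~θ², about 0.4° at 5°, 0.05° below ~1.5°), which the
property tests assert at the correct scaling. Sign mapping: a right-hand
rotation about +x (left axis) tips the head forward, so α negates the raw
x angle (flexion negative); the raw z and y angles already carry the
documented bending/rotation signs. The y–x–z singularity sits at ±90° of
flexion–extension, far outside physiological cervical motion; the
decomposition raises a hard error within 1e-6° of it rather than returning
garbage.

## Synthetic vertebrae

Meshes are built by marching cubes (scikit-image) over an implicit union of
primitives — a superelliptical body cylinder, pedicle and lamina capsules,
two transverse processes and a spinous process — plus a gentle fixed
sinusoidal surface texture (0.3 mm amplitude) that breaks residual
symmetry and sharpens the registration optimum. After meshing, vertices are
rescaled anisotropically so the bounding box matches the built-in per-level
dimension table exactly (height, width, length per C1–C7). Deliberate
asymmetries (unequal transverse-process radii and tip heights, tilted
spinous process) remove rotational and mirror near-symmetries, so the
registration optimum is unique.

These fixtures are *stylized, not anatomically faithful*: what the tests
need is realistic size, surface complexity and broken symmetry — not
atlas-grade anatomy. Default marching-cubes pitch is 0.9 mm
(≈ 7.5 k faces for C5); the evaluation experiments use 1.2 mm
(≈ 4.3 k faces) to keep run times in minutes.

### Perturbation model

`perturb_mesh` emulates an independent re-segmentation in two steps.
*Remeshing* redistributes vertices with one seeded, asymmetrically weighted
Laplacian step whose result is re-projected exactly onto the input surface:
no output vertex coincides with an input vertex (trivial point
correspondence is destroyed, as between CT- and CBCT-derived models), yet
the geometry is preserved exactly — the remesh-only deviation is at
round-off level. `remesh_factor` > 1 midpoint-subdivides first; other
target face-count ratios are reached by shortest-edge midpoint-collapse
decimation with link-condition and normal-flip guards. *Noise* then
displaces each vertex along its local normal by N(0, σ²), modelling
segmentation boundary error (boundary uncertainty is normal to the surface,
not isotropic). The closed-form consequence — mean |d| = σ·√(2/π), about
0.16 mm at σ = 0.2 mm — is asserted within 15 %, the slack covering normal
estimation and curvature effects.

Defaults: σ = 0.2 mm, matching the sub-0.6 mm deviation regime that
segmentation of clinical scans achieves; remesh factor 1.

### Motion scenarios

`make_scenario` chains per-joint 6-DOF displacements bottom-up (C7 fixed)
through a neutral stack whose frames sit at the tabulated vertebral heights
plus a 4 mm disc gap. The presets are qualitative templates of in vivo
patterns with user-settable magnitudes: `ar` concentrates ≈ 30° of axial
rotation at C1–C2 with opposite-direction coupled lateral bending there and
small same-direction bending subaxially; `lb` distributes bending roughly
evenly; `fe` spreads flexion–extension across levels. Injected joint values
are recovered exactly (< 1e-9) by the frame/decomposition chain when the
ground-truth transforms are used directly, which pins the convention
consistency of the whole kinematics stack.

## Problem sizes and tolerances in the evaluation experiments

- Parameter recovery: 50 trials per condition, C5 at 1.2 mm pitch,
  rotations uniform to 35° (covering the largest physiological segmental
  motion, ≈ 31° of C1–C2 axial rotation), translations to 15 mm;
  pass bounds 0.1°/0.1 mm noiseless and 0.5°/0.3 mm at σ = 0.2 mm.
- Euler round-trip: 1,000 random rotations with all angles ≤ 45°, bound
  1e-9.
- End-to-end C1–C2: one 30° scenario at σ = 0.2 mm, bound 0.5° on β and
  0.3 mm on translation.

## Known limitations

- The synthetic fixtures do not emulate real segmentation artifacts:
  spatially correlated noise, missing patches, metal artifacts, or
  modality-dependent bias between CT and CBCT surfaces. Passing tests
  demonstrate the correctness and noise behaviour of the measurement chain,
  not the accuracy of any particular scanner or segmentation pipeline.
- ICP converges to a local optimum; principal-axes initialisation handles
  the tested ±35° basin but global registration is out of scope, and a
  failed basin is reported (`converged=False` / large residual), not
  repaired.
- Frames require user-supplied landmarks on real data; landmark recipes are
  not standardised across studies and a different origin convention changes
  translation (not rotation) readings.
- Only subjacent-vertebra referencing is implemented; C1 motion relative to
  the occiput is not measured.
- Statistics across subjects, time-resolved kinematics and helical-axis
  representations are out of scope.
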