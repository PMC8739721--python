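# Methods

## The model

Normal-tissue response to fractionated irradiation is described by the
linear-quadratic model. A course of `n` equal fractions delivering physical
dose `d` per fraction to a voxel has biologically effective dose

    BED = n · d · (1 + d / (α/β))

where α/β (Gy) is the tissue-specific LQ parameter. `rebed` stores each
course as *total* physical dose and derives `d = D_total / n` at conversion
time; this assumes every fraction delivers the same spatial distribution,
which is the standard planning assumption and is recorded in every run log.
BED is additive across courses under the LQ model, so per-course BED maps on
a common grid sum voxel-by-voxel into a composite; physical dose is not
additive in any biologically meaningful sense once fraction sizes differ,
which is the discrepancy the nominal-sum output makes visible.

The default α/β is 3 Gy, appropriate for late-responding normal tissue.
A composite is tagged with its α/β and maps at different ratios are refused
at summation — BEDs at different α/β are not commensurable. Per-tissue
ratios are obtained by requesting one composite per ratio. EQD2 output uses
the standard identity EQD2 = BED / (1 + 2/(α/β)).

Because the analysis targets normal tissue, tumor voxels can be excluded
via a mask: they are carried as NaN ("not evaluated"), propagate through
summation, and drop out of structure volumes and all DVH statistics. In
exported volumes the exclusion sentinel is −1 (BED is otherwise ≥ 0).
No repair correction is applied for the time interval between courses; the
interval, if known, is a reporting matter only.

## Pipeline order

Physical dose is warped onto the reference grid *first* and converted to
BED *second*. The two orders differ under interpolation (BED is a convex
function of dose, so interpolating BED values overestimates mixed-voxel
BED); the warp-then-convert order is asserted by an internal stage-order
check in the pipeline. The reference course defaults to the first listed —
the choice is arbitrary for two scans of the same patient — and the
accumulation grid defaults to 2.5 mm isotropic voxels.

## Registration

The moving course's CT is aligned to the reference CT in two stages, both
deterministic (full sampling, fixed iteration schedules, no randomized
components), implemented on SimpleITK primitives:

* **Rigid (6-DOF)**: mean-squares metric restricted to the bone-thresholded
  region of the reference image (default 200 HU, configurable), regular-step
  gradient descent, 3-level pyramid, multi-start from identity and from a
  geometry-centered initialization. Bony anatomy is rigid between time
  points, which is why the metric is masked to it.
* **Deformable**: multi-resolution fast-symmetric-forces demons with
  Gaussian regularization of the displacement field (default σ = 2 mm,
  default 3 levels, 50 iterations/level). The rigid stage is applied by
  resampling, so the recovered field composes as `x → rigid(x + d(x))`.
  The mean absolute intensity residual is scored at full resolution after
  every level; if it fails to decrease the best-so-far field is returned
  with a warning, never a silent failure. The discrete Jacobian determinant
  of `identity + d` is checked and the fraction of non-positive voxels
  logged (≥ 99 % positive is expected for a plausible field).

Any smooth, approximately diffeomorphic method would satisfy the contract
the pipeline actually relies on — that OAR dose metrics are preserved — and
the method is pluggable behind the `DeformationField` interface.

**Deformation QA.** After warping, per-OAR Dmax, Dmean and D1cc are
computed on the original (moving-frame) dose and on the warped dose over
the contours propagated through the same transform, and relative changes
are compared against a 2 % tolerance. Structures missing on either side are
listed as unvalidatable rather than failing the run. Contour propagation
warps the binary occupancy with trilinear interpolation and thresholds at
0.5, which preserves thin-structure volume much better than
nearest-neighbour sampling.

## DVH conventions

* `DxCC`: voxel values inside the structure are sorted descending (ties
  broken by voxel index, so results are permutation-invariant and
  deterministic), voxel volumes accumulated, and the value of the voxel
  that first reaches x cc is returned — no sub-voxel interpolation. The
  convention is conservative by at most one voxel value.
* `Vx`: percent of structure volume receiving ≥ x Gy, inclusive at the
  boundary, matching common treatment-planning semantics.
* Lung V5/V20/V35 thresholds are interpreted in composite-BED Gy by
  default (the composite is the grid being analysed); physical-dose
  thresholds are available by running the panel on the nominal-sum grid.
* Requesting `DxCC` beyond the structure volume returns the structure
  minimum with a warning rather than failing.
* The default panel assigns D0.2cc to plexus-class structures; D1cc to
  cord, airway and great-vessel classes; D30cc/D50cc to chest wall and
  esophagus; D5cc/D40cc to heart; V5/V20/V35 to lung. Classes are matched
  by name keyword and the panel is fully configurable.

Constraint comparison reports a margin per entry and flags exceedances; the
report header carries an explicit disclaimer that reference values are
guidance, not validated clinical limits.

## Geometry and I/O

Grids live in the DICOM patient coordinate system (LPS, mm); voxel indices
are 0-based with the origin at the center of voxel (0,0,0), matching
RTDOSE `ImagePositionPatient` semantics. RTDOSE files are read via the
dose-grid-scaling tag (per-fraction objects are scaled to course totals
only on request and only when fraction metadata is present); writing uses
32-bit stored values, so round-trip error is bounded by one scaling
quantum. RTSTRUCT planar contours are rasterized per slice with even-odd
polygon fill sampled at voxel centers; contours more than half a slice
spacing from any grid slice are rejected. Any SimpleITK-readable raster
volume with full geometry is accepted as a research fallback for doses,
anatomies, masks and displacement fields.

Resampling outside a source grid's support yields 0 Gy — conservative for
accumulation — and the out-of-support voxel count is logged for audit.

## The phantom

The synthetic generator emulates a thoracic re-irradiation case: a
soft-tissue body with air outside, a low-intensity lung region,
high-intensity vertebra/rib analogues placed asymmetrically so all six
rigid degrees of freedom are observable, a spherical target, and four OAR
analogues (cord, chest wall, lung, bronchial tree — the latter running
close past the target, the central-structure scenario). Default conditions:
64³ voxels at 2.5 mm, target radius 25 mm, penumbra 5 mm, two courses of
50 Gy/4 fx and 70 Gy/10 fx, a smooth sinusoidal deformation of 4 mm peak
amplitude and 80 mm wavelength plus a small rigid offset (≈5 mm, 3°)
between time points.

Two constructions keep every oracle closed-form:

* The moving course lives in the canonical frame and the reference course
  is its analytic pull-back through the ground-truth map
  `φ(x) = rigid(x + d(x))` — evaluated exactly at voxel centers, so no
  numerical field inversion or interpolation enters the ground truth.
* Dose profiles have an *exactly flat* plateau with a smoothstep penumbra.
  Any mapping that lands inside the plateau samples exactly the
  prescription, so the composite BED in the overlap core (a ball small
  enough that the true map plus a 3 mm registration budget cannot leave
  the plateau) equals the sum of the closed-form per-course BEDs.

Answer-sheet values are recomputed at generation time by an independent
scalar implementation of the LQ form, not copied from the package code.
Optional Gaussian noise perturbs the anatomy only, so dose oracles survive
robustness experiments. Cases are bitwise reproducible from (spec, seed).

What the phantom does *not* emulate: realistic CT texture and artifacts,
sliding motion at pleural interfaces, topology changes (tumor growth or
collapse between courses), beam-model dose (profiles are analytic), and
contouring variability. Passing tests therefore demonstrate correctness of
the algorithmic chain under smooth, well-posed conditions, not clinical
registration accuracy on real anatomy.

## Numerical choices and problem sizes

Registration endpoint error is evaluated over the body region, where the
image carries signal; in the surrounding air any displacement matches the
(constant) intensities and recovery is ill-posed. Multi-resolution depth
matters for large coherent displacements (a ~10 mm offset absorbed by the
deformable stage drops from ≈7.7 mm to ≈1.1 mm mean endpoint error going
from 1 to 3 levels) while for small smooth fields a single level already
converges. Tests and the acceptance script use 64³ grids at 2.5 mm — large
enough that bone, lung and penumbra structures are resolved, small enough
that a full pipeline run takes seconds. Reports contain no timestamps, so
reruns on identical inputs are byte-identical; summation order is fixed for
bit-reproducibility.
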