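# Methods

This note records the model implemented by `admtp`, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic phantom does and does not establish about real data.

## Model and assumptions

The planner assumes co-registered inputs on a shared voxel grid: an integer
parcellation defining the ROIs, binary masks for arteries, veins, sulci and grey
matter, and a watertight skull surface mesh in the same world coordinates. No
registration, resampling or segmentation is performed; trajectories are straight
line segments from a deep target point to a skull-vertex entry point.

All geometry is computed in world millimetres. Voxel indices are 0-based with the
voxel centred on its integer index; a world point belongs to the voxel whose index
coordinates round to it under half-open boundaries `[i−0.5, i+0.5)`. Scalar fields
are sampled at off-grid points by trilinear interpolation with edge extension —
the risk integrand is evaluated along continuous segments, so nearest-voxel
lookups would quantize scores unnecessarily (mask membership for the hard
intersection constraints, by contrast, *is* a nearest-voxel test, since a mask has
no meaningful sub-voxel value).

### Distance fields

Distances to volumetric structures use the exact Euclidean distance transform on
the voxel grid with anisotropic spacing support: exact at voxel resolution, zero
on structure voxels, and 1-Lipschitz in world distance. Distance fields to the
skull *mesh* are computed by subdividing the surface until every edge is shorter
than half a voxel, binning the vertices into grid voxels, and transforming that
rasterised shell — accurate to one voxel diagonal, which matches the resolution of
every other field. Triangle-exact nearest-point (BVH) queries remain available
through the wrapped trimesh object for point-set use; they are not used for whole-
grid fields because a per-voxel mesh query adds cost without adding accuracy at
voxel scale.

The signed GM distance is positive inside GM, negative outside, with the
Heaviside convention H(0) = 1 (the surface counts as inside). Under trilinear
sampling the zero crossing falls halfway between a GM voxel and its background
neighbour.

### Target risk map

`f(c)` combines a spatial prior and vessel avoidance with weights
`w_sp = 0.25`, `w_cri = 0.75` (a single spatial-prior weight exists; the
configuration calls it `w_roi`). Two prior modes are provided:

- **medial_surface** — `f_sp` is the normalized distance to the skull, taken
  directly, so ROI voxels nearest the skull carry the lowest prior value. The
  wording of the underlying model is ambiguous about the sign; the direct
  (non-inverted) form is used because it is the literal normalized distance
  `d̃(c, skull)` and it makes the testable ordering hold: the top-ranked
  candidate's skull distance never exceeds the ROI median.
- **roi_centreline** — the raw distance *to* the ROI is zero everywhere inside
  it and cannot rank interior points, so the prior is instead one minus the
  normalized interior depth (distance to the ROI's complement): the thickest,
  most central part of the ROI attains the lowest prior value.

Both priors are in [0, 1] with maximum exactly 1; `f_cri` is normalized by its
grid-wide maximum, per the defining formula.

Local minima of `f` are regional minima under 26-connectivity. Each connected
plateau of equal value contributes a single representative: its lexicographically
smallest voxel, a deterministic tie-break. K-means clustering of the minima uses
deterministic farthest-point initialisation (first centre = point nearest the
minima centroid, then iteratively the point farthest from the chosen set, ties to
the lowest index) with a single `n_init`, so identical inputs always produce
identical clusters. When one ROI hosts several electrodes, clusters are matched
to electrodes in order of each cluster's best (lowest) `f`. If fewer minima than
electrodes exist, points are assigned round-robin with a warning — a degraded
grouping is more useful to a planner than a hard stop; electrodes left without
any candidate still fail loudly downstream.

### Trajectory scoring

The risk integrand as literally printed, `d_risk − (f_cri(x) − d_safe)`, gives
R = 10/7 when the vessel distance equals `d_safe` and 3/7 at `d_risk` under the
default thresholds, contradicting the stated endpoint behaviour (R = 1 inside the
safe distance, R = 0 beyond the no-risk distance). The implemented form is the
clamped linear ramp `clamp((d_risk − d)/(d_risk − d_safe), 0, 1)` averaged over
1 mm sample points, which reproduces both endpoints exactly; the unclamped
variant is available behind `risk_score(..., printed_form=True)` for comparison.
Two vessel-distance fields are kept deliberately: the raw field in millimetres
for the risk ramp (it is compared against 3 mm and 10 mm) and its normalization
for the target risk map.

Sulci participate in the hard intersection constraint (any sampled point inside
arteries, veins *or* sulci rejects the trajectory) but not in the risk ramp,
which measures distance to blood vessels only. The target risk map's critical
set likewise contains vessels only.

Contacts are modelled 1-D along the trajectory line: centres at 0, 10, …, 90 mm
from the target, probed at the centre and at ±1.2 mm (the contact radius) along
the direction. Contacts beyond the entry point are evaluated at their nominal
offsets — no truncation rule is applied — and simply capture nothing outside the
head. G is therefore always an integer multiple of 1/30, with per-contact values
in {0, 1/3, 2/3, 1}.

Entry angle is `arccos(|⟨direction, vertex normal⟩|)` in degrees. Relaxation
(only triggered when a level leaves no surviving trajectory) raises `d_len` and
`d_ang` in lockstep by 10 mm / 10° per level, saturating at 110 mm / 45°;
exhausting the schedule without survivors is a per-electrode error. Survivors are
ordered by S ascending with ties broken by lower R, then target rank, then entry
index — a total, reproducible order.

### Plan search

The depth-first search visits electrodes in strategy-file order (the order
affects only search effort, not the optimum) and candidates in ascending S,
with branch-and-bound on the partial score sum plus each remaining electrode's
best possible score. The 0.5 mm diversity rule is applied against the
*conflicting* trajectory: after a pairwise conflict, subsequent candidates within
0.5 mm of the conflicting one are skipped at that node. With the diversity
threshold set to 0 the search is exactly optimal on small instances (verified
against exhaustive enumeration); with 0.5 mm it may discard a near-duplicate
optimum but never returns an infeasible plan. A node budget (10⁶ expansions)
guards the combinatorial worst case; exhausting it, like infeasibility, triggers
the fallback: greedy max-min separation over each electrode's 50 lowest-S
candidates, refined by single-electrode swaps until no swap improves the minimum
pairwise distance (ties toward lower mean S), returned with `feasible = False`
and the achieved separation recorded. The search is deterministic throughout —
identical inputs and seed give byte-identical plan JSON.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `m_targets` | 10 | — | candidate targets per electrode |
| `w_roi` (= w_sp) | 0.25 | — | spatial-prior weight in f(c) |
| `w_cri` | 0.75 | — | vessel-avoidance weight in f(c) |
| `d_len` | 80 | mm | maximum trajectory length (cap 110) |
| `d_ang` | 15 | ° | maximum angle to skull normal (cap 45) |
| `d_safe` | 3 | mm | vessel distance of maximum risk |
| `d_risk` | 10 | mm | vessel distance of zero risk |
| `d_traj` | 10 | mm | minimum inter-electrode separation |
| `sampling_step` | 1.0 | mm | along-trajectory sample spacing |
| `diversity_epsilon` | 0.5 | mm | near-duplicate skip threshold |

The S-ordering of candidates is stable once the sampling step is at or below
0.5 mm on the phantom; 1 mm is the default because it matches the voxel size.

## The phantom

The generator emulates the *scale* of the clinical inputs — 1 mm isotropic
voxels, ~180 mm head diameter, a 642-vertex skull mesh — with idealised anatomy:
a spherical skull shell, a 6 mm cortical GM ribbon, eight 8 mm-semi-axis deep ROI
blobs (which are themselves grey matter) on well-separated radial directions, a
midline venous arc plus two branch vessels (one threaded 10 mm from a corridor
axis so that risk scores are exercised without blocking the corridor), and two
thin sulcal sheets. Each ROI declares a radial corridor (half-angle 10°) to the
skull; after rasterisation the generator *verifies* that no vessel or sulcus
voxel lies inside any corridor and refuses to emit an inconsistent phantom.
Scaled-down variants (2 mm voxels on the same world geometry) are used in unit
tests for speed; the end-to-end feasibility check runs at full scale.

What passing on the phantom shows: the formulas, constraint logic, relaxation,
clustering and search behave exactly as specified, deterministically, on inputs
whose ground truth is known by construction. What it does not show: robustness to
segmentation error, vascular trees of clinical density and tortuosity, non-convex
skulls, ROIs abutting vessels, or registration imperfections — the phantom's
corridors guarantee feasibility, so the fallback path and heavy relaxation are
exercised by engineered unit tests rather than by the default phantom.

## Degenerate inputs and errors

Empty structures, all-zero fields to normalize, empty ROIs, GM masks that are
empty or cover the whole grid, zero-length segments, and singular affines are
rejected at construction with descriptive errors. An electrode with no feasible
trajectory after maximal relaxation, or an unknown ROI label, fails individually;
the pipeline plans the remaining electrodes and reports the failures (the CLI
maps these to distinct exit codes: 2 missing input, 3 unknown label, 4
per-electrode failure).

## Known limitations

- Straight rigid trajectories only: no bolt hardware, brain shift or drilling
  mechanics are modelled.
- One shared skull-vertex entry set for all targets (per-pair filtering), so
  entry resolution is bounded by the mesh tessellation.
- The roi_centreline prior ranks by interior depth, which coincides with the
  anatomical centreline for tubular ROIs but degenerates toward the centroid for
  near-spherical ones.
- K-means clusters follow ROI geometry, not anatomical subdivisions; electrodes
  sharing an ROI get geometrically, not clinically, distinct territories.
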