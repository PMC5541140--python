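# admtp — anatomy-driven multiple trajectory planning for SEEG electrodes

Patients with drug-resistant focal epilepsy may need stereo-electroencephalography
(SEEG): depth electrodes implanted through the skull along straight trajectories to
localise the epileptogenic zone. Planning an implantation by hand takes hours — each
trajectory must reach its deep region of interest (ROI), avoid arteries, veins and
sulci, enter the skull at a drillable angle, sample grey matter (GM), and keep clear
of every other electrode. `admtp` automates this: given a brain parcellation, masks
of the critical structures, a skull surface mesh and a strategy file listing the
requested electrodes, it computes a full, mutually non-conflicting implantation plan.

No patient data is required anywhere: a phantom-generator module builds fully
synthetic head anatomy (skull shell, cortical GM ribbon, vessel trees, sulcal
sheets, deep ROI blobs) with *certified* vessel-free corridors, so the entire
pipeline is testable and reproducible from scratch.

## The method

Planning runs in three stages, for `N` requested electrodes:

**1. Candidate target selection.** For each ROI a target risk map is computed on
the voxel grid `C`:

    f(c) = 1                                     if c ∉ Ω_roi
         = 1                                     if c ∈ Ω_cri (arteries ∪ veins)
         = w_sp·f_sp(c) + w_cri·(1 − f_cri(c))   otherwise

where `f_cri` is the normalized distance to the union of vessels, and `f_sp` a
user-chosen spatial prior: the normalized skull distance (to favour the ROI's
medial/deep surface) or one minus the normalized ROI interior depth (to favour the
ROI centreline). Local minima of `f` are extracted by 26-connected regional-minima
flooding, clustered with K-means into one cluster per electrode sharing the ROI,
and the `M = 10` lowest-`f` points per cluster become the candidate targets
`T_{n,i}`.

**2. Trajectory risk scoring.** Entry points `E_{n,j}` are all skull-mesh vertices.
Each (target, entry) pair is screened against four hard constraints — length
≤ `d_len` (80 mm), angle to the skull normal ≤ `d_ang` (15°), traversal of the
superficial ROI when one is requested, and no intersection with arteries, veins or
sulci. If nothing survives, `d_len` and `d_ang` are relaxed in 10 mm / 10° lockstep
up to 110 mm / 45°. Survivors are scored by

    R = mean_x clamp((d_risk − d(x)) / (d_risk − d_safe), 0, 1)    (vessel risk)
    G = Σ_q (H[f_gm(p_q−p_r)] + H[f_gm(p_q)] + H[f_gm(p_q+p_r)]) / 3Q   (GM ratio)
    S = 10·R + G

with `d_safe = 3` mm, `d_risk = 10` mm, `d(x)` the raw vessel distance at 1 mm
sample points, and `Q = 10` contacts spaced 10 mm from the target (contact radius
`p_r = 1.2` mm). The factor 10 makes any risk difference dominate any GM difference.

**3. Implantation plan computation.** The plan `V(N)` minimises the mean `S`
subject to every pairwise trajectory distance exceeding `d_traj = 10` mm, solved by
depth-first search with branch-and-bound; after a conflict, candidates within
0.5 mm of the conflicting trajectory are skipped (diversity pruning). If no
feasible combination exists, a fallback returns the plan with the largest
achievable minimum separation, flagged infeasible.

## Worked example

```bash
python examples/04_full_plan.py
```

generates the default eight-electrode phantom and plans it end to end:

```
feasible: True   mean score S_total = 0.1125
minimum pairwise separation: 45.0 mm (constraint: > 10 mm)
  E1 (roi_centreline ) R=0.000 G=0.133 S=0.133 length= 41.6 mm angle=13.0 deg relax=0
  E2 (medial_surface ) R=0.000 G=0.100 S=0.100 length= 41.4 mm angle=14.1 deg relax=0
  ...
  E8 (medial_surface ) R=0.000 G=0.133 S=0.133 length= 40.3 mm angle=14.6 deg relax=0
```

Every electrode reached its ROI through a vessel-free corridor (`R = 0`), with a
drillable entry (≤ 15° to the skull normal, no relaxation needed) and 2–4 of its 30
contact probe points in grey matter; all pairwise separations far exceed the 10 mm
conflict threshold, so the plan is feasible. `examples/01–03` demonstrate the
phantom generator, target selection and trajectory scoring individually.

A thin CLI wraps the same pipeline for file-based use:

```bash
admtp phantom --out phantom_dir/
admtp plan --config cfg.yaml       # plan.json, plan.csv, candidate tables, timings
admtp score --trajectory traj.json # R/G/S of a single trajectory
```

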