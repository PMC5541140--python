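"""Candidate target selection for one ROI.

Builds the target risk map f(c) — a convex combination of a spatial prior
and the normalized vessel distance, hard-set to 1 outside the ROI and on
vessels — then extracts its local minima and ranks the best M = 10 as
candidate target points. Lower f means a deeper, better-separated, more
prior-consistent target.
"""

import numpy as np

from admtp import (ScalarField, candidate_targets_for_roi, compute_spatial_prior,
                   compute_target_risk_map, distance_field, generate_phantom)
from admtp.phantom import PhantomSpec

phantom = generate_phantom(PhantomSpec(grid_shape=(88, 88, 88),
                                       spacing=(2.0, 2.0, 2.0)))
grid = phantom.grid
label = 1
roi = phantom.parcellation.mask(label)
vessels = phantom.critical_vessels

raw = distance_field(vessels, grid, name="vessel_raw")
f_cri = ScalarField(raw.values / raw.values.max(), grid.affine, "f_cri")
f_sp = compute_spatial_prior("roi_centreline", roi, grid, skull=phantom.skull)
rmap = compute_target_risk_map(roi, label, vessels, f_cri, f_sp,
                               w_sp=0.25, w_cri=0.75)

(cands,) = candidate_targets_for_roi(["E1"], rmap, m=10)
print(f"ROI {label}: {len(cands)} candidate target(s), ranked by f ascending")
for t, f in zip(cands.targets, cands.f_values):
    print(f"  target at ({t[0]:7.2f}, {t[1]:7.2f}, {t[2]:7.2f}) mm  f={f:.4f}")
print("the top-ranked point is the lowest-risk target the prior allows;")
print("all candidates lie strictly inside the ROI and outside every vessel")
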