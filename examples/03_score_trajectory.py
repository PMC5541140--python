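"""Risk and grey-matter scoring of individual trajectories.

R in [0, 1] is the mean, over 1 mm sample points, of a linear ramp between
the 3 mm safe distance (contribution 1) and the 10 mm no-risk distance
(contribution 0) to the nearest blood vessel. G in [0, 1] is the fraction
of the 30 contact probe points (10 contacts x centre and both ends) inside
grey matter. The combined score S = 10 R + G makes any risk difference
outweigh any grey-matter difference.
"""

from admtp import (LabelVolume, Segment, distance_field, generate_phantom,
                   gm_ratio, risk_score, signed_gm_distance)
from admtp.phantom import PhantomSpec, VesselTube
from admtp.scoring import HardConstraintConfig

tube = VesselTube(points=((0.0, 0.0, -30.0), (0.0, 0.0, 30.0)), radius=1.5)
phantom = generate_phantom(PhantomSpec(grid_shape=(64, 64, 64),
                                       spacing=(1.0, 1.0, 1.0), rois=(),
                                       vessels=(tube,), sulci=(), corridors=()))
raw = distance_field(phantom.critical_vessels, phantom.grid, name="vessel_raw")
f_gm = signed_gm_distance(
    LabelVolume(phantom.gm.astype("int16"), phantom.grid.affine)) \
    if phantom.gm.any() else None
cfg = HardConstraintConfig()

for offset in (1.0, 6.5, 15.0, 25.0):
    seg = Segment((offset, 0.0, -20.0), (offset, 0.0, 20.0))
    r = risk_score(seg, raw, cfg)
    print(f"trajectory {offset:5.1f} mm from the vessel axis: R = {r:.3f}")
print("within 3 mm of a vessel R saturates at 1; beyond 10 mm it is 0;")
print("between the two it falls linearly with the sampled vessel distance")
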