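"""Full implantation planning on the default phantom.

Runs all three stages — candidate target selection, trajectory risk
scoring over every skull-vertex entry point, and the depth-first plan
search enforcing > 10 mm between every pair of electrodes — and prints
the resulting plan.
"""

from admtp import Electrode, PlanningInputs, RunConfig, generate_phantom, plan_inputs

phantom = generate_phantom()
electrodes = [Electrode(e["id"], e["deep_roi_label"],
                        e["superficial_roi_label"], e["prior"])
              for e in phantom.strategy]
inputs = PlanningInputs(phantom.parcellation, phantom.arteries, phantom.veins,
                        phantom.sulci, phantom.gm, phantom.skull, electrodes)

result = plan_inputs(inputs, RunConfig())
plan = result.plan

print(f"feasible: {plan.feasible}   mean score S_total = {plan.s_total:.4f}")
print(f"minimum pairwise separation: {plan.min_pairwise_distance:.1f} mm "
      "(constraint: > 10 mm)")
for e, tc in zip(result.electrodes, plan.trajectories):
    print(f"  {e.id} ({e.prior:15s}) R={tc.risk:.3f} G={tc.gm_ratio:.3f} "
          f"S={tc.score:.3f} length={tc.segment.length:5.1f} mm "
          f"angle={tc.entry_angle:4.1f} deg relax={tc.relax_level}")
for stage, secs in result.timings.items():
    print(f"{stage}: {secs:.2f}")
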