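"""Whole-foot minimum clearance for a simulated bout, stride by stride.

Runs the full pipeline — stance detection, dead reckoning, scan fusion with
the flat-foot correction, floor referencing — and prints each stride's
minimum foot clearance (mFC) next to the analytic value computed from the
generator's exact poses.
"""

import footclear as fc

cloud = fc.make_shoe_cloud()
params = fc.scenario_params("typical", seed=1, n_strides=8)
truth = fc.simulate_foot_poses(params, cloud)
rec = fc.synthesize_imu(truth, params)

bout = fc.analyze_bout(rec, cloud)
oracle = fc.oracle_clearance(truth, cloud)

print(f"floor offset applied: {bout.calibration.floor_offset * 1e3:.2f} mm")
print("stride   mFC (mm)   oracle (mm)   error (mm)")
for s in bout.strides:
    o = oracle[s.stride_id]
    print(
        f"{s.stride_id:>6}   {s.mfc_mm:8.2f}   {o.mfc * 1e3:11.2f}"
        f"   {(s.mfc - o.mfc) * 1e3:10.3f}"
    )
print("mFC is the lowest height of *any* shoe point above the floor during")
print("forward swing (heel-height peak to toe-height peak); sub-millimeter")
print("agreement with the oracle shows the pipeline recovers it correctly.")
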