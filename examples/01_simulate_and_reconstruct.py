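"""Simulate a short walking bout and reconstruct the sensor trajectory.

Generates ten strides of typical gait with mild sensor noise, runs stance
detection, stride segmentation and zero-velocity-aided dead reckoning, and
reports how far the reconstructed sensor path strays from the generator's
ground truth.
"""

import numpy as np

import footclear as fc

cloud = fc.make_shoe_cloud()
params = fc.scenario_params(
    "typical", seed=0, n_strides=10, accel_noise_sd=0.02, gyro_noise_sd=0.002
)
truth = fc.simulate_foot_poses(params, cloud)
rec = fc.synthesize_imu(truth, params)

mask = fc.smooth_zupt(fc.detect_zupt(rec))
seg = fc.segment_strides(mask)
pose = fc.reconstruct_pose(rec, mask)

err = pose.position - (truth.position - truth.position[0])
rms_mm = np.sqrt(np.mean(np.sum(err**2, axis=1))) * 1e3

print(f"samples: {len(rec)} at {rec.sample_rate:.0f} Hz")
print(f"strides segmented: {len(seg)} (generator produced {params.n_strides})")
print(f"position RMS error vs ground truth: {rms_mm:.2f} mm")
print("The RMS error is the 3D distance between the dead-reckoned sensor")
print("path and the true path; around a millimeter under sensor noise means")
print("the stance-anchored integration and per-stride corrections work.")
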