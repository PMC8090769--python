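"""Evaluate and rasterize the fronto-occipital template color gradient.

The shipped contrast is a sum of three Gaussians in MNI millimetre
coordinates (sigma = 50 mm): half-intensity red centred occipitally at
(0, -60, 70), full green at the prefrontal pole (0, 70, 0) and full blue
over sensorimotor cortex (0, 20, 70).
"""

import numpy as np

from spectremri import GradientSpec, evaluate_gradient, rasterize_gradient

spec = GradientSpec()

landmarks = {
    "occipital red centre (0,-60,70)": [0.0, -60.0, 70.0],
    "prefrontal green centre (0,70,0)": [0.0, 70.0, 0.0],
    "sensorimotor blue centre (0,20,70)": [0.0, 20.0, 70.0],
    "origin (0,0,0)": [0.0, 0.0, 0.0],
}
for name, r in landmarks.items():
    c = evaluate_gradient(spec, np.array(r))
    print(f"{name}: RGB = ({c[0]:.4f}, {c[1]:.4f}, {c[2]:.4f})")

# rasterize a coarse template volume (10 mm grid to keep the demo small)
shape = (19, 23, 19)
affine = np.diag([10.0, 10.0, 10.0, 1.0])
affine[:3, 3] = -(np.array(shape) - 1) * 10.0 / 2.0
cv = rasterize_gradient(spec, shape, affine)
print(f"\nrasterized template volume: shape {cv.data.shape}, "
      f"max per channel = {cv.data.reshape(-1, 3).max(axis=0).round(4)}")
print("each voxel's RGB says where that template position sits on the "
      "fronto-occipital axis; warped to a subject it becomes the contrast "
      "that streamlines aggregate.")
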