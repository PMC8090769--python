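"""Tensor-deflection tracking through a synthetic corridor phantom.

Builds a straight anisotropic corridor (FA ~ 0.8) in an isotropic
background, then emits a jittered bundle of TEND streamlines from the
corridor centre.
"""

import numpy as np

from spectremri import (
    PhantomSpec,
    TendModel,
    TrackingParams,
    make_tensor_phantom,
    seed_bundle,
)

spec = PhantomSpec()  # 16^3 grid, 2 mm voxels, corridor along +y
field = make_tensor_phantom(spec)
print(f"phantom: {spec.geometry} corridor, grid {spec.shape} at {spec.voxel_mm} mm")
print(f"corridor FA = {field.fa_volume().max():.3f}")

params = TrackingParams(step=1.0, noise=0.05, max_steps=60, seed=7)
bundle = seed_bundle(
    spec.center_mm, 100, TendModel(field), params, field.tracking_mask(),
    seed_sequence=np.random.SeedSequence(7), jitter_linear=spec.affine[:3, :3],
)
lengths = np.array([len(s) for s in bundle.streamlines])
spans = np.array([s.points[-1, 1] - s.points[0, 1] for s in bundle.streamlines])
print(f"\n{len(bundle)} streamlines, step = {params.step} mm, "
      f"noise factor s = {params.noise}")
print(f"points per streamline: mean {lengths.mean():.1f}, "
      f"min {lengths.min()}, max {lengths.max()}")
print(f"corridor span covered (y extent): mean {spans.mean():.1f} mm of "
      f"{spec.extent_mm[1]:.0f} mm")
print("every streamline marches in exact 1 mm steps both ways from its "
      "jittered seed until it leaves the corridor (low anisotropy or grid exit).")
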