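"""Declarative end-to-end run on disk: phantom inputs -> SPECTRE map.

Writes phantom tensors, a target-region mask and an identity deformation
field as NIfTI, then executes the color-field -> warp -> track -> map
pipeline from a single config mapping. Outputs (including a provenance
record with the config digest) land in a scratch directory.
"""

import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np

from spectremri import DeformationField, PhantomSpec, make_tensor_phantom, run_pipeline
from spectremri import io

work = Path(tempfile.mkdtemp(prefix="spectre_demo_"))
spec = PhantomSpec(shape=(12, 12, 12))
field = make_tensor_phantom(spec)
io.write_tensorfield(work / "tensors.nii.gz", field, work / "mask.nii.gz")
region = np.zeros(spec.shape, np.float32)
region[5:7, 5:7, 5:7] = 1
nib.save(nib.Nifti1Image(region, spec.affine), str(work / "region.nii.gz"))
io.write_deformation(work / "warp.nii.gz", DeformationField.identity(spec.shape, spec.affine))

config = {
    "tensors": str(work / "tensors.nii.gz"),
    "region_mask": str(work / "region.nii.gz"),
    "deformation": str(work / "warp.nii.gz"),
    "gradient": {"shape": [12, 12, 12], "sigma": 30.0},
    "template_resolution_mm": 2.0,
    "model": "tend",
    "n_seeds": 25,
    "tracking": {"noise": 0.05, "max_steps": 40},
    "seed": 42,
}
smap = run_pipeline(config, work / "out")
vals = smap.values_in_region()
print(f"outputs in {work / 'out'}:")
for p in sorted((work / "out").iterdir()):
    print(f"  {p.name}")
print(f"\nmap covers {vals.shape[0]} region voxels; "
      f"mean RGB = {vals.mean(axis=0).round(2)}")
print("re-running with the same config reproduces the map bit for bit "
      "(see provenance.json for the config digest and seed).")
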