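# spectremri

Track-weighted template-color mapping (SPECTRE) for diffusion MRI, with
test–retest reproducibility scoring and synthetic phantoms.

## The problem

Neurosurgeons planning deep-brain stimulation — typically in the
subthalamic nucleus (STN) — need to see, per voxel of a small target
region, *where in the brain* that voxel's fibre pathways travel, from
clinically feasible diffusion MRI. Explicit bundle segmentation is
ill-defined in the midbrain; SPECTRE sidesteps it by aggregating a smooth,
template-defined color contrast along streamlines.

## The method

A color field with channels c_k is defined in template (MNI) space as a
sum of three isotropic Gaussians,

    c(r) = Σ_{i=1..3} a_i · exp(−|r_i − r|² / (2σ²)),

with a₁ = [0.5, 0, 0] at r₁ = (0, −60, 70) (occipital red), a₂ = [0, 1, 0]
at r₂ = (0, 70, 0) (prefrontal green), a₃ = [0, 0, 1] at r₃ = (0, 20, 70)
(sensorimotor blue) and σ = 50 mm. The field is warped into subject space
through a dense deformation field. For each voxel r of the target region,
N streamlines (default 500) are propagated bidirectionally — by the
principal tensor direction (DTI) or tensor deflection (TEND,
v_out ∝ D·v_in) with a per-step direction perturbation of magnitude s —
with fixed step α = 1 mm, and the map is the un-normalized sum

    C_k(r) = Σ_{f=0..N−1} Σ_{n=1..L_f} c_k(x_n^{r,f}),

sampled by trilinear interpolation; longer streamlines contribute more.
The output grid may be finer than the acquisition grid (0.5/1 mm). For
display only, maps are divided by the 80th percentile of brightness over
the region and clipped to [0, 1].

Re-scan reproducibility of maps s_n^k (subject n, scan k) on a common grid
is scored by the intraclass-distance index

    icd = 100% · (1 − N Σ_n |s_n1 − s_n2|² / Σ_j Σ_n |s_j1 − s_n2|²),

which is 100% when within-subject re-scan maps coincide relative to
between-subject differences.

## Worked example

`python examples/rescan_icd.py` simulates a five-subject cohort of
straight-corridor phantoms (each subject an individually tilted corridor,
each scan pair differing by tensor noise), maps them with TEND at two
direction-noise levels and prints:

```
tracking noise s = 0.05: icd =  89.2 %  (intra 839 / inter 38977, 5 subjects)
tracking noise s =  0.2: icd =  54.2 %  (intra 22145 / inter 241826, 5 subjects)
```

The low-noise tracker's maps are far more reproducible (89% vs 54%): the
within-subject squared distance (`intra`) grows ~26-fold with the noisier
tracker while between-subject separation (`inter`) grows much less — the
same robustness ordering across trackers seen on clinical re-scan data.
Other examples cover the gradient itself (`color_gradient.py`), bundle
tracking (`track_phantom.py`), map construction with display normalization
(`spectre_map.py`) and the declarative on-disk pipeline
(`full_pipeline.py`).

A thin CLI mirrors the stages for shell use:
`spectre phantom | colorfield | track | spectre | icd | run`.

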