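# Methods

## Model and assumptions

SPECTRE is an instance of track-weighted imaging: the value of a target
voxel is obtained by seeding streamlines there and summing a foreign
contrast along them. Here the contrast is geometric — a smooth color field
defined in template space — so the map encodes, per voxel, the approximate
cortical destination of its pathways rather than any local tissue property.
The approach assumes (i) an anatomically plausible diffeomorphic mapping
between subject and template space is available from anatomical
registration (this package consumes its dense deformation-field output and
never computes registration itself), and (ii) the chosen coloring is smooth
at the scale of tracking uncertainty, so centimetre-level cortical errors
perturb colors only mildly.

The aggregation is deliberately un-normalized: a streamline of length L
contributes L samples, so long pathways dominate short ones. This implicit
tract-length weighting is part of the contrast (short aberrant streamlines
appear dark), and all quantitative comparisons operate on these raw sums.

## Coordinate and sampling conventions

World coordinates are millimetres in the right-handed space of each
volume's voxel-to-world affine; voxel centers sit at `affine @ index`,
indices 0-based. Grid axes must be orthogonal in world space (rotation ×
scale + translation); shears are rejected at load time. Trilinear
interpolation treats each volume as zero-padded: sample points outside the
grid fade to 0 through the boundary voxels (scipy `map_coordinates` with
`mode="grid-constant"`). Colors outside the head carry no connectivity
meaning, so 0 — not edge clamping — is the correct out-of-bounds value.
Deformation fields store, per subject voxel, the *absolute* template
coordinate in mm (not a displacement), matching the "sample template
content at this subject voxel" semantics and avoiding displacement-
convention ambiguity.

## Tracking

Two direction models are built in. DTI follows the leading eigenvector of
the trilinearly interpolated tensor, sign-aligned with the incoming
direction. TEND deflects the incoming direction by the tensor itself,
v_out = normalize(D·v_in), which degrades gracefully in oblate/crossing
regions. Either proposal is then perturbed as normalize(v + s·ε) with
ε ~ N(0, I₃); the noise factor s (default 0.05, studied range 0.05–0.2)
is the knob separating near-deterministic from probabilistic behaviour.
Externally computed peak/FOD fields plug in through the same
direction-model contract; FOD estimation itself is out of scope.

Propagation is bidirectional: the model's direction v₀ at the seed starts
one half along +v₀ and one along −v₀, and the halves are concatenated with
the seed interior (a bidirectional trace counts as one streamline in the
aggregation sum). Steps are exactly α = 1 mm. A half terminates on grid or
mask exit, interpolated FA below 0.10, turning angle above 60°, an
undefined direction (degenerate tensor at the seed), or 250 steps — the
step cap, angle threshold and FA floor are defaults chosen to match common
tractography practice and are all configurable. When the leading eigenpair
is tied within 1e-9 of the trace, the incoming direction is kept
(deterministic tie-break).

Seeds are jittered uniformly inside their output-grid voxel rather than
fixed at centers, which removes grid aliasing and is what makes output
grids finer than the acquisition grid ("super-resolution") meaningful.
Randomness is organised as one root seed with per-(region-voxel,
streamline-index) substreams (`SeedSequence([root, voxel_index])` spawned
per streamline); each streamline's jitter and per-step noise are drawn
from its own substream, so batched/vectorized execution is bit-identical
to sequential execution and independent of iteration order.

## Tensor fitting

The fit is the standard voxel-wise log-linear least squares of
log S = log S₀ − b gᵀDg, requiring at least six distinct non-zero-b
directions and one b≈0 volume. Negative eigenvalues are clamped to zero
(PSD projection); the validity mask keeps voxels with positive b0 signal.
No weighting or robust variants are provided — noiseless recovery is exact
to numerical precision, which is what the phantom tests exercise.

## Display normalization

Brightness is the per-voxel channel sum over the target region; maps are
divided by its 80th percentile (linear interpolation between order
statistics — the common "type 7" definition, fixed for reproducibility)
and clipped to [0, 1]. Display scaling is never applied before
quantitative analysis.

## Reproducibility index

The icd index keeps the j = n diagonal terms in the between-subject double
sum, exactly as defined; an exclusion variant exists behind a flag for
sensitivity analysis only. Channels are weighted equally and no intensity
normalization precedes the distance. For a single subject the index is 0
by construction; if all maps coincide the ratio is 0/0 and the
implementation reports 100% with a warning. The formula does not
algebraically confine the index to [0, 100]% for adversarial inputs;
negative values are reported as computed, never clamped. Voxels absent
(NaN) in any map of a set are dropped from the shared analysis mask
(complete-case comparison), since distances must compare identical
supports.

## Synthetic phantoms

The phantom module replaces scanner data with corridors of known geometry:
straight (optionally tilted in-plane), curved (quarter-circle,
tangent-aligned tensors) and crossing (averaged orthogonal corridors,
deliberately degenerate at the intersection to exercise the tie-break
path). Corridor tensors are prolate with axial/radial diffusivities
1.7/0.3 × 10⁻³ mm²/s (FA ≈ 0.80) in an isotropic 0.7 × 10⁻³ background;
grids default to 2 mm voxels, matching a clinical single-shell protocol,
with a finer research-grade mode available. The default corridor
half-width is 5 mm so that a 3³-voxel mid-corridor seed block plus
sub-voxel jitter stays strictly interior to the corridor: seeds on the
corridor edge measure voxelization jags rather than tracking behaviour,
which is not what the re-scan study is meant to expose (just as STN seeds
sit inside, not on the rim of, their pathway).

Re-scan pairs perturb the tensors directly (symmetric Gaussian
perturbation at a fraction of the mean diffusivity, PSD re-projected)
rather than simulating DWI noise, isolating tracking/aggregation
reproducibility from fitting noise; fitting is tested separately with
forward-simulated signals. The synthetic cohort gives each of 8 subjects
an individual corridor tilt (uniform ±15°) as its "anatomy", a shared
end-cap color field (green/blue caps at the corridor ends) and a shared
mid-corridor target region, with 60 seeds per voxel and a 60-step cap —
sizes chosen so the full two-noise-level study runs in about half a minute
on one core. These phantoms emulate geometry, anisotropy contrast and
session-to-session perturbation; they do not emulate susceptibility
distortion, partial-volume crossing complexity, Rician signal noise in
tracking, or registration error, so passing tests demonstrate algorithmic
correctness and the qualitative noise-robustness ordering, not clinical
performance levels.

## Numerical choices and degenerate inputs

Percentile definition as above; eigen-decompositions via `numpy.linalg.eigh`;
tensor interpolation is component-wise trilinear (smooth deflection), with
the FA floor evaluated on the interpolated tensor. Empty streamline bundles
aggregate to a zero vector with a warning; all-zero maps refuse display
normalization (undefined scale); a missing deformation field is an error —
an identity warp is never silently assumed. Absent (out-of-region) voxels
are NaN in float outputs and 0 in display exports.

## Known limitations

FOD/CSD estimation and global tractography are not implemented (plug-in
contract only), so tracker comparisons here span only the DTI/TEND/noise
axis. The Monte-Carlo scaling of map values follows √N exactly (the
variance of the per-seed mean halves when N doubles), but map *bias* from
systematic tracking errors does not shrink with N. Streamline length is
capped only by the step limit; whether a length cap should apply is left
to configuration.
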