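# Methods

`slicedwi` implements slice-level diffusion encoding: planning the
acquisition schedule, simulating what a scanner running such a schedule
would measure, and correcting the resulting data for motion and
susceptibility distortion. This note records the models, the defaults and
the design choices that were genuinely open.

## Slice parameterization and schedule planning

A 2-D multi-slice EPI diffusion acquisition with `Nd` encodings and `Ns`
slices per volume consists of `Nt = Nd x Ns` slice excitations. The global
(0-based) slice counter `t` determines the volume `v = floor(t/Ns) + 1`, the
within-volume counter `s = (t mod Ns) + 1` and the geometric location
`z = SAO(s)`, where the slice acquisition order SAO is either ascending
(`SAO(s) = s`) or odd-even (`[1, 3, 5, ..., 2, 4, 6, ...]`). The 0-based
convention for `t` (all other indices 1-based) is adopted because it is the
only convention under which the floor/modulo arithmetic yields `v = s = 1`
for the first excitation.

**Superblock & interleave.** The encoding list is split into superblocks of
`L` consecutive encodings; `L` must divide both `Ns` and `Nd`. Within
superblock `l` (local volumes `j = 0..L-1`), slice counter `i` (0-based)
receives local encoding

    e_loc = (i + j * (1 + f)) mod L,

i.e. the `L` encodings are laid out sequentially in time and the pattern
shifts by `1 + f` from volume to volume (`f = 0` is the default shift
factor). The rule is the minimal one with the required properties:
sequential layout, per-volume shift, and completeness — every slice location
sees all `L` encodings of its block after `L` volumes, which holds exactly
when `gcd(1 + f, L) = 1` (enforced). `L = 1` reduces to the conventional
one-volume-one-encoding scheme, and re-sorting any zero-motion superblock
acquisition by encoding reproduces the conventional volumes exactly (a unit
test asserts voxelwise equality).

**Spatial pattern classification.** For one volume, the slices sharing an
encoding sit at counters `s = d, d+L, ...`; their sorted geometric locations
are classified by their gaps: any gap of 1 (back-to-back neighbours) is
`suboptimal`; all gaps equal is `optimal`; anything else `non_uniform`. The
back-to-back test deliberately precedes the equal-gap test so that a pair of
adjacent slices is not called "uniformly spread". Under odd-even ordering an
optimal pattern only exists for odd `Ns` (verified exhaustively for
`Ns = 4..40`).

**Low-b sampling statistics.** With exactly one low-b encoding per
superblock the interleave spaces low-b excitations uniformly at
`L * TR / Ns` seconds; the count per breathing cycle is the cycle length
divided by this spacing, rounded half-up (12.5 rounds to 13). Low-b means
`b <= low_b_threshold`, default 0 s/mm² and configurable.

## Digital phantom and forward model

The phantom is a nested-ellipsoid "brain" on a rectilinear grid (default
2.2 mm isotropic): an isotropic interior (MD 1.0e-3 mm²/s), a central
high-diffusivity ventricle (2.5e-3 mm²/s, long T2), an anisotropic rim with
radially oriented principal eigenvector and eigenvalues (1.8, 0.6, 0.6)e-3
(FA ≈ 0.60), and three anisotropic tracts (cylinders along x, y, z). A
smooth multiplicative texture (Gaussian-filtered noise, 25 % amplitude) on
the proton density provides registration contrast. All structure is
deterministic given the seed.

Signals follow the monoexponential Stejskal–Tanner tensor model
`S = S0 exp(-TE/T2) exp(-b g^T D g)`. Echo times default to 107 ms (echo 1)
and 208 ms (echo 2). Motion is applied as a world-coordinate rigid
transform of the object before slicing (rotations about the volume centre,
trilinear resampling); rotations also reorient the tensor field, handled by
back-rotating the gradient direction. Susceptibility distortion is applied
per slice, 1-D along the phase-encoding axis: signal at true position `y`
appears at `y + s(y)` with `s = pe_sign * field_Hz / bandwidth` pixels, with
Jacobian intensity modulation (stretching dims, pile-up brightens; total
intensity conserved to < 1 % for fields vanishing at the edges). Resampling
of the warp uses cubic splines; through-plane field variation is ignored.
Echo 2 is acquired with reversed polarity, giving equal-opposite
distortions. Noise is additive Gaussian with standard deviation relative to
the mean in-mask b=0 intensity — the simulations target displacement
recovery, not magnitude-bias studies, so a Rician floor is deliberately
omitted. The default noise level for the breathing study is 2 %.

What the phantom does *not* emulate: EPI readout physics (k-space,
ghosting), coil sensitivities, eddy currents, T1 saturation, through-plane
field gradients, and — most importantly — the anatomical richness of a real
fetal brain. Registration against a real, structured b=0 volume is easier
than against a smooth ellipsoid, so passing error bounds here supports but
does not prove performance on real data; conversely the spatial-pattern,
completeness, adjoint and interpolation properties are exact and transfer
directly.

## Motion correction

**Masking and weights.** The brain mask is an Otsu threshold followed by
the largest 26-connected component and a radius-1 median filter
(constant-padded: reflect padding would double the boundary layer and leak
the mask into empty edge slices). Each slice's weight is its in-mask voxel
fraction; below 1 % the slice is an outlier with weight zero.

**Slice-to-volume registration.** Rigid 6-DOF (translations in mm, extrinsic
xyz Euler angles about the volume centre), minimizing the mean squared
intensity difference between the slice and the target resampled at the
moved slice plane; Powell's derivative-free method over a two-level
multi-resolution schedule (stride-2 subsampled pixels against a
sigma-1-voxel smoothed target, then full resolution). Two guards make the
estimator robust on weakly structured slices: the result is only accepted
if it lowers the full-resolution cost relative to the initialization, and a
result that halves the slice's overlap with the brain mask (an escape into
empty background) is reverted. Interpolation snaps coordinates within 1e-6
voxel of the volume faces onto them, because the resampler otherwise zeroes
samples that are one float-rounding step outside the grid — without this the
geometric edge slices evaluate as empty at their true pose.

**SVR bootstrap.** Registration of the low-b stream is coarse-to-fine in
*temporal extent*: low-b slices are grouped per volume and each group
registered as one rigid body against the voxelwise median of the
per-superblock assembled b=0 volumes; groups of a quarter volume follow;
finally each slice is refined individually (default 3 per-slice passes).
Between stages the target is rebuilt by scattered-slice least-squares
reconstruction from the current poses (delta slice profile and few CG
iterations inside the loop; Gaussian profile for the final returned
target). Voxels observed by no weighted slice are filled by the
regularizer; they are excluded from the mask so that invented content never
validates empty slices.

**Temporal regularization.** After each per-slice pass the pose estimates
are averaged over temporal neighbours within ±0.3 s (Gaussian weights,
sigma 0.15 s, in the se(3) log space; outliers excluded). This choice
exploits the central property of the interleaved acquisition: temporally
adjacent low-b slices lie at spatially distant locations, while
physiological motion is smooth on the sub-second scale. The averaging damps
independent registration noise and, critically, breaks the per-location
shear mode — a per-slice registration against a target reconstructed from
the same poses cannot distinguish a consistent per-location offset from
anatomy, and without cross-location coupling that bias is a fixed point of
the registration/reconstruction iteration. For the 5-s breathing period the
±0.3 s window attenuates the true sine by < 2 % at the densest sampling;
at sparse sampling (spacing > 0.3 s) the window contains only the slice
itself and the step is a no-op.

**Pose interpolation.** High-b slices receive
`R(tau) = exp(tau log R1 + (1 - tau) log R0)` between the two temporally
closest non-outlier low-b poses, evaluated with closed-form Rodrigues
log/exp on SE(3) (principal branch, rotations < 180°). Slices before the
first or after the last usable anchor are clamped to it — extrapolation of a
twist is unstable and the clamp is conservative. Weights beyond the binary
outlier gate are not used in the interpolation; only neighbour selection
respects them.

**Error metric.** The estimated transforms map slices into anatomical
space, i.e. they undo the object motion, so they are compared against the
negated simulated translations; the mean absolute deviation along the
breathing axis over all non-excluded slices (low- and high-b) is reported.

## Dynamic distortion correction

Sliding windows centred on every volume gather the temporally closest low-b
slices covering all locations (window size `L`, so the farthest member is
`floor(L/2)` volumes away; edge windows clip forward/backward). Each
window's opposed-polarity echo pair feeds a field estimator that recovers
the per-voxel half-shift `u` (pixels) minimizing
`sum |I1(y+u) - I2(y-u)|^2 + lambda ||grad u||^2`, by an exhaustive coarse
search along PE (half-pixel steps) followed by Gauss–Newton steps over a
smoothing pyramid (sigma 2, 1, 0.5 voxels), each linearized step solved with
sparse CG. Defaults: `lambda = 0.1 * scale^2` per px² with `scale` the 99th
percentile of echo 1; a zero-shift prior of `0.05 * scale^2` anchors the
background two voxels outside the mask (inside the object the field is
interpolated from edges by the smoothness term); shifts are capped at
±4 px. The field is returned in Hz as `u * pixel_bandwidth`; displacement
in mm is `field / bandwidth * voxel_size` along PE.

The two echoes differ in TE and hence tissue contrast. When the global
intensity ratio (a distortion-invariant statistic, since the PE warp
conserves total intensity) departs from unity by more than 20 %, both
volumes are divided by their own local mean (sigma 3 voxels) before
matching. This cancels the slowly varying contrast difference while
preserving edge geometry. A residual contrast-bias floor of roughly
0.08 px rms remains on truly field-free pairs; correcting with such a map
costs a few points of echo-to-echo correlation, which bounds how closely
"zero field in, zero field out" can hold. The dynamic-versus-static
comparisons are unaffected because both arms share the estimator.

Per-slice correction picks the temporally closest field map (ties to the
earlier one; a window's timestamp is the acquisition time of its centre
volume's middle slice) and inverts that slice's polarity with Jacobian
modulation; estimated warps are kept invertible by enforcing a minimum
slope of 0.1 on the warp. Quality is scored by the Pearson correlation of
the two corrected echoes over the brain mask (scale-invariant, so no echo
rescaling is needed).

## Reconstruction

The forward model samples the rigidly moved volume at each slice plane
through a Gaussian slice profile (FWHM = slice thickness, 3 taps spanning
±1.2 sigma; a delta profile is available). Sampling and its adjoint use an
exactly matched trilinear gather/scatter pair, so the normal operator is
symmetric and conjugate gradient on
`sum_t w_t ||P_t x - y_t||^2 + lambda ||grad x||^2` decreases its objective
monotonically (asserted per iteration in tests). Weights are normalized to
unit mean so `lambda` (default 0.01; both terms are quadratic in intensity)
keeps a consistent meaning regardless of the absolute weight scale.
Per-shell 4-D reconstruction couples the same spatial operator with the
real, even, orthonormal spherical-harmonic basis (default order 4, 15
coefficients) evaluated at each slice's *reoriented* gradient direction
(rotation block applied to the b-vector); a shell must offer at least as
many distinct reoriented directions (up to antipodal symmetry) as
coefficients. Reconstruction onto grids finer than the acquisition
(super-resolution) is not implemented; the target grid matches the
acquired one.

## The breathing study

The study grid is fixed by its design: 50 volumes, 4 mm / 5 s sinusoidal
y-translation sampled at every slice time, 30 slices (brain filling the
slab) with superblock lengths {2, 3, 5, 6} and 40 slices (brain occupying
30/40 of the slab) with {2, 4, 5, 8}, each at four repetition times —
32 configurations. The default TR set is {3, 6, 9, 12} s, the set for which
reference per-cycle counts and errors exist; {3, 6, 12, 15} s is supported
as a variant. The in-plane grid is 32 x 32 at 2.2 mm (a desk-scale stand-in
for the original reconstructed fetal volume, which is not public), the
scheme per superblock is one b=0 plus L-1 b=1000 directions, noise is 2 %,
and the pipeline runs with 3 per-slice SVR passes. Because the phantom is
smoother than a real brain and the grid small, the resulting mean errors
are treated as upper-bound comparisons against the reference values rather
than equalities.

## Numerical details and limitations

- Rigid transforms are validated (orthonormal rotation block to 1e-8,
  affine last row); se(3) log/exp uses closed-form Rodrigues formulas with
  an SVD re-orthonormalization of the exponential, and refuses rotations at
  or beyond 180°.
- The CG solvers stop at a relative residual of 1e-6 or an iteration cap;
  the SVR loop deliberately uses few CG iterations for intermediate targets.
- World coordinates are RAS+ millimetres with the origin at the volume
  centre; PE is anatomical y; geometric slice locations are reported
  1-based.
- All randomness flows from explicit integer seeds; the phantom, schedules
  and simulations are bit-reproducible given the seed.
- The schedule planner does not model multiband grouping, vendor export
  formats, or pseudo-random (non-interleaved) encoding orders; the
  estimator does not model eddy currents or through-plane field effects.
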