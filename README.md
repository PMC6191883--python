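# slicedwi

Slice-level diffusion encoding for motion- and distortion-robust diffusion
MRI — schedule planning, acquisition simulation, and the matching slice-wise
correction pipeline.

Conventional diffusion MRI follows a *one volume, one encoding* layout: all
`Ns` slices of a volume share one diffusion weighting, so the anatomically
reliable b=0 slices that drive motion and distortion correction arrive in
rare bursts (once per `Nd` volumes). Single-shot EPI is, however, a planar
acquisition — nothing forces the encoding to be constant within a volume.
`slicedwi` plans **superblock & interleave** schedules in which every group
of `L` volumes interleaves `L` encodings so that each slice location sees
all of them, turning the b=0 stream into a dense, uniform sampling of the
motion trajectory (one low-b slice every `L·TR/Ns` seconds). Combined with
a double spin echo whose second echo reverses the phase-encoding polarity,
every time point also yields an opposed-distortion image pair for dynamic
field mapping. The package targets applications such as fetal and
abdominal imaging where breathing motion and time-varying susceptibility
fields defeat static corrections.

The package provides:

- `slicedwi.schedule` — slice indexing `(t, d, v, s, z, l)` with
  `v = ⌊t/Ns⌋+1`, `s = t mod Ns + 1`, `z = SAO(s)`; the interleave rule
  `d = (l−1)L + (i + j(1+f)) mod L + 1`; spatial-pattern classification
  (optimal / non-uniform / suboptimal); low-b sampling statistics; TSV and
  FSL bvals/bvecs serialization.
- `slicedwi.phantom` — a digital tensor phantom and the forward model:
  Stejskal–Tanner signals `S = S0 e^{−TE/T2} e^{−b gᵀDg}`, rigid motion,
  per-slice PE displacement with Jacobian modulation, double-echo opposed
  polarity, Gaussian noise; full ground truth retained.
- `slicedwi.motion` — brain masking, in-mask slice weights with a 1 %
  outlier gate, slice-to-volume registration with a coarse-to-fine
  (volume → group → slice) bootstrap, and SE(3) pose interpolation
  `R(τ) = exp(τ log R1 + (1−τ) log R0)` onto the high-b slices.
- `slicedwi.distortion` — sliding-window b=0 assembly (window = `L`
  volumes), opposed-echo field estimation (symmetric 1-D shift matching
  with smoothness regularization), per-slice correction with the temporally
  closest map, and the echo-to-echo correlation quality metric.
- `slicedwi.recon` — scattered-slice least-squares reconstruction
  (conjugate gradient, exact adjoint pair, Gaussian slice profile) and
  per-shell spherical-harmonics fitting with gradient reorientation.
- `slicedwi.experiments` — the breathing simulation grid (32
  configurations) and the dynamic-versus-static field-mapping comparison.

## Worked example

Plan the dense-interleave schedule used throughout the breathing study
(30 slices, TR 3 s, 50 encodings in 25 superblocks of one b=0 plus one
b=1000 direction) and inspect its low-b sampling:

```python
from slicedwi.schedule import (AcquisitionGeometry, build_schedule,
                               low_b_sampling_stats, make_superblock_scheme)

geometry = AcquisitionGeometry(n_slices=30, tr=3.0)
scheme = make_superblock_scheme(n_superblocks=25, L=2)
schedule = build_schedule(scheme, geometry, L=2)
spacing, per_cycle = low_b_sampling_stats(schedule, cycle_length_s=5.0)
print(f"low-b spacing {spacing:.1f} s, {per_cycle} samples per 5 s cycle")
```

```
low-b spacing 0.2 s, 25 samples per 5 s cycle
```

A conventional scan with the same geometry sees one b=0 volume every 50
volumes; the interleave samples the breathing cycle 25 times per period.
Running one cell of the breathing study end to end — phantom, sinusoidal
4 mm / 5 s motion, acquisition, low-b slice-to-volume registration, pose
interpolation, error against the known motion —

```python
from slicedwi.experiments import BreathingConfig, run_breathing_experiment

row = run_breathing_experiment(BreathingConfig(n_slices=30, L=2, tr=3.0),
                               seed=1)
print(row)
```

```
{'Ns': 30, 'L': 2, 'TR': 3.0, 'spacing_s': 0.2, 'pc': 25,
 'mean_error_mm': 0.117}
```

i.e. with 25 low-b samples per breathing cycle the pipeline recovers the
4 mm breathing translation with a mean error of ≈ 0.12 mm per slice (a few
minutes on one CPU; errors grow as TR stretches the low-b spacing — run the
same config at TR 6/9/12 s to see the sampling-density dependence).

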