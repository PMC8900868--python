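# tomocor

Center-of-rotation (COR) estimation for single-tilt-axis tomography.

In parallel-beam tomography every reconstruction assumes you know which
detector column the rotation axis projects onto.  Get it wrong by a pixel
and slices grow tuning-fork artifacts (180° scans) or rings (360° scans).
`tomocor` is for synchrotron/micro-CT users and algorithm developers who
need that column fast, from as little as two projections, at photon doses
where correlation-based registration falls apart — e.g. dose-fractionated
scans with a handful of photons per pixel per projection.

## The estimator

A *reflection pair* is two projections taken (approximately) 180° apart.
Summed without any mirroring, the pair is even-symmetric about the rotation
axis: each object point samples opposite ends of its sinusoidal trajectory.
If the axis sits `t'` pixels away from the detector-array center
`(N_t − 1)/2`, that even center is displaced by `t'`, and by the Fourier
shift theorem the displacement shows up as a phase ramp.  The phase is read
at the lowest non-zero spatial frequency — where object power dominates
Poisson noise — of a single 1-D FFT of the summed pair:

```
phi = arctan(I / R)            R, I: real/imag parts at f_min
t'  = −phi · N_t / (2π k)      k: one cycle per detector row
```

Using the principal branch of `arctan` makes the estimate independent of
contrast polarity (transmission vs emission) and of any gain or offset; the
price is a capture range of `|t'| < N_t/4`.

The package also ships the two standard references it is benchmarked
against — sub-pixel phase correlation of the mirrored pair (upsampled-DFT
refinement, `m = 10`) and the mirrored-sinogram double-wedge Fourier
method — plus a two-image correlation SNR estimator
(`SNR = sqrt(r/(1−r))`), an analytic ellipse/ellipsoid phantom simulator
with Poisson noise, dose-budget bookkeeping, and a filtered-backprojection
diagnostic.

## Worked example

```python
import numpy as np
from tomocor import (NoiseSpec, find_center_phase_symmetry,
                     find_center_phase_correlation, make_reflection_pair,
                     shepp_logan_2d)

# Low-contrast head phantom, 256 detector columns, axis displaced +5.3 px
spec = shepp_logan_2d(grid=256, cor_offset=5.3, fill=0.8)

est = find_center_phase_symmetry(make_reflection_pair(spec))
print(f"noiseless: t' = {est.t_prime:+.4f} px")

ps, pc = [], []
for seed in range(100):
    noisy = make_reflection_pair(spec, noise=NoiseSpec(fluence=30_000.0, seed=seed))
    ps.append(find_center_phase_symmetry(noisy).t_prime)
    pc.append(find_center_phase_correlation(noisy).t_prime)
print(f"phase symmetry:    t' = {np.mean(ps):+.2f} +/- {np.std(ps):.2f} px")
print(f"phase correlation: t' = {np.mean(pc):+.2f} +/- {np.std(pc):.2f} px")
```

prints

```
noiseless: t' = +5.2980 px
phase symmetry:    t' = +5.47 +/- 1.89 px
phase correlation: t' = -0.31 +/- 36.63 px
```

Noiseless, the phase-symmetry estimate lands within 0.002 px of the
injected offset.  At a fluence of 30 000 photons/pixel the projection SNR
of this faint phantom is about 1; phase symmetry still scatters by under
2 px around the truth while phase correlation's peak-picking fails
outright — the robustness gap the estimator exists for.

## Command line

```bash
tomocor simulate --phantom shepp2d --cor-offset 4 --n-t 256 --out sim.h5
tomocor find-center --method ps --pair 0,180 --hdf5 sim.h5
tomocor sweep-snr --n-seeds 25 --out sweep.csv
tomocor dose-fractionation --total-fluence 300000 --out dose.csv
tomocor reconstruct --hdf5 sim.h5 --out slice.tif
```

`find-center` also reads TomoBank-style data-exchange HDF5 (with flat/dark
normalization) and TIFF stacks; `--method pc` and `--method vo` select the
reference estimators.

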