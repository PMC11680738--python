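# ztefill

Dead-time-gap infilling for zero-echo-time (ZTE) radial MRI.

ZTE sequences excite the spins while the readout gradients are already on
and sample the free induction decay along center-out radial spokes. The RF
pulse plus transmit/receive switching impose a dead time `Δt_d` during
which nothing can be acquired, so the first `ceil(r·g)` samples of every
spoke are missing (`g = Δt_d/dt` in nominal Nyquist dwells, `r` the readout
oversampling factor) — including the k-space origin. Left zero-filled,
this is a convolution of the image with a sinc-like kernel: strong
amplitude modulation and loss of contrast. The package is for
reconstruction researchers who want to simulate this regime end to end and
compare gap-recovery algorithms under controlled gap sizes and noise
levels.

It provides, behind one common radial k-space container:

* **Simulation** — 2D uniform and 3D phyllotaxis center-out trajectories
  with diametric spoke pairing, synthetic phantoms, smooth multi-coil
  sensitivities, a gridding NUFFT forward model, and complex Gaussian
  noise calibrated to a target SNR
  `SNR(dB) = 10·log₁₀(Σ|x|² / Σ|Fᴴn|²)`.
* **Five gap-infilling methods**
  * *algebraic* — per spoke-pair least squares minimizing the signal
    outside the nominal FOV band that 2× readout oversampling provides;
  * *Stoch–Olejniczak* — single-spoke variant minimizing only the real
    out-of-band signal;
  * *ZINFANDEL* — GRAPPA-style 1D kernel calibrated near the gap on the
    five nearest spokes, extrapolating inward one dwell at a time;
  * *CG SENSE* — iterative sensitivity-encoded reconstruction
    `min_x ‖DFSx − y‖²_W + λ‖x‖²` with the gap excluded, resampled back
    onto the gap coordinates;
  * *structured low-rank iterative infilling* — the centerpiece: regrid
    the innermost spoke fraction onto a small Cartesian center volume,
    lift it into a block-Hankel (C-matrix) form with coils concatenated
    along the kernel axis, threshold its singular values (hard, at 1.5% of
    the leading value), and alternate with data-consistency projections
    until the relative k-space change falls below 1e-6. The finite spatial
    support of the object guarantees annihilating filters in k-space,
    hence the low rank of the lifted matrix.
* **Evaluation** — squared-error metrics on magnitude images, Monte Carlo
  sweeps over gap × SNR × realization with bit-reproducible seeding, and
  convergence diagnostics.

## Worked example

Simulate the two-disc reference phantom (256², 402 paired spokes, 4
coils), knock out a two-dwell dead-time gap, and repair it:

```python
import numpy as np
import ztefill as z
from ztefill.evaluation import gap_sample_error, reconstruct_magnitude, squared_error

truth = z.make_disc_phantom(256, outer_radius=80, inner_radius=40)
traj  = z.make_uniform_spokes_2d(402, n_readout=256, oversampling=2)
maps  = z.make_coil_maps(truth.shape, n_coils=4, seed=0)
ksp   = z.simulate_kspace(truth, maps, traj)

gap    = z.DeadTimeGap(2.0)               # 4 missing samples on the 2x grid
gapped = z.apply_gap(ksp, traj, gap)

filled, trace = z.lowrank_infill(gapped, traj, gap, z.LowRankConfig())
err_gap = gap_sample_error(filled, ksp, traj, gap)

mag_zf = reconstruct_magnitude(gapped, traj, maps)
mag_lr = reconstruct_magnitude(filled, traj, maps)
t      = np.abs(truth.values)
print(f"iterations           : {trace.n_iter} (converged={trace.converged})")
print(f"gap-sample error     : {100*err_gap:.2f} %")
print(f"squared error zero-filled: {squared_error(t, mag_zf):.1f}")
print(f"squared error low-rank   : {squared_error(t, mag_lr):.1f}")
```

Output:

```
iterations           : 260 (converged=True)
gap-sample error     : 0.39 %
squared error zero-filled: 6513.9
squared error low-rank   : 18.5
```

The low-rank loop converges in 260 sweeps, restores the four missing
k-space samples per spoke to within 0.39% of the ground truth, and cuts
the image-domain squared error by a factor of ~350 relative to the
zero-filled baseline (the residual is dominated by the unsampled k-space
corners, which are common to all methods).

The same pipeline is scriptable from the shell:

```bash
ztefill simulate --dim 2 --grid 64 --n-coils 4 --seed 1 --out sim.h5
ztefill infill --input sim.h5 --method lowrank --gap 2.0 --out filled.h5 --recon-out recon.nii
ztefill sweep --dim 2 --grid 64 --gaps 1,2,3 --snrs-db 10 --n-realizations 5 --seed 1 --out sweep.csv
```

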