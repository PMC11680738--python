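# Methods

## The problem

Zero-echo-time (ZTE) MRI excites the spins while the readout gradients are
already on, and acquires the free induction decay along center-out radial
spokes. The RF pulse duration plus transmit/receive switching impose a dead
time during which no samples can be taken, so the first few samples of
every spoke — the lowest spatial frequencies, including the k-space origin
— are missing. Zero-filling this gap is equivalent to convolving the image
with a sinc-like kernel: broad amplitude modulations and a marked loss of
contrast. The gap is measured in nominal Nyquist dwells `g = Δt_d / dt`;
with `r`-fold readout oversampling the per-spoke sample cost is
`ceil(r·g)`, counting a sample that falls exactly on the gap boundary as
acquired (this rule reproduces both printed count pairs 3↔5 and 5↔9).

This package simulates multi-coil ZTE acquisitions of synthetic phantoms
and fills the gap with five methods — algebraic, Stoch–Olejniczak,
ZINFANDEL, CG SENSE, and structured low-rank iterative infilling — then
compares them through one shared reconstruction pipeline so that
differences isolate the Fourier coefficients inside the gap.

## Conventions

k-space coordinates are in cycles/FOV; one unit is the nominal Nyquist
step `Δk = 1/FOV`. Sample `m` of a spoke sits at `(m/r)·Δk` along its unit
direction; sample 0 is the origin. An image grid of `N` voxels puts the
k-space origin at index `N//2` after an FFT shift; every module shares this
convention. Radial data is stored `(spoke, readout sample, coil)` with an
acquisition mask and a `synthesized` flag that marks method-filled samples.

## Non-uniform Fourier transform

No NUFFT library is used; the transform is classic Kaiser–Bessel gridding:
deapodization, zero-padding onto a 2× oversampled Cartesian grid, FFT, and
separable interpolation with a Kaiser–Bessel kernel using Beatty's shape
parameter. Forward and adjoint share one precomputed interpolation table,
so they are exact transposes (the adjoint test holds to ~1e-16) while the
approximation error against the exact non-uniform DFT is set by the kernel
width: default width 6 in 1D/2D (~1e-6 relative), 5 in 3D (~1e-5), and 12
for 1D plans where the extra accuracy is free. The normal operator
`A^H W A` is applied through its Toeplitz embedding — two FFTs on a doubled
grid — which is both faster than chaining two gridding transforms and
closer to the exact discrete model.

Inverse gridding (`cg_nufft_inverse`) runs conjugate gradients on the
density-weighted normal equations `(A^H W A) x = A^H W y` with radial
density weights `w ∝ max(|k|, k_min/2)^{d−1}`. The weights act as a
preconditioner — for consistent data the solution is unchanged — and are
what make 10 iterations sufficient; unweighted CG on a radial system
stagnates far from the solution at that budget. A hard-edged object whose
spectrum extends into the un-sampled corner region of k-space (radius
beyond `k_max`) retains an irreducible error that no iteration count
removes; consistency experiments therefore use smooth test images.

## Center-volume regridding

Only the innermost `spoke_fraction` of each spoke (default 20%) feeds the
low-resolution Cartesian center volume: `n_keep = round(f·n_readout)`
samples covering radius `ρ = (n_keep−1)/r` dwells. The cube of side `c`
covers exactly that radius with spacing `2ρ/c`. By default `c = 2·floor(ρ)`
so the spacing is about one nominal dwell — the proportion of the reference
26³ cube — and an explicit `c` is validated against the over-resolution
bound `c ≤ 2ρ + 1`. A coarser cube (spacing up to two dwells) is legitimate
whenever the object occupies at most half the field of view, and is what
the scaled-down 3D runs use. Regridding inverts the truncated data with the
10-iteration CG-NUFFT per coil and takes the centered FFT of the low-res
image, i.e. consistent Cartesian Fourier coefficients rather than raw
kernel accumulation; degridding evaluates the cube's trigonometric
interpolant back at the radial coordinates.

## The five infilling methods

**Algebraic.** With 2× readout oversampling, a diametric spoke pair forms a
single line of `L = 2·n_readout − 1` uniformly spaced samples (the shared
origin counted once), whose inverse DFT is a 1D profile over twice the
nominal FOV. The object occupies only the central band, so the gap entries
(the `2·ceil(r·g) − 1` unknowns `|u| < r·g`) are chosen to minimize the
out-of-band energy — a small dense least-squares problem solved once per
geometry and applied to every pair line and coil. Tikhonov (relative
λ = 1e-12 by default) or truncated SVD guards the deep-gap regime, where
the system's condition number grows rapidly; an unregularized singular
system raises instead of returning garbage.

**Stoch–Olejniczak.** The same finite-support idea using only a single
spoke: the half-line is embedded in a full line with zero negative half, so
the real part of its profile equals the profile of the Hermitian-symmetrized
line, and only the real out-of-band signal is minimized (over the complex
gap entries, as a real least-squares problem). Two details matter. The
origin enters the symmetrization at half weight, so its column is scaled by
1/2 — without that, DC is double-counted and the out-of-band real signal
cannot vanish even at the true solution. And each line is first rotated to
a canonical zero-order phase and rotated back afterwards, which makes the
whole algorithm exactly equivariant under a global phase of the data — the
phase robustness this method is chosen for. The phase is estimated as
`½·arg(Σ y_m²)` over the first eight acquired samples: squaring removes
the sign flips of oscillating radial profiles (jinc side lobes), which
would put a single-sample phase anchor 180° off whenever a zero crossing
falls near the gap. The imaginary part of DC is invisible to a real-part
objective (its column is exactly zero); regularization resolves it to the
minimum-norm value, which is the correct answer for a real object.

**ZINFANDEL.** A GRAPPA-style 1D kernel (5 taps across all coils, default)
is calibrated by least squares on the first 16 acquired readout samples of
the target spoke's five nearest angular neighbors, then used to extrapolate
the gap inward one dwell at a time, recalibrating per missing position;
previously synthesized samples serve as sources for deeper positions
(a non-recursive variant trains a longer-range kernel per depth instead).
Calibration is Tikhonov-regularized (relative 1e-6) and warns when
underdetermined. Because every center-out spoke samples the identical
k-space origin, the per-spoke DC predictions are averaged into one
consistent value at the end — an exact trajectory constraint that roughly
halves the gap error.

**CG SENSE.** The sensitivity-encoded least-squares problem
`min_x ‖D F S x − y‖²_W + λ‖x‖²` is solved by CG on its normal equations,
with the gap excluded by `D`, radial density weights `W`, and the
simulation's ground-truth coil maps (map estimation is out of scope). The
method fills the gap implicitly in image space; to compare on gap
coefficients the induced explicit fill re-evaluates `F(S_c x̂)` at the gap
coordinates, leaving acquired samples bit-identical. Defaults: λ = 0,
30 iterations with early stop at relative residual 1e-6.

**Structured low-rank (the method of interest).** An image with finite
spatial support admits annihilating filters: a band-limited k-space filter
whose convolution with the data vanishes. Stacking every w-isotropic
k-space patch of the center volume as a row — coils concatenated along the
column axis, the support-based C-matrix without phase-constrained rows —
yields a matrix with a non-trivial numerical null space, hence low rank.
The gap is recovered by alternating projections:

1. *Data consistency:* per coil, `cg_iters` (default 10) CG-NUFFT steps
   pull the center-volume image toward the acquired truncated samples
   (the gap carries no measurements, so its weight is zero and the
   normal-equation right-hand side is fixed — computed once). Each sweep's
   CG warm-starts from the previous sweep's low-rank projection, so the
   inverse keeps refining as the loop proceeds.
2. *Low-rank projection:* lift the multi-coil cube, threshold the singular
   values (hard mode by default, cutoff 1.5% of the current iterate's
   largest singular value; soft mode available), un-lift with the
   count-normalized adjoint.
3. Degrid the projected cube at the gap coordinates and keep synthesized
   values only there; stop when the relative Euclidean k-space change
   drops below `tol` (default 1e-6) or at `max_iter` (non-convergence is
   flagged on the returned trace, not raised).

Gap samples start at zero. Iterations to convergence grow steeply with gap
depth — the unacquired center lies in an increasingly stiff subspace of
the regridding inverse — and the method degrades once the gap radius
exceeds roughly a quarter of the covered center radius, which is why
scaled-down experiments must preserve the gap-to-coverage proportion of
the full-size geometry rather than the spoke fraction itself.

The interpretation of "transform back to non-Cartesian space" as NUFFT
evaluation of the cube's low-resolution image, and the choice to exclude
the gap from the regrid data term (zeros are the absence of measurements,
not measurements of zero), are the two main interpretive decisions; the
alternative of feeding the zero-filled gap in as data makes the zero-filled
state a near-fixed point and the loop stalls.

## Phantoms, coils, and noise

The 2D reference phantom is two concentric discs (outer radius 80, inner
40, values 1.0 and 0.5 on a 256² grid). Its support fits the nominal FOV —
the signal-free band that the finite-support methods exploit lives in the
2×-oversampled FOV of the spoke lines. The 3D phantom is a deterministic
procedural stack of nested smooth-boundary ellipsoids with distinct
intensities, confined to the central half-cube of the FOV; it stands in
for an anatomical brain volume and emulates piecewise-smooth anatomy with
limited support, but not realistic tissue contrast, relaxation, or
off-resonance physics — conclusions about those require real data.

Coil sensitivities are synthesized from random Fourier coefficients limited
to the two lowest bins per axis (band-limited, hence genuinely smooth and
periodic) with a dominant DC term per coil, then jointly normalized to unit
root-sum-of-squares. They emulate smooth receive profiles and inter-coil
encoding diversity, not the amplitude fall-off of any physical coil array.

Noise is i.i.d. circular complex Gaussian on every radial sample. The SNR
definition compares the energy of the noise-free image against the energy
of the pure-noise channel transported to image space by the
density-compensated adjoint gridding transform. Because that noise image is
exactly linear in σ, the calibration solves σ in closed form from one
unit-variance realization — deterministic per seed, and the realized SNR
equals the request to floating-point precision. The identical realization
is reused across all methods within a sweep cell; seeds derive from the
base seed through a fixed (gap, SNR, realization) counter scheme, making
sweeps bit-reproducible. Noise is added before gap masking (equivalent to
adding after, since gap samples are never read).

## Evaluation

Reconstruction error is the squared error between ground-truth and
reconstructed magnitude images, `‖a − b‖² = Σ(a_i − b_i)²` (a normalized
column is emitted alongside). All methods are reconstructed by one
CG-NUFFT SENSE pipeline (10 iterations) in which every radial sample enters
the data term with whatever value the method left there — zeros for the
zero-filled baseline — so reconstructions differ only by the gap
coefficients. The Monte Carlo sweep crosses gaps (default 1…4.5 dwells in
half-dwell steps) with SNRs (default 5/10/15/20 dB) and realizations
(default 20); a method failure is recorded as a NaN row and the sweep
continues.

## Problem sizes used by the test suite and acceptance script

Full-size runs of the reference geometry are not needed to exercise the
science, and the suite is sized accordingly: unit tests run on a 64² disc
with 102 spokes; the noiseless end-to-end check runs the reference 256²
two-disc phantom with 402 paired spokes and 4 coils at gap 2; the noisy 3D
method comparison runs a 32³ procedural phantom with 2000 phyllotaxis
spokes, 4 coils, SNR 10 dB, gaps 3 and 4, and 5 noise realizations, with
the center geometry scaled to preserve the reference gap-to-coverage
proportion (80% spoke fraction, 14³ cube at ~1.8-dwell spacing, kernel 3).
Convergence-versus-gap curves use the 64² setup with a 40% spoke fraction
for the same reason.

## Known limitations

* The algebraic method's deep-gap divergence means its output for gaps
  beyond ~3 dwells is numerically dominated by noise amplification; this is
  the expected behavior of the method, not an implementation artifact.
* The Stoch–Olejniczak method amplifies noise more than the pair-based
  algebraic method (its real-part system is more poorly conditioned and
  has an exactly invisible direction at DC); it is the weakest method under
  noise here, consistent with its single-spoke information budget.
* The low-rank loop's convergence constant depends on the center-volume
  geometry; with a gap deeper than about a quarter of the covered radius it
  converges slowly or stalls, mirroring the method's behavior at very wide
  imaging bandwidths.
* Angular undersampling, motion, contrast changes, in vivo map estimation,
  and coil compression are out of scope.
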