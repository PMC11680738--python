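"""Synthetic phantoms, coil sensitivities, forward simulation, and noise.

The forward model is ``y_c = F(S_c * x)`` per coil ``c``: sensitivity
weighting followed by a non-uniform Fourier transform onto the radial
trajectory.  Noise is injected as i.i.d. circular complex Gaussian samples
along every radial sample, with the standard deviation calibrated so that

    SNR(dB) = 10 log10( sum |x|^2 / sum |F^H n|^2 )

evaluated on the realized noise equals the requested level; ``F^H`` is the
density-compensated adjoint gridding transform onto the nominal image grid.
Because the noise image scales linearly with sigma the calibration is a
one-shot exact rescaling of a unit-variance realization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ImageVolume, MultiCoilKSpace, SensitivityMaps
from .geometry import RadialTrajectory
from .nufft import NufftPlan

__all__ = [
    "NoiseSpec",
    "make_disc_phantom",
    "make_brain_like_phantom_3d",
    "make_coil_maps",
    "simulate_kspace",
    "add_noise_at_snr",
    "gridding_adjoint_images",
]


@dataclass
class NoiseSpec:
    """Target SNR in dB plus the seed of the noise realization."""

    snr_db: float
    seed: int = 0
    sigma: float | None = None  # realized per-sample SD, set by calibration

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def make_disc_phantom(
    n: int,
    outer_radius: float,
    inner_radius: float,
    outer_value: float = 1.0,
    inner_value: float = 0.5,
) -> ImageVolume:
    """Two concentric discs centered on an ``n x n`` grid.

    Voxels within ``inner_radius`` of the center take ``inner_value``, the
    remaining voxels within ``outer_radius`` take ``outer_value``; the rest
    are zero.  Distances are measured from the grid center ``n // 2``.
    """
    if not 0 < inner_radius < outer_radius < n / 2:
        raise ValueError("need 0 < inner_radius < outer_radius < n/2")
    idx = np.arange(n) - n // 2
    rr = np.sqrt(idx[:, None] ** 2 + idx[None, :] ** 2)
    img = np.zeros((n, n))
    img[rr <= outer_radius] = outer_value
    img[rr <= inner_radius] = inner_value
    return ImageVolume(img)


def make_brain_like_phantom_3d(
    n: int, n_ellipsoids: int = 6, seed: int = 0
) -> ImageVolume:
    """Procedural nested-ellipsoid phantom with brain-like intensity layers.

    Deterministic per seed.  The object support is kept strictly inside the
    central ``n/2`` cube so that twice-oversampled readouts see a signal-free
    outer band -- the premise of the finite-support prior.
    """
    if n < 16:
        raise ValueError("grid size must be at least 16")
    rng = np.random.default_rng(seed)
    idx = (np.arange(n) - n // 2) / (n / 2)  # [-1, 1)
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    img = np.zeros((n, n, n))
    # outermost shell: fixed "skull" ellipsoid just inside half the FOV
    semi = np.array([0.46, 0.42, 0.40])
    levels = [1.0]
    levels += list(0.25 + 0.7 * rng.random(max(n_ellipsoids - 1, 0)))
    shells = [(np.zeros(3), semi, 0.0)]
    for _ in range(max(n_ellipsoids - 1, 0)):
        scale = 0.15 + 0.55 * rng.random()
        axes = semi * scale * (0.7 + 0.6 * rng.random(3))
        center = (semi - axes) * (2 * rng.random(3) - 1) * 0.8
        angle = rng.uniform(0, np.pi)
        shells.append((center, axes, angle))
    for (center, axes, angle), level in zip(shells, levels):
        ca, sa = np.cos(angle), np.sin(angle)
        Xr = ca * (X - center[0]) + sa * (Y - center[1])
        Yr = -sa * (X - center[0]) + ca * (Y - center[1])
        Zr = Z - center[2]
        q = (Xr / axes[0]) ** 2 + (Yr / axes[1]) ** 2 + (Zr / axes[2]) ** 2
        # smooth boundary: raised-cosine roll-off over ~5% of the radius
        t = np.clip((1.05 - q) / 0.10, 0.0, 1.0)
        mask = 0.5 - 0.5 * np.cos(np.pi * t)
        img = img * (1 - mask) + level * mask
    # enforce the support contract exactly
    half = np.abs(np.stack([X, Y, Z])).max(axis=0) < 0.5
    img *= half
    return ImageVolume(img)


def make_coil_maps(
    grid_shape, n_coils: int, seed: int = 0
) -> SensitivityMaps:
    """Smooth surrogate receive-coil profiles, jointly RSS-normalized.

    Each coil is synthesized from random Fourier coefficients restricted to
    the lowest two spatial-frequency bins per axis (so the field is
    band-limited and periodic, hence genuinely smooth), with a dominant DC
    term and a per-coil phase offset; the joint root-sum-of-squares is
    normalized to one everywhere, hence in particular on the phantom
    support.  Deterministic per seed.
    """
    grid_shape = tuple(int(n) for n in np.atleast_1d(grid_shape))
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if any(n < 8 for n in grid_shape):
        raise ValueError("grid too small for coil synthesis")
    d = len(grid_shape)
    rng = np.random.default_rng(seed)
    kmax = 2  # highest Fourier bin per axis -> very low band
    maps = np.empty((n_coils,) + grid_shape, dtype=np.complex128)
    for c in range(n_coils):
        spec = np.zeros(grid_shape, dtype=np.complex128)
        for offs in np.ndindex(*(2 * kmax + 1,) * d):
            k = np.array(offs) - kmax
            decay = np.exp(-0.5 * float(k @ k))
            coef = decay * (rng.normal() + 1j * rng.normal())
            idx = tuple(n // 2 + ki for n, ki in zip(grid_shape, k))
            spec[idx] = coef
        # dominant DC keeps each coil away from zeros inside the FOV
        center = tuple(n // 2 for n in grid_shape)
        spec[center] += 4.0 * np.exp(1j * 2 * np.pi * c / max(n_coils, 1))
        field = np.fft.ifftn(np.fft.ifftshift(spec))
        maps[c] = np.fft.fftshift(field)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps /= rss
    return SensitivityMaps(maps)


def simulate_kspace(
    image: ImageVolume,
    maps: SensitivityMaps,
    traj: RadialTrajectory,
    plan: NufftPlan | None = None,
) -> MultiCoilKSpace:
    """Forward-simulate multi-coil radial k-space (all samples acquired)."""
    if maps.grid_shape != image.shape:
        raise ValueError("coil maps are not conformal with the image")
    if not np.all(np.isfinite(image.values)):
        raise ValueError("image contains non-finite voxels")
    if plan is None:
        plan = NufftPlan(
            traj.coords.reshape(-1, traj.ndim), image.shape
        )
    data = np.empty(
        (traj.n_spokes, traj.n_readout, maps.n_coils), dtype=np.complex128
    )
    for c in range(maps.n_coils):
        samples = plan.forward(maps.maps[c] * image.values)
        data[:, :, c] = samples.reshape(traj.n_spokes, traj.n_readout)
    mask = np.ones((traj.n_spokes, traj.n_readout), dtype=bool)
    return MultiCoilKSpace(data, mask)


def gridding_adjoint_images(
    samples: np.ndarray,
    traj: RadialTrajectory,
    grid_shape,
    plan: NufftPlan | None = None,
) -> np.ndarray:
    """Density-compensated adjoint gridding of per-coil radial samples.

    ``samples`` is ``(n_spokes, n_readout, n_coils)``; returns per-coil
    images ``(n_coils, *grid_shape)`` on the nominal grid.  This is the
    ``F^H`` used by the SNR definition.
    """
    grid_shape = tuple(int(n) for n in np.atleast_1d(grid_shape))
    coords = traj.coords.reshape(-1, traj.ndim)
    if plan is None:
        plan = NufftPlan(coords, grid_shape)
    d = traj.ndim
    rho = np.linalg.norm(coords, axis=1)
    drho = traj.dwell_spacing / traj.oversampling
    solid_angle = 2 * np.pi if d == 2 else (4 * np.pi if d == 3 else 2.0)
    w = rho ** (d - 1) * drho * solid_angle / traj.n_spokes
    # origin sample: volume of the half-shell it owns, shared by all spokes
    vol0 = {1: drho, 2: np.pi * (drho / 2) ** 2, 3: 4 / 3 * np.pi * (drho / 2) ** 3}[d]
    w[rho <= 1e-12] = vol0 / traj.n_spokes
    # the forward model sums over voxels, so inverting it carries 1/N^d;
    # with this factor the weighted adjoint lands on the image scale
    # (checked against the simulated phantom to within a few percent)
    w = w / float(np.prod(grid_shape))
    n_coils = samples.shape[2]
    out = np.empty((n_coils,) + grid_shape, dtype=np.complex128)
    for c in range(n_coils):
        out[c] = plan.adjoint(w * samples[:, :, c].ravel())
    return out


def add_noise_at_snr(
    kspace: MultiCoilKSpace,
    noise: NoiseSpec,
    reference_image: ImageVolume,
    traj: RadialTrajectory,
) -> tuple[MultiCoilKSpace, np.ndarray]:
    """Add complex Gaussian noise calibrated to the requested image SNR.

    Noise is applied to every radial sample (gap samples are re-zeroed by
    ``apply_gap`` downstream).  The SNR definition transforms the pure-noise
    channel to the nominal image grid with the adjoint gridding transform and
    compares its energy against the noise-free reference image; sigma is
    solved exactly from a unit-variance realization, so the realized SNR
    matches the request to floating-point precision.  Returns the noisy
    k-space and the per-coil noise-only images (for SNR bookkeeping).
    """
    signal_power = float(np.sum(np.abs(reference_image.values) ** 2))
    if signal_power == 0:
        raise ValueError("reference image has zero energy; SNR undefined")
    rng = np.random.default_rng(noise.seed)
    shape = kspace.data.shape
    unit = (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    ) / np.sqrt(2.0)
    noise_imgs = gridding_adjoint_images(
        unit, traj, reference_image.shape
    )
    unit_power = float(np.sum(np.abs(noise_imgs) ** 2))
    sigma = np.sqrt(
        signal_power / (unit_power * 10.0 ** (noise.snr_db / 10.0))
    )
    noise.sigma = float(sigma)
    out = kspace.copy()
    out.data = out.data + sigma * unit
    return out, sigma * noise_imgs
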