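"""Center-out radial trajectories and the dead-time gap.

A zero-echo-time (ZTE) acquisition samples the free induction decay along
center-out radial spokes with the gradients always on.  Transmit/receive
switching forbids sampling for a dead time ``dt_d`` after excitation, so the
first few samples of every spoke -- the lowest spatial frequencies -- are
missing.  The gap is quantified in nominal Nyquist dwells ``g = dt_d / dt``
(``dt = 1/RBW``); with ``r``-fold readout oversampling the number of missing
samples per spoke is ``ceil(r * g)``, counting a sample that falls exactly on
the gap boundary as acquired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MultiCoilKSpace

__all__ = [
    "RadialTrajectory",
    "DeadTimeGap",
    "make_uniform_spokes_2d",
    "make_phyllotaxis_spokes_3d",
    "missing_sample_count",
    "apply_gap",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))  # ~137.5 deg azimuthal increment

NO_PAIR = -1


@dataclass
class RadialTrajectory:
    """Center-out radial spokes on an oversampled readout grid.

    Sample ``m`` of spoke ``s`` sits at ``(m / oversampling) * dk *
    spoke_dirs[s]`` with ``dk = dwell_spacing`` in cycles/FOV; sample 0 is the
    k-space origin.  ``pair_index[s]`` is the diametric counterpart of spoke
    ``s`` (or ``-1`` when unpaired).
    """

    spoke_dirs: np.ndarray  # (n_spokes, d) unit vectors
    n_readout: int
    oversampling: float = 2.0
    dwell_spacing: float = 1.0
    pair_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.spoke_dirs = np.asarray(self.spoke_dirs, dtype=float)
        if self.spoke_dirs.ndim != 2:
            raise ValueError("spoke_dirs must be (n_spokes, d)")
        norms = np.linalg.norm(self.spoke_dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("spoke directions must be unit vectors")
        if self.n_readout < 1:
            raise ValueError("n_readout must be positive")
        if self.oversampling < 1:
            raise ValueError("oversampling factor must be >= 1")
        if self.pair_index is None:
            self.pair_index = np.full(self.n_spokes, NO_PAIR, dtype=int)
        self.pair_index = np.asarray(self.pair_index, dtype=int)
        self._check_pairing()

    def _check_pairing(self) -> None:
        for s, t in enumerate(self.pair_index):
            if t == NO_PAIR:
                continue
            if self.pair_index[t] != s:
                raise ValueError("pair_index is not an involution")
            if not np.allclose(
                self.spoke_dirs[t], -self.spoke_dirs[s], atol=1e-9
            ):
                raise ValueError(f"spokes {s} and {t} are not diametric")

    @property
    def n_spokes(self) -> int:
        return self.spoke_dirs.shape[0]

    @property
    def ndim(self) -> int:
        return self.spoke_dirs.shape[1]

    @property
    def sample_radii(self) -> np.ndarray:
        """Radius of each readout sample in cycles/FOV."""
        m = np.arange(self.n_readout)
        return (m / self.oversampling) * self.dwell_spacing

    @property
    def max_radius(self) -> float:
        return float(self.sample_radii[-1])

    @property
    def coords(self) -> np.ndarray:
        """Per-sample k-space coordinates, shape (n_spokes, n_readout, d)."""
        return (
            self.spoke_dirs[:, None, :] * self.sample_radii[None, :, None]
        )

    @property
    def is_paired(self) -> bool:
        return bool(np.all(self.pair_index != NO_PAIR))


@dataclass
class DeadTimeGap:
    """Dead time expressed in nominal Nyquist dwells (may be half-integer)."""

    gap_dwells: float

    def __post_init__(self) -> None:
        if self.gap_dwells < 0:
            raise ValueError("dead-time gap must be non-negative")

    def n_missing(self, oversampling: float) -> int:
        return missing_sample_count(self.gap_dwells, oversampling)


def missing_sample_count(gap_dwells: float, oversampling: float) -> int:
    """Number of missing readout samples for a gap of ``g`` Nyquist dwells.

    Counts readout-grid times ``m * dt / r`` strictly inside ``[0, g * dt)``;
    a sample coinciding exactly with the gap boundary is acquired.  On the
    nominal grid (``r = 1``) a gap of 2.5 dwells costs 3 samples, on a twice
    oversampled grid 5; a gap of 4.5 dwells costs 5 and 9 respectively.
    """
    if gap_dwells < 0:
        raise ValueError("dead-time gap must be non-negative")
    if oversampling < 1:
        raise ValueError("oversampling factor must be >= 1")
    rg = oversampling * gap_dwells
    # snap to the grid before applying the strict inequality
    if abs(rg - round(rg)) < 1e-9:
        return int(round(rg))
    return int(np.ceil(rg))


def make_uniform_spokes_2d(
    n_spokes: int,
    n_readout: int,
    oversampling: float = 2.0,
    paired: bool = True,
) -> RadialTrajectory:
    """Uniform 2D center-out spokes; paired spokes come with their antipodes.

    With ``paired=True`` the first ``n_spokes // 2`` spokes take angles
    ``j * pi / (n_spokes // 2)`` and the second half are their diametric
    partners, so unique line orientations are spaced ``pi / (n_spokes / 2)``
    apart.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be positive")
    if paired:
        if n_spokes % 2:
            raise ValueError("paired trajectories need an even spoke count")
        half = n_spokes // 2
        angles = np.arange(half) * np.pi / half
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        dirs = np.concatenate([dirs, -dirs], axis=0)
        pair = np.concatenate(
            [np.arange(half) + half, np.arange(half)]
        )
    else:
        angles = np.arange(n_spokes) * np.pi / n_spokes
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        pair = np.full(n_spokes, NO_PAIR)
    # renormalize against rounding
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return RadialTrajectory(dirs, n_readout, oversampling, pair_index=pair)


def make_phyllotaxis_spokes_3d(
    n_spokes: int,
    n_readout: int,
    oversampling: float = 2.0,
    bidirectional: bool = True,
) -> RadialTrajectory:
    """Spherical phyllotaxis spokes with golden-angle azimuthal increments.

    The polar sweep is area-uniform and monotone.  With
    ``bidirectional=True`` the ``n_spokes`` tips cover one hemisphere and
    each spoke's antipode is appended (``2 * n_spokes`` spokes total, all
    paired); otherwise the sweep covers the full sphere unpaired.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    i = np.arange(n_spokes)
    if bidirectional:
        z = 1.0 - (i + 0.5) / n_spokes  # hemisphere z in (0, 1)
    else:
        z = 1.0 - 2.0 * (i + 0.5) / n_spokes  # full sphere z in (-1, 1)
    phi = i * GOLDEN_ANGLE
    rho = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    dirs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if bidirectional:
        dirs = np.concatenate([dirs, -dirs], axis=0)
        pair = np.concatenate(
            [np.arange(n_spokes) + n_spokes, np.arange(n_spokes)]
        )
    else:
        pair = np.full(n_spokes, NO_PAIR)
    return RadialTrajectory(dirs, n_readout, oversampling, pair_index=pair)


def apply_gap(
    kspace: MultiCoilKSpace,
    traj: RadialTrajectory,
    gap: DeadTimeGap,
) -> MultiCoilKSpace:
    """Zero and un-flag the leading gap samples of every spoke.

    Samples with index ``m`` such that ``m / r < g`` are zeroed and marked
    unacquired; everything else is bit-identical to the input.  Idempotent.
    """
    if kspace.data.shape[:2] != (traj.n_spokes, traj.n_readout):
        raise ValueError("k-space is not conformal with the trajectory")
    ng = gap.n_missing(traj.oversampling)
    out = kspace.copy()
    out.data[:, :ng, :] = 0.0
    out.mask[:, :ng] = False
    out.synthesized[:, :ng] = False
    return out
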