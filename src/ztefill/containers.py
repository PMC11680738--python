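"""Shared in-memory containers for radial k-space data and images.

Conventions used throughout the package:

* k-space coordinates are expressed in cycles/FOV, so one unit equals the
  nominal Nyquist step ``dk = 1/FOV``.  On an image grid of ``N`` voxels per
  axis the k-space origin sits at index ``N // 2`` after an FFT shift.
* radial k-space data is stored as ``(n_spokes, n_readout, n_coils)``.
* ``mask`` marks samples that were actually acquired; ``synthesized`` marks
  samples filled in by a gap-infilling method.  The two are mutually
  exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultiCoilKSpace", "ImageVolume", "SensitivityMaps"]


@dataclass
class MultiCoilKSpace:
    """Complex radial samples indexed ``(spoke, readout sample, coil)``."""

    data: np.ndarray
    mask: np.ndarray
    synthesized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_spokes, n_readout, n_coils)")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask must be (n_spokes, n_readout)")
        if self.synthesized is None:
            self.synthesized = np.zeros_like(self.mask)
        self.synthesized = np.asarray(self.synthesized, dtype=bool)
        if self.synthesized.shape != self.mask.shape:
            raise ValueError("synthesized must match mask shape")

    @property
    def n_spokes(self) -> int:
        return self.data.shape[0]

    @property
    def n_readout(self) -> int:
        return self.data.shape[1]

    @property
    def n_coils(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "MultiCoilKSpace":
        return MultiCoilKSpace(
            self.data.copy(), self.mask.copy(), self.synthesized.copy()
        )


@dataclass
class ImageVolume:
    """Complex voxel array with isotropic grid shape ``N**d`` (d = 2 or 3)."""

    values: np.ndarray
    fov: tuple = None  # type: ignore[assignment]  # mm per axis

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim not in (1, 2, 3):
            raise ValueError("only 1D/2D/3D volumes are supported")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite voxels")
        if self.fov is None:
            self.fov = tuple(float(n) for n in self.values.shape)
        else:
            self.fov = tuple(float(f) for f in np.atleast_1d(self.fov))
            if len(self.fov) == 1:
                self.fov = self.fov * self.values.ndim
        if len(self.fov) != self.values.ndim:
            raise ValueError("fov must provide one extent per axis")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class SensitivityMaps:
    """Smooth per-coil complex spatial weights, jointly RSS-normalized."""

    maps: np.ndarray  # (n_coils, *grid_shape)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim < 2:
            raise ValueError("maps must be (n_coils, *grid_shape)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.maps.shape[1:]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))
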