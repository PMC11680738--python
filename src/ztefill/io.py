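"""HDF5 and NIfTI containers for trajectories, k-space, and images.

The HDF5 layout:

* group ``trajectory`` with datasets ``dirs`` (n_spokes x d) and
  ``pair_index``, plus attributes ``oversampling``, ``n_readout``,
  ``fov_mm``;
* datasets ``data`` (spoke x sample x coil, complex), ``mask``, and
  ``synthesized`` for multi-coil k-space.

Images go to NIfTI with the voxel size (FOV / N) encoded in the affine.
All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .containers import ImageVolume, MultiCoilKSpace
from .geometry import RadialTrajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_kspace",
    "load_kspace",
    "save_image",
    "load_image",
    "atomic_path",
]


class atomic_path:
    """Context manager yielding a temp path renamed into place on success."""

    def __init__(self, target):
        self.target = Path(target)
        self.tmp = None

    def __enter__(self) -> Path:
        fd, tmp = tempfile.mkstemp(
            dir=self.target.parent, suffix="".join(self.target.suffixes)
        )
        os.close(fd)
        self.tmp = Path(tmp)
        return self.tmp

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            os.replace(self.tmp, self.target)
        else:
            self.tmp.unlink(missing_ok=True)
        return False


def _write_traj_group(grp: h5py.Group, traj: RadialTrajectory, fov_mm):
    grp.create_dataset("dirs", data=traj.spoke_dirs)
    grp.create_dataset("pair_index", data=traj.pair_index)
    grp.attrs["oversampling"] = traj.oversampling
    grp.attrs["n_readout"] = traj.n_readout
    grp.attrs["fov_mm"] = float(fov_mm)


def _read_traj_group(grp: h5py.Group) -> tuple[RadialTrajectory, float]:
    traj = RadialTrajectory(
        spoke_dirs=np.asarray(grp["dirs"]),
        n_readout=int(grp.attrs["n_readout"]),
        oversampling=float(grp.attrs["oversampling"]),
        pair_index=np.asarray(grp["pair_index"]),
    )
    return traj, float(grp.attrs["fov_mm"])


def save_trajectory(path, traj: RadialTrajectory, fov_mm: float = 240.0):
    with atomic_path(path) as tmp:
        with h5py.File(tmp, "w") as f:
            _write_traj_group(f.create_group("trajectory"), traj, fov_mm)


def load_trajectory(path) -> RadialTrajectory:
    with h5py.File(path, "r") as f:
        traj, _ = _read_traj_group(f["trajectory"])
    return traj


def save_kspace(
    path,
    kspace: MultiCoilKSpace,
    traj: RadialTrajectory,
    fov_mm: float = 240.0,
) -> None:
    with atomic_path(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("data", data=kspace.data)
            f.create_dataset("mask", data=kspace.mask)
            f.create_dataset("synthesized", data=kspace.synthesized)
            _write_traj_group(f.create_group("trajectory"), traj, fov_mm)


def load_kspace(path) -> tuple[MultiCoilKSpace, RadialTrajectory]:
    with h5py.File(path, "r") as f:
        ksp = MultiCoilKSpace(
            np.asarray(f["data"]),
            np.asarray(f["mask"]),
            np.asarray(f["synthesized"]) if "synthesized" in f else None,
        )
        traj, _ = _read_traj_group(f["trajectory"])
    return ksp, traj


def save_image(path, image: ImageVolume) -> None:
    """Write a volume as NIfTI; complex data is stored as magnitude."""
    vals = image.values
    data = np.abs(vals) if np.iscomplexobj(vals) else vals
    vox = [f / n for f, n in zip(image.fov, image.shape)]
    affine = np.diag(list(vox) + [1.0] * (4 - len(vox)))
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    with atomic_path(path) as tmp:
        nib.save(img, str(tmp))


def load_image(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    vox = np.abs(np.diag(img.affine)[: data.ndim])
    fov = tuple(v * n for v, n in zip(vox, data.shape))
    return ImageVolume(data.astype(np.complex128), fov)
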