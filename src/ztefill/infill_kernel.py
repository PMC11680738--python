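"""ZINFANDEL-style kernel interpolation along radial spokes.

A GRAPPA-like 1D kernel is calibrated on acquired samples just outside the
dead-time gap, using the target spoke's nearest angular neighbors, and then
applied to extrapolate the gap inward one dwell at a time.  Because the
kernel weights vary with spoke angle, they are recalibrated for every
(spoke, gap position) pair.  Previously synthesized samples serve as sources
for deeper gap positions by default (the recursive fill); a non-recursive
variant trains a longer-range kernel per depth so that only acquired samples
are ever used as sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import MultiCoilKSpace
from .geometry import DeadTimeGap, RadialTrajectory, missing_sample_count

__all__ = ["KernelParams", "KernelCalibration", "calibrate_kernel", "zinfandel_infill"]


@dataclass
class KernelParams:
    """Calibration geometry: 1D kernel of 5 taps trained on 16 readout
    samples within the nearest five spokes (the original settings)."""

    kernel_length: int = 5
    calib_readout: int = 16
    calib_spokes: int = 5
    tikhonov: float = 1e-6  # relative to the Gram trace
    recursive: bool = True


@dataclass
class KernelCalibration:
    weights: np.ndarray  # (n_coils * kernel_length, n_coils)
    spoke: int
    offset: int  # source offset: target m predicted from m+offset ...
    neighbors: np.ndarray


def nearest_spokes(traj: RadialTrajectory, spoke: int, count: int) -> np.ndarray:
    """Indices of the ``count`` nearest spokes by great-circle angle.

    The target spoke itself (angle zero) is included; ties break toward the
    lower spoke index via a stable sort.
    """
    cosang = np.clip(traj.spoke_dirs @ traj.spoke_dirs[spoke], -1.0, 1.0)
    ang = np.arccos(cosang)
    order = np.argsort(ang, kind="stable")
    return order[: min(count, traj.n_spokes)]


def calibrate_kernel(
    kspace: MultiCoilKSpace,
    traj: RadialTrajectory,
    spoke: int,
    gap: DeadTimeGap,
    params: KernelParams | None = None,
    offset: int = 1,
) -> KernelCalibration:
    """Least-squares calibration of the inward-extrapolation kernel.

    Builds source/target pairs by sliding the kernel over the first
    ``calib_readout`` acquired samples of the target spoke's nearest
    neighbors: the target at readout index ``m`` is regressed (across all
    coils) onto the ``kernel_length`` samples at ``m + offset ...
    m + offset + kernel_length - 1``.  Tikhonov-regularized; an
    underdetermined calibration triggers a rank warning.
    """
    params = params or KernelParams()
    K = params.kernel_length
    if params.calib_readout < K + 1:
        raise ValueError("calib_readout must exceed kernel_length")
    ng = missing_sample_count(gap.gap_dwells, traj.oversampling)
    first = ng  # first acquired readout index
    if first + params.calib_readout > traj.n_readout:
        raise ValueError("calibration region exceeds the readout")
    if params.calib_readout - K - offset + 1 < 1:
        raise ValueError("offset too deep for the calibration region")
    neigh = nearest_spokes(traj, spoke, params.calib_spokes)
    targets = []
    sources = []
    for n in neigh:
        # target + sources stay inside the calib_readout acquired window
        for m in range(first, first + params.calib_readout - K - offset + 1):
            targets.append(kspace.data[n, m, :])
            sources.append(
                kspace.data[n, m + offset : m + offset + K, :].ravel()
            )
    A = np.asarray(sources)  # (rows, K * nc)
    b = np.asarray(targets)  # (rows, nc)
    if A.shape[0] < A.shape[1]:
        warnings.warn(
            "underdetermined kernel calibration; relying on Tikhonov",
            RuntimeWarning,
            stacklevel=2,
        )
    gram = A.conj().T @ A
    lam = params.tikhonov * np.trace(gram).real / max(gram.shape[0], 1)
    gram[np.diag_indices_from(gram)] += lam
    weights = np.linalg.solve(gram, A.conj().T @ b)
    return KernelCalibration(weights, spoke, offset, neigh)


def zinfandel_infill(
    kspace: MultiCoilKSpace,
    traj: RadialTrajectory,
    gap: DeadTimeGap,
    params: KernelParams | None = None,
) -> MultiCoilKSpace:
    """Fill the gap from the outside inward with per-position kernels.

    For each spoke the gap samples are synthesized one dwell at a time,
    recalibrating the kernel for every missing position.  Acquired samples
    are untouched.  Readout sample 0 of every spoke is the identical k-space
    origin, so the per-spoke DC predictions are averaged into one consistent
    value at the end (an exact constraint of center-out trajectories).
    """
    params = params or KernelParams()
    ng = missing_sample_count(gap.gap_dwells, traj.oversampling)
    out = kspace.copy()
    if ng == 0:
        return out
    K = params.kernel_length
    for s in range(traj.n_spokes):
        cal_cache: dict[int, KernelCalibration] = {}
        for p in range(ng - 1, -1, -1):
            offset = 1 if params.recursive else ng - p
            # recalibration per (spoke, position); identical offsets share
            # the identical least-squares problem, so the result is cached
            if offset not in cal_cache:
                cal_cache[offset] = calibrate_kernel(
                    kspace, traj, s, gap, params, offset
                )
            cal = cal_cache[offset]
            src_data = out.data if params.recursive else kspace.data
            src = src_data[s, p + offset : p + offset + K, :].ravel()
            pred = src @ cal.weights  # (nc,)
            if not np.all(np.isfinite(pred)):
                raise FloatingPointError(
                    f"non-finite fill at spoke {s}, position {p}"
                )
            out.data[s, p, :] = pred
        out.synthesized[s, :ng] = True
    # all spokes share the origin sample: enforce one consistent DC value
    out.data[:, 0, :] = out.data[:, 0, :].mean(axis=0, keepdims=True)
    out.mask[:, :ng] = False
    return out
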