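"""Explicit per-spoke gap solvers based on the finite-support prior.

With twice readout oversampling the reconstructed 1D field of view along a
spoke pair is twice the nominal one, so the object occupies only the central
band of the inverse-DFT domain.  The algebraic method solves, for each
diametric spoke pair and coil, the small linear system that chooses the gap
entries minimizing the energy of the 1D profile outside the nominal band;
the Stoch-Olejniczak variant minimizes only the *real* part of the
out-of-band signal and needs a single spoke (the missing diametric half is
implicitly the conjugate reflection, so the method is insensitive to a
global phase).

Both are "explicit" methods: samples outside the gap are bit-identical
before and after infilling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MultiCoilKSpace
from .geometry import DeadTimeGap, RadialTrajectory, missing_sample_count

__all__ = [
    "SpokeSystem",
    "IllConditionedError",
    "build_pair_line",
    "algebraic_infill",
    "stoch_olejniczak_infill",
]


class IllConditionedError(RuntimeError):
    """Raised when the unregularized gap system is numerically singular."""


@dataclass
class Regularization:
    """Either Tikhonov (relative lambda) or truncated SVD (relative cutoff)."""

    tikhonov: float | None = 1e-12
    tsvd_rcond: float | None = None


def _as_reg(regularization) -> Regularization:
    if regularization is None:
        return Regularization()
    if isinstance(regularization, Regularization):
        return regularization
    if isinstance(regularization, dict):
        return Regularization(**regularization)
    return Regularization(tikhonov=float(regularization))


def _centered_idft_matrix(L: int) -> np.ndarray:
    """Matrix of the centered inverse DFT: x[p] = (1/L) sum_u y[u] e^{2pi i up/L}."""
    p = np.arange(L) - (L - 1) // 2 if L % 2 else np.arange(L) - L // 2
    u = p.copy()
    return np.exp(2j * np.pi * np.outer(p, u) / L) / L


def _support_selector(L: int, oversampling: float) -> np.ndarray:
    """Boolean mask of the central nominal-FOV band (True inside)."""
    n_nom = int(round(L / oversampling))
    inside = np.zeros(L, dtype=bool)
    start = (L - n_nom) // 2
    inside[start : start + n_nom] = True
    return inside


@dataclass
class SpokeSystem:
    """Dense 1D system shared by every line of a given geometry.

    ``line_length`` is the oversampled DFT length, ``gap_cols`` indexes the
    unknown (missing) entries of the line, ``w_out`` maps a full line to the
    out-of-band profile, and ``solve_op`` maps a zero-filled line directly to
    the least-squares gap estimate.
    """

    line_length: int
    gap_cols: np.ndarray
    w_out: np.ndarray
    solve_op: np.ndarray
    real_part: bool
    condition_number: float

    def solve(self, zero_filled_lines: np.ndarray) -> np.ndarray:
        """Gap entries for lines stacked as columns (L, n_lines)."""
        if self.real_part:
            rhs = (self.w_out @ zero_filled_lines).real
            parts = -self.solve_op @ rhs
            ng = self.gap_cols.size
            return parts[:ng] + 1j * parts[ng:]
        return -self.solve_op @ (self.w_out @ zero_filled_lines)


def build_spoke_system(
    line_length: int,
    oversampling: float,
    gap_cols: np.ndarray,
    regularization=None,
    real_part: bool = False,
    column_scale: np.ndarray | None = None,
) -> SpokeSystem:
    reg = _as_reg(regularization)
    W = _centered_idft_matrix(line_length)
    inside = _support_selector(line_length, oversampling)
    w_out = W[~inside, :]
    B = w_out[:, gap_cols]
    if column_scale is not None:
        B = B * np.asarray(column_scale)[None, :]
    if real_part:
        B = np.concatenate([B.real, -B.imag], axis=1)
    sv = np.linalg.svd(B, compute_uv=False) if B.size else np.array([0.0])
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if reg.tsvd_rcond is not None:
        solve_op = np.linalg.pinv(B, rcond=reg.tsvd_rcond)
    else:
        lam = reg.tikhonov or 0.0
        if lam == 0.0 and cond > 1e12:
            raise IllConditionedError(
                f"gap system condition number {cond:.2e}; "
                "supply Tikhonov or truncated-SVD regularization"
            )
        gram = B.conj().T @ B
        lam_abs = lam * np.trace(gram).real / max(gram.shape[0], 1)
        gram[np.diag_indices_from(gram)] += lam_abs
        solve_op = np.linalg.solve(gram, B.conj().T)
    return SpokeSystem(
        line_length,
        np.asarray(gap_cols),
        w_out,
        solve_op,
        real_part,
        cond,
    )


def build_pair_line(
    kspace: MultiCoilKSpace, traj: RadialTrajectory, spoke: int
) -> np.ndarray:
    """Concatenate a diametric spoke pair into one line through the origin.

    Returns ``(n_coils, L)`` with ``L = 2 * n_readout - 1``; entry ``l``
    corresponds to signed sample ``u = l - (n_readout - 1)`` along the
    spoke's direction, the negative half coming from the partner spoke
    reversed.  The shared origin sample is taken once, from ``spoke``.
    """
    partner = traj.pair_index[spoke]
    if partner < 0:
        raise ValueError(f"spoke {spoke} has no diametric partner")
    n = traj.n_readout
    pos = kspace.data[spoke, :, :]  # (n, coils)
    neg = kspace.data[partner, 1:, :][::-1, :]  # samples n-1..1 reversed
    return np.concatenate([neg, pos], axis=0).T.copy()


def _pair_gap_cols(n_readout: int, ng: int) -> np.ndarray:
    """Line indices of the 2*ng - 1 unknowns (|u| < ng)."""
    center = n_readout - 1
    return np.arange(center - (ng - 1), center + ng)


def algebraic_infill(
    kspace: MultiCoilKSpace,
    traj: RadialTrajectory,
    gap: DeadTimeGap,
    regularization=None,
) -> MultiCoilKSpace:
    """Fill the gap by out-of-band energy minimization on spoke-pair lines.

    Requires every spoke to be paired and readout oversampling >= 2 (the
    source of the signal-free band).  Solved per pair line and per coil with
    Tikhonov (default relative lambda 1e-12) or truncated SVD.
    """
    if not traj.is_paired:
        raise ValueError("the algebraic method needs diametric spoke pairs")
    if traj.oversampling < 2:
        raise ValueError("the algebraic method needs >= 2x oversampling")
    ng = missing_sample_count(gap.gap_dwells, traj.oversampling)
    out = kspace.copy()
    if ng == 0:
        return out
    n = traj.n_readout
    L = 2 * n - 1
    gap_cols = _pair_gap_cols(n, ng)
    system = build_spoke_system(
        L, traj.oversampling, gap_cols, regularization
    )
    done = np.zeros(traj.n_spokes, dtype=bool)
    for s in range(traj.n_spokes):
        if done[s]:
            continue
        t = traj.pair_index[s]
        lines = build_pair_line(kspace, traj, s)  # (coils, L)
        zf = lines.copy()
        zf[:, gap_cols] = 0.0
        filled = system.solve(zf.T)  # (2ng-1, coils)
        center = n - 1
        for j, col in enumerate(gap_cols):
            u = col - center
            if u >= 0:
                out.data[s, u, :] = filled[j]
            if u <= 0:
                out.data[t, -u, :] = filled[j]
        out.synthesized[s, :ng] = True
        out.synthesized[t, :ng] = True
        done[s] = done[t] = True
    out.mask[:, :ng] = False
    return out


def stoch_olejniczak_infill(
    kspace: MultiCoilKSpace,
    traj: RadialTrajectory,
    gap: DeadTimeGap,
    regularization=None,
) -> MultiCoilKSpace:
    """Fill the gap by minimizing the *real* out-of-band signal per spoke.

    Operates on single spokes (no diametric pairing required): the spoke's
    half-line is embedded in a full line whose negative half is zero, so the
    real part of its 1D profile is the profile of the Hermitian-symmetrized
    line.  The real and imaginary parts of the gap entries are the unknowns
    of a real least-squares problem.

    Each line is first rotated to a canonical zero-order phase and the
    recovered entries are rotated back, which makes the algorithm exactly
    equivariant under a global phase of the data -- the phase-robustness the
    real-part objective is meant to provide.  The canonical phase is
    estimated as ``arg(sum y_m^2) / 2`` over the first acquired samples:
    squaring removes the sign flips of oscillating k-space profiles (e.g.
    jinc side lobes), which would otherwise corrupt a single-sample phase
    anchor by 180 degrees.
    """
    if traj.oversampling < 2:
        raise ValueError("the method needs >= 2x readout oversampling")
    ng = missing_sample_count(gap.gap_dwells, traj.oversampling)
    out = kspace.copy()
    if ng == 0:
        return out
    n = traj.n_readout
    L = 2 * n - 1
    center = n - 1
    gap_cols = np.arange(center, center + ng)  # u = 0 .. ng-1
    # the origin enters the Hermitian-symmetrized line at half weight, so
    # its column is scaled by 1/2 (otherwise DC is double-counted and the
    # out-of-band real signal cannot vanish at the true solution)
    col_scale = np.ones(ng)
    col_scale[0] = 0.5
    system = build_spoke_system(
        L,
        traj.oversampling,
        gap_cols,
        regularization,
        real_part=True,
        column_scale=col_scale,
    )
    half = kspace.data.copy()
    half[:, :ng, :] = 0.0
    # canonical zero-order phase per (spoke, coil), sign-invariant
    anchor = np.sum(half[:, ng : ng + 8, :] ** 2, axis=1)
    anchor = np.where(anchor == 0, 1.0, anchor)
    phase = np.exp(-0.5j * np.angle(anchor))
    half = half * phase[:, None, :]
    lines = np.zeros((L, traj.n_spokes * kspace.n_coils), dtype=complex)
    lines[center:, :] = half.transpose(1, 0, 2).reshape(n, -1)
    filled = system.solve(lines)  # (ng, n_spokes*n_coils)
    filled = filled.reshape(ng, traj.n_spokes, kspace.n_coils).transpose(
        1, 0, 2
    )
    out.data[:, :ng, :] = filled * np.conj(phase)[:, None, :]
    out.synthesized[:, :ng] = True
    out.mask[:, :ng] = False
    return out


def gap_system_condition(
    n_readout: int, oversampling: float, gap_dwells: float
) -> float:
    """Condition number of the pair-line gap system (diagnostic)."""
    ng = missing_sample_count(gap_dwells, oversampling)
    if ng == 0:
        return 1.0
    L = 2 * n_readout - 1
    gap_cols = _pair_gap_cols(n_readout, ng)
    W = _centered_idft_matrix(L)
    inside = _support_selector(L, oversampling)
    B = W[~inside][:, gap_cols]
    sv = np.linalg.svd(B, compute_uv=False)
    return float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
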