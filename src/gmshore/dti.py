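"""Diffusion tensor fitting and scalar indices (FA, MD).

The tensor is fitted by weighted log-linear least squares to the b=0 and
low-shell (b <= 700 s/mm^2) measurements only, with the squared signal as
weight — the standard WLS estimator for the log-linearized Stejskal-Tanner
equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme, B0_THRESHOLD

__all__ = ["DiffusionTensor", "fit_dti", "fit_dti_block", "dti_fa", "dti_md", "DTI_B_MAX"]

#: DTI uses only measurements with b at or below this shell.
DTI_B_MAX = 700.0


@dataclass(frozen=True)
class DiffusionTensor:
    """Fitted tensor with its sorted eigensystem."""

    d: np.ndarray             # 3x3, mm^2/s
    s0: float
    eigenvalues: np.ndarray   # descending
    e1: np.ndarray            # principal direction, unit norm


def _design_matrix(scheme: AcquisitionScheme, mask: np.ndarray) -> np.ndarray:
    b = scheme.bvals[mask]
    g = scheme.bvecs[mask]
    return np.column_stack([
        np.ones(mask.sum()),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _dti_mask(scheme: AcquisitionScheme) -> np.ndarray:
    mask = scheme.bvals <= DTI_B_MAX
    dwi = mask & ~scheme.b0_mask
    if scheme.n_b0 < 1:
        raise ValueError("scheme needs at least one b=0 measurement")
    # at least 6 distinct directions on the low shell
    dirs = np.unique(np.round(np.abs(scheme.bvecs[dwi]), 6), axis=0)
    if dirs.shape[0] < 6:
        raise ValueError("scheme needs >= 6 distinct directions at b <= 700")
    return mask


def _tensor_from_params(params: np.ndarray) -> DiffusionTensor:
    s0 = float(np.exp(params[0]))
    dxx, dyy, dzz, dxy, dxz, dyz = params[1:]
    d = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    w, v = np.linalg.eigh(d)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    return DiffusionTensor(d=d, s0=s0, eigenvalues=w, e1=v[:, 0])


def fit_dti(signal: np.ndarray, scheme: AcquisitionScheme) -> DiffusionTensor:
    """Weighted log-linear LS fit using only b=0 and b<=700 measurements."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(scheme),):
        raise ValueError(f"signal length {signal.shape} does not match scheme {len(scheme)}")
    bad = np.flatnonzero(~(signal > 0))
    if bad.size:
        raise ValueError(f"non-positive signal at measurement index {bad[0]}")
    mask = _dti_mask(scheme)
    x = _design_matrix(scheme, mask)
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("rank-deficient DTI design matrix")
    y = np.log(signal[mask])
    w = signal[mask] ** 2
    xtw = x.T * w
    params = np.linalg.solve(xtw @ x, xtw @ y)
    return _tensor_from_params(params)


def fit_dti_block(signals: np.ndarray, scheme: AcquisitionScheme):
    """Batched WLS tensor fit over a (voxels, measurements) block.

    Voxels with non-positive or non-finite signals are returned as NaN
    rows instead of raising.

    Returns
    -------
    eigenvalues : (voxels, 3) descending
    e1 : (voxels, 3)
    s0 : (voxels,)
    """
    signals = np.asarray(signals, dtype=float)
    n_vox = signals.shape[0]
    if signals.shape[1] != len(scheme):
        raise ValueError("signal block does not match scheme length")
    mask = _dti_mask(scheme)
    x = _design_matrix(scheme, mask)
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("rank-deficient DTI design matrix")
    s = signals[:, mask]
    valid = np.all(np.isfinite(s) & (s > 0), axis=1)

    evals = np.full((n_vox, 3), np.nan)
    e1 = np.full((n_vox, 3), np.nan)
    s0 = np.full(n_vox, np.nan)
    if not valid.any():
        return evals, e1, s0

    sv = s[valid]
    y = np.log(sv)
    w = sv**2
    # per-voxel normal equations: A_v = X' W_v X, b_v = X' W_v y_v
    a = np.einsum("mi,vm,mj->vij", x, w, x)
    b = np.einsum("mi,vm,vm->vi", x, w, y)
    params = np.linalg.solve(a, b[..., None])[..., 0]
    dxx, dyy, dzz, dxy, dxz, dyz = params[:, 1:].T
    d = np.empty((params.shape[0], 3, 3))
    d[:, 0, 0], d[:, 1, 1], d[:, 2, 2] = dxx, dyy, dzz
    d[:, 0, 1] = d[:, 1, 0] = dxy
    d[:, 0, 2] = d[:, 2, 0] = dxz
    d[:, 1, 2] = d[:, 2, 1] = dyz
    w_eig, v_eig = np.linalg.eigh(d)
    evals[valid] = w_eig[:, ::-1]
    e1[valid] = v_eig[:, :, 2]
    s0[valid] = np.exp(params[:, 0])
    return evals, e1, s0


def dti_md(t) -> float:
    """Mean diffusivity (lambda1 + lambda2 + lambda3) / 3."""
    ev = t.eigenvalues if isinstance(t, DiffusionTensor) else np.asarray(t, dtype=float)
    return float(np.mean(ev))


def dti_fa(t) -> float:
    """Fractional anisotropy; defined as 0 for the zero tensor."""
    ev = t.eigenvalues if isinstance(t, DiffusionTensor) else np.asarray(t, dtype=float)
    return float(fa_from_eigenvalues(ev[None, :])[0])


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Vectorized FA over (voxels, 3) eigenvalue arrays."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = ((evals - md) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)
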