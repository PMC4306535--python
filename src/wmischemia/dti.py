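"""Diffusion tensor fitting and FA / ADC scalar maps.

The tensor is estimated per voxel by ordinary (unweighted) log-linear least
squares on ln S_i = ln s0 - b g_i^T D g_i, the canonical baseline estimator.
It is exact on noiseless data, which is what makes the phantom round-trip
tests meaningful.  Negative eigenvalues (possible under noise) are clamped to
zero before computing FA and ADC so that FA stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScalarMap",
    "design_matrix",
    "fit_tensor",
    "fa_from_eigenvalues",
    "adc_from_eigenvalues",
    "compute_maps",
]


@dataclass
class ScalarMap:
    """A per-voxel scalar map on a regular grid.

    ``kind`` is one of ``"FA"`` (dimensionless), ``"ADC"`` (mm^2/s) or
    ``"Tmax"`` (s).  NaN marks voxels outside the mask or excluded by the fit.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("FA", "ADC", "Tmax"):
            raise ValueError(f"unknown map kind {self.kind!r}")


def design_matrix(directions: np.ndarray, bvals: np.ndarray) -> np.ndarray:
    """Log-linear design matrix: columns [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz] so that X @ [ln s0, Dxx, Dyy, Dzz,
    Dxy, Dxz, Dyz] = ln S."""
    g = np.asarray(directions, dtype=float)
    b = np.asarray(bvals, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ])


def _tensor_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """(..., 6) unique components -> (..., 3, 3) symmetric matrices."""
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(coeffs, -1, 0)
    out = np.empty(coeffs.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


def fit_tensor(dwi: np.ndarray, scheme, mask: np.ndarray | None = None):
    """Fit the diffusion tensor per voxel.

    Parameters
    ----------
    dwi : (X, Y, Z, n_volumes) signal array, volumes ordered as in ``scheme``.
    scheme : AcquisitionScheme with ``gradient_table()`` giving (directions,
        bvals) for every volume (b=0 rows have zero direction).
    mask : optional boolean (X, Y, Z) array; voxels outside are NaN.

    Returns
    -------
    tensor : (X, Y, Z, 3, 3) array of tensors (NaN outside mask / excluded).
    s0 : (X, Y, Z) baseline signal estimate.

    Voxels with any nonpositive signal cannot be log-transformed; they are
    excluded (NaN) rather than floored, per the error contract.
    """
    dwi = np.asarray(dwi, dtype=float)
    directions, bvals = scheme.gradient_table()
    n_vol = dwi.shape[-1]
    if n_vol != len(bvals):
        raise ValueError(
            f"DWI has {n_vol} volumes but scheme describes {len(bvals)}")
    n_dwi = int(np.sum(bvals > 0))
    if n_dwi < 6:
        raise ValueError("tensor fit needs at least 6 diffusion-weighted volumes")
    X = design_matrix(directions, bvals)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design matrix: directions are collinear")
    pinv = np.linalg.pinv(X)

    shape = dwi.shape[:-1]
    flat = dwi.reshape(-1, n_vol)
    if mask is None:
        sel = np.ones(flat.shape[0], dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool).reshape(-1)
    ok = sel & np.all(flat > 0, axis=1)

    coeffs = np.full((flat.shape[0], 7), np.nan)
    coeffs[ok] = np.log(flat[ok]) @ pinv.T

    tensor = np.full(shape + (3, 3), np.nan)
    tensor.reshape(-1, 3, 3)[ok] = _tensor_from_coeffs(coeffs[ok, 1:])
    s0 = np.full(shape, np.nan)
    s0.reshape(-1)[ok] = np.exp(coeffs[ok, 0])
    return tensor, s0


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy sqrt(3/2) * ||lambda - mean|| / ||lambda||.

    Accepts scalars or broadcastable arrays.  Eigenvalues are clamped at zero
    first; the zero tensor maps to FA = 0 (total function).
    """
    lam = np.stack(np.broadcast_arrays(
        np.clip(l1, 0, None), np.clip(l2, 0, None), np.clip(l3, 0, None)),
        axis=-1).astype(float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return fa if fa.ndim else float(fa)


def adc_from_eigenvalues(l1, l2, l3):
    """Mean diffusivity (lambda1 + lambda2 + lambda3) / 3 in mm^2/s."""
    out = (np.asarray(l1, dtype=float) + np.asarray(l2) + np.asarray(l3)) / 3.0
    return out if np.ndim(out) else float(out)


def compute_maps(dwi: np.ndarray, scheme, mask: np.ndarray | None = None,
                 voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)):
    """Tensor fit -> eigen-decomposition -> (FA map, ADC map).

    Eigenvalues are sorted descending and clamped at zero.  Voxels excluded by
    the fit (outside the mask or with nonpositive signal) are NaN in both maps.
    """
    tensor, _ = fit_tensor(dwi, scheme, mask)
    shape = tensor.shape[:-2]
    flat = tensor.reshape(-1, 3, 3)
    ok = np.isfinite(flat[:, 0, 0])
    fa = np.full(shape, np.nan).reshape(-1)
    adc = np.full(shape, np.nan).reshape(-1)
    if ok.any():
        evals = np.linalg.eigvalsh(flat[ok])[:, ::-1]  # descending
        evals = np.clip(evals, 0, None)
        fa[ok] = fa_from_eigenvalues(evals[:, 0], evals[:, 1], evals[:, 2])
        adc[ok] = adc_from_eigenvalues(evals[:, 0], evals[:, 1], evals[:, 2])
    return (ScalarMap(fa.reshape(shape), voxel_size, "FA"),
            ScalarMap(adc.reshape(shape), voxel_size, "ADC"))
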