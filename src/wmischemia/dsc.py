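"""DSC perfusion: signal-to-concentration conversion, block-circulant SVD
deconvolution, and Tmax maps.

The deconvolution solves c = A k for the flow-scaled residue function k(t) =
CBF * R(t - delay), where A is the convolution matrix of the arterial input
function (AIF).  A is built *block-circulant* at zero-padded length 2N, which
makes the inverse insensitive to bolus arrival delay: circularly shifting the
tissue curve circularly shifts the recovered residue.  Regularization is a
fixed global truncation of singular values below ``threshold_frac`` times the
largest.  Tmax is the time at which the recovered residue peaks, reported on
the acquisition grid (multiples of TR) or, optionally, with parabolic
sub-sample interpolation around the peak.
"""

from __future__ import annotations

import numpy as np

from .dti import ScalarMap

__all__ = [
    "signal_to_concentration",
    "block_circulant_matrix",
    "deconvolution_operator",
    "deconvolve_osvd",
    "tmax_from_residue",
    "tmax_map",
    "fit_tmax",
]

_SIGNAL_FLOOR = 1e-6


def signal_to_concentration(signal: np.ndarray, te: float, baseline_n: int):
    """Convert DSC signal S(t) to DeltaR2* concentration -ln(S/S0)/TE.

    ``signal`` may be a single time series (N,) or an array (..., N); the
    baseline S0 is the mean of the first ``baseline_n`` samples per voxel.
    Nonpositive samples are clipped to a small positive floor before the log
    (the returned ``flagged`` mask marks voxels where this happened).
    All-zero (or nonpositive-baseline) voxels are excluded as NaN.

    Returns ``(conc, flagged)``.
    """
    if baseline_n < 3:
        raise ValueError("baseline_n must be >= 3")
    s = np.asarray(signal, dtype=float)
    s0 = s[..., :baseline_n].mean(axis=-1, keepdims=True)
    bad = (s0 <= 0)[..., 0]
    flagged = np.any(s <= 0, axis=-1) & ~bad
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = -np.log(np.clip(s, _SIGNAL_FLOOR, None)
                       / np.where(s0 > 0, s0, 1.0)) / te
    conc[bad] = np.nan
    return conc, flagged


def block_circulant_matrix(aif: np.ndarray, dt: float) -> np.ndarray:
    """Circulant convolution matrix of the AIF at zero-padded length 2N.

    Row i, column j holds aif[(i - j) mod 2N] * dt, so that A @ k is the
    circular discrete convolution of the (zero-padded) AIF with k.
    """
    a = np.asarray(aif, dtype=float)
    n = a.size
    pad = np.concatenate([a, np.zeros(n)])
    idx = (np.arange(2 * n)[:, None] - np.arange(2 * n)[None, :]) % (2 * n)
    return pad[idx] * dt


def deconvolution_operator(aif: np.ndarray, dt: float,
                           threshold_frac: float = 0.10) -> np.ndarray:
    """Truncated-SVD pseudo-inverse of the block-circulant AIF matrix.

    Singular values below ``threshold_frac`` times the largest are discarded.
    The returned (2N, 2N) matrix maps a zero-padded tissue curve to the
    residue estimate.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    aif = np.asarray(aif, dtype=float)
    if not np.any(aif):
        raise ValueError("AIF is identically zero")
    A = block_circulant_matrix(aif, dt)
    u, s, vt = np.linalg.svd(A)
    keep = s >= threshold_frac * s[0]
    s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return (vt.T * s_inv) @ u.T


def deconvolve_osvd(tissue: np.ndarray, aif: np.ndarray, dt: float,
                    threshold_frac: float = 0.10) -> np.ndarray:
    """Deconvolve tissue concentration curve(s) against the AIF.

    ``tissue`` is (N,) or (..., N) with the same N as ``aif``.  Returns the
    flow-scaled residue k(t) with the same leading shape and N samples (the
    2N-padded estimate truncated back to the acquisition window).
    """
    tissue = np.asarray(tissue, dtype=float)
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    if tissue.shape[-1] != n:
        raise ValueError("tissue and AIF lengths differ")
    op = deconvolution_operator(aif, dt, threshold_frac)
    padded = np.concatenate(
        [tissue, np.zeros(tissue.shape[:-1] + (n,))], axis=-1)
    k = padded @ op.T
    return k[..., :n]


def tmax_from_residue(k: np.ndarray, dt: float,
                      interpolate: bool = False) -> np.ndarray:
    """Time of the residue peak: argmax * dt, optionally refined by fitting a
    parabola through the peak and its two neighbours.

    Works on (N,) or (..., N); all-zero or non-finite residues give NaN.
    """
    k = np.asarray(k, dtype=float)
    scalar = k.ndim == 1
    k2 = k.reshape(-1, k.shape[-1])
    bad = ~np.all(np.isfinite(k2), axis=-1) | np.all(k2 == 0, axis=-1)
    safe = np.where(np.isfinite(k2), k2, -np.inf)
    idx = np.argmax(safe, axis=-1)
    t = idx.astype(float) * dt
    if interpolate:
        n = k2.shape[-1]
        interior = (idx > 0) & (idx < n - 1) & ~bad
        ii = idx[interior]
        rows = np.nonzero(interior)[0]
        y0 = k2[rows, ii - 1]
        y1 = k2[rows, ii]
        y2 = k2[rows, ii + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(denom != 0, 0.5 * (y0 - y2)
                         / np.where(denom != 0, denom, 1.0), 0.0)
        t[interior] = (ii + shift) * dt
    t[bad] = np.nan
    return float(t[0]) if scalar else t.reshape(k.shape[:-1])


def tmax_map(residues: np.ndarray, dt: float, mask: np.ndarray | None = None,
             interpolate: bool = False,
             voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> ScalarMap:
    """Tmax ScalarMap from per-voxel residues (X, Y, Z, N)."""
    t = tmax_from_residue(residues, dt, interpolate=interpolate)
    if mask is not None:
        t = np.where(np.asarray(mask, dtype=bool), t, np.nan)
    return ScalarMap(t, voxel_size, "Tmax")


def fit_tmax(dsc: np.ndarray, aif: np.ndarray, scheme,
             mask: np.ndarray | None = None, baseline_n: int = 8,
             threshold_frac: float = 0.10, interpolate: bool = False,
             voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> ScalarMap:
    """Signal (X, Y, Z, T) + AIF concentration curve -> Tmax map.

    Convenience composition of signal_to_concentration, deconvolve_osvd and
    tmax_map using the scheme's TR and TE.
    """
    conc, _ = signal_to_concentration(dsc, scheme.dsc_te, baseline_n)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        conc = np.where(m[..., None], conc, 0.0)
    conc = np.where(np.isfinite(conc), conc, 0.0)
    k = deconvolve_osvd(conc, aif, scheme.dsc_tr, threshold_frac)
    return tmax_map(k, scheme.dsc_tr, mask=mask, interpolate=interpolate,
                    voxel_size=voxel_size)
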