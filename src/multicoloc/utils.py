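"""Shared numerical helpers (log-space reductions, PSD repair)."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["logsumexp", "logsumexp_excluding", "nearest_psd", "check_correlation"]


def logsumexp_excluding(a: np.ndarray) -> np.ndarray:
    """For a 1-D log-value array ``a`` return ``r`` with
    ``r[j] = logsumexp(a with element j removed)``.

    Runs in O(Q log Q). Stable: for every j other than the argmax the
    remaining sum is dominated by the maximum, which stays in place; the
    argmax entry is recomputed exactly on the deleted array.
    """
    a = np.asarray(a, dtype=float)
    q = a.shape[0]
    if q < 2:
        raise ValueError("need at least two entries to exclude one")
    jmax = int(np.argmax(a))
    m = a[jmax]
    shifted = np.exp(a - m)
    total = shifted.sum()
    with np.errstate(divide="ignore"):
        r = m + np.log(total - shifted)
    r[jmax] = logsumexp(np.delete(a, jmax))
    return r


def nearest_psd(mat: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation-like matrix.

    Negative eigenvalues are clipped at ``eig_floor`` and the diagonal is
    renormalized back to one.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= 0:
        out = sym
    else:
        vals = np.clip(vals, eig_floor, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def check_correlation(mat: np.ndarray, name: str = "correlation", tol: float = 1e-8) -> np.ndarray:
    """Validate a correlation matrix: square, symmetric, unit diagonal,
    entries in [-1, 1], PSD within ``tol`` on the smallest eigenvalue."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise ValueError(f"{name} must have unit diagonal")
    if np.any(np.abs(mat) > 1 + 1e-8):
        raise ValueError(f"{name} entries must lie in [-1, 1]")
    if np.linalg.eigvalsh(mat).min() < -tol:
        raise ValueError(f"{name} is not positive semidefinite within {tol}")
    return mat
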