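"""Algebraic circle fitting in 2D.

:func:`hyper_fit` is the "Hyper" (hyperaccurate) algebraic fit of
Al-Sharadqah & Chernov (2009): it solves the same generalized eigenproblem
family as the Pratt and Taubin fits but with a constraint matrix chosen so
the leading bias term of the radius estimate vanishes. It is exact on
noiseless circles and, on noisy data, its radius bias is an order smaller
than the naive Kåsa least-squares fit (:func:`kasa_fit`, kept here as the
comparison baseline).
"""

from __future__ import annotations

import numpy as np

__all__ = ["hyper_fit", "kasa_fit"]


def hyper_fit(xy: np.ndarray, max_iter: int = 99, tol: float = 1e-12):
    """Hyperaccurate algebraic circle fit.

    Parameters
    ----------
    xy:
        (N, 2) sample points, N >= 3.

    Returns
    -------
    (cx, cy, r):
        Circle center and radius.
    """
    xy = np.asarray(xy, dtype=np.float64).reshape(-1, 2)
    if len(xy) < 3:
        raise ValueError("need at least 3 points to fit a circle")
    mean = xy.mean(axis=0)
    x = xy[:, 0] - mean[0]
    y = xy[:, 1] - mean[1]
    z = x * x + y * y

    mxx = np.mean(x * x)
    myy = np.mean(y * y)
    mxy = np.mean(x * y)
    mxz = np.mean(x * z)
    myz = np.mean(y * z)
    mzz = np.mean(z * z)

    mz = mxx + myy
    cov_xy = mxx * myy - mxy * mxy
    var_z = mzz - mz * mz

    a2 = 4.0 * cov_xy - 3.0 * mz * mz - mzz
    a1 = var_z * mz + 4.0 * cov_xy * mz - mxz * mxz - myz * myz
    a0 = (mxz * (mxz * myy - myz * mxy)
          + myz * (myz * mxx - mxz * mxy)
          - var_z * cov_xy)
    a22 = a2 + a2

    # Newton iteration on the characteristic polynomial, from eta = 0; the
    # relevant root is the smallest non-negative one and Newton from 0
    # converges to it monotonically.
    eta = 0.0
    val = a0
    for _ in range(max_iter):
        deriv = a1 + eta * (a22 + 16.0 * eta * eta)
        if deriv == 0.0:
            break
        eta_new = eta - val / deriv
        if not np.isfinite(eta_new) or abs(eta_new - eta) <= tol * (1 + abs(eta)):
            eta = eta_new
            break
        eta = eta_new
        val = a0 + eta * (a1 + eta * (a2 + 4.0 * eta * eta))
        if abs(val) <= tol:
            break

    det = eta * eta - eta * mz + cov_xy
    if det == 0.0:
        raise ValueError("degenerate point configuration (collinear points?)")
    cx = (mxz * (myy - eta) - myz * mxy) / det / 2.0
    cy = (myz * (mxx - eta) - mxz * mxy) / det / 2.0
    r = float(np.sqrt(cx * cx + cy * cy + mz + 2.0 * eta))
    return float(cx + mean[0]), float(cy + mean[1]), r


def kasa_fit(xy: np.ndarray):
    """Naive Kåsa algebraic fit (linear least squares on x²+y²+Dx+Ey+F=0).

    Kept as the baseline the hyperaccurate fit is compared against: on
    noisy or partial arcs its radius estimate is biased toward smaller
    circles.
    """
    xy = np.asarray(xy, dtype=np.float64).reshape(-1, 2)
    if len(xy) < 3:
        raise ValueError("need at least 3 points to fit a circle")
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    (d, e, f), *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = d / 2.0, e / 2.0
    r = float(np.sqrt(f + cx * cx + cy * cy))
    return float(cx), float(cy), r
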