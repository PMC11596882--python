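"""Independent reference implementations used only to check the package.

These deliberately share no code with ``nirpls``: SIMPLS (de Jong 1993)
as a second PLS algorithm (for univariate y its coefficients coincide
with NIPALS PLS1), closed-form normal equations for straight-line fits,
and a brute-force local polynomial fit for Savitzky-Golay interiors.
"""

from __future__ import annotations

import numpy as np


def simpls_coefficients(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """SIMPLS regression vector for a univariate response.

    Returns b such that yhat = mean(y) + (X - mean(X)) @ b.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    s = Xc.T @ yc
    R, V, Q = [], [], []
    for _ in range(n_components):
        r = s.copy()
        t = Xc @ r
        normt = np.linalg.norm(t)
        t /= normt
        r /= normt
        p = Xc.T @ t
        Q.append(float(yc @ t))
        v = p.copy()
        for vprev in V:
            v -= (vprev @ p) * vprev
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        R.append(r)
        V.append(v)
    return np.column_stack(R) @ np.asarray(Q)


def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares regression vector on centered data (lstsq)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.lstsq(Xc, yc, rcond=None)[0]


def line_fit_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Straight-line fit y ~ a + b x via the 2x2 normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    b = (n * sxy - sx * sy) / det
    a = (sy - b * sx) / n
    return a, b


def sg_pointwise(x: np.ndarray, i: int, order: int, window: int,
                 polyorder: int) -> float:
    """Derivative at interior index i from a direct polynomial fit over
    the centered window (the definition of Savitzky-Golay smoothing)."""
    half = window // 2
    idx = np.arange(-half, half + 1, dtype=float)
    seg = x[i - half: i + half + 1]
    coef = np.polyfit(idx, seg, polyorder)
    return float(np.polyval(np.polyder(coef, order), 0.0))
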