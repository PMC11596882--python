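"""Univariate-response partial least squares regression (NIPALS).

The model projects mean-centered spectra X onto successive latent
components that maximize covariance with the mean-centered response y
(analyte content, w/w%).  For a single response the NIPALS weight step
is closed-form: w_a = X_a' y_a / ||X_a' y_a||, t_a = X_a w_a, followed
by rank-one deflation of X (and y).  Components are nested, so one fit
at the maximum component count yields predictions for every smaller
count — which is how the cross-validation routine stays cheap.

Channels are mean-centered but not autoscaled: all wavenumber channels
share the same physical units, so unit-variance scaling would only
amplify noise-dominated channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-13


@dataclass
class PLSModel:
    """Fitted NIPALS state.

    Attributes
    ----------
    n_components : number of extracted latent components N.
    x_mean, y_mean : centering terms.
    weights : (p, N) deflated-X weights W.
    x_loadings : (p, N) X loadings P.
    y_loadings : (N,) per-component y loadings q.
    scores : (n, N) training scores T (mutually orthogonal columns).
    coefficients : (p,) regression vector b on centered data, so that
        yhat = y_mean + (X - x_mean) @ b.
    explained_x_variance : (N,) percent of the centered-X sum of squares
        removed by each deflation step.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coefficients: np.ndarray
    explained_x_variance: np.ndarray


def _nipals(Xc: np.ndarray, yc: np.ndarray, max_components: int):
    """Run NIPALS on centered data; stops early if X or y is exhausted.

    Returns (W, P, q, T, explained) with as many columns as could be
    extracted (possibly zero).
    """
    Xc = Xc.copy()
    yc = yc.copy()
    n, p = Xc.shape
    ssx = float((Xc**2).sum())
    W, P, T, q, ev = [], [], [], [], []
    w0 = np.linalg.norm(Xc.T @ yc)
    for _ in range(max_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= _EPS * max(1.0, w0):
            break
        w = w / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t / tt)
        Xc -= np.outer(t, pvec)
        yc = yc - qa * t
        W.append(w)
        P.append(pvec)
        T.append(t)
        q.append(qa)
        ev.append(100.0 * tt * float(pvec @ pvec) / ssx if ssx > 0 else 0.0)
    if not W:
        shape = (p, 0)
        return (np.empty(shape), np.empty(shape), np.zeros(0), np.empty((n, 0)),
                np.zeros(0))
    return (np.column_stack(W), np.column_stack(P), np.asarray(q),
            np.column_stack(T), np.asarray(ev))


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """b_k = W_k (P_k' W_k)^-1 q_k for the first k components."""
    if k == 0:
        return np.zeros(W.shape[0])
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS1 model with exactly ``n_components`` latent components.

    Raises if the response has zero variance or the requested component
    count exceeds the rank of the centered X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if y.shape != (n,):
        raise ValueError("y must be a vector with one entry per row of X")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T, ev = _nipals(X - x_mean, y - y_mean, n_components)
    if W.shape[1] < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds the rank of centered X "
            f"(extracted {W.shape[1]})"
        )
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=_coefficients(W, P, q, n_components),
        explained_x_variance=ev,
    )


def predict(model: PLSModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """yhat = y_mean + (X - x_mean) @ b; predictions are never clipped."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X.shape[1]} channels, model was trained on {model.x_mean.size}"
        )
    if n_components is None:
        b = model.coefficients
    else:
        if not 1 <= n_components <= model.n_components:
            raise ValueError("n_components out of fitted range")
        b = _coefficients(model.weights, model.x_loadings, model.y_loadings,
                          n_components)
    return model.y_mean + (X - model.x_mean) @ b


def variance_contributions(model: PLSModel) -> np.ndarray:
    """Percent of the centered-X total sum of squares captured per
    component (the deflation bookkeeping of the fit)."""
    return model.explained_x_variance.copy()


def cumulative_variance(model: PLSModel) -> np.ndarray:
    return np.cumsum(model.explained_x_variance)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """RMSECV for component counts 1..K by leave-one-group-out CV.

    ``groups`` identifies the physical sample of each spectrum; all
    replicates of a sample are held out together (no replicate leakage).
    With ``groups=None`` every row is its own group (leave-one-out).
    K is ``max_components`` capped at what the smallest training fold can
    support; if a fold's X is exhausted before k components, the largest
    attainable model is used for the remaining counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    groups = np.arange(n) if groups is None else np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("cross-validation needs at least 2 groups")
    min_train = min(int(n - (groups == g).sum()) for g in uniq)
    if min_train < 2:
        raise ValueError("a CV fold has fewer than 2 training samples")
    cap = int(min(max_components, min_train - 1, p))
    preds = np.empty((n, cap))
    for g in uniq:
        test = groups == g
        Xtr, ytr = X[~test], y[~test]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, q, _, _ = _nipals(Xtr - x_mean, ytr - y_mean, cap)
        m = W.shape[1]
        Xt = X[test] - x_mean
        for k in range(1, cap + 1):
            b = _coefficients(W, P, q, min(k, m))
            preds[test, k - 1] = y_mean + Xt @ b
    resid = y[:, None] - preds
    return np.sqrt((resid**2).mean(axis=0))


def select_n_components(rmsecv_curve: np.ndarray, tol_rel: float = 0.02) -> int:
    """Parsimonious component count: the smallest k whose RMSECV lies
    within ``tol_rel`` (relative) of the curve minimum."""
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    cmin = np.nanmin(curve)
    threshold = cmin * (1.0 + tol_rel)
    return int(np.argmax(curve <= threshold)) + 1


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def model_to_dict(model: PLSModel) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "n_components": model.n_components,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "scores": model.scores.tolist(),
        "coefficients": model.coefficients.tolist(),
        "explained_x_variance": model.explained_x_variance.tolist(),
    }


def model_from_dict(data: dict) -> PLSModel:
    if data.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {data.get('format_version')!r}")
    return PLSModel(
        n_components=int(data["n_components"]),
        x_mean=np.asarray(data["x_mean"], dtype=float),
        y_mean=float(data["y_mean"]),
        weights=np.asarray(data["weights"], dtype=float),
        x_loadings=np.asarray(data["x_loadings"], dtype=float),
        y_loadings=np.asarray(data["y_loadings"], dtype=float),
        scores=np.asarray(data["scores"], dtype=float),
        coefficients=np.asarray(data["coefficients"], dtype=float),
        explained_x_variance=np.asarray(data["explained_x_variance"], dtype=float),
    )
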