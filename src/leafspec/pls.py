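"""Single-response partial least squares regression (PLS1, NIPALS).

PLSR projects the predictor matrix onto a small number of orthogonal
latent variables, each a linear combination of the original bands chosen
to maximise covariance with the response, and regresses the response on
those scores.  Unlike ordinary least squares it is well defined when the
bands outnumber the samples and when bands are collinear — the regime of
1-nm spectroscopy, where ~1400 highly correlated bands describe a few
dozen plants.

Predictors and response are mean-centred; bands are not scaled to unit
variance by default because reflectance-type spectra already share a
common physical scale (scaling is available as a switch).  With the
number of latent variables equal to the rank of the centred predictor
matrix, the PLS coefficients coincide with the least-squares solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONVERGENCE_TOL = 1e-10
MAX_INNER_ITERATIONS = 500

DEFAULT_NLV_CAP = 15


def default_nlv_max(n_train: int) -> int:
    """Default cap on latent variables: min(n_train - 2, 15)."""
    return max(1, min(n_train - 2, DEFAULT_NLV_CAP))


@dataclass
class PLSModel:
    """Fitted PLS1 model with nested coefficient vectors for every k <= nlv_max.

    ``coef[k - 1]`` is the regression-coefficient vector of the
    k-component model on the original (centred) band scale, so that
    predictions are ``y_mean + (X - x_mean) @ coef[k - 1]``.
    """

    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray
    weights: np.ndarray      # bands x nlv_max
    x_loadings: np.ndarray   # bands x nlv_max
    y_loadings: np.ndarray   # nlv_max
    scores: np.ndarray       # samples x nlv_max
    coef: np.ndarray         # nlv_max x bands
    nlv_max: int

    @property
    def n_bands(self) -> int:
        return self.x_mean.size

    def predict(self, X_new: np.ndarray, nlv: int) -> np.ndarray:
        return predict(self, X_new, nlv)

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "x_scale": self.x_scale.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "nlv_max": self.nlv_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.zeros((0, int(d["nlv_max"]))),
            coef=np.asarray(d["coef"], dtype=float),
            nlv_max=int(d["nlv_max"]),
        )


def fit_plsr(
    X: np.ndarray, y: np.ndarray, nlv_max: int | None = None,
    scale: bool = False,
) -> PLSModel:
    """Fit PLS1 by the NIPALS sequence.

    For a single response the NIPALS inner iteration converges in one
    pass, so each component is extracted directly: weight w proportional
    to X_r' y_r, score t = X_r w, loadings p = X_r't/t't and q = y_r't/t't,
    then rank-one deflation of X_r and y_r.  Extraction stops early if
    the residual covariance vanishes (tolerance 1e-10); coefficient
    vectors are produced for every component count up to ``nlv_max``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x bands)")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has length {y.size}, X has {n} rows")
    if n < 3:
        raise ValueError("PLSR needs at least 3 samples")
    if np.var(y) == 0:
        raise ValueError("response is constant (zero variance)")
    if nlv_max is None:
        nlv_max = min(default_nlv_max(n), p)
    if not 1 <= nlv_max <= min(n - 1, p):
        raise ValueError(
            f"nlv_max={nlv_max} outside valid range [1, {min(n - 1, p)}]"
        )

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    Xr = (X - x_mean) / x_scale
    yr = y - y_mean

    W = np.zeros((p, nlv_max))
    P = np.zeros((p, nlv_max))
    Q = np.zeros(nlv_max)
    T = np.zeros((n, nlv_max))

    n_extracted = 0
    for a in range(nlv_max):
        w = Xr.T @ yr
        wn = np.linalg.norm(w)
        if wn <= CONVERGENCE_TOL:
            break
        w /= wn
        t = Xr @ w
        tt = float(t @ t)
        if tt <= CONVERGENCE_TOL:
            break
        W[:, a] = w
        P[:, a] = Xr.T @ t / tt
        Q[a] = float(yr @ t) / tt
        T[:, a] = t
        Xr -= np.outer(t, P[:, a])
        yr = yr - Q[a] * t
        n_extracted = a + 1

    if n_extracted == 0:
        raise ValueError("no latent variable could be extracted "
                         "(response uncorrelated with all bands)")

    # Nested coefficients: B_k = W_k (P_k' W_k)^{-1} q_k on the scaled axis.
    coef = np.zeros((n_extracted, p))
    for k in range(1, n_extracted + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], Q[:k]
        beta = Wk @ np.linalg.solve(Pk.T @ Wk, qk)
        coef[k - 1] = beta / x_scale

    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, x_scale=x_scale,
        weights=W[:, :n_extracted], x_loadings=P[:, :n_extracted],
        y_loadings=Q[:n_extracted], scores=T[:, :n_extracted],
        coef=coef, nlv_max=n_extracted,
    )


def predict(model: PLSModel, X_new: np.ndarray, nlv: int) -> np.ndarray:
    """Predict with the first ``nlv`` latent variables (0 = the mean model)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_bands:
        raise ValueError(
            f"X_new has {X_new.shape[1]} bands, model expects {model.n_bands}"
        )
    if not 0 <= nlv <= model.nlv_max:
        raise ValueError(f"nlv={nlv} outside [0, {model.nlv_max}]")
    if nlv == 0:
        return np.full(X_new.shape[0], model.y_mean)
    return model.y_mean + (X_new - model.x_mean) @ model.coef[nlv - 1]


def rmse(observed, predicted) -> float:
    """Root mean square error between observed and predicted values."""
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} observed, {p.size} predicted")
    if o.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot is taken about the observed mean, so the value may be
    negative: below zero means the model's residuals exceed those of
    simply predicting the mean observation.
    """
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} observed, {p.size} predicted")
    if o.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant")
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot
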