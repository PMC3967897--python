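"""Leave-one-out validation, latent-variable choice, and band selection.

The number of latent variables is chosen to minimise the RMSE of
leave-one-out (LOO) validation.  For each LOO fitting the regression
coefficients are recorded; a two-sided one-sample t-test per band asks
whether the mean fold coefficient differs from zero, and a band is
retained when P < alpha (0.1 by default).  Models are then refitted
iteratively on the significant bands of the prior run, until all
retained bands are significant or until cropping no longer improves the
validation RMSE (strictly).  If no band at all is significant, all
current bands are retained and the loop stops.

The fold coefficients of LOO models are strongly dependent (each pair of
training sets shares all but two samples), so the per-band t-test is
anti-conservative relative to its nominal level; it is used here as the
stated selection heuristic, not as calibrated inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pls import PLSModel, default_nlv_max, fit_plsr, predict, r_squared, rmse

DEFAULT_ALPHA = 0.1
DEFAULT_MAX_ITERATIONS = 20


@dataclass
class FitMetrics:
    """Calibration/validation accuracy of one fitted model."""

    nlv: int
    r2_cal: float
    r2_val: float
    rmse_cal: float
    rmse_val: float
    n_bands: int

    def to_dict(self) -> dict:
        return {
            "nlv": self.nlv, "r2_cal": self.r2_cal, "r2_val": self.r2_val,
            "rmse_cal": self.rmse_cal, "rmse_val": self.rmse_val,
            "n_bands": self.n_bands,
        }


@dataclass
class LooResult:
    """Held-out predictions and fold coefficients from LOO validation.

    ``predictions[i, k-1]`` is the prediction for sample i from the
    k-component model fitted without sample i; ``fold_coefs[i, k-1]`` the
    corresponding coefficient vector.  ``rmse_val``/``r2_val`` are indexed
    by k - 1.
    """

    predictions: np.ndarray   # samples x nlv
    rmse_val: np.ndarray      # nlv
    r2_val: np.ndarray        # nlv
    fold_coefs: np.ndarray    # samples x nlv x bands

    @property
    def nlv_available(self) -> int:
        return self.predictions.shape[1]

    def coefs_at(self, nlv: int) -> np.ndarray:
        """Folds x bands coefficient matrix at a given component count."""
        return self.fold_coefs[:, nlv - 1, :]


def loo_validate(X: np.ndarray, y: np.ndarray, nlv_max: int | None = None,
                 scale: bool = False) -> LooResult:
    """Leave-one-out validation of PLS1 at every component count.

    Each sample is predicted by a model fitted on the remaining n - 1
    samples, at every nlv up to min(nlv_max, n - 3, bands); the held-out
    predictions give the validation RMSE and r^2 per nlv.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 4:
        raise ValueError("LOO validation needs at least 4 samples")
    cap = default_nlv_max(n) if nlv_max is None else nlv_max
    k_max = max(1, min(cap, n - 3, p))

    predictions = np.full((n, k_max), np.nan)
    fold_coefs = np.zeros((n, k_max, p))
    for i in range(n):
        keep = np.arange(n) != i
        m = fit_plsr(X[keep], y[keep], nlv_max=k_max, scale=scale)
        for k in range(1, k_max + 1):
            kk = min(k, m.nlv_max)  # degenerate folds may extract fewer LVs
            predictions[i, k - 1] = predict(m, X[i:i + 1], kk)[0]
            fold_coefs[i, k - 1] = m.coef[kk - 1]

    rmse_val = np.array([rmse(y, predictions[:, k]) for k in range(k_max)])
    r2_val = np.array([r_squared(y, predictions[:, k]) for k in range(k_max)])
    return LooResult(predictions, rmse_val, r2_val, fold_coefs)


def select_nlv(loo: LooResult) -> int:
    """Component count minimising LOO RMSE; ties go to the smaller count."""
    if loo.rmse_val.size == 0:
        raise ValueError("empty validation curve")
    return int(np.argmin(loo.rmse_val)) + 1


def band_significance(
    fold_coefs: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided one-sample t-test of fold coefficients against zero.

    Returns ``(p_values, significant)`` per band, significant meaning
    p < alpha.  Degenerate bands with zero variance across folds get
    p = 0 when the common value is non-zero and p = 1 when it is zero.
    """
    fold_coefs = np.asarray(fold_coefs, dtype=float)
    if fold_coefs.ndim != 2 or fold_coefs.shape[0] < 3:
        raise ValueError("need a folds x bands matrix with at least 3 folds")
    mean = fold_coefs.mean(axis=0)
    sd = fold_coefs.std(axis=0, ddof=1)
    p_values = np.ones(fold_coefs.shape[1])
    regular = sd > 0
    if regular.any():
        res = stats.ttest_1samp(fold_coefs[:, regular], 0.0, axis=0)
        p_values[regular] = res.pvalue
    p_values[(~regular) & (mean != 0)] = 0.0
    p_values[(~regular) & (mean == 0)] = 1.0
    return p_values, p_values < alpha


@dataclass
class SelectionResult:
    """Outcome of the iterative band-selection loop.

    ``band_mask`` indicates the finally retained bands over the original
    axis; ``metrics`` records one entry per accepted iteration and
    ``final_model`` is the all-sample refit on the retained bands at the
    selected component count.
    """

    band_mask: np.ndarray
    nlv: int
    metrics: list[FitMetrics]
    p_values: np.ndarray
    iterations: int
    stop_reason: str
    final_model: PLSModel
    loo: LooResult = field(repr=False, default=None)

    @property
    def final_metrics(self) -> FitMetrics:
        return self.metrics[-1]


def _evaluate(X, y, mask, nlv_max, scale):
    """LOO + nlv choice + all-sample refit on the bands selected by mask."""
    Xm = X[:, mask]
    loo = loo_validate(Xm, y, nlv_max=nlv_max, scale=scale)
    nlv = select_nlv(loo)
    model = fit_plsr(Xm, y, nlv_max=max(nlv, 1), scale=scale)
    nlv_eff = min(nlv, model.nlv_max)
    fitted = predict(model, Xm, nlv_eff)
    metrics = FitMetrics(
        nlv=nlv_eff,
        r2_cal=r_squared(y, fitted),
        r2_val=float(loo.r2_val[nlv - 1]),
        rmse_cal=rmse(y, fitted),
        rmse_val=float(loo.rmse_val[nlv - 1]),
        n_bands=int(mask.sum()),
    )
    return loo, nlv, model, metrics


def iterative_band_selection(
    X: np.ndarray,
    y: np.ndarray,
    nlv_max: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    scale: bool = False,
) -> SelectionResult:
    """Iteratively crop the predictors to the significant bands.

    Each pass runs LOO validation on the current bands, picks the
    component count minimising validation RMSE, and t-tests the fold
    coefficients per band.  If every band is significant the loop stops
    (``all_significant``); if none is, all current bands are retained and
    the loop stops; otherwise the model is refitted on the significant
    bands and the crop is kept only if it strictly lowers the validation
    RMSE (``no_improvement`` otherwise, returning the pre-crop model).
    Masks are nested: retained bands never grow across iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a non-empty samples x bands matrix")
    n_bands = X.shape[1]
    mask = np.ones(n_bands, dtype=bool)

    loo, nlv, model, metrics = _evaluate(X, y, mask, nlv_max, scale)
    history = [metrics]
    p_full = np.full(n_bands, np.nan)
    p_values, significant = band_significance(loo.coefs_at(metrics.nlv), alpha)
    p_full[mask] = p_values
    iterations = 1
    stop_reason = "max_iterations"

    while iterations <= max_iterations:
        if significant.all():
            stop_reason = "all_significant"
            break
        if not significant.any():
            # no significant band: retain all current bands
            stop_reason = "no_improvement"
            break
        candidate = mask.copy()
        candidate[np.flatnonzero(mask)[~significant]] = False
        c_loo, c_nlv, c_model, c_metrics = _evaluate(
            X, y, candidate, nlv_max, scale)
        if c_metrics.rmse_val >= metrics.rmse_val:
            stop_reason = "no_improvement"
            break
        mask, loo, nlv, model, metrics = candidate, c_loo, c_nlv, c_model, c_metrics
        history.append(metrics)
        p_full = np.full(n_bands, np.nan)
        p_values, significant = band_significance(loo.coefs_at(metrics.nlv), alpha)
        p_full[mask] = p_values
        iterations += 1

    return SelectionResult(
        band_mask=mask, nlv=metrics.nlv, metrics=history,
        p_values=p_full, iterations=iterations, stop_reason=stop_reason,
        final_model=model, loo=loo,
    )
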