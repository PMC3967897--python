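"""Model/Results interface tying spectra to one trait.

:class:`SpectralTraitModel` is constructed from a spectral matrix and a
trait vector; :meth:`fit` runs the full estimation procedure — PLS1 with
leave-one-out selection of the latent-variable count and, optionally,
iterative significance-based band selection — and returns a
:class:`SpectralTraitResults` carrying the coefficients, accuracy
metrics, retained bands, per-band p-values and held-out predictions,
with a ``summary()`` table and JSON-serialisable report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bandstats import band_correlations
from .containers import SpectralMatrix
from .pls import PLSModel, predict, r_squared, rmse
from .selection import (
    DEFAULT_ALPHA,
    DEFAULT_MAX_ITERATIONS,
    SelectionResult,
    iterative_band_selection,
)
from .traits import log_transform


class SpectralTraitModel:
    """Predict one leaf trait from one spectrum kind via PLSR.

    Parameters
    ----------
    spectra : SpectralMatrix
        Plants x bands predictor matrix with its wavelength axis.
    trait : array-like or pandas.Series
        One trait value per plant, aligned with ``spectra.plant_ids``.
    trait_name : str
        Label used in summaries and reports.
    log10 : bool
        Model the base-10 logarithm of the trait (requires positive
        values).  Off by default; the command-line pipeline switches it
        on to mirror the usual right-skew of trait distributions.
    nlv_max : int or None
        Cap on latent variables; ``None`` uses min(n - 2, 15).
    alpha : float
        Per-band significance threshold of the fold-coefficient t-test.
    scale : bool
        Autoscale bands to unit variance before fitting (off by default;
        reflectance-type spectra share a physical scale).
    """

    def __init__(self, spectra: SpectralMatrix, trait, trait_name: str = "trait",
                 log10: bool = False, nlv_max: int | None = None,
                 alpha: float = DEFAULT_ALPHA, scale: bool = False):
        y = np.asarray(trait, dtype=float).ravel()
        if y.size != spectra.n_plants:
            raise ValueError(
                f"trait has {y.size} values for {spectra.n_plants} plants")
        self.spectra = spectra
        self.trait_name = trait_name
        self.log10 = log10
        self.y = log_transform(y, spectra.plant_ids) if log10 else y
        self.nlv_max = nlv_max
        self.alpha = alpha
        self.scale = scale

    @classmethod
    def from_tables(cls, spectra: SpectralMatrix, traits: pd.DataFrame,
                    trait_name: str, **kwargs) -> "SpectralTraitModel":
        """Align a trait table with a spectral matrix on plant_id."""
        if trait_name not in traits.columns:
            raise ValueError(f"trait table has no column {trait_name!r}")
        table = traits.set_index(traits["plant_id"].astype(str))
        common = [p for p in spectra.plant_ids if p in table.index]
        if not common:
            raise ValueError("no plant occurs in both spectra and trait table")
        sub = spectra.select_plants(common)
        y = table.loc[common, trait_name].to_numpy(dtype=float)
        return cls(sub, y, trait_name=trait_name, **kwargs)

    def fit(self, band_selection: bool = True,
            max_iterations: int = DEFAULT_MAX_ITERATIONS) -> "SpectralTraitResults":
        """Estimate the model and return a results object."""
        selection = iterative_band_selection(
            self.spectra.values, self.y, nlv_max=self.nlv_max,
            alpha=self.alpha, scale=self.scale,
            max_iterations=max_iterations if band_selection else 0,
        )
        return SpectralTraitResults(self, selection)


@dataclass
class SpectralTraitResults:
    """Fitted trait-spectrum model with accuracy metrics and diagnostics."""

    model: SpectralTraitModel
    selection: SelectionResult

    @property
    def pls(self) -> PLSModel:
        return self.selection.final_model

    @property
    def nlv(self) -> int:
        return self.selection.nlv

    @property
    def band_mask(self) -> np.ndarray:
        return self.selection.band_mask

    @property
    def wavelengths_retained(self) -> np.ndarray:
        return self.model.spectra.axis.values[self.band_mask]

    @property
    def params(self) -> pd.Series:
        """Regression coefficients indexed by retained wavelength (nm)."""
        return pd.Series(self.pls.coef[self.nlv - 1],
                         index=self.wavelengths_retained, name="coef")

    @property
    def p_values(self) -> pd.Series:
        """Fold-coefficient t-test p-values over the original axis."""
        return pd.Series(self.selection.p_values,
                         index=self.model.spectra.axis.values, name="p")

    @property
    def r2_cal(self) -> float:
        return self.selection.final_metrics.r2_cal

    @property
    def r2_val(self) -> float:
        return self.selection.final_metrics.r2_val

    @property
    def rmse_cal(self) -> float:
        return self.selection.final_metrics.rmse_cal

    @property
    def rmse_val(self) -> float:
        return self.selection.final_metrics.rmse_val

    @property
    def stop_reason(self) -> str:
        return self.selection.stop_reason

    @property
    def iterations(self) -> int:
        return self.selection.iterations

    @property
    def fittedvalues(self) -> np.ndarray:
        X = self.model.spectra.values[:, self.band_mask]
        return predict(self.pls, X, min(self.nlv, self.pls.nlv_max))

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def loo_predictions(self) -> np.ndarray:
        """Held-out predictions at the selected component count."""
        return self.selection.loo.predictions[:, self.nlv - 1]

    def predict(self, spectra: SpectralMatrix) -> np.ndarray:
        """Predict the (possibly log10) trait for new plants."""
        if spectra.axis != self.model.spectra.axis:
            raise ValueError("new spectra are not on the training axis")
        X = spectra.values[:, self.band_mask]
        return predict(self.pls, X, min(self.nlv, self.pls.nlv_max))

    def correlation_profile(self):
        """Pearson r of the modelled trait with every band (diagnostic)."""
        return band_correlations(self.model.spectra, self.model.y,
                                 self.model.trait_name)

    def to_dict(self) -> dict:
        """Machine-readable run report for one trait x spectrum pair."""
        axis = self.model.spectra.axis.values
        pv = self.selection.p_values
        return {
            "trait": self.model.trait_name,
            "spectrum_kind": self.model.spectra.kind,
            "log10": self.model.log10,
            "n_plants": self.model.spectra.n_plants,
            "nlv": int(self.nlv),
            "r2_cal": float(self.r2_cal),
            "r2_val": float(self.r2_val),
            "rmse_cal": float(self.rmse_cal),
            "rmse_val": float(self.rmse_val),
            "iterations": int(self.iterations),
            "stop_reason": self.stop_reason,
            "n_bands_retained": int(self.band_mask.sum()),
            "retained_wavelengths_nm": self.wavelengths_retained.tolist(),
            "p_values": {str(int(w)) if float(w).is_integer() else str(w):
                         (None if np.isnan(p) else float(p))
                         for w, p in zip(axis, pv)},
            "plant_ids": list(self.model.spectra.plant_ids),
            "observed": self.model.y.tolist(),
            "loo_predictions": self.loo_predictions.tolist(),
            "residuals": self.resid.tolist(),
            "correlation_r": self.correlation_profile().r.tolist(),
        }

    def summary(self) -> str:
        """Plain-text summary table in the style of a regression results
        printout."""
        m = self.model
        lines = [
            "Spectral trait model (PLS1, LOO validation, band selection)",
            "=" * 62,
            f"trait:               {m.trait_name}"
            + ("  [log10]" if m.log10 else ""),
            f"spectrum kind:       {m.spectra.kind}",
            f"plants:              {m.spectra.n_plants}",
            f"bands (orig/kept):   {m.spectra.n_bands} / {int(self.band_mask.sum())}",
            f"latent variables:    {self.nlv}",
            f"selection stop:      {self.stop_reason} "
            f"after {self.iterations} iteration(s)",
            "-" * 62,
            f"r2_cal   = {self.r2_cal:8.3f}    rmse_cal = {self.rmse_cal:.4g}",
            f"r2_val   = {self.r2_val:8.3f}    rmse_val = {self.rmse_val:.4g}",
            "=" * 62,
        ]
        return "\n".join(lines)
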