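"""Exploratory statistics: band-trait correlations and trait summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectralMatrix, WavelengthAxis


@dataclass
class CorrelationProfile:
    """Per-band Pearson correlation between one trait and one spectrum kind."""

    axis: WavelengthAxis
    r: np.ndarray
    trait_name: str
    spectrum_kind: str
    zero_variance: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.r, index=self.axis.values,
                         name=f"{self.trait_name}:{self.spectrum_kind}")


def band_correlations(X: SpectralMatrix, y, trait_name: str = "") -> CorrelationProfile:
    """Pearson r between a trait vector and every spectral band.

    Bands with zero variance across plants get r = 0 and are flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.n_plants:
        raise ValueError(f"trait has {y.size} values, spectra {X.n_plants} plants")
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")
    V = X.values
    xc = V - V.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc ** 2, axis=0))
    sy = np.sqrt(np.sum(yc ** 2))
    zero_var = sx == 0
    denom = np.where(zero_var, 1.0, sx * sy)
    r = np.where(zero_var, 0.0, yc @ xc / denom)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationProfile(X.axis, r, trait_name, X.kind, zero_var)


def strength_label(r: float) -> str:
    """Correlation-strength label on |r|: strong > 0.7, moderate in
    (0.5, 0.7], weak <= 0.5."""
    a = abs(float(r))
    if a > 1:
        raise ValueError(f"|r| = {a} exceeds 1")
    if a > 0.7:
        return "strong"
    if a > 0.5:
        return "moderate"
    return "weak"


def trait_correlation_matrix(traits: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over trait columns."""
    df = traits[columns] if columns is not None else traits.select_dtypes("number")
    if len(df) < 3:
        raise ValueError("need at least 3 plants")
    variances = df.var(ddof=1)
    dead = variances[variances == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance trait(s): {dead}")
    corr = df.corr(method="pearson")
    # enforce exact symmetry and unit diagonal against rounding noise
    out = (corr + corr.T) / 2.0
    np.fill_diagonal(out.values, 1.0)
    return out


def pca_variance_explained(traits: pd.DataFrame, k: int, columns=None) -> np.ndarray:
    """Cumulative variance fractions of the first k principal components.

    Traits carry heterogeneous units, so the PCA decomposes the trait
    correlation matrix (i.e. traits are standardised to unit variance).
    """
    corr = trait_correlation_matrix(traits, columns=columns)
    p = corr.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside [1, {p}] components")
    eigenvalues = np.linalg.eigvalsh(corr.values)[::-1]
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    fractions = eigenvalues / eigenvalues.sum()
    return np.cumsum(fractions)[:k]
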