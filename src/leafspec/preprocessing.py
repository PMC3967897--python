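"""Reduction of raw integrating-sphere radiances to analysis-ready spectra.

The reduction chain is: white-reference normalisation with stray-light
subtraction, per-plant leaf averaging, cropping to the analysed range
(400-1800 nm by default), split-window Savitzky-Golay smoothing, and
absorbance derivation as A = 1 - R - T.

Smoothing uses two window lengths (31 nm below/at the stitch boundary at
800 nm, 51 nm above it); both filters are run over the full spectrum and
the outputs stitched, which avoids edge artifacts at the seam.  Edge
bands are fitted by least-squares polynomials over the truncated
available window rather than by padding, so polynomials up to the filter
order pass through unchanged everywhere, including the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .containers import (
    AxisMismatchError,
    DegenerateReferenceError,
    SphereMeasurement,
    SpectralMatrix,
    WavelengthAxis,
)

DEFAULT_CROP_NM = (400.0, 1800.0)
DEFAULT_WINDOW_A_NM = 31.0
DEFAULT_WINDOW_B_NM = 51.0
DEFAULT_BOUNDARY_NM = 800.0
DEFAULT_SG_ORDER = 2


def normalize_reflectance(m: SphereMeasurement) -> np.ndarray:
    """Reduce a raw sphere measurement to absolute reflectance.

    The leaf radiance is stray-light corrected, divided by the
    stray-corrected white-reference radiance, and scaled by the absolute
    reflectance of the reference panel:

        R = (sample - stray) / (white - stray) * panel_reflectance
    """
    denom = m.white_radiance - m.stray_radiance
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        wl = m.axis.values[bad[0]]
        raise DegenerateReferenceError(
            f"white minus stray radiance is zero at {wl:g} nm "
            f"({bad.size} degenerate band(s))"
        )
    return (m.sample_radiance - m.stray_radiance) / denom * m.panel_reflectance


def crop(s: SpectralMatrix, lo_nm: float, hi_nm: float) -> SpectralMatrix:
    """Restrict a spectral matrix to bands with lo_nm <= lambda <= hi_nm.

    Both endpoints are inclusive: a 1 nm grid cropped to 400-1800 nm
    retains 1401 bands.
    """
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo_nm < hi_nm, got ({lo_nm}, {hi_nm})")
    keep = (s.axis.values >= lo_nm) & (s.axis.values <= hi_nm)
    if not keep.any():
        raise ValueError(
            f"no band in [{lo_nm}, {hi_nm}] nm on an axis covering "
            f"[{s.axis.values[0]:g}, {s.axis.values[-1]:g}] nm"
        )
    return SpectralMatrix(
        s.plant_ids,
        WavelengthAxis(s.axis.values[keep]),
        s.values[:, keep],
        s.kind,
        out_of_range=s.out_of_range[:, keep],
    )


def _savgol_truncated(y: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay filter with truncated least-squares windows at the edges.

    Interior points use the standard convolution; each of the first and
    last ``window // 2`` points is the value at that point of an
    order-``order`` polynomial least-squares fitted to the bands that
    fall inside the (clipped) window.
    """
    n = y.shape[-1]
    if window > n:
        raise ValueError(f"window of {window} samples exceeds spectrum length {n}")
    out = savgol_filter(y, window, order, mode="interp")
    half = window // 2
    y2 = np.atleast_2d(y)
    o2 = np.atleast_2d(out)
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = np.arange(lo, hi) - i
        # Vandermonde LS fit evaluated at the centre (x = 0).
        deg = min(order, len(x) - 1)
        V = np.vander(x, deg + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y2[:, lo:hi].T, rcond=None)
        o2[:, i] = coef[0]
    return o2.reshape(y.shape)


def savgol_smooth(
    s: SpectralMatrix,
    order: int = DEFAULT_SG_ORDER,
    window_a_nm: float = DEFAULT_WINDOW_A_NM,
    window_b_nm: float = DEFAULT_WINDOW_B_NM,
    boundary_nm: float = DEFAULT_BOUNDARY_NM,
) -> SpectralMatrix:
    """Split-window Savitzky-Golay smoothing of every spectrum.

    Each row is filtered twice over the full axis, once per window; the
    result takes the ``window_a_nm`` filter for bands at or below
    ``boundary_nm`` and the ``window_b_nm`` filter above it.
    """
    if not s.axis.is_uniform:
        raise ValueError("smoothing requires a uniform wavelength grid")
    wa = s.axis.nm_to_samples(window_a_nm)
    wb = s.axis.nm_to_samples(window_b_nm)
    for w in (wa, wb):
        if order >= w:
            raise ValueError(f"polynomial order {order} must be < window {w}")
    smooth_a = _savgol_truncated(s.values, wa, order)
    smooth_b = _savgol_truncated(s.values, wb, order)
    use_a = s.axis.values <= boundary_nm
    values = np.where(use_a[None, :], smooth_a, smooth_b)
    return SpectralMatrix(s.plant_ids, s.axis, values, s.kind)


def average_leaves(leaf_spectra, plant_id=None) -> np.ndarray:
    """Arithmetic per-band mean over the leaves of one plant."""
    arrs = [np.asarray(v, dtype=float) for v in leaf_spectra]
    if not arrs:
        raise ValueError(f"no leaf spectra to average for plant {plant_id!r}")
    n = arrs[0].shape
    if any(a.shape != n for a in arrs):
        raise AxisMismatchError(
            f"leaf spectra for plant {plant_id!r} are not on a common axis"
        )
    return np.mean(arrs, axis=0)


@dataclass
class AbsorbanceResult:
    """Absorbance matrix plus the attrition record of the R/T intersection."""

    absorbance: SpectralMatrix
    only_in_reflectance: list = field(default_factory=list)
    only_in_transmittance: list = field(default_factory=list)

    @property
    def dropped(self) -> list:
        return sorted(set(self.only_in_reflectance)
                      | set(self.only_in_transmittance))


def compute_absorbance(r: SpectralMatrix, t: SpectralMatrix) -> AbsorbanceResult:
    """Derive absorbance as A = 1 - R - T on the plant intersection.

    Plants present in only one of the two inputs are dropped and listed
    in the result.  Cells falling outside [0, 1] (possible when R + T
    exceeds one) are flagged but never clamped.
    """
    if r.axis != t.axis:
        raise AxisMismatchError("reflectance and transmittance axes differ")
    common = [p for p in r.plant_ids if p in set(t.plant_ids)]
    if not common:
        raise ValueError("no plant occurs in both reflectance and transmittance")
    rs = r.select_plants(common)
    ts = t.select_plants(common)
    a = SpectralMatrix(common, r.axis, 1.0 - rs.values - ts.values, "absorbance")
    return AbsorbanceResult(
        absorbance=a,
        only_in_reflectance=[p for p in r.plant_ids if p not in set(t.plant_ids)],
        only_in_transmittance=[p for p in t.plant_ids if p not in set(r.plant_ids)],
    )
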