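"""Correction of masked (reduced-aperture) sphere measurements.

Leaves narrower than the integrating-sphere port are measured through a
slit mask; the mask then contributes to every recorded signal.  With
masked and unmasked spectra of two reference materials (a bright and a
dark standard) the contamination can be inverted per band as an affine
map: the gain/offset pair that carries both masked references exactly
onto their known true spectra also carries a masked leaf signal onto an
estimate of its unmasked spectrum.

The module also flags spectrometer-seam artifacts: masked measurements
occasionally show an abrupt reflectance step exactly at the transition
wavelengths between the instrument's three internal spectrometers, and
such spectra are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AxisMismatchError,
    DegenerateReferenceError,
    SpectralMatrix,
    WavelengthAxis,
)

DEFAULT_SEAM_WAVELENGTHS_NM = (1000.0, 1800.0)
DEFAULT_SEAM_JUMP_THRESHOLD = 0.05


@dataclass
class MaskCalibration:
    """Masked and true spectra of the two calibration references."""

    axis: WavelengthAxis
    masked_white: np.ndarray
    masked_black: np.ndarray
    true_white: np.ndarray
    true_black: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.axis)
        for name in ("masked_white", "masked_black", "true_white", "true_black"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {v.shape}")
            setattr(self, name, v)


@dataclass
class MaskCorrection:
    """Per-band affine correction: corrected = gain * masked + offset."""

    axis: WavelengthAxis
    gain: np.ndarray
    offset: np.ndarray


def fit_mask_calibration(c: MaskCalibration) -> MaskCorrection:
    """Solve the per-band two-reference affine inversion.

    gain = (true_white - true_black) / (masked_white - masked_black)
    offset = true_white - gain * masked_white

    so both references map exactly onto their true spectra.
    """
    denom = c.masked_white - c.masked_black
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        wl = c.axis.values[bad[0]]
        raise DegenerateReferenceError(
            f"masked white and black references coincide at {wl:g} nm "
            f"({bad.size} degenerate band(s))"
        )
    gain = (c.true_white - c.true_black) / denom
    offset = c.true_white - gain * c.masked_white
    return MaskCorrection(c.axis, gain, offset)


def correct_masked_spectrum(
    leaf_masked: np.ndarray, correction: MaskCorrection
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted mask correction to one masked leaf signal.

    Returns ``(corrected, out_of_range)`` where the second array flags
    bands whose corrected value falls outside [0, 1]; values are kept,
    never clamped.
    """
    leaf_masked = np.asarray(leaf_masked, dtype=float)
    if leaf_masked.shape != (len(correction.axis),):
        raise AxisMismatchError(
            f"masked spectrum has {leaf_masked.shape[0] if leaf_masked.ndim == 1 else '?'}"
            f" bands, calibration has {len(correction.axis)}"
        )
    corrected = correction.gain * leaf_masked + correction.offset
    return corrected, (corrected < 0) | (corrected > 1)


def detect_seam_jumps(
    s: SpectralMatrix,
    seam_wavelengths_nm=DEFAULT_SEAM_WAVELENGTHS_NM,
    threshold: float = DEFAULT_SEAM_JUMP_THRESHOLD,
) -> list:
    """Flag plants whose spectrum steps abruptly at a spectrometer seam.

    A plant is flagged when the absolute first difference of its
    spectrum at (the band nearest to) any configured seam wavelength
    exceeds ``threshold`` reflectance units.  Returns the flagged
    plant_ids, which mirror the exclusions applied to such measurements.
    """
    diffs = np.abs(np.diff(s.values, axis=1))
    flagged: list = []
    for wl in seam_wavelengths_nm:
        if wl < s.axis.values[0] or wl > s.axis.values[-1]:
            continue
        # the two first differences adjacent to the seam band
        j = int(np.searchsorted(s.axis.values, wl))
        candidates = [k for k in (j - 1, j) if 0 <= k < diffs.shape[1]]
        jump = diffs[:, candidates].max(axis=1)
        for i in np.flatnonzero(jump > threshold):
            if s.plant_ids[i] not in flagged:
                flagged.append(s.plant_ids[i])
    return flagged
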