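"""Core in-memory containers for leaf spectroscopy data.

A spectrum is a vector of dimensionless fractions (reflectance,
transmittance or absorbance) on an explicit wavelength axis in
nanometres.  Collections of spectra for many plants are held as a
:class:`SpectralMatrix` (plants x bands); raw integrating-sphere
radiances for a single leaf are held as a :class:`SphereMeasurement`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECTRUM_KINDS = ("reflectance", "transmittance", "absorbance")


class DegenerateReferenceError(ValueError):
    """Raised when a reference signal is unusable at one or more bands."""


class AxisMismatchError(ValueError):
    """Raised when two spectral objects do not share a wavelength axis."""


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing wavelength grid in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength axis must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavelength axis contains non-finite values")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthAxis) and np.array_equal(
            self.values, other.values
        )

    @property
    def step(self) -> float:
        """Nominal spacing in nm (median of the first differences)."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.values)))

    @property
    def is_uniform(self) -> bool:
        if len(self) < 2:
            return True
        return bool(np.allclose(np.diff(self.values), self.step, atol=1e-9))

    def nm_to_samples(self, width_nm: float) -> int:
        """Convert a window width in nm to an odd sample count on this grid.

        Requires a uniform grid; a 31 nm window on a 1 nm grid is 31 samples.
        """
        if not self.is_uniform:
            raise ValueError("nm-to-sample conversion requires a uniform axis")
        samples = int(round(width_nm / self.step))
        if samples % 2 == 0:
            raise ValueError(
                f"window of {width_nm} nm maps to an even sample count "
                f"({samples}) on a {self.step} nm grid"
            )
        return samples

    @classmethod
    def regular(cls, lo_nm: float, hi_nm: float, step: float = 1.0) -> "WavelengthAxis":
        n = int(round((hi_nm - lo_nm) / step)) + 1
        return cls(lo_nm + step * np.arange(n))


@dataclass
class SphereMeasurement:
    """Raw integrating-sphere radiances for one leaf measurement.

    ``sample_radiance`` is the leaf signal, ``white_radiance`` the white
    spectralon reference, ``stray_radiance`` the light-trap (stray light)
    signal, and ``panel_reflectance`` the manufacturer-certified absolute
    reflectance of the reference panel, all on the same axis.
    """

    axis: WavelengthAxis
    sample_radiance: np.ndarray
    white_radiance: np.ndarray
    stray_radiance: np.ndarray
    panel_reflectance: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.axis)
        for name in ("sample_radiance", "white_radiance", "stray_radiance",
                     "panel_reflectance"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {v.shape}")
            setattr(self, name, v)
        pr = self.panel_reflectance
        if np.any((pr < 0) | (pr > 1)):
            raise ValueError("panel_reflectance must lie in [0, 1]")


@dataclass
class SpectralMatrix:
    """Plants x wavelengths grid of one spectrum kind.

    ``values[i, j]`` is the dimensionless fraction for ``plant_ids[i]`` at
    ``axis.values[j]``.  ``out_of_range`` marks cells outside [0, 1] that
    were kept (never clamped) by a reduction step.
    """

    plant_ids: list
    axis: WavelengthAxis
    values: np.ndarray
    kind: str
    out_of_range: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}")
        self.plant_ids = [str(p) for p in self.plant_ids]
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (plants x bands)")
        if v.shape != (len(self.plant_ids), len(self.axis)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.plant_ids)} plants x {len(self.axis)} bands"
            )
        self.values = v
        if self.out_of_range is None:
            self.out_of_range = (v < 0) | (v > 1)
        else:
            self.out_of_range = np.asarray(self.out_of_range, dtype=bool)

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_bands(self) -> int:
        return len(self.axis)

    def select_plants(self, ids) -> "SpectralMatrix":
        idx = [self.plant_ids.index(str(p)) for p in ids]
        return SpectralMatrix(
            [self.plant_ids[i] for i in idx], self.axis,
            self.values[idx], self.kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            columns=[_fmt_wavelength(w) for w in self.axis.values],
        )
        df.insert(0, "plant_id", self.plant_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str) -> "SpectralMatrix":
        if "plant_id" not in df.columns:
            raise ValueError("spectra table must have a 'plant_id' column")
        band_cols = [c for c in df.columns if c not in ("plant_id", "leaf_id")]
        wavelengths = np.array([float(c) for c in band_cols])
        return cls(
            list(df["plant_id"].astype(str)),
            WavelengthAxis(wavelengths),
            df[band_cols].to_numpy(dtype=float),
            kind,
        )


def _fmt_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))
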