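"""Synthetic leaf spectra and traits with known ground truth.

The generator emulates the statistical structure the analysis assumes:
1-nm spectra on 400-1800 nm whose Gaussian absorption features are
linearly tied to latent leaf constituents (pigment, water, dry matter),
and measured traits that correlate with those constituents only up to a
configurable coupling rho.  With rho = 1 a trait is a noiseless affine
function of its spectrally active constituent; with rho < 1 the trait is
partially decoupled from what actually drives the spectrum — the
mechanism invoked to explain why mass-based nitrogen content is poorly
predictable when the chlorophyll fraction of leaf N varies across
growing conditions.  The theoretical ceiling on the validation r^2 of a
linear model is then rho^2.

Reflectance is a smooth green-leaf baseline (low in the visible, a steep
red edge near 710 nm, high plateau in the near infrared) minus the
constituent-weighted absorption features plus additive noise;
transmittance is generated analogously with independent noise and
rescaled where needed so R + T <= 1, and absorbance closes the energy
balance exactly: A = 1 - R - T.

All randomness flows from a single integer seed.  Constituent values and
noise innovations are drawn from a standard normal truncated at +/-3.5
standard deviations so that configured feature depths keep noiseless
spectra inside [0, 1] and affinely placed traits strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectralMatrix, WavelengthAxis
from .mask import MaskCalibration

Z_TRUNCATION = 3.5


@dataclass(frozen=True)
class AbsorptionFeature:
    """One Gaussian absorption feature tied to a latent constituent."""

    center_nm: float
    width_nm: float
    max_depth: float
    constituent: str


DEFAULT_FEATURES = (
    AbsorptionFeature(680.0, 40.0, 0.035, "pigment"),
    AbsorptionFeature(1200.0, 50.0, 0.030, "water"),
    AbsorptionFeature(1450.0, 60.0, 0.050, "water"),
    AbsorptionFeature(1700.0, 80.0, 0.035, "dry_matter"),
)

# traits tied to a spectrally active constituent, as (location, scale)
TRAIT_COUPLINGS = {
    "lnc_mg_g": ("pigment", 20.0, 3.5),
    "ldmc_mg_g": ("dry_matter", 250.0, 45.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the analysed design: 35 plants, 1-nm bands on
    400-1800 nm (1401 bands), pigment/water/dry-matter absorption
    features, trait-constituent coupling rho = 0.9 and additive spectral
    noise of 0.005 reflectance units.
    """

    n_plants: int = 35
    lo_nm: float = 400.0
    hi_nm: float = 1800.0
    step_nm: float = 1.0
    features: tuple = DEFAULT_FEATURES
    coupling_rho: float = 0.9
    noise_sd: float = 0.005
    seed: int = 0

    def axis(self) -> WavelengthAxis:
        return WavelengthAxis.regular(self.lo_nm, self.hi_nm, self.step_nm)

    def validate(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        wl = self.axis().values
        # worst-case noiseless reflectance must stay inside [0, 1]
        depth = np.zeros_like(wl)
        for f in self.features:
            depth += f.max_depth * np.exp(-((wl - f.center_nm) ** 2)
                                          / (2 * f.width_nm ** 2))
        low = _reflectance_baseline(wl) - Z_TRUNCATION * depth
        if low.min() < 0 or _reflectance_baseline(wl).max() > 1:
            raise ValueError(
                "feature depths drive noiseless spectra outside [0, 1]; "
                "reduce max_depth values"
            )


@dataclass
class SyntheticDataset:
    """Generated spectra, trait table, and the generating truth."""

    reflectance: SpectralMatrix
    transmittance: SpectralMatrix
    absorbance: SpectralMatrix
    traits: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _truncated_normal(rng: np.random.Generator, size) -> np.ndarray:
    """Standard normal truncated at +/- Z_TRUNCATION (resampled tails)."""
    z = rng.standard_normal(size)
    bad = np.abs(z) > Z_TRUNCATION
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > Z_TRUNCATION
    return z


def _reflectance_baseline(wl: np.ndarray) -> np.ndarray:
    """Green-leaf reflectance continuum: dark VIS, red edge, bright NIR."""
    return 0.22 + 0.30 / (1.0 + np.exp(-(wl - 710.0) / 25.0))


def _transmittance_baseline(wl: np.ndarray) -> np.ndarray:
    return 0.16 + 0.26 / (1.0 + np.exp(-(wl - 710.0) / 25.0))


def _feature_profiles(config: GeneratorConfig, wl: np.ndarray):
    constituents = sorted({f.constituent for f in config.features})
    profiles = np.zeros((len(constituents), wl.size))
    for f in config.features:
        i = constituents.index(f.constituent)
        profiles[i] += f.max_depth * np.exp(
            -((wl - f.center_nm) ** 2) / (2 * f.width_nm ** 2))
    return constituents, profiles


def informative_band_mask(config: GeneratorConfig,
                          constituent: str | None = None,
                          n_widths: float = 2.0) -> np.ndarray:
    """Bands within +/- n_widths feature widths of any feature centre."""
    wl = config.axis().values
    mask = np.zeros(wl.size, dtype=bool)
    for f in config.features:
        if constituent is not None and f.constituent != constituent:
            continue
        mask |= np.abs(wl - f.center_nm) <= n_widths * f.width_nm
    return mask


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = config.axis().values
    n = config.n_plants
    plant_ids = [f"plant_{i + 1:03d}" for i in range(n)]

    constituents, profiles = _feature_profiles(config, wl)
    Z = _truncated_normal(rng, (n, len(constituents)))  # latent constituents

    signal = Z @ profiles                     # plants x bands depletion
    R = _reflectance_baseline(wl) - signal \
        + config.noise_sd * rng.standard_normal((n, wl.size))
    T = _transmittance_baseline(wl) - 0.8 * signal \
        + config.noise_sd * rng.standard_normal((n, wl.size))
    # keep the energy balance physical: rescale T where R + T approaches 1
    excess = R + T
    cap = 0.995
    factor = np.minimum(1.0, (cap - R) / np.where(T > 0, T, 1.0))
    T = np.where(excess > cap, T * factor, T)
    A = 1.0 - R - T

    rho = config.coupling_rho
    traits = pd.DataFrame({"plant_id": plant_ids})
    for trait, (constituent, loc, scale) in TRAIT_COUPLINGS.items():
        zc = Z[:, constituents.index(constituent)] if constituent in constituents \
            else _truncated_normal(rng, n)
        eps = _truncated_normal(rng, n)
        mixed = rho * zc + np.sqrt(1.0 - rho ** 2) * eps
        traits[trait] = loc + scale * mixed

    # raw laboratory quantities consistent with the derived-trait identities
    dry_mass = 25.0 + 4.0 * _truncated_normal(rng, n)
    sla = 17.0 + 3.0 * _truncated_normal(rng, n)
    np_ratio = np.clip(13.3 + 6.6 * _truncated_normal(rng, n), 2.0, None)
    traits["lpc_mg_g"] = traits["lnc_mg_g"] / np_ratio
    traits["lcc_mg_g"] = 450.0 + 12.0 * _truncated_normal(rng, n)
    traits["dry_mass_mg"] = dry_mass
    traits["fresh_mass_mg"] = 1000.0 * dry_mass / traits["ldmc_mg_g"]
    traits["leaf_area_mm2"] = sla * dry_mass

    axis = config.axis()
    truth = {
        "constituent_names": constituents,
        "constituents": Z,
        "informative_band_mask": informative_band_mask(config),
        "trait_constituents": {t: c for t, (c, _, _) in TRAIT_COUPLINGS.items()},
        "theoretical_r2": rho ** 2,
        "coupling_rho": rho,
    }
    return SyntheticDataset(
        reflectance=SpectralMatrix(plant_ids, axis, R, "reflectance"),
        transmittance=SpectralMatrix(plant_ids, axis, T, "transmittance"),
        absorbance=SpectralMatrix(plant_ids, axis, A, "absorbance"),
        traits=traits,
        truth=truth,
    )


@dataclass
class MaskScenario:
    """Forward-simulated masked measurements with known truth."""

    calibration: MaskCalibration
    true_spectra: np.ndarray      # leaves x bands
    masked_spectra: np.ndarray    # leaves x bands, contaminated
    gain: np.ndarray
    offset: np.ndarray


def generate_mask_scenario(config: GeneratorConfig) -> MaskScenario:
    """Simulate the two-reference mask-calibration setup.

    A smooth per-band affine contamination (gain g > 0, offset o) maps a
    true spectrum r to the masked signal m = (r - o) / g, so that the
    fitted correction g * m + o recovers r exactly.  Reference materials
    are a bright panel (0.99) and a dark panel (0.02).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    wl = config.axis().values
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    # smooth contamination fields from a low-order random polynomial basis
    g_coefs = rng.uniform(-0.15, 0.15, size=3)
    o_coefs = rng.uniform(-0.05, 0.05, size=3)
    basis = np.vstack([t, t ** 2, np.sin(2 * np.pi * t)])
    gain = 1.4 + g_coefs @ basis      # bounded away from zero
    offset = 0.05 + o_coefs @ basis

    true_white = np.full(wl.size, 0.99)
    true_black = np.full(wl.size, 0.02)
    dataset = generate(config)
    true_spectra = dataset.reflectance.values
    masked = (true_spectra - offset) / gain

    calibration = MaskCalibration(
        axis=config.axis(),
        masked_white=(true_white - offset) / gain,
        masked_black=(true_black - offset) / gain,
        true_white=true_white,
        true_black=true_black,
    )
    return MaskScenario(calibration, true_spectra, masked, gain, offset)
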