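"""Run configuration for the end-to-end pipeline.

Defaults are the analysis values used throughout: crop to 400-1800 nm,
second-order Savitzky-Golay smoothing with a 31 nm window up to the
800 nm stitch boundary and 51 nm above it, per-band significance
threshold alpha = 0.1, latent-variable cap 15, log10 trait transform,
spectrometer-seam detection at 1000 and 1800 nm with a 0.05 jump
threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mask import DEFAULT_SEAM_JUMP_THRESHOLD, DEFAULT_SEAM_WAVELENGTHS_NM
from .pls import DEFAULT_NLV_CAP
from .preprocessing import (
    DEFAULT_BOUNDARY_NM,
    DEFAULT_CROP_NM,
    DEFAULT_SG_ORDER,
    DEFAULT_WINDOW_A_NM,
    DEFAULT_WINDOW_B_NM,
)
from .selection import DEFAULT_ALPHA, DEFAULT_MAX_ITERATIONS


@dataclass
class RunConfig:
    crop_lo_nm: float = DEFAULT_CROP_NM[0]
    crop_hi_nm: float = DEFAULT_CROP_NM[1]
    sg_order: int = DEFAULT_SG_ORDER
    window_a_nm: float = DEFAULT_WINDOW_A_NM
    window_b_nm: float = DEFAULT_WINDOW_B_NM
    boundary_nm: float = DEFAULT_BOUNDARY_NM
    alpha: float = DEFAULT_ALPHA
    nlv_max: int = DEFAULT_NLV_CAP
    max_iterations: int = DEFAULT_MAX_ITERATIONS
    log10: bool = True
    scale: bool = False
    band_selection: bool = True
    traits: list = field(default_factory=lambda: [
        "lnc_mg_g", "lpc_mg_g", "lcc_mg_g", "sla_mm2_mg", "ldmc_mg_g",
        "lnc_area_g_m2", "lpc_area_g_m2",
    ])
    spectrum_kinds: list = field(default_factory=lambda: [
        "reflectance", "transmittance", "absorbance",
    ])
    seam_wavelengths_nm: list = field(
        default_factory=lambda: list(DEFAULT_SEAM_WAVELENGTHS_NM))
    seam_jump_threshold: float = DEFAULT_SEAM_JUMP_THRESHOLD
    subset_column: str | None = None
    subset_value: str | None = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not self.crop_lo_nm < self.crop_hi_nm:
            raise ValueError("crop_lo_nm must be below crop_hi_nm")
        for w in (self.window_a_nm, self.window_b_nm):
            if w <= self.sg_order:
                raise ValueError("smoothing window must exceed the filter order")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.nlv_max < 1:
            raise ValueError("nlv_max must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
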