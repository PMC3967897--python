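"""Leaf functional traits: derivation, units, and nutrient-limitation classes.

Measured laboratory quantities per plant (fresh mass, dry mass, leaf
area, and mass-based nitrogen / phosphorus / carbon content) are turned
into the standard derived traits:

* SLA  — specific leaf area, leaf area per dry mass (mm^2/mg)
* LDMC — leaf dry matter content, dry mass per fresh mass (mg/g)
* LNC_area, LPC_area — nutrient content per leaf area (g/m^2), obtained
  by dividing the mass-based content by SLA; (mg/g) / (mm^2/mg) equals
  1e-3 mg/mm^2 which is exactly 1 g/m^2, so no unit factor appears.
* N:P ratio and the nutrient-limitation class it implies
  (N-limited below 14, P-limited above 16, colimited between).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAIT_TABLE_COLUMNS = [
    "plant_id", "fresh_mass_mg", "dry_mass_mg", "leaf_area_mm2",
    "lnc_mg_g", "lpc_mg_g", "lcc_mg_g",
]

DERIVED_TRAIT_NAMES = [
    "sla_mm2_mg", "ldmc_mg_g", "lnc_area_g_m2", "lpc_area_g_m2", "np_ratio",
]

N_LIMITED_BELOW = 14.0
P_LIMITED_ABOVE = 16.0


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    num = df[TRAIT_TABLE_COLUMNS[1:]]
    if (num <= 0).any().any():
        bad = df.loc[(num <= 0).any(axis=1), "plant_id"].tolist()
        raise ValueError(f"non-positive trait quantities for plants {bad}")
    if (df["dry_mass_mg"] > df["fresh_mass_mg"]).any():
        bad = df.loc[df["dry_mass_mg"] > df["fresh_mass_mg"], "plant_id"].tolist()
        raise ValueError(f"dry mass exceeds fresh mass for plants {bad}")
    return df


def derive_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Append derived traits and limitation classes to a trait table."""
    df = validate_trait_table(df).copy()
    df["sla_mm2_mg"] = df["leaf_area_mm2"] / df["dry_mass_mg"]
    df["ldmc_mg_g"] = 1000.0 * df["dry_mass_mg"] / df["fresh_mass_mg"]
    df["lnc_area_g_m2"] = df["lnc_mg_g"] / df["sla_mm2_mg"]
    df["lpc_area_g_m2"] = df["lpc_mg_g"] / df["sla_mm2_mg"]
    df["np_ratio"] = df["lnc_mg_g"] / df["lpc_mg_g"]
    df["limitation"] = [classify_limitation(v) for v in df["np_ratio"]]
    return df


def classify_limitation(np_ratio: float) -> str:
    """Classify nutrient limitation from the leaf N:P ratio.

    Below 14 the ecosystem is taken as N-limited, above 16 as P-limited;
    the boundary values belong to the colimited class.
    """
    if not np_ratio > 0:
        raise ValueError(f"N:P ratio must be positive, got {np_ratio}")
    if np_ratio < N_LIMITED_BELOW:
        return "N_limited"
    if np_ratio > P_LIMITED_ABOVE:
        return "P_limited"
    return "colimited"


def log_transform(values, plant_ids=None) -> np.ndarray:
    """Base-10 logarithm of positive trait values.

    Trait distributions are right-skewed; the analysis works on
    log10-transformed values.  Non-positive entries raise, naming the
    offending plant when identifiers are supplied.
    """
    v = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(v > 0))
    if bad.size:
        who = (f"plant {plant_ids[bad[0]]!r}" if plant_ids is not None
               else f"index {bad[0]}")
        raise ValueError(f"log transform requires positive values; {who} "
                         f"has value {v[bad[0]]!r}")
    return np.log10(v)


def inverse_log_transform(values) -> np.ndarray:
    return np.power(10.0, np.asarray(values, dtype=float))
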