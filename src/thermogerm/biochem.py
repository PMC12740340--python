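"""Deterministic arithmetic on seed fatty-acid profiles and water content.

The seed lot's oil chemistry enters the germination story through two
summary numbers: the total fatty-acid content (mg per g fresh seed,
conventionally also quoted as a percentage, mg/g ÷ 10) and the
saturated:unsaturated ratio (palmitic + stearic over linoleic + oleic).
Water content can be re-expressed on an oil-free fresh basis, which removes
the inert lipid mass from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FattyAcidProfile",
    "fatty_acid_table",
    "total_fatty_acids",
    "sat_unsat_ratio",
    "oil_free_water_content",
    "ACID_COLUMNS",
]

ACID_COLUMNS = ("palmitic", "linoleic", "oleic", "stearic", "nonadecylic")

# Measured concentrations (mg per g fresh seed) per elevational seed
# population (m a.s.l.): palmitic, linoleic, oleic, stearic, nonadecylic.
_FATTY_ACIDS = {
    1260: (24.232, 90.525, 146.011, 10.988, 3.702),
    1660: (14.800, 67.969, 97.199, 8.227, 3.709),
    2040: (23.611, 106.627, 127.372, 11.825, 3.824),
    2345: (30.506, 174.380, 84.317, 14.193, 4.760),
    2500: (47.185, 272.063, 215.242, 19.290, 3.690),
}


@dataclass(frozen=True)
class FattyAcidProfile:
    """Per-acid concentrations (mg per g fresh seed) of one seed lot."""

    elevation: float
    palmitic: float
    linoleic: float
    oleic: float
    stearic: float
    nonadecylic: float

    def __post_init__(self) -> None:
        for name in ACID_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be nonnegative")


def fatty_acid_table() -> pd.DataFrame:
    """The built-in five-elevation fatty-acid concentration table (mg/g)."""
    df = pd.DataFrame.from_dict(_FATTY_ACIDS, orient="index", columns=list(ACID_COLUMNS))
    df.index.name = "elevation_m"
    return df


def profile_for_elevation(elevation: int) -> FattyAcidProfile:
    """Built-in profile for one of the five sampled elevations."""
    try:
        row = _FATTY_ACIDS[elevation]
    except KeyError:
        raise KeyError(f"no built-in profile for elevation {elevation} m") from None
    return FattyAcidProfile(elevation, *row)


def total_fatty_acids(profile: FattyAcidProfile) -> tuple[float, float]:
    """Total fatty-acid content: (mg per g fresh seed, percent of fresh mass).

    The percentage is mg/g divided by 10 (mg per g -> g per 100 g).
    """
    total_mg_g = sum(getattr(profile, name) for name in ACID_COLUMNS)
    return total_mg_g, total_mg_g / 10.0


def sat_unsat_ratio(profile: FattyAcidProfile, include_nonadecylic: bool = False) -> float:
    """Saturated : unsaturated fatty-acid ratio.

    Saturated = palmitic + stearic; unsaturated = linoleic + oleic.
    Nonadecylic acid, although chemically saturated, is excluded by default
    (its trace-level concentration is conventionally left out of the
    ratio); pass ``include_nonadecylic=True`` to count it.
    """
    unsat = profile.linoleic + profile.oleic
    if unsat <= 0:
        raise ValueError("unsaturated fatty-acid sum must be positive")
    sat = profile.palmitic + profile.stearic
    if include_nonadecylic:
        sat += profile.nonadecylic
    return sat / unsat


def oil_free_water_content(wc_fresh_basis: float, lipid_fresh_basis: float) -> float:
    """Seed water content (%) on an oil-free fresh basis.

    WC_of = 100 * WC_fb / (100 - LC_fb), where WC_fb is the fresh-basis
    water content (%) and LC_fb the fresh-basis total lipid content (%).
    """
    if not (0.0 <= wc_fresh_basis <= 100.0):
        raise ValueError("fresh-basis water content must be in [0, 100] %")
    if not (0.0 <= lipid_fresh_basis < 100.0):
        raise ValueError("fresh-basis lipid content must be in [0, 100) %")
    return 100.0 * wc_fresh_basis / (100.0 - lipid_fresh_basis)
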