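"""Chromophores, tissue oxygen saturation and metabolic rate of oxygen.

Muscle absorption at 730 and 830 nm is decomposed into oxy- and deoxy-
(hemoglobin + myoglobin) — NIRS cannot separate the two globins, so they are
reported jointly — on top of fixed water (62.5%) and lipid (20%) background
fractions:

    mua(lambda) - f_w mua_w(lambda) - f_l mua_l(lambda)
        = ln(10) * [eps_HbO2(lambda) C_oxy + eps_Hb(lambda) C_deoxy]

a 2x2 linear system solved exactly (extinction coefficients are base-10 molar
values, hence the ln(10); a classic source of 2.303x errors).  StO2 is the
oxygenated fraction of the total; MRO2 combines blood hemoglobin content, flow
index and the arterio-tissue saturation gap:

    MRO2 = (HGB / mw_Hb) * BFi * (SpO2 - StO2) / venous_ratio

reported in mol * mm^2 / (L s) — pseudo-units inherited from BFi, linear in both
BFi and the saturation gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreSet",
    "MRO2Params",
    "ExtinctionTable",
    "load_extinction_table",
    "mua_to_chromophores",
    "chromophores_to_mua",
    "compute_sto2",
    "compute_mro2",
    "DEFAULT_WATER_FRACTION",
    "DEFAULT_LIPID_FRACTION",
    "hgb_for_sex",
]

DEFAULT_WATER_FRACTION = 0.625
DEFAULT_LIPID_FRACTION = 0.20

#: Blood hemoglobin content defaults (g/dL), keyed by reported sex.
_HGB_G_PER_DL = {"female": 14.0, "male": 16.0}

LN10 = math.log(10.0)


def hgb_for_sex(sex: str) -> float:
    """Default blood hemoglobin concentration (g/dL) for a reported sex."""
    try:
        return _HGB_G_PER_DL[sex.lower()]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}; expected 'female' or 'male'") from None


@dataclass(frozen=True)
class ChromophoreSet:
    """Oxy/deoxy [Hb+Mb] in umol/L plus the assumed background fractions."""

    oxy: float
    deoxy: float
    water_fraction: float = DEFAULT_WATER_FRACTION
    lipid_fraction: float = DEFAULT_LIPID_FRACTION
    non_physical: bool = False

    @property
    def total(self) -> float:
        return self.oxy + self.deoxy


@dataclass(frozen=True)
class MRO2Params:
    """Constants of the MRO2 relation."""

    hgb_g_per_dl: float = 16.0
    spo2: float = 0.98
    venous_ratio: float = 0.75
    mw_hb_g_per_mol: float = 64_500.0

    def __post_init__(self) -> None:
        if self.hgb_g_per_dl <= 0 or self.mw_hb_g_per_mol <= 0:
            raise ValueError("hgb and mw_hb must be positive")
        if not 0 < self.spo2 <= 1:
            raise ValueError("spo2 must be a fraction in (0, 1]")
        if not 0 < self.venous_ratio <= 1:
            raise ValueError("venous_ratio must be in (0, 1]")


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-wavelength extinction/background-absorption constants."""

    wavelengths: tuple[float, ...]
    eps_hbo2: dict[float, float]  # 1/(cm M), base-10
    eps_hb: dict[float, float]
    mua_water: dict[float, float]  # mm^-1 (pure)
    mua_lipid: dict[float, float]  # mm^-1 (pure)


def load_extinction_table() -> ExtinctionTable:
    """Load the packaged extinction/background table (730 and 830 nm)."""
    with resources.files("layerlut.data").joinpath("extinction_730_830.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    wl = tuple(float(w) for w in df["wavelength_nm"])
    col = lambda name: dict(zip(wl, df[name].astype(float)))
    return ExtinctionTable(
        wavelengths=wl,
        eps_hbo2=col("eps_hbo2_percm_perM"),
        eps_hb=col("eps_hb_percm_perM"),
        mua_water=col("mua_water_permm"),
        mua_lipid=col("mua_lipid_permm"),
    )


def _extinction_matrix(table: ExtinctionTable, wavelengths=(730.0, 830.0)) -> np.ndarray:
    """2x2 matrix mapping (oxy, deoxy) in uM to mua contributions in mm^-1.

    Units: eps [1/(cm M)] * C [uM] -> ln10 * eps * C * 1e-7 in mm^-1.
    """
    return LN10 * 1e-7 * np.array(
        [[table.eps_hbo2[wl], table.eps_hb[wl]] for wl in wavelengths]
    )


def mua_to_chromophores(
    mua_730: float,
    mua_830: float,
    water_fraction: float = DEFAULT_WATER_FRACTION,
    lipid_fraction: float = DEFAULT_LIPID_FRACTION,
    extinction_table: ExtinctionTable | None = None,
) -> ChromophoreSet:
    """Invert the two-wavelength Beer-Lambert system for oxy/deoxy [Hb+Mb] (uM).

    Negative concentrations are returned as-is with ``non_physical=True``
    rather than clipped, so downstream quality control can see them.
    """
    if not 0 <= water_fraction <= 1 or not 0 <= lipid_fraction <= 1:
        raise ValueError("fractions must be in [0, 1]")
    table = extinction_table or load_extinction_table()
    wls = (730.0, 830.0)
    E = _extinction_matrix(table, wls)
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(f"extinction matrix is ill-conditioned (cond={cond:.2g})")
    background = np.array(
        [
            water_fraction * table.mua_water[wl] + lipid_fraction * table.mua_lipid[wl]
            for wl in wls
        ]
    )
    rhs = np.array([mua_730, mua_830]) - background
    oxy, deoxy = np.linalg.solve(E, rhs)
    return ChromophoreSet(
        oxy=float(oxy),
        deoxy=float(deoxy),
        water_fraction=water_fraction,
        lipid_fraction=lipid_fraction,
        non_physical=bool(oxy < 0 or deoxy < 0),
    )


def chromophores_to_mua(
    chromophores: ChromophoreSet,
    extinction_table: ExtinctionTable | None = None,
) -> tuple[float, float]:
    """Forward-compose muscle mua at (730, 830) nm from chromophores, mm^-1."""
    table = extinction_table or load_extinction_table()
    wls = (730.0, 830.0)
    E = _extinction_matrix(table, wls)
    background = np.array(
        [
            chromophores.water_fraction * table.mua_water[wl]
            + chromophores.lipid_fraction * table.mua_lipid[wl]
            for wl in wls
        ]
    )
    mua = E @ np.array([chromophores.oxy, chromophores.deoxy]) + background
    return float(mua[0]), float(mua[1])


def compute_sto2(oxy: float, total: float) -> float:
    """Tissue saturation StO2 = 100 * oxy / total, percent."""
    if total <= 0:
        raise ValueError("total [Hb+Mb] must be positive to define StO2")
    return 100.0 * oxy / total


def compute_mro2(params: MRO2Params, bfi: float, sto2_percent: float) -> float:
    """Metabolic rate of oxygen, mol mm^2 L^-1 s^-1 (pseudo-units, linear in BFi).

    ``sto2_percent`` is on the 0-100 scale and converted to a fraction
    internally; HGB is converted from g/dL to g/L.
    """
    if not 0 <= sto2_percent <= 100:
        raise ValueError("sto2_percent must be in [0, 100]")
    hgb_g_per_l = params.hgb_g_per_dl * 10.0
    sat_gap = params.spo2 - sto2_percent / 100.0
    return (hgb_g_per_l / params.mw_hb_g_per_mol) * bfi * sat_gap / params.venous_ratio
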