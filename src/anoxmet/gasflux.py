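"""Closed-chamber gas flux estimation and headspace/slurry unit conversions.

A static chamber of volume V (m³) sealed over a soil footprint A (m²)
accumulates an emitted gas; the mixing ratio (ppmv) is sampled a few times
over 0–3 h and the soil–atmosphere flux follows from the linear accumulation
rate: with slope b in ppmv h⁻¹ and n_air = P·V/(R·T) moles of air in the
chamber, the flux is

    F = b · P·V / (R·T·A)   [μmol m⁻² h⁻¹],

since 1 ppmv of chamber air is 10⁻⁶·n_air mol = n_air μmol per 10⁶. The
slope comes from ordinary least squares over all timepoints; no curvature
correction is applied and negative slopes (gas uptake) are reported as-is.

Also provided: CO₂:CH₄ ratio series, conversion of a headspace volume
percentage to mmol per litre of slurry (ideal gas), and the μM → μmol per
gram dry weight conversion used for diluted peat slurries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants, stats

__all__ = [
    "ChamberSeries",
    "FluxEstimate",
    "GasConversionContext",
    "RatioSeries",
    "chamber_flux",
    "ratio_series",
    "headspace_to_slurry",
    "umol_per_gdw",
]

logger = logging.getLogger(__name__)

R_GAS = constants.R  # J mol^-1 K^-1

#: Default incubation/field conditions: 20 °C, 1 atm.
DEFAULT_TEMPERATURE_K = 293.15
DEFAULT_PRESSURE_PA = 101325.0


@dataclass(frozen=True)
class ChamberSeries:
    """Mixing-ratio time series from one closed chamber deployment.

    ``hours`` must be strictly increasing with at least two timepoints;
    geometry (volume, footprint area) and conditions (T, P) must be
    positive.
    """

    plot_id: str
    gas: str
    hours: tuple[float, ...]
    ppmv: tuple[float, ...]
    volume_m3: float
    area_m2: float
    temperature_k: float = DEFAULT_TEMPERATURE_K
    pressure_pa: float = DEFAULT_PRESSURE_PA

    def __post_init__(self) -> None:
        hours = tuple(float(t) for t in self.hours)
        ppmv = tuple(float(v) for v in self.ppmv)
        object.__setattr__(self, "hours", hours)
        object.__setattr__(self, "ppmv", ppmv)
        if len(hours) < 2:
            raise ValueError("chamber series needs at least 2 timepoints")
        if len(hours) != len(ppmv):
            raise ValueError("hours and ppmv must have equal length")
        if not all(b > a for a, b in zip(hours, hours[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("volume_m3", "area_m2", "temperature_k", "pressure_pa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FluxEstimate:
    """An areal gas flux from a chamber accumulation slope.

    ``slope`` is in ppmv h⁻¹, ``flux`` and ``flux_se`` in μmol m⁻² h⁻¹;
    ``r_squared`` is the coefficient of determination of the OLS fit.
    """

    plot_id: str
    gas: str
    slope_ppmv_per_h: float
    slope_se: float
    flux_umol_m2_h: float
    flux_se: float
    r_squared: float
    n_points: int


def _mol_per_ppmv(pressure_pa: float, volume_m3: float, temperature_k: float) -> float:
    """μmol of gas per ppmv of chamber mixing ratio (ideal gas)."""
    return pressure_pa * volume_m3 / (R_GAS * temperature_k)


def chamber_flux(series: ChamberSeries) -> FluxEstimate:
    """Estimate the soil–atmosphere flux from a chamber series by OLS.

    The slope of mixing ratio on time is converted to μmol m⁻² h⁻¹ via the
    ideal-gas mole content of the chamber; the slope standard error (needs
    ≥ 3 timepoints, reported as NaN for exactly 2) converts with the same
    factor. The estimate is invariant to uniform time shifts.
    """
    t = np.asarray(series.hours, dtype=float)
    y = np.asarray(series.ppmv, dtype=float)
    factor = _mol_per_ppmv(series.pressure_pa, series.volume_m3, series.temperature_k)
    factor /= series.area_m2
    if t.size == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        slope_se, r2 = float("nan"), 1.0
    else:
        fit = stats.linregress(t, y)
        slope, slope_se = float(fit.slope), float(fit.stderr)
        r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return FluxEstimate(
        plot_id=series.plot_id,
        gas=series.gas,
        slope_ppmv_per_h=float(slope),
        slope_se=slope_se,
        flux_umol_m2_h=float(slope) * factor,
        flux_se=slope_se * factor,
        r_squared=r2,
        n_points=int(t.size),
    )


@dataclass(frozen=True)
class RatioSeries:
    """Elementwise CO₂:CH₄ ratios with an explicit undefined mask.

    Points where the denominator is ≤ 0 carry NaN and are marked in
    ``undefined`` rather than raising — the remaining points are unaffected.
    """

    ratios: pd.Series
    undefined: pd.Series


def ratio_series(co2: pd.Series, ch4: pd.Series) -> RatioSeries:
    """CO₂:CH₄ ratio per matched point of two aligned series.

    Both inputs must share an identical index (time/plot keys); a key
    mismatch is an error, not an implicit alignment.
    """
    if not co2.index.equals(ch4.index):
        raise ValueError("CO2 and CH4 series are not aligned on identical keys")
    ch4_values = ch4.astype(float)
    undefined = ch4_values <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = co2.astype(float) / ch4_values
    ratios = ratios.where(~undefined, np.nan)
    if undefined.any():
        logger.warning(
            "CO2:CH4 ratio undefined at %d point(s) with non-positive CH4", int(undefined.sum())
        )
    return RatioSeries(ratios=ratios, undefined=undefined)


@dataclass(frozen=True)
class GasConversionContext:
    """Geometry and conditions of a sealed slurry microcosm.

    ``umol_per_gdw_divisor`` converts μM of slurry to μmol per g dry weight
    of soil; it is a configured constant for the standard 1:10 peat slurry
    rather than a quantity derived from the flask geometry.
    """

    headspace_volume_l: float
    slurry_volume_l: float
    temperature_k: float = DEFAULT_TEMPERATURE_K
    pressure_pa: float = DEFAULT_PRESSURE_PA
    umol_per_gdw_divisor: float = 10.5

    def __post_init__(self) -> None:
        for name in (
            "headspace_volume_l",
            "slurry_volume_l",
            "temperature_k",
            "pressure_pa",
            "umol_per_gdw_divisor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def headspace_to_slurry(vol_percent: float, ctx: GasConversionContext) -> float:
    """Convert a headspace volume percentage to mmol per litre of slurry.

    The gas amount is (vol%/100)·P·V_headspace/(R·T) moles (ideal gas),
    referenced to the slurry volume. Linear in vol_percent.
    """
    if not 0 <= vol_percent <= 100:
        raise ValueError(f"vol_percent must be in [0, 100], got {vol_percent}")
    mol = (
        (vol_percent / 100.0)
        * ctx.pressure_pa
        * (ctx.headspace_volume_l * 1e-3)
        / (R_GAS * ctx.temperature_k)
    )
    return mol / ctx.slurry_volume_l * 1e3  # mol/L -> mmol/L


def umol_per_gdw(conc_uM: float, ctx: GasConversionContext | float = 10.5) -> float:
    """Convert a slurry concentration (μM) to μmol per g dry weight of soil.

    ``ctx`` may be a :class:`GasConversionContext` or a bare divisor
    (default 10.5 for the standard 1:10 peat slurry).
    """
    divisor = ctx.umol_per_gdw_divisor if isinstance(ctx, GasConversionContext) else float(ctx)
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return conc_uM / divisor
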