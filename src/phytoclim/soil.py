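"""Monthly soil-moisture bucket model with Hargreaves-type PET.

Plant-available soil moisture is tracked per cell as a single bucket
bounded by the wilting point (wp) and field capacity (fc). Each month

    W' = clamp(W + P - AET, wp, fc),   AET = min(PET * f(W), W - wp + P)

with the soil-limitation factor ``f(W) = (W - wp) / (fc - wp)`` and any
excess above fc lost to runoff/drainage. The annual cycle is iterated
until it reaches a periodic steady state. Vegetation does not feed back
on evapotranspiration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConvergenceError
from .grids import DAYS_IN_MONTH, Climatology

__all__ = ["SoilMoistureSeries", "hargreaves_pet", "simulate_soil_moisture"]

#: Hargreaves coefficient, offset (degC) and MJ m-2 day-1 -> mm day-1 conversion
HARGREAVES_COEF = 0.0023
HARGREAVES_OFFSET = 17.8
MJ_TO_MM = 0.408

MAX_CYCLES = 50
TOLERANCE_MM = 0.01


@dataclass
class SoilMoistureSeries:
    """12 monthly layers of plant-available water (mm) and PET (mm/month)."""

    moisture: np.ndarray
    pet: np.ndarray


def hargreaves_pet(tmin, tmean, tmax, ra, days_in_month=30.0):
    """Monthly potential evapotranspiration (mm month^-1).

    PET = max(0, 0.0023 * 0.408 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin))
          * days_in_month

    with Ra extraterrestrial/solar radiation in MJ m^-2 day^-1. The
    0.408 factor converts radiative flux to evaporation-equivalent mm
    day^-1. Negative values (very cold cells) clamp to zero.
    """
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    if np.any(tmax < tmin):
        raise ValueError("hargreaves_pet requires tmax >= tmin")
    daily = (
        HARGREAVES_COEF
        * MJ_TO_MM
        * np.asarray(ra, float)
        * (np.asarray(tmean, float) + HARGREAVES_OFFSET)
        * np.sqrt(tmax - tmin)
    )
    return np.maximum(daily, 0.0) * np.asarray(days_in_month, float)


def simulate_soil_moisture(
    clim: Climatology,
    max_cycles: int = MAX_CYCLES,
    tolerance: float = TOLERANCE_MM,
    initial: str = "wp",
) -> SoilMoistureSeries:
    """Run the bucket model to a periodic steady state over the whole grid.

    Iterates the 12-month cycle from ``initial`` ("wp" or "fc") until the
    January state changes by less than ``tolerance`` mm everywhere, then
    records one final annual cycle. Raises ConvergenceError (naming the
    worst cells) if ``max_cycles`` is exhausted.
    """
    fc = clim.field_capacity
    wp = clim.wilting_point
    pet = np.stack(
        [
            hargreaves_pet(clim.tmin[m], clim.tmean[m], clim.tmax[m], clim.rad[m],
                           DAYS_IN_MONTH[m])
            for m in range(12)
        ]
    )
    W = fc.copy() if initial == "fc" else wp.copy()

    span = np.maximum(fc - wp, 1e-12)
    for _ in range(max_cycles):
        w_start = W.copy()
        for m in range(12):
            W = _step(W, clim.precip[m], pet[m], wp, fc, span)
        delta = np.abs(W - w_start)
        if np.nanmax(np.where(clim.grid.land_mask, delta, 0.0)) < tolerance:
            break
    else:
        worst = np.argwhere(np.where(clim.grid.land_mask, delta, 0.0) >= tolerance)
        raise ConvergenceError(
            f"soil moisture did not converge after {max_cycles} annual cycles "
            f"at cells {worst[:10].tolist()}"
        )

    moisture = np.empty_like(pet)
    for m in range(12):
        W = _step(W, clim.precip[m], pet[m], wp, fc, span)
        moisture[m] = W
    return SoilMoistureSeries(moisture=moisture, pet=pet)


def _step(W, P, pet, wp, fc, span):
    avail = W - wp + P          # water above wilting point this month
    aet = np.minimum(pet * (W - wp) / span, np.maximum(avail, 0.0))
    return np.clip(W + P - aet, wp, fc)


def annual_water_balance(clim: Climatology, series: SoilMoistureSeries) -> np.ndarray:
    """Per-cell closure residual over one converged annual cycle (mm).

    Re-steps the converged cycle tracking actual evapotranspiration and
    runoff; the residual sum(P) - sum(AET) - sum(runoff) - dW should be
    ~0 at steady state.
    """
    wp = clim.wilting_point
    fc = clim.field_capacity
    span = np.maximum(fc - wp, 1e-12)
    W = series.moisture[11].copy()
    w0 = W.copy()
    total_p = np.zeros_like(W)
    total_aet = np.zeros_like(W)
    total_runoff = np.zeros_like(W)
    for m in range(12):
        P = clim.precip[m]
        avail = W - wp + P
        aet = np.minimum(series.pet[m] * (W - wp) / span, np.maximum(avail, 0.0))
        w_next_unclamped = W + P - aet
        w_next = np.clip(w_next_unclamped, wp, fc)
        total_p += P
        total_aet += aet
        total_runoff += np.maximum(w_next_unclamped - fc, 0.0)
        W = w_next
    return total_p - total_aet - total_runoff - (W - w0)
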