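"""Ecocrop-style crop climatic suitability index.

For each grid cell and each candidate start month i (1..12, wrapping
December into January), a growing season of the crop's fixed length L is
scored as

    SUIT_i = Tsuit_i * Rsuit_i

where Tsuit_i is the minimum over the season's months of a monthly
temperature score, and Rsuit_i scores the season's total rainfall. Both
factors are trapezoidal (piecewise-linear) memberships over the crop's
absolute and optimal thresholds: 0 at or beyond the absolute limits, 1 on
the optimal plateau, linear on the shoulders. A month whose minimum
temperature falls to the kill temperature or below zeroes that month's
score (and hence the whole season, via the min): frost or heat-kill admits
no compensation by otherwise favourable conditions.

The index lies in [0, 1]; categories follow the conventional five-band
scheme (unsuitable up to 0.2, then very marginal, marginal, suitable,
highly suitable in 0.2-wide bands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .climate_io import MonthlyClimatology
from .crop_params import CropParameters

__all__ = [
    "SuitabilityCube",
    "CATEGORY_LABELS",
    "CATEGORY_EDGES",
    "trapezoid_suitability",
    "monthly_temperature_suitability",
    "season_suitability",
    "compute_suitability",
    "compute_suitability_cube",
    "classify_siv",
]

CATEGORY_LABELS = [
    "Unsuitable",
    "Very Marginally suitable",
    "Marginally suitable",
    "Suitable",
    "Highly suitable",
]
# contiguous upper-inclusive bands: [0,0.2], (0.2,0.4], ... (0.8,1.0]
CATEGORY_EDGES = np.array([0.2, 0.4, 0.6, 0.8])


@dataclass
class SuitabilityCube:
    """Suitability index per cell and candidate start month (lat x lon x 12)."""

    lats: np.ndarray
    lons: np.ndarray
    suit: np.ndarray
    mask: np.ndarray
    crop_name: str
    member_id: str = "member"
    period: tuple[int, int] = (0, 0)

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.suit,
            coords={
                "lat": self.lats,
                "lon": self.lons,
                "start_month": np.arange(1, 13),
            },
            dims=("lat", "lon", "start_month"),
            name="suitability_index",
            attrs={
                "crop": self.crop_name,
                "member_id": self.member_id,
                "period_start": int(self.period[0]),
                "period_end": int(self.period[1]),
                "long_name": "Ecocrop suitability index",
            },
        )


def trapezoid_suitability(
    x, abs_min: float, opt_min: float, opt_max: float, abs_max: float
):
    """Piecewise-linear membership: 0 outside the absolute range, 1 on the
    optimal plateau, linear shoulders between. The plateau wins at a
    degenerate zero-width shoulder (abs == opt). Accepts scalars or arrays.
    """
    if not (abs_min <= opt_min <= opt_max <= abs_max):
        raise ValueError(
            f"unordered trapezoid bounds ({abs_min}, {opt_min}, {opt_max}, {abs_max})"
        )
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    plateau = (x >= opt_min) & (x <= opt_max)
    out[plateau] = 1.0
    if opt_min > abs_min:
        lo = (x > abs_min) & (x < opt_min)
        out[lo] = (x[lo] - abs_min) / (opt_min - abs_min)
    if abs_max > opt_max:
        hi = (x > opt_max) & (x < abs_max)
        out[hi] = (abs_max - x[hi]) / (abs_max - opt_max)
    out = np.where(np.isnan(x), np.nan, out)
    return out if out.ndim else float(out)


def monthly_temperature_suitability(tmin_m, tmean_m, p: CropParameters):
    """Monthly temperature score: kill rule on tmin, trapezoid on tmean."""
    score = trapezoid_suitability(
        tmean_m, p.t_abs_min, p.t_opt_min, p.t_opt_max, p.t_abs_max
    )
    killed = np.asarray(tmin_m) <= p.ktmp
    score = np.where(killed, 0.0, score)
    score = np.where(np.isnan(np.asarray(tmin_m, dtype=float)), np.nan, score)
    return score if np.ndim(score) else float(score)


def compute_suitability(
    tmin: np.ndarray, tmean: np.ndarray, prec: np.ndarray, p: CropParameters
) -> np.ndarray:
    """Vectorised SUIT for all 12 start months.

    Inputs have shape (..., 12) with the last axis the calendar month; the
    output has the same shape with the last axis the candidate start month.
    Seasons wrap December -> January. NaN climate propagates to NaN scores.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    prec = np.asarray(prec, dtype=float)
    if tmin.shape[-1] != 12:
        raise ValueError("last axis must be the 12 calendar months")
    L = int(p.season_length)
    monthly = monthly_temperature_suitability(tmin, tmean, p)
    monthly = np.asarray(monthly)

    suit = np.empty_like(tmean)
    for start in range(12):
        idx = (start + np.arange(L)) % 12
        tsuit = np.min(monthly[..., idx], axis=-1)
        season_rain = np.sum(prec[..., idx], axis=-1)
        rsuit = trapezoid_suitability(
            season_rain, p.r_abs_min, p.r_opt_min, p.r_opt_max, p.r_abs_max
        )
        suit[..., start] = tsuit * rsuit
    return suit


def season_suitability(
    tmin12: np.ndarray, tmean12: np.ndarray, prec12: np.ndarray,
    start_month: int, p: CropParameters,
) -> float:
    """SUIT for one cell and one start month (1 = January)."""
    if not 1 <= start_month <= 12:
        raise ValueError("start_month must be in 1..12")
    return float(
        compute_suitability(
            np.asarray(tmin12)[None, :],
            np.asarray(tmean12)[None, :],
            np.asarray(prec12)[None, :],
            p,
        )[0, start_month - 1]
    )


def compute_suitability_cube(
    c: MonthlyClimatology, p: CropParameters
) -> SuitabilityCube:
    """Evaluate the index for every valid cell and all 12 start months."""
    p.validated()
    suit = compute_suitability(c.tmin, c.tmean, c.prec, p)
    suit = np.where(c.mask[..., None], suit, np.nan)
    return SuitabilityCube(
        lats=c.lats, lons=c.lons, suit=suit, mask=c.mask,
        crop_name=p.crop_name, member_id=c.member_id, period=c.period,
    )


def classify_siv(siv):
    """Map index values to category labels (vectorised).

    Bands are upper-inclusive: (0.2, 0.4] is 'Very Marginally suitable' etc.
    """
    arr = np.asarray(siv, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("suitability index must lie in [0, 1]")
    idx = np.searchsorted(CATEGORY_EDGES, arr, side="left")
    if np.ndim(siv) == 0:
        return CATEGORY_LABELS[int(idx)] if np.isfinite(arr) else None
    labels = np.asarray(CATEGORY_LABELS, dtype=object)[idx]
    labels[~np.isfinite(arr)] = None
    return labels
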