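"""Planting-window extraction and planting-month shifts.

The planting month (PM) is the first month of the best three consecutive
months of the 12-value suitability cycle, with December wrapping into
January; the window mean of those three values is the reported suitability.
Shifts between periods are the minimal circular month difference, positive
for a delay (e.g. April to June is +2, February to December is -2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .crop_params import CropParameters
from .ecocrop import SuitabilityCube

__all__ = [
    "PlantingResult",
    "best_consecutive_window",
    "circular_window_means",
    "planting_month_map",
    "planting_shift",
]

YEAR_ROUND_EPS = 1e-9


@dataclass(frozen=True)
class PlantingResult:
    """Best planting window at one cell."""

    best_start_month: int
    window_mean_siv: float
    year_round: bool = False


def circular_window_means(suit: np.ndarray, k: int = 3) -> np.ndarray:
    """Mean of k consecutive values for each start (last axis = 12, wraps)."""
    suit = np.asarray(suit, dtype=float)
    if suit.shape[-1] != 12:
        raise ValueError("last axis must have length 12")
    out = np.empty_like(suit)
    for start in range(12):
        idx = (start + np.arange(k)) % 12
        out[..., start] = suit[..., idx].mean(axis=-1)
    return out


def best_consecutive_window(
    suit12, k: int = 3, search_order_start: int = 1
) -> PlantingResult:
    """Best k-month circular window of a 12-value suitability cycle.

    Ties go to the earliest start month in the search order beginning at
    ``search_order_start`` (default January). NaN input yields a NaN result
    rather than raising, so masked cells propagate.
    """
    v = np.asarray(suit12, dtype=float)
    if v.shape != (12,):
        raise ValueError("suit12 must be a 12-vector")
    if np.any(np.isnan(v)):
        return PlantingResult(best_start_month=-1, window_mean_siv=float("nan"))
    means = circular_window_means(v, k)
    order = (np.arange(12) + (search_order_start - 1)) % 12
    best = order[int(np.argmax(means[order]))]
    year_round = bool(np.all(means >= means.max() - YEAR_ROUND_EPS))
    return PlantingResult(
        best_start_month=int(best) + 1,
        window_mean_siv=float(means[best]),
        year_round=year_round,
    )


def planting_month_map(
    cube: SuitabilityCube,
    p: CropParameters | None = None,
    k: int = 3,
    search_order_start: int = 1,
) -> xr.Dataset:
    """Per-cell best planting month and window-mean suitability grids.

    Crops flagged ``plant_any_month`` are marked year-round everywhere; the
    window mean is still reported so changes remain comparable.
    """
    means = circular_window_means(cube.suit, k)  # (lat, lon, 12)
    order = (np.arange(12) + (search_order_start - 1)) % 12
    reordered = means[..., order]
    with np.errstate(invalid="ignore"):
        arg = np.argmax(np.nan_to_num(reordered, nan=-np.inf), axis=-1)
    best_start = order[arg] + 1.0
    best_mean = np.take_along_axis(means, (order[arg])[..., None], axis=-1)[..., 0]
    invalid = ~cube.mask | np.isnan(cube.suit).any(axis=-1)
    best_start = np.where(invalid, np.nan, best_start)
    best_mean = np.where(invalid, np.nan, best_mean)
    with warnings.catch_warnings():
        # masked cells are all-NaN along the start axis; they are dropped
        # by the `invalid` guard below
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanmax(means, axis=-1) - np.nanmin(means, axis=-1)
    year_round = np.where(invalid, False, spread <= YEAR_ROUND_EPS)
    if p is not None and p.plant_any_month:
        year_round = np.where(invalid, False, True)
    coords = {"lat": cube.lats, "lon": cube.lons}
    return xr.Dataset(
        {
            "planting_month": (("lat", "lon"), best_start),
            "planting_window_mean_siv": (("lat", "lon"), best_mean),
            "year_round": (("lat", "lon"), year_round.astype(bool)),
        },
        coords=coords,
        attrs={"crop": cube.crop_name, "member_id": cube.member_id,
               "window_months": k},
    )


def planting_shift(pm_hist: int, pm_gwl: int) -> int:
    """Signed minimal circular month shift, in [-5, +6]; + is a delay.

    An exact six-month displacement is ambiguous and reported as +6.
    """
    for m in (pm_hist, pm_gwl):
        if not (isinstance(m, (int, np.integer)) and 1 <= int(m) <= 12):
            raise ValueError(f"month out of range: {m!r}")
    d = (int(pm_gwl) - int(pm_hist)) % 12
    return d - 12 if d > 6 else d


def planting_shift_map(pm_hist: np.ndarray, pm_gwl: np.ndarray) -> np.ndarray:
    """Elementwise circular shift grid; NaN propagates."""
    a = np.asarray(pm_hist, dtype=float)
    b = np.asarray(pm_gwl, dtype=float)
    d = np.mod(b - a, 12)
    d = np.where(d > 6, d - 12, d)
    return np.where(np.isnan(a) | np.isnan(b), np.nan, d)
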