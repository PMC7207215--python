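"""Gridded monthly climate containers, NetCDF I/O, regions, and model skill.

The analysis runs on monthly climatologies of minimum temperature, mean
temperature and total precipitation over a West African domain
(2-20N, 20W-20E). Agro-ecological zones follow the conventional latitude
bands: Guinea (4-8N), Savanna (8-12N), Sahel (12-20N); a band boundary
belongs to the zone to its north (half-open intervals).

All gridded I/O is CF-style NetCDF through xarray. Inputs must share one
grid; mismatches are errors, never silent interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "MonthlyClimatology",
    "AnnualRealizations",
    "RegionDefinition",
    "DEFAULT_REGIONS",
    "DOMAIN",
    "read_monthly_climatology",
    "write_climatology",
    "write_field",
    "assign_aez",
    "evaluate_against_reference",
]

MONTHS = np.arange(1, 13)


@dataclass
class RegionDefinition:
    """A named latitude/longitude box."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float = -20.0
    lon_max: float = 20.0

    def __post_init__(self):
        if not self.lat_min < self.lat_max:
            raise ValueError(f"region {self.name}: lat_min must be < lat_max")

    def contains_lat(self, lat: np.ndarray) -> np.ndarray:
        return (lat >= self.lat_min) & (lat < self.lat_max)


DOMAIN = RegionDefinition("domain", 2.0, 20.0, -20.0, 20.0)
DEFAULT_REGIONS = [
    RegionDefinition("Guinea", 4.0, 8.0),
    RegionDefinition("Savanna", 8.0, 12.0),
    RegionDefinition("Sahel", 12.0, 20.0),
]


@dataclass
class MonthlyClimatology:
    """lat x lon x 12 monthly fields for one member and one 30-year window.

    ``tmin``/``tmean`` in degC, ``prec`` in mm/month. ``mask`` is True on
    valid (land) cells; invalid cells may hold NaN.
    """

    lats: np.ndarray
    lons: np.ndarray
    tmin: np.ndarray
    tmean: np.ndarray
    prec: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    member_id: str = "member"
    period: tuple[int, int] = (1971, 2000)

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        shape = (self.lats.size, self.lons.size, 12)
        for name in ("tmin", "tmean", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        if self.mask is None:
            self.mask = np.isfinite(self.tmean).all(axis=-1)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != shape[:2]:
            raise ValueError("mask shape must be lat x lon")

    def check_invariants(self) -> None:
        m = self.mask
        if np.any(self.tmin[m] > self.tmean[m] + 1e-9):
            raise ValueError("tmin exceeds tmean on valid cells")
        if np.any(self.prec[m] < -1e-9):
            raise ValueError("negative precipitation on valid cells")

    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.lats, "lon": self.lons, "month": MONTHS}
        dims = ("lat", "lon", "month")
        ds = xr.Dataset(
            {
                "tmin": (dims, self.tmin, {"units": "degC"}),
                "tmean": (dims, self.tmean, {"units": "degC"}),
                "prec": (dims, self.prec, {"units": "mm/month"}),
                "mask": (("lat", "lon"), self.mask.astype(np.int8)),
            },
            coords=coords,
            attrs={
                "member_id": self.member_id,
                "period_start": int(self.period[0]),
                "period_end": int(self.period[1]),
                "Conventions": "CF-1.8",
            },
        )
        ds["lat"].attrs["units"] = "degrees_north"
        ds["lon"].attrs["units"] = "degrees_east"
        return ds


@dataclass
class AnnualRealizations:
    """Per-year monthly fields (year x lat x lon x 12) for one 30-yr window.

    Averaging over the year axis reproduces a MonthlyClimatology; the
    per-year fields feed the per-member significance test.
    """

    lats: np.ndarray
    lons: np.ndarray
    tmin: np.ndarray
    tmean: np.ndarray
    prec: np.ndarray
    mask: np.ndarray
    member_id: str = "member"
    period: tuple[int, int] = (1971, 2000)

    @property
    def n_years(self) -> int:
        return self.tmean.shape[0]

    def mean_climatology(self) -> MonthlyClimatology:
        return MonthlyClimatology(
            lats=self.lats,
            lons=self.lons,
            tmin=self.tmin.mean(axis=0),
            tmean=self.tmean.mean(axis=0),
            prec=self.prec.mean(axis=0),
            mask=self.mask,
            member_id=self.member_id,
            period=self.period,
        )


def _coerce_temperature(da: xr.DataArray) -> np.ndarray:
    units = str(da.attrs.get("units", "degC")).lower()
    values = np.asarray(da, dtype=float)
    if units in {"k", "kelvin"}:
        return values - 273.15
    if units in {"degc", "celsius", "deg_c", "c", "degrees_celsius", "°c"}:
        return values
    raise ValueError(f"unrecognised temperature unit '{da.attrs.get('units')}'")


def _coerce_precip(da: xr.DataArray) -> np.ndarray:
    units = str(da.attrs.get("units", "mm/month")).lower()
    values = np.asarray(da, dtype=float)
    if units in {"mm/month", "mm month-1", "mm", "mm/mon"}:
        return values
    raise ValueError(f"unrecognised precipitation unit '{da.attrs.get('units')}'")


def read_monthly_climatology(
    path: str | Path,
    variables: Mapping[str, str] | None = None,
    member_id: str | None = None,
    period: tuple[int, int] | None = None,
) -> MonthlyClimatology:
    """Read a CF-style NetCDF monthly climatology.

    ``variables`` maps the canonical names tmin/tmean/prec to the file's
    variable names (identity by default). Temperatures are coerced to degC
    (Kelvin recognised), latitude is returned ascending, and the mask is
    taken from the file's mask variable or from non-finite values.
    """
    variables = dict(variables or {})
    ds = xr.open_dataset(path)
    try:
        month_dim = "month" if "month" in ds.dims else "time"
        if month_dim not in ds.dims or ds.sizes[month_dim] != 12:
            raise ValueError(f"{path}: month axis must have length 12")
        if month_dim != "month":
            ds = ds.rename({month_dim: "month"})
        ds = ds.transpose("lat", "lon", "month", missing_dims="ignore")
        lats = np.asarray(ds["lat"], dtype=float)
        flip = lats.size > 1 and lats[0] > lats[-1]
        if flip:
            ds = ds.isel(lat=slice(None, None, -1))
            lats = lats[::-1]
        names = {v: variables.get(v, v) for v in ("tmin", "tmean", "prec")}
        for canon, actual in names.items():
            if actual not in ds:
                raise ValueError(f"{path}: missing variable '{actual}' ({canon})")
        tmin = _coerce_temperature(ds[names["tmin"]])
        tmean = _coerce_temperature(ds[names["tmean"]])
        prec = _coerce_precip(ds[names["prec"]])
        if "mask" in ds:
            mask = np.asarray(ds["mask"], dtype=bool)
        else:
            mask = np.isfinite(tmean).all(axis=-1)
        clim = MonthlyClimatology(
            lats=lats,
            lons=np.asarray(ds["lon"], dtype=float),
            tmin=tmin,
            tmean=tmean,
            prec=prec,
            mask=mask,
            member_id=member_id or str(ds.attrs.get("member_id", "member")),
            period=period
            or (
                int(ds.attrs.get("period_start", 0)),
                int(ds.attrs.get("period_end", 0)),
            ),
        )
    finally:
        ds.close()
    return clim


def write_climatology(clim: MonthlyClimatology, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clim.to_dataset().to_netcdf(path)
    return path


def write_field(
    field_da: xr.DataArray | xr.Dataset,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> Path:
    """Write a result field as CF-style NetCDF with provenance attributes.

    NaN is encoded as the fill value; metadata (crop, GWL, member, seed,
    config hash ...) lands in the global attributes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj = field_da.copy()
    for k, v in (metadata or {}).items():
        obj.attrs[k] = v
    encoding = None
    if isinstance(obj, xr.DataArray):
        if obj.name is None:
            obj.name = "field"
        if np.issubdtype(np.asarray(obj).dtype, np.floating):
            encoding = {obj.name: {"_FillValue": np.float64(np.nan)}}
    obj.to_netcdf(path, encoding=encoding)
    return path


def assign_aez(
    lats: np.ndarray | float,
    regions: Sequence[RegionDefinition] = tuple(DEFAULT_REGIONS),
) -> np.ndarray:
    """Map latitudes to agro-ecological zone labels.

    Boundaries are half-open [lo, hi): a printed boundary latitude (8, 12)
    belongs to the zone to its north. Latitudes in no zone get 'outside'.
    """
    arr = np.atleast_1d(np.asarray(lats, dtype=float))
    labels = np.full(arr.shape, "outside", dtype=object)
    for region in regions:
        labels[region.contains_lat(arr)] = region.name
    return labels if np.ndim(lats) else labels.item()


def evaluate_against_reference(
    model: MonthlyClimatology,
    ref: MonthlyClimatology,
    pooling: str = "monthly",
) -> pd.DataFrame:
    """Spatial Pearson correlation of model vs reference per variable.

    ``pooling='monthly'`` pools all valid (cell, month) pairs;
    ``pooling='annual'`` correlates annual-mean fields. Used as the skill
    screen before feeding a model's climate into the suitability engine
    (temperature is expected to correlate more strongly than rainfall).
    """
    if model.lats.shape != ref.lats.shape or not np.allclose(model.lats, ref.lats):
        raise ValueError("latitude grids differ")
    if model.lons.shape != ref.lons.shape or not np.allclose(model.lons, ref.lons):
        raise ValueError("longitude grids differ")
    if not np.array_equal(model.mask, ref.mask):
        raise ValueError("masks differ")
    rows = []
    for name in ("tmin", "tmean", "prec"):
        a = getattr(model, name)
        b = getattr(ref, name)
        if pooling == "monthly":
            sel = np.broadcast_to(model.mask[..., None], a.shape)
            x, y = a[sel], b[sel]
        elif pooling == "annual":
            x = a.mean(axis=-1)[model.mask]
            y = b.mean(axis=-1)[model.mask]
        else:
            raise ValueError(f"unknown pooling '{pooling}'")
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise ValueError(f"{name}: fewer than 3 valid pairs")
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"variable": name, "r": r, "n_cells": int(x.size)})
    return pd.DataFrame(rows)
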