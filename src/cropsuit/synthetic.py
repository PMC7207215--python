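"""Synthetic monsoon-like climate with the structure the analysis assumes.

The generator emulates a West African domain (2-20N, 20W-20E): mean
temperature increases northward along a linear meridional gradient with a
small annual harmonic; rainfall is a single wet season, a Gaussian-in-month
bump whose amplitude decays exponentially northward and whose peak month
migrates slowly with latitude (the monsoon arriving later inland).
Ensemble members differ by a constant temperature offset and a fractional
precipitation factor; annual realizations add year-to-year noise around a
member's climatology. All randomness flows from explicit seeds, never
global state, so identical seeds give identical fields.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .climate_io import AnnualRealizations, MonthlyClimatology
from .gwl_timing import GsatSeries

__all__ = [
    "SyntheticClimateSpec",
    "generate_gsat_series",
    "generate_monsoon_climatology",
    "generate_ensemble",
    "generate_annual_realizations",
    "circular_month_distance",
]


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of the synthetic monsoon climate.

    Temperatures in degC, precipitation in mm/month, gradients per degree
    latitude northward from the southern edge.
    """

    lat_min: float = 2.0
    lat_max: float = 20.0
    lon_min: float = -20.0
    lon_max: float = 20.0
    spacing: float = 0.5
    t_south: float = 26.0           # annual-mean tmean at the southern edge
    t_gradient: float = 0.5         # degC per degree latitude, northward
    seasonal_amplitude: float = 2.0  # annual harmonic half-range
    seasonal_peak_month: float = 4.0  # hottest month (pre-monsoon)
    p_peak_south: float = 250.0     # wet-season peak rainfall at south edge
    p_gradient: float = 0.08        # exponential decay per degree northward
    wet_center_south: float = 7.0   # wet-season peak month at south edge
    wet_center_gradient: float = 0.08  # months per degree latitude
    wet_season_width: float = 2.0   # Gaussian width in months
    diurnal_offset: float = 8.0     # tmean - tmin
    member_sigma_t: float = 0.3     # member temperature offset scale
    member_sigma_p: float = 0.10    # member fractional precip scale
    interannual_sigma_t: float = 0.5
    interannual_sigma_p: float = 0.15
    seed: int = 0

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre latitudes (ascending) and longitudes."""
        lats = np.arange(self.lat_min + self.spacing / 2, self.lat_max, self.spacing)
        lons = np.arange(self.lon_min + self.spacing / 2, self.lon_max, self.spacing)
        return lats, lons

    def wet_season_center(self, lat) -> np.ndarray:
        return self.wet_center_south + self.wet_center_gradient * (
            np.asarray(lat, dtype=float) - self.lat_min
        )

    def with_shifted_wet_season(self, months: float) -> "SyntheticClimateSpec":
        return replace(self, wet_center_south=self.wet_center_south + months)


def circular_month_distance(m, center):
    """Signed distance in months on the 12-month circle, in (-6, 6]."""
    d = np.mod(np.asarray(m, dtype=float) - np.asarray(center, dtype=float), 12.0)
    return np.where(d > 6.0, d - 12.0, d)


def _member_rng(spec: SyntheticClimateSpec, member_id: str, seed: int | None) -> np.random.Generator:
    root = spec.seed if seed is None else seed
    return np.random.default_rng(
        np.random.SeedSequence([int(root), zlib.crc32(member_id.encode())])
    )


def generate_gsat_series(
    start_year: int = 1861,
    end_year: int = 2100,
    base_temp: float = 13.8,
    warming_rate: float = 0.02,
    noise_sd: float = 0.1,
    seed: int = 0,
    member_id: str = "member",
) -> GsatSeries:
    """Annual global-mean temperature: linear ramp plus Gaussian noise."""
    if warming_rate < 0:
        raise ValueError("warming_rate must be >= 0")
    years = np.arange(start_year, end_year + 1)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(member_id.encode())])
    )
    temps = base_temp + warming_rate * (years - start_year)
    if noise_sd > 0:
        temps = temps + rng.normal(0.0, noise_sd, size=years.size)
    return GsatSeries(years, temps, member_id)


def _base_fields(
    spec: SyntheticClimateSpec, delta_t: float, precip_scale: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    lats, lons = spec.grid()
    months = np.arange(1, 13, dtype=float)
    seasonal = spec.seasonal_amplitude * np.cos(
        2 * np.pi * (months - spec.seasonal_peak_month) / 12.0
    )
    tmean = (
        spec.t_south
        + spec.t_gradient * (lats - spec.lat_min)[:, None, None]
        + seasonal[None, None, :]
        + delta_t
    ) * np.ones((1, lons.size, 1))
    amp = spec.p_peak_south * np.exp(-spec.p_gradient * (lats - spec.lat_min))
    center = spec.wet_season_center(lats)
    d = circular_month_distance(months[None, :], center[:, None])
    bump = np.exp(-0.5 * (d / spec.wet_season_width) ** 2)
    prec = precip_scale * (amp[:, None] * bump)[:, None, :] * np.ones((1, lons.size, 1))
    return lats, lons, tmean, prec


def generate_monsoon_climatology(
    spec: SyntheticClimateSpec,
    member_id: str = "m01",
    period: tuple[int, int] = (1971, 2000),
    delta_t: float = 0.0,
    precip_scale: float = 1.0,
    seed: int | None = None,
) -> MonthlyClimatology:
    """One member's 30-year monthly climatology.

    ``delta_t`` shifts both temperatures uniformly; ``precip_scale``
    multiplies rainfall. The member perturbation is a constant temperature
    offset and fractional precipitation factor drawn deterministically from
    (seed, member_id), so the same member keeps its identity across periods
    and forcing levels.
    """
    lats, lons, tmean, prec = _base_fields(spec, delta_t, precip_scale)
    rng = _member_rng(spec, member_id, seed)
    member_dt = rng.normal(0.0, spec.member_sigma_t)
    member_pf = max(0.0, 1.0 + rng.normal(0.0, spec.member_sigma_p))
    tmean = tmean + member_dt
    prec = prec * member_pf
    clim = MonthlyClimatology(
        lats=lats,
        lons=lons,
        tmin=tmean - spec.diurnal_offset,
        tmean=tmean,
        prec=prec,
        mask=np.ones((lats.size, lons.size), dtype=bool),
        member_id=member_id,
        period=period,
    )
    clim.check_invariants()
    return clim


def generate_ensemble(
    spec: SyntheticClimateSpec,
    n_members: int = 10,
    period: tuple[int, int] = (1971, 2000),
    delta_t: float = 0.0,
    precip_scale: float = 1.0,
    seed: int | None = None,
) -> list[MonthlyClimatology]:
    """Independent member climatologies m01..mNN, deterministic under seed."""
    if n_members < 2:
        raise ValueError("an ensemble needs at least 2 members")
    return [
        generate_monsoon_climatology(
            spec, f"m{i + 1:02d}", period, delta_t, precip_scale, seed=seed
        )
        for i in range(n_members)
    ]


def generate_annual_realizations(
    clim: MonthlyClimatology,
    interannual_sigma: tuple[float, float] = (0.5, 0.15),
    n_years: int = 30,
    seed: int = 0,
) -> AnnualRealizations:
    """Per-year monthly fields around a member climatology.

    Each (year, month) draws one temperature offset (degC) and one
    fractional precipitation factor, shared across the grid — emulating
    region-wide interannual variability. The year-mean converges on the
    climatology as the noise scales shrink.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years")
    sigma_t, sigma_p = interannual_sigma
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), zlib.crc32(clim.member_id.encode()),
             int(clim.period[0]), int(clim.period[1])]
        )
    )
    dt = rng.normal(0.0, sigma_t, size=(n_years, 12)) if sigma_t > 0 else np.zeros((n_years, 12))
    pf = (
        np.maximum(0.0, 1.0 + rng.normal(0.0, sigma_p, size=(n_years, 12)))
        if sigma_p > 0
        else np.ones((n_years, 12))
    )
    tmean = clim.tmean[None] + dt[:, None, None, :]
    tmin = clim.tmin[None] + dt[:, None, None, :]
    prec = clim.prec[None] * pf[:, None, None, :]
    return AnnualRealizations(
        lats=clim.lats,
        lons=clim.lons,
        tmin=tmin,
        tmean=tmean,
        prec=prec,
        mask=clim.mask,
        member_id=clim.member_id,
        period=clim.period,
    )
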