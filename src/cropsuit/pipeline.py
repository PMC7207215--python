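"""End-to-end orchestration: synthetic climate -> warming-level windows ->
suitability cubes -> planting windows -> ensemble change and robustness ->
regional summaries and trend tables.

Stages write their products under the output directory and can be resumed:
a stage whose outputs already exist is reloaded rather than recomputed
(except the change stage's annual noise, which is cheap and deterministic
under the configured seed, so it is always regenerated from the config).
Every product carries the config hash and seed in its attributes, and a
run manifest lists all files written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import change as change_mod
from . import climate_io, ecocrop, gwl_timing, planting, synthetic, trends
from .crop_params import CropParameters, load_crop_parameters

logger = logging.getLogger("cropsuit.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    Defaults reproduce the analysis constants: warming levels 1.5/2.0/3.0,
    reference period 1971-2000, pre-industrial baseline 1861-1890, 30-year
    windows, 80% robustness thresholds at the 1% significance level.
    """

    outdir: str = "out"
    crop_registry: str = "builtin"
    crops: Sequence[str] | None = None  # None = all crops in the registry
    levels: Sequence[float] = (1.5, 2.0, 3.0)
    baseline_period: tuple[int, int] = (1971, 2000)
    preindustrial_baseline: tuple[int, int] = (1861, 1890)
    window_length: int = 30
    n_members: int = 10
    agreement_threshold: float = 0.8
    significance_alpha: float = 0.01
    regional_amplification: float = 1.2   # regional dT per degC of global warming
    precip_change_per_degree: float = -0.03  # fractional precip change per degC
    gsat_base_temp: float = 13.8
    gsat_warming_rate: float = 0.02
    gsat_noise_sd: float = 0.1
    seed: int = 42
    synthetic: synthetic.SyntheticClimateSpec = field(
        default_factory=synthetic.SyntheticClimateSpec
    )

    def __post_init__(self):
        if not isinstance(self.synthetic, synthetic.SyntheticClimateSpec):
            self.synthetic = synthetic.SyntheticClimateSpec(**dict(self.synthetic))
        self.levels = tuple(float(v) for v in self.levels)
        self.baseline_period = tuple(int(v) for v in self.baseline_period)
        self.preindustrial_baseline = tuple(int(v) for v in self.preindustrial_baseline)

    # -- forcing mapping -------------------------------------------------
    def delta_t(self, level: float) -> float:
        return self.regional_amplification * level

    def precip_scale(self, level: float) -> float:
        return max(0.0, 1.0 + self.precip_change_per_degree * level)

    def period_keys(self) -> list[str]:
        return ["historical"] + [f"GWL{lvl}" for lvl in self.levels]

    def level_of(self, key: str) -> float:
        return 0.0 if key == "historical" else float(key[3:])

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = synthetic.SyntheticClimateSpec(**d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_crops(config: PipelineConfig) -> list[CropParameters]:
    records = load_crop_parameters(config.crop_registry)
    if config.crops is None:
        return records
    wanted = set(config.crops)
    records = [p for p in records if p.crop_name in wanted]
    missing = wanted - {p.crop_name for p in records}
    if missing:
        raise FileNotFoundError(
            f"crop registry '{config.crop_registry}' lacks: {sorted(missing)}"
        )
    return records


def _member_ids(config: PipelineConfig) -> list[str]:
    return [f"m{i + 1:02d}" for i in range(config.n_members)]


# ---------------------------------------------------------------------------
# stages


def stage_gwl(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Per-member GSAT series and warming-level crossing table."""
    path = outdir / "gwl" / "gwl_windows.csv"
    if path.exists():
        logger.info("gwl: reusing %s", path)
        return pd.read_csv(path)
    series = [
        synthetic.generate_gsat_series(
            base_temp=config.gsat_base_temp,
            warming_rate=config.gsat_warming_rate,
            noise_sd=config.gsat_noise_sd,
            seed=config.seed,
            member_id=m,
        )
        for m in _member_ids(config)
    ]
    table = gwl_timing.gwl_windows_table(
        series, levels=tuple(config.levels), baseline=config.preindustrial_baseline
    )
    if table[["mid_year"]].isna().any().any():
        bad = table[table["mid_year"].isna()]
        raise RuntimeError(
            "gwl: some members never reach a level: "
            + ", ".join(f"{r.member_id}@{r.level}" for r in bad.itertuples())
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return table


def _period_years(
    config: PipelineConfig, gwl_table: pd.DataFrame, key: str, member_id: str
) -> tuple[int, int]:
    if key == "historical":
        return config.baseline_period
    level = config.level_of(key)
    row = gwl_table[
        (gwl_table["member_id"] == member_id) & (gwl_table["level"] == level)
    ]
    return int(row["start_year"].iloc[0]), int(row["end_year"].iloc[0])


def stage_climate(
    config: PipelineConfig, outdir: Path, gwl_table: pd.DataFrame
) -> dict[str, list[climate_io.MonthlyClimatology]]:
    """Member climatologies per period, forced per warming level."""
    climates: dict[str, list[climate_io.MonthlyClimatology]] = {}
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    for key in config.period_keys():
        level = config.level_of(key)
        members = []
        for m in _member_ids(config):
            path = outdir / "climate" / key / f"{m}.nc"
            if path.exists():
                clim = climate_io.read_monthly_climatology(path)
            else:
                clim = synthetic.generate_monsoon_climatology(
                    config.synthetic,
                    member_id=m,
                    period=_period_years(config, gwl_table, key, m),
                    delta_t=config.delta_t(level),
                    precip_scale=config.precip_scale(level),
                    seed=config.seed,
                )
                ds = clim.to_dataset()
                ds.attrs.update(meta, gwl=level)
                path.parent.mkdir(parents=True, exist_ok=True)
                ds.to_netcdf(path)
            members.append(clim)
        climates[key] = members
    return climates


def stage_suitability(
    config: PipelineConfig,
    outdir: Path,
    climates: dict[str, list[climate_io.MonthlyClimatology]],
    crops: list[CropParameters],
) -> dict[tuple[str, str], xr.Dataset]:
    """Suitability cubes and planting maps per crop x period (member-stacked)."""
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    products: dict[tuple[str, str], xr.Dataset] = {}
    for crop in crops:
        for key, members in climates.items():
            path = outdir / "suitability" / f"{crop.crop_name}_{key}.nc"
            if path.exists():
                products[(crop.crop_name, key)] = xr.load_dataset(path)
                continue
            cubes = [ecocrop.compute_suitability_cube(c, crop) for c in members]
            maps = [planting.planting_month_map(cb, crop) for cb in cubes]
            ds = xr.Dataset(
                {
                    "suitability_index": (
                        ("member", "lat", "lon", "start_month"),
                        np.stack([cb.suit for cb in cubes]),
                    ),
                    "planting_month": (
                        ("member", "lat", "lon"),
                        np.stack([m["planting_month"].values for m in maps]),
                    ),
                    "planting_window_mean_siv": (
                        ("member", "lat", "lon"),
                        np.stack(
                            [m["planting_window_mean_siv"].values for m in maps]
                        ),
                    ),
                },
                coords={
                    "member": [c.member_id for c in members],
                    "lat": cubes[0].lats,
                    "lon": cubes[0].lons,
                    "start_month": np.arange(1, 13),
                },
                attrs={**meta, "crop": crop.crop_name, "period": key,
                       "gwl": config.level_of(key)},
            )
            path.parent.mkdir(parents=True, exist_ok=True)
            ds.to_netcdf(path)
            products[(crop.crop_name, key)] = ds
    return products


def _annual_window_means(
    config: PipelineConfig,
    climates: dict[str, list[climate_io.MonthlyClimatology]],
    crops: list[CropParameters],
) -> dict[tuple[str, str], np.ndarray]:
    """(member, year, lat, lon) annual best-window suitability per crop x period.

    Regenerated from config (cheap, deterministic) rather than stored: the
    per-year noisy fields would dominate the on-disk footprint.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    sigma = (config.synthetic.interannual_sigma_t, config.synthetic.interannual_sigma_p)
    for key, members in climates.items():
        annual_stack: dict[str, list[np.ndarray]] = {c.crop_name: [] for c in crops}
        for clim in members:
            ann = synthetic.generate_annual_realizations(
                clim, interannual_sigma=sigma,
                n_years=config.window_length, seed=config.seed,
            )
            for crop in crops:
                suit = ecocrop.compute_suitability(ann.tmin, ann.tmean, ann.prec, crop)
                means = planting.circular_window_means(suit, k=3)
                annual_stack[crop.crop_name].append(np.max(means, axis=-1))
        for crop in crops:
            out[(crop.crop_name, key)] = np.stack(annual_stack[crop.crop_name])
    return out


def stage_change(
    config: PipelineConfig,
    outdir: Path,
    climates: dict[str, list[climate_io.MonthlyClimatology]],
    suitability: dict[tuple[str, str], xr.Dataset],
    crops: list[CropParameters],
) -> dict[tuple[str, float], change_mod.EnsembleChangeField]:
    """Ensemble change fields, robustness and planting shifts per crop x level."""
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    annual = _annual_window_means(config, climates, crops)
    fields: dict[tuple[str, float], change_mod.EnsembleChangeField] = {}
    lats = climates["historical"][0].lats
    lons = climates["historical"][0].lons
    member_ids = _member_ids(config)
    for crop in crops:
        hist = suitability[(crop.crop_name, "historical")]
        for level in config.levels:
            key = f"GWL{level}"
            fut = suitability[(crop.crop_name, key)]
            ecf = change_mod.ensemble_change(
                baseline_window_siv=hist["planting_window_mean_siv"].values,
                gwl_window_siv=fut["planting_window_mean_siv"].values,
                baseline_annual=annual[(crop.crop_name, "historical")],
                gwl_annual=annual[(crop.crop_name, key)],
                lats=lats,
                lons=lons,
                level=level,
                crop_name=crop.crop_name,
                member_ids=member_ids,
                alpha=config.significance_alpha,
                threshold=config.agreement_threshold,
            )
            shift = planting.planting_shift_map(
                hist["planting_month"].values, fut["planting_month"].values
            )
            ds = ecf.to_dataset()
            ds["planting_shift"] = (("member", "lat", "lon"), shift)
            ds["marginal_mask_hist"] = (
                ("lat", "lon"),
                change_mod.marginal_suitability_mask(
                    np.nanmean(hist["planting_window_mean_siv"].values, axis=0)
                ).astype(np.int8),
            )
            ds.attrs.update(meta)
            path = outdir / "change" / f"{crop.crop_name}_GWL{level}.nc"
            path.parent.mkdir(parents=True, exist_ok=True)
            ds.to_netcdf(path)
            fields[(crop.crop_name, level)] = ecf
    return fields


def stage_summaries(
    config: PipelineConfig,
    outdir: Path,
    suitability: dict[tuple[str, str], xr.Dataset],
    crops: list[CropParameters],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """AEZ summaries and the cross-level trend tables."""
    regions = list(climate_io.DEFAULT_REGIONS)
    rows = []
    suit_means: dict[str, dict[str, float]] = {}
    pm_means: dict[str, dict[str, float]] = {}
    for crop in crops:
        suit_means[crop.crop_name] = {}
        pm_means[crop.crop_name] = {}
        for key in config.period_keys():
            ds = suitability[(crop.crop_name, key)]
            ens = np.nanmean(ds["planting_window_mean_siv"].values, axis=0)
            lats = ds["lat"].values
            summary = change_mod.regional_summary(ens, lats, regions)
            summary.insert(0, "crop", crop.crop_name)
            summary.insert(1, "period", key)
            rows.append(summary)
            domain = change_mod.regional_summary(
                ens, lats, [climate_io.DOMAIN], categorize=False
            )
            suit_means[crop.crop_name][key] = float(domain["mean"].iloc[0])
            pm = np.nanmean(ds["planting_month"].values, axis=0)
            pm_dom = change_mod.regional_summary(
                pm, lats, [climate_io.DOMAIN], categorize=False
            )
            pm_means[crop.crop_name][key] = float(pm_dom["mean"].iloc[0])
    regional = pd.concat(rows, ignore_index=True)
    trend_suit = trends.suitability_trend_table(
        suit_means, levels=config.levels, historical_key="historical"
    )
    trend_pm = trends.suitability_trend_table(
        pm_means, levels=config.levels, historical_key="historical"
    )
    sdir = outdir / "summaries"
    sdir.mkdir(parents=True, exist_ok=True)
    regional.to_csv(sdir / "regional_summary.csv", index=False)
    trend_suit.to_csv(sdir / "suitability_trends.csv", index=False)
    trend_pm.to_csv(sdir / "planting_month_trends.csv", index=False)
    return regional, trend_suit, trend_pm


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    products: list[str] = []
    timings: dict[str, float] = {}

    def _timed(name, fn, *args):
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            result = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, timings[name])
        return result

    crops = _load_crops(config)
    gwl_table = _timed("gwl", stage_gwl, config, outdir)
    climates = _timed("climate", stage_climate, config, outdir, gwl_table)
    suitability = _timed(
        "suitability", stage_suitability, config, outdir, climates, crops
    )
    _timed("change", stage_change, config, outdir, climates, suitability, crops)
    _timed("summaries", stage_summaries, config, outdir, suitability, crops)

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            products.append(str(path.relative_to(outdir)))
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "crops": [c.crop_name for c in crops],
        "levels": list(config.levels),
        "n_members": config.n_members,
        "stage_seconds": timings,
        "products": products,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
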