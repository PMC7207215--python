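"""Per-crop climatic threshold records.

Each crop is described by an Ecocrop-style set of temperature and seasonal
rainfall thresholds: a kill temperature ``ktmp`` (a single month with minimum
temperature at or below it makes the season unviable), an absolute and an
optimal temperature range for the monthly mean, absolute and optimal bounds
on the growing-season rainfall total, and a fixed season length in months.

The built-in registry (``data/crop_registry.csv``) ships FAO-Ecocrop-derived
defaults for the six staple crops of the West African analysis; the values
are editable configuration, not ground truth, and any CSV with the same
columns can be substituted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CropParameters",
    "CropParameterError",
    "load_crop_parameters",
    "write_crop_parameters",
    "validate_crop_parameters",
]

REGISTRY_COLUMNS = [
    "crop_name",
    "ktmp",
    "t_abs_min",
    "t_opt_min",
    "t_opt_max",
    "t_abs_max",
    "r_abs_min",
    "r_opt_min",
    "r_opt_max",
    "r_abs_max",
    "season_length",
    "plant_any_month",
]

_NUMERIC_FIELDS = [
    "ktmp",
    "t_abs_min",
    "t_opt_min",
    "t_opt_max",
    "t_abs_max",
    "r_abs_min",
    "r_opt_min",
    "r_opt_max",
    "r_abs_max",
]


class CropParameterError(ValueError):
    """A crop parameter record is malformed, naming the crop and field."""


@dataclass(frozen=True)
class CropParameters:
    """Climatic thresholds for one crop.

    Temperatures in degrees Celsius; rainfall bounds in mm per growing
    season; ``season_length`` in months (1-12). ``plant_any_month`` marks
    year-round crops whose planting month is not meaningful.
    """

    crop_name: str
    ktmp: float
    t_abs_min: float
    t_opt_min: float
    t_opt_max: float
    t_abs_max: float
    r_abs_min: float
    r_opt_min: float
    r_opt_max: float
    r_abs_max: float
    season_length: int
    plant_any_month: bool = False

    def validated(self) -> "CropParameters":
        report = validate_crop_parameters(self)
        if report:
            raise CropParameterError(
                f"crop '{self.crop_name}': " + "; ".join(report)
            )
        return self

    def with_overrides(self, **kwargs) -> "CropParameters":
        return replace(self, **kwargs).validated()


def validate_crop_parameters(p: CropParameters) -> list[str]:
    """Return a list of violated invariants (empty iff the record is valid)."""
    report: list[str] = []
    for f in _NUMERIC_FIELDS:
        v = getattr(p, f)
        if not isinstance(v, (int, float)) or v != v:  # NaN check
            report.append(f"{f} is not a finite number")
    if report:
        return report
    temp_chain = ["ktmp", "t_abs_min", "t_opt_min", "t_opt_max", "t_abs_max"]
    for lo, hi in zip(temp_chain, temp_chain[1:]):
        if getattr(p, lo) > getattr(p, hi):
            report.append(f"{lo} > {hi} ({getattr(p, lo)} > {getattr(p, hi)})")
    rain_chain = ["r_abs_min", "r_opt_min", "r_opt_max", "r_abs_max"]
    if p.r_abs_min < 0:
        report.append(f"r_abs_min < 0 ({p.r_abs_min})")
    for lo, hi in zip(rain_chain, rain_chain[1:]):
        if getattr(p, lo) > getattr(p, hi):
            report.append(f"{lo} > {hi} ({getattr(p, lo)} > {getattr(p, hi)})")
    if not (1 <= int(p.season_length) <= 12):
        report.append(f"season_length out of [1, 12] ({p.season_length})")
    return report


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "t"}
    return bool(value)


def _records_from_frame(df: pd.DataFrame, source: str) -> list[CropParameters]:
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise CropParameterError(
            f"{source}: missing column(s) {', '.join(missing)}"
        )
    records = []
    for _, row in df.iterrows():
        name = str(row["crop_name"])
        kwargs = {"crop_name": name}
        for f in _NUMERIC_FIELDS:
            try:
                kwargs[f] = float(row[f])
            except (TypeError, ValueError):
                raise CropParameterError(
                    f"crop '{name}': field {f} is non-numeric ({row[f]!r})"
                ) from None
        try:
            kwargs["season_length"] = int(row["season_length"])
        except (TypeError, ValueError):
            raise CropParameterError(
                f"crop '{name}': season_length is non-numeric"
            ) from None
        kwargs["plant_any_month"] = _coerce_bool(row["plant_any_month"])
        records.append(CropParameters(**kwargs).validated())
    return records


def load_crop_parameters(
    source: str | Path = "builtin",
) -> list[CropParameters]:
    """Load crop records from a CSV path or the built-in registry.

    ``source='builtin'`` (or 'registry') reads the packaged default table.
    """
    if str(source) in {"builtin", "registry"}:
        ref = importlib.resources.files("cropsuit") / "data" / "crop_registry.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path)
        return _records_from_frame(df, "built-in registry")
    path = Path(source)
    if not path.exists():
        raise CropParameterError(f"crop parameter file not found: {path}")
    return _records_from_frame(pd.read_csv(path), str(path))


def write_crop_parameters(
    records: Iterable[CropParameters], path: str | Path
) -> Path:
    """Write records to CSV in the registry column order (round-trip safe)."""
    rows = []
    for p in records:
        rows.append({f.name: getattr(p, f.name) for f in fields(CropParameters)})
    df = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def get_crop(name: str, records: Sequence[CropParameters] | None = None) -> CropParameters:
    """Look one crop up by name (defaults to the built-in registry)."""
    records = records if records is not None else load_crop_parameters()
    for p in records:
        if p.crop_name == name:
            return p
    raise CropParameterError(f"no crop named '{name}' in registry")
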