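"""Timing of global warming levels from an annual global-mean series.

A warming level (1.5/2.0/3.0 degC) is reached at the mid-year of the first
30-year window whose mean temperature anomaly, relative to the 1861-1890
pre-industrial baseline, meets the level. The mid-year is taken as the 15th
year of the window, so the window runs mid_year-14 .. mid_year+15 inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GsatSeries",
    "GwlWindow",
    "PREINDUSTRIAL_BASELINE",
    "compute_anomaly",
    "gwl_crossing_midyear",
    "extract_gwl_window",
    "gwl_windows_table",
]

PREINDUSTRIAL_BASELINE = (1861, 1890)
WINDOW_LENGTH = 30
# index of the mid-year within a 30-year window (15th year)
_MID_OFFSET = 14


@dataclass
class GsatSeries:
    """Annual global-mean surface temperature for one ensemble member."""

    years: np.ndarray
    temps: np.ndarray
    member_id: str = "member"

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.years.size != self.temps.size:
            raise ValueError("years and temps must have equal length")
        if self.years.size and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be strictly consecutive")


@dataclass(frozen=True)
class GwlWindow:
    """A warming level, its crossing mid-year and the 30-year window."""

    level: float
    mid_year: int
    window: tuple[int, int]
    member_id: str = "member"

    def __post_init__(self):
        start, end = self.window
        if end - start + 1 != WINDOW_LENGTH:
            raise ValueError("GWL window must span exactly 30 years")
        if self.mid_year != start + _MID_OFFSET:
            raise ValueError("mid_year must be the 15th year of the window")


def compute_anomaly(
    s: GsatSeries, baseline: tuple[int, int] = PREINDUSTRIAL_BASELINE
) -> GsatSeries:
    """Subtract the baseline-period mean; the output's baseline mean is 0."""
    b0, b1 = baseline
    sel = (s.years >= b0) & (s.years <= b1)
    if sel.sum() != b1 - b0 + 1:
        raise ValueError(
            f"series {s.member_id} does not fully cover baseline {baseline}"
        )
    return GsatSeries(s.years, s.temps - s.temps[sel].mean(), s.member_id)


def gwl_crossing_midyear(
    anomaly: GsatSeries,
    level: float,
    window_length: int = WINDOW_LENGTH,
    convention: str = "centered",
) -> int | None:
    """Mid-year of the first complete window whose mean anomaly >= level.

    Running means are taken over complete windows only (no edge padding).
    ``convention='centered'`` reports the 15th year of the window;
    ``'trailing'`` reports its final year. Returns None if never reached.
    """
    n = anomaly.temps.size
    if window_length > n:
        raise ValueError("window longer than series")
    means = np.convolve(anomaly.temps, np.ones(window_length), "valid") / window_length
    hits = np.nonzero(means >= level)[0]
    if hits.size == 0:
        return None
    start = int(anomaly.years[hits[0]])
    if convention == "centered":
        return start + _mid_offset(window_length)
    if convention == "trailing":
        return start + window_length - 1
    raise ValueError(f"unknown convention '{convention}'")


def _mid_offset(window_length: int) -> int:
    # 15th year of a 30-year window; for odd lengths the true centre
    return window_length // 2 - 1 if window_length % 2 == 0 else window_length // 2


def extract_gwl_window(mid_year: int, window_length: int = WINDOW_LENGTH) -> tuple[int, int]:
    """Inclusive (start, end) of the window whose mid-year is ``mid_year``."""
    half = _mid_offset(window_length)
    return (mid_year - half, mid_year + (window_length - 1 - half))


def gwl_windows_table(
    series: list[GsatSeries],
    levels: tuple[float, ...] = (1.5, 2.0, 3.0),
    baseline: tuple[int, int] = PREINDUSTRIAL_BASELINE,
) -> pd.DataFrame:
    """Per-member crossing table: member_id, level, mid/start/end year."""
    rows = []
    for s in series:
        anom = compute_anomaly(s, baseline)
        for level in levels:
            mid = gwl_crossing_midyear(anom, level)
            if mid is None:
                rows.append(
                    {"member_id": s.member_id, "level": level, "mid_year": pd.NA,
                     "start_year": pd.NA, "end_year": pd.NA}
                )
            else:
                start, end = extract_gwl_window(mid)
                rows.append(
                    {"member_id": s.member_id, "level": level, "mid_year": mid,
                     "start_year": start, "end_year": end}
                )
    return pd.DataFrame(rows)


def read_gsat_csv(path: str | Path, member_id: str | None = None) -> GsatSeries:
    """Read a year,temp CSV into a series."""
    df = pd.read_csv(path)
    if not {"year", "temp"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns year,temp")
    return GsatSeries(
        df["year"].to_numpy(), df["temp"].to_numpy(),
        member_id or Path(path).stem,
    )
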