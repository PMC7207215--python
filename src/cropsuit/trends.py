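"""Theil-Sen trend estimation and the per-crop trend table.

The Theil-Sen estimator is the median of all pairwise slopes between data
points; it tolerates up to ~29% outliers before breaking down, unlike
ordinary least squares. The trend table reports, per crop and warming
level, the regional mean window suitability normalised by its historical
value (so "no change" reads 1.000) together with the Theil-Sen slope of
that ratio across the ordered warming-level sequence.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["theil_sen_slope", "suitability_trend_table"]


def theil_sen_slope(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Median pairwise slope and median-residual intercept.

    Pairs with equal x are excluded; if every pair has equal x there is no
    defined slope and a ValueError is raised. An even number of pairwise
    slopes is resolved as the mean of the central pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (x, y) points")
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i, j in combinations(range(x.size), 2)
        if x[j] != x[i]
    ]
    if not slopes:
        raise ValueError("all x values are identical; slope undefined")
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def suitability_trend_table(
    regional_means: Mapping[str, Mapping[str, float]],
    levels: Sequence[float] = (1.5, 2.0, 3.0),
    historical_key: str = "historical",
) -> pd.DataFrame:
    """Per-crop normalised suitability ratios and the cross-level trend.

    ``regional_means[crop]`` maps 'historical' and each warming level key
    (e.g. 'GWL1.5') to the crop's domain-mean window suitability. The ratio
    column for a level is that level's mean divided by the historical mean
    (1.000 = no change); 'theil_sen_slope' is the estimator applied to the
    ratios against warming amount {0, 1.5, 2.0, 3.0}. A zero historical
    mean leaves the crop's ratios undefined (NaN).
    """
    rows = []
    for crop, means in regional_means.items():
        hist = means[historical_key]
        row: dict[str, object] = {"crop": crop, historical_key: 1.0}
        xs = [0.0]
        ys = [1.0]
        defined = hist != 0 and np.isfinite(hist)
        for level in levels:
            key = f"GWL{level}"
            ratio = means[key] / hist if defined else np.nan
            row[key] = ratio
            if defined and np.isfinite(ratio):
                xs.append(float(level))
                ys.append(float(ratio))
        if defined and len(xs) >= 2:
            slope, _ = theil_sen_slope(xs, ys)
            row["theil_sen_slope"] = slope
        else:
            row[historical_key] = np.nan
            row["theil_sen_slope"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
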