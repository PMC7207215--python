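"""Ensemble change in suitability and the two-condition robustness rule.

A projected change at a cell is called robust when (1) at least 80% of the
ensemble members agree on the sign of the change of the ensemble mean, and
(2) at least 80% of the members individually show a statistically
significant change at the 99% confidence level (two-sample Welch t test on
the 30 annual window-mean suitability values of the baseline vs the warming
window). Cells meeting both conditions would be stippled on a map.

Also here: the marginal-suitability band mask (index between 0.41 and 0.59,
the transition line separating the suitable south from the unsuitable
north) and cosine-latitude-weighted regional summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .climate_io import RegionDefinition
from .ecocrop import CATEGORY_LABELS, classify_siv

__all__ = [
    "EnsembleChangeField",
    "delta_suitability",
    "sign_agreement",
    "member_significance",
    "robustness",
    "marginal_suitability_mask",
    "regional_summary",
    "AGREEMENT_THRESHOLD",
    "SIGNIFICANCE_ALPHA",
]

AGREEMENT_THRESHOLD = 0.8
SIGNIFICANCE_ALPHA = 0.01
MARGINAL_BOUNDS = (0.41, 0.59)


@dataclass
class EnsembleChangeField:
    """Per-cell suitability change across an ensemble at one warming level."""

    lats: np.ndarray
    lons: np.ndarray
    delta: np.ndarray  # (member, lat, lon)
    ensemble_mean_delta: np.ndarray
    agreement_fraction: np.ndarray
    significant_fraction: np.ndarray
    robust: np.ndarray
    level: float
    crop_name: str
    member_ids: tuple[str, ...] = ()

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "member": list(self.member_ids) or list(range(self.delta.shape[0])),
            "lat": self.lats,
            "lon": self.lons,
        }
        return xr.Dataset(
            {
                "delta": (("member", "lat", "lon"), self.delta),
                "ensemble_mean_delta": (("lat", "lon"), self.ensemble_mean_delta),
                "agreement_fraction": (("lat", "lon"), self.agreement_fraction),
                "significant_fraction": (("lat", "lon"), self.significant_fraction),
                "robust": (("lat", "lon"), self.robust.astype(np.int8)),
            },
            coords=coords,
            attrs={"crop": self.crop_name, "gwl": self.level},
        )


def delta_suitability(baseline: np.ndarray, gwl: np.ndarray) -> np.ndarray:
    """Per-member change (member, lat, lon): warming minus baseline."""
    baseline = np.asarray(baseline, dtype=float)
    gwl = np.asarray(gwl, dtype=float)
    if baseline.shape != gwl.shape:
        raise ValueError(
            f"member/grid mismatch: {baseline.shape} vs {gwl.shape}"
        )
    return gwl - baseline


def sign_agreement(deltas: np.ndarray) -> np.ndarray:
    """Fraction of members agreeing with the sign of the ensemble mean.

    ``deltas`` has members on axis 0. Zero deltas count as agreeing with
    either sign (a cell saturated at index 0 or 1 should not read as
    disagreement); where the ensemble mean is exactly zero the fraction is
    the share of zero deltas.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape[0] < 2:
        raise ValueError("need at least 2 members")
    n = deltas.shape[0]
    mean = deltas.mean(axis=0)
    mean_sign = np.sign(mean)
    agree = (np.sign(deltas) == mean_sign) | (deltas == 0)
    frac = agree.sum(axis=0) / n
    frac = np.where(np.isnan(mean), np.nan, frac)
    return frac


def member_significance(
    baseline_annual: np.ndarray,
    gwl_annual: np.ndarray,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> np.ndarray:
    """Per-member, per-cell Welch t test on annual window-mean suitability.

    Inputs are (member, year, lat, lon) stacks of the 30 annual values for
    the baseline and warming windows. Returns a boolean (member, lat, lon)
    array, True where p < alpha. Identical zero-variance samples are not
    significant (p = 1 convention).
    """
    a = np.asarray(baseline_annual, dtype=float)
    b = np.asarray(gwl_annual, dtype=float)
    if a.shape != b.shape:
        raise ValueError("baseline and warming stacks must share shape")
    with warnings.catch_warnings():
        # cells saturated at index 0 or 1 have (near-)constant samples;
        # their NaN p-value is mapped to "not significant" below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue)
    # zero variance on both sides: scipy yields NaN; equal means -> p=1
    p = np.where(np.isnan(p), 1.0, p)
    return p < alpha


def robustness(
    agreement_fraction: np.ndarray,
    significant_fraction: np.ndarray,
    threshold: float = AGREEMENT_THRESHOLD,
) -> np.ndarray:
    """Both 80% conditions met: sign agreement AND member significance."""
    a = np.asarray(agreement_fraction, dtype=float)
    s = np.asarray(significant_fraction, dtype=float)
    return (a >= threshold) & (s >= threshold)


def marginal_suitability_mask(
    siv: np.ndarray, bounds: tuple[float, float] = MARGINAL_BOUNDS
) -> np.ndarray:
    """True where the index lies in the marginal band [0.41, 0.59]."""
    arr = np.asarray(siv, dtype=float)
    lo, hi = bounds
    return (arr >= lo) & (arr <= hi)


def ensemble_change(
    baseline_window_siv: np.ndarray,
    gwl_window_siv: np.ndarray,
    baseline_annual: np.ndarray,
    gwl_annual: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    level: float,
    crop_name: str,
    member_ids: Sequence[str] = (),
    alpha: float = SIGNIFICANCE_ALPHA,
    threshold: float = AGREEMENT_THRESHOLD,
) -> EnsembleChangeField:
    """Assemble the full change field from per-member window suitability."""
    delta = delta_suitability(baseline_window_siv, gwl_window_siv)
    agreement = sign_agreement(delta)
    sig = member_significance(baseline_annual, gwl_annual, alpha=alpha)
    sig_frac = sig.mean(axis=0)
    return EnsembleChangeField(
        lats=lats,
        lons=lons,
        delta=delta,
        ensemble_mean_delta=delta.mean(axis=0),
        agreement_fraction=agreement,
        significant_fraction=sig_frac,
        robust=robustness(agreement, sig_frac, threshold=threshold),
        level=level,
        crop_name=crop_name,
        member_ids=tuple(member_ids),
    )


def regional_summary(
    field: np.ndarray,
    lats: np.ndarray,
    regions: Sequence[RegionDefinition],
    categorize: bool = True,
) -> pd.DataFrame:
    """Area-weighted regional means (cos-latitude weights) and category tallies.

    ``field`` is (lat, lon); NaN cells are excluded from the weights.
    """
    field = np.asarray(field, dtype=float)
    lats = np.asarray(lats, dtype=float)
    w = np.cos(np.deg2rad(lats))[:, None] * np.ones(field.shape[1])[None, :]
    rows = []
    for region in regions:
        sel = region.contains_lat(lats)
        if not sel.any():
            raise ValueError(f"region {region.name}: empty latitude intersection")
        sub = field[sel]
        wsub = w[sel]
        ok = np.isfinite(sub)
        if not ok.any():
            raise ValueError(f"region {region.name}: no valid cells")
        mean = float((sub[ok] * wsub[ok]).sum() / wsub[ok].sum())
        row = {"region": region.name, "mean": mean, "n_cells": int(ok.sum())}
        if categorize:
            labels = classify_siv(np.clip(sub[ok], 0.0, 1.0))
            counts = pd.Series(labels).value_counts()
            for label in CATEGORY_LABELS:
                row[label] = int(counts.get(label, 0))
        rows.append(row)
    return pd.DataFrame(rows)
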