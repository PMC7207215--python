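"""Suitability cubes and planting windows for every crop, member and period.

For each crop the engine scores all twelve candidate start months per cell;
the planting month is the first month of the best three consecutive months
and the window mean is the reported suitability. Prints where each crop's
historical suitability peaks and which planting month dominates.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import study_config

from cropsuit.pipeline import _load_crops, stage_climate, stage_gwl, stage_suitability


def main() -> None:
    cfg = study_config()
    out = Path(cfg.outdir)
    climates = stage_climate(cfg, out, stage_gwl(cfg, out))
    crops = _load_crops(cfg)
    products = stage_suitability(cfg, out, climates, crops)
    print(f"{len(products)} crop x period suitability files under {out / 'suitability'}")
    for crop in crops:
        ds = products[(crop.crop_name, "historical")]
        siv = np.nanmean(ds["planting_window_mean_siv"].values, axis=0)
        zonal = siv.mean(axis=1)
        peak_lat = float(ds["lat"].values[int(np.argmax(zonal))])
        pm = ds["planting_month"].values
        months, counts = np.unique(pm[np.isfinite(pm)], return_counts=True)
        mode = int(months[counts.argmax()]) if months.size else None
        print(
            f"  {crop.crop_name:<13s} peak zonal-mean SIV {zonal.max():.2f} "
            f"at {peak_lat:.2f} N; modal planting month {mode}"
        )


if __name__ == "__main__":
    main()
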