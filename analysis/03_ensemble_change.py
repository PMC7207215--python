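"""Ensemble suitability change and robustness at each warming level.

Per crop and level: per-member change in window-mean suitability against
the historical baseline, the fraction of members agreeing on the sign of
the change, the fraction individually significant (Welch t test on 30
annual values, 99% level), and the two-condition robustness flag. Prints
the robust-area fraction per crop and level.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import study_config

from cropsuit.pipeline import (
    _load_crops,
    stage_change,
    stage_climate,
    stage_gwl,
    stage_suitability,
)


def main() -> None:
    cfg = study_config()
    out = Path(cfg.outdir)
    climates = stage_climate(cfg, out, stage_gwl(cfg, out))
    crops = _load_crops(cfg)
    cubes = stage_suitability(cfg, out, climates, crops)
    fields = stage_change(cfg, out, climates, cubes, crops)
    print(f"change fields under {out / 'change'}")
    print(f"{'crop':<13s}" + "".join(f"  robust@GWL{lvl}" for lvl in cfg.levels))
    for crop in crops:
        cells = []
        for lvl in cfg.levels:
            ecf = fields[(crop.crop_name, lvl)]
            cells.append(f"{float(np.mean(ecf.robust)):>13.2f}")
        print(f"{crop.crop_name:<13s}" + "  ".join(cells))


if __name__ == "__main__":
    main()
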