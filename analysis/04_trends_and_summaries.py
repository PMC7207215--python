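"""Regional summaries and cross-level trend tables.

Cosine-latitude-weighted mean suitability and category tallies per
agro-ecological zone (Guinea 4-8 N, Savanna 8-12 N, Sahel 12-20 N), plus
per-crop suitability ratios (warming level / historical, 1.000 = no
change) with a Theil-Sen slope across the level sequence.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from run_config import study_config

from cropsuit.pipeline import (
    _load_crops,
    stage_climate,
    stage_gwl,
    stage_suitability,
    stage_summaries,
)


def main() -> None:
    cfg = study_config()
    out = Path(cfg.outdir)
    climates = stage_climate(cfg, out, stage_gwl(cfg, out))
    crops = _load_crops(cfg)
    cubes = stage_suitability(cfg, out, climates, crops)
    regional, trend_suit, trend_pm = stage_summaries(cfg, out, cubes, crops)
    print("suitability ratios vs historical (1.000 = no change):")
    print(trend_suit.round(3).to_string(index=False))
    print()
    print("planting-month ratios vs historical:")
    print(trend_pm.round(3).to_string(index=False))
    print()
    hist = regional[regional["period"] == "historical"]
    print("historical zone means:")
    print(hist[["crop", "region", "mean"]].round(3).to_string(index=False))
    print(f"tables written under {out / 'summaries'}")


if __name__ == "__main__":
    main()
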