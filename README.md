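# cropsuit

Crop climatic suitability under global warming levels: an Ecocrop-style
monthly suitability index driven by gridded climate, evaluated in 30-year
windows at 1.5/2.0/3.0 °C of global warming, with planting-window
extraction, ensemble robustness classification and Theil–Sen trends.

## The problem

Rainfed agriculture in the West African monsoon region is acutely exposed
to warming: temperature rises northward into the Sahel while rainfall
decays in the same direction, so the zone where a crop's temperature and
seasonal-rainfall requirements are simultaneously met is a latitude band
that climate change can move, widen or erase. This package implements the
full analysis chain a climate-impact study of that question needs, for
researchers who want to run it on their own ensemble — or on the built-in
synthetic monsoon climate that reproduces the domain's structure without
any data download.

The index for a cell, crop and candidate start month *i* is

```
SUIT_i = Tsuit_i × Rsuit_i ∈ [0, 1]
```

where Tsuit_i is the minimum over the growing season's months of a
trapezoidal membership of monthly mean temperature (zeroed outright for
any month whose minimum temperature falls to the crop's kill temperature),
and Rsuit_i is the same trapezoid applied to the season's total rainfall.
The planting month is the first month of the best three consecutive months
of the 12-value cycle; a change is *robust* where at least 80% of ensemble
members agree on its sign **and** at least 80% are individually
significant at the 99% level (Welch t test on 30 annual values). See
`docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from cropsuit import (
    SyntheticClimateSpec, generate_monsoon_climatology,
    load_crop_parameters, compute_suitability_cube,
)
from cropsuit.planting import planting_month_map

crops = {c.crop_name: c for c in load_crop_parameters()}
clim = generate_monsoon_climatology(SyntheticClimateSpec(seed=0), "m01")
cube = compute_suitability_cube(clim, crops["maize"])
pm = planting_month_map(cube, crops["maize"])
siv = pm["planting_window_mean_siv"].values
for lat_band, name in [((4, 8), "Guinea"), ((8, 12), "Savanna"), ((12, 20), "Sahel")]:
    sel = (clim.lats >= lat_band[0]) & (clim.lats < lat_band[1])
    print(f"{name:<8s} mean SIV {np.nanmean(siv[sel]):.2f}")
```

prints

```
Guinea   mean SIV 0.66
Savanna  mean SIV 0.06
Sahel    mean SIV 0.00
```

— the north–south suitability gradient: maize is suitable in the humid
Guinea zone, marginal in the Savanna and unsuitable in the dry Sahel of
the synthetic climate.

The full study runs from the command line:

```bash
cropsuit run-all --outdir out/ --seed 42          # all six crops, 10 members
cropsuit gwl --outdir out/ --seed 42              # warming-level windows only
```

or stage by stage through the numbered scripts in `analysis/`
(01 synthetic climate and warming-level windows, 02 suitability and
planting maps, 03 ensemble change and robustness, 04 regional summaries
and trend tables), which share `results/run/` and print what they found;
for example script 04 reports per-crop suitability ratios relative to the
historical period (1.000 = no change) with a Theil–Sen slope across the
warming levels, showing every crop's domain-mean suitability declining
with warming and cassava declining fastest.

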