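# Methods

## The suitability model

The package scores how climatically suitable a location is for a crop with
an Ecocrop-style empirical index. For a grid cell, a candidate start month
*i* (1–12) and a crop with fixed growing-season length *L* months:

- **Monthly temperature score.** Each month's mean temperature is passed
  through a trapezoidal membership over the crop's thresholds
  (t_abs_min ≤ t_opt_min ≤ t_opt_max ≤ t_abs_max): 0 at or beyond the
  absolute limits, 1 on the optimal plateau, linear on the shoulders. If
  the month's *minimum* temperature is at or below the kill temperature
  KTMP the month scores 0 outright — frost (or cold-night) kill admits no
  compensation.
- **Season temperature factor.** Tsuit_i is the *minimum* of the monthly
  scores over months *i … i+L−1* (wrapping December into January): the
  limiting-month principle, since a single lethal or far-from-optimal
  month ruins the season. A mean aggregation can be swapped in by editing
  `season_suitability`'s building blocks, but the minimum is the default
  and the tested behaviour.
- **Season rainfall factor.** Rsuit_i applies the same trapezoid to the
  *total* rainfall of the season's months against the crop's seasonal
  bounds (r_abs_min … r_abs_max, mm per season).
- **Index.** SUIT_i = Tsuit_i × Rsuit_i ∈ [0, 1]. The 12-vector over start
  months is the "suitability cycle" of the cell.

Degenerate trapezoids (absolute bound equal to an optimal bound) resolve
in favour of the plateau, so a zero-width shoulder is a step function that
is optimal at the shared bound. The kill rule is a strict cutoff
(tmin ≤ KTMP → 0) with no taper between KTMP and t_abs_min.

Index values are categorised in five contiguous, upper-inclusive bands:
[0, 0.2] unsuitable, (0.2, 0.4] very marginally suitable, (0.4, 0.6]
marginally suitable, (0.6, 0.8] suitable, (0.8, 1.0] highly suitable.
The conventional two-decimal presentation of these bands (0.21–0.40 etc.)
leaves gaps between printed bounds; the implementation treats the bands as
half-open intervals, which reproduces the printed labels at any input.

Crop thresholds ship as an editable CSV registry
(`src/cropsuit/data/crop_registry.csv`) with FAO-Ecocrop-derived defaults
for cassava, cowpea, groundnut, maize, pearl millet and plantain. The
values are configuration, not ground truth: any table with the same
columns can be substituted, and every record is validated against the
threshold orderings on load. Season length is a single fixed duration per
crop; plantain is flagged `plant_any_month` (a year-round crop whose
planting month is not meaningful). Maximum-temperature thresholds are not
part of the model because its inputs are tmin, tmean and prec only.

## Planting windows and shifts

The planting month (PM) at a cell is the first month of the best three
consecutive months of the suitability cycle (circular mean over k = 3
starts, wrap-around allowed). Ties go to the earliest start month in the
search order, which begins at January by default; the search-order origin
only affects ties. A cell whose 12 window means are all within 1e-9 of
the maximum is flagged year-round, as are all cells of `plant_any_month`
crops. Shifts between two periods are the minimal circular month
difference in [−5, +6], positive for a delay; an exactly-ambiguous
six-month displacement is reported as +6.

## Warming-level timing

Warming levels (1.5, 2.0, 3.0 °C) are located on each ensemble member's
annual global-mean temperature series: anomalies are taken relative to the
1861–1890 pre-industrial mean, a 30-year running mean is computed over
complete windows only, and the level's mid-year is the 15th year of the
first window whose mean anomaly reaches the level (window = mid−14 …
mid+15). The 15th-year choice resolves the ambiguity of an even-length
window's centre and is configurable, as is a trailing-window convention.
The impact analysis then compares each member's 30-year warming-level
window against the 1971–2000 reference period.

## Ensemble change and robustness

For each crop and level, the per-member change Δ in window-mean
suitability (warming window minus baseline) is summarised per cell by:

- **Sign agreement**: the fraction of members whose Δ matches the sign of
  the ensemble-mean Δ. Zero deltas count as agreeing with either sign —
  a cell saturated at index 0 or 1 in both periods should not read as
  model disagreement. If the ensemble mean is exactly zero the fraction
  is the share of zero deltas.
- **Member significance**: per member, a two-sample Welch t test on the 30
  annual best-window suitability values of the baseline versus the warming
  window, significant when p < 0.01. The Welch (unequal-variance) form is
  used because the two windows need not share variance. Samples that are
  constant and equal on both sides are not significant (p = 1 convention).
  No multiple-testing correction is applied across cells; the flag is a
  per-cell descriptive device (stippling), a known limitation.
- **Robustness**: both fractions ≥ 0.8. Each member is tested individually
  (rather than testing the ensemble mean once) so that the significance
  condition is a member count comparable against the 80% threshold.

The marginal-suitability band is the set of cells with index in
[0.41, 0.59] — the transition line separating the suitable south of the
domain from the unsuitable north.

Regional summaries weight cells by cos(latitude) and report means and
category tallies over the agro-ecological zones Guinea (4–8°N), Savanna
(8–12°N) and Sahel (12–20°N); bands are half-open northward, so a printed
boundary latitude belongs to the zone north of it.

## Trends

The Theil–Sen estimator (median of all pairwise slopes; pairs with equal
x excluded; even slope counts resolved as the mean of the central pair)
summarises how the domain-mean suitability ratio changes across the level
sequence {historical = 0, 1.5, 2.0, 3.0}. The trend table reports, per
crop and level, the regional mean window suitability normalised by its
historical value — 1.000 means no change — together with that slope. Both
the ratio and the slope are emitted because a single published "trend
value" can be read either way; reporting both removes the ambiguity.

## Synthetic climate generator

The generator emulates the structure of the West African monsoon domain
(2–20°N, 20°W–20°E, 0.5° cell centres by default) that the analysis
assumes, not any particular model's dynamics:

- mean temperature = 26 °C at the southern edge + 0.5 °C per degree
  latitude northward + a 2 °C annual harmonic peaking in April
  (pre-monsoon), identical across longitude; tmin = tmean − 8 °C;
- rainfall = a single Gaussian-in-month wet season (width 2 months) whose
  peak amplitude is 250 mm/month at the southern edge decaying
  exponentially at 0.08 per degree northward, and whose peak month drifts
  from July at 2°N by 0.08 months per degree (the monsoon arriving later
  inland);
- members differ by one N(0, 0.3 °C) temperature offset and one
  N(1, 0.10) fractional rainfall factor (clipped at 0), drawn
  deterministically from (seed, member id);
- annual realizations add one N(0, 0.5 °C) offset and one N(1, 0.15)
  rainfall factor per (year, month), shared across the grid — emulating
  region-wide interannual variability, which is what the per-member t test
  consumes.

Magnitudes were chosen once as representative of the region: the
meridional temperature span (26→35 °C) and the wet-season rainfall range
(roughly 160–680 mm per 3-month season across the domain) bracket the
observed Guinea-to-Sahel contrast, and the noise scales are of the order
of observed interannual variability. Warming levels force the synthetic
climate as Δt = 1.2 × level (a modest continental amplification of the
global mean) and a 3% rainfall reduction per °C of global warming; both
are configuration fields of the pipeline. The generator's global-mean
temperature series is a linear ramp (0.02 °C/yr from 1861) plus N(0,
0.1 °C) noise — sufficient for exercising the window-finding logic, with
no claim to an emission-scenario trajectory.

What the generator does **not** emulate: coastal bimodal rainfall,
orographic maxima, spatially correlated noise, member-dependent seasonal
timing, or bias-correction artefacts. Passing tests therefore demonstrate
that the pipeline recovers structure it is pointed at — a constructed
optimal band, a marginal line poleward of it, an imposed planting-month
shift, a warming-driven decline — not that the index is accurate for any
real crop or that real-ensemble results would match.

## Numerical choices and degenerate inputs

- All engine maths is vectorised float64 numpy; the cube computation
  accepts arbitrary leading dimensions before the month axis, which is how
  the 30-year annual stacks are scored in one call per member.
- NaN climate (masked cells) propagates to NaN scores, NaN planting
  results and NaN deltas; it never raises mid-grid.
- Planting-window ties break to the earliest start in search order;
  argmax-style first-max semantics are mirrored exactly by the test
  oracles.
- Duplicate x values in Theil–Sen are excluded pairwise; an all-duplicate
  x input is an error rather than a NaN.
- The GWL search uses complete windows only; a series that never crosses
  returns None rather than raising.
- Pipeline stages are deterministic functions of (config, seed); child
  seeds derive from the root seed plus stable identifiers (CRC32 of the
  member id, period years), never global RNG state.

## Problem sizes

The default study conditions are 6 crops × 10 members × a 36 × 80
half-degree grid × 4 periods, with 30 annual realizations per member and
period feeding the significance test. A full run executes in well under
a minute on one CPU; the test suite runs the complete default
configuration end to end and the acceptance checks use 10,000-vector and
1,000-set enumeration oracles.

## Known limitations

- The index is an empirical climate-matching score, not a yield model.
- Soil, management, pests, cultivar differences, CO2 fertilisation and
  multi-season (double-cropping) calendars are out of scope.
- The robustness stipple tests each cell independently (no field
  significance / false-discovery control).
- Real-ensemble results (specific published maps and tables) depend on
  the driving climate models and are not reproduction targets of the
  synthetic runs.
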