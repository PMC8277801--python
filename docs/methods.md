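# Methods

This note documents the model the package implements, the choices
made where the design was genuinely open, and what the test suite
does and does not demonstrate.

## Inventory model

Emissions are compiled bottom-up as emission-factor × activity-data
products over a province × year grid (31 provinces, 1978–2016),
separated into primary emissions (field operations: residue open
burning, rice paddies, land conversion, cropland nitrogen) and
secondary emissions (embodied in machinery energy and in
fertilizer/pesticide manufacture). Tertiary emissions (equipment
manufacture, farm buildings) are out of scope, as are livestock
enteric-fermentation and manure-management CH₄ — livestock enter only
through the manure-nitrogen term of the cropland N₂O budget.

**Residue burning.** Burned dry matter is production × straw-to-grain
ratio (13 crops) × provincial open-burning ratio × burning efficiency
(0.90). CH₄ and N₂O factors are 3.23 g/kg and 0.008 g/kg burned. CO₂
from the fire is booked as zero because the carbon was fixed by the
same crop within the year.

**Rice.** CH₄ = area × growing-period length × EF, with the EF a
weighted mean of four regime factors: half the area is assumed to
receive organic amendment, one third continuous flooding, two thirds
intermittent irrigation (weights 1/6, 1/3, 1/6, 1/3; they sum to 1
exactly in floating point). Source tables distinguish middle from
single-late rice; the model pools them, taking for five lower-Yangtze
provinces (zone 6A) the mean of the two source entries, and for four
southwest provinces (zone 6B) the middle-rice factors in place of
missing early/double-late entries.

**Cropland change.** Committed-emissions bookkeeping: the full
carbon-stock difference (biomass + soil, t C/ha) between the old and
new land class is booked in the conversion year and converted by
44/12. Snapshot maps (1980/1990/2000/2010/2015) give interval areas;
the annual area is the interval mean, assigned to years
(start, end]; 1978–1979 reuse the 1980 rate and 2015–2016 the 2014
rate. Because the 2014 value *is* the 2010–2015 interval rate, the
stated 2015–2016 rule and the interval rate coincide, so no separate
switch is provided. Cropland soil carbon follows a trajectory
anchored at the 1980 density with annual change rates for 1980–2009,
edge years holding the nearest rate; all other pools are constant.

**Cropland N₂O.** A regional nitrogen-budget account: fertilizer N
(effective component) + manure N + residue N. Manure N is population
× excretion rate × the summed partition fractions to anaerobic,
liquid and solid management, scaled by (1 − f_enn) for gaseous NH₃/NOₓ
loss. Residue N splits into a root pool and a straw pool (dry-matter
fraction, root-shoot ratio, harvest index, tissue N fraction), with
only the returned fraction (0.14) of straw N entering the budget; the
residue crop list defaults to the 13 burning crops minus fiber crops
and tobacco and is configurable. Direct N₂O uses a provincial factor;
indirect N₂O adds redeposited volatilized N (fertilizer fraction 0.1,
organic fraction 0.2, factor 0.01) and leached N (fraction 0.3,
factor 0.0075). The volatilization fraction written with symbol
f^Ovolat is applied to *organic* (manure) N, which its symbol, value
and equation position indicate despite an inconsistent prose gloss in
the source literature. All factors are in N₂O-N; the 44/28 mass
conversion is applied before GWP weighting.

**Machinery energy.** Generalized-agriculture energy consumption is
scaled to cropping by the GDP ratio of narrow to generalized
agriculture, converted to energy by carrier-specific low calorific
values, and to CO₂ by carbon content × oxidation factor × 44/12.
Electricity bypasses the carbon route via a year-indexed national
grid factor (its LCV slot is a unit passthrough). Only CO₂ is
computed — the defining relations produce no CH₄/N₂O term — and the
gas columns for CH₄/N₂O are structurally zero; a combustion non-CO₂
extension would enter as additional carrier factors.

**Input production.** Fertilizer manufacture emits 6.08 kg CO₂,
0.02 kg CH₄ and 0.0009 kg N₂O per kg effective N. Pesticide
manufacture is denominated directly in CO₂-eq (16.35 kg per kg
effective component) and is therefore carried in a dedicated
`co2eq_direct` column rather than faked into a gas split. The
effective-component proportion is observed for 2010–2014 and extended
to 1990–2009 and 2015–2016 by OLS of the proportion on (centered)
calendar year; anchor years also take fitted values, and predictions
are clamped to [0, 1] as a safeguard. No pesticide emissions are
booked before 1990, when the use statistics begin.

## Units and parameters

Parameters are stored in their published units (g/kg, t C/ha,
kg N/head/yr, GJ/t, …) with a units string attached, and each
sub-model applies its conversions explicitly (g→kg, t C→kg,
N₂O-N→N₂O, C→CO₂). Internal panel units are kg, ha, head and
physical energy units; outputs are reported in Mt CO₂-eq with
2-decimal CSV rounding, full precision retained in memory.

The registry pre-fills every constant printed in the primary
literature. Per-province supplementary tables (straw ratios, burning
ratios, rice EF quadruples and growing lengths, excretion/partition
factors, residue parameters, provincial direct-N₂O factors, LCVs and
carbon/oxidation factors, annual grid factors, SOC level and rates,
grassland carbon pools, the 2010–2014 proportion anchors) are not
published in full; they carry field-typical placeholder values
flagged `source="placeholder"`, uniform across provinces where no
spatial information exists, and are replaced via YAML config or keyed
CSV tables (`dimension…,value,units,dist,cv,a,b`). Headline national
numbers produced with placeholder tables characterize the pipeline,
not China.

## Uncertainty

Monte-Carlo propagation with 50,000 draws by default. Normal
distributions use sd = cv × value; triangular distributions use the
published (a, b) range with the point value as mode. Negative normal
draws are *not* truncated by default (truncation is an option,
`floor_negative_samples`), since the compilation literature does not
state a truncation rule. Within a draw, each scalar parameter is
drawn once and shared across provinces and years — the fully
correlated, most conservative choice, producing the widest intervals;
entries of keyed tables are drawn independently (a per-province
factor is a distinct parameter), and a `scalars_by_province` flag
switches scalars to independent per-province draws, which narrows
national bands through spatial averaging. Activity data are treated
as certain, reflecting their official-statistics provenance.
Percentiles are empirical order statistics with linear rank
interpolation. The point estimate is computed with unsampled values,
so degenerate (all-fixed) registries collapse the interval onto it
exactly.

## Synthetic data

The generator emulates the *structure* of the source statistics:
every series is share × national-level exponential trend × AR(1)
log-noise (ρ = 0.7, innovation sd chosen so the stationary log-sd is
0.08), with seeded Dirichlet province shares. National base levels
and growth rates are set to the documented magnitudes of the Chinese
record (e.g. fertilizer N growing ~3.4%/yr from ~9 Mt, diesel 3%/yr,
electricity 6%/yr, rural population slowly declining) so that
synthetic national totals land in the hundreds-of-Mt CO₂-eq decade —
a readability choice, not a calibration target. Structural features
reproduced: land transitions observed only at the four snapshot
intervals; pesticide series starting in 1990; child provinces absent
before their founding years (their activity merged into the parent);
optional missing-year masks to exercise interpolation. Not
reproduced: real provincial heterogeneity, cross-variable correlation
(e.g. fertilizer vs. crop production), policy breakpoints, or any
actual historical values. Passing tests therefore demonstrate
correctness of the accounting and uncertainty machinery on
realistically shaped inputs, not agreement with China's historical
inventory, which requires the official activity statistics and the
full supplementary factor tables.

## Numerical and design notes

- Vectorized engines operate on dense (province, year, …) arrays;
  every sub-model is checked against an independent naive per-row
  loop at 1e-9 relative tolerance on random panels.
- Gap interpolation is per (province, series), linear in year with
  constant edge extension, idempotent, and exact on linear series.
  Pre-founding years of Hainan (before 1988) and Chongqing (before
  1997) are structural zeros, not interpolation targets; "founded in
  1987" is read as first independent year 1988, configurable through
  the registry.
- Province folding sums child rows into the parent for all variables
  (conserving national totals); transition intervals fold when they
  end before the founding year. The GDP ratio is intensive — real
  pre-founding child rows do not exist for it, and folding a panel
  that has them can push the summed ratio past 1, which the machinery
  stage rejects.
- The OLS stage centers the year covariate; on exactly collinear
  anchors slope and predictions are recovered to ~1e-16.
- Monte-Carlo draw order is fixed by a single seeded generator, so
  results are bit-reproducible by (panel, registry, seed, n).
- Degenerate inputs: empty activity series are rejected at
  interpolation; zero harvest index, partition fractions above 1,
  GDP ratios outside [0, 1], overlapping snapshot intervals and
  unknown labels all raise with the offending key named.
- The GWP₂₀ set (CH₄ = 84, N₂O = 264) is provided as an alternative
  weighting config; it changes only the CO₂-eq aggregation, never the
  gas masses.

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run the full pipeline on
31-province × 39-year synthetic panels; loop-oracle equivalence uses
twenty 3-province × 6-year panels; full-pipeline Monte-Carlo bands
use 5,000 draws, and the single-factor calibration and
triangular-mean checks the full 50,000. These sizes give
Monte-Carlo standard errors well inside the asserted tolerances while
keeping a complete run in the minutes range.

## Known limitations

- Placeholder factor tables mean absolute national numbers are
  illustrative until users supply the real supplementary tables.
- Committed-emissions booking of land conversion ignores multi-year
  decay/regrowth dynamics.
- Interval-mean annualization smooths land-change dynamics inside
  each snapshot decade.
- The shared-draw correlation assumption is conservative; published
  inventory intervals built from other correlation structures (or
  truncated/asymmetric sampling schemes) will differ, especially for
  single-factor activities.
- No uncertainty is attached to activity data or to gap
  interpolation.
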