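# cropghg

A provincial greenhouse-gas inventory engine for cropping systems,
covering China's 31 mainland provinces over 1978–2016. It is written
for emission-inventory compilers and agricultural-mitigation analysts
who need a reproducible, testable pipeline from raw activity
statistics (crop production, rice area, land-use change, livestock and
rural population, fertilizer/pesticide use, farm energy consumption)
to CO₂-equivalent emission matrices with Monte-Carlo uncertainty
bands.

## What it computes

Seven activities, each an emission-factor × activity-data model, per
province *i* and year *j*:

| Activity | Gases | Core relation |
|---|---|---|
| Crop residue open burning | CH₄, N₂O | E = (Σₛ Prodₛ·f_str,ₛ)·f_open,ᵢ·f_burn·EF_CROP |
| Rice cultivation | CH₄ | E = Σᵣ RAᵣ·f_length·EF_RICE, EF_RICE = ½(⅓EF^F&CI + ⅔EF^F&SI + ⅓EF^NF&CI + ⅔EF^NF&SI) |
| Cropland change | ±CO₂ | E = Σₗ ΔCAₗ·(C_old − C_new)·44/12, with an annually updated cropland SOC trajectory |
| Cropland N₂O (direct + indirect) | N₂O | Nitr = NFert + Manu + RCrop; direct = Nitr·EF_d·44/28; indirect = (volatilization + leaching)·44/28 |
| Machinery energy use | CO₂ | E = Σₑ EC·f_pGDP·LCV·(f_carb·f_oxid·44/12); electricity by a year-indexed grid factor |
| N-fertilizer production | CO₂, CH₄, N₂O | E = NFert·EF_FERT (6.08 / 0.02 / 0.0009 kg per kg N) |
| Pesticide production | CO₂-eq | E = Pest·f_plPest(j)·EF_PEST, f_plPest regressed on year from 2010–2014 anchors, years ≥ 1990 |

Gas masses aggregate to CO₂-eq with GWP₁₀₀ (CH₄ = 28, N₂O = 265;
GWP₂₀ available as a config swap). Activity panels are gap-filled by
linear interpolation (constant at the edges), and Hainan/Chongqing
fold into Guangdong/Sichuan before their founding years. Parameter
uncertainty propagates through 50,000-draw Monte-Carlo simulation
(normal distributions by coefficient of variation, triangular by
published range) to 95% confidence intervals per year and activity.

Every published constant ships in a typed parameter registry with
units, provenance and distribution metadata; per-province factor
tables that are not published in full carry clearly flagged
placeholder defaults that users replace via keyed CSV files. A
synthetic activity-data generator reproduces the structure of the
real statistics (multi-decade trends, snapshot-only land-use maps,
post-1990 pesticide series) so the whole pipeline runs and is tested
without any data download.

## Worked example

```sh
cropghg run --seed 11 --out demo
```

generates a synthetic 31-province panel, runs all seven sub-models and
writes the national year × activity matrix (Mt CO₂-eq), a provincial
total matrix and seven per-activity provincial matrices. The first
rows of `demo/national_by_activity.csv`:

```
year,residue_burning,rice,cropland_change,cropland_n2o,machinery,fertilizer_production,pesticide_production,total
1978,7.45,185.53,-3.43,100.00,92.27,62.04,0.00,443.86
1979,7.52,185.11,-3.42,102.80,94.21,63.50,0.00,449.72
1980,7.64,185.42,-3.42,104.40,94.81,64.61,0.00,453.46
```

Reading the 1978 row: paddy CH₄ dominates (185.53 Mt CO₂-eq),
cropland change is a small net sink (−3.43 Mt, afforestation of
cropland stores carbon), pesticide production is zero because its
activity statistics begin in 1990, and the total column is the sum of
the seven activities. By 2016 the same run reports 865.86 Mt, with
cropland N₂O (256.84 Mt) and input production growing fastest —
the fertilizer/machinery-driven trend the synthetic generator encodes.

The same from Python:

```python
import cropghg as cg

ps = cg.load_params()                       # default registry
panel = cg.generate_panel(seed=11)          # or cg.read_panel("dir/")
panel = cg.fold_provinces(cg.interpolate_gaps(panel))
tensor = cg.compute_tensor(panel, ps)
national = cg.assemble_outputs(tensor)["national_by_activity"]

mc = cg.run_mc(panel, ps, n_samples=50_000, seed=11)
lo, hi = cg.relative_bounds(mc)             # e.g. (-4%, +4%) for rice
```

Real activity statistics enter through the documented long CSV
schemas (`cropghg synth --seed 1 --out dir` writes templates);
parameter replacements through a YAML config plus keyed CSV tables
(`cropghg validate-params --export tables/` exports the current set).

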