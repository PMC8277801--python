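"""Canonical dimension labels shared across the inventory.

Every keyed parameter table and activity panel is indexed by the label
lists below.  Order matters: vectorized engines pivot panels into dense
arrays whose axes follow these lists.
"""

from __future__ import annotations

# 13 crop types entering the residue-burning budget.
CROPS: list[str] = [
    "rice",
    "wheat",
    "corn",
    "millet",
    "jowar",
    "other_cereal",
    "beans",
    "tubers",
    "cotton",
    "oil_bearing",
    "fiber",
    "sugar",
    "tobacco",
]

# 11 crops whose residues enter the cropland nitrogen budget: the burning
# list minus fiber crops and tobacco (configurable at call sites).
RESIDUE_CROPS: list[str] = [c for c in CROPS if c not in ("fiber", "tobacco")]

# Rice types of the cultivation model: early rice, middle & single-late
# rice (one pooled type), and double-late rice.
RICE_TYPES: list[str] = ["early", "middle_single_late", "double_late"]

# Source emission-factor table types before pooling middle/single-late.
RICE_SOURCE_TYPES: list[str] = ["early", "middle", "single_late", "double_late"]

# Water/organic-input regimes of the paddy CH4 emission-factor quadruple:
# (organic input F / no organic input NF) x (continuous CI / intermittent SI).
RICE_REGIMES: list[str] = ["f_ci", "f_si", "nf_ci", "nf_si"]

# Land classes of the land-use-change carbon bookkeeping.
LAND_CLASSES: list[str] = [
    "cropland",
    "wood",
    "grassland",
    "water_residential",
    "others",
]

# 8 cropland-change types: 4 counterpart classes x 2 directions.
CHANGE_TYPES: list[str] = [
    "cropland_to_wood",
    "wood_to_cropland",
    "cropland_to_grassland",
    "grassland_to_cropland",
    "cropland_to_water_residential",
    "water_residential_to_cropland",
    "cropland_to_others",
    "others_to_cropland",
]

# 6 excreta-producing classes feeding the manure-N budget.  The rural
# human population is one class; the livestock split is configurable.
CREATURES: list[str] = [
    "rural_population",
    "cattle",
    "pigs",
    "sheep_goats",
    "poultry",
    "other_livestock",
]

# 9 energy carriers of generalized agriculture.  Physical units: tonnes
# for fuels, 10^3 m3 for natural gas, kWh for electricity.
ENERGY_CARRIERS: list[str] = [
    "coal",
    "coke",
    "gasoline",
    "kerosene",
    "diesel",
    "fuel_oil",
    "lpg",
    "natural_gas",
    "electricity",
]
PRIMARY_ENERGY: list[str] = [e for e in ENERGY_CARRIERS if e != "electricity"]

# The seven inventory activities, in reporting order.
ACTIVITIES: list[str] = [
    "residue_burning",
    "rice",
    "cropland_change",
    "cropland_n2o",
    "machinery",
    "fertilizer_production",
    "pesticide_production",
]

FIRST_YEAR = 1978
LAST_YEAR = 2016
YEARS: list[int] = list(range(FIRST_YEAR, LAST_YEAR + 1))

# Land-use snapshot years behind the transition intervals.
SNAPSHOT_YEARS: tuple[int, ...] = (1980, 1990, 2000, 2010, 2015)

# Agro-ecological-zone groups triggering rice EF substitution rules.
AEZ_6A_PROVINCES: tuple[str, ...] = ("shanghai", "jiangsu", "anhui", "henan", "hubei")
AEZ_6B_PROVINCES: tuple[str, ...] = ("chongqing", "sichuan", "guizhou", "yunnan")

# Gas columns of every emission frame.  ``co2eq_direct`` carries
# quantities whose emission factor is already denominated in CO2-eq
# (pesticide production); it keeps the per-gas columns honest.
GAS_COLUMNS: list[str] = ["co2", "ch4", "n2o", "co2eq_direct"]

MOLAR_CO2_PER_C = 44.0 / 12.0  # CO2 mass per C mass
MOLAR_N2O_PER_N = 44.0 / 28.0  # N2O mass per N2O-N mass
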