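"""Published summary statistics from the white lupin validation program.

Small reference tables — water budgets of the managed environments used for
genomic-selection model training and validation, environment-level trait
means from the 2 x 2 factorial validation trial, and the genotype-group
comparison for the drought-selected breeding lines.  They serve as worked
example inputs for the trial-analysis operations (water-budget accounting,
stress-reduction summaries, crossover detection); plot-level raw data are
not available, only these summaries.
"""

from __future__ import annotations

import pandas as pd

from .trial import WaterBudget

__all__ = [
    "WATER_BUDGETS",
    "ENVIRONMENT_MEANS",
    "ENVIRONMENT_MEANS_LSD",
    "DROUGHT_LINE_MEANS",
    "DROUGHT_LINE_LSD",
]

#: Water amounts (mm) before sowing / sowing-to-treatment / during treatment
#: for the drought-stress and moisture-favorable regimes of each managed
#: environment pair.
WATER_BUDGETS: dict[str, WaterBudget] = {
    "training_breeding_lines": WaterBudget(30, 120, 50, 240),
    "training_landraces": WaterBudget(30, 120, 21, 332),
    "validation_sandy_loam": WaterBudget(220, 80, 0, 70),
    "validation_silty_clay": WaterBudget(220, 100, 0, 200),
}

#: Trait means of the four managed validation environments (grain yield and
#: straw biomass in t/ha, harvest index as a fraction, flowering/maturity in
#: days from 1 April, plant height in cm).
ENVIRONMENT_MEANS = pd.DataFrame(
    {
        "grain_yield": [3.67, 2.63, 4.31, 3.49],
        "straw_biomass": [4.33, 2.55, 5.19, 4.44],
        "harvest_index": [0.456, 0.510, 0.449, 0.446],
        "flowering_time": [15.7, 15.7, 16.1, 16.3],
        "maturity_time": [76.8, 82.8, 81.3, 90.3],
        "plant_height": [102.5, 72.3, 108.7, 92.1],
    },
    index=[
        "drought/sandy_loam",
        "drought/silty_clay",
        "favorable/sandy_loam",
        "favorable/silty_clay",
    ],
)

#: LSD (p < 0.05) for the environment means above.
ENVIRONMENT_MEANS_LSD = pd.Series(
    {
        "grain_yield": 0.32,
        "straw_biomass": 0.53,
        "harvest_index": 0.019,
        "flowering_time": 0.4,
        "maturity_time": 0.9,
        "plant_height": 7.3,
    }
)

#: Breeding lines selected for adaptation to drought: grain yield (t/ha)
#: under drought (D) and moisture-favorable (F) water treatments (means
#: across the two soil types), and mean flowering time (days from 1 April).
DROUGHT_LINE_MEANS = pd.DataFrame(
    {
        "grain_yield_drought": [3.45, 3.75, 3.19, 2.66],
        "grain_yield_favorable": [3.90, 4.25, 4.96, 3.66],
        "flowering_time_mean": [15.3, 16.5, 19.9, 17.9],
    },
    index=["PS_top", "GS_top", "GS_mid", "GS_bottom"],
)

#: LSD (p < 0.05) for the columns of DROUGHT_LINE_MEANS.
DROUGHT_LINE_LSD = pd.Series(
    {
        "grain_yield_drought": 0.45,
        "grain_yield_favorable": 0.55,
        "flowering_time_mean": 0.6,
    }
)
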