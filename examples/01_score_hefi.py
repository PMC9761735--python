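"""Score a single day of eating with the HEFI-2019.

Builds two dietary profiles — one aligned with Canada's Food Guide 2019
(half of food intake as vegetables and fruits, all grains whole, plant-
forward protein, water as the only beverage, favourable fats, low free
sugars and sodium) and one typical Western day — and prints the 10
component scores and the 80-point total for each.
"""

import pandas as pd

from hefi_cvd import full_credit_profile, score_hefi

profiles = pd.DataFrame(
    [
        full_credit_profile(),
        {
            "vf_ra": 1.5, "whole_grain_ra": 0.5, "refined_grain_ra": 3.0,
            "protein_ra": 2.0, "plant_protein_ra": 0.2, "other_food_ra": 2.5,
            "rec_bev_g": 600.0, "other_bev_g": 700.0, "energy_kcal": 2300.0,
            "sfa_g": 32.0, "mufa_g": 28.0, "pufa_g": 11.0,
            "free_sugars_g": 90.0, "sodium_mg": 3500.0,
        },
    ],
    index=["guide-aligned", "typical"],
)

scored = score_hefi(profiles)
components = [c for c in scored.columns if not c.startswith(("ratio_", "flag_"))]
print(scored[components].T.round(1))
print(
    "\nEach row is a component's points (Vegetables & fruits out of 20,"
    "\nProtein foods out of 5, ...); 'total' is the 80-point HEFI-2019."
    "\nThe guide-aligned day reaches the 80-point maximum; the typical day"
    "\nloses points on whole grains, beverages, free sugars and sodium."
)
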