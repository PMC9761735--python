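# Default HEFI-2019 scoring standards.
#
# The scoring engine is cutoff-agnostic: every component is defined by a named
# ratio (computed by hefi_cvd.scoring.compute_ratios), a direction, a
# zero-credit cutoff, a full-credit cutoff and a maximum number of points.
# Points are allocated proportionally between the two cutoffs.
#
# The component structure (5 food components, 1 beverage component, 4 nutrient
# components; 80 points total; Vegetables & fruits worth 20 points, Protein
# foods worth 5) follows the published HEFI-2019. Numeric cutoffs transcribed
# from the HEFI-2019 source publication to the precision available; they are
# configuration and may be replaced wholesale by passing a different standards
# file.
version: "hefi2019-default-1"
components:
  - name: vegetables_fruits
    ratio: vf_share                # RA of vegetables & fruits / total food RA
    max_points: 20
    direction: higher
    zero_cutoff: 0.05
    full_cutoff: 0.50
  - name: whole_grain_foods
    ratio: whole_grain_share       # RA whole grains / total food RA
    max_points: 5
    direction: higher
    zero_cutoff: 0.00
    full_cutoff: 0.25
  - name: grain_foods_ratio
    ratio: grain_ratio             # RA whole grains / RA total grains
    max_points: 5
    direction: higher
    zero_cutoff: 0.00
    full_cutoff: 1.00
  - name: protein_foods
    ratio: protein_share           # RA protein foods / total food RA
    max_points: 5
    direction: higher
    zero_cutoff: 0.05
    full_cutoff: 0.25
  - name: plant_protein_foods
    ratio: plant_protein_ratio     # RA plant protein / RA total protein foods
    max_points: 5
    direction: higher
    zero_cutoff: 0.00
    full_cutoff: 0.50
  - name: beverages
    ratio: recommended_bev_ratio   # g water & unsweetened bev / g all beverages
    max_points: 10
    direction: higher
    zero_cutoff: 0.40
    full_cutoff: 1.00
  - name: fatty_acids
    ratio: unsat_sat_ratio         # (MUFA + PUFA) / SFA, g/g
    max_points: 5
    direction: higher
    zero_cutoff: 1.1
    full_cutoff: 2.6
  - name: saturated_fats
    ratio: sfa_pct_energy          # % of energy from saturated fat
    max_points: 5
    direction: lower
    zero_cutoff: 15.0
    full_cutoff: 10.0
  - name: free_sugars
    ratio: free_sugars_pct_energy  # % of energy from free sugars
    max_points: 10
    direction: lower
    zero_cutoff: 20.0
    full_cutoff: 10.0
  - name: sodium
    ratio: sodium_density          # mg sodium per kcal
    max_points: 10
    direction: lower
    zero_cutoff: 2.0
    full_cutoff: 1.0
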