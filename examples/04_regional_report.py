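"""Compose public treatment rates and build population-weighted aggregates.

The public treatment rate is the per-realisation product of the any-medical
rate and the public fraction; regional and combined series are
population-weighted means of member-country realisations, summarised into
percentile intervals only after aggregation so cross-country correlation
from shared ensemble runs is preserved.
"""

import pandas as pd

from feverseek import (
    EnsembleConfig,
    PipelineInputs,
    WorldConfig,
    aggregate_report,
    run_ensemble,
    summarise_cube,
    survey_prep,
    synthetic_data,
)

config = WorldConfig(n_regions=3, countries_per_region=5, survey_cadence=5,
                     children_per_survey=2000, no_data_fraction=0.2,
                     short_span_fraction=0.1, seed=13)
truth, panel, region_map = synthetic_data.generate_world(config)
responses, _ = synthetic_data.apply_missingness(
    pd.concat(synthetic_data.generate_surveys(truth, config), ignore_index=True), config
)
observations = survey_prep.aggregate_surveys(
    [g for _, g in responses.groupby("survey_id", sort=False)]
)
inputs = PipelineInputs(observations, panel, region_map)

cubes = run_ensemble(inputs, EnsembleConfig(n_runs=15, draws_per_run=15, base_seed=6))
cubes["public_rate"] = aggregate_report.compose_public_rate(
    cubes["any_medical"], cubes["public_fraction"]
)

regional = aggregate_report.regional_estimates(cubes, region_map, years=(1990, 2005, 2020))
table = regional[regional["outcome"] == "any_medical"].copy()
table[["point", "lo95", "hi95"]] = (table[["point", "lo95", "hi95"]] * 100).round(0)
print("population-weighted any-medical treatment-seeking (%) by region:")
print(table.pivot_table(index="grouping", columns="year", values="point").to_string())

change = aggregate_report.absolute_change(cubes["any_medical"], 1990, 2020)
print("\ncountries with a declining any-medical rate 1990 -> 2020:")
declining = change[change["change"] < 0]
for _, row in declining.iterrows():
    print(f"  {row['country']}: {row['change']:+.2f} "
          f"[{row['lo95']:+.2f}, {row['hi95']:+.2f}]")

summary = summarise_cube(cubes["any_medical"])
low = aggregate_report.threshold_counts(summary, 2020, 0.30, "below")
print(f"\ncountries with a mean 2020 treatment-seeking rate below 30%: "
      f"{low}/{len(cubes['any_medical'].countries)}")
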