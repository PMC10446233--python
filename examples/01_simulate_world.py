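"""Generate a synthetic survey world and inspect its known truth.

The generator builds regions, countries, smooth regional trends, country
random offsets and covariate effects on the logit scale, then simulates
child-level fever surveys observing that truth.
"""

import pandas as pd

from feverseek import WorldConfig, survey_prep, synthetic_data

config = WorldConfig(
    n_regions=2, countries_per_region=5, survey_cadence=5,
    children_per_survey=2000, no_data_fraction=0.2, short_span_fraction=0.1,
    seed=1,
)
truth, panel, region_map = synthetic_data.generate_world(config)
surveys = synthetic_data.generate_surveys(truth, config)
responses = pd.concat([s for s in surveys if not s.empty], ignore_index=True)
responses, record = synthetic_data.apply_missingness(responses, config)
observations = survey_prep.aggregate_surveys(
    [g for _, g in responses.groupby("survey_id", sort=False)]
)

print(f"{len(region_map.countries)} countries in {len(region_map.regions)} regions")
print(f"{len(responses):,} child-level rows -> {len(observations)} national observations")
print(f"countries with no surveys (to be donor-matched): {record.no_data_countries}")
print(f"countries truncated to <5-year spans:           {record.short_span_countries}")

example = observations.head(3)
print("\nfirst national observations (rate with Wilson 95% CI, Kish effective n):")
print(example.to_string(index=False))

check = truth.rate(example.iloc[0]["country"], int(example.iloc[0]["year"]),
                   example.iloc[0]["outcome"])
print(f"\ntrue rate behind the first observation: {check:.3f} "
      f"(observed {example.iloc[0]['rate']:.3f} from ~{example.iloc[0]['n_eff']:.0f} "
      "effective febrile children)")
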