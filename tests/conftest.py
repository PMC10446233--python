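import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from feverseek import (
    EnsembleConfig,
    PipelineConfig,
    PipelineInputs,
    WorldConfig,
    run_ensemble,
    survey_prep,
    synthetic_data,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_world(config: WorldConfig):
    """Generate a world, its surveys, and aggregated national observations."""
    truth, panel, region_map = synthetic_data.generate_world(config)
    surveys = synthetic_data.generate_surveys(truth, config)
    responses = pd.concat([s for s in surveys if not s.empty], ignore_index=True)
    responses, record = synthetic_data.apply_missingness(responses, config)
    observations = survey_prep.aggregate_surveys(
        [g for _, g in responses.groupby("survey_id", sort=False)]
    )
    return truth, panel, region_map, responses, observations, record


@pytest.fixture(scope="session")
def small_world():
    """A compact 2-region world with every data pathology present."""
    config = WorldConfig(
        n_regions=2, countries_per_region=6, survey_cadence=4,
        children_per_survey=1500, no_data_fraction=0.2, short_span_fraction=0.1,
        seed=11,
    )
    truth, panel, region_map, responses, observations, record = build_world(config)
    return {
        "config": config, "truth": truth, "panel": panel, "region_map": region_map,
        "responses": responses, "observations": observations, "record": record,
    }


@pytest.fixture(scope="session")
def small_inputs(small_world):
    return PipelineInputs(
        small_world["observations"], small_world["panel"].copy(),
        small_world["region_map"],
    )


@pytest.fixture(scope="session")
def small_cubes(small_inputs):
    """A 6×8 ensemble on the small world, shared across reporting tests."""
    config = EnsembleConfig(n_runs=6, draws_per_run=8, base_seed=5)
    return run_ensemble(small_inputs, config)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()
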