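"""Two-layer Monte-Carlo propagation of data and covariate uncertainty.

Layer one perturbs the inputs: every observed rate and covariate value is
replaced by a draw from inside its 95% CI (uniform by default) and both
models are refitted.  Layer two draws coefficient realisations from each
refitted model's Gaussian coefficient distribution.  With the default
100 runs × 100 draws this yields 10,000 realisations of each outcome per
country-year, from which percentile confidence intervals are read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import gamm_engine
from .covariate_prep import CovariatePanel
from .errors import EnsembleError, SummaryError
from .pipeline import (
    OUTCOMES,
    PipelineConfig,
    PipelineInputs,
    PointModels,
    fit_point_models,
    prediction_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    n_runs: int = 100
    draws_per_run: int = 100
    base_seed: int = 0
    perturb_distribution: str = "uniform"  # uniform | truncnorm
    include_coef_uncertainty: bool = True
    refit_selection: bool = False
    refit_matching: bool = False
    max_failure_fraction: float = 0.1
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def replace(self, **kw) -> "EnsembleConfig":
        return replace(self, **kw)


@dataclass
class RealisationCube:
    """country × year × realisation array of rates in (0, 1) for one outcome."""

    values: np.ndarray
    countries: list[str]
    years: np.ndarray
    outcome: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (len(self.countries), len(self.years))
        if self.values.shape[:2] != expected:
            raise ValueError(f"cube shape {self.values.shape} != {expected} + realisations")

    @property
    def n_realisations(self) -> int:
        return self.values.shape[2]

    def country_year(self, country: str, year: int) -> np.ndarray:
        i = self.countries.index(country)
        j = int(np.flatnonzero(self.years == year)[0])
        return self.values[i, j]


def _interval_draw(lo, hi, point, rng, distribution: str):
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo > hi):
        raise ValueError("lo95 > hi95 in interval inputs")
    width = hi - lo
    if distribution == "uniform":
        return lo + width * rng.random(lo.shape)
    if distribution == "truncnorm":
        point = np.asarray(point, dtype=float)
        sd = np.where(width > 0, width / (2 * 1.959963984540054), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(sd > 0, (lo - point) / sd, 0.0)
            b = np.where(sd > 0, (hi - point) / sd, 0.0)
        draw = stats.truncnorm.rvs(a, b, loc=point, scale=np.where(sd > 0, sd, 1.0),
                                   random_state=rng)
        return np.where(width > 0, draw, point)
    raise ValueError(f"unknown perturbation distribution {distribution!r}")


def perturb_inputs(observations: pd.DataFrame, panel: CovariatePanel, seed,
                   distribution: str = "uniform") -> tuple[pd.DataFrame, CovariatePanel]:
    """Independent CI draws for every observed rate and covariate value.

    Deterministic given ``seed``; zero-width intervals return the point
    value unchanged.  Covariates are perturbed on their raw (reported)
    scale and re-prepared with the frozen transform/standardisation state.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = observations.copy()
    obs["rate"] = _interval_draw(
        obs["lo95"].to_numpy(), obs["hi95"].to_numpy(), obs["rate"].to_numpy(),
        rng, distribution,
    )
    if panel.data.empty:
        return obs, panel
    new_values = _interval_draw(
        panel.data["lo95"].to_numpy(), panel.data["hi95"].to_numpy(),
        panel.data["value"].to_numpy(), rng, distribution,
    )
    return obs, panel.with_values(new_values)


def run_ensemble(inputs: PipelineInputs, config: EnsembleConfig,
                 years=None) -> dict[str, RealisationCube]:
    """The full two-layer ensemble; one realisation cube per outcome.

    Per run r: perturb inputs with a seed derived from (base_seed, r),
    refit both models (selection and donor matching frozen from the
    unperturbed point fit by default), draw coefficient realisations, and
    predict every country-year.  Failed runs are skipped and logged; more
    than ``max_failure_fraction`` failures aborts the ensemble.
    """
    if years is None:
        years = inputs.years
    years = np.asarray(years, dtype=int)

    point_models = fit_point_models(inputs, config.pipeline)
    frame = prediction_frame(inputs.region_map, years)
    countries = inputs.region_map.countries
    n_total = config.n_runs * config.draws_per_run

    cubes = {
        outcome: np.empty((len(countries), len(years), n_total)) for outcome in OUTCOMES
    }
    run_seeds = []
    failures = []
    filled = 0
    for run in range(config.n_runs):
        seq = np.random.SeedSequence(entropy=config.base_seed, spawn_key=(run,))
        perturb_rng, draw_rng = [np.random.default_rng(s) for s in seq.spawn(2)]
        run_seeds.append(int(seq.generate_state(1)[0] % (2**31)))
        try:
            obs_r, panel_r = perturb_inputs(
                inputs.observations, point_models.panel, perturb_rng,
                config.perturb_distribution,
            )
            run_inputs = PipelineInputs(obs_r, panel_r, inputs.region_map)
            if config.refit_selection:
                from .pipeline import select_covariates_per_outcome

                selected = select_covariates_per_outcome(run_inputs, config.pipeline)
            else:
                selected = point_models.selected
            frozen = None if config.refit_matching else point_models
            models_r = fit_point_models(
                run_inputs, config.pipeline, selected=selected, frozen_state=frozen
            )
            for outcome in OUTCOMES:
                fit = models_r.fits[outcome]
                if config.include_coef_uncertainty:
                    draws = gamm_engine.sample_coefficients(
                        fit, config.draws_per_run, draw_rng
                    ).T
                else:
                    draws = np.tile(fit.coefficients[:, None], (1, config.draws_per_run))
                rates = gamm_engine.predict_frame(fit, frame, models_r.panel, draws)
                block = rates.reshape(len(countries), len(years), config.draws_per_run)
                cubes[outcome][:, :, filled:filled + config.draws_per_run] = block
        except Exception as exc:
            logger.warning("ensemble run %d failed: %s", run, exc)
            failures.append(run)
            continue
        filled += config.draws_per_run

    n_failed = len(failures)
    if n_failed > config.max_failure_fraction * config.n_runs:
        raise EnsembleError(
            f"{n_failed}/{config.n_runs} ensemble runs failed (limit "
            f"{config.max_failure_fraction:.0%})"
        )
    if n_failed:
        logger.warning("ensemble completed with %d/%d failed runs", n_failed, config.n_runs)

    provenance = {
        "n_runs": config.n_runs - n_failed,
        "draws_per_run": config.draws_per_run,
        "base_seed": config.base_seed,
        "run_seeds": run_seeds,
        "failed_runs": failures,
    }
    return {
        outcome: RealisationCube(
            cubes[outcome][:, :, :filled], list(countries), years, outcome, dict(provenance)
        )
        for outcome in OUTCOMES
    }


def summarise_cube(cube: RealisationCube, probs=(0.025, 0.975)) -> pd.DataFrame:
    """Realisation mean and percentile interval per country-year.

    Percentiles use linear interpolation between order statistics.
    """
    if cube.values.size == 0 or cube.n_realisations < 2:
        raise SummaryError("cube has fewer than 2 realisations")
    point = cube.values.mean(axis=2)
    lo = np.quantile(cube.values, probs[0], axis=2, method="linear")
    hi = np.quantile(cube.values, probs[1], axis=2, method="linear")
    rows = []
    for i, country in enumerate(cube.countries):
        rows.append(pd.DataFrame({
            "country": country,
            "year": cube.years,
            "outcome": cube.outcome,
            "point": point[i],
            "lo95": lo[i],
            "hi95": hi[i],
        }))
    return pd.concat(rows, ignore_index=True)


def save_cube(cube: RealisationCube, directory) -> None:
    """Store a cube as a binary array plus a CSV index."""
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / f"cube_{cube.outcome}.npy", cube.values)
    index = pd.DataFrame({
        "axis": (["country"] * len(cube.countries)) + (["year"] * len(cube.years)),
        "label": list(cube.countries) + [str(y) for y in cube.years],
    })
    index.to_csv(out / f"cube_{cube.outcome}_index.csv", index=False)
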