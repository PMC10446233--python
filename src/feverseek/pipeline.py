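"""End-to-end orchestration: prepare → select → fit → gap-fill → tail-fix.

This module wires the stages together into point-model fits for both
outcomes; the uncertainty module reuses it inside every ensemble run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import covariate_prep, gamm_engine, gap_fill
from .covariate_prep import CovariatePanel, PCScores
from .errors import ConfigurationError
from .gamm_engine import FitConfig, GAMMFit
from .gap_fill import RegionMap

logger = logging.getLogger(__name__)

OUTCOMES = ("any_medical", "public_fraction")


@dataclass
class PipelineInputs:
    """Everything one analysis needs: observations, covariates, geography."""

    observations: pd.DataFrame  # country, year, outcome, rate, lo95, hi95, n_eff
    panel: CovariatePanel
    region_map: RegionMap

    @property
    def years(self) -> np.ndarray:
        if not self.panel.data.empty:
            years = self.panel.data["year"]
        else:
            years = self.observations["year"]
        return np.arange(int(years.min()), int(years.max()) + 1)


@dataclass
class PipelineConfig:
    """Choices shared by the point fit and the uncertainty ensemble."""

    fit: FitConfig = field(default_factory=FitConfig)
    covariates: dict[str, list[str]] | None = None  # outcome -> covariates; None = select
    select_max_size: int = 3
    select_p_threshold: float = 0.05
    anchor_years: tuple[int, ...] = (2000, 2010, 2020)
    pca_var_threshold: float = 0.9
    fix_tails: bool = True
    late_window: tuple[int, ...] = (2019, 2020, 2021)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass
class PointModels:
    """Point fits for both outcomes plus the frozen gap-fill state."""

    fits: dict[str, GAMMFit]
    selected: dict[str, list[str]]
    pc_scores: dict[str, PCScores]
    matches: dict[str, pd.DataFrame]
    panel: CovariatePanel


def prepare_panel(inputs: PipelineInputs) -> CovariatePanel:
    """Fit transform + standardisation state on the raw covariate panel."""
    if inputs.panel.data.empty:
        return inputs.panel
    if not inputs.panel.standardisation:
        inputs.panel.prepare()
    return inputs.panel


def select_covariates_per_outcome(inputs: PipelineInputs, config: PipelineConfig
                                  ) -> dict[str, list[str]]:
    """AIC + p-value subset selection, independently per outcome."""
    panel = prepare_panel(inputs)
    if config.covariates is not None:
        return {outcome: list(config.covariates.get(outcome, [])) for outcome in OUTCOMES}
    if panel.data.empty:
        return {outcome: [] for outcome in OUTCOMES}
    selected = {}
    for outcome in OUTCOMES:
        def template(obs, pnl, subset, outcome=outcome):
            fit_config = config.fit.replace(outcome=outcome, covariates=tuple(subset))
            return gamm_engine.fit_gamm(obs, pnl, inputs.region_map, fit_config)

        chosen, _ = covariate_prep.select_covariates(
            inputs.observations, panel, template,
            max_size=config.select_max_size, p_threshold=config.select_p_threshold,
        )
        selected[outcome] = chosen
    return selected


def fit_point_models(inputs: PipelineInputs, config: PipelineConfig,
                     selected: dict[str, list[str]] | None = None,
                     frozen_state: PointModels | None = None) -> PointModels:
    """Fit both outcome models with gap filling and tail fixing applied.

    When ``frozen_state`` is given (ensemble runs), covariate selection and
    donor-match assignments are copied from it instead of being recomputed.
    """
    panel = prepare_panel(inputs)
    inputs.region_map.with_spans(inputs.observations)
    if selected is None:
        if frozen_state is not None:
            selected = frozen_state.selected
        else:
            selected = select_covariates_per_outcome(inputs, config)

    fits: dict[str, GAMMFit] = {}
    pc_scores: dict[str, PCScores] = {}
    matches: dict[str, pd.DataFrame] = {}
    for outcome in OUTCOMES:
        covariates = tuple(selected[outcome])
        fit_config = config.fit.replace(outcome=outcome, covariates=covariates)
        fit = gamm_engine.fit_gamm(inputs.observations, panel, inputs.region_map, fit_config)

        if config.fix_tails:
            obs = inputs.observations
            obs = obs[obs["outcome"] == outcome] if "outcome" in obs.columns else obs
            for region in fit.regions:
                members = set(inputs.region_map.members(region))
                region_years = obs.loc[obs["country"].isin(members), "year"]
                if region_years.empty:
                    continue
                gamm_engine.fix_tail_trend(
                    fit, region, int(region_years.min()), config.late_window
                )

        needs_fill = (
            set(inputs.region_map.countries) - set(fit.countries)
            or any(inputs.region_map.span_length(c) < gap_fill.SHORT_SPAN_YEARS
                   for c in fit.countries)
        )
        if needs_fill and not panel.data.empty:
            if frozen_state is not None:
                _apply_frozen_matches(fit, frozen_state.fits[outcome])
                pc_scores[outcome] = frozen_state.pc_scores[outcome]
                matches[outcome] = frozen_state.matches[outcome]
            else:
                match_covs = list(covariates) if covariates else panel.covariates
                scores = covariate_prep.principal_components(
                    panel, config.anchor_years, var_threshold=config.pca_var_threshold,
                    covariates=match_covs,
                )
                wide = panel.wide(match_covs)
                matches[outcome] = gap_fill.assign_gap_fill(
                    fit, inputs.region_map, scores, wide, config.anchor_years
                )
                pc_scores[outcome] = scores
        elif needs_fill:
            # no covariates at all: fall back to zero effects for no-data countries
            for country in set(inputs.region_map.countries) - set(fit.countries):
                fit.zero_effect_countries.add(country)
            matches[outcome] = pd.DataFrame()
        else:
            matches[outcome] = pd.DataFrame()
        fits[outcome] = fit
    return PointModels(fits, selected, pc_scores, matches, panel)


def _apply_frozen_matches(fit: GAMMFit, reference: GAMMFit) -> None:
    """Copy donor assignments, trend scales and zero-effect fallbacks."""
    for target, donor in reference.donor_of.items():
        if donor in fit.country_index:
            fit.country_index[target] = fit.country_index[donor]
            fit.donor_of[target] = donor
        else:
            fit.zero_effect_countries.add(target)
    fit.trend_scale.update(reference.trend_scale)
    fit.zero_effect_countries |= reference.zero_effect_countries


def prediction_frame(region_map: RegionMap, years) -> pd.DataFrame:
    """All (country, year) rows the pipeline predicts, in a stable order."""
    countries = region_map.countries
    years = np.asarray(years, dtype=int)
    return pd.DataFrame({
        "country": np.repeat(countries, years.size),
        "year": np.tile(years, len(countries)),
    })


def predict_point(models: PointModels, region_map: RegionMap, years) -> pd.DataFrame:
    """Point predictions for all countries × years × outcomes."""
    frame = prediction_frame(region_map, years)
    out = []
    for outcome, fit in models.fits.items():
        rates = gamm_engine.predict_frame(fit, frame, models.panel)
        piece = frame.copy()
        piece["outcome"] = outcome
        piece["rate"] = rates
        out.append(piece)
    return pd.concat(out, ignore_index=True)
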