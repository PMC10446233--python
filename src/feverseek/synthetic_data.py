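"""Synthetic DHS/MICS-like worlds with known treatment-seeking truth.

The generator builds a small "world" of regions and countries whose true
any-medical treatment rates and public fractions follow exactly the additive
structure the estimation model assumes on the logit scale:

    logit(rate) = region intercept + smooth region trend
                  + country offset + smooth covariate effects

Country offsets are zero-mean normal (matching the random-effect model);
region trends are draws from the same constrained spline basis the model
uses, rescaled so their standard deviation over years equals the configured
amplitude.  Covariates are produced on a raw scale chosen so the Box-Cox
step recovers the intended transform (lognormal raw values for a log
covariate, square-root-scaled values for a square covariate), carry stated
CI widths, and act on the truth through linear or centred-quadratic shapes
of their standardised values.

Child-level surveys then observe that truth: each survey draws febrile
children, a two-stage cluster caricature assigns lognormal weight
multipliers at cluster level, and treatment outcomes are multinomial so the
expected weighted proportion of treated-among-febrile equals the true rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .covariate_prep import CovariatePanel
from .errors import BoundsError, ConfigurationError
from .gamm_engine import build_spline_basis
from .gap_fill import RegionMap

logger = logging.getLogger(__name__)

OUTCOMES = ("any_medical", "public_fraction")


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic covariate: its effect shape and measurement uncertainty.

    ``link`` controls the raw scale the covariate is reported on (and hence
    the transform the preparation stage should pick): ``exp`` yields
    lognormal raw values (log transform), ``sqrt`` yields square-root-scaled
    values (square transform), ``identity`` yields roughly normal values.
    ``effect`` is in logit units per standard deviation of the underlying
    score; ``ci_width`` is the relative (exp) or sd-relative half-width of
    the reported 95% CI.
    """

    name: str
    shape: str = "linear"  # linear | quadratic | none
    effect: float = 0.5
    ci_width: float = 0.1
    link: str = "identity"  # identity | exp | sqrt


DEFAULT_COVARIATES = (
    CovariateSpec("health_spend", shape="linear", effect=0.5, ci_width=0.10, link="exp"),
    CovariateSpec("anc_coverage", shape="quadratic", effect=0.3, ci_width=0.08, link="sqrt"),
)


@dataclass(frozen=True)
class WorldConfig:
    """Study-design parameters of a synthetic world.

    Defaults emulate the scale of the multi-country survey compilations the
    model targets: ~40% of countries without any survey, surveys every five
    years, and around two thousand febrile children per survey.
    """

    n_regions: int = 3
    countries_per_region: int = 10
    year_range: tuple[int, int] = (1990, 2020)
    trend_amplitude: float = 0.6
    country_effect_sd: float = 0.5
    covariate_specs: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    survey_cadence: int = 5
    children_per_survey: int = 8000
    no_data_fraction: float = 0.4
    short_span_fraction: float = 0.1
    seed: int = 0
    fever_prevalence: float = 0.27
    nonmedical_seek: float = 0.3
    cluster_size: int = 25
    design_weight_sd: float = 0.3
    intercept_spread: float = 0.5
    base_rate_any: float = 0.55
    base_rate_public: float = 0.5
    effect_covariate_corr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_regions", "countries_per_region", "survey_cadence", "cluster_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.children_per_survey < 0:
            raise ConfigurationError("children_per_survey must be >= 0")
        for name in ("no_data_fraction", "short_span_fraction", "fever_prevalence",
                     "nonmedical_seek"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.no_data_fraction + self.short_span_fraction > 1.0:
            raise ConfigurationError(
                "no_data_fraction + short_span_fraction must not exceed 1"
            )
        if self.year_range[1] < self.year_range[0]:
            raise ConfigurationError("year_range is empty")
        for name in ("trend_amplitude", "country_effect_sd", "design_weight_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)

    def replace(self, **kw) -> "WorldConfig":
        return replace(self, **kw)


@dataclass
class TruthSurface:
    """True rates per (country, year, outcome) plus their logit components."""

    frame: pd.DataFrame  # country, year, outcome, true_rate, and component columns
    region_of: dict[str, str]

    COMPONENTS = ("region_intercept", "region_trend", "country_offset", "covariate_effect")

    def __post_init__(self) -> None:
        rates = self.frame["true_rate"]
        if not ((rates > 0) & (rates < 1)).all():
            raise ValueError("true rates must lie strictly in (0, 1)")

    def rate(self, country: str, year: int, outcome: str) -> float:
        frame = self.frame
        row = frame[(frame["country"] == country) & (frame["year"] == year)
                    & (frame["outcome"] == outcome)]
        if row.empty:
            raise BoundsError(f"no truth at ({country}, {year}, {outcome})")
        return float(row["true_rate"].iloc[0])

    def pivot(self, outcome: str) -> pd.DataFrame:
        """country × year matrix of true rates for one outcome."""
        sub = self.frame[self.frame["outcome"] == outcome]
        return sub.pivot(index="country", columns="year", values="true_rate")


def _smooth_trend(years: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """A random smooth trend from the model's own spline space, sd = amplitude."""
    if amplitude == 0.0 or years.size < 5:
        return np.zeros(years.size)
    basis = build_spline_basis(years.astype(float), 5)
    values = basis.matrix(years.astype(float)) @ rng.standard_normal(basis.n_columns)
    values -= values.mean()
    sd = values.std()
    if sd < 1e-12:
        return np.zeros(years.size)
    return values * (amplitude / sd)


def _covariate_series(config: WorldConfig, rng: np.random.Generator,
                      countries: list[str]) -> dict[str, pd.DataFrame]:
    """Latent standard scores z(country, year) per covariate, smooth in time."""
    years = config.years
    t_std = (years - years.mean()) / max((years.max() - years.min()) / 2.0, 1.0)
    out = {}
    for spec in config.covariate_specs:
        level = rng.normal(0.0, 1.0, size=len(countries))
        slope = rng.normal(0.0, 0.6, size=len(countries))
        curve = rng.normal(0.0, 0.3, size=len(countries))
        z = (level[:, None] + slope[:, None] * t_std[None, :]
             + curve[:, None] * (t_std[None, :] ** 2 - 1.0 / 3.0))
        out[spec.name] = pd.DataFrame(z, index=countries, columns=years)
    return out


def _raw_covariate(spec: CovariateSpec, z: np.ndarray):
    """Map latent scores to the reported raw scale, with 95% CI bounds."""
    if spec.link == "exp":
        value = np.exp(0.6 * z + 3.0)
        lo = value * (1.0 - spec.ci_width)
        hi = value * (1.0 + spec.ci_width)
    elif spec.link == "sqrt":
        shifted = np.clip(z + 5.0, 0.1, None)
        value = np.sqrt(shifted)
        half = spec.ci_width * max(float(np.std(value)), 1e-6)
        lo = np.clip(value - half, 1e-6, None)
        hi = value + half
    else:
        value = z.copy()
        half = spec.ci_width * max(float(np.std(value)), 1e-6)
        lo = value - half
        hi = value + half
    return value, lo, hi


def _effect_contribution(spec: CovariateSpec, z: np.ndarray) -> np.ndarray:
    g = (z - z.mean()) / max(z.std(), 1e-12)
    if spec.shape == "linear":
        return spec.effect * g
    if spec.shape == "quadratic":
        return spec.effect * (g**2 - 1.0) / np.sqrt(2.0)
    if spec.shape == "none":
        return np.zeros_like(z)
    raise ConfigurationError(f"unknown effect shape {spec.shape!r}")


def generate_world(config: WorldConfig) -> tuple[TruthSurface, CovariatePanel, RegionMap]:
    """Generate truth, a covariate panel with CIs, and a region map.

    Deterministic given ``config.seed``: the same configuration yields
    bitwise-identical outputs on repeated calls.
    """
    rng = np.random.default_rng([config.seed, 1])
    years = config.years
    regions = [f"R{r:02d}" for r in range(config.n_regions)]
    countries = []
    region_of = {}
    for r, region in enumerate(regions):
        for c in range(config.countries_per_region):
            name = f"{region}C{c:02d}"
            countries.append(name)
            region_of[name] = region

    base_logit = {
        "any_medical": float(logit(config.base_rate_any)),
        "public_fraction": float(logit(config.base_rate_public)),
    }
    intercepts = {
        outcome: {region: base_logit[outcome] + rng.normal(0.0, config.intercept_spread)
                  for region in regions}
        for outcome in OUTCOMES
    }
    trends = {
        outcome: {region: _smooth_trend(years, config.trend_amplitude, rng)
                  for region in regions}
        for outcome in OUTCOMES
    }

    z_scores = _covariate_series(config, rng, countries)

    offsets: dict[str, dict[str, float]] = {}
    for outcome in OUTCOMES:
        raw = rng.normal(0.0, 1.0, size=len(countries))
        if config.effect_covariate_corr > 0 and config.covariate_specs:
            # optionally correlate offsets with the first covariate's country level
            first = config.covariate_specs[0].name
            anchor = z_scores[first].mean(axis=1).to_numpy()
            anchor = (anchor - anchor.mean()) / max(anchor.std(), 1e-12)
            rho = config.effect_covariate_corr
            raw = rho * anchor + np.sqrt(1.0 - rho**2) * raw
        offsets[outcome] = {
            c: config.country_effect_sd * raw[i] for i, c in enumerate(countries)
        }

    effects = np.zeros((len(countries), len(years)))
    panel_rows = []
    for spec in config.covariate_specs:
        z = z_scores[spec.name].to_numpy()
        effects += _effect_contribution(spec, z)
        value, lo, hi = _raw_covariate(spec, z)
        for i, country in enumerate(countries):
            panel_rows.append(pd.DataFrame({
                "country": country,
                "year": years,
                "covariate": spec.name,
                "value": value[i],
                "lo95": lo[i],
                "hi95": hi[i],
            }))
    panel_frame = (pd.concat(panel_rows, ignore_index=True) if panel_rows
                   else pd.DataFrame(columns=["country", "year", "covariate",
                                              "value", "lo95", "hi95"]))

    truth_rows = []
    for outcome in OUTCOMES:
        for i, country in enumerate(countries):
            region = region_of[country]
            intercept = intercepts[outcome][region]
            trend = trends[outcome][region]
            offset = offsets[outcome][country]
            cov_effect = effects[i]
            lin = intercept + trend + offset + cov_effect
            truth_rows.append(pd.DataFrame({
                "country": country,
                "year": years,
                "outcome": outcome,
                "true_rate": expit(lin),
                "region_intercept": intercept,
                "region_trend": trend,
                "country_offset": offset,
                "covariate_effect": cov_effect,
            }))
    truth = TruthSurface(pd.concat(truth_rows, ignore_index=True), region_of)

    base_pop = rng.lognormal(mean=np.log(5e6), sigma=1.0, size=len(countries))
    growth = rng.normal(0.02, 0.01, size=len(countries))
    pop_rows = []
    for i, country in enumerate(countries):
        pop_rows.append(pd.DataFrame({
            "country": country,
            "year": years,
            "population": base_pop[i] * np.exp(growth[i] * (years - years[0])),
        }))
    region_map = RegionMap(region_of, pd.concat(pop_rows, ignore_index=True))

    panel = CovariatePanel(panel_frame) if not panel_frame.empty else CovariatePanel(
        pd.DataFrame({"country": [], "year": [], "covariate": [], "value": [],
                      "lo95": [], "hi95": []})
    )
    return truth, panel, region_map


def generate_surveys(truth: TruthSurface, config: WorldConfig) -> list[pd.DataFrame]:
    """Simulate child-level survey tables observing the truth surface.

    One survey per scheduled country-year (country-specific phase within the
    cadence).  Each row is a child: fever flag, sought-treatment flag,
    source class, and a positive sampling weight from a two-stage cluster
    caricature.  The expected weighted treated-among-febrile proportion
    equals the true any-medical rate.
    """
    rng = np.random.default_rng([config.seed, 2])
    years = config.years
    any_pivot = truth.pivot("any_medical")
    pub_pivot = truth.pivot("public_fraction")
    countries = list(any_pivot.index)
    surveys = []
    survey_counter = 0
    for country in countries:
        phase = int(rng.integers(config.survey_cadence))
        survey_years = [int(y) for y in years if (y - years[0]) % config.survey_cadence == phase]
        for year in survey_years:
            survey_counter += 1
            surveys.append(simulate_survey(
                truth, config, country, year,
                survey_id=f"S{survey_counter:04d}",
                rng=rng,
                p_any=float(any_pivot.loc[country, year]),
                p_public=float(pub_pivot.loc[country, year]),
            ))
    return surveys


def simulate_survey(truth: TruthSurface, config: WorldConfig, country: str, year: int,
                    survey_id: str = "S0001", rng=None,
                    p_any: float | None = None, p_public: float | None = None) -> pd.DataFrame:
    """One survey table for a given country-year (empty when no children)."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    if p_any is None:
        p_any = truth.rate(country, year, "any_medical")
    if p_public is None:
        p_public = truth.rate(country, year, "public_fraction")
    n = config.children_per_survey
    columns = ["survey_id", "country", "year", "weight", "fever", "sought", "source_class"]
    if n == 0:
        return pd.DataFrame(columns=columns)

    n_clusters = max(1, int(np.ceil(n / config.cluster_size)))
    cluster_mult = rng.lognormal(mean=0.0, sigma=config.design_weight_sd, size=n_clusters)
    cluster_of = rng.integers(n_clusters, size=n)
    weight = cluster_mult[cluster_of]

    fever = rng.random(n) < config.fever_prevalence
    u = rng.random(n)
    v = rng.random(n)
    medical = fever & (u < p_any)
    nonmed = fever & ~medical & (rng.random(n) < config.nonmedical_seek)
    sought = medical | nonmed

    source = np.full(n, None, dtype=object)
    source[medical & (v < p_public)] = "public"
    source[medical & (v >= p_public)] = "other_medical"
    source[nonmed] = "non_medical"

    sought_col = pd.array([bool(s) if f else None for s, f in zip(sought, fever)],
                          dtype="boolean")
    return pd.DataFrame({
        "survey_id": survey_id,
        "country": country,
        "year": year,
        "weight": weight,
        "fever": fever,
        "sought": sought_col,
        "source_class": source,
    })


@dataclass
class MissingnessRecord:
    no_data_countries: list[str]
    short_span_countries: list[str]


def apply_missingness(observations: pd.DataFrame, config: WorldConfig
                      ) -> tuple[pd.DataFrame, MissingnessRecord]:
    """Remove or truncate surveys to emulate data-sparse countries.

    A configured fraction of countries loses all rows; another fraction is
    truncated to a span of fewer than five years.  Country selection uses
    the seeded generator over the identifier-sorted country list, so the
    result is reproducible.  Works on any table with country and year
    columns (child responses or national observations).
    """
    if observations.empty:
        raise ConfigurationError("observation set is empty")
    if config.no_data_fraction + config.short_span_fraction > 1.0:
        raise ConfigurationError(
            "no_data_fraction + short_span_fraction must not exceed 1"
        )
    rng = np.random.default_rng([config.seed, 3])
    countries = sorted(observations["country"].unique())
    n = len(countries)
    n_drop = int(np.floor(config.no_data_fraction * n + 0.5))
    n_short = int(np.floor(config.short_span_fraction * n + 0.5))
    chosen = rng.permutation(n)[: n_drop + n_short]
    drop = sorted(countries[i] for i in chosen[:n_drop])
    shorten = sorted(countries[i] for i in chosen[n_drop:])

    frame = observations[~observations["country"].isin(drop)].copy()
    for country in shorten:
        mask = frame["country"] == country
        years = np.sort(frame.loc[mask, "year"].unique())
        if years.size == 0:
            continue
        span = int(rng.integers(1, SHORT_SPAN_MAX + 1))
        anchor = int(rng.choice(years))
        keep = (frame["year"] >= anchor) & (frame["year"] <= anchor + span - 1)
        frame = frame[~mask | keep]
    frame = frame.reset_index(drop=True)
    return frame, MissingnessRecord(drop, shorten)


#: truncated spans are at most this long (strictly below the 5-year rule)
SHORT_SPAN_MAX = 4


# ---------------------------------------------------------------------------
# CSV export


def write_world(out_dir, truth: TruthSurface, panel: CovariatePanel,
                region_map: RegionMap, responses: pd.DataFrame | None = None) -> None:
    """Write truth.csv, covariates.csv, regions.csv (and responses.csv)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.frame.to_csv(out / "truth.csv", index=False)
    panel.data.rename(columns={"covariate": "name"}).to_csv(out / "covariates.csv", index=False)
    regions = region_map.populations.copy()
    regions["region"] = regions["country"].map(region_map.country_region)
    regions[["country", "region", "year", "population"]].to_csv(
        out / "regions.csv", index=False
    )
    if responses is not None:
        responses.to_csv(out / "responses.csv", index=False)


def read_regions(path) -> RegionMap:
    frame = pd.read_csv(path)
    country_region = dict(frame.drop_duplicates("country")[["country", "region"]].values)
    populations = frame[["country", "year", "population"]]
    return RegionMap(country_region, populations)
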