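"""Fill estimation gaps for countries with no or short-span survey data.

Countries with no surveys borrow the country random effect of their nearest
neighbour (Euclidean distance in covariate principal-component space,
within the same region, ties broken lexicographically).  Countries whose
surveys span fewer than five years additionally borrow the regional
temporal trend, rescaled by the ratio of their own anchor-year covariate
change to the regional mean change (clipped to [0, 2] for stability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariate_prep import PCScores
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: data spans shorter than this many years trigger trend borrowing
SHORT_SPAN_YEARS = 5


@dataclass
class RegionMap:
    """Country → region assignment with populations and data-span records."""

    country_region: dict[str, str]
    populations: pd.DataFrame  # columns country, year, population
    spans: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    # spans: country -> (first survey year, last survey year, span length);
    # absent entry means the country has no data (span 0)

    def __post_init__(self) -> None:
        if (self.populations["population"] <= 0).any():
            raise ConfigurationError("populations must be positive")

    @property
    def countries(self) -> list[str]:
        return sorted(self.country_region)

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.country_region.values()))

    def region_of(self, country: str) -> str:
        return self.country_region[country]

    def members(self, region: str) -> list[str]:
        return sorted(c for c, r in self.country_region.items() if r == region)

    def span_length(self, country: str) -> int:
        return self.spans.get(country, (0, 0, 0))[2]

    def population(self, country: str, year: int) -> float:
        pop = self.populations
        row = pop[(pop["country"] == country) & (pop["year"] == year)]
        if row.empty:
            raise KeyError(f"no population for ({country}, {year})")
        return float(row["population"].iloc[0])

    def with_spans(self, observations: pd.DataFrame) -> "RegionMap":
        """Record per-country data spans from an observation table."""
        self.spans = compute_spans(observations)
        return self


def compute_spans(observations: pd.DataFrame) -> dict[str, tuple[int, int, int]]:
    """First/last observed year and span length per country."""
    spans = {}
    if observations.empty:
        return spans
    for country, group in observations.groupby("country"):
        first = int(group["year"].min())
        last = int(group["year"].max())
        spans[str(country)] = (first, last, last - first + 1)
    return spans


def match_country(target: str, donor_set, pc_scores: PCScores) -> str | None:
    """Nearest-neighbour donor for a data-less country, in PC-score space.

    Returns the donor minimising Euclidean distance to the target; exact
    ties break to the lexicographically first identifier.  An empty donor
    set returns ``None`` (caller falls back to a zero region-mean effect)
    with a logged warning.
    """
    donors = sorted(str(d) for d in donor_set)
    if not donors:
        logger.warning("no within-region donors for %s; falling back to zero effect", target)
        return None
    target_score = pc_scores.scores[target]
    distances = np.array([np.linalg.norm(pc_scores.scores[d] - target_score) for d in donors])
    dmin = distances.min()
    tied = [d for d, dist in zip(donors, distances) if dist <= dmin + 1e-12 * max(dmin, 1.0)]
    return min(tied)


def covariate_change(country: str, panel_wide: pd.DataFrame, anchor_years) -> float:
    """Mean prepared-covariate change from the first to the last anchor year."""
    first, last = min(anchor_years), max(anchor_years)
    try:
        v_first = panel_wide.loc[(country, first)]
        v_last = panel_wide.loc[(country, last)]
    except KeyError as exc:
        raise KeyError(f"anchor-year covariates missing for {country}") from exc
    return float(np.mean(v_last.to_numpy() - v_first.to_numpy()))


def trend_scale_ratio(target: str, region_donors, panel_wide: pd.DataFrame,
                      anchor_years) -> float:
    """Ratio of the target's anchor-year covariate change to the regional mean.

    Clipped to [0, 2]; a regional mean change of (numerically) zero falls
    back to an unscaled trend with a warning.
    """
    target_change = covariate_change(target, panel_wide, anchor_years)
    donor_changes = [covariate_change(d, panel_wide, anchor_years) for d in region_donors]
    regional_mean = float(np.mean(donor_changes)) if donor_changes else 0.0
    if abs(regional_mean) < 1e-12:
        logger.warning(
            "regional mean covariate change is zero for %s; using unscaled trend", target
        )
        return 1.0
    return float(np.clip(target_change / regional_mean, 0.0, 2.0))


def borrow_trend(target: str, region_fit, panel_wide: pd.DataFrame | None = None,
                 anchor_years=(2000, 2010, 2020), region_donors=None,
                 span_length: int | None = None):
    """Temporal-trend evaluator for a data-sparse country.

    Countries with a data span of at least five years keep their own
    (regional) fitted trend unchanged; shorter or absent spans receive the
    regional trend rescaled by :func:`trend_scale_ratio`.  Returns
    ``(evaluator, scale)`` where ``evaluator(years)`` gives trend values.
    """
    region = region_fit.region_of[target] if target in region_fit.region_of else None
    if region is None:
        raise KeyError(f"country {target!r} has no region in the fit")
    if span_length is None:
        span_length = 0
    if span_length >= SHORT_SPAN_YEARS:
        scale = 1.0
    else:
        if panel_wide is None or region_donors is None:
            raise ConfigurationError("panel_wide and region_donors required for borrowing")
        scale = trend_scale_ratio(target, region_donors, panel_wide, anchor_years)

    def evaluator(years):
        return region_fit.trend_values(region, years) * scale

    return evaluator, scale


def assign_gap_fill(fit, region_map: RegionMap, pc_scores: PCScores,
                    panel_wide: pd.DataFrame, anchor_years=(2000, 2010, 2020)) -> pd.DataFrame:
    """Apply donor matching and trend borrowing to a fitted model in place.

    Donor pools contain same-region countries that have data spanning at
    least five years (avoiding chains of borrowed quantities).  Returns a
    matches table (target, donor, distance, ratio) mirroring the role of a
    matched-units supplementary record.
    """
    fitted = set(fit.countries)
    rows = []
    for country in region_map.countries:
        span = region_map.span_length(country)
        region = region_map.region_of(country)
        donors = [c for c in region_map.members(region)
                  if c in fitted and region_map.span_length(c) >= SHORT_SPAN_YEARS]
        if country not in fitted:
            donor = match_country(country, donors, pc_scores)
            if donor is None:
                fit.zero_effect_countries.add(country)
            else:
                fit.country_index[country] = fit.country_index[donor]
                fit.donor_of[country] = donor
            distance = (pc_scores.distance(country, donor) if donor is not None else np.nan)
        else:
            donor, distance = None, np.nan
        if span < SHORT_SPAN_YEARS:
            ratio = trend_scale_ratio(country, donors, panel_wide, anchor_years)
            fit.trend_scale[country] = ratio
        else:
            ratio = 1.0
        if country not in fitted or span < SHORT_SPAN_YEARS:
            rows.append({
                "target": country,
                "donor": donor if donor is not None else "",
                "distance": distance,
                "trend_scale": ratio,
                "span_years": span,
            })
    return pd.DataFrame(rows)


def write_matches(matches: pd.DataFrame, path) -> None:
    matches.to_csv(path, index=False)
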