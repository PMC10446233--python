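"""Collapse child-level survey responses to national treatment-seeking observations.

Two outcomes are produced per survey:

* ``any_medical`` — among febrile children, the weighted proportion taken to
  any source supplying legitimate medication (public sector, private/NGO
  facilities, pharmacies).  Friends, family and traditional or homeopathic
  healers do not count as medical treatment.
* ``public_fraction`` — among children taken for any medical treatment, the
  weighted proportion taken to public-sector points of care.

Confidence intervals use the Wilson score interval evaluated at the Kish
effective sample size ``n_eff = (Σw)² / Σw²``, which accounts for unequal
sampling weights without requiring cluster-level design information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _logit

from .errors import DegenerateDenominatorError

logger = logging.getLogger(__name__)

OUTCOMES = ("any_medical", "public_fraction")
MEDICAL_SOURCES = frozenset({"public", "other_medical"})
SOURCE_CLASSES = ("public", "other_medical", "non_medical")

#: normal quantile for 95% intervals
Z95 = 1.959963984540054


@dataclass(frozen=True)
class NationalObservation:
    """A country-year survey estimate of one outcome with its 95% CI."""

    country: str
    year: int
    outcome: str
    rate: float
    lo95: float
    hi95: float
    n_eff: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo95 <= self.rate <= self.hi95 <= 1.0):
            raise ValueError(
                f"CI ordering violated for {self.country} {self.year}: "
                f"{self.lo95} <= {self.rate} <= {self.hi95}"
            )
        if self.n_eff <= 0:
            raise ValueError("n_eff must be positive")


def weighted_proportion(flags, weights) -> tuple[float, float, float, float]:
    """Survey-weighted proportion with a Wilson 95% CI at the Kish effective n.

    Parameters
    ----------
    flags : array-like of bool
        Numerator membership per record.
    weights : array-like of float
        Positive sampling weights.

    Returns
    -------
    (rate, lo95, hi95, n_eff)
    """
    flags = np.asarray(flags, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if flags.size == 0 or weights.size == 0:
        raise DegenerateDenominatorError("no records supplied")
    if flags.shape != weights.shape:
        raise ValueError("flags and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    wsum = weights.sum()
    if wsum <= 0:
        raise DegenerateDenominatorError("all weights are zero")
    rate = float(min(max(np.dot(weights, flags) / wsum, 0.0), 1.0))
    n_eff = float(wsum**2 / np.dot(weights, weights))
    lo, hi = wilson_interval(rate, n_eff)
    return rate, lo, hi, n_eff


def wilson_interval(p: float, n: float, z: float = Z95) -> tuple[float, float]:
    """Wilson score interval for a proportion at (possibly fractional) n."""
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2.0 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z**2 / (4.0 * n**2)) / denom
    lo = min(max(0.0, centre - half), p)
    hi = max(min(1.0, centre + half), p)
    return float(lo), float(hi)


def aggregate_survey(responses: pd.DataFrame, outcome: str) -> NationalObservation | None:
    """Aggregate one survey's child-level rows to a national observation.

    ``responses`` must come from a single country-year and carry columns
    ``country, year, weight, fever, sought, source_class``.  Returns ``None``
    (with a logged warning) when the outcome's denominator is empty.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if responses.empty:
        logger.warning("empty survey table; skipping %s observation", outcome)
        return None
    countries = responses["country"].unique()
    years = responses["year"].unique()
    if len(countries) != 1 or len(years) != 1:
        raise ValueError("aggregate_survey expects rows from a single country-year")

    fever = responses["fever"].to_numpy(dtype=bool)
    sought = responses["sought"].fillna(False).to_numpy(dtype=bool)
    source = responses["source_class"]
    medical = sought & source.isin(MEDICAL_SOURCES).to_numpy()

    if outcome == "any_medical":
        denom_mask = fever
        flags = medical
    else:
        denom_mask = fever & medical
        flags = sought & (source == "public").to_numpy()

    weights = responses["weight"].to_numpy(dtype=float)
    if not denom_mask.any():
        logger.warning(
            "empty %s denominator for %s %s; observation skipped",
            outcome, countries[0], years[0],
        )
        return None
    rate, lo, hi, n_eff = weighted_proportion(flags[denom_mask], weights[denom_mask])
    return NationalObservation(str(countries[0]), int(years[0]), outcome, rate, lo, hi, n_eff)


def aggregate_surveys(surveys: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate a list of survey tables to a tidy observation table.

    Multiple surveys falling in the same country-year are pooled by
    precision-weighted averaging on the logit scale (effective sample sizes
    add; the CI is recomputed by Wilson at the pooled n).
    """
    rows: dict[tuple[str, int, str], list[NationalObservation]] = {}
    for survey in surveys:
        if survey.empty:
            continue
        for (country, year), group in survey.groupby(["country", "year"], sort=False):
            for outcome in OUTCOMES:
                obs = aggregate_survey(group, outcome)
                if obs is not None:
                    rows.setdefault((str(country), int(year), outcome), []).append(obs)
    records = []
    for (country, year, outcome), group_obs in rows.items():
        pooled = group_obs[0] if len(group_obs) == 1 else pool_observations(group_obs)
        records.append(pooled)
    frame = pd.DataFrame(
        [
            {
                "country": o.country,
                "year": o.year,
                "outcome": o.outcome,
                "rate": o.rate,
                "lo95": o.lo95,
                "hi95": o.hi95,
                "n_eff": o.n_eff,
            }
            for o in records
        ]
    )
    if not frame.empty:
        frame = frame.sort_values(["outcome", "country", "year"]).reset_index(drop=True)
    return frame


def pool_observations(group: list[NationalObservation]) -> NationalObservation:
    """Precision-weighted pooling of same country-year observations on the logit scale."""
    first = group[0]
    logits = np.array([empirical_logit(o.rate, o.n_eff) for o in group])
    precisions = np.array([1.0 / logit_variance(o.rate, o.n_eff) for o in group])
    pooled_logit = float(np.dot(precisions, logits) / precisions.sum())
    n_eff = float(sum(o.n_eff for o in group))
    rate = float(np.clip(inverse_empirical_logit(pooled_logit, n_eff), 0.0, 1.0))
    lo, hi = wilson_interval(rate, n_eff)
    return NationalObservation(first.country, first.year, first.outcome, rate, lo, hi, n_eff)


def empirical_logit(rate: float, n_eff: float) -> float:
    """Empirical logit with the (+0.5, +1) continuity correction.

    ``log(p*/(1-p*))`` with ``p* = (x + 0.5) / (n_eff + 1)`` and
    ``x = rate * n_eff``, so rates of exactly 0 or 1 stay finite.
    """
    x = rate * n_eff
    p_star = (x + 0.5) / (n_eff + 1.0)
    return float(_logit(p_star))

def inverse_empirical_logit(value: float, n_eff: float) -> float:
    """Invert :func:`empirical_logit` at the same effective sample size."""
    p_star = float(expit(value))
    x = p_star * (n_eff + 1.0) - 0.5
    return x / n_eff


def logit_variance(rate: float, n_eff: float) -> float:
    """Delta-method variance of the empirical logit, evaluated at the corrected rate."""
    p_star = (rate * n_eff + 0.5) / (n_eff + 1.0)
    return 1.0 / (n_eff * p_star * (1.0 - p_star))


def read_responses(path) -> pd.DataFrame:
    """Read a responses.csv written by the synthetic-data module."""
    frame = pd.read_csv(path)
    frame["fever"] = frame["fever"].astype(bool)
    frame["sought"] = frame["sought"].astype("boolean")
    return frame


def write_observations(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
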