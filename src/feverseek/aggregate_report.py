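"""Compose public treatment rates and population-weighted aggregates.

All composition and aggregation happens realisation by realisation so the
correlation induced by shared ensemble runs survives into the aggregate
intervals: the public treatment rate is the elementwise product of the
any-medical and public-fraction cubes, and regional/combined series are
population-weighted means of member-country realisations summarised only
at the end.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AlignmentError, BoundsError, WeightingError
from .gap_fill import RegionMap
from .uncertainty import RealisationCube, summarise_cube

logger = logging.getLogger(__name__)


def compose_public_rate(cube_any: RealisationCube,
                        cube_fraction: RealisationCube) -> RealisationCube:
    """Public treatment rate = any-medical rate × public fraction, per realisation."""
    if (cube_any.values.shape != cube_fraction.values.shape
            or cube_any.countries != cube_fraction.countries
            or not np.array_equal(cube_any.years, cube_fraction.years)):
        raise AlignmentError("cubes do not share dimensions and alignment")
    return RealisationCube(
        cube_any.values * cube_fraction.values,
        list(cube_any.countries),
        cube_any.years.copy(),
        "public_rate",
        {"composed_from": (cube_any.outcome, cube_fraction.outcome),
         **cube_any.provenance},
    )


def _population_matrix(region_map: RegionMap, countries, years) -> np.ndarray:
    pop = region_map.populations.pivot(index="country", columns="year", values="population")
    try:
        matrix = pop.loc[countries, years].to_numpy(dtype=float)
    except KeyError as exc:
        raise WeightingError(f"population weights missing: {exc}") from exc
    if np.isnan(matrix).any():
        raise WeightingError("population weights missing for some country-years")
    return matrix


def population_weighted(cube: RealisationCube, region_map: RegionMap,
                        grouping: str = "region", probs=(0.025, 0.975)) -> pd.DataFrame:
    """Population-weighted aggregate series with percentile intervals.

    ``grouping`` is ``"region"`` (one series per region), ``"combined"``
    (all countries pooled directly), or a single region identifier.
    Aggregation happens before summarisation, per realisation.
    """
    years = [int(y) for y in cube.years]
    pop = _population_matrix(region_map, cube.countries, years)

    if grouping == "region":
        groups = {r: region_map.members(r) for r in region_map.regions}
    elif grouping == "combined":
        groups = {"combined": list(cube.countries)}
    elif grouping in region_map.regions:
        groups = {grouping: region_map.members(grouping)}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    index_of = {c: i for i, c in enumerate(cube.countries)}
    for name, members in groups.items():
        idx = [index_of[c] for c in members if c in index_of]
        if not idx:
            continue
        weights = pop[idx]  # (members, years)
        totals = weights.sum(axis=0)
        if np.any(totals <= 0):
            raise WeightingError(f"zero total population in grouping {name!r}")
        # (members, years, realisations) weighted mean over members
        agg = np.einsum("my,myr->yr", weights, cube.values[idx]) / totals[:, None]
        rows.append(pd.DataFrame({
            "grouping": name,
            "year": cube.years,
            "outcome": cube.outcome,
            "point": agg.mean(axis=1),
            "lo95": np.quantile(agg, probs[0], axis=1),
            "hi95": np.quantile(agg, probs[1], axis=1),
            "n_members": len(idx),
        }))
    return pd.concat(rows, ignore_index=True)


def aggregate_realisations(cube: RealisationCube, region_map: RegionMap,
                           members) -> np.ndarray:
    """(years, realisations) population-weighted mean over the given countries."""
    years = [int(y) for y in cube.years]
    index_of = {c: i for i, c in enumerate(cube.countries)}
    idx = [index_of[c] for c in members]
    pop = _population_matrix(region_map, [cube.countries[i] for i in idx], years)
    totals = pop.sum(axis=0)
    if np.any(totals <= 0):
        raise WeightingError("zero total population")
    return np.einsum("my,myr->yr", pop, cube.values[idx]) / totals[:, None]


def absolute_change(cube: RealisationCube, year_a: int, year_b: int,
                    probs=(0.025, 0.975)) -> pd.DataFrame:
    """Per-country change point(year_b) − point(year_a) with a realisation CI."""
    for year in (year_a, year_b):
        if year not in cube.years:
            raise BoundsError(f"year {year} not present in the cube")
    ja = int(np.flatnonzero(cube.years == year_a)[0])
    jb = int(np.flatnonzero(cube.years == year_b)[0])
    diff = cube.values[:, jb, :] - cube.values[:, ja, :]  # (countries, realisations)
    return pd.DataFrame({
        "country": cube.countries,
        "outcome": cube.outcome,
        "year_a": year_a,
        "year_b": year_b,
        "change": diff.mean(axis=1),
        "lo95": np.quantile(diff, probs[0], axis=1),
        "hi95": np.quantile(diff, probs[1], axis=1),
    })


def threshold_counts(series: pd.DataFrame, year: int, threshold: float,
                     direction: str = "below") -> int:
    """Count countries whose point estimate at ``year`` is below/above a threshold."""
    at_year = series[series["year"] == year]
    if at_year.empty:
        raise BoundsError(f"year {year} not present in the series")
    points = at_year["point"]
    if direction == "below":
        return int((points < threshold).sum())
    if direction == "above":
        return int((points > threshold).sum())
    raise ValueError(f"unknown direction {direction!r}")


def country_estimates(cubes: dict[str, RealisationCube]) -> pd.DataFrame:
    """Country-year point estimates and CIs for every outcome (tidy)."""
    return pd.concat(
        [summarise_cube(cube) for cube in cubes.values()], ignore_index=True
    )


def regional_estimates(cubes: dict[str, RealisationCube], region_map: RegionMap,
                       years=None) -> pd.DataFrame:
    """Regional plus combined population-weighted series for every outcome."""
    pieces = []
    for cube in cubes.values():
        pieces.append(population_weighted(cube, region_map, "region"))
        pieces.append(population_weighted(cube, region_map, "combined"))
    frame = pd.concat(pieces, ignore_index=True)
    if years is not None:
        frame = frame[frame["year"].isin(list(years))].reset_index(drop=True)
    return frame


def write_reports(out_dir, cubes: dict[str, RealisationCube], region_map: RegionMap,
                  change_years: tuple[int, int] | None = None) -> None:
    """Write country_estimates.csv, regional_estimates.csv and changes.csv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    country_estimates(cubes).to_csv(out / "country_estimates.csv", index=False)
    regional_estimates(cubes, region_map).to_csv(out / "regional_estimates.csv", index=False)
    if change_years is not None:
        changes = pd.concat(
            [absolute_change(cube, *change_years) for cube in cubes.values()],
            ignore_index=True,
        )
        changes.to_csv(out / "changes.csv", index=False)
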