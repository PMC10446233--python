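"""Covariate transformation, standardisation, selection, and PCA scores.

Covariates enter the treatment-seeking models as smooth terms on a
standardised scale.  The preparation pipeline is:

1. choose a normalising transform per covariate (none / log / square) by
   profiling the Box-Cox likelihood over a λ grid and snapping λ̂ to the
   nearest canonical value;
2. z-score each transformed covariate, remembering the fitting-set mean/sd
   so prediction-set values are mapped identically;
3. (for donor matching) compute principal-component scores of the prepared
   covariates at a set of anchor years.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateScaleError, RankError

logger = logging.getLogger(__name__)

TRANSFORMS = ("none", "log", "square")
DEFAULT_ANCHOR_YEARS = (2000, 2010, 2020)


def choose_transform(values, grid: np.ndarray | None = None) -> str:
    """Pick a normalising transform by Box-Cox profile likelihood.

    λ̂ is the grid maximiser of the Box-Cox log-likelihood; it maps to
    ``log`` when λ̂ < 0.5, ``none`` when 0.5 ≤ λ̂ < 1.5 and ``square`` when
    λ̂ ≥ 1.5.  Non-positive data cannot enter the Box-Cox likelihood; the
    transform falls back to ``none`` with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10 or np.any(values <= 0):
        if np.any(values <= 0):
            logger.warning("non-positive values; falling back to 'none' transform")
        return "none"
    if np.ptp(values) == 0:
        return "none"
    if grid is None:
        grid = np.linspace(-2.0, 3.0, 101)
    llf = np.array([stats.boxcox_llf(lam, values) for lam in grid])
    lam_hat = float(grid[int(np.argmax(llf))])
    if lam_hat < 0.5:
        return "log"
    if lam_hat < 1.5:
        return "none"
    return "square"


def apply_transform(values, transform: str):
    values = np.asarray(values, dtype=float)
    if transform == "none":
        return values
    if transform == "log":
        if np.any(values <= 0):
            logger.warning("non-positive values under 'log'; falling back to 'none'")
            return values
        return np.log(values)
    if transform == "square":
        return np.square(values)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class CovariatePanel:
    """Country-year covariate values with 95% CIs and preparation state.

    ``data`` is a tidy frame with columns ``country, year, covariate, value,
    lo95, hi95`` on the raw scale.  ``transforms`` and ``standardisation``
    hold the fitted preparation state and are reapplied unchanged to new
    (e.g. perturbed) values.
    """

    data: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)
    standardisation: dict[str, tuple[float, float]] = field(default_factory=dict)
    ddof: int = 1

    def __post_init__(self) -> None:
        required = {"country", "year", "covariate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"covariate panel missing columns: {sorted(missing)}")
        for bound in ("lo95", "hi95"):
            if bound not in self.data.columns:
                # zero-width intervals degrade the uncertainty ensemble gracefully
                self.data[bound] = self.data["value"]
        bad = self.data["lo95"] > self.data["hi95"]
        if bad.any():
            raise ValueError("lo95 > hi95 in covariate panel")

    @property
    def covariates(self) -> list[str]:
        return sorted(self.data["covariate"].unique())

    def fit_transforms(self) -> "CovariatePanel":
        """Choose and record a Box-Cox-guided transform per covariate."""
        for name, group in self.data.groupby("covariate"):
            self.transforms[str(name)] = choose_transform(group["value"].to_numpy())
        return self

    def fit_standardisation(self) -> "CovariatePanel":
        """Record mean/sd of each transformed covariate over the fitting set."""
        if not self.transforms:
            self.fit_transforms()
        for name, group in self.data.groupby("covariate"):
            transformed = apply_transform(group["value"].to_numpy(), self.transforms[str(name)])
            mean = float(np.mean(transformed))
            sd = float(np.std(transformed, ddof=self.ddof))
            if not np.isfinite(sd) or sd <= 1e-12:
                raise DegenerateScaleError(f"covariate {name!r} is constant after transform")
            self.standardisation[str(name)] = (mean, sd)
        return self

    def prepare(self) -> "CovariatePanel":
        """Fit transforms then standardisation (idempotent on refitted panels)."""
        return self.fit_transforms().fit_standardisation()

    def prepared_values(self, covariate: str, values=None) -> np.ndarray:
        """Transform + standardise raw values using the stored state."""
        if covariate not in self.standardisation:
            raise KeyError(f"covariate {covariate!r} has no standardisation state")
        if values is None:
            values = self.data.loc[self.data["covariate"] == covariate, "value"].to_numpy()
        mean, sd = self.standardisation[covariate]
        return (apply_transform(values, self.transforms[covariate]) - mean) / sd

    def wide(self, covariates: list[str] | None = None) -> pd.DataFrame:
        """Prepared values as a (country, year)-indexed wide frame."""
        names = covariates if covariates is not None else self.covariates
        pieces = {}
        for name in names:
            sub = self.data[self.data["covariate"] == name]
            series = pd.Series(
                self.prepared_values(name, sub["value"].to_numpy()),
                index=pd.MultiIndex.from_arrays([sub["country"], sub["year"]]),
                name=name,
            )
            pieces[name] = series
        frame = pd.DataFrame(pieces)
        frame.index.names = ["country", "year"]
        return frame

    def with_values(self, values: np.ndarray) -> "CovariatePanel":
        """A copy carrying new raw values but the same frozen preparation state."""
        data = self.data.copy()
        data["value"] = values
        out = CovariatePanel(data, dict(self.transforms), dict(self.standardisation), self.ddof)
        return out

    def copy(self) -> "CovariatePanel":
        return CovariatePanel(
            self.data.copy(), dict(self.transforms), dict(self.standardisation), self.ddof
        )


def standardise(panel: CovariatePanel) -> CovariatePanel:
    """Fit (or refit) transform + standardisation state on the panel in place."""
    return panel.prepare()


@dataclass
class PCScores:
    """Per-country principal-component scores at the anchor years."""

    scores: dict[str, np.ndarray]
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    anchor_years: tuple[int, ...]
    feature_names: list[str]

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.scores[a] - self.scores[b]))


def principal_components(
    panel: CovariatePanel,
    anchor_years=DEFAULT_ANCHOR_YEARS,
    n_components: int | None = None,
    var_threshold: float = 0.9,
    covariates: list[str] | None = None,
) -> PCScores:
    """PCA of the country × (covariate × anchor-year) prepared-value matrix.

    Components are retained up to ``var_threshold`` cumulative explained
    variance (or exactly ``n_components`` when given).  The sign of each
    component is fixed by making its largest-magnitude loading positive, so
    scores are deterministic and order-invariant.
    """
    names = covariates if covariates is not None else panel.covariates
    wide = panel.wide(names).reset_index()
    wide = wide[wide["year"].isin(anchor_years)]
    matrix = wide.pivot_table(index="country", columns="year", values=names, sort=True)
    countries = [str(c) for c in matrix.index]
    feature_names = [f"{cov}@{year}" for cov, year in matrix.columns]
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        logger.warning("missing anchor-year covariate values mean-imputed for PCA")
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means, X)
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size and S[0] > 0 else 0
    if n_components is not None:
        if n_components > rank:
            raise RankError(f"requested {n_components} components but rank is {rank}")
        k = n_components
    else:
        var = S**2
        ratio = var / var.sum() if var.sum() > 0 else var
        cum = np.cumsum(ratio)
        k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
        k = min(k, max(rank, 1))
    # deterministic sign: largest-magnitude loading of each component positive
    signs = np.ones(k)
    for j in range(k):
        lead = Vt[j, int(np.argmax(np.abs(Vt[j])))]
        if lead < 0:
            signs[j] = -1.0
    scores_matrix = (U[:, :k] * S[:k]) * signs
    loadings = Vt[:k] * signs[:, None]
    total = (S**2).sum()
    ratio = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCScores(
        scores={c: scores_matrix[i].copy() for i, c in enumerate(countries)},
        loadings=loadings,
        explained_variance_ratio=ratio,
        anchor_years=tuple(int(y) for y in anchor_years),
        feature_names=feature_names,
    )


def select_covariates(
    observations: pd.DataFrame,
    panel: CovariatePanel,
    model_template,
    candidates: list[str] | None = None,
    max_size: int = 5,
    p_threshold: float = 0.05,
):
    """Exhaustive AIC subset selection with a per-term p-value screen.

    Every candidate subset up to ``max_size`` is fitted with the supplied
    model template — a callable ``template(observations, panel, subset)``
    returning a fitted model exposing ``aic`` and ``covariate_p_values()``
    (the pipeline supplies one wrapping the full mixed-model fit).  Subsets
    whose every covariate smooth has an approximate Wald p-value below
    ``p_threshold`` compete on AIC against the empty model; the AIC
    minimiser wins.  Returns ``(selected, table)`` where ``table`` records
    AIC and screening outcomes per subset.
    """
    if candidates is None:
        candidates = panel.covariates
    if len(candidates) > 12:
        raise ValueError("exhaustive search over >12 candidates is not supported")

    def fit_subset(subset):
        return model_template(observations, panel, list(subset))

    results = []
    best_aic = np.inf
    best_subset: tuple[str, ...] = ()
    empty_fit = fit_subset(())
    results.append({"subset": (), "aic": empty_fit.aic, "passes_screen": True, "p_values": {}})
    best_aic = empty_fit.aic
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(candidates, size):
            try:
                fit = fit_subset(subset)
            except Exception as exc:  # singular subsets are simply not selectable
                logger.warning("subset %s failed to fit: %s", subset, exc)
                continue
            p_values = fit.covariate_p_values()
            passes = all(p_values.get(name, 1.0) < p_threshold for name in subset)
            results.append(
                {"subset": subset, "aic": fit.aic, "passes_screen": passes, "p_values": p_values}
            )
            if passes and fit.aic < best_aic:
                best_aic = fit.aic
                best_subset = subset
    if not best_subset:
        logger.warning("no covariate subset passed the p-value screen; selecting none")
    table = pd.DataFrame(
        [
            {
                "subset": "+".join(r["subset"]) or "(empty)",
                "aic": r["aic"],
                "passes_screen": r["passes_screen"],
            }
            for r in results
        ]
    )
    return list(best_subset), table


def read_covariates(path) -> CovariatePanel:
    """Read a covariates.csv (country, year, covariate|name, value, lo95, hi95)."""
    frame = pd.read_csv(path)
    if "name" in frame.columns and "covariate" not in frame.columns:
        frame = frame.rename(columns={"name": "covariate"})
    return CovariatePanel(frame)


def write_prepared(panel: CovariatePanel, csv_path, yaml_path=None) -> None:
    """Write prepared values plus a transforms audit record."""
    import yaml

    rows = []
    for name in panel.covariates:
        sub = panel.data[panel.data["covariate"] == name]
        prepared = panel.prepared_values(name, sub["value"].to_numpy())
        out = sub[["country", "year", "covariate", "value"]].copy()
        out["prepared"] = prepared
        rows.append(out)
    pd.concat(rows).to_csv(csv_path, index=False)
    if yaml_path is not None:
        audit = {
            name: {
                "transform": panel.transforms[name],
                "mean": panel.standardisation[name][0],
                "sd": panel.standardisation[name][1],
            }
            for name in panel.covariates
        }
        with open(yaml_path, "w") as handle:
            yaml.safe_dump(audit, handle)
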