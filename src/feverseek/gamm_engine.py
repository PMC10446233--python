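"""Logit-scale additive mixed model for national treatment-seeking rates.

The model for an observed national rate or fraction Y in country c,
region r, year t is

    logit(Y) = beta_region(r) + s_region(t) + b_country(c) + sum_k s_k(x_k) + eps

with region-specific intercepts and smooth temporal trends, a country
random effect b ~ N(0, tau^2), shared smooth covariate effects, and
Gaussian error on the logit scale.  Smooths are penalized B-splines;
random effects are represented as a ridge-penalized coefficient block, so
the whole model is one weighted penalized least-squares problem.  Smoothing
parameters (and hence tau^2 = sigma^2 / lambda_country) are chosen by
restricted maximum likelihood via a grid search refined with Nelder-Mead.

Observation weights default to inverse delta-method variances of the
empirical-logit values, so precise surveys pull harder on the fit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2

from . import survey_prep
from .errors import (
    BasisError,
    ConfigurationError,
    ConvergenceError,
    IdentifiabilityError,
    MissingEffectError,
)

logger = logging.getLogger(__name__)

#: linear predictors are clipped here before inverse-logit, keeping
#: predicted rates strictly inside (3e-7, 1 - 3e-7)
LINEAR_PREDICTOR_CLIP = 15.0


# ---------------------------------------------------------------------------
# spline basis


@dataclass
class SplineBasis:
    """A constrained penalized B-spline basis over one input variable.

    The raw basis has ``max_basis_dim`` B-spline columns; a sum-to-zero
    constraint over the fitting inputs is absorbed by reparameterisation
    (``constraint`` maps the ``max_basis_dim - 1`` free coefficients back to
    raw B-spline coefficients), so constrained columns are orthogonal to the
    intercept.  The penalty combines the second-order difference penalty
    with a shrinkage penalty on its null space, making the block penalty
    full rank: a large smoothing parameter annihilates the whole term
    rather than leaving an unpenalized linear component behind.
    """

    knots: np.ndarray
    degree: int
    max_basis_dim: int
    constraint: np.ndarray  # (m, m-1) null-space transform of the constraint
    penalty: np.ndarray  # (m-1, m-1) constrained penalty, full rank
    x_min: float
    x_max: float

    @property
    def n_columns(self) -> int:
        return self.constraint.shape[1]

    def raw_matrix(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return BSpline.design_matrix(x, self.knots, self.degree, extrapolate=True).toarray()

    def matrix(self, x) -> np.ndarray:
        """Constrained basis matrix at new inputs."""
        return self.raw_matrix(x) @ self.constraint


def build_spline_basis(inputs, max_basis_dim: int) -> SplineBasis:
    """Build a constrained cubic B-spline basis with evenly spaced knots.

    The spline degree is ``min(3, max_basis_dim - 1)`` — a cubic basis needs
    at least four columns, so a dimension-3 block is quadratic.  Requires at
    least ``max_basis_dim`` distinct input values.
    """
    x = np.asarray(inputs, dtype=float)
    distinct = np.unique(x)
    if max_basis_dim < 2:
        raise BasisError("max_basis_dim must be at least 2")
    if distinct.size < max_basis_dim:
        raise BasisError(
            f"need at least {max_basis_dim} distinct inputs, got {distinct.size}"
        )
    degree = min(3, max_basis_dim - 1)
    n_interior = max_basis_dim - degree - 1
    lo, hi = float(distinct[0]), float(distinct[-1])
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])

    raw = BSpline.design_matrix(x, knots, degree).toarray()
    m = raw.shape[1]
    assert m == max_basis_dim

    # sum-to-zero constraint over fitting inputs, absorbed via QR null space
    c = raw.sum(axis=0)
    q, _ = np.linalg.qr(c[:, None], mode="complete")
    Z = q[:, 1:]

    order = min(2, m - 1)
    D = np.diff(np.eye(m), n=order, axis=0)
    S = Z.T @ (D.T @ D) @ Z
    # shrink the difference-penalty null space with unit weight -> full rank
    eigval, eigvec = np.linalg.eigh(S)
    tol = max(eigval.max(), 1.0) * 1e-10
    null_vecs = eigvec[:, eigval < tol]
    if null_vecs.size:
        S = S + null_vecs @ null_vecs.T
    return SplineBasis(knots, degree, max_basis_dim, Z, S, lo, hi)


# ---------------------------------------------------------------------------
# configuration and fitted-model containers


@dataclass(frozen=True)
class FitConfig:
    """Tunable choices for one outcome's model fit."""

    outcome: str = "any_medical"
    covariates: tuple[str, ...] = ()
    trend_basis_dim: int = 5
    cov_basis_dim: int = 3
    include_country: bool = True
    weighted: bool = True
    per_block_smoothing: bool = False
    fixed_smoothing: dict | None = None  # group (or block) name -> lambda
    log_lambda_grid: tuple[float, ...] = (-2.0, 1.0, 4.0, 7.0)
    refine: bool = True
    clip: float = LINEAR_PREDICTOR_CLIP

    def replace(self, **kw) -> "FitConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class DesignBlock:
    name: str
    kind: str  # region_intercept | country | trend | covariate
    start: int
    size: int
    penalty: np.ndarray | None = None
    basis: SplineBasis | None = None
    region: str | None = None
    covariate: str | None = None
    group: str = "fixed"
    rank: int = 0
    logdet_pos: float = 0.0

    @property
    def sl(self) -> slice:
        return slice(self.start, self.start + self.size)


@dataclass
class GAMMFit:
    """A fitted additive mixed model plus everything prediction needs."""

    coefficients: np.ndarray
    coef_covariance: np.ndarray
    blocks: list[DesignBlock]
    smoothing_params: dict[str, float]  # block name -> lambda
    residual_variance: float
    reml_score: float
    edf: float
    n_obs: int
    rss_weighted: float
    config: FitConfig
    regions: list[str]
    countries: list[str]
    region_of: dict[str, str]
    country_index: dict[str, int]  # country -> coefficient column (donors share)
    region_index: dict[str, int]
    trend_scale: dict[str, float] = field(default_factory=dict)
    tail_fix: dict[str, tuple[int, tuple[int, ...]]] = field(default_factory=dict)
    donor_of: dict[str, str] = field(default_factory=dict)
    zero_effect_countries: set[str] = field(default_factory=set)
    reml_trace: list = field(default_factory=list)
    sum_log_weights: float = 0.0

    # -- derived views ------------------------------------------------------

    @property
    def region_intercepts(self) -> dict[str, float]:
        block = self._block("region_intercept")
        return {r: float(self.coefficients[block.start + i]) for r, i in
                sorted(self.region_index.items(), key=lambda kv: kv[1])}

    @property
    def country_effects(self) -> dict[str, float]:
        return {c: float(self.coefficients[idx]) for c, idx in self.country_index.items()
                if c in self.countries}

    @property
    def country_effect_sd(self) -> float:
        """REML estimate of the country random-effect standard deviation."""
        lam = self.smoothing_params.get("country")
        if lam is None:
            return 0.0
        return float(np.sqrt(self.residual_variance / lam))

    @property
    def aic(self) -> float:
        """Conditional AIC: Gaussian -2 log-likelihood plus 2 * (edf + 1)."""
        n = self.n_obs
        sigma2_ml = max(self.rss_weighted / n, 1e-300)
        m2ll = n * np.log(2 * np.pi * sigma2_ml) + n - self.sum_log_weights
        return float(m2ll + 2.0 * (self.edf + 1.0))

    def _block(self, kind: str, **match) -> DesignBlock:
        for block in self.blocks:
            if block.kind == kind and all(getattr(block, k) == v for k, v in match.items()):
                return block
        raise KeyError(f"no {kind} block matching {match}")

    def trend_block(self, region: str) -> DesignBlock:
        return self._block("trend", region=region)

    def covariate_blocks(self) -> list[DesignBlock]:
        return [b for b in self.blocks if b.kind == "covariate"]

    def covariate_p_values(self) -> dict[str, float]:
        """Approximate Wald p-value per covariate smooth term."""
        out = {}
        for block in self.covariate_blocks():
            beta = self.coefficients[block.sl]
            V = self.coef_covariance[block.sl, block.sl]
            try:
                stat = float(beta @ np.linalg.solve(V, beta))
            except np.linalg.LinAlgError:
                stat = float(beta @ np.linalg.pinv(V) @ beta)
            out[block.covariate] = float(chi2.sf(max(stat, 0.0), df=block.size))
        return out

    # -- trend evaluation (with tail fixing and per-country scaling) --------

    def trend_values(self, region: str, years, country: str | None = None) -> np.ndarray:
        """Evaluate the regional temporal trend at the given years."""
        block = self.trend_block(region)
        rows = self._trend_rows(block, np.asarray(years, dtype=float))
        values = rows @ self.coefficients[block.sl]
        scale = self.trend_scale.get(country, 1.0) if country is not None else 1.0
        return values * scale

    def _trend_rows(self, block: DesignBlock, years: np.ndarray) -> np.ndarray:
        basis = block.basis
        fix = self.tail_fix.get(block.region)
        if fix is None:
            return basis.matrix(years)
        first_year, window = fix
        eff = years.copy()
        eff[eff < first_year] = float(first_year)
        rows = basis.matrix(eff)
        in_window = np.isin(years, np.asarray(window, dtype=float))
        if in_window.any():
            window_mean = basis.matrix(np.asarray(window, dtype=float)).mean(axis=0)
            rows[in_window] = window_mean
        return rows


# ---------------------------------------------------------------------------
# design assembly


def _region_lookup(region_map) -> dict[str, str]:
    if hasattr(region_map, "country_region"):
        return dict(region_map.country_region)
    return dict(region_map)


def _panel_wide(panel, covariates) -> pd.DataFrame | None:
    if not covariates:
        return None
    if panel is None:
        raise ConfigurationError("covariates requested but no panel supplied")
    if isinstance(panel, pd.DataFrame):
        return panel
    return panel.wide(list(covariates))


def _covariate_values(wide: pd.DataFrame, frame: pd.DataFrame, name: str) -> np.ndarray:
    idx = pd.MultiIndex.from_arrays([frame["country"], frame["year"]])
    values = wide[name].reindex(idx).to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = frame.loc[np.isnan(values), ["country", "year"]].iloc[0]
        raise MissingEffectError(
            f"covariate {name!r} unavailable at ({bad['country']}, {bad['year']})"
        )
    return values


def _build_blocks(obs: pd.DataFrame, wide, region_of, config: FitConfig):
    """Declare design blocks and return (blocks, X) for the fitting rows."""
    regions = sorted({region_of[c] for c in obs["country"]})
    countries = sorted(obs["country"].unique())
    obs_regions = obs["country"].map(region_of)

    blocks: list[DesignBlock] = []
    columns: list[np.ndarray] = []
    start = 0
    n = len(obs)

    X_region = np.zeros((n, len(regions)))
    for i, region in enumerate(regions):
        X_region[:, i] = (obs_regions == region).to_numpy(dtype=float)
    blocks.append(DesignBlock("region_intercept", "region_intercept", start, len(regions)))
    columns.append(X_region)
    start += len(regions)

    if config.include_country:
        X_country = np.zeros((n, len(countries)))
        for i, country in enumerate(countries):
            X_country[:, i] = (obs["country"] == country).to_numpy(dtype=float)
        block = DesignBlock(
            "country", "country", start, len(countries),
            penalty=np.eye(len(countries)), group="country",
            rank=len(countries), logdet_pos=0.0,
        )
        blocks.append(block)
        columns.append(X_country)
        start += len(countries)

    years = obs["year"].to_numpy(dtype=float)
    for region in regions:
        mask = (obs_regions == region).to_numpy()
        region_years = years[mask]
        dim = min(config.trend_basis_dim, np.unique(region_years).size)
        if dim < 2:
            logger.warning("region %s has <2 distinct years; trend omitted", region)
            continue
        basis = build_spline_basis(region_years, dim)
        X_trend = np.zeros((n, basis.n_columns))
        X_trend[mask] = basis.matrix(region_years)
        group = f"trend:{region}" if config.per_block_smoothing else "trend"
        block = DesignBlock(
            f"trend:{region}", "trend", start, basis.n_columns,
            penalty=basis.penalty, basis=basis, region=region, group=group,
        )
        _finish_penalty(block)
        blocks.append(block)
        columns.append(X_trend)
        start += basis.n_columns

    for name in config.covariates:
        idx = pd.MultiIndex.from_arrays([obs["country"], obs["year"]])
        values = wide[name].reindex(idx).to_numpy(dtype=float)
        if np.isnan(values).any():
            raise MissingEffectError(f"covariate {name!r} missing at fitting rows")
        basis = build_spline_basis(values, config.cov_basis_dim)
        group = f"cov:{name}" if config.per_block_smoothing else "cov"
        block = DesignBlock(
            f"cov:{name}", "covariate", start, basis.n_columns,
            penalty=basis.penalty, basis=basis, covariate=name, group=group,
        )
        _finish_penalty(block)
        blocks.append(block)
        columns.append(basis.matrix(values))
        start += basis.n_columns

    X = np.hstack(columns)
    return blocks, X, regions, countries


def _finish_penalty(block: DesignBlock) -> None:
    eigval = np.linalg.eigvalsh(block.penalty)
    positive = eigval[eigval > max(eigval.max(), 1.0) * 1e-12]
    block.rank = int(positive.size)
    block.logdet_pos = float(np.log(positive).sum())


# ---------------------------------------------------------------------------
# REML machinery


def _assemble_penalty(blocks, lam_of_group, p) -> tuple[np.ndarray, float, int]:
    """Total penalty matrix, log|S|_+ and total penalized rank."""
    S = np.zeros((p, p))
    logdet = 0.0
    rank = 0
    for block in blocks:
        if block.penalty is None:
            continue
        lam = lam_of_group[block.group]
        S[block.sl, block.sl] += lam * block.penalty
        logdet += block.rank * np.log(lam) + block.logdet_pos
        rank += block.rank
    return S, logdet, rank


def _reml_score(log_lams, groups, cache):
    lam_of_group = {g: float(np.exp(v)) for g, v in zip(groups, log_lams)}
    S, logdet_S, rank = _assemble_penalty(cache["blocks"], lam_of_group, cache["p"])
    A = cache["XtWX"] + S
    try:
        factor = cho_factor(A, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = cho_solve(factor, cache["XtWy"], check_finite=False)
    D = float(cache["yWy"] - beta @ cache["XtWy"])
    D = max(D, 1e-12)
    n = cache["n"]
    p_f = cache["p"] - rank
    dof = n - p_f
    if dof <= 0:
        return np.inf, None
    sigma2 = D / dof
    logdet_A = 2.0 * float(np.log(np.diag(factor[0])).sum())
    score = 0.5 * (
        dof * (np.log(2 * np.pi * sigma2) + 1.0)
        - cache["sum_log_w"]
        + logdet_A
        - logdet_S
    )
    return float(score), (beta, factor, sigma2, D, lam_of_group, p_f)


def fit_gamm(observations: pd.DataFrame, panel, region_map, config: FitConfig) -> GAMMFit:
    """Fit the logit-scale additive mixed model by penalized weighted least squares.

    Parameters
    ----------
    observations : DataFrame
        National observations (columns country, year, rate, n_eff; an
        ``outcome`` column, when present, is filtered to ``config.outcome``).
    panel : CovariatePanel or prepared wide DataFrame or None
        Source of prepared covariate values for the smooth terms.
    region_map : RegionMap or mapping country -> region
    config : FitConfig
    """
    obs = observations
    if "outcome" in obs.columns:
        obs = obs[obs["outcome"] == config.outcome]
    obs = obs.reset_index(drop=True)
    if obs.empty:
        raise ConfigurationError(f"no observations for outcome {config.outcome!r}")
    region_of = _region_lookup(region_map)
    unmapped = set(obs["country"]) - set(region_of)
    if unmapped:
        raise ConfigurationError(f"countries without region assignment: {sorted(unmapped)}")

    y = np.array([
        survey_prep.empirical_logit(r, n) for r, n in zip(obs["rate"], obs["n_eff"])
    ])
    if config.weighted:
        w = np.array([
            1.0 / survey_prep.logit_variance(r, n) for r, n in zip(obs["rate"], obs["n_eff"])
        ])
    else:
        w = np.ones(len(obs))

    wide = _panel_wide(panel, config.covariates)
    blocks, X, regions, countries = _build_blocks(obs, wide, region_of, config)
    n, p = X.shape

    Xw = X * np.sqrt(w)[:, None]
    cache = {
        "blocks": blocks,
        "XtWX": Xw.T @ Xw,
        "XtWy": X.T @ (w * y),
        "yWy": float(w @ (y * y)),
        "sum_log_w": float(np.log(w).sum()),
        "n": n,
        "p": p,
    }

    groups = sorted({b.group for b in blocks if b.penalty is not None})
    trace: list[tuple[dict, float]] = []

    if not groups:
        lam_star: dict[str, float] = {}
    elif config.fixed_smoothing is not None:
        lam_star = {g: _lookup_fixed(config.fixed_smoothing, g, blocks) for g in groups}
    else:
        lam_star = _optimise_smoothing(groups, cache, config, trace)

    log_lams = [np.log(lam_star[g]) for g in groups]
    score, solution = _reml_score(log_lams, groups, cache)
    if solution is None:
        raise IdentifiabilityError(
            "singular penalized design; confounded blocks: "
            + ", ".join(b.name for b in blocks)
        )
    beta, factor, sigma2, D, lam_of_group, p_f = solution
    cov = cho_solve(factor, np.eye(p), check_finite=False) * sigma2
    cov = 0.5 * (cov + cov.T)
    edf = float(np.trace(cho_solve(factor, cache["XtWX"], check_finite=False)))
    resid = y - X @ beta
    rss_w = float(w @ (resid * resid))

    fit = GAMMFit(
        coefficients=beta,
        coef_covariance=cov,
        blocks=blocks,
        smoothing_params={b.name: lam_of_group[b.group] for b in blocks if b.penalty is not None},
        residual_variance=float(sigma2),
        reml_score=float(score),
        edf=edf,
        n_obs=n,
        rss_weighted=rss_w,
        config=config,
        regions=regions,
        countries=countries,
        region_of=region_of,
        country_index=_country_columns(blocks, countries),
        region_index={r: i for i, r in enumerate(regions)},
        reml_trace=trace,
        sum_log_weights=cache["sum_log_w"],
    )
    return fit


def _country_columns(blocks, countries) -> dict[str, int]:
    for block in blocks:
        if block.kind == "country":
            return {c: block.start + i for i, c in enumerate(countries)}
    return {}


def _lookup_fixed(fixed: dict, group: str, blocks) -> float:
    if group in fixed:
        return float(fixed[group])
    for block in blocks:
        if block.group == group and block.name in fixed:
            return float(fixed[block.name])
    raise ConfigurationError(f"fixed_smoothing missing a value for group {group!r}")


def _optimise_smoothing(groups, cache, config: FitConfig, trace) -> dict[str, float]:
    """Grid search over log-lambda followed by Nelder-Mead refinement."""
    grid = np.asarray(config.log_lambda_grid, dtype=float)
    best_score = np.inf
    best_point = np.full(len(groups), grid[len(grid) // 2])
    mesh = np.meshgrid(*[grid] * len(groups), indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    for point in points:
        score, _ = _reml_score(point, groups, cache)
        trace.append(({g: float(np.exp(v)) for g, v in zip(groups, point)}, score))
        if score < best_score:
            best_score = score
            best_point = point.copy()
    if not np.isfinite(best_score):
        raise ConvergenceError("REML score non-finite at every grid candidate")
    if config.refine:
        result = optimize.minimize(
            lambda v: _reml_score(v, groups, cache)[0],
            best_point,
            method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 1e-4, "maxfev": 80 * len(groups)},
        )
        if np.isfinite(result.fun) and result.fun <= best_score:
            best_point = result.x
            best_score = float(result.fun)
    return {g: float(np.exp(v)) for g, v in zip(groups, best_point)}


# ---------------------------------------------------------------------------
# prediction


def build_prediction_matrix(fit: GAMMFit, frame: pd.DataFrame, panel=None) -> np.ndarray:
    """Design matrix for arbitrary (country, year) rows under a fitted model.

    Applies tail-trend fixing, per-country trend scaling, and the donor
    country-effect mapping.  Covariate smooth inputs are clipped to the
    fitted basis range.
    """
    p = fit.coefficients.size
    n = len(frame)
    X = np.zeros((n, p))
    region_block = fit._block("region_intercept")
    countries = frame["country"].to_numpy()
    years = frame["year"].to_numpy(dtype=float)

    for i, country in enumerate(countries):
        region = fit.region_of.get(country)
        if region is None:
            raise MissingEffectError(f"country {country!r} has no region assignment")
        if region not in fit.region_index:
            raise MissingEffectError(f"region {region!r} was not fitted")
        X[i, region_block.start + fit.region_index[region]] = 1.0
        col = fit.country_index.get(country)
        if col is not None:
            X[i, col] = 1.0
        elif country not in fit.zero_effect_countries:
            raise MissingEffectError(
                f"country {country!r} has neither a fitted nor a donor effect"
            )

    for block in fit.blocks:
        if block.kind == "trend":
            mask = np.array([fit.region_of[c] == block.region for c in countries])
            if not mask.any():
                continue
            rows = fit._trend_rows(block, years[mask])
            scales = np.array([fit.trend_scale.get(c, 1.0) for c in countries[mask]])
            X[np.flatnonzero(mask), block.sl] = rows * scales[:, None]
        elif block.kind == "covariate":
            wide = _panel_wide(panel, [block.covariate])
            values = _covariate_values(wide, frame, block.covariate)
            values = np.clip(values, block.basis.x_min, block.basis.x_max)
            X[:, block.sl] = block.basis.matrix(values)
    return X


def predict_frame(fit: GAMMFit, frame: pd.DataFrame, panel=None,
                  coefficients: np.ndarray | None = None) -> np.ndarray:
    """Predicted rates for the rows of ``frame``.

    ``coefficients`` may be the fitted vector (default), or a (p, k) matrix
    of coefficient draws, in which case an (n, k) array is returned.
    """
    X = build_prediction_matrix(fit, frame, panel)
    coef = fit.coefficients if coefficients is None else coefficients
    eta = np.clip(X @ coef, -fit.config.clip, fit.config.clip)
    return expit(eta)


def predict_rate(fit: GAMMFit, country: str, year: int, panel=None) -> float:
    """Predicted rate for one country-year, strictly inside (0, 1)."""
    frame = pd.DataFrame({"country": [country], "year": [year]})
    return float(predict_frame(fit, frame, panel)[0])


# ---------------------------------------------------------------------------
# tail-trend fixing and coefficient simulation


def fix_tail_trend(fit: GAMMFit, region: str, first_data_year: int,
                   late_window=(2019, 2020, 2021)) -> GAMMFit:
    """Freeze the regional trend outside the data-supported year range.

    For years before ``first_data_year`` the trend evaluator returns its
    value at ``first_data_year``; for years inside ``late_window`` it
    returns the arithmetic mean of the trend over the window.
    """
    window = tuple(int(y) for y in late_window)
    if len(window) == 0:
        raise ConfigurationError("late_window must not be empty")
    fit.trend_block(region)  # raises KeyError when the region has no trend
    fit.tail_fix[region] = (int(first_data_year), window)
    return fit


def sample_coefficients(fit: GAMMFit, n_draws: int, seed) -> np.ndarray:
    """Multivariate-normal coefficient draws about the penalized estimate.

    Deterministic given ``seed`` (an int or a numpy Generator).  A failed
    Cholesky factorisation is retried once with a 1e-10 ridge; an all-zero
    covariance yields the point estimate in every draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = fit.coef_covariance
    p = fit.coefficients.size
    if not np.any(cov):
        return np.tile(fit.coefficients, (n_draws, 1))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        scale = max(float(np.trace(cov)) / p, 1.0)
        L = np.linalg.cholesky(cov + 1e-10 * scale * np.eye(p))
    z = rng.standard_normal((n_draws, p))
    return fit.coefficients[None, :] + z @ L.T
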