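"""Covariate preparation: Box-Cox transforms, standardisation, selection, PCA."""

import numpy as np
import pandas as pd
import pytest

from feverseek import covariate_prep
from feverseek.covariate_prep import (
    CovariatePanel,
    choose_transform,
    principal_components,
    select_covariates,
)
from feverseek.errors import DegenerateScaleError, RankError


def make_panel(frames: dict[str, np.ndarray], countries, years) -> CovariatePanel:
    rows = []
    for name, matrix in frames.items():
        for i, country in enumerate(countries):
            rows.append(pd.DataFrame({
                "country": country, "year": years, "covariate": name,
                "value": matrix[i], "lo95": matrix[i], "hi95": matrix[i],
            }))
    return CovariatePanel(pd.concat(rows, ignore_index=True))


class TestChooseTransform:
    def test_lognormal_data_selects_log(self):
        rng = np.random.default_rng(1)
        assert choose_transform(rng.lognormal(0.0, 1.0, 5000)) == "log"

    def test_normal_data_selects_none(self):
        rng = np.random.default_rng(2)
        assert choose_transform(rng.normal(50.0, 5.0, 5000)) == "none"

    def test_health_expenditure_like_log_and_anc_like_square(self):
        """Synthetic proxies of the classic covariates: per-capita health
        spending (heavily right-skewed) takes log; antenatal-care coverage
        (left-skewed proportion near 1) takes square."""
        rng = np.random.default_rng(3)
        health_spend = np.exp(rng.normal(4.0, 0.9, 5000))  # USD per capita
        anc = np.sqrt(rng.normal(0.7, 0.05, 5000).clip(0.3, 0.999))
        assert choose_transform(health_spend) == "log"
        assert choose_transform(anc) == "square"

    def test_non_positive_values_fall_back_to_none(self, caplog):
        values = np.concatenate([np.exp(np.linspace(-2, 2, 50)), [-1.0]])
        with caplog.at_level("WARNING"):
            assert choose_transform(values) == "none"


class TestStandardise:
    def test_constant_covariate_errors_with_name(self):
        panel = make_panel({"flat": np.full((2, 3), 5.0)}, ["A", "B"], [2000, 2001, 2002])
        with pytest.raises(DegenerateScaleError, match="flat"):
            panel.prepare()

    def test_one_two_three_maps_to_unit_steps(self):
        panel = make_panel({"x": np.array([[1.0, 2.0, 3.0]])}, ["A"], [2000, 2001, 2002])
        panel.transforms["x"] = "none"
        panel.fit_standardisation()
        np.testing.assert_allclose(panel.prepared_values("x"), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_prepared_panel_has_zero_mean_unit_sd(self):
        rng = np.random.default_rng(4)
        panel = make_panel({"a": rng.lognormal(1, 0.5, (4, 10)),
                            "b": rng.normal(0, 2, (4, 10))},
                           list("ABCD"), list(range(2000, 2010)))
        panel.prepare()
        for name in panel.covariates:
            values = panel.prepared_values(name)
            assert np.mean(values) == pytest.approx(0.0, abs=1e-12)
            assert np.std(values, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_frozen_state_reapplied_to_new_values(self):
        rng = np.random.default_rng(5)
        panel = make_panel({"a": rng.normal(10, 2, (3, 5))}, list("ABC"),
                           list(range(2000, 2005)))
        panel.transforms["a"] = "none"
        panel.fit_standardisation()
        mean, sd = panel.standardisation["a"]
        new = panel.with_values(panel.data["value"].to_numpy() + 1.0)
        shifted = new.prepared_values("a")
        np.testing.assert_allclose(
            shifted, panel.prepared_values("a") + 1.0 / sd, atol=1e-12
        )


class TestSelectCovariates:
    @staticmethod
    def template(observations, panel, subset):
        """A plain weighted-least-squares template with quadratic terms,
        mimicking the structure the full model gives each covariate."""
        import statsmodels.api as sm

        from feverseek import survey_prep

        y = np.array([survey_prep.empirical_logit(r, n)
                      for r, n in zip(observations["rate"], observations["n_eff"])])
        columns = [np.ones_like(y)]
        names = ["intercept"]
        wide = panel.wide(list(subset)) if subset else None
        for name in subset:
            idx = pd.MultiIndex.from_arrays([observations["country"], observations["year"]])
            x = wide[name].reindex(idx).to_numpy()
            columns += [x, x**2 - 1]
            names += [f"{name}:1", f"{name}:2"]
        X = np.column_stack(columns)
        fit = sm.OLS(y, X).fit()

        class Result:
            aic = fit.aic

            @staticmethod
            def covariate_p_values():
                out = {}
                for name in subset:
                    i = names.index(f"{name}:1")
                    contrast = np.zeros((2, X.shape[1]))
                    contrast[0, i] = 1.0
                    contrast[1, i + 1] = 1.0
                    out[name] = float(fit.f_test(contrast).pvalue)
                return out

        return Result()

    @staticmethod
    def simulate(rng, n=600):
        countries = [f"C{i:02d}" for i in range(20)]
        years = list(range(2000, 2030))
        signal = rng.normal(0, 1, (20, 30))
        noise = rng.normal(0, 1, (20, 30))
        panel = make_panel({"signal": signal, "noise": noise}, countries, years)
        panel.prepare()
        rows = rng.choice(20 * 30, size=n, replace=True)
        country = np.repeat(countries, 30)[rows]
        year = np.tile(years, 20)[rows]
        x = signal.ravel()[rows]
        logits = 0.2 + 0.8 * x + rng.normal(0, 0.4, n)
        from scipy.special import expit
        obs = pd.DataFrame({
            "country": country, "year": year,
            "rate": expit(logits), "n_eff": 400.0,
        })
        return obs, panel

    def test_generating_covariate_selected_over_noise(self):
        """With one true driver and one noise candidate, selection keeps
        exactly the driver in at least 95% of 100 replicates."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            obs, panel = self.simulate(rng)
            selected, _ = select_covariates(obs, panel, self.template, max_size=2)
            hits += selected == ["signal"]
        assert hits >= 95

    def test_zero_max_size_forces_empty_selection(self):
        rng = np.random.default_rng(7)
        obs, panel = self.simulate(rng)
        selected, table = select_covariates(obs, panel, self.template, max_size=0)
        assert selected == []
        assert len(table) == 1

    def test_duplicate_covariate_kept_once(self):
        """Two identical copies: AIC's penalty keeps exactly one, matching a
        brute-force enumeration over the four subsets."""
        rng = np.random.default_rng(8)
        obs, base = self.simulate(rng)
        twin = base.data[base.data["covariate"] == "signal"].copy()
        twin["covariate"] = "signal_copy"
        panel = CovariatePanel(
            pd.concat([base.data[base.data["covariate"] == "signal"], twin],
                      ignore_index=True)
        )
        panel.prepare()
        selected, table = select_covariates(obs, panel, self.template, max_size=2)
        assert len(selected) == 1
        assert selected[0] in ("signal", "signal_copy")
        # oracle: enumerate all four subsets directly
        aics = {}
        for subset in [(), ("signal",), ("signal_copy",), ("signal", "signal_copy")]:
            aics[subset] = self.template(obs, panel, subset).aic
        best = min(aics, key=aics.get)
        assert set(selected) == set(best)


class TestPrincipalComponents:
    def test_identical_histories_share_scores(self):
        rng = np.random.default_rng(0)
        jitter = make_panel({"a": rng.normal(0, 1, (3, 3)),
                             "b": rng.normal(0, 1, (3, 3))},
                            ["A", "B", "C"], [2000, 2010, 2020])
        data = jitter.data.copy()
        # make B an exact copy of A
        for name in ("a", "b"):
            a_vals = data.loc[(data.country == "A") & (data.covariate == name),
                              "value"].to_numpy()
            data.loc[(data.country == "B") & (data.covariate == name), "value"] = a_vals
            data.loc[(data.country == "B") & (data.covariate == name), "lo95"] = a_vals
            data.loc[(data.country == "B") & (data.covariate == name), "hi95"] = a_vals
        panel = CovariatePanel(data)
        panel.prepare()
        scores = principal_components(panel, (2000, 2010, 2020))
        np.testing.assert_allclose(scores.scores["A"], scores.scores["B"], atol=1e-10)

    def test_rank_one_panel_explained_by_first_component(self):
        spread = np.linspace(-1, 1, 6)[:, None] * np.ones((1, 3))
        # one varying covariate, another constant across countries
        panel = make_panel({"vary": spread + 5.0}, [f"C{i}" for i in range(6)],
                           [2000, 2010, 2020])
        panel.prepare()
        scores = principal_components(panel, (2000, 2010, 2020), n_components=1)
        assert scores.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_identity_with_all_components(self):
        rng = np.random.default_rng(9)
        panel = make_panel({"a": rng.normal(0, 1, (20, 3)),
                            "b": rng.normal(0, 1, (20, 3))},
                           [f"C{i:02d}" for i in range(20)], [2000, 2010, 2020])
        panel.prepare()
        wide = panel.wide().reset_index()
        wide = wide[wide["year"].isin((2000, 2010, 2020))]
        matrix = wide.pivot_table(index="country", columns="year",
                                  values=["a", "b"], sort=True).to_numpy()
        centred = matrix - matrix.mean(axis=0)
        scores = principal_components(panel, (2000, 2010, 2020), n_components=6)
        stacked = np.array([scores.scores[f"C{i:02d}"] for i in range(20)])
        np.testing.assert_allclose(stacked @ scores.loadings, centred, atol=1e-10)

    def test_scores_invariant_to_country_order(self):
        rng = np.random.default_rng(10)
        values = {"a": rng.normal(0, 1, (5, 3))}
        countries = list("ABCDE")
        panel = make_panel(values, countries, [2000, 2010, 2020])
        panel.prepare()
        direct = principal_components(panel, (2000, 2010, 2020))
        shuffled = CovariatePanel(
            panel.data.sample(frac=1.0, random_state=1).reset_index(drop=True),
            dict(panel.transforms), dict(panel.standardisation),
        )
        redone = principal_components(shuffled, (2000, 2010, 2020))
        for country in countries:
            np.testing.assert_allclose(direct.scores[country],
                                       redone.scores[country], atol=1e-10)

    def test_rank_error_when_too_many_components(self):
        panel = make_panel({"a": np.linspace(0, 1, 6).reshape(2, 3)}, ["A", "B"],
                           [2000, 2010, 2020])
        panel.prepare()
        with pytest.raises(RankError):
            principal_components(panel, (2000, 2010, 2020), n_components=4)


def test_transform_then_standardise_idempotent():
    rng = np.random.default_rng(11)
    panel = make_panel({"a": rng.lognormal(0, 0.7, (4, 6))}, list("ABCD"),
                       list(range(2000, 2006)))
    panel.prepare()
    first = {name: panel.standardisation[name] for name in panel.covariates}
    panel.prepare()  # refit on the same data
    for name, (mean, sd) in first.items():
        assert panel.standardisation[name][0] == pytest.approx(mean, abs=1e-12)
        assert panel.standardisation[name][1] == pytest.approx(sd, abs=1e-12)
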