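"""Stepwise AICc, MLR diagnostics, k-fold CV and prediction profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteoreg import (
    builtin_factors,
    candidate_terms,
    code_design,
    effect_significance_table,
    fit_mlr,
    kfold_cv,
    make_truth,
    profile,
    pure_error_df,
    simulate,
    stepwise_aicc,
)
from proteoreg.response_surface import aicc, assign_folds
from proteoreg.simulate import TruthModel, VariableTruth


def _series(design, values) -> pd.Series:
    return pd.Series(np.asarray(values, dtype=float), index=design.run_ids)


def _truth_var(terms: dict, noise_sd=0.0, intercept=5.0):
    return TruthModel(
        variables=[VariableTruth(
            var_id="v", var_class="spot", cluster=1, intercept=intercept,
            terms=tuple(terms.items()), noise_sd=noise_sd, missing_rate=0.0,
        )],
        scaling="unit",
    )


def _coded_y(design, terms: dict, intercept=5.0) -> pd.Series:
    coded = code_design(design, terms=list(terms))
    y = np.full(design.n_runs, intercept)
    for t, b in terms.items():
        y = y + b * coded.columns[t].to_numpy()
    return _series(design, y)


class TestStepwise:
    def test_single_linear_truth_selected_exactly(self, design):
        y = _coded_y(design, {"acetate": 2.0})
        assert stepwise_aicc(y, design) == ["acetate"]

    def test_matches_all_subsets_enumeration_on_noise_free_truths(self, design):
        # the greedy path must land on the global AICc optimum, which in
        # turn must be the generating term set (enumeration up to size 4)
        universe = candidate_terms(design)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            size = int(rng.integers(1, 5))
            chosen = sorted(rng.choice(len(universe), size=size, replace=False))
            terms = {universe[i]: float(rng.uniform(0.5, 2.0)) for i in chosen}
            y = _coded_y(design, terms)
            selected = stepwise_aicc(y, design)
            assert sorted(selected) == sorted(terms)
            # enumeration oracle over all subsets of size <= 4
            yv = y.to_numpy()
            n = len(yv)
            sst = float(((yv - yv.mean()) ** 2).sum())
            floor = max(sst, 1.0) * 1e-14
            best, best_set = np.inf, ()
            for k in range(5):
                for subset in itertools.combinations(universe, k):
                    coded = code_design(design, terms=list(subset))
                    X = np.column_stack([np.ones(n)] +
                                        [coded.columns[t] for t in subset])
                    resid = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
                    score = aicc(float(resid @ resid), n, k, floor)
                    if score < best:
                        best, best_set = score, subset
            assert sorted(best_set) == sorted(terms)

    def test_pure_noise_greedy_path_matches_stepwise_oracle(self, design):
        rng = np.random.default_rng(3)
        universe = candidate_terms(design)
        for s in range(5):
            y = _series(design, rng.normal(size=32))
            # verify the forward core against an independent greedy oracle
            selected = stepwise_aicc(y, design, purge=False, lookahead=False)
            # oracle: independent greedy re-evaluation
            yv = y.to_numpy()
            n = 32
            sst = float(((yv - yv.mean()) ** 2).sum())
            floor = max(sst, 1.0) * 1e-14
            current: list[str] = []
            current_score = aicc(sst, n, 0, floor)
            while True:
                scored = []
                for t in universe:
                    if t in current:
                        continue
                    trial = current + [t]
                    coded = code_design(design, terms=trial)
                    X = np.column_stack([np.ones(n)] +
                                        [coded.columns[u] for u in trial])
                    resid = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
                    scored.append((aicc(float(resid @ resid), n, len(trial),
                                        floor), t))
                scored.sort(key=lambda z: (z[0], universe.index(z[1])))
                if scored and scored[0][0] < current_score:
                    current_score = scored[0][0]
                    current.append(scored[0][1])
                else:
                    break
            assert selected == current


class TestFitMlr:
    def test_exact_linear_fit_diagnostics(self, design):
        y = _coded_y(design, {"light": 3.0})
        model = fit_mlr(y, design, ["light"])
        assert model.r2 == pytest.approx(1.0, abs=1e-12)
        assert model.rmse_f == pytest.approx(0.0, abs=1e-10)
        assert abs(model.beta_weights["light"]) == pytest.approx(1.0, abs=1e-10)

    def test_all_diagnostics_match_normal_equations_oracle(self, design):
        # independent oracle: explicit normal equations + printed formulas
        rng = np.random.default_rng(4)
        universe = candidate_terms(design)
        for _ in range(20):
            k = int(rng.integers(1, 6))
            terms = list(rng.choice(universe, size=k, replace=False))
            y = _series(design, rng.normal(size=32) * 3 + 10)
            model = fit_mlr(y, design, terms)
            coded = code_design(design, terms=terms)
            X = np.column_stack([np.ones(32)] +
                                [coded.columns[t] for t in terms])
            beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
            yv = y.to_numpy()
            fitted = X @ beta
            sse = ((yv - fitted) ** 2).sum()
            sst = ((yv - yv.mean()) ** 2).sum()
            ssm = ((fitted - yv.mean()) ** 2).sum()
            n = 32
            assert model.intercept == pytest.approx(beta[0], abs=1e-10)
            for i, t in enumerate(terms):
                assert model.coefficients[t] == pytest.approx(beta[i + 1],
                                                              abs=1e-10)
            assert model.r2 == pytest.approx(ssm / sst, abs=1e-10)
            assert model.r2_adjusted == pytest.approx(
                1 - (sse / (n - k - 1)) / (sst / (n - 1)), abs=1e-10
            )
            assert model.rmse_f == pytest.approx(
                np.sqrt(sse / (n - k - 1)), abs=1e-10
            )
            assert model.response_average_scale == pytest.approx(
                yv.mean() - yv.min(), abs=1e-12
            )
            f = (ssm / k) / (sse / (n - k - 1))
            assert model.f_whole_model == pytest.approx(f, rel=1e-10)
            assert model.p_whole_model == pytest.approx(
                stats.f.sf(f, k, n - k - 1), abs=1e-12
            )
            # per-effect extra sum of squares
            for t in terms:
                reduced = [u for u in terms if u != t]
                codr = code_design(design, terms=reduced)
                Xr = np.column_stack([np.ones(32)] +
                                     [codr.columns[u] for u in reduced])
                br = np.linalg.lstsq(Xr, yv, rcond=None)[0]
                sse_r = ((yv - Xr @ br) ** 2).sum()
                f_eff = (sse_r - sse) / (sse / (n - k - 1))
                assert model.effect_f[t] == pytest.approx(f_eff, rel=1e-8)
            # lack-of-fit split: conservation and df over the design
            lof = model.lack_of_fit
            assert lof is not None
            assert lof["df_pure"] == pure_error_df(design) == 3
            assert lof["ss_lof"] + lof["ss_pure"] == pytest.approx(
                sse, abs=1e-10 * max(1.0, sse)
            )

    def test_r2_adjusted_identity(self, design):
        rng = np.random.default_rng(5)
        y = _series(design, rng.normal(size=32))
        model = fit_mlr(y, design, ["acetate", "no3^2"])
        n, k = model.n, model.k
        assert model.r2_adjusted == pytest.approx(
            1 - (1 - model.r2) * (n - 1) / (n - k - 1), abs=1e-12
        )

    def test_beta_weights_match_definition(self, design):
        rng = np.random.default_rng(6)
        y = _series(design, rng.normal(size=32))
        terms = ["light", "nh4:no3"]
        model = fit_mlr(y, design, terms)
        coded = code_design(design, terms=terms)
        for t in terms:
            expected = (model.coefficients[t]
                        * coded.columns[t].std(ddof=1) / y.std(ddof=1))
            assert model.beta_weights[t] == pytest.approx(expected, abs=1e-12)

    def test_missing_responses_dropped(self, design):
        y = _coded_y(design, {"acetate": 2.0})
        y.iloc[3] = np.nan
        model = fit_mlr(y, design, ["acetate"])
        assert model.n == 31
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_rank_deficiency_rejected(self, design):
        # restrict to two-level acetate runs: acetate^2 == acetate under
        # unit coding, so the two columns are exactly collinear
        from proteoreg import DesignTable

        keep = [r for r in design.run_ids
                if design.settings.loc[r, "acetate"] in (0.0, 1.0)]
        sub = DesignTable(keep, design.settings.loc[keep], design.factors)
        y = pd.Series(np.arange(len(keep), dtype=float), index=keep)
        with pytest.raises(np.linalg.LinAlgError):
            fit_mlr(y, sub, ["acetate", "acetate^2"])


class TestEffectTable:
    def test_single_term_truths_fill_one_cell_each(self, design):
        models = []
        for i, term in enumerate(["acetate", "no3^2", "light:co2"]):
            y = _coded_y(design, {term: 1.5 + i})
            models.append(fit_mlr(y, design, stepwise_aicc(y, design),
                                  response_id=f"v{i}"))
        table = effect_significance_table(models, design)
        assert table.notna().sum(axis=1).tolist() == [1, 1, 1]
        assert not np.isnan(table.loc["v1", "no3^2"])

    def test_filled_cells_subset_of_selected_terms(self, design, noisy_matrix):
        _, matrix = noisy_matrix
        from proteoreg import fit_all

        models = fit_all(matrix.subset(matrix.variables[:5]), design)
        table = effect_significance_table(models, design)
        for m in models:
            filled = table.loc[m.response_id].dropna().index
            assert set(filled) <= set(m.terms)

    def test_cluster_sign_pattern_matches_truth(self, design):
        truth = make_truth(n_vars=8, n_clusters=2, effect_size_range=(1.0, 2.0),
                           noise_sd=0.0, seed=7, design=design)
        matrix = simulate(design, truth, seed=8)
        from proteoreg import fit_all

        models = fit_all(matrix, design)
        table = effect_significance_table(models, design)
        for v in truth.variables:
            for term, b in v.terms:
                cell = table.loc[v.var_id, term]
                assert not np.isnan(cell)
                assert np.sign(cell) == np.sign(b)


class TestKfoldCv:
    def test_noise_free_truth_gives_zero_cv_error(self, design):
        y = _coded_y(design, {"acetate": 2.0, "no3": -1.0})
        res = kfold_cv(y, design, ["acetate", "no3"], seed=0)
        assert res.pooled_rmse_cv == pytest.approx(0.0, abs=1e-10)
        assert all(r == pytest.approx(0.0, abs=1e-10)
                   for r in res.per_fold_rmse_cv)

    def test_folds_partition_all_runs(self, design):
        y = _coded_y(design, {"light": 1.0})
        res = kfold_cv(y, design, ["light"], seed=3)
        assert sorted(res.folds) == sorted(design.run_ids)
        sizes = pd.Series(list(res.folds.values())).value_counts()
        assert sorted(sizes) == [8, 8, 8, 8]

    def test_hand_assigned_folds_match_manual_refit_oracle(self, design):
        rng = np.random.default_rng(9)
        y = _series(design, rng.normal(size=32))
        folds = {r: i % 4 for i, r in enumerate(design.run_ids)}
        res = kfold_cv(y, design, ["acetate", "light"], folds=folds)
        coded = code_design(design, terms=["acetate", "light"])
        X = np.column_stack([np.ones(32), coded.values])
        yv = y.to_numpy()
        for lab in range(4):
            test = np.array([folds[r] == lab for r in design.run_ids])
            beta = np.linalg.lstsq(X[~test], yv[~test], rcond=None)[0]
            err = yv[test] - X[test] @ beta
            expected = np.sqrt((err @ err) / test.sum())
            assert res.per_fold_rmse_cv[lab] == pytest.approx(expected,
                                                              abs=1e-10)

    def test_same_seed_same_folds(self, design):
        a = assign_folds(design.run_ids, seed=11)
        b = assign_folds(design.run_ids, seed=11)
        assert a == b


class TestProfile:
    def test_linear_model_gives_straight_line(self, design):
        y = _coded_y(design, {"light": 2.0})
        model = fit_mlr(y, design, ["light"])
        grid = np.linspace(0, 200, 5)
        curve = profile(model, "light", grid,
                        {"acetate": 0.5, "nh4": 7.5, "no3": 10, "co2": 0.035})
        slopes = np.diff(curve["prediction"]) / np.diff(grid)
        # coefficient is on the unit-coded scale: slope = b / range
        np.testing.assert_allclose(slopes, 2.0 / 200, atol=1e-12)

    def test_concave_profile_vertex_at_minus_b_over_2a(self, design):
        terms = {"no3": 2.0, "no3^2": -1.6}
        y = _coded_y(design, terms)
        model = fit_mlr(y, design, list(terms))
        grid = np.linspace(0, 20, 401)
        curve = profile(model, "no3", grid,
                        {"acetate": 0.5, "light": 100, "nh4": 7.5,
                         "co2": 0.035})
        vertex_coded = -terms["no3"] / (2 * terms["no3^2"])  # on [0,1] scale
        expected = vertex_coded * 20
        got = grid[curve["prediction"].idxmax()]
        assert got == pytest.approx(expected, abs=0.1)

    def test_interaction_changes_profile_slope(self, design):
        terms = {"acetate": 1.0, "light": 0.5, "acetate:light": 2.0}
        y = _coded_y(design, terms)
        model = fit_mlr(y, design, list(terms))
        grid = np.array([0.0, 200.0])
        lo = profile(model, "light", grid,
                     {"acetate": 0.0, "nh4": 0, "no3": 0, "co2": 0.035})
        hi = profile(model, "light", grid,
                     {"acetate": 1.0, "nh4": 0, "no3": 0, "co2": 0.035})
        slope_lo = np.diff(lo["prediction"])[0]
        slope_hi = np.diff(hi["prediction"])[0]
        # coded slopes differ by the interaction coefficient
        assert slope_hi - slope_lo == pytest.approx(2.0, abs=1e-10)

    def test_extrapolation_warns(self, design):
        y = _coded_y(design, {"acetate": 1.0})
        model = fit_mlr(y, design, ["acetate"])
        with pytest.warns(UserWarning, match="extrapolation"):
            profile(model, "acetate", np.linspace(0, 2, 3),
                    {"light": 0, "nh4": 0, "no3": 0, "co2": 0.035})


class TestStatisticalProperties:
    def test_whole_model_p_uniform_under_null(self, design):
        # forced terms on pure noise: p-values ~ Uniform(0,1) across seeds
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(200):
            y = _series(design, rng.normal(size=32))
            model = fit_mlr(y, design, ["acetate", "light", "no3^2"])
            pvals.append(model.p_whole_model)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_whole_model_p_near_zero_on_structured_data(self, design):
        y = _coded_y(design, {"acetate": 2.0})
        y = y + np.random.default_rng(13).normal(size=32) * 0.01
        model = fit_mlr(y, design, ["acetate"])
        assert model.p_whole_model < 1e-12
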