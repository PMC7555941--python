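"""Response-surface encoding, term expansion, selection, prediction."""

import itertools

import numpy as np
import pytest

import uedopt
from uedopt import FactorSpec, ResponseSurface
from uedopt.surrogate import build_terms, encode_factors, improvement_report


def brute_force_argmax(results, factors):
    """Literal enumeration oracle: predict each grid point one at a time."""
    best_settings, best_val = None, -np.inf
    for combo in itertools.product(*(f.levels for f in factors)):
        val = results.predict(np.array(combo, dtype=float))
        if val > best_val:
            best_settings, best_val = tuple(float(v) for v in combo), val
    return best_settings, best_val


class TestEncoding:
    def test_three_level_midpoint_and_endpoints(self, plan6):
        coded, maps = encode_factors(plan6)
        a = plan6.factors[0]  # levels 3, 5, 7
        col = plan6.settings[:, 0]
        assert np.all(coded[col == 5, 0] == 0.0)
        assert np.all(coded[col == 3, 0] == -1.0)
        assert np.all(coded[col == 7, 0] == 1.0)

    def test_unequally_spaced_middle_level(self, plan6):
        coded, _ = encode_factors(plan6)
        f_col = plan6.settings[:, 5]  # conv2 filters: 8, 16, 32
        assert np.allclose(coded[f_col == 16, 5], -1.0 / 3.0)

    def test_two_level_endpoints(self, plan6):
        coded, _ = encode_factors(plan6)
        d_col = plan6.settings[:, 3]  # padding 0/1
        assert set(np.unique(coded[:, 3])) == {-1.0, 1.0}
        assert np.all(coded[d_col == 1, 3] == 1.0)

    def test_constant_factor_rejected(self, factors8):
        settings = np.tile([3, 4, 1, 0, 3, 8, 1, 0], (5, 1)).astype(float)
        settings[:, 1] = [4, 6, 12, 4, 6]  # vary one factor, keep the rest fixed
        plan = uedopt.ExperimentPlan(factors=tuple(factors8), settings=settings)
        with pytest.raises(uedopt.ValidationError):
            encode_factors(plan)


class TestTermExpansion:
    def test_full_expansion_count(self, plan6):
        coded, _ = encode_factors(plan6)
        matrix, terms = build_terms(coded, plan6.factors, prune=False)
        assert len(terms) == 1 + 8 + 8 + 8 + 28 == 53

    def test_structural_pruning_count(self, plan6):
        coded, _ = encode_factors(plan6)
        matrix, terms = build_terms(coded, plan6.factors)
        assert len(terms) == 1 + 8 + 4 + 0 + 28 == 41
        kinds = [t.kind for t in terms]
        assert kinds.count("quadratic") == 4 and kinds.count("cubic") == 0

    def test_pruned_matrix_rank_bounded_by_runs(self, plan6):
        coded, _ = encode_factors(plan6)
        matrix, _ = build_terms(coded, plan6.factors)
        assert np.linalg.matrix_rank(matrix) <= 17

    def test_no_structurally_collinear_pair_after_allocation(self):
        # pruning must remove every collinearity forced by 2/3-level coding
        design = uedopt.construct_glp_design(9, 4, search_budget=50, seed=2,
                                             refine_restarts=0)
        factors = (
            FactorSpec("p", (1, 2)),
            FactorSpec("q", (0, 1)),
            FactorSpec("r", (3, 5, 7)),
            FactorSpec("s", (8, 16, 32)),
        )
        plan = uedopt.allocate(design, factors)
        coded, _ = encode_factors(plan)
        matrix, terms = build_terms(coded, factors)
        low_order = [i for i, t in enumerate(terms) if t.kind != "interaction"]
        sub = matrix[:, low_order]
        assert np.linalg.matrix_rank(sub) == len(low_order)


class TestFit:
    def test_constant_response_gives_intercept_only(self, plan6):
        res = ResponseSurface(plan6, np.full(17, 81.5)).fit()
        assert res.n_terms == 1
        assert res.selected_terms[0].kind == "intercept"
        assert res.params[0] == pytest.approx(81.5)

    def test_published_table_beats_intercept_only(self, plan6, table7):
        res = ResponseSurface.from_response_table(table7).fit()
        intercept_rss = float(np.sum((table7.means - table7.means.mean()) ** 2))
        assert res.rss < intercept_rss
        assert res.n_terms <= 15

    def test_selection_path_rss_never_increases(self, plan6, table7):
        res = ResponseSurface.from_response_table(table7).fit()
        rss_path = [r for _, _, r in res.selection_path]
        assert all(b <= a + 1e-12 for a, b in zip(rss_path, rss_path[1:]))

    def test_noiseless_sparse_truth_recovered(self, plan6):
        coded, _ = encode_factors(plan6)
        matrix, terms = build_terms(coded, plan6.factors)
        names = [t.name for t in terms]
        truth = {
            "1": 80.0,
            "conv1_Kernel size": 2.0,
            "conv1_Kernel size^2": -3.0,
            "conv2_Filter": 1.5,
            "conv1_Padding": -1.0,
            "conv1_Kernel size*conv2_Filter": 1.2,
        }
        y = sum(c * matrix[:, names.index(n)] for n, c in truth.items())
        res = ResponseSurface(plan6, y).fit()
        fitted = res.coefficients
        assert set(truth) <= set(fitted)
        for name, coef in truth.items():
            assert fitted[name] == pytest.approx(coef, abs=1e-6)
        for name, coef in fitted.items():
            if name not in truth:
                assert coef == pytest.approx(0.0, abs=1e-6)

    def test_max_terms_cap_enforced(self, plan6, table7):
        with pytest.raises(uedopt.ValidationError):
            ResponseSurface.from_response_table(table7).fit(max_terms=16)

    def test_too_few_runs_rejected(self, factors8):
        plan = uedopt.ExperimentPlan(
            factors=(FactorSpec("a", (0, 1)),),
            settings=np.array([[0.0], [1.0]]),
        )
        with pytest.raises(uedopt.ValidationError):
            ResponseSurface(plan, np.array([1.0, 2.0]))


class TestPredict:
    def test_intercept_only_is_constant(self, plan6):
        res = ResponseSurface(plan6, np.full(17, 77.0)).fit()
        assert res.predict(plan6.settings[3]) == pytest.approx(77.0)
        assert res.predict(plan6.settings[9]) == pytest.approx(77.0)

    def test_single_linear_term_slope(self):
        # y = 10 + 4*X on a 2-level factor: coded span is 2, so the
        # difference between the two levels is 2 * coefficient
        plan = uedopt.ExperimentPlan(
            factors=(FactorSpec("a", (1, 2)), FactorSpec("b", (0, 1))),
            settings=np.array(
                [[1, 0], [2, 0], [1, 1], [2, 1]], dtype=float
            ),
        )
        y = np.array([6.0, 14.0, 6.0, 14.0])
        res = ResponseSurface(plan, y).fit()
        alpha = res.coefficients["a"]
        assert res.predict((2.0, 0.0)) - res.predict((1.0, 0.0)) == pytest.approx(
            2 * alpha
        )

    def test_interpolating_quadratic_reproduces_observations(self):
        # 5 runs over one 3-level factor; y exactly quadratic in the level
        plan = uedopt.ExperimentPlan(
            factors=(FactorSpec("a", (1, 2, 4)),),
            settings=np.array([[1], [2], [4], [2], [1]], dtype=float),
        )
        y = np.array([3.0, 7.0, 6.0, 7.0, 3.0])
        res = ResponseSurface(plan, y).fit()
        for xi, yi in zip(plan.settings[:, 0], y):
            assert res.predict((float(xi),)) == pytest.approx(yi, abs=1e-9)

    def test_illegal_settings_rejected(self, plan6, table7):
        res = ResponseSurface.from_response_table(table7).fit()
        with pytest.raises(uedopt.ValidationError):
            res.predict((4.0, 12.0, 1.0, 0.0, 3.0, 8.0, 1.0, 1.0))


class TestRecommend:
    def test_equals_brute_force_on_published_fit(self, table7):
        res = ResponseSurface.from_response_table(table7).fit()
        rec = res.recommend()
        oracle_settings, oracle_val = brute_force_argmax(res, res.model.plan.factors)
        assert rec.settings == oracle_settings
        assert rec.predicted_response == pytest.approx(oracle_val)
        assert rec.grid_size == 1296

    def test_equals_brute_force_on_synthetic_fit(self, plan6, factors8):
        optimum = (7.0, 12.0, 2.0, 1.0, 3.0, 8.0, 1.0, 1.0)
        surf = uedopt.make_synthetic_surface(factors8, optimum, noise_sd=1.0, seed=3)
        rt = uedopt.run_experiments(plan6, surf, replicates=3, seed=3)
        res = ResponseSurface.from_response_table(rt).fit()
        rec = res.recommend()
        oracle_settings, _ = brute_force_argmax(res, factors8)
        assert rec.settings == oracle_settings

    def test_tie_break_is_lexicographically_smallest(self, plan6):
        res = ResponseSurface(plan6, np.full(17, 80.0)).fit()  # flat surface
        rec = res.recommend()
        assert rec.settings == tuple(f.levels[0] for f in plan6.factors)

    def test_noiseless_end_to_end_recovery(self, plan6, factors8):
        optimum = (5.0, 6.0, 1.0, 0.0, 5.0, 16.0, 1.0, 0.0)
        surf = uedopt.make_synthetic_surface(factors8, optimum, noise_sd=0.0)
        rt = uedopt.run_experiments(plan6, surf, replicates=3, seed=0)
        res = ResponseSurface.from_response_table(rt).fit()
        assert res.recommend().settings == optimum

    def test_minimize_flag(self, plan6, factors8):
        optimum = (5.0, 6.0, 1.0, 0.0, 5.0, 16.0, 1.0, 0.0)
        surf = uedopt.make_synthetic_surface(factors8, optimum, noise_sd=0.0)
        rt = uedopt.run_experiments(plan6, surf, replicates=3, seed=0)
        res = ResponseSurface.from_response_table(rt).fit()
        worst = res.recommend(minimize=True)
        best = res.recommend()
        assert worst.predicted_response < best.predicted_response


class TestImprovementReport:
    def test_published_improvement(self, table7):
        rep = improvement_report(table7, 84.41)
        assert rep.best_run_id == 2
        assert rep.improvement == pytest.approx(1.01, abs=0.005)
        assert not rep.regressed

    def test_zero_improvement(self, table7):
        rep = improvement_report(table7, uedopt.best_observed(table7).mean)
        assert rep.improvement == pytest.approx(0.0, abs=1e-12)

    def test_regression_flagged(self, table7):
        rep = improvement_report(table7, 80.0)
        assert rep.regressed
        assert rep.improvement < 0
        assert "WARNING" in str(rep)


class TestSerialization:
    def test_model_json_round_trip_fields(self, tmp_path, table7):
        import json

        res = ResponseSurface.from_response_table(table7).fit()
        path = tmp_path / "model.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["format"] == "uedopt.response_surface.v1"
        assert len(payload["terms"]) == res.n_terms
        assert payload["terms"][0]["name"] == "1"
        assert [m for m in payload["coding_maps"]] == [
            list(m) for m in res.model.coding_maps
        ]

    def test_summary_lists_all_selected_terms(self, table7):
        res = ResponseSurface.from_response_table(table7).fit()
        text = res.summary()
        for t in res.selected_terms:
            assert t.name in text
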