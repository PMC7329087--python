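import numpy as np
import pytest

from fsopa.errors import ConfigError, NumericError
from fsopa.survival import (CoxSpec, cox_fit, encode_covariates, encoded_width,
                            forward_aic, normalize_aic,
                            null_log_partial_likelihood)
from fsopa.table import ColumnRoleConfig

from conftest import make_table
from _oracles import cox_logpl_newton


def surv_table(X: dict, t, e):
    cols = dict(X)
    cols["T"] = np.round(t, 6)
    cols["E"] = np.asarray(e, int)
    return make_table(cols, ColumnRoleConfig(duration="T", event="E"))


class TestEncoding:
    def test_binary_categorical_reference_is_most_frequent(self):
        t = make_table({"sex": ["F", "F", "M", "F"], "T": [1, 2, 3, 4]})
        X, idx, _ = encode_covariates(t, ["sex"])
        assert list(X.columns) == ["sex=M"]
        assert X["sex=M"].tolist() == [0, 0, 1, 0]

    def test_numeric_passthrough_counts_one(self):
        t = make_table({"age": [1.5, 2.5], "T": [1, 2]})
        X, _, _ = encode_covariates(t, ["age"])
        assert list(X.columns) == ["age"]
        assert encoded_width(t, "age") == 1

    def test_three_level_categorical_two_indicators(self):
        t = make_table({"c": ["a", "b", "c", "a"], "T": [1, 2, 3, 4]})
        X, _, _ = encode_covariates(t, ["c"])
        assert sorted(X.columns) == ["c=b", "c=c"]
        assert encoded_width(t, "c") == 2

    def test_single_level_feature_dropped_with_note(self):
        t = make_table({"c": ["a", "a"], "T": [1, 2]})
        X, _, notes = encode_covariates(t, ["c"])
        assert X.shape[1] == 0 and notes

    def test_complete_case_rows(self):
        t = make_table({"x": ["1", "", "3"], "T": [1, 2, 3]})
        _, idx, _ = encode_covariates(t, ["x"])
        assert idx.tolist() == [0, 2]


class TestCoxFit:
    def test_null_model_closed_form(self):
        # distinct times, all events: logPL0 = -sum log(n), log(n-1), ...
        t = surv_table({}, [3.0, 1.0, 2.0, 4.0], [1, 1, 1, 1])
        pt = cox_fit(t, CoxSpec("T", "E"), ())
        expected = -(np.log(4) + np.log(3) + np.log(2) + np.log(1))
        assert pt.log_partial_likelihood == pytest.approx(expected)
        assert pt.k == 0 and pt.aic == pytest.approx(-2 * expected)

    def test_aic_formula(self, survival_table):
        pt = cox_fit(survival_table, CoxSpec("T", "E"), ["x"])
        assert pt.aic == pytest.approx(-2 * pt.log_partial_likelihood + 2 * pt.k)
        assert pt.k == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_logpl_matches_newton_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        X = rng.standard_normal((n, 2))
        t = rng.exponential(1 / (0.1 * np.exp(X @ [0.6, -0.4])))
        e = (rng.random(n) > 0.25).astype(int)
        if e.sum() < 3:
            e[:3] = 1
        table = surv_table({"x1": np.round(X[:, 0], 6),
                            "x2": np.round(X[:, 1], 6)}, t, e)
        pt = cox_fit(table, CoxSpec("T", "E"), ["x1", "x2"])
        oracle = cox_logpl_newton(X, np.round(t, 6), e)
        assert pt.log_partial_likelihood == pytest.approx(oracle, abs=1e-6)

    def test_parameter_recovery_bias_shrinks(self):
        def fit_beta(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(n)
            t = rng.exponential(1 / (0.1 * np.exp(0.7 * x)))
            table = surv_table({"x": np.round(x, 6)}, t, np.ones(n, int))
            return cox_fit(table, CoxSpec("T", "E"), ["x"]).coefficients["x"]

        small = np.mean([fit_beta(200, s) for s in range(8)])
        large = np.mean([fit_beta(2000, s) for s in range(8)])
        assert abs(large - 0.7) < abs(small - 0.7) + 0.05
        assert abs(large - 0.7) < 0.05

    def test_missing_duration_column(self, survival_table):
        with pytest.raises(ConfigError):
            cox_fit(survival_table, CoxSpec("nope"), ())


class TestForwardAIC:
    def test_informative_covariate_kept_and_decreasing(self, survival_table):
        pt, steps = forward_aic(survival_table, CoxSpec("T", "E"),
                                ["x", "noise"])
        assert "x" in pt.features
        accepted = [s.aic_after for s in steps if s.kept]
        befores = [s.aic_before for s in steps if s.kept]
        assert all(a < b for a, b in zip(accepted, befores))
        assert sorted(accepted, reverse=True) == accepted

    def test_duplicate_covariate_rejected(self, survival_table):
        t = survival_table
        dup = make_table(
            {"x": t.values("x"), "x_copy": t.values("x"),
             "T": t.values("T"), "E": t.values("E")},
            ColumnRoleConfig(duration="T", event="E"))
        pt, steps = forward_aic(dup, CoxSpec("T", "E"), ["x", "x_copy"])
        assert pt.features == ("x",)
        assert not steps[1].kept

    def test_all_noise_returns_null_model(self):
        rng = np.random.default_rng(42)
        n = 150
        t = rng.exponential(10, n)
        table = surv_table({"n1": np.round(rng.standard_normal(n), 4),
                            "n2": np.round(rng.standard_normal(n), 4)},
                           t, np.ones(n, int))
        pt, steps = forward_aic(table, CoxSpec("T", "E"), ["n1", "n2"])
        assert pt.features == ()
        assert all(not s.kept for s in steps)

    def test_design_width_guard_skips_id_like_columns(self):
        rng = np.random.default_rng(0)
        n = 80
        table = surv_table({"code": [f"p{i}" for i in range(n)],
                            "x": np.round(rng.standard_normal(n), 4)},
                           rng.exponential(10, n), np.ones(n, int))
        pt, steps = forward_aic(table, CoxSpec("T", "E"), ["code", "x"])
        assert "code" not in pt.features
        assert "wide" in steps[0].reason

    def test_empty_candidates_rejected(self, survival_table):
        with pytest.raises(ConfigError):
            forward_aic(survival_table, CoxSpec("T", "E"), [])


class TestNormalizeAIC:
    def test_reference_rules(self, survival_table):
        pts = [cox_fit(survival_table, CoxSpec("T", "E"), ["x"], label="m1"),
               cox_fit(survival_table, CoxSpec("T", "E"), (), label="null")]
        normed = normalize_aic(pts, reference="max")
        ref = max(p.aic for p in pts)
        assert max(p.normalized_aic for p in normed) == pytest.approx(1.0)
        assert normed[0].normalized_aic == pytest.approx(pts[0].aic / ref)

    def test_explicit_reference(self, survival_table):
        pt = cox_fit(survival_table, CoxSpec("T", "E"), ())
        normed = normalize_aic([pt], reference=2 * pt.aic)
        assert normed[0].normalized_aic == pytest.approx(0.5)

    def test_nonpositive_reference_rejected(self, survival_table):
        pt = cox_fit(survival_table, CoxSpec("T", "E"), ())
        with pytest.raises(NumericError):
            normalize_aic([pt], reference=0.0)
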