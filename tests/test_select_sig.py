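"""Selection stack: normalization, ICC, pruning, LASSO, scoring."""

import numpy as np
import pandas as pd
import pytest

from radsig.reference import DLR_INTERCEPT, dlr_score_model, rad_score_model
from radsig.select_sig import (
    SelectionConfig,
    SignatureModel,
    build_signature,
    cv_select_lambda,
    icc_2_1,
    lambda_max,
    lasso_path,
    label_correlation_ranking,
    pearson_prune,
    score,
    top_k_retain,
    zscore_apply,
    zscore_fit,
)
from radsig.syndata import generate_feature_cohort

from _oracles import lasso_objective, lasso_proximal_gradient


class TestZScore:
    def test_forced_by_definition(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        params = zscore_fit(t)
        np.testing.assert_allclose(zscore_apply(t, params)["a"], [-1.0, 0.0, 1.0])

    def test_training_columns_centered_and_reapplication(self, rng):
        t = pd.DataFrame(rng.normal(5, 3, size=(40, 4)), columns=list("abcd"))
        params = zscore_fit(t)
        z = zscore_apply(t, params)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)
        # a validation column equal to a training column transforms identically
        val = pd.DataFrame({c: t[c] for c in t})
        pd.testing.assert_frame_equal(zscore_apply(val, params), z)

    def test_constant_feature_dropped(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="flat"):
            params = zscore_fit(t)
        assert "flat" not in params


class TestICC:
    def test_perfect_agreement(self):
        assert icc_2_1(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])) == pytest.approx(1.0)

    def test_constant_offset_example(self):
        # MSR 2, MSC 1.5, MSE 0 -> (2-0)/(2+0+2*1.5/3) = 2/3
        r = icc_2_1(np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]))
        assert r == pytest.approx(2.0 / 3.0)

    def test_matches_mixed_anova_oracle(self, rng):
        import pingouin as pg

        for _ in range(5):
            x = rng.normal(size=(12, 2))
            x += rng.normal(size=(12, 1))  # subject effect
            data = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(12), 2),
                    "rater": np.tile(["r1", "r2"], 12),
                    "value": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(
                data=data, targets="subject", raters="rater", ratings="value"
            )
            # two-way random, absolute agreement, single rater
            icc2 = float(ref.loc[ref["Type"].str.contains("A,1"), "ICC"].iloc[0])
            assert icc_2_1(x) == pytest.approx(icc2, abs=1e-10)

    def test_zero_between_subject_variance(self):
        with pytest.warns(UserWarning, match="between-subject"):
            assert icc_2_1(np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])) == 0.0


class TestPearsonPrune:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=30)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        kept = pearson_prune(t, 0.9, ranking=["a", "b", "c"])
        assert kept == ["a", "c"]

    def test_orthogonal_columns_all_kept(self):
        t = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        assert pearson_prune(t, 0.9) == ["a", "b"]

    def test_matches_exhaustive_greedy_oracle(self, rng):
        t = pd.DataFrame(rng.normal(size=(25, 12)), columns=[f"f{i}" for i in range(12)])
        t["f3"] = t["f0"] * 0.97 + rng.normal(scale=0.05, size=25)
        t["f7"] = -t["f1"]
        ranking = label_correlation_ranking(t, rng.integers(0, 2, 25))
        kept = pearson_prune(t, 0.9, ranking)
        # independent re-derivation of the greedy rule
        corr = t[ranking].corr().to_numpy()
        expected = []
        for j, name in enumerate(ranking):
            if all(abs(corr[j, ranking.index(k)]) <= 0.9 for k in expected):
                expected.append(name)
        assert kept == expected
        assert "f7" not in kept or "f1" not in kept


class TestLasso:
    def test_null_model_threshold(self, rng):
        x = rng.normal(size=(50, 6))
        y = rng.integers(0, 2, 50).astype(float)
        lam = lambda_max(x, y)
        beta, _ = lasso_path(x, y, lam * 1.0001)
        np.testing.assert_array_equal(beta, 0.0)

    def test_soft_threshold_closed_form(self):
        # orthonormal design (X'X/n = I), gaussian response with OLS
        # coefficient 1.0: lasso coefficient = 1.0 - lambda = 0.7
        n = 64
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(n, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered, orthonormal
        x = q * np.sqrt(n)
        beta_true = np.array([1.0, 0.0, 0.0, 0.0])
        y = x @ beta_true  # noiseless; OLS coefficient exactly 1.0
        beta, b0 = lasso_path(x, y, 0.3, family="gaussian")
        assert beta[0] == pytest.approx(0.7, abs=1e-6)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-6)

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_matches_proximal_gradient_oracle(self, family, rng):
        x = rng.normal(size=(30, 3))
        if family == "binomial":
            y = (rng.uniform(size=30) < 1 / (1 + np.exp(-x[:, 0]))).astype(float)
        else:
            y = x[:, 0] * 0.8 + rng.normal(scale=0.4, size=30)
        lam = 0.05
        beta, b0 = lasso_path(x, y, lam, family=family)
        beta_o, b0_o = lasso_proximal_gradient(x, y, lam, family=family)
        np.testing.assert_allclose(beta, beta_o, atol=1e-5)
        assert b0 == pytest.approx(b0_o, abs=1e-5)
        # objective at the solution is no worse than the oracle's
        obj = lasso_objective(x, y, beta, b0, lam, family)
        obj_o = lasso_objective(x, y, beta_o, b0_o, lam, family)
        assert obj <= obj_o + 1e-8

    def test_nan_rejected(self):
        x = np.zeros((10, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            lasso_path(x, np.zeros(10), 0.1)


class TestCVSelect:
    def test_same_seed_same_lambda(self, rng):
        x = rng.normal(size=(60, 8))
        y = rng.integers(0, 2, 60).astype(float)
        l1, _ = cv_select_lambda(x, y, seed=9)
        l2, _ = cv_select_lambda(x, y, seed=9)
        assert l1 == l2

    def test_single_class_fold_rejected(self):
        x = np.random.default_rng(0).normal(size=(12, 3))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        with pytest.raises(ValueError, match="fewer folds"):
            cv_select_lambda(x, y, folds=5)

    def test_pure_noise_selects_nearly_nothing_with_one_se(self):
        """On pure-noise features the sparsity-conservative 1-SE rule keeps
        at most one coefficient in nearly all replicates."""
        hits = 0
        for seed in range(20):
            table, y, _ = generate_feature_cohort(120, 15, 0, 0.0, seed=300 + seed)
            x = table.to_numpy()
            x = (x - x.mean(0)) / x.std(0, ddof=1)
            lam, _ = cv_select_lambda(x, y.astype(float), seed=seed, one_se_rule=True)
            beta, _ = lasso_path(x, y.astype(float), lam)
            hits += (beta != 0).sum() <= 1
        assert hits >= 18

    def test_informative_features_get_nonzero_coefficients(self):
        table, y, truth = generate_feature_cohort(400, 20, 3, 1.5, seed=4)
        model = build_signature(table, y, SelectionConfig(seed=4))
        for f in truth["informative"]:
            assert f in model.coefficients


class TestTopKAndScore:
    def _model(self, coefs):
        return SignatureModel(intercept=0.5, coefficients=coefs)

    def test_truncates_to_k_largest(self):
        coefs = {f"f{i:02d}": (i + 1) * 0.01 for i in range(19)}
        m = top_k_retain(self._model(coefs), 15)
        assert len(m.coefficients) == 15
        assert "f00" not in m.coefficients and "f18" in m.coefficients

    def test_identity_when_k_not_exceeded(self):
        m = self._model({"a": 0.1, "b": -0.2})
        assert top_k_retain(m, 15) is m

    def test_tie_at_rank_k_drops_later_name(self):
        coefs = {"a": 0.3, "b": 0.2, "z_tie": 0.1, "a_tie": -0.1}
        m = top_k_retain(self._model(coefs), 3)
        assert set(m.coefficients) == {"a", "b", "a_tie"}

    def test_published_dlr_intercept_on_zero_vector(self):
        model = dlr_score_model()
        table = pd.DataFrame({f: [0.0] for f in model.coefficients})
        assert score(model, table)[0] == DLR_INTERCEPT

    def test_published_single_term_sum(self):
        model = dlr_score_model()
        row = {f: [0.0] for f in model.coefficients}
        row["DL_148"] = [1.0]
        val = score(model, pd.DataFrame(row))[0]
        assert val == pytest.approx(DLR_INTERCEPT + 0.019473, abs=1e-12)

    def test_linearity_in_coefficients(self, rng):
        model = self._model({"a": 0.25, "b": -0.4})
        t = pd.DataFrame({"a": rng.normal(size=5), "b": rng.normal(size=5)})
        base = score(model, t)
        doubled = SignatureModel(0.5, {"a": 0.5, "b": -0.4})
        np.testing.assert_allclose(
            score(doubled, t) - base, 0.25 * t["a"].to_numpy(), atol=1e-12
        )

    def test_missing_feature_named_in_error(self):
        model = self._model({"a": 1.0, "missing_one": 2.0})
        with pytest.raises(KeyError, match="missing_one"):
            score(model, pd.DataFrame({"a": [1.0]}))

    def test_rad_score_alias_resolves_to_canonical_name(self):
        model = rad_score_model()
        table = pd.DataFrame({f: [0.0] for f in model.coefficients})
        table = table.rename(
            columns={"log_sigma_2_0_mm_3D_glszm_Zone%": "log_sigma_2_0_mm_3D_glszm_ZonePercentage"}
        )
        assert score(model, table)[0] == DLR_INTERCEPT

    def test_json_round_trip(self, tmp_path):
        m = SignatureModel(0.2, {"a": 0.1}, {"a": (1.0, 2.0)}, lam=0.05)
        p = tmp_path / "m.json"
        m.to_json(p)
        m2 = SignatureModel.from_json(p)
        assert m2.intercept == m.intercept
        assert m2.coefficients == m.coefficients
        assert m2.normalization == m.normalization


class TestLeakageGuard:
    def test_validation_rows_never_influence_the_model(self):
        """Shuffling (or replacing) rows outside the training slice leaves
        the fitted signature identical."""
        table, y, _ = generate_feature_cohort(200, 12, 2, 1.2, seed=8)
        tr = slice(0, 140)
        m1 = build_signature(table.iloc[tr], y[tr], SelectionConfig(seed=1))
        scrambled = table.copy()
        scrambled.iloc[140:] = scrambled.iloc[140:].sample(frac=1.0, random_state=0).to_numpy()
        m2 = build_signature(scrambled.iloc[tr], y[tr], SelectionConfig(seed=1))
        assert m1.intercept == m2.intercept
        assert m1.coefficients == m2.coefficients
        assert m1.normalization == m2.normalization
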