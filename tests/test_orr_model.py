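"""Lasso ORR model: shrinkage limits, a coordinate-descent oracle at fixed
penalty, prediction semantics of the published equation, and
leave-one-cancer-type-out validation."""

import math

import numpy as np
import pandas as pd
import pytest

import methorr as m
from methorr.orr_model import fit_lasso, loocv, predict_cohort, predict_orr


def _profiles_from_matrix(X: np.ndarray, codes, probes) -> pd.DataFrame:
    """Rows = cancer types in X → probes × cancer-types DataFrame."""
    return pd.DataFrame(X.T, index=probes, columns=codes)


def _lasso_coordinate_descent(X, y, alpha, n_iter=20_000, tol=1e-14):
    """Independent oracle: cyclic coordinate descent on the scikit-learn
    objective (1/2n)·||y − a − Xb||² + alpha·Σ|b|, X already standardised."""
    n, p = X.shape
    b = np.zeros(p)
    a = y.mean()
    col_sq = (X**2).sum(axis=0) / n
    for _ in range(n_iter):
        b_old = b.copy()
        r = y - a - X @ b
        for j in range(p):
            r = r + X[:, j] * b[j]
            rho_j = (X[:, j] @ r) / n
            b[j] = np.sign(rho_j) * max(abs(rho_j) - alpha, 0.0) / col_sq[j]
            r = r - X[:, j] * b[j]
        a = (y - X @ b).mean()
        if np.max(np.abs(b - b_old)) < tol:
            break
    return a, b


class TestFitLasso:
    def test_infinite_penalty_gives_intercept_only(self, orr_fixture, rng):
        probes = [f"cg{i}" for i in range(5)]
        profiles = _profiles_from_matrix(
            rng.random((18, 5)), orr_fixture.index, probes
        )
        model = fit_lasso(profiles, orr_fixture, lambda_=math.inf)
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(orr_fixture.mean())

    def test_fixed_penalty_matches_coordinate_descent_oracle(self, rng):
        codes = [f"C{i}" for i in range(5)]
        probes = ["p1", "p2", "p3"]
        X = rng.random((5, 3))
        y = rng.random(5) * 0.4
        alpha = 0.01
        model = fit_lasso(
            _profiles_from_matrix(X, codes, probes),
            pd.Series(y, index=codes),
            lambda_=alpha,
        )
        mean, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        a_std, b_std = _lasso_coordinate_descent((X - mean) / sd, y, alpha)
        expected = {}
        intercept = a_std
        for j, probe in enumerate(probes):
            if abs(b_std[j]) > 1e-10:
                expected[probe] = b_std[j] / sd[j]
                intercept -= b_std[j] * mean[j] / sd[j]
        assert model.intercept == pytest.approx(intercept, abs=1e-6)
        assert set(model.coefficients) == set(expected)
        for probe, coef in expected.items():
            assert model.coefficients[probe] == pytest.approx(coef, abs=1e-6)

    def test_support_non_increasing_in_penalty(self, small_profiles, small_cohort):
        screened = m.spearman_screen(small_profiles, small_cohort.orr)
        selected = screened.index[screened["passes"]]
        sizes = [
            len(fit_lasso(small_profiles.loc[selected], small_cohort.orr,
                          lambda_=lam).coefficients)
            for lam in (1e-5, 1e-3, 1e-2, 1e-1, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_row_order_invariance(self, small_profiles, small_cohort, rng):
        screened = m.spearman_screen(small_profiles, small_cohort.orr)
        selected = screened.index[screened["passes"]]
        profiles = small_profiles.loc[selected]
        a = fit_lasso(profiles, small_cohort.orr, seed=42)
        shuffled_cols = rng.permutation(profiles.columns)
        shuffled_rows = rng.permutation(profiles.index)
        b = fit_lasso(profiles.loc[shuffled_rows, shuffled_cols],
                      small_cohort.orr, seed=42)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)
        assert a.coefficients == pytest.approx(b.coefficients, abs=1e-12)
        assert a.lambda_ == b.lambda_

    def test_planted_probe_recovery(self):
        """3 planted probes among 200 at effect 0.95: the selected support
        recovers ≥90% of them across 20 seeded cohorts."""
        recovered = []
        for seed in range(20):
            config = m.SyntheticConfig(seed=seed, n_probes=200,
                                       n_informative_probes=3, effect_size=0.95)
            cohorts = m.simulate_cohorts(config)
            profiles = m.aggregate_to_cancer_profiles(cohorts.matrices)
            model = fit_lasso(profiles, cohorts.orr, seed=seed)
            planted = set(cohorts.truth["informative_probes"])
            recovered.append(len(planted & set(model.support)) / len(planted))
        assert np.mean(recovered) >= 0.90

    def test_too_few_cancer_types_rejected(self):
        profiles = pd.DataFrame({"A": [0.1], "B": [0.2]}, index=["cg01"])
        with pytest.raises(ValueError, match="3 cancer types"):
            fit_lasso(profiles, pd.Series({"A": 0.1, "B": 0.2}))


class TestPredict:
    def test_published_intercept_at_zero_betas(self):
        model = m.load_published_model(quiet=True)
        pred = predict_orr(model, {p: 0.0 for p in model.support})
        assert pred.value == pytest.approx(0.793)

    def test_published_coefficient_slope(self):
        model = m.load_published_model(quiet=True)
        base = {p: 0.5 for p in model.support}
        bumped = dict(base, cg24644201=0.6)
        delta = predict_orr(model, bumped).value - predict_orr(model, base).value
        assert delta == pytest.approx(0.1058, abs=1e-12)

    def test_hand_computed_toy_model(self):
        model = m.OrrLassoModel(intercept=0.1, coefficients={"c1": 0.5})
        assert predict_orr(model, {"c1": 0.4}).value == pytest.approx(0.3)

    def test_missing_probe_listed_in_error(self):
        model = m.OrrLassoModel(intercept=0.1, coefficients={"c1": 0.5, "c2": 0.1})
        with pytest.raises(KeyError, match="c2"):
            predict_orr(model, {"c1": 0.4})

    def test_out_of_range_flagged(self):
        model = m.OrrLassoModel(intercept=1.2, coefficients={"c1": 1.0})
        pred = predict_orr(model, {"c1": 0.5})
        assert pred.out_of_range
        assert pred.value == pytest.approx(1.7)

    def test_linearity_under_convex_combination(self, rng):
        model = m.OrrLassoModel(
            intercept=0.2, coefficients={f"c{i}": v for i, v in
                                         enumerate(rng.normal(size=4))}
        )
        u = {p: rng.random() for p in model.support}
        v = {p: rng.random() for p in model.support}
        for w in (0.0, 0.3, 1.0):
            mix = {p: w * u[p] + (1 - w) * v[p] for p in model.support}
            expected = (w * predict_orr(model, u).value
                        + (1 - w) * predict_orr(model, v).value)
            assert predict_orr(model, mix).value == pytest.approx(expected, abs=1e-12)


class TestPredictCohort:
    def test_identical_samples_equal_single_sample(self):
        model = m.OrrLassoModel(intercept=0.1, coefficients={"cg01": 0.5, "cg02": -0.2})
        beta = pd.DataFrame({"s1": [0.4, 0.6], "s2": [0.4, 0.6]},
                            index=["cg01", "cg02"])
        cohort = predict_cohort(model, beta)
        single = predict_orr(model, {"cg01": 0.4, "cg02": 0.6})
        assert cohort.value == pytest.approx(single.value)

    def test_two_sample_mean(self):
        model = m.OrrLassoModel(intercept=0.0, coefficients={"cg01": 1.0})
        beta = pd.DataFrame({"s1": [0.2], "s2": [0.4]}, index=["cg01"])
        assert predict_cohort(model, beta).value == pytest.approx(0.3)

    def test_missing_model_probe_rejected(self):
        model = m.OrrLassoModel(intercept=0.0, coefficients={"cgX": 1.0})
        beta = pd.DataFrame({"s1": [0.2]}, index=["cg01"])
        with pytest.raises(KeyError, match="cgX"):
            predict_cohort(model, beta)


class TestLoocv:
    def test_noiseless_planted_signal_ranks_perfectly(self, orr_fixture):
        codes = orr_fixture.index
        probes = [f"cg{i}" for i in range(6)]
        X = np.column_stack([
            0.2 + 1.5 * orr_fixture.to_numpy() * (1 + 0.1 * j) for j in range(6)
        ])
        profiles = _profiles_from_matrix(X, codes, probes)
        result = loocv(profiles, orr_fixture, seed=0)
        assert result.rho == pytest.approx(1.0)
        assert not result.pairs["fallback"].any()

    def test_no_signal_falls_back_to_training_mean(self, orr_fixture, rng):
        profiles = _profiles_from_matrix(
            rng.random((18, 10)) * 0.01 + 0.5, orr_fixture.index,
            [f"cg{i}" for i in range(10)]
        )
        result = loocv(profiles, orr_fixture, seed=0)
        fallback = result.pairs[result.pairs["fallback"]]
        assert len(fallback) > 0
        for code, row in fallback.iterrows():
            assert row["predicted"] == pytest.approx(orr_fixture.drop(code).mean())

    def test_too_few_cancer_types_rejected(self):
        profiles = pd.DataFrame({"A": [0.1], "B": [0.2], "C": [0.3]}, index=["cg01"])
        orr = pd.Series({"A": 0.1, "B": 0.2, "C": 0.3})
        with pytest.raises(ValueError, match="4 cancer types"):
            loocv(profiles, orr)


def test_model_json_round_trip(tmp_path):
    model = m.OrrLassoModel(intercept=0.7, coefficients={"cg01": -0.5, "cg02": 1.1},
                            lambda_=0.01, cv_mse=0.004,
                            training_meta={"cancer_codes": ["A", "B", "C"]})
    path = tmp_path / "model.json"
    m.save_model(model, path)
    back = m.load_model(path)
    assert back == model
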