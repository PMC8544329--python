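"""Final OLS age model, tuning split, cross-application, model combination."""

import numpy as np
import pandas as pd
import pytest

from immunage import (ImmuneAgeModel, ImmuneAgeResults, PenalizedSpec,
                      SimulationConfig, combine_models, fit_final,
                      generate_cohort)

FAST = PenalizedSpec(alpha_grid=(0.1, 0.5, 1.0), n_cv_repeats=3, n_folds=5,
                     n_bootstrap=30, retain_threshold=15, seed=0)


def test_exact_linear_relationship_recovered(rng):
    x1 = rng.uniform(-5, 5, 50)
    feats = pd.DataFrame({"x1": x1})
    age = 2.0 * x1 + 30.0
    res = fit_final(feats, age)
    assert res.metrics["r_squared"] == pytest.approx(1.0, abs=1e-12)
    assert res.metrics["rmse"] == pytest.approx(0.0, abs=1e-9)
    # coefficients are per standardized unit; back out the raw slope/intercept
    raw_slope = res.coefficients["x1"] / res.scale["x1"]
    raw_intercept = res.intercept - float(
        (res.coefficients * res.center / res.scale).sum())
    assert raw_slope == pytest.approx(2.0, abs=1e-9)
    assert raw_intercept == pytest.approx(30.0, abs=1e-9)


def test_intercept_only_model_predicts_mean_age(rng):
    age = rng.uniform(20, 70, 30)
    res = fit_final(pd.DataFrame(index=range(30)), age, allow_empty=True)
    assert res.intercept == pytest.approx(age.mean())
    assert res.metrics["r_squared"] == pytest.approx(0.0, abs=1e-12)
    pred = res.predict(pd.DataFrame(index=range(5)))
    np.testing.assert_allclose(pred.to_numpy(), age.mean())


def test_final_fit_matches_independent_regression_routine(rng):
    """Cross-check R^2/RMSE against a second implementation (scikit-learn)."""
    from sklearn.linear_model import LinearRegression
    from sklearn.metrics import mean_squared_error, r2_score
    X = pd.DataFrame(rng.standard_normal((80, 6)),
                     columns=[f"f{j}" for j in range(6)])
    age = 45 + X.iloc[:, 0] * 5 - X.iloc[:, 1] * 3 + rng.standard_normal(80)
    res = fit_final(X, age)
    lr = LinearRegression().fit(X, age)
    pred = lr.predict(X)
    assert res.metrics["r_squared"] == pytest.approx(r2_score(age, pred),
                                                     abs=1e-10)
    assert res.metrics["rmse"] == pytest.approx(
        np.sqrt(mean_squared_error(age, pred)), abs=1e-10)


def test_collinear_retained_set_names_dependent_subset(rng):
    a = rng.standard_normal(40)
    X = pd.DataFrame({"a": a, "b": 2 * a + 1, "c": rng.standard_normal(40)})
    with pytest.raises(ValueError, match="collinear"):
        fit_final(X, rng.uniform(20, 70, 40))


def test_predict_on_training_data_reproduces_fitted_values(rng):
    X = pd.DataFrame(rng.standard_normal((50, 4)))
    X.columns = [str(c) for c in X.columns]
    age = 40 + X.iloc[:, 0] * 6 + rng.standard_normal(50)
    res = fit_final(X, age)
    np.testing.assert_allclose(res.predict(X).to_numpy(),
                               res.fitted_values.to_numpy(), atol=1e-10)


def test_prediction_at_training_means_equals_intercept(rng):
    X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
    age = rng.uniform(20, 70, 50)
    res = fit_final(X, age)
    at_means = res.center.to_frame().T
    assert res.predict(at_means).iloc[0] == pytest.approx(res.intercept,
                                                          abs=1e-10)


def test_predict_lists_missing_parameters(rng):
    X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
    res = fit_final(X, rng.uniform(20, 70, 30))
    with pytest.raises(KeyError, match="'b'"):
        res.predict(X[["a", "c"]])


def _planted_cohort(seed=0, n_per_group=60, rho=0.8):
    cfg = SimulationConfig(n_per_group=n_per_group, n_features=40,
                           n_shared_age=6, n_groupA_only=0, n_groupB_only=0,
                           n_opposite=0, effect_rho=rho, n_plasma=0,
                           group_index_shift=0.0, aging_rate_multiplier=1.0,
                           seed=seed)
    return generate_cohort(cfg)


def test_tune_is_deterministic_and_reports_heldout_metrics():
    c = _planted_cohort()
    model = ImmuneAgeModel(c.features, c.cohort["age"], spec=FAST, group="HC")
    a = model.tune()
    b = ImmuneAgeModel(c.features, c.cohort["age"], spec=FAST,
                       group="HC").tune()
    assert a.parameters == b.parameters
    pd.testing.assert_series_equal(a.coefficients, b.coefficients)
    assert a.test_metrics == b.test_metrics
    assert a.test_metrics["rmse"] >= 0
    assert set(a.importance.index) == set(a.parameters)


def test_permutation_importance_ranks_signal_over_noise():
    c = _planted_cohort(seed=4, n_per_group=80, rho=0.9)
    model = ImmuneAgeModel(c.features, c.cohort["age"], spec=FAST, group="HC")
    res = model.tune()
    planted = set(c.truth)
    retained_planted = [p for p in res.parameters if p in planted]
    assert retained_planted, "no planted feature retained"
    imp = res.importance
    # the strongest importance belongs to a planted feature...
    assert imp.idxmax() in planted
    # ...and permuting retained noise columns barely moves test RMSE
    noise = [p for p in res.parameters if p not in planted]
    if noise:
        assert imp[noise].abs().max() < imp[retained_planted].max()


def test_summary_mentions_key_quantities():
    c = _planted_cohort()
    res = ImmuneAgeModel(c.features, c.cohort["age"], spec=FAST,
                         group="HC").tune()
    text = res.summary()
    assert "alpha*" in text and "R^2" in text and "intercept" in text


def test_json_roundtrip_preserves_predictions(tmp_path):
    c = _planted_cohort()
    res = ImmuneAgeModel(c.features, c.cohort["age"], spec=FAST,
                         group="HC").tune()
    res.to_json(tmp_path / "m.json")
    back = ImmuneAgeResults.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(back.predict(c.features).to_numpy(),
                               res.predict(c.features).to_numpy(), atol=1e-12)


def test_combine_is_idempotent_for_identical_models(rng):
    X = pd.DataFrame(rng.standard_normal((60, 5)), columns=list("abcde"))
    age = 40 + X["a"] * 6 + X["b"] * 3 + rng.standard_normal(60)
    res = fit_final(X[["a", "b"]], age, group="G1")
    comb = combine_models(res, res, {"G1": X}, {"G1": np.asarray(age)})
    assert comb.parameters == ["a", "b"]
    np.testing.assert_allclose(comb.per_group["G1"].coefficients,
                               res.coefficients, atol=1e-10)


def test_combine_union_order_and_cardinality(rng):
    X = pd.DataFrame(rng.standard_normal((60, 7)), columns=list("abcdefg"))
    age = rng.uniform(20, 70, 60)
    ra = fit_final(X[["a", "b", "c"]], age, group="G1")
    rb = fit_final(X[["d", "e", "f", "g"]], age, group="G2")
    comb = combine_models(ra, rb, {"G1": X, "G2": X},
                          {"G1": np.asarray(age), "G2": np.asarray(age)})
    assert comb.parameters == ["a", "b", "c", "d", "e", "f", "g"]
    assert comb.union_size == 7
    # overlapping sets: 3 + 4 with 2 common -> union 5
    rc = fit_final(X[["c", "d", "e", "f"]], age, group="G2")
    comb2 = combine_models(ra, rc, {"G1": X, "G2": X},
                           {"G1": np.asarray(age), "G2": np.asarray(age)})
    assert comb2.parameters == ["a", "b", "c", "d", "e", "f"]


def test_combine_rejects_inestimable_union(rng):
    X = pd.DataFrame(rng.standard_normal((8, 7)), columns=list("abcdefg"))
    age = rng.uniform(20, 70, 8)
    ra = fit_final(X[["a", "b", "c"]], age, group="G1")
    rb = fit_final(X[["d", "e", "f", "g"]], age, group="G2")
    with pytest.raises(ValueError, match="estimable"):
        combine_models(ra, rb, {"G1": X, "G2": X},
                       {"G1": np.asarray(age), "G2": np.asarray(age)})


def test_cross_application_loses_accuracy_on_group_without_effects():
    """A model trained on group-A-specific signal degrades on group B."""
    cfg = SimulationConfig(n_per_group=100, n_features=30, n_shared_age=0,
                           n_groupA_only=8, n_groupB_only=0, n_opposite=0,
                           effect_rho=0.8, n_plasma=0, group_index_shift=0.0,
                           aging_rate_multiplier=1.0, seed=2)
    c = generate_cohort(cfg)
    hc = c.group_mask("HC")
    model = ImmuneAgeModel(c.features[hc], c.cohort.loc[hc, "age"],
                           spec=FAST, group="HC")
    res = model.tune()
    r2_own = res.test_metrics["r_squared"]
    from immunage.agemodel import _metrics
    hiv = ~hc
    r2_cross = _metrics(c.cohort.loc[hiv, "age"].to_numpy(),
                        res.predict(c.features[hiv]).to_numpy())["r_squared"]
    assert r2_own > 0.3
    assert r2_cross <= 0.5 * r2_own
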