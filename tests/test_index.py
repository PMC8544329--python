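"""Inflammatory index: stepwise selection, PC1 weighting, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunage import (InflammatoryIndex, InflammatoryIndexResults,
                      backward_stepwise_select, contrast_index_by_group,
                      generate_cohort)
from immunage.index import _aic
from immunage.simulate import SimulationConfig


def test_dominant_exact_predictor_is_sole_survivor(rng):
    age = rng.uniform(20, 70, 100)
    plasma = pd.DataFrame({"marker1": age,
                           "marker2": rng.standard_normal(100),
                           "marker3": rng.standard_normal(100)})
    assert backward_stepwise_select(plasma, age) == ["marker1"]


def test_stepwise_criterion_never_worse_than_full_model(rng):
    for _ in range(5):
        age = rng.uniform(20, 70, 60)
        plasma = pd.DataFrame(rng.standard_normal((60, 8)),
                              columns=[f"m{j}" for j in range(8)])
        plasma["m0"] += 0.05 * age
        kept = backward_stepwise_select(plasma, age)
        full = _aic(age, plasma.to_numpy(float))
        final = _aic(age, plasma[kept].to_numpy(float))
        assert final <= full + 1e-12


def test_stepwise_rejects_collinear_design(rng):
    age = rng.uniform(20, 70, 50)
    a = rng.standard_normal(50)
    plasma = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.standard_normal(50)})
    with pytest.raises(ValueError, match="collinear"):
        backward_stepwise_select(plasma, age)


def test_pvalue_criterion_variant_drops_noise(rng):
    age = rng.uniform(20, 70, 120)
    plasma = pd.DataFrame({"signal": age + rng.standard_normal(120),
                           "noise1": rng.standard_normal(120),
                           "noise2": rng.standard_normal(120)})
    kept = backward_stepwise_select(plasma, age, criterion="pvalue")
    assert "signal" in kept and "noise1" not in kept


def test_two_perfectly_correlated_markers_share_weight(rng):
    base = rng.standard_normal(40)
    age = np.sort(rng.uniform(20, 70, 40))
    plasma = pd.DataFrame({"m1": base, "m2": 3.0 * base + 7.0})
    res = InflammatoryIndex(plasma, age, selection="none").fit()
    np.testing.assert_allclose(np.abs(res.weights), 1 / np.sqrt(2), atol=1e-9)


def test_weights_are_unit_norm(small_cohort):
    c = small_cohort
    res = InflammatoryIndex(c.plasma, c.cohort["age"]).fit()
    assert np.sum(res.weights ** 2) == pytest.approx(1.0, abs=1e-12)


def test_hand_arithmetic_score():
    res = InflammatoryIndexResults(
        markers=["m1", "m2"],
        center=pd.Series({"m1": 10.0, "m2": 20.0}),
        scale=pd.Series({"m1": 2.0, "m2": 5.0}),
        weights=pd.Series({"m1": 0.6, "m2": 0.8}),
        sign=1, selection="none")
    score = res.score(pd.DataFrame({"m1": [12.0], "m2": [25.0]}))
    assert score.iloc[0] == pytest.approx(0.6 * 1 + 0.8 * 1)  # = 1.4


def test_participant_at_marker_centers_scores_zero(small_cohort):
    c = small_cohort
    res = InflammatoryIndex(c.plasma, c.cohort["age"]).fit()
    at_center = res.center.to_frame().T
    assert res.score(at_center).iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_affine_rescaling_invariance_after_refit(small_cohort):
    c = small_cohort
    age = c.cohort["age"]
    res = InflammatoryIndex(c.plasma, age, selection="none").fit()
    rng = np.random.default_rng(1)
    scales = rng.uniform(0.5, 20.0, c.plasma.shape[1])
    shifts = rng.uniform(-50.0, 50.0, c.plasma.shape[1])
    rescaled = c.plasma * scales + shifts
    res2 = InflammatoryIndex(rescaled, age, selection="none").fit()
    np.testing.assert_allclose(res2.fitted_scores.to_numpy(),
                               res.fitted_scores.to_numpy(), atol=1e-9)


def test_sign_convention_nonnegative_age_correlation(small_cohort):
    c = small_cohort
    res = InflammatoryIndex(c.plasma, c.cohort["age"]).fit()
    rho = stats.spearmanr(res.fitted_scores, c.cohort["age"]).statistic
    assert rho >= 0


def test_fitted_weights_rank_match_planted_loadings():
    """Well-separated planted loadings are recovered in rank order by PC1."""
    cfg = SimulationConfig(n_per_group=200, n_features=6, n_shared_age=0,
                           n_groupA_only=0, n_groupB_only=0, n_opposite=0,
                           effect_rho=0.5, n_plasma=4, inflammatory_loading=0.9,
                           group_index_shift=0.0, aging_rate_multiplier=1.0,
                           seed=3)
    c = generate_cohort(cfg)
    res = InflammatoryIndex(c.plasma, c.cohort["age"], selection="none").fit()
    fitted_order = res.weights.abs().rank(ascending=False)
    planted_order = c.plasma_loadings.rank(ascending=False)
    assert (fitted_order == planted_order).all()


def test_zero_variance_marker_named(rng):
    age = rng.uniform(20, 70, 30)
    plasma = pd.DataFrame({"flat": np.ones(30),
                           "ok": rng.standard_normal(30)})
    with pytest.raises(ValueError, match="flat"):
        InflammatoryIndex(plasma, age, selection="none").fit()


def test_score_reports_missing_markers(small_cohort):
    c = small_cohort
    res = InflammatoryIndex(c.plasma, c.cohort["age"]).fit()
    stripped = c.plasma.drop(columns=res.markers[:1])
    with pytest.raises(KeyError, match=res.markers[0]):
        res.score(stripped)


def test_json_roundtrip_preserves_scores(tmp_path, small_cohort):
    c = small_cohort
    res = InflammatoryIndex(c.plasma, c.cohort["age"]).fit()
    res.to_json(tmp_path / "idx.json")
    back = InflammatoryIndexResults.from_json(tmp_path / "idx.json")
    np.testing.assert_allclose(back.score(c.plasma).to_numpy(),
                               res.score(c.plasma).to_numpy(), atol=1e-12)


def test_contrast_identical_groups_is_null():
    scores = np.concatenate([np.arange(10.0), np.arange(10.0)])
    groups = np.array(["A"] * 10 + ["B"] * 10)
    out = contrast_index_by_group(scores, groups)
    assert out.difference == pytest.approx(0.0)
    assert out.p == pytest.approx(1.0)


def test_contrast_direction_follows_planted_shift(small_cohort):
    c = small_cohort   # group_index_shift > 0 in the HIV group
    res = InflammatoryIndex(c.plasma, c.cohort["age"]).fit()
    out = res.contrast(c.features, c.cohort["group"].to_numpy())
    shifted = out.labels.index("HIV")
    assert out.means[shifted] > out.means[1 - shifted]


def test_contrast_significant_at_adequate_sample_size():
    cfg = SimulationConfig(n_per_group=300, n_features=12, n_shared_age=0,
                           n_groupA_only=0, n_groupB_only=0, n_opposite=0,
                           effect_rho=0.5, n_plasma=10, group_index_shift=0.8,
                           aging_rate_multiplier=1.0, seed=9)
    c = generate_cohort(cfg)
    res = InflammatoryIndex(c.plasma, c.cohort["age"], selection="none").fit()
    out = res.contrast(c.features, c.cohort["group"].to_numpy())
    shifted = out.labels.index("HIV")
    assert out.means[shifted] > out.means[1 - shifted]
    assert out.p < 0.05


def test_contrast_null_rejection_rate_calibrated():
    """Under the null configuration the Welch test rejects at ~alpha."""
    rejections = 0
    n_rep = 200
    for seed in range(n_rep):
        cfg = SimulationConfig(n_per_group=25, n_features=8, n_shared_age=0,
                               n_groupA_only=0, n_groupB_only=0, n_opposite=0,
                               effect_rho=0.5, n_plasma=6,
                               group_index_shift=0.0,
                               aging_rate_multiplier=1.0, seed=seed)
        c = generate_cohort(cfg)
        res = InflammatoryIndex(c.plasma, c.cohort["age"], selection="none").fit()
        out = res.contrast(c.features, c.cohort["group"].to_numpy())
        rejections += out.p < 0.05
    rate = rejections / n_rep
    tol = 3 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) <= tol


def test_contrast_requires_two_groups():
    with pytest.raises(ValueError, match="two group"):
        contrast_index_by_group(np.arange(6.0), np.array(["A"] * 6))
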