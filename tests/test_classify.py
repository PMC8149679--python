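"""Grade classifier: fits, likelihood-ratio oracles, responsible vectors, CV."""

import numpy as np
import pytest
from scipy import optimize

from vqradiomics.classify import (
    GradeModel,
    crossvalidate,
    effect_lr_test,
    fit_grade_model,
    identify_responsible_vectors,
    metrics_from_confusion,
    penalized_objective,
    univariate_lr_test,
)
from vqradiomics.histogram import HistogramFeature


def _hists(counts, grades):
    counts = np.asarray(counts)
    return [
        HistogramFeature(counts=c.astype(np.int64), volume_id=f"v{i}", n_slices=1,
                         latent_positions_per_slice=int(c.sum()), grade=int(g))
        for i, (c, g) in enumerate(zip(counts, grades))
    ]


def _simulate(n=40, k=6, seed=0, strength=1.0):
    """Non-separable synthetic counts with one informative codeword (column 0)."""
    rng = np.random.default_rng(seed)
    x = rng.poisson(20, size=(n, k)).astype(float)
    eta = strength * (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    if min(y.sum(), n - y.sum()) < 2:  # pragma: no cover - seed chosen to avoid
        raise AssertionError("degenerate simulation")
    return _hists(x, y), y


def test_separable_counts_fit_with_fallback():
    counts = np.zeros((10, 4))
    counts[:, 1] = [1, 2, 1, 2, 1, 30, 31, 32, 30, 33]
    counts[:, 2] = 10
    grades = [0] * 5 + [1] * 5
    with pytest.warns(RuntimeWarning, match="falling back"):
        model = fit_grade_model(_hists(counts, grades), regularization="none")
    assert model.regularization == "l2"
    x = counts
    assert np.array_equal(model.predict(x), grades)


def test_zero_coefficient_model_predicts_logistic_intercept():
    model = GradeModel(intercept=0.4, coefficients=np.zeros(3),
                       feature_subset=np.arange(3), regularization="none",
                       l2_lambda=0.0, feature_means=np.zeros(3),
                       feature_stds=np.ones(3), objective=0.0, converged=True,
                       n_samples=4)
    p = model.predict_proba(np.arange(12).reshape(4, 3))
    np.testing.assert_allclose(p, 1 / (1 + np.exp(-0.4)))


def test_fitted_likelihood_at_least_null():
    hists, y = _simulate(seed=1)
    model = fit_grade_model(hists, regularization="none")
    assert model.regularization == "none"
    n1, n = y.sum(), len(y)
    ll_null = n1 * np.log(n1 / n) + (n - n1) * np.log(1 - n1 / n)
    assert model.objective >= ll_null - 1e-9


def test_effect_lr_statistic_matches_independent_recomputation():
    """2*(l_full - l_reduced) recomputed from scratch with scipy.optimize."""
    hists, y = _simulate(n=60, k=4, seed=2)
    model = fit_grade_model(hists, regularization="none")
    res = effect_lr_test(model, hists)

    x = np.stack([h.counts for h in hists]).astype(float)
    xs = (x - x.mean(0)) / np.where(x.std(0) < 1e-12, 1.0, x.std(0))

    def nll(params, cols):
        eta = params[0] + xs[:, cols] @ params[1:]
        return -(y @ eta - np.logaddexp(0, eta).sum())

    def ml(cols):
        out = optimize.minimize(nll, np.zeros(len(cols) + 1), args=(list(cols),),
                                method="BFGS", options={"gtol": 1e-10})
        return -out.fun

    full = ml(range(4))
    for k in range(4):
        reduced = ml([c for c in range(4) if c != k])
        expected = max(2 * (full - reduced), 0.0)
        assert res.statistic[k] == pytest.approx(expected, abs=1e-6)
    # statistics are nonnegative and p-values valid
    assert np.all(res.statistic >= 0)
    assert np.all((res.p_value >= 0) & (res.p_value <= 1))


def test_effect_lr_penalized_objective_recomputation():
    """Under the l2 fallback the statistic uses the penalized objective,
    which an independent evaluation of the stored coefficients reproduces."""
    counts = np.zeros((12, 3))
    counts[:, 0] = [0, 1, 0, 2, 1, 0, 9, 8, 9, 10, 9, 8]
    counts[:, 1] = np.arange(12)
    grades = [0] * 6 + [1] * 6
    hists = _hists(counts, grades)
    model = fit_grade_model(hists, regularization="l2", l2_lambda=1.0)
    x = counts.copy()
    xs = (x - model.feature_means) / model.feature_stds
    obj = penalized_objective(xs, np.array(grades), model.intercept,
                              model.coefficients, 1.0)
    assert model.objective == pytest.approx(obj, abs=1e-9)
    res = effect_lr_test(model, hists)
    assert np.all(res.statistic[np.isfinite(res.statistic)] >= 0)


def test_uninformative_codeword_has_unit_pvalue():
    hists, _ = _simulate(n=30, k=3, seed=3)
    for h in hists:
        h.counts[2] = 7  # constant across volumes
    model = fit_grade_model(hists, regularization="none")
    res = effect_lr_test(model, hists)
    assert res.statistic[2] == pytest.approx(0.0, abs=1e-8)
    assert res.p_value[2] == pytest.approx(1.0, abs=1e-8)
    uni = univariate_lr_test(hists)
    assert uni.p_value[2] == 1.0


def test_planted_covariate_beats_noise():
    """On simulated counts the planted covariate's LR statistic dominates."""
    hists, _ = _simulate(n=100, k=5, seed=11, strength=2.0)
    model = fit_grade_model(hists, regularization="none")
    res = effect_lr_test(model, hists)
    assert res.statistic[0] > np.max(res.statistic[1:])
    uni = univariate_lr_test(hists)
    assert uni.statistic[0] > np.max(uni.statistic[1:])


def test_univariate_separation_gives_extreme_statistic():
    counts = np.zeros((10, 2))
    counts[:, 0] = [1, 2, 3, 2, 1, 50, 52, 51, 49, 50]
    hists = _hists(counts, [0] * 5 + [1] * 5)
    uni = univariate_lr_test(hists)
    # complete separation: statistic equals the null deviance
    assert uni.statistic[0] == pytest.approx(-2 * 10 * np.log(0.5), abs=1e-9)
    assert uni.p_value[1] == 1.0


def test_identify_responsible_vectors_directions():
    rng = np.random.default_rng(5)
    n = 20
    counts = np.zeros((2 * n, 4))
    counts[:, 0] = np.concatenate([rng.integers(0, 3, n), rng.integers(30, 40, n)])
    counts[:, 1] = np.concatenate([rng.integers(30, 40, n), rng.integers(0, 3, n)])
    counts[:, 2] = 5  # identical across classes -> excluded
    counts[:, 3] = rng.integers(10, 20, 2 * n)
    grades = [0] * n + [1] * n
    hists = _hists(counts, grades)
    uni = univariate_lr_test(hists)
    rv = identify_responsible_vectors(hists, lr_pvalues=uni.p_value)
    assert rv.hgg_responsible == [0]
    assert rv.lgg_responsible == [1]
    assert 2 not in rv.hgg_responsible + rv.lgg_responsible
    # every HGG-responsible codeword is more frequent in class-1 volumes
    rec = rv.records.set_index("codeword")
    assert rec.loc[0, "mean_count_hgg"] > rec.loc[0, "mean_count_lgg"]
    # the exclude list removes candidates outright
    rv2 = identify_responsible_vectors(hists, lr_pvalues=uni.p_value, exclude=(0,))
    assert rv2.hgg_responsible == []


def test_identify_with_signed_rank_option():
    rng = np.random.default_rng(6)
    counts = np.zeros((20, 2))
    counts[:, 0] = np.concatenate([rng.integers(0, 3, 10), rng.integers(20, 30, 10)])
    hists = _hists(counts, [0] * 10 + [1] * 10)
    uni = univariate_lr_test(hists)
    rv = identify_responsible_vectors(hists, lr_pvalues=uni.p_value, test="signed-rank")
    assert rv.test_used == "signed-rank"
    assert rv.hgg_responsible == [0]


def test_metrics_from_confusion_arithmetic():
    m = metrics_from_confusion(tp=3, fp=1, fn=1, tn=5)
    assert m["precision"] == pytest.approx(0.75)
    assert m["recall"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(5 / 6)
    assert m["npv"] == pytest.approx(5 / 6)
    assert m["accuracy"] == pytest.approx(0.8)


def test_crossvalidate_deterministic_and_accurate():
    rng = np.random.default_rng(7)
    n = 20
    counts = np.zeros((2 * n, 6))
    counts[:, 0] = np.concatenate([rng.integers(0, 5, n), rng.integers(25, 40, n)])
    counts[:, 1:] = rng.integers(0, 30, (2 * n, 5))
    hists = _hists(counts, [0] * n + [1] * n)
    r1 = crossvalidate(hists, k_folds=5, seed=9)
    r2 = crossvalidate(hists, k_folds=5, seed=9)
    assert r1.per_fold.equals(r2.per_fold)
    assert r1.mean["accuracy"] >= 0.9
    assert r1.final_model is not None
    with pytest.raises(ValueError):
        crossvalidate(hists, k_folds=1)


def test_fit_requires_two_per_class():
    hists = _hists(np.ones((3, 2)), [0, 1, 1])
    with pytest.raises(ValueError):
        fit_grade_model(hists)
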