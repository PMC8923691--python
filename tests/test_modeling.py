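"""Metrics, estimators, stepwise selection, and grouped cross-validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold

from renaltlco.modeling import (
    CvConfig,
    RsvmConfig,
    _grouped_folds,
    fit_rrf,
    fit_rsvm,
    forward_stepwise_select,
    multiple_regression_baseline,
    pearson_correlation,
    rmse,
    subject_cv_evaluate,
)


def test_rmse_examples_and_oracle():
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse([4, 5, 6], [1, 2, 3]) == pytest.approx(3.0)
    assert rmse([1, 2, 3], [2, 2, 5]) == pytest.approx(np.sqrt(5 / 3), abs=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(10):
        f, t = rng.normal(size=50), rng.normal(size=50)
        oracle = np.sqrt(np.sum((f - t) ** 2) / 50)  # literal formula
        assert rmse(f, t) == pytest.approx(oracle, abs=1e-10)
    with pytest.raises(ValueError):
        rmse([1, 2], [1])


def test_pearson_examples_and_oracle():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_correlation(2 * t + 5, t) == pytest.approx(1.0)
    assert pearson_correlation(-t, t) == pytest.approx(-1.0)
    assert pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)
    rng = np.random.default_rng(1)
    for _ in range(10):
        f, v = rng.normal(size=40), rng.normal(size=40)
        # (N-1)-normalised textbook formula
        oracle = np.sum(
            (f - f.mean()) * (v - v.mean())
        ) / ((40 - 1) * f.std(ddof=1) * v.std(ddof=1))
        assert pearson_correlation(f, v) == pytest.approx(oracle, abs=1e-10)
    with pytest.raises(ValueError):
        pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_robust_scale_rule_estimates_sd():
    rng = np.random.default_rng(2)
    y = rng.normal(10.0, 3.0, size=20000)
    iqr = np.subtract(*np.percentile(y, [75, 25]))
    assert iqr / 1.349 == pytest.approx(y.std(), rel=0.05)


def _planted(n=100, p=10, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    y = 3.0 * x[:, 0] + noise * rng.normal(size=n)
    return x, y


def test_rsvm_fits_planted_signal():
    x, y = _planted()
    model = fit_rsvm(x, y, RsvmConfig(rng_seed=0))
    r = pearson_correlation(model.predict(x), y)
    assert r >= 0.99
    # beats the mean-only predictor in-sample
    assert rmse(model.predict(x), y) <= rmse(np.full_like(y, y.mean()), y)


def test_rsvm_deterministic_for_duplicates():
    x, y = _planted(n=40)
    x2, y2 = np.vstack([x, x[:5]]), np.concatenate([y, y[:5]])
    model = fit_rsvm(x2, y2)
    p = model.predict(x2)
    assert np.allclose(p[:5], p[40:])


def test_rsvm_permuted_labels_give_null_cv():
    rng = np.random.default_rng(3)
    x, y = _planted(n=100)
    y_perm = rng.permutation(y)
    preds = np.empty(100)
    for tr, te in KFold(5, shuffle=True, random_state=0).split(x):
        preds[te] = fit_rsvm(x[tr], y_perm[tr]).predict(x[te])
    assert abs(pearson_correlation(preds, y_perm)) < 0.3


def test_rrf_importance_and_determinism():
    x, y = _planted(n=120, seed=4)
    model = fit_rrf(x, y, rng_seed=7)
    assert np.argmax(model.details["importances"]) == 0
    again = fit_rrf(x, y, rng_seed=7)
    assert np.allclose(model.predict(x), again.predict(x))


def test_rrf_ensemble_beats_single_tree():
    rng = np.random.default_rng(5)
    deltas = []
    for rep in range(5):
        x = rng.normal(size=(60, 5))
        y = x[:, 0] + rng.normal(0, 1.0, size=60)
        e_big, e_one = [], []
        for tr, te in KFold(3, shuffle=True, random_state=rep).split(x):
            e_big.append(rmse(fit_rrf(x[tr], y[tr], 300, rep).predict(x[te]), y[te]))
            e_one.append(rmse(fit_rrf(x[tr], y[tr], 1, rep).predict(x[te]), y[te]))
        deltas.append(np.mean(e_one) - np.mean(e_big))
    assert np.median(deltas) >= 0


def test_ols_baseline_exact_recovery_and_oracle():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(100, 12))
    beta = rng.normal(size=12)
    y = x @ beta + 2.0
    report = multiple_regression_baseline(x, y, rng_seed=0)
    assert report.pearson_r >= 0.999
    assert report.rmse < 1e-8

    # coefficients equal the normal-equations solution on a fixed matrix
    from renaltlco.modeling import _ols_fit

    x20 = rng.normal(size=(20, 12))
    y20 = rng.normal(size=20)
    design = np.column_stack([np.ones(20), x20])
    oracle = np.linalg.solve(design.T @ design, design.T @ y20)
    assert np.allclose(_ols_fit(x20, y20), oracle, atol=1e-9)


def test_ols_baseline_null_is_near_zero():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(100, 12))
    y = rng.normal(size=100)
    report = multiple_regression_baseline(x, y, rng_seed=0)
    assert abs(report.pearson_r) < 0.3


def test_stepwise_selects_informative_feature_first():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(60, 21))
        y = 2.0 * x[:, 7] + 0.3 * rng.normal(size=60)
        sel, _ = forward_stepwise_select(
            x, y, lambda a, b: fit_rsvm(a, b), max_features=1
        )
        hits += sel[0] == 7
    assert hits >= 18


def test_stepwise_trace_and_stopping():
    x, y = _planted(n=60, p=6, seed=8)
    factory = lambda a, b: fit_rsvm(a, b)
    sel, trace = forward_stepwise_select(x, y, factory, tolerance=np.inf)
    assert len(sel) == 1  # infinite tolerance stops immediately

    sel, trace = forward_stepwise_select(x, y, factory, max_features=5)
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))  # non-increasing


def test_grouped_folds_partition():
    groups = np.array([f"s{i}" for i in range(23)])
    seen = np.zeros(23, dtype=int)
    for tr, te in _grouped_folds(groups, 5, rng_seed=0):
        assert set(tr) | set(te) == set(range(23))
        assert not set(tr) & set(te)
        seen[te] += 1
    assert (seen == 1).all()  # every subject tested exactly once
    with pytest.raises(ValueError):
        list(_grouped_folds(groups[:3], 5, 0))


def test_subject_cv_shuffled_targets_are_null():
    rng = np.random.default_rng(9)
    x = pd.DataFrame(
        rng.normal(size=(80, 30)),
        index=[f"s{i}" for i in range(80)],
        columns=[f"f{j}" for j in range(30)],
    )
    y = rng.normal(60, 20, size=80)
    report = subject_cv_evaluate(x, y, CvConfig(rng_seed=0, screen_size=10, max_features=5))
    assert abs(report.pearson_r) < 0.3


def test_leakage_free_selection_is_less_optimistic():
    """Selecting features on all data then cross-validating inflates r on
    pure-noise data; per-fold re-selection must not show that bias."""
    rng = np.random.default_rng(12)
    x = pd.DataFrame(
        rng.normal(size=(60, 120)),
        index=[f"s{i}" for i in range(60)],
        columns=[f"f{j}" for j in range(120)],
    )
    y = rng.normal(size=60)
    kwargs = dict(rng_seed=0, screen_size=20, max_features=4)
    leaky = subject_cv_evaluate(x, y, CvConfig(leakage_free=False, **kwargs))
    clean = subject_cv_evaluate(x, y, CvConfig(leakage_free=True, **kwargs))
    assert clean.pearson_r < leaky.pearson_r


def test_rsvm_input_contracts():
    with pytest.raises(ValueError):
        fit_rsvm(np.ones((3, 2)), np.ones(3))  # too few rows
    x = np.random.default_rng(0).normal(size=(10, 2))
    y = np.ones(10)
    y[0] = np.nan
    with pytest.raises(ValueError):
        fit_rsvm(x, y)
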