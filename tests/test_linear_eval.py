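"""Linear-evaluation protocol: penalty grid, normalization discipline,
ridge-vs-closed-form oracle, bootstrap machinery."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from pclr.architecture import EncoderConfig, build_encoder
from pclr.errors import DegenerateLabelsError, FeatureTableError
from pclr.experiments import INPUT_LENGTH
from pclr.linear_eval import (PENALTY_GRID, FeatureTable, Probe, ProbeResult,
                              compare_models, evaluate_probe,
                              extract_features, fit_probe)
from pclr.preprocess import preprocess_cohort
from pclr.synthetic import generate_cohort

RNG = np.random.default_rng(99)


def make_table(n, d, rng=RNG):
    return FeatureTable(record_ids=[f"r{i}" for i in range(n)],
                        features=rng.normal(size=(n, d)))


def test_penalty_grid_shape():
    grid = np.array(PENALTY_GRID)
    assert grid.size == 10
    assert grid[0] == pytest.approx(1e-6)
    assert grid[-1] == pytest.approx(1e5)
    ratios = grid[1:] / grid[:-1]
    assert np.allclose(ratios, 10 ** (11.0 / 9.0))
    assert ratios[0] == pytest.approx(16.68, rel=1e-3)


def test_extract_features_contracts():
    enc = build_encoder(EncoderConfig.tiny(256), seed=0)
    cohort = generate_cohort(3, 2, seed=2)
    groups = preprocess_cohort(cohort, resample_to=256)
    records = [t for g in groups for t in g.records]
    table = extract_features(enc, records)
    assert table.features.shape == (len(records), 16)
    assert table.record_ids == [t.record_id for t in records]

    empty = extract_features(enc, [])
    assert empty.features.shape == (0, 16)

    dup = extract_features(enc, [records[0], records[0]])
    assert np.array_equal(dup.features[0], dup.features[1])


def test_training_normalization_is_zscore():
    table = make_table(50, 6)
    norm = table.normalized()
    assert np.allclose(norm.features.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(norm.features.std(axis=0), 1.0, atol=1e-10)


def test_holdout_uses_training_statistics():
    train, hold = make_table(40, 4), make_table(30, 4)
    tn = train.normalized()
    hn = hold.normalized(tn.stats)
    # holdout columns are NOT self-normalized
    assert not np.allclose(hn.features.mean(axis=0), 0.0, atol=1e-3)
    expected = (hold.features - tn.stats.mean) / tn.stats.std
    assert np.allclose(hn.features, expected)

    # corrupting holdout rows must not change the training statistics
    before = (tn.stats.mean.copy(), tn.stats.std.copy())
    hold.features[...] = 1e9
    assert np.array_equal(tn.stats.mean, before[0])
    assert np.array_equal(tn.stats.std, before[1])


def test_constant_column_std_floor():
    t = make_table(20, 3)
    t.features[:, 1] = 7.0
    norm = t.normalized()
    assert np.all(np.isfinite(norm.features))
    assert norm.stats.std[1] == pytest.approx(1e-12)


def test_stats_width_mismatch_rejected():
    t = make_table(10, 4)
    stats = make_table(10, 5).normalized().stats
    with pytest.raises(FeatureTableError):
        t.normalized(stats)


def test_ridge_matches_closed_form_oracle():
    """sklearn ridge coefficients vs (X'X + lam I)^-1 X'y on centered
    data, at every grid penalty, to 1e-8."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 6))
    y = rng.normal(size=40)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    for lam in PENALTY_GRID:
        coef = np.linalg.solve(Xc.T @ Xc + lam * np.eye(6), Xc.T @ yc)
        model = Ridge(alpha=lam).fit(X, y)
        assert np.allclose(model.coef_, coef, atol=1e-8)


def test_probe_on_noiseless_linear_labels():
    """Exactly linear labels: minimal shrinkage wins and fits ~perfectly."""
    rng = np.random.default_rng(5)
    table = make_table(60, 5, rng).normalized()
    w = rng.normal(size=5)
    y = table.features @ w
    probe = fit_probe(table, y, "regression", seed=0)
    assert probe.selected_penalty == pytest.approx(min(PENALTY_GRID))
    from sklearn.metrics import r2_score
    assert r2_score(y, probe.predict(table)) > 0.999


def test_cv_determinism():
    rng = np.random.default_rng(6)
    table = make_table(48, 4, rng).normalized()
    y = (table.features[:, 0] + 0.5 * rng.normal(size=48) > 0).astype(int)
    a = fit_probe(table, y, "classification", seed=3)
    b = fit_probe(table, y, "classification", seed=3)
    assert a.selected_penalty == b.selected_penalty
    assert a.cv_scores == b.cv_scores


def test_fit_probe_errors():
    t = make_table(3, 4)
    with pytest.raises(FeatureTableError):
        fit_probe(t, np.zeros(3), "regression", seed=0)      # < 4 folds
    t = make_table(12, 4)
    with pytest.raises(DegenerateLabelsError):
        fit_probe(t, np.zeros(12, dtype=int), "classification", seed=0)
    with pytest.raises(FeatureTableError):
        fit_probe(t, np.zeros(5), "regression", seed=0)      # misaligned


class _FixedModel:
    def __init__(self, pred):
        self.pred = np.asarray(pred)

    def predict(self, X):
        return self.pred[:X.shape[0]]


def _probe_with_predictions(pred, task):
    return Probe(model=_FixedModel(pred), task=task, selected_penalty=1.0,
                 cv_scores={})


def test_perfect_predictions_give_f1_one_sd_zero():
    y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
    probe = _probe_with_predictions(y, "classification")
    res = evaluate_probe(probe, make_table(8, 2), y, n_bootstraps=50, seed=0)
    assert res.point_estimate == pytest.approx(1.0)
    assert res.bootstrap_sd == pytest.approx(0.0)


def test_mean_predictor_has_zero_r2():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    probe = _probe_with_predictions(np.full(4, y.mean()), "regression")
    res = evaluate_probe(probe, make_table(4, 2), y, n_bootstraps=10, seed=0)
    assert res.point_estimate == pytest.approx(0.0, abs=1e-12)


def test_f1_from_printed_contingency():
    """TP=2, FP=1, FN=1 -> f1 = 2/3."""
    y_true = np.array([1, 1, 1, 0, 0, 0])
    y_pred = np.array([1, 1, 0, 1, 0, 0])
    probe = _probe_with_predictions(y_pred, "classification")
    res = evaluate_probe(probe, make_table(6, 2), y_true,
                         n_bootstraps=5, seed=0)
    assert res.point_estimate == pytest.approx(2.0 / 3.0)


def _result(y_true, y_pred, ids=None):
    return ProbeResult(task="classification", metric="f1",
                       point_estimate=float(
                           2 * ((y_pred == 1) & (y_true == 1)).sum()
                           / max((y_pred == 1).sum() + (y_true == 1).sum(), 1)),
                       bootstrap_sd=0.0, n_bootstraps=1, selected_penalty=1.0,
                       record_ids=ids or [f"r{i}" for i in range(len(y_true))],
                       y_true=np.asarray(y_true), y_pred=np.asarray(y_pred))


def test_compare_models_dominance_and_ties():
    rng = np.random.default_rng(8)
    y = rng.integers(0, 2, size=60)
    perfect = y.copy()
    noisy = y.copy()
    flip = rng.choice(60, size=20, replace=False)
    noisy[flip] = 1 - noisy[flip]
    ranking = compare_models({"good": _result(y, perfect),
                              "bad": _result(y, noisy)},
                             n_bootstraps=100, seed=0)
    assert ranking[0].name == "good" and ranking[0].is_best
    assert not ranking[1].is_best

    ranking = compare_models({"a": _result(y, noisy), "b": _result(y, noisy)},
                             n_bootstraps=100, seed=0)
    assert all(r.is_best for r in ranking)


def test_compare_models_matches_bruteforce_oracle():
    """Flags agree with an independent recomputation over the same
    shared resamples."""
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, size=80)
    preds = {}
    for name, k in [("m1", 8), ("m2", 20), ("m3", 24)]:
        p = y.copy()
        flip = rng.choice(80, size=k, replace=False)
        p[flip] = 1 - p[flip]
        preds[name] = p
    results = {n: _result(y, p) for n, p in preds.items()}
    seed, n_boot = 4, 150
    ranking = compare_models(results, n_bootstraps=n_boot, seed=seed)

    # oracle: replicate the shared resample stream and recompute flags
    from sklearn.metrics import f1_score
    rng2 = np.random.default_rng([seed, 2003])
    boot = {n: [] for n in preds}
    for _ in range(n_boot):
        while True:
            idx = rng2.integers(0, 80, size=80)
            if np.unique(y[idx]).size > 1:
                break
        for n, p in preds.items():
            boot[n].append(f1_score(y[idx], p[idx]))
    points = {n: results[n].point_estimate for n in preds}
    leader = max(preds, key=lambda n: points[n])
    expected = {}
    for n in preds:
        if n == leader:
            expected[n] = True
        else:
            diff = np.array(boot[leader]) - np.array(boot[n])
            lo, hi = np.quantile(diff, [0.025, 0.975])
            expected[n] = bool(lo <= 0.0 <= hi)
    for r in ranking:
        assert r.is_best == expected[r.name], r.name


def test_compare_models_rejects_mismatched_holdouts():
    y = np.array([0, 1, 0, 1])
    a = _result(y, y)
    b = _result(y, y, ids=["x0", "x1", "x2", "x3"])
    with pytest.raises(FeatureTableError):
        compare_models({"a": a, "b": b}, n_bootstraps=10, seed=0)


def test_monotone_data_benefit(tiny_pretrained):
    """Holdout f1 of the probe is nondecreasing in training-set size
    across {64, 128, 256, 512} labels (within one bootstrap SD) in at
    least 4 of 5 seeds."""
    cohort = generate_cohort(700, 1, seed=31415)
    groups = preprocess_cohort(cohort, resample_to=INPUT_LENGTH)
    records = [g.records[0] for g in groups]
    y = np.array([g.records[0].labels["sex_like"] for g in cohort])
    table = extract_features(tiny_pretrained.encoder, records)

    def subset(idx):
        return FeatureTable(record_ids=[table.record_ids[i] for i in idx],
                            features=table.features[idx])

    ok = 0
    for seed in range(5):
        rng = np.random.default_rng([seed, 161])
        perm = rng.permutation(700)
        hold = perm[512:]
        monotone = True
        prev, prev_sd = -np.inf, 0.0
        for size in (64, 128, 256, 512):
            train = perm[:size]
            tr = subset(train).normalized()
            ho = subset(hold).normalized(tr.stats)
            probe = fit_probe(tr, y[train], "classification", seed=seed)
            res = evaluate_probe(probe, ho, y[hold], n_bootstraps=200,
                                 seed=seed)
            if res.point_estimate < prev - prev_sd:
                monotone = False
            prev, prev_sd = res.point_estimate, res.bootstrap_sd
        ok += monotone
    assert ok >= 4
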