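"""Linear evaluation of frozen representations.

Three steps: (1) apply the trained encoder to N ECGs to obtain an
N x representation_dim feature table and z-score each column using
statistics of the *training* rows; (2) fit a linear (regression) or
logistic (classification) ridge model, selecting the l2 penalty by
4-fold cross-validation from 10 log-evenly spaced values between 1e-6
and 1e5; (3) evaluate on holdout rows normalized with the training
statistics, reporting the point estimate plus the standard deviation
over 1,000 bootstrap resamples of the holdout set.

Metrics: positive-class f1 for classification, r^2 for regression.
For logistic probes the grid value lambda enters as sklearn's
C = 1 / lambda, so the penalty semantics match the linear probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import f1_score, r2_score
from sklearn.model_selection import KFold

from .errors import DegenerateLabelsError, FeatureTableError

logger = logging.getLogger(__name__)

PENALTY_GRID = tuple(np.logspace(-6.0, 5.0, 10))
STD_FLOOR = 1e-12


@dataclass
class NormalizationStats:
    mean: np.ndarray
    std: np.ndarray


@dataclass
class FeatureTable:
    """Per-record representation features, one row per ECG."""

    record_ids: list
    features: np.ndarray
    stats: NormalizationStats | None = None   # stats used to normalize

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise FeatureTableError("features must be a 2-D table")
        if len(self.record_ids) != self.features.shape[0]:
            raise FeatureTableError(
                f"{len(self.record_ids)} record ids for "
                f"{self.features.shape[0]} rows")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def fit_normalization(self) -> NormalizationStats:
        """Column stats from *these* rows (call on the training table)."""
        mean = self.features.mean(axis=0)
        std = self.features.std(axis=0)
        n_floor = int((std < STD_FLOOR).sum())
        if n_floor:
            logger.warning(
                "%d constant feature column(s); std floored at %g",
                n_floor, STD_FLOOR)
        return NormalizationStats(mean=mean, std=np.maximum(std, STD_FLOOR))

    def normalized(self, stats: NormalizationStats | None = None) -> "FeatureTable":
        """Z-scored copy. Without ``stats``, fits them on these rows
        (training use); holdout tables must pass the training stats."""
        stats = stats or self.fit_normalization()
        if stats.mean.shape[0] != self.n_features:
            raise FeatureTableError(
                f"stats width {stats.mean.shape[0]} != table width "
                f"{self.n_features}")
        return FeatureTable(
            record_ids=list(self.record_ids),
            features=(self.features - stats.mean) / stats.std,
            stats=stats)

    def to_frame(self):
        import pandas as pd
        cols = {f"f{j}": self.features[:, j] for j in range(self.n_features)}
        return pd.DataFrame({"record_id": self.record_ids} | cols)


def extract_features(encoder, records, batch_size: int = 128) -> FeatureTable:
    """Run the frozen encoder over preprocessed records (step 1, raw)."""
    records = list(records)
    feats = encoder.encode(records, batch_size=batch_size)
    width = encoder.config.representation_dim
    if feats.shape[1] != width:
        raise FeatureTableError(
            f"encoder emitted width {feats.shape[1]}, expected {width}")
    ids = [getattr(r, "record_id", str(i)) for i, r in enumerate(records)]
    return FeatureTable(record_ids=ids, features=feats)


@dataclass
class Probe:
    model: object
    task: str
    selected_penalty: float
    cv_scores: dict               # penalty -> mean fold score
    positive_class: int = 1

    def predict(self, table: FeatureTable) -> np.ndarray:
        return self.model.predict(table.features)

    @property
    def coef_(self):
        return self.model.coef_


def _make_model(task: str, penalty: float, seed: int):
    if task == "classification":
        # default l2 penalty; the grid value lambda maps to C = 1/lambda
        return LogisticRegression(C=1.0 / penalty, solver="lbfgs",
                                  max_iter=5000, random_state=seed)
    return Ridge(alpha=penalty)


def _score(task: str, y_true, y_pred, positive_class=1) -> float:
    if task == "classification":
        return f1_score(y_true, y_pred, pos_label=positive_class,
                        zero_division=0.0)
    return r2_score(y_true, y_pred)


def fit_probe(train: FeatureTable, labels, task: str, seed: int = 0,
              n_folds: int = 4, penalties=PENALTY_GRID,
              positive_class: int = 1) -> Probe:
    """Ridge probe with seeded 4-fold CV over the l2 penalty grid.

    CV folds are scored with the task metric (f1 / r^2); the winning
    penalty (ties break toward less regularization) is refit on all
    training rows.
    """
    y = np.asarray(labels)
    X = train.features
    if X.shape[0] != y.shape[0]:
        raise FeatureTableError(
            f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    if X.shape[0] < n_folds:
        raise FeatureTableError(
            f"{X.shape[0]} rows is fewer than {n_folds} CV folds")
    if task == "classification" and np.unique(y).size < 2:
        raise DegenerateLabelsError(
            "classification labels contain a single class")

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    cv_scores = {}
    for lam in penalties:
        scores = []
        for tr, te in folds:
            model = _make_model(task, lam, seed)
            model.fit(X[tr], y[tr])
            scores.append(_score(task, y[te], model.predict(X[te]),
                                 positive_class))
        cv_scores[float(lam)] = float(np.mean(scores))
    best = min(cv_scores, key=lambda lam: (-cv_scores[lam], lam))
    final = _make_model(task, best, seed)
    final.fit(X, y)
    return Probe(model=final, task=task, selected_penalty=best,
                 cv_scores=cv_scores, positive_class=positive_class)


@dataclass
class ProbeResult:
    task: str
    metric: str                   # "f1" or "r2"
    point_estimate: float
    bootstrap_sd: float
    n_bootstraps: int
    selected_penalty: float
    record_ids: list = field(default_factory=list)
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None
    n_redrawn: int = 0            # single-class f1 resamples redrawn

    def summary(self) -> str:
        return (f"{self.task}: {self.metric} = {self.point_estimate:.3f} "
                f"± {self.bootstrap_sd:.3f} "
                f"(lambda = {self.selected_penalty:g}, "
                f"{self.n_bootstraps} bootstraps)")


def bootstrap_metric(y_true, y_pred, task: str, n_bootstraps: int, seed: int,
                     positive_class: int = 1) -> tuple:
    """SD of the metric over seeded with-replacement resamples.

    Classification resamples whose truth collapses to one class are
    redrawn (f1 undefined); the count is reported.
    """
    rng = np.random.default_rng([seed, 1009])
    n = len(y_true)
    vals = np.empty(n_bootstraps)
    n_redrawn = 0
    for b in range(n_bootstraps):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if task != "classification" or np.unique(y_true[idx]).size > 1:
                break
            n_redrawn += 1
        vals[b] = _score(task, y_true[idx], y_pred[idx], positive_class)
    if n_redrawn:
        logger.info("redrew %d single-class bootstrap resamples", n_redrawn)
    return float(vals.std()), n_redrawn


def evaluate_probe(probe: Probe, holdout: FeatureTable, labels,
                   n_bootstraps: int = 1000, seed: int = 0) -> ProbeResult:
    """Step 3: holdout point estimate plus bootstrap SD.

    ``holdout`` must already be normalized with the training statistics.
    """
    y = np.asarray(labels)
    pred = probe.predict(holdout)
    point = _score(probe.task, y, pred, probe.positive_class)
    sd, n_redrawn = bootstrap_metric(y, pred, probe.task, n_bootstraps, seed,
                                     probe.positive_class)
    return ProbeResult(
        task=probe.task,
        metric="f1" if probe.task == "classification" else "r2",
        point_estimate=float(point), bootstrap_sd=sd,
        n_bootstraps=n_bootstraps, selected_penalty=probe.selected_penalty,
        record_ids=list(holdout.record_ids), y_true=y, y_pred=pred,
        n_redrawn=n_redrawn)


@dataclass
class ModelRank:
    name: str
    point_estimate: float
    is_best: bool


def compare_models(results: dict, n_bootstraps: int = 1000,
                   seed: int = 0, positive_class: int = 1) -> list:
    """Paired-bootstrap comparison of models evaluated on one holdout.

    ``results`` maps model name -> ProbeResult carrying predictions on
    identical holdout records. Every model is scored on shared resamples;
    the top point estimate is flagged best, and any model whose paired
    difference interval (2.5-97.5%) with the leader includes zero ties.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    ref = results[names[0]]
    for name in names[1:]:
        r = results[name]
        if list(r.record_ids) != list(ref.record_ids):
            raise FeatureTableError(
                f"model {name!r} was evaluated on different holdout records")
        if not np.array_equal(r.y_true, ref.y_true):
            raise FeatureTableError(
                f"model {name!r} carries different truth labels")
    task = ref.task
    y = ref.y_true
    n = len(y)
    rng = np.random.default_rng([seed, 2003])
    boot = {name: np.empty(n_bootstraps) for name in names}
    for b in range(n_bootstraps):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if task != "classification" or np.unique(y[idx]).size > 1:
                break
        for name in names:
            boot[name][b] = _score(task, y[idx], results[name].y_pred[idx],
                                   positive_class)
    points = {name: results[name].point_estimate for name in names}
    leader = max(names, key=lambda nm: points[nm])
    flags = {}
    for name in names:
        if name == leader:
            flags[name] = True
            continue
        diff = boot[leader] - boot[name]
        lo, hi = np.quantile(diff, [0.025, 0.975])
        flags[name] = bool(lo <= 0.0 <= hi)
    ranking = sorted(names, key=lambda nm: -points[nm])
    return [ModelRank(name=nm, point_estimate=points[nm], is_best=flags[nm])
            for nm in ranking]
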