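"""Feature elimination over importance-providing classifiers.

Two elimination strategies search for a minimal gene panel that separates
load-stress samples from everything else:

* **RFE** (recursive feature elimination) removes a fixed number of the
  least-important features per round, refitting the classifier each round,
  until a requested panel size is reached.
* **RGIFE** (rank-guided iterative feature elimination) removes *adaptive
  blocks* of low-ranked features, but only keeps a removal when the
  stratified cross-validated f1 of the load-stress class does not degrade.
  Blocks start at 25% of the current feature count; after five consecutive
  failed trials (or after every block of the current epoch has been tried)
  the block size is divided by 4, and once the block size reaches 1 the
  algorithm stops after five failed single-feature trials, deciding the
  final panel size automatically.

Both strategies consume feature importances produced by the classifier
itself: impurity-based importances for the random forest, absolute
coefficient magnitudes for the linear SVM.  Ties rank by ascending feature
index so runs are reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .preprocess import LoadsenseError

RANDOM_FOREST = "random_forest"
LINEAR_SVM = "linear_svm"

#: bound for seeds handed to sklearn
_SEED_BOUND = 2**31 - 1


@dataclass
class ClassifierSpec:
    """A classifier kind plus hyperparameters, with an importance contract.

    After fitting, the classifier must yield one non-negative importance per
    feature: Gini importances for ``random_forest``, |coefficients| for
    ``linear_svm``.  Defaults: 100 trees; linear SVM with unit regularization.
    """

    kind: str = RANDOM_FOREST
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (RANDOM_FOREST, LINEAR_SVM):
            raise LoadsenseError(f"unknown classifier kind {self.kind!r}")

    def build(self, seed: int | None = None):
        if self.kind == RANDOM_FOREST:
            params = {"n_estimators": 100, "random_state": seed, "n_jobs": 1}
            params.update(self.hyperparameters)
            return RandomForestClassifier(**params)
        params = {"C": 1.0, "random_state": seed, "max_iter": 10000, "dual": "auto"}
        params.update(self.hyperparameters)
        # mean-centering makes a constant feature identically zero, so its
        # coefficient (and hence importance) is exactly 0 under the L2 penalty
        return make_pipeline(StandardScaler(with_std=False), LinearSVC(**params))

    def importances(self, fitted) -> np.ndarray:
        if self.kind == RANDOM_FOREST:
            return np.asarray(fitted.feature_importances_, dtype=float)
        est = fitted[-1] if isinstance(fitted, Pipeline) else fitted
        return np.abs(np.asarray(est.coef_, dtype=float)).ravel()


@dataclass
class CVConfig:
    """Stratified k-fold setup scoring f1 of the load-stress (positive) class."""

    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise LoadsenseError("n_folds must be >= 2")


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise LoadsenseError("X must be samples x features aligned with y")
    if not np.all(np.isfinite(X)):
        raise LoadsenseError("feature matrix contains non-finite values")
    classes = np.unique(y)
    if classes.size != 2:
        raise LoadsenseError(f"need exactly two classes, got {classes.tolist()}")
    return X, y


def cv_f1(
    X: np.ndarray,
    y: np.ndarray,
    clf: ClassifierSpec,
    cv: CVConfig,
    seed: int | None = None,
) -> float:
    """Mean f1 of the positive class over stratified folds, deterministic per seed."""
    X, y = _check_xy(X, y)
    minority = int(np.bincount(y).min())
    if cv.n_folds > minority:
        raise LoadsenseError(
            f"cannot make {cv.n_folds} stratified folds with minority class of "
            f"{minority} samples"
        )
    fold_seed = cv.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=fold_seed)
    scores = []
    for k, (train, test) in enumerate(skf.split(X, y)):
        model = clf.build(seed=(fold_seed + k) % _SEED_BOUND)
        model.fit(X[train], y[train])
        scores.append(f1_score(y[test], model.predict(X[test]), pos_label=1, zero_division=0))
    return float(np.mean(scores))


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    clf: ClassifierSpec,
    seed: int | None = None,
) -> np.ndarray:
    """Feature order, least important first; ties keep ascending index."""
    X, y = _check_xy(X, y)
    model = clf.build(seed=seed)
    model.fit(X, y)
    imp = clf.importances(model)
    if imp.shape[0] != X.shape[1]:
        raise LoadsenseError("importance vector length does not match feature count")
    # stable sort on ascending importance -> ties stay in index order
    return np.argsort(imp, kind="stable")


def rfe(
    X: np.ndarray,
    y: np.ndarray,
    clf: ClassifierSpec,
    cv: CVConfig,
    n_select: int,
    step: int = 2,
    seed: int | None = None,
) -> np.ndarray:
    """Recursive elimination down to exactly ``n_select`` features.

    Each round refits on the surviving features and drops the ``step`` least
    important; the last round drops fewer if ``step`` would overshoot.
    Returns surviving original column indices in ascending order.
    """
    X, y = _check_xy(X, y)
    if step < 1:
        raise LoadsenseError("step must be >= 1")
    n_features = X.shape[1]
    if n_select >= n_features:
        warnings.warn(
            f"n_select={n_select} >= feature count {n_features}; returning all features"
        )
        return np.arange(n_features)
    current = np.arange(n_features)
    rng = np.random.default_rng(seed)
    while current.size > n_select:
        fit_seed = int(rng.integers(_SEED_BOUND))
        order = rank_features(X[:, current], y, clf, seed=fit_seed)
        n_drop = min(step, current.size - n_select)
        drop_positions = order[:n_drop]
        keep = np.ones(current.size, dtype=bool)
        keep[drop_positions] = False
        current = current[keep]
    return np.sort(current)


# ---------------------------------------------------------------------------
# RGIFE
# ---------------------------------------------------------------------------

def initial_block_size(n_features: int, block_fraction: float = 0.25) -> int:
    """Block size for a feature count: floor(fraction * n), at least 1."""
    return max(1, math.floor(block_fraction * n_features))


def rgife(
    X: np.ndarray,
    y: np.ndarray,
    clf: ClassifierSpec,
    cv: CVConfig,
    block_fraction: float = 0.25,
    max_consecutive_failures: int = 5,
    tolerance: float = 0.0,
    seed: int | None = None,
    max_trials: int = 20000,
) -> tuple[np.ndarray, list[dict]]:
    """Rank-guided iterative elimination; returns (features, trace).

    A trial removes the next untried block (in ranking order, least important
    first) and is accepted when its cross-validated f1 is no worse than the
    current reference (``trial >= reference - tolerance``, tolerance 0 by
    default).  On acceptance the reference f1, ranking, and block size are
    all refreshed from the surviving features.  After
    ``max_consecutive_failures`` failures, or once every block of the current
    epoch has been tried, the block size is divided by 4 (floor, minimum 1)
    and a new epoch starts; at block size 1 the failure counter carries
    across epoch restarts so the run stops after
    ``max_consecutive_failures`` failed single-feature trials.

    CV folds are re-drawn from the run seed at every trial; every seed used
    is recorded in the trace.
    """
    X, y = _check_xy(X, y)
    if X.shape[1] < 2:
        raise LoadsenseError("RGIFE needs at least 2 features")
    rng = np.random.default_rng(seed)

    def next_seed() -> int:
        return int(rng.integers(_SEED_BOUND))

    current = np.arange(X.shape[1])
    init_seed = next_seed()
    reference_f1 = cv_f1(X[:, current], y, clf, cv, seed=init_seed)
    trace: list[dict] = [
        {
            "event": "init",
            "n_features": int(current.size),
            "f1": reference_f1,
            "cv_seed": init_seed,
        }
    ]

    block_size = initial_block_size(current.size, block_fraction)
    ranking = current[rank_features(X[:, current], y, clf, seed=next_seed())]
    pos = 0
    failures = 0
    n_trials = 0

    while n_trials < max_trials:
        if current.size <= 1:
            break
        if pos >= ranking.size:
            # epoch exhausted without the failure cap being hit
            if block_size == 1:
                # failure counter deliberately carries over so that size-1
                # epochs cannot cycle forever on a tiny feature set
                if failures >= max_consecutive_failures:
                    break
                pos = 0
                continue
            block_size = max(1, block_size // 4)
            pos = 0
            failures = 0
            continue

        block = ranking[pos : pos + block_size]
        if block.size >= current.size:  # never remove every feature
            block = block[: current.size - 1]
        trial = np.setdiff1d(current, block)
        trial_seed = next_seed()
        trial_f1 = cv_f1(X[:, trial], y, clf, cv, seed=trial_seed)
        n_trials += 1
        accepted = trial_f1 >= reference_f1 - tolerance
        trace.append(
            {
                "event": "trial",
                "block": [int(b) for b in block],
                "block_size": int(block_size),
                "n_features_before": int(current.size),
                "n_features_after": int(trial.size if accepted else current.size),
                "f1_reference": reference_f1,
                "f1_trial": trial_f1,
                "accepted": bool(accepted),
                "consecutive_failures": int(0 if accepted else failures + 1),
                "cv_seed": trial_seed,
            }
        )
        if accepted:
            current = trial
            reference_f1 = trial_f1
            failures = 0
            if current.size <= 1:
                break
            block_size = initial_block_size(current.size, block_fraction)
            ranking = current[rank_features(X[:, current], y, clf, seed=next_seed())]
            pos = 0
        else:
            failures += 1
            pos += block_size
            if failures >= max_consecutive_failures:
                if block_size == 1:
                    break
                block_size = max(1, block_size // 4)
                pos = 0
                failures = 0

    trace.append(
        {
            "event": "final",
            "n_features": int(current.size),
            "f1": reference_f1,
            "n_trials": n_trials,
        }
    )
    return np.sort(current), trace


def permutation_null_f1(
    X: np.ndarray,
    y: np.ndarray,
    clf: ClassifierSpec,
    cv: CVConfig,
    n_shuffles: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """CV f1 under label permutation: the chance band for a panel's score."""
    X, y = _check_xy(X, y)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        y_perm = rng.permutation(y)
        scores[i] = cv_f1(X, y_perm, clf, cv, seed=int(rng.integers(_SEED_BOUND)))
    return scores


def write_trace_jsonl(trace: list[dict], path) -> None:
    import json
    from pathlib import Path

    Path(path).write_text("\n".join(json.dumps(rec) for rec in trace) + "\n")
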