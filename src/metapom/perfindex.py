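"""Cross-validated performance-index evaluation of molecular representations.

A representation is scored on a dataset by a random-forest model under
leave-one-out cross-validation (datasets with N <= 200 molecules; training
data jackknife-resampled per seed) or fivefold cross-validation (N > 200;
training data bootstrap-resampled per seed).  Classification is scored by
AUROC and regression by R²; both are rescaled to a common performance index
where 0 is random and 100 is perfect:

    index = (AUROC − 0.5) / 0.5 * 100  (classification)
    index = R² * 100                   (regression)

Per-seed indices are pooled over held-out predictions, averaged across seeds
and targets, and their SD across seeds quantifies run-to-run dispersion.
A correlation-based index variant serves neural-distance datasets, where the
quantity of interest is how well representation distances between odorants
track neural-activity distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .correlation import pearson_r
from .representations import RepresentationTable


@dataclass
class EvalDataset:
    name: str
    keys: list[str]
    targets: pd.DataFrame  # molecule x target, index aligned with keys
    task: str  # "classification" | "regression"

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.keys) != len(self.targets):
            raise ValueError("keys and targets are misaligned")
        if self.task == "classification":
            for col in self.targets:
                vals = set(self.targets[col].unique())
                if not vals <= {0, 1}:
                    raise ValueError(f"classification target {col!r} is not binary")
                if len(vals) < 2:
                    raise ValueError(f"classification target {col!r} has a single class")


@dataclass(frozen=True)
class EvalProtocol:
    split: str = "auto"  # "auto" | "loo" | "fivefold"
    n_seeds: int = 5
    resample: str = "auto"  # "auto" | "jackknife" | "bootstrap" | "none"
    model_grid: tuple[dict, ...] = (dict(),)

    def resolve_split(self, n: int) -> str:
        if self.split != "auto":
            return self.split
        return "loo" if n <= 200 else "fivefold"

    def resolve_resample(self, split: str) -> str:
        if self.resample != "auto":
            return self.resample
        return "jackknife" if split == "loo" else "bootstrap"


@dataclass
class PerformanceResult:
    dataset: str
    representation: str
    index: float
    sd_across_seeds: float
    raw_metric: dict[str, float]
    per_seed_indices: np.ndarray
    seeds: tuple[int, ...]
    best_params: dict = field(default_factory=dict)


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann–Whitney) AUROC with average-rank tie handling."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def r_squared(y: Sequence[float], pred: Sequence[float]) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if y.shape != pred.shape or y.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y")
    ss_res = float(np.sum((y - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def to_performance_index(metric: float, task: str) -> float:
    """Rescale AUROC or R² so 0 is random and 100 is perfect performance.

    Classification maps AUROC through the anchors (0.5 -> 0, 1.0 -> 100);
    regression multiplies R² by 100.
    """
    if task == "classification":
        if not 0.0 <= metric <= 1.0:
            raise ValueError(f"AUROC {metric} outside [0, 1]")
        return (metric - 0.5) / 0.5 * 100.0
    if task == "regression":
        return metric * 100.0
    raise ValueError(f"unknown task {task!r}")


def _default_model(task: str, params: Mapping, random_state: int):
    cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
    defaults = dict(n_estimators=25, n_jobs=1)
    defaults.update(params)
    return cls(random_state=random_state, **defaults)


def _score_predictions(ds: EvalDataset, preds: np.ndarray) -> dict[str, float]:
    metrics = {}
    for j, col in enumerate(ds.targets.columns):
        y = ds.targets[col].to_numpy()
        if ds.task == "classification":
            metrics[str(col)] = auroc(y, preds[:, j])
        else:
            metrics[str(col)] = r_squared(y, preds[:, j])
    return metrics


def _fit_predict(model, x_train, y_train, x_test, task: str) -> np.ndarray:
    model.fit(x_train, y_train)
    if task == "classification":
        proba = model.predict_proba(x_test)
        pos = list(model.classes_).index(1) if 1 in model.classes_ else proba.shape[1] - 1
        return proba[:, pos]
    return model.predict(x_test)


def _run_one_seed(
    x: np.ndarray,
    ds: EvalDataset,
    split: str,
    resample: str,
    params: Mapping,
    seed: int,
    model_factory: Callable,
) -> tuple[float, dict[str, float]]:
    """One seed's pooled held-out predictions -> mean index over targets."""
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    preds = np.empty((n, ds.targets.shape[1]))
    targets = ds.targets.to_numpy()
    if split == "loo":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif split == "fivefold":
        if n < 5:
            raise ValueError("fivefold split needs N >= 5")
        kf = KFold(n_splits=5, shuffle=True, random_state=int(rng.integers(2**31)))
        folds = list(kf.split(x))
    else:
        raise ValueError(f"unknown split {split!r}")
    for train_idx, test_idx in folds:
        if resample == "jackknife":
            drop = int(rng.integers(train_idx.size))
            train_idx = np.delete(train_idx, drop)
        elif resample == "bootstrap":
            train_idx = rng.choice(train_idx, size=train_idx.size, replace=True)
        for j in range(targets.shape[1]):
            y_train = targets[train_idx, j]
            if ds.task == "classification" and len(set(y_train.tolist())) < 2:
                # degenerate resample: fall back to the un-resampled fold
                y_train = targets[:, j][np.setdiff1d(np.arange(n), test_idx)]
                x_tr = x[np.setdiff1d(np.arange(n), test_idx)]
            else:
                x_tr = x[train_idx]
            model = model_factory(ds.task, params, int(rng.integers(2**31)))
            preds[test_idx, j] = _fit_predict(model, x_tr, y_train, x[test_idx], ds.task)
    metrics = _score_predictions(ds, preds)
    idx = float(np.mean([to_performance_index(m, ds.task) for m in metrics.values()]))
    return idx, metrics


def evaluate_dataset(
    ds: EvalDataset,
    table: RepresentationTable,
    proto: EvalProtocol = EvalProtocol(),
    model_factory: Callable = _default_model,
    base_seed: int = 0,
) -> PerformanceResult:
    """Cross-validated performance index of one representation on one dataset.

    Every entry of the model grid is evaluated under the identical protocol
    and the best (by mean index across seeds) is reported.
    """
    x = table.matrix(ds.keys)
    n = x.shape[0]
    split = proto.resolve_split(n)
    resample = proto.resolve_resample(split)
    seeds = tuple(base_seed + i for i in range(proto.n_seeds))
    best: Optional[PerformanceResult] = None
    for params in proto.model_grid:
        per_seed = []
        per_seed_metrics = []
        for seed in seeds:
            idx, metrics = _run_one_seed(x, ds, split, resample, params, seed, model_factory)
            per_seed.append(idx)
            per_seed_metrics.append(metrics)
        per_seed = np.array(per_seed)
        raw = {
            col: float(np.mean([m[col] for m in per_seed_metrics]))
            for col in per_seed_metrics[0]
        }
        result = PerformanceResult(
            dataset=ds.name,
            representation=table.name,
            index=float(per_seed.mean()),
            sd_across_seeds=float(per_seed.std(ddof=1)) if per_seed.size > 1 else 0.0,
            raw_metric=raw,
            per_seed_indices=per_seed,
            seeds=seeds,
            best_params=dict(params),
        )
        if best is None or result.index > best.index:
            best = result
    assert best is not None
    return best


def representation_delta(a: PerformanceResult, b: PerformanceResult) -> tuple[float, float]:
    """Mean and SD of per-seed index differences a − b on the same dataset."""
    if a.dataset != b.dataset:
        raise ValueError("results come from different datasets")
    if a.seeds != b.seeds:
        raise ValueError("seed lists are not aligned")
    diffs = a.per_seed_indices - b.per_seed_indices
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return float(diffs.mean()), sd


def neural_distance_index(
    activity: pd.DataFrame,
    tables: Sequence[RepresentationTable],
    conditions: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Correlation-based index: representation vs. neural distances.

    Per experimental condition (a subset of neurons): center the activity
    per neuron, compute correlation distances between odorant activity
    rows; center each representation per feature over the same odorants and
    compute molecular correlation distances; Pearson-correlate the two
    pairwise vectors.  The index is the condition-mean r × 100.
    """
    if activity.shape[0] < 3:
        raise ValueError("need at least 3 odorants")
    odorants = list(activity.index)
    rep_dists = {}
    for table in tables:
        mat = table.matrix(odorants)
        mat = mat - mat.mean(axis=0, keepdims=True)
        rep_dists[table.name] = pdist(mat, metric="correlation")
    out: dict[str, float] = {}
    for table in tables:
        rs = []
        for cond, neurons in conditions.items():
            if len(neurons) < 2:
                raise ValueError(f"condition {cond!r} has fewer than 2 neurons")
            sub = activity[list(neurons)].to_numpy(dtype=float)
            if np.any(np.ptp(sub, axis=1) == 0):
                raise ValueError(f"constant odorant rows in condition {cond!r}")
            sub = sub - sub.mean(axis=0, keepdims=True)
            neural = pdist(sub, metric="correlation")
            rs.append(pearson_r(neural, rep_dists[table.name]))
        out[table.name] = float(np.mean(rs) * 100.0)
    return out


# -- I/O -----------------------------------------------------------------

def read_eval_dataset(csv_path, sidecar_json) -> EvalDataset:
    """Dataset CSV (key column + target columns) with a task-declaring sidecar JSON."""
    import json

    with open(sidecar_json) as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path)
    key_col = df.columns[0]
    targets = df.drop(columns=[key_col])
    return EvalDataset(
        name=meta.get("name", str(csv_path)),
        keys=[str(k) for k in df[key_col]],
        targets=targets,
        task=meta["task"],
    )
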