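"""Regression and binary-classification evaluation of speech features.

The protocol: participants with UCLA score >= round(mean + 1*SD) form the
high-loneliness class; models (kNN, random forest, RBF-SVM) are evaluated
by iterated stratified/shuffled 10-fold cross-validation.  Inside every
training fold — and only there — features are median-imputed and z-scored,
the 16 acoustic features with the largest |Spearman rho| against the
training scores are pre-selected (joining the 16 prosodic and 16 linguistic
features to form the 48-candidate set), a sequential forward selection
picks the model inputs by inner-CV score, and a hyperparameter grid search
refines the model.  Metrics are computed per iteration over the pooled
out-of-fold predictions and summarized as mean with a 95% t-interval over
iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR

REGRESSION = "regression"
CLASSIFICATION = "classification"

FAMILIES = ("knn", "random_forest", "svm")

#: grid-search ranges; the searched parameters follow the protocol, the
#: ranges are package defaults
DEFAULT_GRIDS = {
    ("knn", REGRESSION): [{"n_neighbors": k} for k in (3, 5, 7)],
    ("knn", CLASSIFICATION): [{"n_neighbors": k} for k in (3, 5, 7)],
    ("random_forest", REGRESSION): [
        {"n_estimators": n, "max_depth": d} for n in (100, 300) for d in (3, 5, None)
    ],
    ("random_forest", CLASSIFICATION): [
        {"n_estimators": n, "max_depth": d} for n in (100, 300) for d in (3, 5, None)
    ],
    ("svm", REGRESSION): [
        {"C": c, "gamma": g, "epsilon": e}
        for c in (1.0, 3.0, 10.0)
        for g in ("scale",)
        for e in (0.5, 1.0, 2.0)
    ],
    ("svm", CLASSIFICATION): [
        {"C": c, "gamma": g, "class_weight": w}
        for c in (1.0, 3.0, 10.0)
        for g in ("scale",)
        for w in (None, "balanced")
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    task: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def needs_scaling(self) -> bool:
        return self.family in ("knn", "svm")


def build_estimator(spec: ModelSpec, seed: int = 0):
    hp = dict(spec.hyperparameters)
    if spec.family == "knn":
        cls = KNeighborsRegressor if spec.task == REGRESSION else KNeighborsClassifier
        return cls(n_neighbors=hp.get("n_neighbors", 5))
    if spec.family == "random_forest":
        cls = RandomForestRegressor if spec.task == REGRESSION else RandomForestClassifier
        return cls(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", None),
            random_state=seed,
        )
    if spec.task == REGRESSION:
        return SVR(kernel="rbf", C=hp.get("C", 3.0), gamma=hp.get("gamma", "scale"),
                   epsilon=hp.get("epsilon", 1.0))
    return SVC(kernel="rbf", C=hp.get("C", 3.0), gamma=hp.get("gamma", "scale"),
               class_weight=hp.get("class_weight", "balanced"))


# ---------------------------------------------------------------------------
# cutoff and metrics


def determine_cutoff(scores) -> int:
    """High-loneliness cutoff: mean + 1 sample SD, rounded half up to an
    integer.  Participants scoring >= cutoff form the positive class."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need n >= 2")
    sd = float(np.std(scores, ddof=1))
    return int(math.floor(scores.mean() + sd + 0.5))


def regression_metrics(y, yhat):
    """(R^2, EV, MAE, RMSE).  MAE = mean |y - yhat|; RMSE = sqrt(mean sq err);
    R^2 = 1 - SSE/SST; EV = 1 - Var(y - yhat)/Var(y)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length non-empty vectors")
    if np.ptp(y) == 0:
        raise ValueError("R^2 and EV undefined for constant y")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((err**2).sum()) / sst
    ev = 1.0 - float(np.var(err)) / float(np.var(y))
    return r2, ev, mae, rmse


def classification_metrics(tp, fn, fp, tn):
    """(accuracy, sensitivity, specificity, F1) as fractions in [0,1].

    Counts may be fractional (iteration-averaged confusion matrices)."""
    for c in (tp, fn, fp, tn):
        if c < 0:
            raise ValueError("counts must be non-negative")
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("empty confusion matrix")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no positive cases")
    if tn + fp == 0:
        raise ValueError("specificity undefined: no negative cases")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    if 2 * tp + fp + fn == 0:
        raise ValueError("F1 undefined: no predicted or actual positives")
    f1 = 2 * tp / (2 * tp + fp + fn)
    return accuracy, sensitivity, specificity, f1


# ---------------------------------------------------------------------------
# per-fold feature machinery


def _abs_spearman(table: pd.DataFrame, scores: np.ndarray) -> pd.Series:
    """|Spearman rho| per column, vectorized over columns."""
    ranks = table.rank(method="average").to_numpy(dtype=float)
    ry = stats.rankdata(scores)
    rx = ranks - ranks.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry[:, None]).sum(axis=0) / denom
    rho = np.where(np.isfinite(rho), rho, 0.0)
    return pd.Series(np.abs(rho), index=table.columns)


def select_acoustic_subset(train_table: pd.DataFrame, train_scores, k: int = 16):
    """Top-k feature names by |Spearman rho| with the training scores,
    ties broken by name."""
    if train_table.shape[1] < k:
        raise ValueError(f"need at least {k} features")
    strength = _abs_spearman(train_table, np.asarray(train_scores, dtype=float))
    order = sorted(strength.index, key=lambda n: (-strength[n], n))
    return order[:k]


def _inner_objective(X, y, spec: ModelSpec, inner_folds: int, seed: int) -> float:
    """Inner-CV objective: pooled R^2 for regression, accuracy for
    classification."""
    n = y.size
    folds = min(inner_folds, n)
    if spec.task == CLASSIFICATION:
        _, counts = np.unique(y, return_counts=True)
        folds = max(2, min(folds, counts.min()))
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = splitter.split(X)
    pred = np.empty(n)
    for tr, te in splits:
        est = build_estimator(spec, seed=seed)
        est.fit(X[tr], y[tr])
        pred[te] = est.predict(X[te])
    if spec.task == CLASSIFICATION:
        return float(np.mean(pred == y))
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("degenerate targets: zero variance")
    return 1.0 - float(((y - pred) ** 2).sum()) / sst


def sequential_forward_selection(
    candidates,
    model: ModelSpec,
    X: pd.DataFrame,
    y,
    inner_folds: int = 3,
    max_features: int = 12,
    seed: int = 0,
):
    """Greedy forward selection over candidate feature names.

    At each step the candidate whose addition maximizes the inner-CV
    objective (R^2 or accuracy) is added; selection stops when no candidate
    improves the objective or ``max_features`` is reached.  Ties break to
    the alphabetically first candidate, making the result deterministic
    given the seed.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("no candidates")
    y = np.asarray(y)
    selected: list = []
    best_obj = -np.inf
    Xv = {c: X[c].to_numpy(dtype=float) for c in candidates}
    while len(selected) < max_features:
        best_c, best_gain_obj = None, best_obj
        for c in candidates:
            if c in selected:
                continue
            cols = selected + [c]
            mat = np.column_stack([Xv[k] for k in cols])
            obj = _inner_objective(mat, y, model, inner_folds, seed)
            if obj > best_gain_obj + 1e-12:
                best_gain_obj, best_c = obj, c
        if best_c is None:
            break
        selected.append(best_c)
        best_obj = best_gain_obj
    if not selected:
        # never return an empty model: fall back to the single best candidate
        objs = {
            c: _inner_objective(Xv[c][:, None], y, model, inner_folds, seed)
            for c in candidates
        }
        selected = [max(sorted(objs), key=lambda c: objs[c])]
    return selected


def _grid_search(X, y, family, task, inner_folds, seed):
    """Pick the grid point with the best inner-CV objective (ties keep the
    first grid entry)."""
    best_spec, best_obj = None, -np.inf
    for hp in DEFAULT_GRIDS[(family, task)]:
        spec = ModelSpec(family, task, hp)
        try:
            obj = _inner_objective(X, y, spec, inner_folds, seed)
        except ValueError:
            continue
        if obj > best_obj + 1e-12:
            best_spec, best_obj = spec, obj
    if best_spec is None:
        best_spec = ModelSpec(family, task, {})
    return best_spec


# ---------------------------------------------------------------------------
# cross-validation protocol


@dataclass
class EvalReport:
    task: str
    metrics: dict            # name -> {"mean": m, "ci": (lo, hi)}
    iteration_values: dict   # name -> list over iterations
    confusion: dict | None   # mean TP/FN/FP/TN over iterations (classification)
    selected_features: list  # list of lists, one per (iteration, fold)
    predictions: list        # per-iteration (y, yhat) pooled over folds
    group_metrics: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "task": self.task,
            "metrics": {
                k: {"mean": v["mean"], "ci": list(v["ci"])}
                for k, v in self.metrics.items()
            },
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion
        if self.group_metrics is not None:
            d["group_metrics"] = self.group_metrics
        counts: dict = {}
        for sel in self.selected_features:
            for name in sel:
                counts[name] = counts.get(name, 0) + 1
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:12]
        d["selection"] = {
            "n_fold_models": len(self.selected_features),
            "mean_subset_size": (
                float(np.mean([len(s) for s in self.selected_features]))
                if self.selected_features else 0.0
            ),
            "most_selected": [{"feature": n, "folds": c} for n, c in top],
        }
        return d


def _t_ci(values: np.ndarray):
    """Mean and 95% t-interval over iteration values."""
    m = float(values.mean())
    if values.size < 2 or np.ptp(values) == 0:
        return m, (m, m)
    half = stats.t.ppf(0.975, values.size - 1) * values.std(ddof=1) / np.sqrt(values.size)
    return m, (m - half, m + half)


def _prepare_fold(X: pd.DataFrame, tr_idx, te_idx, scores_tr, acoustic_k, scale):
    """Median-impute and (optionally) z-score using training rows only, then
    build the candidate list: top-k acoustic by training |rho| plus all
    prosodic and linguistic columns."""
    Xtr = X.iloc[tr_idx].copy()
    Xte = X.iloc[te_idx].copy()
    med = Xtr.median()
    med = med.fillna(0.0)
    Xtr = Xtr.fillna(med)
    Xte = Xte.fillna(med)
    if scale:
        mu, sd = Xtr.mean(), Xtr.std(ddof=0).replace(0.0, 1.0)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    acoustic = [c for c in X.columns if c.startswith("ac.")]
    other = [c for c in X.columns if not c.startswith("ac.")]
    if len(acoustic) > acoustic_k:
        acoustic = select_acoustic_subset(Xtr[acoustic], scores_tr, k=acoustic_k)
    candidates = list(acoustic) + other
    return Xtr, Xte, candidates


def run_cv(
    table: pd.DataFrame,
    targets,
    task: str,
    model_family: str = "svm",
    n_iter: int = 20,
    k_folds: int = 10,
    seed: int = 0,
    acoustic_k: int = 16,
    sfs_max_features: int = 12,
    sfs_inner_folds: int = 3,
    grid_search: bool = True,
    selection_family: str | None = None,
    model_hyperparameters: dict | None = None,
    group_labels=None,
) -> EvalReport:
    """Iterated k-fold cross-validation of one model family.

    ``table`` holds feature columns only; ``targets`` are UCLA scores
    (regression) or binary labels (classification).  Folds are reshuffled
    each iteration with a seed derived from ``seed``; classification folds
    are stratified.  All data-dependent choices (imputation, scaling,
    acoustic pre-selection, SFS, grid search) see training rows only.

    ``selection_family`` is the model family whose inner-CV objective
    drives the forward selection.  It defaults to ``model_family``, except
    for random forests, where hundreds of forest refits per fold are
    prohibitive and an RBF-SVM objective selects instead.
    """
    y = np.asarray(targets)
    n = len(table)
    if n < k_folds:
        raise ValueError("need n >= k_folds")
    if task == CLASSIFICATION:
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("classification needs both classes")
    else:
        y = y.astype(float)

    if selection_family is None:
        selection_family = "svm" if model_family == "random_forest" else model_family
    baseline = ModelSpec(model_family, task, model_hyperparameters or {})
    selector = ModelSpec(selection_family, task, {})
    iter_vals: dict = {}
    confusions = []
    selected_all = []
    predictions = []

    for it in range(n_iter):
        it_seed = (seed * 10007 + it * 101 + 1) % (2**31 - 1)
        if task == CLASSIFICATION:
            splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=it_seed)
            splits = splitter.split(table, y)
        else:
            splitter = KFold(n_splits=k_folds, shuffle=True, random_state=it_seed)
            splits = splitter.split(table)
        yhat = np.empty(n, dtype=float)
        for tr, te in splits:
            if task == CLASSIFICATION and len(np.unique(y[tr])) < 2:
                raise ValueError("a class is absent from a training split")
            Xtr, Xte, candidates = _prepare_fold(
                table, tr, te, y[tr], acoustic_k,
                baseline.needs_scaling or selector.needs_scaling,
            )
            selected = sequential_forward_selection(
                candidates, selector, Xtr, y[tr],
                inner_folds=sfs_inner_folds, max_features=sfs_max_features,
                seed=it_seed,
            )
            selected_all.append(selected)
            Xtr_s = Xtr[selected].to_numpy(dtype=float)
            Xte_s = Xte[selected].to_numpy(dtype=float)
            if grid_search:
                spec = _grid_search(Xtr_s, y[tr], model_family, task,
                                    sfs_inner_folds, it_seed)
            else:
                spec = baseline
            est = build_estimator(spec, seed=it_seed)
            est.fit(Xtr_s, y[tr])
            yhat[te] = est.predict(Xte_s)

        predictions.append((y.copy(), yhat.copy()))
        if task == REGRESSION:
            r2, ev, mae, rmse = regression_metrics(y, yhat)
            for k, v in zip(("r2", "ev", "mae", "rmse"), (r2, ev, mae, rmse)):
                iter_vals.setdefault(k, []).append(v)
        else:
            pred = yhat.astype(int)
            tp = int(np.sum((pred == 1) & (y == 1)))
            fn = int(np.sum((pred == 0) & (y == 1)))
            fp = int(np.sum((pred == 1) & (y == 0)))
            tn = int(np.sum((pred == 0) & (y == 0)))
            confusions.append((tp, fn, fp, tn))
            acc, sens, spec_, f1 = classification_metrics(tp, fn, fp, tn)
            for k, v in zip(
                ("accuracy", "sensitivity", "specificity", "f1"),
                (acc, sens, spec_, f1),
            ):
                iter_vals.setdefault(k, []).append(v)

    metrics = {}
    for k, vals in iter_vals.items():
        m, ci = _t_ci(np.asarray(vals, dtype=float))
        metrics[k] = {"mean": m, "ci": ci}
    confusion = None
    if confusions:
        arr = np.asarray(confusions, dtype=float).mean(axis=0)
        confusion = dict(zip(("tp", "fn", "fp", "tn"), arr.tolist()))
    report = EvalReport(
        task=task,
        metrics=metrics,
        iteration_values={k: list(v) for k, v in iter_vals.items()},
        confusion=confusion,
        selected_features=selected_all,
        predictions=predictions,
    )
    if group_labels is not None:
        report.group_metrics = evaluate_by_group(report, group_labels)
    return report


def evaluate_by_group(report: EvalReport, group_labels) -> dict:
    """Pooled-prediction metrics restricted to each group, with per-iteration
    95% t-intervals.  Groups with fewer than 2 members are skipped."""
    groups = np.asarray(group_labels)
    out = {}
    for g in sorted(map(str, np.unique(groups))):
        mask = groups.astype(str) == g
        if mask.sum() < 2:
            continue
        vals: dict = {}
        for y, yhat in report.predictions:
            yg, pg = y[mask], yhat[mask]
            try:
                if report.task == REGRESSION:
                    r2, ev, mae, rmse = regression_metrics(yg, pg)
                    names_vals = zip(("r2", "ev", "mae", "rmse"), (r2, ev, mae, rmse))
                else:
                    pred = pg.astype(int)
                    tp = int(np.sum((pred == 1) & (yg == 1)))
                    fn = int(np.sum((pred == 0) & (yg == 1)))
                    fp = int(np.sum((pred == 1) & (yg == 0)))
                    tn = int(np.sum((pred == 0) & (yg == 0)))
                    acc = (tp + tn) / mask.sum()
                    names_vals = [("accuracy", acc)]
            except ValueError:
                continue
            for k, v in names_vals:
                vals.setdefault(k, []).append(v)
        out[g] = {
            k: dict(zip(("mean", "ci"), _t_ci(np.asarray(v, dtype=float))))
            for k, v in vals.items()
        }
    return out
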