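"""Feature sets, model families and grouped leave-one-subject-out evaluation.

Six basic feature sets are crossed with four model families (rounded linear
regression, CART decision tree, k-nearest neighbours, random forest) to
predict, per activity scale, whether a dataset shows a considerable
(SRD-exceeding) improvement. Evaluation removes *all* datasets of one
participant per fold (both body sides), pools the fold predictions into a
single confusion matrix, and reports balanced accuracy, sensitivity,
specificity and precision, plus whether the designated unexpected
non-responder was predicted correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .cohort import Cohort
from .errors import CrossValidationError, FeatureUnavailableError, ParameterError
from .labeling import SCALES
from .metrics import METRIC_NAMES

#: Columns of each basic feature set, on the encoded cohort frame.
FEATURE_SETS: dict[int, tuple[str, ...]] = {
    1: ("age", "chronicity", "sex_m", "ms_RR", "ms_PP", "ms_SP"),
    2: ("group_1", "group_2", "group_3"),
    3: ("edss", "disability_group"),
    4: ("motricity", "static_fatigue_index", "monofilament_index",
        "sdmt", "fahn_tremor"),
    5: METRIC_NAMES,
    6: ("arat_pre", "bbt_pre", "nhpt_pre"),
}

FEATURE_SET_LABELS = {
    1: "patient master data", 2: "intervention group", 3: "disability",
    4: "conventional body-function scales", 5: "digital health metrics",
    6: "pre-intervention activity scales",
}

MODEL_FAMILIES = ("linreg", "tree", "knn", "rf")

#: Families whose distance/threshold geometry warrants within-fold z-scoring.
_STANDARDIZED = frozenset({"linreg", "knn"})


@dataclass(frozen=True)
class ModelSpec:
    """A model family with frozen default hyperparameters and a seed."""

    family: str
    k_neighbors: int = 3
    n_trees: int = 100
    seed: int = 17

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ParameterError(
                f"unknown family {self.family!r}; expected one of {MODEL_FAMILIES}")

    def describe(self) -> str:
        return {
            "linreg": "ordinary least squares on 0/1 labels, rounded at 0.5",
            "tree": "CART, Gini impurity, unlimited depth, min leaf 1",
            "knn": f"k-nearest neighbours (k={self.k_neighbors}, "
                   "z-scored Euclidean distance)",
            "rf": f"random forest ({self.n_trees} trees, sqrt(p) features/split, "
                  f"seed {self.seed})",
        }[self.family]


@dataclass(frozen=True)
class PerformanceSummary:
    """Pooled LOSO confusion counts and the derived rates (fractions)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    balanced_accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class GridResult:
    """Full cross of (outcome, feature set, model family) evaluations."""

    table: pd.DataFrame
    predictions: dict
    labels: pd.DataFrame
    skipped: list
    hyperparameters: dict


# --------------------------------------------------------------------------
# feature construction


def encode_features(cohort: Cohort) -> pd.DataFrame:
    """Numeric dataset-by-feature frame: one-hot MS type and intervention
    group, binary sex (0 = F, 1 = M), remaining columns passed through."""
    df = cohort.to_frame()
    enc = pd.DataFrame(index=df.index)
    enc["age"] = df["age"].astype(float)
    enc["chronicity"] = df["chronicity"].astype(float)
    enc["sex_m"] = (df["sex"] == "M").astype(float)
    for t in ("RR", "PP", "SP"):
        enc[f"ms_{t}"] = (df["ms_type"] == t).astype(float)
    for g in (1, 2, 3):
        enc[f"group_{g}"] = (df["intervention_group"] == g).astype(float)
    enc["edss"] = df["edss"].astype(float)
    for c in ("disability_group", "motricity", "static_fatigue_index",
              "monofilament_index", "sdmt", "fahn_tremor",
              "arat_pre", "bbt_pre", "nhpt_pre"):
        if c in df.columns:
            enc[c] = df[c].astype(float)
    return enc


def build_feature_matrix(cohort: Cohort,
                         sets: frozenset[int] | set[int] | tuple[int, ...],
                         metric_table: pd.DataFrame | None = None
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix for a combination of basic sets, plus participant ids.

    ``metric_table`` must carry the ten normalized digital health metrics
    indexed by dataset id when set 5 is requested. Raises
    :class:`FeatureUnavailableError` naming the set when a required column
    is absent or entirely null.
    """
    sets = sorted(set(int(s) for s in sets))
    if not sets or any(s not in FEATURE_SETS for s in sets):
        raise ParameterError(f"feature sets must be a non-empty subset of 1-6: {sets}")
    enc = encode_features(cohort)
    if metric_table is not None:
        missing_rows = [i for i in enc.index if i not in metric_table.index]
        if missing_rows:
            raise FeatureUnavailableError(
                f"metric table lacks datasets {missing_rows}")
        enc = enc.join(metric_table.loc[enc.index, list(METRIC_NAMES)])
    cols: list[str] = []
    for s in sets:
        for c in FEATURE_SETS[s]:
            if c not in enc.columns or enc[c].isna().all():
                raise FeatureUnavailableError(
                    f"feature set {s} ({FEATURE_SET_LABELS[s]}): "
                    f"column {c!r} unavailable")
        cols.extend(FEATURE_SETS[s])
    X = enc[cols]
    if X.isna().any().any():
        raise FeatureUnavailableError(
            f"feature sets {sets}: missing values in {list(X.columns[X.isna().any()])}")
    pids = np.array([rec.participant_id for rec in cohort])
    return X, pids


# --------------------------------------------------------------------------
# cross-validation


def loso_folds(participant_ids: np.ndarray
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fold per participant; the test fold holds *all* their datasets."""
    pids = np.asarray(participant_ids)
    unique = pd.unique(pids)
    if len(unique) < 2:
        raise CrossValidationError(
            "leave-one-subject-out needs at least 2 participants")
    folds = []
    for p in unique:
        test = np.flatnonzero(pids == p)
        train = np.flatnonzero(pids != p)
        folds.append((train, test))
    return folds


def fit_predict(spec: ModelSpec,
                X_train: np.ndarray, y_train: np.ndarray,
                X_test: np.ndarray) -> np.ndarray:
    """Train one model on a fold and return 0/1 predictions for the test rows.

    A single-class training fold yields a constant prediction of that class.
    Features are z-scored with training-fold statistics for the families
    that rely on distances or a fixed rounding threshold.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(X_train) == 0:
        raise CrossValidationError("empty training set")
    classes = np.unique(y_train)
    if len(classes) == 1:
        return np.full(len(X_test), classes[0], dtype=int)
    if spec.family in _STANDARDIZED:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    if spec.family == "linreg":
        model = LinearRegression().fit(X_train, y_train)
        return (model.predict(X_test) >= 0.5).astype(int)
    if spec.family == "tree":
        model = DecisionTreeClassifier(criterion="gini",
                                       random_state=spec.seed)
    elif spec.family == "knn":
        k = min(spec.k_neighbors, len(y_train))
        model = KNeighborsClassifier(n_neighbors=k)
    else:
        model = RandomForestClassifier(n_estimators=spec.n_trees,
                                       random_state=spec.seed)
    return model.fit(X_train, y_train).predict(X_test).astype(int)


def evaluate(labels, predictions) -> PerformanceSummary:
    """Confusion counts and rates, with positive = considerable improvement.

    If a class is absent from the labels its conditional rate is NaN and
    the balanced accuracy falls back to the defined rate, with a warning.
    """
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if len(y) == 0 or len(y) != len(yhat):
        raise ParameterError("labels and predictions must be equal-length, non-empty")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec_ = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    defined = [r for r in (sens, spec_) if not np.isnan(r)]
    if len(defined) < 2:
        warnings.warn("one-class labels: balanced accuracy computed from the "
                      "defined rate only", stacklevel=2)
    ba = float(np.mean(defined))
    return PerformanceSummary(tp=tp, fp=fp, tn=tn, fn=fn,
                              sensitivity=sens, specificity=spec_,
                              precision=prec, balanced_accuracy=ba)


def loso_predict(spec: ModelSpec, X: pd.DataFrame, y: np.ndarray,
                 participant_ids: np.ndarray) -> pd.Series:
    """Pooled leave-one-subject-out predictions, one per dataset."""
    Xv = X.to_numpy(dtype=float)
    preds = np.empty(len(y), dtype=int)
    for train, test in loso_folds(participant_ids):
        preds[test] = fit_predict(spec, Xv[train], y[train], Xv[test])
    return pd.Series(preds, index=X.index, name=spec.family)


# --------------------------------------------------------------------------
# the grid

DEFAULT_FEATURE_SETS: tuple[frozenset, ...] = tuple(
    frozenset(s) for s in
    [{1}, {2}, {3}, {4}, {5}, {6},
     {1, 2}, {1, 3}, {1, 4}, {1, 5}, {1, 6},
     {1, 2, 3}, {1, 4, 6}, {1, 5, 6}, {1, 4, 5, 6}, {1, 2, 3, 4, 5, 6}])


def _set_label(s: frozenset) -> str:
    return ",".join(str(i) for i in sorted(s))


def run_grid(cohort: Cohort,
             labels: pd.DataFrame,
             feature_sets: tuple = DEFAULT_FEATURE_SETS,
             families: tuple = MODEL_FAMILIES,
             outcomes: tuple = SCALES,
             metric_table: pd.DataFrame | None = None,
             nonresponder_id: str = "02-right",
             seed: int = 17) -> GridResult:
    """Evaluate every (outcome, feature set, family) configuration via LOSO.

    Configurations whose features are unavailable (e.g. sets 3-5 without
    synthetic columns) are recorded under ``skipped`` rather than failing
    the run. Results are deterministic for a fixed seed.
    """
    rows = []
    predictions: dict = {}
    skipped: list = []
    specs = {fam: ModelSpec(fam, seed=seed) for fam in families}
    for fset in feature_sets:
        try:
            X, pids = build_feature_matrix(cohort, fset, metric_table)
        except FeatureUnavailableError as exc:
            skipped.append({"feature_sets": _set_label(fset), "reason": str(exc)})
            continue
        for outcome in outcomes:
            y = labels.loc[X.index, f"{outcome}_improved"].to_numpy(dtype=int)
            for fam in families:
                pred = loso_predict(specs[fam], X, y, pids)
                perf = evaluate(y, pred.to_numpy())
                nonresp_ok = None
                if nonresponder_id in pred.index:
                    nonresp_ok = bool(
                        pred[nonresponder_id]
                        == labels.loc[nonresponder_id, f"{outcome}_improved"])
                predictions[(outcome, _set_label(fset), fam)] = pred
                rows.append({
                    "outcome": outcome,
                    "feature_sets": _set_label(fset),
                    "model": fam,
                    "balanced_accuracy": perf.balanced_accuracy,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                    "precision": perf.precision,
                    "tp": perf.tp, "fp": perf.fp, "tn": perf.tn, "fn": perf.fn,
                    "nonresponder_correct": nonresp_ok,
                })
    table = pd.DataFrame(rows)
    hyper = {fam: specs[fam].describe() for fam in families}
    hyper["seed"] = seed
    return GridResult(table=table, predictions=predictions, labels=labels,
                      skipped=skipped, hyperparameters=hyper)


def nonresponder_check(grid: GridResult, dataset_id: str) -> pd.DataFrame:
    """Per-configuration flag: was this dataset's LOSO prediction correct?

    Raises ``KeyError`` for a dataset id absent from the evaluated cohort.
    """
    rows = []
    for (outcome, fsets, fam), pred in grid.predictions.items():
        if dataset_id not in pred.index:
            raise KeyError(f"dataset {dataset_id!r} not in the evaluated cohort")
        truth = bool(grid.labels.loc[dataset_id, f"{outcome}_improved"])
        rows.append({"outcome": outcome, "feature_sets": fsets, "model": fam,
                     "correct": bool(pred[dataset_id]) == truth})
    return pd.DataFrame(rows)


def best_models(grid: GridResult) -> pd.DataFrame:
    """Per outcome: the configuration with maximal balanced accuracy among
    those that predicted the unexpected non-responder correctly (falling
    back to all configurations when none did), ties broken toward fewer
    feature sets."""
    out = []
    t = grid.table.copy()
    t["n_sets"] = t["feature_sets"].str.count(",") + 1
    for outcome in t["outcome"].unique():
        sub = t[t["outcome"] == outcome]
        ok = sub[sub["nonresponder_correct"] == True]  # noqa: E712
        pool = ok if len(ok) else sub
        pool = pool.sort_values(["balanced_accuracy", "n_sets"],
                                ascending=[False, True], kind="mergesort")
        out.append(pool.iloc[0].drop(labels="n_sets"))
    return pd.DataFrame(out).reset_index(drop=True)


# --------------------------------------------------------------------------
# gain correlations


def correlate_gains(cohort: Cohort, covariate: str, scale: str
                    ) -> tuple[float, float]:
    """Pearson correlation between a covariate and the raw score change.

    The gain is post - pre for ARAT and BBT; for NHPT it is pre - post so
    that positive gains are improvements on every scale.
    """
    if scale not in SCALES:
        raise ParameterError(f"unknown scale {scale!r}")
    df = cohort.to_frame()
    if covariate not in df.columns:
        raise ParameterError(f"unknown covariate {covariate!r}")
    if len(df) < 3:
        raise ParameterError("need at least 3 datasets for a correlation")
    gain = (df[f"{scale}_pre"] - df[f"{scale}_post"] if scale == "nhpt"
            else df[f"{scale}_post"] - df[f"{scale}_pre"])
    x = df[covariate].astype(float)
    if x.std() == 0 or gain.std() == 0:
        raise ParameterError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, gain)
    return float(r), float(p)
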