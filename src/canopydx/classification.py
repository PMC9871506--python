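"""Imbalanced three-class deficiency diagnosis models.

The diagnosis task is three-class — CK (control), ND (nitrogen-deficient)
and the pooled PD\\KD (phosphorus/potassium-deficient) group, whose canopy
spectra are too similar to separate — with class sizes 48/48/96, so the
training protocol is built for imbalance:

1. stratified random 7:3 train/test split;
2. standardize, then PCA (components retaining 95% of variance by default),
   both fitted on training rows only;
3. SMOTE oversampling of the training rows (in PCA space) to equal class
   counts — the test set is never touched;
4. one of six classifiers — KNN, logistic regression (LR), Gaussian naive
   Bayes (NBM), SVM, decision tree (DT), random forest (RF) — tuned by grid
   search with stratified five-fold cross-validation maximising macro
   one-vs-rest ROC AUC;
5. precision, recall and F1 per class from one-vs-rest confusion counts
   (precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean)
   plus macro AUC — the unweighted mean of per-class one-vs-rest ROC areas —
   averaged over ten random splits.

SMOTE is implemented in-package: each synthetic minority sample is a
uniform interpolation between a real minority sample and one of its k
nearest within-class neighbours (k = 5 by default), seeded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .canopy_features import FEATURE_COLUMNS

ALGORITHMS: tuple[str, ...] = ("KNN", "LR", "NBM", "SVM", "DT", "RF")

#: pooled positive-class label for the P/K-deficient group
PDKD = "PD\\KD"

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "KNN": {"n_neighbors": [3, 5, 7, 9]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "NBM": {},
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "DT": {"max_depth": [3, 5, None]},
    "RF": {"n_estimators": [100, 300]},
}


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "KNN":
        return KNeighborsClassifier(**params)
    if algorithm == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if algorithm == "NBM":
        return GaussianNB(**params)
    if algorithm == "SVM":
        return SVC(decision_function_shape="ovr", random_state=seed, **params)
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    raise KeyError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _class_scores(clf, X: np.ndarray) -> np.ndarray:
    """Per-class score matrix (n, n_classes) for ROC analysis.

    Probabilities where the estimator provides them; otherwise the
    one-vs-rest decision margins, which are a monotone stand-in for class
    membership scores.
    """
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)
    scores = clf.decision_function(X)
    if scores.ndim == 1:
        scores = np.column_stack([-scores, scores])
    return scores


# ---------------------------------------------------------------------------
# dataset preparation


def pool_pk_labels(table: pd.DataFrame, include_recovery: bool = False) -> pd.DataFrame:
    """Map raw group labels to the three diagnostic classes.

    PD and KD rows are pooled into one PD\\KD class; recovery rows (NS, PS,
    KS) are excluded by default, as they are not part of the training
    protocol.
    """
    df = table.copy()
    keep = df["label"].isin(["CK", "ND", "PD", "KD"])
    if include_recovery:
        keep |= df["label"].isin(["NS", "PS", "KS"])
    df = df.loc[keep].reset_index(drop=True)
    df["class"] = df["label"].replace({"PD": PDKD, "KD": PDKD})
    return df


def split_dataset(table: pd.DataFrame, ratio: float = 0.7, seed: int = 0):
    """Stratified-by-class random split into train and test tables."""
    if not 0 < ratio < 1:
        raise ValueError("split ratio must be strictly between 0 and 1")
    y = table["class"] if "class" in table.columns else table["label"]
    counts = y.value_counts()
    if (counts < 2).any():
        raise ValueError(
            "every class needs >= 2 samples to appear on both sides of the "
            f"split; got {counts.to_dict()}"
        )
    train, test = train_test_split(
        table, train_size=ratio, stratify=y, random_state=seed
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# SMOTE


def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0):
    """Balance classes by synthetic-minority oversampling.

    Every class is brought up to the majority count. A synthetic sample is
    ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)``, where ``x_nn`` is one of
    the ``k`` nearest within-class neighbours of a randomly chosen real
    minority sample. Returns the augmented ``(X, y)`` with original rows
    first.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    X_new, y_new = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = int(n_max - cnt)
        if need == 0:
            continue
        Xc = X[y == cls]
        if len(Xc) == 1:
            synth = np.repeat(Xc, need, axis=0)
        else:
            kk = min(k, len(Xc) - 1)
            nn = NearestNeighbors(n_neighbors=kk + 1).fit(Xc)
            _, idx = nn.kneighbors(Xc)
            base = rng.integers(0, len(Xc), size=need)
            pick = rng.integers(1, kk + 1, size=need)  # skip self at column 0
            neigh = Xc[idx[base, pick]]
            u = rng.uniform(0.0, 1.0, size=(need, 1))
            synth = Xc[base] + u * (neigh - Xc[base])
        X_new.append(synth)
        y_new.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(X_new), np.concatenate(y_new)


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class TrainedModel:
    """Fitted standardize -> PCA -> SMOTE -> classifier pipeline."""

    algorithm: str
    scaler: StandardScaler
    pca: PCA
    classifier: object
    classes_: np.ndarray
    best_params: dict
    cv_auc: float
    feature_names: list[str]
    pca_variance: float | int
    smote_k: int
    seed: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(np.asarray(X, float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(self.transform(X))

    def scores(self, X: np.ndarray) -> np.ndarray:
        return _class_scores(self.classifier, self.transform(X))


def _fit_leg(X_tr, y_tr, algorithm, params, pca_variance, smote_k, seed):
    """Fit scaler -> PCA -> SMOTE -> classifier on one set of training rows."""
    scaler = StandardScaler().fit(X_tr)
    Xs = scaler.transform(X_tr)
    if isinstance(pca_variance, int):
        keep = min(pca_variance, min(Xs.shape))
    else:
        probe = PCA(svd_solver="full").fit(Xs)
        cum = np.cumsum(probe.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, pca_variance - 1e-12) + 1)
    pca = PCA(n_components=keep, svd_solver="full", random_state=seed).fit(Xs)
    Xp = pca.transform(Xs)
    Xb, yb = smote_oversample(Xp, y_tr, k=smote_k, seed=seed)
    clf = _make_estimator(algorithm, params, seed).fit(Xb, yb)
    return scaler, pca, clf


def _macro_auc(y_true, scores, classes) -> float:
    aucs = []
    y_true = np.asarray(y_true)
    for j, cls in enumerate(classes):
        pos = (y_true == cls).astype(int)
        if pos.min() == pos.max():
            continue  # class absent on one side; skip its one-vs-rest curve
        aucs.append(roc_auc_score(pos, scores[:, j]))
    return float(np.mean(aucs)) if aucs else float("nan")


def fit_model(
    train: pd.DataFrame,
    algorithm: str = "LR",
    grid: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    features=None,
    pca_variance: float | int = 0.95,
    smote_k: int = 5,
) -> TrainedModel:
    """Grid-search a classifier under the full preprocessing protocol.

    Each grid point is scored by stratified ``cv_folds``-fold CV macro
    one-vs-rest AUC; scaling, PCA and SMOTE are re-fitted inside every fold
    on that fold's training rows only, so no information leaks across the
    fold boundary. The winning point is refitted on all training rows.
    """
    if algorithm not in ALGORITHMS:
        raise KeyError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if len(train) == 0:
        raise ValueError("training table is empty")
    feats = list(features) if features is not None else [
        c for c in train.columns if c in FEATURE_COLUMNS
    ]
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    keys = sorted(grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))] or [{}]

    X = train[feats].to_numpy(float)
    y = train["class"].to_numpy() if "class" in train.columns else train["label"].to_numpy()
    classes = np.unique(y)

    best_params, best_auc = combos[0], -np.inf
    if len(combos) > 1:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        for params in combos:
            fold_aucs = []
            for tr_idx, va_idx in folds:
                scaler, pca, clf = _fit_leg(
                    X[tr_idx], y[tr_idx], algorithm, params, pca_variance, smote_k, seed
                )
                Xv = pca.transform(scaler.transform(X[va_idx]))
                fold_aucs.append(_macro_auc(y[va_idx], _class_scores(clf, Xv), clf.classes_))
            mean_auc = float(np.nanmean(fold_aucs))
            if mean_auc > best_auc:
                best_auc, best_params = mean_auc, params
    else:
        best_auc = float("nan")

    scaler, pca, clf = _fit_leg(X, y, algorithm, best_params, pca_variance, smote_k, seed)
    return TrainedModel(
        algorithm=algorithm,
        scaler=scaler,
        pca=pca,
        classifier=clf,
        classes_=clf.classes_,
        best_params=best_params,
        cv_auc=best_auc,
        feature_names=feats,
        pca_variance=pca_variance,
        smote_k=smote_k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    precision_undefined: bool = False


@dataclass
class EvaluationResult:
    """One test split: one-vs-rest counts, printed-equation metrics, AUC."""

    per_class: dict[str, ClassMetrics]
    macro_auc: float
    n_test: int

    def metric(self, cls: str, name: str) -> float:
        return getattr(self.per_class[cls], name)


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> ClassMetrics:
    """Precision/recall/F1 from one-vs-rest confusion counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = 2*precision*recall/(precision+recall). A precision with no
    positive predictions is reported as 0 and flagged.
    """
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return ClassMetrics(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                        recall=recall, f1=f1, precision_undefined=undefined)


def evaluate(model: TrainedModel, test: pd.DataFrame) -> EvaluationResult:
    """Score a fitted model on held-out rows."""
    if len(test) == 0:
        raise ValueError("test table is empty")
    X = test[model.feature_names].to_numpy(float)
    y = test["class"].to_numpy() if "class" in test.columns else test["label"].to_numpy()
    pred = model.predict(X)
    scores = model.scores(X)

    per_class = {}
    for cls in model.classes_:
        tp = int(np.sum((y == cls) & (pred == cls)))
        fp = int(np.sum((y != cls) & (pred == cls)))
        fn = int(np.sum((y == cls) & (pred != cls)))
        tn = int(np.sum((y != cls) & (pred != cls)))
        per_class[cls] = metrics_from_counts(tp, fp, fn, tn)
    return EvaluationResult(
        per_class=per_class,
        macro_auc=_macro_auc(y, scores, model.classes_),
        n_test=len(y),
    )


@dataclass
class EvaluationReport:
    """Metrics averaged over repeated random splits."""

    algorithm: str
    per_repeat: pd.DataFrame  # one row per (repeat, class) + macro AUC column
    means: pd.DataFrame  # per-class means over repeats
    macro_auc_mean: float
    seeds: list[int]
    day: int | None = None
    agl: float | None = None


def repeated_evaluation(
    table: pd.DataFrame,
    algorithm: str = "LR",
    n_repeats: int = 10,
    base_seed: int = 0,
    ratio: float = 0.7,
    grid: dict | None = None,
    cv_folds: int = 5,
    features=None,
    pca_variance: float | int = 0.95,
    smote_k: int = 5,
    reuse_grid: bool = False,
) -> EvaluationReport:
    """Average the split/fit/evaluate protocol over repeated random splits.

    Repeat ``r`` uses seed ``base_seed + r`` for the split, the CV folds,
    SMOTE and the estimator. Grid search re-runs inside every repeat unless
    ``reuse_grid`` fixes the first repeat's winning hyperparameters.
    """
    if "class" not in table.columns:
        table = pool_pk_labels(table)
    seeds = [base_seed + r for r in range(n_repeats)]
    rows = []
    fixed_grid = None
    for r, seed in enumerate(seeds):
        train, test = split_dataset(table, ratio=ratio, seed=seed)
        try:
            model = fit_model(
                train, algorithm=algorithm,
                grid=fixed_grid if fixed_grid is not None else grid,
                cv_folds=cv_folds, seed=seed, features=features,
                pca_variance=pca_variance, smote_k=smote_k,
            )
        except Exception as exc:  # noqa: BLE001 - annotate with repeat index
            raise RuntimeError(f"repeat {r} (seed {seed}) failed: {exc}") from exc
        if reuse_grid and fixed_grid is None:
            fixed_grid = {k: [v] for k, v in model.best_params.items()}
        result = evaluate(model, test)
        for cls, m in result.per_class.items():
            rows.append({
                "repeat": r, "seed": seed, "class": cls,
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
                "macro_auc": result.macro_auc,
            })
    per_repeat = pd.DataFrame(rows)
    means = per_repeat.groupby("class")[["precision", "recall", "f1"]].mean()
    macro = float(per_repeat.drop_duplicates("repeat")["macro_auc"].mean())
    return EvaluationReport(
        algorithm=algorithm,
        per_repeat=per_repeat,
        means=means,
        macro_auc_mean=macro,
        seeds=seeds,
    )


def compare_conditions(
    datasets: dict,
    algorithms=("LR",),
    n_repeats: int = 10,
    base_seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Evaluate algorithms across acquisition conditions.

    ``datasets`` maps ``(day, agl)`` to a feature table. Returns a
    long-format grid (algorithm, day, agl, class, metric, mean, sd) plus
    macro-AUC rows (class = "macro"), ready for plotting.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    rows = []
    for (day, agl), table in datasets.items():
        for algorithm in algorithms:
            report = repeated_evaluation(
                table, algorithm=algorithm, n_repeats=n_repeats,
                base_seed=base_seed, **kwargs,
            )
            pr = report.per_repeat
            for cls, grp in pr.groupby("class"):
                for metric in ("precision", "recall", "f1"):
                    rows.append({
                        "algorithm": algorithm, "day": day, "agl": agl,
                        "class": cls, "metric": metric,
                        "mean": float(grp[metric].mean()),
                        "sd": float(grp[metric].std(ddof=1)) if len(grp) > 1 else 0.0,
                    })
            auc = pr.drop_duplicates("repeat")["macro_auc"]
            rows.append({
                "algorithm": algorithm, "day": day, "agl": agl,
                "class": "macro", "metric": "auc",
                "mean": float(auc.mean()),
                "sd": float(auc.std(ddof=1)) if len(auc) > 1 else 0.0,
            })
    return pd.DataFrame(rows)
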