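"""QDA classification of lesions with patient-level cross-validation.

The lesion-level feature table (one row per lesion: ``lesion_id``,
``patient_id``, ``label`` plus named global features) is classified by
quadratic discriminant analysis (QDA): class-conditional multivariate
Gaussians with empirical priors and a 0.5 posterior threshold, malignant
being the positive class.  Feature selection is a sequential forward search
(SFS) maximising training ROC AUC, run independently inside every fold of a
leave-one-patient-out cross-validation (LOPO-CV) so the left-out patient
never informs selection or training.  Features chosen in at least half the
folds form the pool's ``fselected`` set, and pool-specific QDA posteriors
are combined by a weighted average whose weights are optimised on a 0.1-step
simplex grid inside an inner LOPO-CV loop (closest point to the ideal ROC
corner).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from math import isqrt

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import BENIGN, MALIGNANT

__all__ = [
    "QdaModel",
    "train_qda",
    "roc_auc",
    "sfs_select",
    "lopo_cv",
    "sweep_n_sfs",
    "selection_frequency",
    "compute_metrics",
    "simplex_grid",
    "optimize_weights",
    "ensemble_predict",
    "ensemble_lopo",
    "CVResult",
    "CLINICAL_CONFUSIONS",
]

#: Confusion matrices (TN, FP, FN, TP; malignant positive) printed for the
#: clinical 60-lesion evaluation of this pipeline; used as worked examples
#: for the metric computations.
CLINICAL_CONFUSIONS: dict[str, tuple[int, int, int, int]] = {
    "phasor": (33, 8, 6, 13),
    "biexponential": (29, 12, 3, 16),
    "intensity": (13, 28, 3, 16),
    "ensemble_phasor_biexponential": (37, 4, 3, 16),
    "ensemble_biexponential_intensity": (27, 14, 3, 16),
    "ensemble_phasor_intensity": (37, 4, 4, 15),
}


# ---------------------------------------------------------------------------
# QDA


@dataclass
class QdaModel:
    """Class-conditional Gaussian (QDA) classifier for benign vs malignant."""

    feature_names: tuple[str, ...]
    means: np.ndarray          # (2, k): rows benign, malignant
    covs: np.ndarray           # (2, k, k)
    priors: np.ndarray         # (2,), sums to one
    _chol: np.ndarray = field(repr=False, default=None)
    _logdet: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.covs)
            self._logdet = 2.0 * np.sum(
                np.log(np.diagonal(self._chol, axis1=-2, axis2=-1)), axis=-1
            )

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Per-class Gaussian log density, shape (n, 2)."""
        from scipy.linalg import solve_triangular

        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = X.shape[1]
        out = np.empty((len(X), 2))
        for c in range(2):
            d = (X - self.means[c]).T
            z = solve_triangular(self._chol[c], d, lower=True)
            maha = np.sum(z * z, axis=0)
            out[:, c] = -0.5 * (maha + self._logdet[c] + k * np.log(2 * np.pi))
        return out

    def posterior_malignant(self, X: np.ndarray) -> np.ndarray:
        """Bayes posterior probability of the malignant class, in [0, 1]."""
        ll = self.log_likelihood(X) + np.log(self.priors)
        m = ll.max(axis=1, keepdims=True)
        p = np.exp(ll - m)
        return p[:, 1] / p.sum(axis=1)


def _records_matrix(records: pd.DataFrame, feature_names) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in feature_names if f not in records.columns]
    if missing:
        raise KeyError(f"missing features: {missing}")
    X = records.loc[:, list(feature_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in records")
    y = (records["label"] == MALIGNANT).to_numpy()
    return X, y


def train_qda(
    records: pd.DataFrame,
    feature_names,
    priors: str = "empirical",
    ridge_rel: float = 1e-6,
) -> QdaModel:
    """Fit class-conditional Gaussians with empirical (or equal) priors.

    Covariances use the unbiased (1/(n-1)) estimator; a ridge of
    ``ridge_rel`` times the mean diagonal is added whenever a class
    covariance is near-singular (few malignant training lesions against 5-7
    features can be ill-conditioned).
    """
    X, y = _records_matrix(records, feature_names)
    k = X.shape[1]
    means = np.empty((2, k))
    covs = np.empty((2, k, k))
    counts = np.empty(2)
    for c, mask in enumerate([~y, y]):
        Xi = X[mask]
        if len(Xi) < 2:
            raise ValueError("each class needs at least two records")
        counts[c] = len(Xi)
        means[c] = Xi.mean(axis=0)
        covs[c] = np.cov(Xi, rowvar=False).reshape(k, k)
    for c in range(2):
        eps = ridge_rel * np.mean(np.diag(covs[c]))
        for _ in range(4):
            try:
                np.linalg.cholesky(covs[c])
                break
            except np.linalg.LinAlgError:
                covs[c] = covs[c] + max(eps, 1e-300) * np.eye(k)
                eps *= 1e3
        else:
            raise np.linalg.LinAlgError(
                "class covariance singular after regularization"
            )
        if np.min(np.linalg.eigvalsh(covs[c])) < eps:
            covs[c] = covs[c] + eps * np.eye(k)
    pri = counts / counts.sum() if priors == "empirical" else np.array([0.5, 0.5])
    return QdaModel(feature_names=tuple(feature_names), means=means, covs=covs,
                    priors=pri)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, malignant as the positive class.

    ``labels`` may be booleans or benign/malignant strings.  Equals the
    normalised Mann-Whitney U statistic (ties counted half).
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = labels == MALIGNANT
    labels = labels.astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# SFS + LOPO-CV


def _candidate_auc(records: pd.DataFrame, feats: list[str], priors: str,
                   eval_mode: str) -> float:
    if eval_mode == "resub":
        model = train_qda(records, feats, priors=priors)
        X, y = _records_matrix(records, feats)
        return roc_auc(model.posterior_malignant(X), y)
    if eval_mode == "inner-lopo":
        post, truth = [], []
        for _, inner_train, inner_test in _iter_folds(records):
            model = train_qda(inner_train, feats, priors=priors)
            X, y = _records_matrix(inner_test, feats)
            post.append(model.posterior_malignant(X))
            truth.append(y)
        return roc_auc(np.concatenate(post), np.concatenate(truth))
    raise ValueError("eval_mode must be 'resub' or 'inner-lopo'")


def sfs_select(
    records: pd.DataFrame,
    pool,
    n_sfs: int,
    priors: str = "empirical",
    eval_mode: str = "resub",
) -> list[str]:
    """Greedy sequential forward selection maximising training-set AUC.

    At each step the feature whose addition yields the highest AUC of a QDA
    fit on the training records is appended; exact AUC ties keep the earlier
    feature in the pool's canonical order.  ``eval_mode`` scores candidates by
    resubstitution on the training set (default) or by an inner
    leave-one-patient-out loop (``"inner-lopo"``).  Candidates whose QDA fit
    fails are skipped with a warning.
    """
    pool = list(pool)
    if n_sfs > len(pool):
        raise ValueError("n_sfs exceeds the pool size")
    selected: list[str] = []
    for _ in range(n_sfs):
        best_auc, best_feat = -np.inf, None
        for feat in pool:
            if feat in selected:
                continue
            try:
                auc = _candidate_auc(records, selected + [feat], priors, eval_mode)
            except (np.linalg.LinAlgError, ValueError) as exc:
                warnings.warn(f"SFS skipped {feat!r}: {exc}")
                continue
            if auc > best_auc:
                best_auc, best_feat = auc, feat
        if best_feat is None:
            raise RuntimeError("no candidate feature could be fit")
        selected.append(best_feat)
    return selected


@dataclass
class FoldResult:
    patient_id: str
    selected_features: tuple[str, ...]
    lesion_ids: tuple[str, ...]
    posteriors: np.ndarray
    true_malignant: np.ndarray
    weights: tuple[float, ...] | None = None


@dataclass
class CVResult:
    """Aggregate outcome of a leave-one-patient-out cross-validation."""

    folds: list[FoldResult]
    confusion: tuple[int, int, int, int]   # TN, FP, FN, TP
    metrics: dict[str, float]              # percentages
    n_sfs: int | None = None

    @property
    def n_lesions(self) -> int:
        return int(sum(self.confusion))


def _confusion(posteriors: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    pred = posteriors >= 0.5
    tn = int(np.sum(~truth & ~pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    tp = int(np.sum(truth & pred))
    return tn, fp, fn, tp


def compute_metrics(tn: int, fp: int, fn: int, tp: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and F-score as percentages.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); the F-score is the
    harmonic mean of precision and sensitivity with malignant positive.
    Undefined ratios (zero denominators) come back as NaN.
    """
    if min(tn, fp, fn, tp) < 0 or tn + fp + fn + tp == 0:
        raise ValueError("confusion counts must be non-negative with total > 0")

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = (tp + tn) / (tn + fp + fn + tp)
    prec = ratio(tp, tp + fp)
    f = ratio(2 * prec * sn, prec + sn) if np.isfinite(prec) and np.isfinite(sn) else float("nan")
    return {
        "accuracy": 100.0 * acc,
        "sensitivity": 100.0 * sn,
        "specificity": 100.0 * sp,
        "f_score": 100.0 * f,
    }


def _iter_folds(records: pd.DataFrame):
    for patient in pd.unique(records["patient_id"]):
        test = records["patient_id"] == patient
        yield str(patient), records[~test], records[test]


def lopo_cv(
    records: pd.DataFrame,
    pool,
    n_sfs: int,
    priors: str = "empirical",
    eval_mode: str = "resub",
) -> CVResult:
    """Leave-one-patient-out CV with per-fold SFS feature selection.

    One fold per patient: SFS on the remaining patients, QDA retrained on the
    selected subset, the left-out patient's lesions classified at the 0.5
    posterior threshold.  The aggregate confusion matrix covers every lesion
    exactly once.
    """
    if records["patient_id"].nunique() < 2:
        raise ValueError("need at least two patients for LOPO-CV")
    folds: list[FoldResult] = []
    post_all, true_all = [], []
    for patient, train, test in _iter_folds(records):
        y_train = (train["label"] == MALIGNANT).to_numpy()
        if y_train.all() or not y_train.any():
            raise ValueError(f"fold {patient}: training data has a single class")
        feats = sfs_select(train, pool, n_sfs, priors=priors, eval_mode=eval_mode)
        model = train_qda(train, feats, priors=priors)
        X_test, y_test = _records_matrix(test, feats)
        post = model.posterior_malignant(X_test)
        folds.append(
            FoldResult(
                patient_id=patient,
                selected_features=tuple(feats),
                lesion_ids=tuple(test["lesion_id"]),
                posteriors=post,
                true_malignant=y_test,
            )
        )
        post_all.append(post)
        true_all.append(y_test)
    posteriors = np.concatenate(post_all)
    truth = np.concatenate(true_all)
    conf = _confusion(posteriors, truth)
    return CVResult(folds=folds, confusion=conf, metrics=compute_metrics(*conf),
                    n_sfs=n_sfs)


def max_features(n_lesions: int) -> int:
    """Feature-count cap: the integer part of sqrt(n_lesions) (7 for 60)."""
    return isqrt(n_lesions)


def sweep_n_sfs(
    records: pd.DataFrame,
    pool,
    n_range=None,
    priors: str = "empirical",
) -> tuple[int, CVResult, pd.DataFrame]:
    """Run the LOPO-CV for each feature count and pick the best F-score.

    The sweep runs from 1 to min(pool size, floor(sqrt(n_lesions))).  Ties on
    F-score prefer higher sensitivity (missing a malignant lesion is the
    costlier error), remaining ties the smaller feature count.
    """
    pool = list(pool)
    if n_range is None:
        n_range = range(1, min(len(pool), max_features(len(records))) + 1)
    results: dict[int, CVResult] = {}
    rows = []
    for n in n_range:
        cv = lopo_cv(records, pool, n, priors=priors)
        results[n] = cv
        rows.append({"n_sfs": n, **cv.metrics})
    table = pd.DataFrame(rows)
    best = None
    for n, cv in results.items():
        f = np.nan_to_num(cv.metrics["f_score"], nan=-1.0)
        sn = np.nan_to_num(cv.metrics["sensitivity"], nan=-1.0)
        key = (f, sn, -n)
        if best is None or key > best[0]:
            best = (key, n)
    n_selected = best[1]
    return n_selected, results[n_selected], table


def selection_frequency(cv: CVResult) -> pd.DataFrame:
    """Per-feature fraction of folds (percent) in which SFS chose it.

    Features at or above 50% form the pool's ``fselected`` set (column
    ``selected``); the table is sorted by decreasing frequency.
    """
    counts: dict[str, int] = {}
    for fold in cv.folds:
        for f in fold.selected_features:
            counts[f] = counts.get(f, 0) + 1
    n = len(cv.folds)
    table = pd.DataFrame(
        {
            "feature": list(counts),
            "frequency_pct": [100.0 * c / n for c in counts.values()],
        }
    ).sort_values(["frequency_pct", "feature"], ascending=[False, True], ignore_index=True)
    table["selected"] = table["frequency_pct"] >= 50.0
    return table


def fselected(cv: CVResult) -> list[str]:
    """Features selected in at least half the LOPO-CV folds."""
    table = selection_frequency(cv)
    return table.loc[table["selected"], "feature"].tolist()


# ---------------------------------------------------------------------------
# ensembles


def simplex_grid(k: int, step: float = 0.1) -> np.ndarray:
    """All weight vectors on the unit simplex with the given grid step.

    Lexicographically ordered; 11 vectors for k=2, 66 for k=3 at step 0.1.
    """
    n = int(round(1.0 / step))
    grid = []
    for combo in product(range(n + 1), repeat=k - 1):
        if sum(combo) <= n:
            rest = n - sum(combo)
            grid.append(tuple(c / n for c in combo) + (rest / n,))
    return np.array(sorted(grid))


def ensemble_predict(posteriors: np.ndarray, weights: np.ndarray,
                     tol: float = 1e-9) -> np.ndarray:
    """Weighted average of pool posteriors; weights must sum to one."""
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > tol or np.any(weights < -tol):
        raise ValueError("weights must be non-negative and sum to one")
    return np.asarray(posteriors, dtype=float) @ weights


def _pool_posteriors_inner(
    train: pd.DataFrame, pools: dict[str, list[str]], priors: str
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out posteriors per pool from an inner LOPO loop over ``train``."""
    post_rows, truth = [], []
    for patient, inner_train, inner_test in _iter_folds(train):
        y_inner = (inner_train["label"] == MALIGNANT).to_numpy()
        if y_inner.all() or not y_inner.any():
            raise ValueError(f"inner fold {patient}: single-class training data")
        models = {name: train_qda(inner_train, feats, priors=priors)
                  for name, feats in pools.items()}
        cols = []
        for name, feats in pools.items():
            X, _ = _records_matrix(inner_test, feats)
            cols.append(models[name].posterior_malignant(X))
        post_rows.append(np.column_stack(cols))
        truth.append((inner_test["label"] == MALIGNANT).to_numpy())
    return np.vstack(post_rows), np.concatenate(truth)


def optimize_weights(
    train: pd.DataFrame,
    pools: dict[str, list[str]],
    step: float = 0.1,
    priors: str = "empirical",
) -> np.ndarray:
    """Grid-search ensemble weights closest to the ideal ROC corner.

    An inner LOPO-CV over the training patients produces held-out posteriors
    for each pool; every simplex-grid weight vector is scored by the
    Euclidean distance of its (1-Sp, Sn) operating point (0.5 threshold)
    from the ideal (0, 1).  Ties return the lexicographically smallest
    vector.
    """
    if train["patient_id"].nunique() < 2:
        raise ValueError("need at least two training patients")
    post, truth = _pool_posteriors_inner(train, pools, priors)
    grid = simplex_grid(len(pools), step)
    best_dist, best_w = np.inf, None
    for w in grid:
        conf = _confusion(post @ w, truth)
        m = compute_metrics(*conf)
        dist = float(
            np.hypot(1.0 - m["specificity"] / 100.0, 1.0 - m["sensitivity"] / 100.0)
        )
        if dist < best_dist:
            best_dist, best_w = dist, w
    return best_w


def ensemble_lopo(
    records: pd.DataFrame,
    pools: dict[str, list[str]],
    step: float = 0.1,
    priors: str = "empirical",
) -> CVResult:
    """Weighted-posterior ensemble evaluated by outer LOPO-CV.

    Per outer fold: weights are optimised on the training patients (inner
    LOPO loop), the pool QDAs are retrained on all training data, and the
    left-out lesions are classified by the weighted posterior at 0.5.  The
    feature sets per pool are fixed in advance (selection-frequency output).
    """
    folds: list[FoldResult] = []
    post_all, true_all = [], []
    for patient, train, test in _iter_folds(records):
        w = optimize_weights(train, pools, step=step, priors=priors)
        models = {name: train_qda(train, feats, priors=priors)
                  for name, feats in pools.items()}
        cols = []
        for name, feats in pools.items():
            X, _ = _records_matrix(test, feats)
            cols.append(models[name].posterior_malignant(X))
        post = ensemble_predict(np.column_stack(cols), w)
        y_test = (test["label"] == MALIGNANT).to_numpy()
        folds.append(
            FoldResult(
                patient_id=patient,
                selected_features=tuple(f for fs in pools.values() for f in fs),
                lesion_ids=tuple(test["lesion_id"]),
                posteriors=post,
                true_malignant=y_test,
                weights=tuple(float(x) for x in w),
            )
        )
        post_all.append(post)
        true_all.append(y_test)
    posteriors = np.concatenate(post_all)
    truth = np.concatenate(true_all)
    conf = _confusion(posteriors, truth)
    return CVResult(folds=folds, confusion=conf, metrics=compute_metrics(*conf))
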