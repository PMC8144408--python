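"""Linear discriminant analysis with grouped cross-validation.

Binary LDA over the 32 normalized ROI features, classifying each tested
stimulation setting as optimal (label 1) or non-optimal (label 0).  The two
classes share a pooled within-class covariance which, with only tens of
settings against 32 features, is shrunk toward the average-variance diagonal:

    Sigma_lambda = (1 - lambda) * Sigma + lambda * mean(diag(Sigma)) * I

The discriminant is w = Sigma_lambda^{-1} (mu1 - mu0) with bias placing the
boundary at the midpoint of the class means (plus a log-prior offset; priors
are equal by default).  Cross-validation folds are grouped by patient so
that all runs of one patient stay on the same side of every split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LdaModel",
    "CvResult",
    "ConfusionMatrix",
    "fit_lda",
    "predict_lda",
    "cross_validate",
    "evaluate",
    "permutation_cv",
]


@dataclass
class LdaModel:
    mu0: np.ndarray
    mu1: np.ndarray
    cov: np.ndarray  # shrunk pooled covariance Sigma_lambda
    shrinkage: float
    priors: tuple[float, float]
    w: np.ndarray
    b: float
    feature_names: tuple[str, ...] | None = None
    train_patients: frozenset = field(default_factory=frozenset)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w.size:
            raise ValueError("feature dimension mismatch")
        return X @ self.w + self.b


@dataclass
class CvResult:
    fold_accuracies: list[float]
    pooled_accuracy: float
    fold_patients: list[list]
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pooled_accuracy <= 1.0):
            raise ValueError("pooled accuracy must be in [0, 1]")


@dataclass
class ConfusionMatrix:
    """Counts with optimal as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
        }


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float = 0.1,
    priors: tuple[float, float] = (0.5, 0.5),
    feature_names=None,
    train_patients=(),
) -> LdaModel:
    """Fit shrinkage-regularized LDA; score(x) > 0 predicts optimal."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p with one label per row")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 samples")
    if not (0 <= shrinkage <= 1):
        raise ValueError("shrinkage must be in [0, 1]")
    if not np.isclose(sum(priors), 1.0):
        raise ValueError("priors must sum to 1")

    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    # pooled within-class covariance
    S = np.zeros((X.shape[1], X.shape[1]))
    for Xc, mu in ((X0, mu0), (X1, mu1)):
        D = Xc - mu
        S += D.T @ D
    denom = max(n0 + n1 - 2, 1)
    S /= denom
    avg_var = np.trace(S) / S.shape[0]
    cov = (1.0 - shrinkage) * S + shrinkage * avg_var * np.eye(S.shape[0])
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized covariance is not positive definite; increase shrinkage"
        ) from exc
    w = np.linalg.solve(cov, mu1 - mu0)
    b = float(-w @ (mu0 + mu1) / 2.0 + np.log(priors[1] / priors[0]))
    return LdaModel(
        mu0=mu0,
        mu1=mu1,
        cov=cov,
        shrinkage=shrinkage,
        priors=tuple(priors),
        w=w,
        b=b,
        feature_names=tuple(feature_names) if feature_names is not None else None,
        train_patients=frozenset(train_patients),
    )


def predict_lda(model: LdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and raw discriminant scores; a score of exactly 0 is non-optimal."""
    scores = model.score(X)
    return (scores > 0).astype(int), scores


def _group_folds(patients: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    unique = np.array(sorted(set(patients), key=str))
    if unique.size < k:
        raise ValueError(f"need at least {k} patient groups, got {unique.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    return [np.array(f) for f in np.array_split(perm, k)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    patient_groups,
    k: int = 5,
    shrinkage: float = 0.1,
    seed: int = 0,
    priors: tuple[float, float] = (0.5, 0.5),
) -> CvResult:
    """Grouped k-fold CV: patients shuffled by seed, runs follow their patient.

    Raises if any training split lacks one of the classes.  The pooled
    accuracy aggregates all held-out rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    patients = np.asarray(patient_groups)
    folds = _group_folds(patients, k, seed)
    correct = 0
    fold_acc: list[float] = []
    for fold in folds:
        test_mask = np.isin(patients, fold)
        if set(np.unique(y[~test_mask])) != {0, 1}:
            raise ValueError("a training split is missing a class")
        model = fit_lda(
            X[~test_mask], y[~test_mask], shrinkage=shrinkage, priors=priors
        )
        pred, _ = predict_lda(model, X[test_mask])
        hits = int((pred == y[test_mask]).sum())
        correct += hits
        fold_acc.append(hits / max(int(test_mask.sum()), 1))
    return CvResult(
        fold_accuracies=fold_acc,
        pooled_accuracy=correct / len(y),
        fold_patients=[list(f) for f in folds],
        seed=seed,
    )


def evaluate(
    model: LdaModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    test_patients=None,
) -> ConfusionMatrix:
    """Confusion matrix on held-out data; refuses train/test patient overlap."""
    y_test = np.asarray(y_test).astype(int)
    if test_patients is not None and model.train_patients:
        overlap = set(test_patients) & set(model.train_patients)
        if overlap:
            raise ValueError(f"test patients overlap training set: {sorted(overlap)}")
    pred, _ = predict_lda(model, X_test)
    tp = int(((pred == 1) & (y_test == 1)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def permutation_cv(
    X: np.ndarray,
    y: np.ndarray,
    patient_groups,
    n_permutations: int = 100,
    k: int = 5,
    shrinkage: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Pooled CV accuracies under uniformly permuted labels (chance control).

    Permutation i uses seed ``seed + i`` for both the label shuffle and the
    fold assignment.  The mean should sit near 0.5 for an unbiased,
    leakage-free pipeline regardless of the class base rate (equal priors).
    """
    y = np.asarray(y).astype(int)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        rng = np.random.default_rng(seed + i)
        y_perm = rng.permutation(y)
        res = cross_validate(
            X, y_perm, patient_groups, k=k, shrinkage=shrinkage, seed=seed + i
        )
        accs[i] = res.pooled_accuracy
    return accs
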