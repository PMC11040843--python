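"""Covariance-manifold features and linear classifiers for EEG decoding.

Both decoding pipelines represent an EEG window by its spatial covariance
matrix, a symmetric positive-definite (SPD) matrix living on a curved
manifold.  Under the affine-invariant Riemannian metric the distance between
SPD matrices P and Q is ``d(P, Q) = ||log(Q^{-1/2} P Q^{-1/2})||_F``; mapping
every covariance to the tangent space at the Riemannian mean of the training
set turns them into Euclidean feature vectors that a linear classifier can
separate.

This module implements that machinery directly — sample covariance with SPD
safeguards, the Karcher mean, the tangent-space (log) map and its inverse,
XDawn spatial filtering for evoked responses, and the two linear classifiers
used downstream (L2 logistic regression and shrinkage LDA) — with a thin
scikit-learn estimator layer (`Covariances`, `TangentSpace`,
`XdawnCovariances`, `ShrinkageLDA`) so the pieces compose into Pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .signals import DegenerateInputError

__all__ = [
    "sample_covariance",
    "spd_mean",
    "tangent_map",
    "tangent_inverse",
    "airm_distance",
    "xdawn_filters",
    "xdawn_augment",
    "fit_classifier",
    "kfold_scores",
    "LinearClassifier",
    "TrainingMetrics",
    "Covariances",
    "TangentSpace",
    "XdawnCovariances",
    "ShrinkageLDA",
]


# ---------------------------------------------------------------------------
# SPD primitives


def _eigh_fun(P: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, V = np.linalg.eigh(P)
    return (V * fun(w)) @ V.T


def _logm(P: np.ndarray) -> np.ndarray:
    return _eigh_fun(P, np.log)


def _expm(S: np.ndarray) -> np.ndarray:
    return _eigh_fun(S, np.exp)


def _invsqrtm(P: np.ndarray) -> np.ndarray:
    return _eigh_fun(P, lambda w: 1.0 / np.sqrt(w))


def _sqrtm(P: np.ndarray) -> np.ndarray:
    return _eigh_fun(P, np.sqrt)


def sample_covariance(epoch: np.ndarray) -> np.ndarray:
    """Mean-centered sample covariance of one epoch (channels x samples).

    Guarantees an SPD output: if the smallest eigenvalue falls below
    1e-8 of the trace (rank deficiency, duplicated channels), a
    trace-scaled diagonal loading is added.

    Raises
    ------
    DegenerateInputError
        If the epoch carries no variance at all (constant channels), where
        no amount of relative loading can produce a meaningful covariance.
    """
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("epoch must be channels x samples with >= 2 of each")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / (X.shape[1] - 1)
    tr = np.trace(C)
    if tr <= 0:
        raise DegenerateInputError("epoch has zero variance on every channel")
    w = np.linalg.eigvalsh(C)
    floor = 1e-8 * tr
    if w[0] < floor:
        C = C + (floor - min(w[0], 0.0) + floor) * np.eye(C.shape[0])
    return 0.5 * (C + C.T)


def spd_mean(
    matrices: np.ndarray, tol: float = 1e-8, max_iter: int = 300
) -> np.ndarray:
    """Affine-invariant Riemannian (Karcher) mean of SPD matrices.

    Fixed-point iteration: at each step the matrices are mapped to the
    tangent space at the current estimate, averaged, and the estimate is
    moved along the resulting geodesic (with a backtracking line search on
    the Karcher cost, which keeps the iteration convergent on widely spread
    inputs).  Converged when the Frobenius norm of the mean tangent update
    drops below ``tol``; log-scale tangents make this threshold effectively
    scale-free.
    """
    Ps = np.asarray(matrices, dtype=float)
    if Ps.ndim != 3 or Ps.shape[1] != Ps.shape[2]:
        raise ValueError("matrices must be a stack of square matrices")

    def logs_at(M):
        M_isqrt = _invsqrtm(M)
        L = np.stack([_logm(M_isqrt @ P @ M_isqrt) for P in Ps])
        return L, float(np.sum(L**2))  # cost = sum of squared distances

    M = Ps.mean(axis=0)
    L, cost = logs_at(M)
    step = 1.0
    for _ in range(max_iter):
        S = L.mean(axis=0)
        norm = np.linalg.norm(S, "fro")
        if norm < tol:
            return M
        # gradient step along the geodesic with Armijo backtracking: the
        # Karcher cost is geodesically convex, so enforcing descent makes
        # the iteration globally convergent even when a unit step (the
        # classical fixed point) would overshoot on widely spread inputs.
        M_sqrt = _sqrtm(M)
        step = min(step * 1.5, 1.0)
        while True:
            cand = M_sqrt @ _expm(step * S) @ M_sqrt
            cand = 0.5 * (cand + cand.T)
            L_new, cost_new = logs_at(cand)
            if cost_new <= cost - 1e-4 * step * len(Ps) * norm**2 or step < 1e-4:
                break
            step /= 2.0
        M, L, cost = cand, L_new, cost_new
    raise RuntimeError(
        f"Karcher mean did not converge within {max_iter} iterations "
        f"(last update norm {norm:.3e})"
    )


def tangent_map(P: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map an SPD matrix to the tangent space at ``reference``.

    Returns the vectorized upper triangle of
    ``log(reference^{-1/2} P reference^{-1/2})`` with off-diagonal entries
    weighted by sqrt(2), so the Euclidean norm of the vector equals the
    affine-invariant distance ``d(P, reference)``.
    """
    P = np.asarray(P, dtype=float)
    R = np.asarray(reference, dtype=float)
    if P.shape != R.shape:
        raise ValueError(f"dimension mismatch: P {P.shape} vs reference {R.shape}")
    R_isqrt = _invsqrtm(R)
    S = _logm(R_isqrt @ P @ R_isqrt)
    return _vech(S)


def tangent_inverse(vec: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_map` (the exponential map at ``reference``)."""
    S = _unvech(np.asarray(vec, dtype=float))
    R_sqrt = _sqrtm(np.asarray(reference, dtype=float))
    return R_sqrt @ _expm(S) @ R_sqrt


def _vech(S: np.ndarray) -> np.ndarray:
    n = S.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return S[iu] * weights


def _unvech(v: np.ndarray) -> np.ndarray:
    # solve n(n+1)/2 = len(v)
    n = int(round((np.sqrt(8 * len(v) + 1) - 1) / 2))
    if n * (n + 1) // 2 != len(v):
        raise ValueError(f"vector length {len(v)} is not triangular")
    iu = np.triu_indices(n)
    S = np.zeros((n, n))
    weights = np.where(iu[0] == iu[1], 1.0, 1.0 / np.sqrt(2.0))
    S[iu] = v * weights
    S = S + np.triu(S, 1).T
    return S


def airm_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Affine-invariant Riemannian distance: sqrt(sum log^2 eig(Q^{-1} P))."""
    w = sla.eigvalsh(P, Q)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


# ---------------------------------------------------------------------------
# XDawn spatial filtering


def xdawn_filters(
    epochs: np.ndarray,
    labels: np.ndarray,
    n_filters: int = 4,
    target_label="target",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evoked-response spatial filters via a generalized eigenproblem.

    Maximizes the ratio of evoked-response energy (covariance of the
    target-averaged template) to total signal energy (average covariance of
    all epochs).  Returns ``(filters, template, eigenvalues)`` where
    ``filters`` is n_filters x channels (rows are unit-norm filters ordered
    by decreasing eigenvalue) and ``template`` is the target-averaged evoked
    response (channels x samples).
    """
    epochs = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    is_target = labels == target_label
    if not is_target.any() or is_target.all():
        raise ValueError("epochs must contain both target and non-target labels")
    template = epochs[is_target].mean(axis=0)
    Tc = template - template.mean(axis=1, keepdims=True)
    S_evoked = (Tc @ Tc.T) / (Tc.shape[1] - 1)
    S_total = np.mean(
        [sample_covariance(e) for e in epochs], axis=0
    )
    w, V = sla.eigh(S_evoked, S_total)
    order = np.argsort(w)[::-1][:n_filters]
    filters = V[:, order].T
    filters = filters / np.linalg.norm(filters, axis=1, keepdims=True)
    return filters, template, w[np.argsort(w)[::-1]]


def xdawn_augment(
    epoch: np.ndarray, filters: np.ndarray, template: np.ndarray
) -> np.ndarray:
    """XDawn covariance of one epoch.

    The epoch is row-stacked with the spatially filtered evoked template and
    the covariance of the augmented matrix is returned; its off-diagonal
    blocks measure how strongly the epoch expresses the evoked prototype,
    which is what separates target from non-target windows.

    The covariance uses Ledoit-Wolf shrinkage toward the scaled identity
    rather than the raw sample estimate: a 600 ms window band-limited to
    0.1-15 Hz carries fewer effective temporal degrees of freedom than the
    augmented channel count, so the sample covariance is rank-deficient and
    its near-null eigenvalues are pure noise; shrinkage keeps the matrices
    well-conditioned and close enough on the manifold for stable tangent
    mapping.
    """
    from sklearn.covariance import ledoit_wolf

    aug = np.vstack([filters @ template, np.asarray(epoch, dtype=float)])
    Xc = aug - aug.mean(axis=1, keepdims=True)
    C, _ = ledoit_wolf(Xc.T, assume_centered=True)
    tr = np.trace(C)
    if tr <= 0:
        raise DegenerateInputError("epoch has zero variance on every channel")
    return 0.5 * (C + C.T)


# ---------------------------------------------------------------------------
# Linear classifiers


@dataclass
class LinearClassifier:
    """A fitted binary linear decision rule on tangent-space features.

    ``kind`` is ``"logistic"`` (L2-regularized maximum likelihood) or
    ``"slda"`` (LDA on a shrinkage-regularized pooled covariance).  Both
    expose a monotone decision score and a calibrated posterior; for sLDA
    the posterior is a logistic link on the LDA decision score.
    """

    weights: np.ndarray
    bias: float
    kind: str
    classes: np.ndarray
    shrinkage: float | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior P(class) columns ordered as ``self.classes``; rows sum to 1."""
        s = self.decision(X)
        p1 = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[(self.decision(X) > 0).astype(int)]


def _ledoit_wolf_shrinkage(Xc: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity toward the scaled identity.

    ``Xc`` holds class-centered observations (rows).  Direct implementation
    of the optimal-intensity estimator for the pooled covariance.
    """
    n, p = Xc.shape
    S = (Xc.T @ Xc) / n
    mu = np.trace(S) / p
    d2 = np.sum((S - mu * np.eye(p)) ** 2) / p
    b2_sum = 0.0
    for i in range(n):
        xi = Xc[i][:, None]
        b2_sum += np.sum((xi @ xi.T - S) ** 2) / p
    b2 = min(b2_sum / n**2, d2)
    return float(b2 / d2) if d2 > 0 else 1.0


def _fit_slda(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None
) -> LinearClassifier:
    classes = np.unique(y)
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Xc = np.vstack([X0 - mu0, X1 - mu1])
    n, p = X.shape
    # pooled within-class covariance, unbiased over N - 2 dof
    S = (Xc.T @ Xc) / (n - 2)
    gamma = _ledoit_wolf_shrinkage(Xc) if shrinkage is None else float(shrinkage)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"shrinkage must be in [0, 1], got {gamma}")
    mu_bar = np.trace(S) / p
    S_shrunk = (1 - gamma) * S + gamma * mu_bar * np.eye(p)
    w = np.linalg.solve(S_shrunk, mu1 - mu0)
    b = -0.5 * w @ (mu0 + mu1) + np.log(len(X1) / len(X0))
    return LinearClassifier(weights=w, bias=float(b), kind="slda",
                            classes=classes, shrinkage=gamma)


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "logistic",
    shrinkage: float | None = None,
    C: float = 1.0,
) -> LinearClassifier:
    """Fit a binary linear classifier on tangent-space features.

    ``kind="logistic"``: L2-regularized logistic regression (deterministic
    lbfgs solver, tolerance 1e-8, inverse regularization ``C``).
    ``kind="slda"``: shrinkage LDA; ``shrinkage=None`` selects the analytic
    Ledoit-Wolf intensity, a float in [0, 1] fixes it.

    The positive class is the lexicographically larger label.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 examples per class")
    if kind == "logistic":
        lr = LogisticRegression(C=C, solver="lbfgs", tol=1e-8, max_iter=5000)
        lr.fit(X, y)
        return LinearClassifier(
            weights=lr.coef_.ravel(), bias=float(lr.intercept_[0]),
            kind="logistic", classes=lr.classes_,
        )
    if kind == "slda":
        return _fit_slda(X, y, shrinkage)
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class TrainingMetrics:
    """Cross-validated training scores pooled over validation folds.

    precision = TP/(TP+FP), recall = TP/(TP+FN); the confusion matrix counts
    all validation predictions, rows = true class, columns = predicted, in
    the order (positive, negative).
    """

    accuracy: float
    precision: float
    recall: float
    confusion: np.ndarray
    k: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "confusion": self.confusion.tolist(),
            "k": self.k,
        }


def kfold_scores(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    kind: str = "logistic",
    shrinkage: float | None = None,
    pos_label=None,
    seed: int = 0,
) -> TrainingMetrics:
    """Stratified k-fold cross-validated accuracy/precision/recall.

    ``pos_label`` names the class treated as positive for precision/recall
    (default: the lexicographically larger label, matching
    :func:`fit_classifier`'s decision convention).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("kfold_scores handles binary problems only")
    min_count = min((y == c).sum() for c in classes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min_count:
        raise ValueError(
            f"k={k} exceeds the smallest class count ({min_count}); "
            "stratified folds are impossible"
        )
    if pos_label is None:
        pos_label = classes[1]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for train_idx, val_idx in skf.split(X, y):
        clf = fit_classifier(X[train_idx], y[train_idx], kind=kind, shrinkage=shrinkage)
        pred = clf.predict(X[val_idx])
        truth = y[val_idx]
        tp += int(np.sum((truth == pos_label) & (pred == pos_label)))
        fn += int(np.sum((truth == pos_label) & (pred != pos_label)))
        fp += int(np.sum((truth != pos_label) & (pred == pos_label)))
        tn += int(np.sum((truth != pos_label) & (pred != pos_label)))
    total = tp + fp + tn + fn
    return TrainingMetrics(
        accuracy=(tp + tn) / total,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
        confusion=np.array([[tp, fn], [fp, tn]]),
        k=k,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator layer


class Covariances(BaseEstimator, TransformerMixin):
    """Transform epochs (n, channels, samples) to SPD covariances (n, C, C)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([sample_covariance(e) for e in X])


class XdawnCovariances(BaseEstimator, TransformerMixin):
    """XDawn-augmented covariances for evoked-response epochs.

    Fits evoked-response spatial filters on the training epochs and, at
    transform time, augments each epoch with the filtered evoked template
    before taking the sample covariance.
    """

    def __init__(self, n_filters: int = 4, target_label="target"):
        self.n_filters = n_filters
        self.target_label = target_label

    def fit(self, X, y):
        self.filters_, self.template_, self.eigenvalues_ = xdawn_filters(
            X, y, n_filters=self.n_filters, target_label=self.target_label
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "filters_")
        return np.stack(
            [xdawn_augment(e, self.filters_, self.template_) for e in np.asarray(X, float)]
        )


class TangentSpace(BaseEstimator, TransformerMixin):
    """Map SPD matrices to tangent-space vectors at the training Karcher mean."""

    def __init__(self, tol: float = 1e-6, max_iter: int = 300):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.reference_ = spd_mean(X, tol=self.tol, max_iter=self.max_iter)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        return np.stack([tangent_map(P, self.reference_) for P in np.asarray(X, float)])


class ShrinkageLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant analysis with a shrinkage-regularized pooled covariance.

    ``shrinkage=None`` uses the analytic Ledoit-Wolf intensity; a float in
    [0, 1] fixes it (0 recovers plain LDA on well-conditioned data).
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        self.rule_ = fit_classifier(X, y, kind="slda", shrinkage=self.shrinkage)
        self.classes_ = self.rule_.classes
        self.coef_ = self.rule_.weights[None, :]
        self.intercept_ = np.array([self.rule_.bias])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "rule_")
        return self.rule_.decision(X)

    def predict_proba(self, X):
        check_is_fitted(self, "rule_")
        return self.rule_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "rule_")
        return self.rule_.predict(X)
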