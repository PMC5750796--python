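"""Entropy-weight local-hyperplane k-nearest-neighbor (EWHK) classification.

The classifier assigns a query spectrum ``q`` to the class whose *local
hyperplane* — the affine hull of the k nearest same-class training
spectra — is closest to ``q`` under an entropy-weighted metric.  It
generalizes the K-local hyperplane distance nearest-neighbor classifier
(HKNN), which is recovered exactly by ``mode="hknn"`` (all feature
weights equal to one, i.e. plain Euclidean geometry).

Three stages:

1.  *Entropy feature weights.*  Each feature column j of the training
    matrix is normalized across samples, z_ij = x_ij / sum_i x_ij, and its
    Shannon entropy H_j = -(1/ln m) * sum_i z_ij ln z_ij is computed
    (0 ln 0 := 0).  Features whose values are spread unevenly across
    samples — typically those that separate classes — have low entropy
    and receive high weight:

        w_j = (1 - H_j) / (n - sum_j H_j),     sum_j w_j = 1.

2.  *Prototype selection.*  For each class c, the k training rows of
    class c closest to q under the weighted Euclidean distance
    D(x, q) = sqrt(sum_j w_j (x_j - q_j)^2).

3.  *Local hyperplane distance.*  With prototype centroid m_c and
    centered prototype basis V (columns p_i - m_c), the ridge-regularized
    weighted squared distance from q to the hyperplane is

        J_c(q) = min_alpha (s - q)^T W (s - q) + lambda * alpha^T alpha,
        s = V alpha + m_c,  W = diag(w),

    whose minimizer solves (V^T W V + lambda I_k) alpha = V^T W (q - m_c).
    The query is assigned to argmin_c J_c(q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraDataset
from .exceptions import NotFittedError, ValidationError

__all__ = [
    "EntropyWeights",
    "HyperplaneFit",
    "EWHKClassifier",
    "entropy_weights",
    "weighted_distance",
    "hyperplane_distance",
    "fit",
]

MODES = ("ewhk", "hknn")


@dataclass(frozen=True)
class EntropyWeights:
    """Per-feature entropy weights: w sums to 1, every H_j in [0, 1]."""

    w: np.ndarray
    h: np.ndarray
    beta: float


@dataclass(frozen=True)
class HyperplaneFit:
    """Solve artifacts for one class hyperplane: centroid, basis, alpha, J_c."""

    class_label: str | None
    centroid: np.ndarray
    basis: np.ndarray  # n x k, columns p_i - centroid
    alpha: np.ndarray
    jc: float


def entropy_weights(train_x: np.ndarray) -> EntropyWeights:
    """Compute entropy-based feature weights from a training matrix.

    Columns containing non-positive values (SNV output is signed) are
    shifted by ``-min + eps`` first so the column-share normalization
    z_ij = x_ij / sum_i x_ij is well defined; strictly positive columns
    are used as-is.  The shift preserves within-column ordering and
    spread, which is all the entropy responds to.

    If every feature has maximal entropy (e.g. a constant matrix) the
    weight formula is 0/0; we fall back to uniform weights with a warning.
    """
    x = np.atleast_2d(np.asarray(train_x, dtype=float))
    m, n = x.shape
    if m < 2:
        raise ValidationError("entropy weights need at least 2 training samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("training matrix contains non-finite values")

    mins = x.min(axis=0)
    ranges = x.max(axis=0) - mins
    eps = np.where(ranges > 0, 1e-12 * ranges, 1e-12)
    needs_shift = mins <= 0
    x = np.where(needs_shift, x - mins + eps, x)

    z = x / x.sum(axis=0, keepdims=True)
    beta = 1.0 / np.log(m)
    plogp = np.where(z > 0, z * np.log(np.maximum(z, 1e-300)), 0.0)
    h = np.minimum(-beta * plogp.sum(axis=0), 1.0)  # clip fp overshoot above 1

    denom = n - h.sum()
    if denom <= n * 1e-12:
        warnings.warn(
            "all features have maximal entropy; falling back to uniform weights",
            stacklevel=2,
        )
        w = np.full(n, 1.0 / n)
    else:
        w = (1.0 - h) / denom
    return EntropyWeights(w=w, h=h, beta=beta)


def _weights_vector(w) -> np.ndarray:
    if isinstance(w, EntropyWeights):
        return w.w
    return np.asarray(w, dtype=float)


def weighted_distance(x: np.ndarray, q: np.ndarray, w) -> float:
    """Weighted Euclidean distance sqrt(sum_j w_j (x_j - q_j)^2)."""
    x = np.asarray(x, dtype=float)
    q = np.asarray(q, dtype=float)
    wv = _weights_vector(w)
    if x.shape != q.shape or x.shape != wv.shape:
        raise ValidationError(
            f"dimension mismatch: x {x.shape}, q {q.shape}, w {wv.shape}"
        )
    return float(np.sqrt(np.sum(wv * (x - q) ** 2)))


def hyperplane_distance(
    q: np.ndarray,
    prototypes: np.ndarray,
    w,
    lam: float = 0.0,
    class_label: str | None = None,
) -> HyperplaneFit:
    """Ridge-regularized weighted distance from q to the prototype hyperplane.

    Solves ``(V^T W V + lam I_k) alpha = V^T W (q - m_c)`` with
    ``V[:, i] = p_i - m_c``.  A singular system at ``lam = 0`` is resolved
    by the minimum-norm least-squares solution; any minimizer yields the
    same J_c.
    """
    q = np.asarray(q, dtype=float)
    p = np.atleast_2d(np.asarray(prototypes, dtype=float))
    wv = _weights_vector(w)
    if lam < 0:
        raise ValidationError("lam must be >= 0")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(p))):
        raise ValidationError("hyperplane inputs contain NaN/Inf")
    k = p.shape[0]
    if p.shape[1] != q.size or wv.size != q.size:
        raise ValidationError("prototype/query/weight dimensions do not match")

    centroid = p.mean(axis=0)
    basis = (p - centroid).T  # n x k
    wu = basis * wv[:, None]  # W V, n x k
    gram = wu.T @ basis + lam * np.eye(k)
    rhs = wu.T @ (q - centroid)
    if lam > 0:
        alpha = np.linalg.solve(gram, rhs)
    else:
        alpha, *_ = np.linalg.lstsq(gram, rhs, rcond=None)
    s = basis @ alpha + centroid
    jc = float(np.sum(wv * (s - q) ** 2) + lam * alpha @ alpha)
    return HyperplaneFit(class_label=class_label, centroid=centroid, basis=basis,
                         alpha=alpha, jc=max(jc, 0.0))


class EWHKClassifier:
    """EWHK / HKNN classifier over spectra or plain feature matrices.

    Parameters
    ----------
    k : int
        Nearest neighbors per class used to span the local hyperplane;
        clipped per class to the class size at prediction time.
    lam : float
        Ridge regularization lambda >= 0 on the hyperplane coefficients.
    mode : {"ewhk", "hknn"}
        "ewhk" computes entropy feature weights from the training matrix;
        "hknn" uses unit weights (plain Euclidean), the classical baseline.
    """

    def __init__(self, k: int = 5, lam: float = 1.0, mode: str = "ewhk"):
        if k < 1:
            raise ValidationError("k must be >= 1")
        if lam < 0:
            raise ValidationError("lam must be >= 0")
        if mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
        self.k = int(k)
        self.lam = float(lam)
        self.mode = mode
        self._fitted = False

    # -- fitting -------------------------------------------------------------

    def fit(self, train, y=None) -> "EWHKClassifier":
        """Fit on a SpectraDataset, or on (X, y) arrays.

        Entropy weights are computed once on the full training matrix;
        class labels play no role in the weighting.  Training data is
        stored by reference.  A single-class training set is accepted
        with a warning (prediction then degenerates to that class).
        """
        if isinstance(train, SpectraDataset):
            x, y = train.absorbance, train.labels
        else:
            x = np.atleast_2d(np.asarray(train, dtype=float))
            if y is None:
                raise ValidationError("labels required when fitting on a plain matrix")
        y = np.asarray([str(v) for v in y], dtype=object)
        if x.shape[0] != y.size:
            raise ValidationError("X and y length mismatch")
        if x.shape[0] < 2:
            raise ValidationError("need at least 2 training samples")

        self.classes_ = sorted(set(y))
        if len(self.classes_) < 2:
            warnings.warn("single-class training set: every query will get that class",
                          stacklevel=2)
        if self.mode == "ewhk":
            self.weights_ = entropy_weights(x)
            self.feature_weights_ = self.weights_.w
        else:
            self.weights_ = None
            self.feature_weights_ = np.ones(x.shape[1])
        self.train_x_ = x
        self.train_y_ = y
        self._class_rows_ = {c: np.flatnonzero(y == c) for c in self.classes_}
        self._fitted = True
        return self

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise NotFittedError("classifier is not fitted; call fit first")

    # -- prediction ----------------------------------------------------------

    def select_prototypes(self, q: np.ndarray, c: str) -> np.ndarray:
        """Row indices (into the training set) of the k nearest class-c
        neighbors of q, in ascending distance order; ties break toward the
        lower training-row index."""
        self._check_fitted()
        if c not in self._class_rows_:
            raise ValidationError(f"unknown class {c!r}")
        q = np.asarray(q, dtype=float)
        rows = self._class_rows_[c]
        diffs = self.train_x_[rows] - q
        d = np.sqrt(np.sum(self.feature_weights_ * diffs**2, axis=1))
        order = np.argsort(d, kind="stable")  # stable sort = row-index tie-break
        return rows[order[: min(self.k, rows.size)]]

    def classify(self, q: np.ndarray) -> tuple[str, dict[str, float]]:
        """Label and per-class hyperplane distances J_c for one query.

        Ties in J_c resolve to the lexicographically smallest label
        (classes_ is sorted, and argmin is strict).
        """
        self._check_fitted()
        q = np.asarray(q, dtype=float)
        if q.shape != (self.train_x_.shape[1],):
            raise ValidationError(
                f"query has {q.size} features, model expects {self.train_x_.shape[1]}"
            )
        scores: dict[str, float] = {}
        for c in self.classes_:
            idx = self.select_prototypes(q, c)
            fit_c = hyperplane_distance(
                q, self.train_x_[idx], self.feature_weights_, self.lam, class_label=c
            )
            scores[c] = fit_c.jc
        best = min(scores, key=lambda c: (scores[c], c))
        return best, scores

    def predict(self, x) -> np.ndarray:
        """Predict labels for a SpectraDataset or an (m, n) matrix."""
        labels, _ = self.predict_with_scores(x)
        return labels

    def predict_with_scores(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Labels plus the (m, L) matrix of J_c scores (columns = classes_)."""
        self._check_fitted()
        if isinstance(x, SpectraDataset):
            x = x.absorbance
        x = np.atleast_2d(np.asarray(x, dtype=float))
        labels = np.empty(x.shape[0], dtype=object)
        scores = np.empty((x.shape[0], len(self.classes_)))
        for i, q in enumerate(x):
            label, sc = self.classify(q)
            labels[i] = label
            scores[i] = [sc[c] for c in self.classes_]
        return labels, scores


def fit(train, k: int = 5, lam: float = 1.0, mode: str = "ewhk", y=None) -> EWHKClassifier:
    """Convenience constructor: build and fit an :class:`EWHKClassifier`."""
    return EWHKClassifier(k=k, lam=lam, mode=mode).fit(train, y=y)
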