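"""Common spatial patterns (CSP), its one-versus-rest multiclass
extension, log-variance features and the LDA baseline classifier.

CSP seeks spatial filters ``w`` maximizing the Rayleigh quotient
``w' R1 w / w' R2 w`` of the two class-average covariance matrices.  It
is solved here as the generalized symmetric eigenproblem
``R1 w = lambda R2 w`` (numerically stabler than forming ``R2^-1 R1``,
with identical spectrum).  The one-versus-rest variant maximizes one
class's projected power against the summed power of the remaining
classes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg

from .epochs import EpochSet

__all__ = [
    "CovarianceModel",
    "SpatialFilterBank",
    "LDAModel",
    "epoch_covariance",
    "class_mean_covariances",
    "solve_csp_pair",
    "solve_ovr_csp",
    "apply_filters",
    "csp_features",
    "fit_lda",
    "predict_lda",
]


@dataclasses.dataclass
class CovarianceModel:
    """Per-epoch trace-normalized covariances and their class averages."""

    per_epoch: list[np.ndarray]
    labels: np.ndarray
    class_means: list[np.ndarray]  # index c-1 -> mean covariance of class c
    class_counts: np.ndarray


@dataclasses.dataclass
class SpatialFilterBank:
    """M spatial filters as rows, with the eigenvalue of each filter.

    ``origin`` is ``"csp_pair"`` (rows: m largest-eigenvalue filters then
    m smallest) or ``"ovr"`` (rows grouped by source class, m per class,
    ``source_class`` giving the class of each row).
    """

    filters: np.ndarray  # M x N
    eigenvalues: np.ndarray  # M
    origin: str = "csp_pair"
    source_class: np.ndarray | None = None

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


def epoch_covariance(X: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance ``X X' / tr(X X')`` of a zero-mean epoch."""
    X = np.asarray(X, dtype=float)
    R = X @ X.T
    tr = np.trace(R)
    if tr <= 0 or not np.isfinite(tr):
        raise ValueError("degenerate epoch: tr(XX') must be positive")
    return R / tr


def class_mean_covariances(es: EpochSet) -> CovarianceModel:
    """Per-epoch normalized covariances and arithmetic class means."""
    per_epoch = [epoch_covariance(X) for X in es.epochs]
    C = es.n_classes or int(es.labels.max())
    means, counts = [], []
    for c in range(1, C + 1):
        idx = es.class_indices(c)
        if len(idx) == 0:
            raise ValueError(f"class {c} has no epochs")
        means.append(np.mean([per_epoch[i] for i in idx], axis=0))
        counts.append(len(idx))
    return CovarianceModel(
        per_epoch=per_epoch,
        labels=es.labels.copy(),
        class_means=means,
        class_counts=np.array(counts),
    )


def _fix_sign(w: np.ndarray) -> np.ndarray:
    # Filter signs are unidentifiable; make the largest-|.| entry positive.
    k = np.argmax(np.abs(w))
    return w if w[k] >= 0 else -w


def _generalized_eig(R1: np.ndarray, R2: np.ndarray):
    """Eigenpairs of R1 w = lambda R2 w, eigenvalues ascending.

    R2 gets a tiny ridge when near-singular; raises if that is not enough.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    N = R2.shape[0]
    ev_min = linalg.eigvalsh(R2)[0]
    if ev_min < 1e-10 * np.trace(R2) / N:
        R2 = R2 + (1e-10 * np.trace(R2) / N) * np.eye(N)
    try:
        vals, vecs = linalg.eigh(R1, R2)
    except linalg.LinAlgError as exc:
        raise ValueError("second covariance matrix is singular") from exc
    return vals, vecs


def solve_csp_pair(R1: np.ndarray, R2: np.ndarray, m: int) -> SpatialFilterBank:
    """CSP filter bank for two classes.

    Returns ``2m`` unit-norm filters: the ``m`` of largest generalized
    eigenvalue (class-1 power maximized) followed by the ``m`` of
    smallest (class-2 power maximized), with eigenvalues attached.
    """
    N = R1.shape[0]
    if 2 * m > N:
        raise ValueError(f"2m = {2 * m} exceeds channel count N = {N}")
    vals, vecs = _generalized_eig(R1, R2)
    # ascending order: smallest first
    top = [vecs[:, -(j + 1)] for j in range(m)]
    bot = [vecs[:, j] for j in range(m)]
    lam = np.concatenate([vals[::-1][:m], vals[:m]])
    W = np.array([_fix_sign(w / np.linalg.norm(w)) for w in top + bot])
    return SpatialFilterBank(filters=W, eigenvalues=lam, origin="csp_pair")


def solve_ovr_csp(class_means: list[np.ndarray], m: int) -> SpatialFilterBank:
    """One-versus-rest CSP bank: for each class c the ``m`` filters
    maximizing ``w' Rc w / w' (sum_{j != c} Rj) w``.

    If all class covariances coincide the problem carries no
    discriminative information (all eigenvalues ``1/(C-1)``); a warning
    is emitted, not an error.
    """
    C = len(class_means)
    if C < 2:
        raise ValueError("need at least two classes")
    N = class_means[0].shape[0]
    if m > N:
        raise ValueError(f"m = {m} exceeds channel count N = {N}")
    filters, eigvals, src = [], [], []
    for c in range(C):
        rest = sum(class_means[j] for j in range(C) if j != c)
        vals, vecs = _generalized_eig(class_means[c], rest)
        for j in range(m):
            w = vecs[:, -(j + 1)]
            filters.append(_fix_sign(w / np.linalg.norm(w)))
            eigvals.append(vals[::-1][j])
            src.append(c + 1)
    eigvals = np.array(eigvals)
    if np.allclose(eigvals, 1.0 / (C - 1), atol=1e-8):
        warnings.warn(
            "all OVR-CSP eigenvalues equal 1/(C-1): class covariances are "
            "indistinguishable, filters are non-discriminative",
            stacklevel=2,
        )
    return SpatialFilterBank(
        filters=np.array(filters),
        eigenvalues=eigvals,
        origin="ovr",
        source_class=np.array(src),
    )


def apply_filters(bank: SpatialFilterBank, X: np.ndarray) -> np.ndarray:
    """Spatially filter an epoch: row k of the result is filter k applied to X."""
    X = np.asarray(X, dtype=float)
    if bank.filters.shape[1] != X.shape[0]:
        raise ValueError(
            f"filter length {bank.filters.shape[1]} != channel count {X.shape[0]}"
        )
    return bank.filters @ X


def csp_features(Z: np.ndarray) -> np.ndarray:
    """Log of each row's variance share: ``f_k = log(var_k / sum_l var_l)``.

    Uses the population (1/T) variance convention; consequently
    ``sum_k exp(f_k) == 1``.
    """
    Z = np.asarray(Z, dtype=float)
    v = Z.var(axis=1)  # rows are zero-mean up to filtering; ddof=0
    if np.any(v <= 0):
        raise ValueError("zero-variance filtered row: degenerate feature")
    return np.log(v / v.sum())


@dataclasses.dataclass
class LDAModel:
    """Linear discriminant analysis with pooled within-class covariance.

    Multiclass decision by one linear discriminant per class (argmax),
    i.e. a linear machine; empirical class priors.
    """

    coef: np.ndarray  # C x M
    intercept: np.ndarray  # C
    classes: np.ndarray


def fit_lda(features: np.ndarray, labels: np.ndarray) -> LDAModel:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    K, M = X.shape
    if any((y == c).sum() < 2 for c in classes):
        raise ValueError("need at least two epochs per class")
    means = np.array([X[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((M, M))
    for c, mu in zip(classes, means):
        d = X[y == c] - mu
        Sw += d.T @ d
    Sw /= K - len(classes)
    try:
        Sw_inv = np.linalg.inv(Sw)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled within-class covariance") from exc
    priors = np.array([(y == c).mean() for c in classes])
    coef = means @ Sw_inv
    intercept = -0.5 * np.einsum("cm,cm->c", coef, means) + np.log(priors)
    return LDAModel(coef=coef, intercept=intercept, classes=classes)


def predict_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    scores = X @ model.coef.T + model.intercept
    return model.classes[np.argmax(scores, axis=1)]


# -- plain-text serialization (CLI artifacts) --------------------------------

def save_filter_bank(bank: SpatialFilterBank, path) -> None:
    """One filter per row; trailing columns: eigenvalue, source class (0 = pair)."""
    src = bank.source_class if bank.source_class is not None else np.zeros(
        bank.n_filters, dtype=int)
    with open(path, "w") as fh:
        fh.write(f"# origin={bank.origin}\n")
        for w, lam, c in zip(bank.filters, bank.eigenvalues, src):
            fh.write("\t".join(f"{v:.17g}" for v in w)
                     + f"\t{lam:.17g}\t{int(c)}\n")


def load_filter_bank(path) -> SpatialFilterBank:
    origin = "csp_pair"
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln.startswith("# origin="):
                origin = ln.split("=", 1)[1]
            elif ln:
                rows.append([float(x) for x in ln.split("\t")])
    arr = np.array(rows)
    src = arr[:, -1].astype(int)
    return SpatialFilterBank(
        filters=arr[:, :-2],
        eigenvalues=arr[:, -2],
        origin=origin,
        source_class=src if origin == "ovr" else None,
    )


def save_lda(model: LDAModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("# lda: rows = class, coef..., intercept\n")
        for c, coef, b0 in zip(model.classes, model.coef, model.intercept):
            fh.write(f"{int(c)}\t" + "\t".join(f"{v:.17g}" for v in coef)
                     + f"\t{b0:.17g}\n")


def load_lda(path) -> LDAModel:
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln and not ln.startswith("#"):
                rows.append([float(x) for x in ln.split("\t")])
    arr = np.array(rows)
    return LDAModel(
        coef=arr[:, 1:-1],
        intercept=arr[:, -1],
        classes=arr[:, 0].astype(int),
    )
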