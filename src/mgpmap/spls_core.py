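"""Regularized (lasso-thresholded) partial least squares, first axis only.

Both blocks are standardized column-wise, so the cross-block matrix is a
correlation matrix and the regularization strength lives on the
correlation scale. A lasso soft-threshold shrinks small cross-block
correlations to exactly zero, and the leading singular triple of the
thresholded matrix gives the paired genetic (u) and phenotypic (v)
loading axes. Variance explained is the trace ratio of the covariance of
score-predicted shapes to the covariance of observed shapes. Only the
first paired axes are estimated; multi-component deflation is out of
scope by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DENSE_SVD_LIMIT = 2000


class PLSError(ValueError):
    pass


class DegenerateDataError(PLSError):
    """The phenotype block has no variance: R^2 undefined."""


@dataclass
class Standardization:
    """Column means/scales of a block; zero-variance columns keep scale 1."""

    means: np.ndarray
    scales: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardization":
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=1)
        scales = np.where(scales > 0, scales, 1.0)
        return cls(means, scales)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.scales


def _standardize(X: np.ndarray) -> tuple[np.ndarray, Standardization]:
    std = Standardization.fit(X)
    return std.apply(X), std


def cross_correlation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cross-block correlation matrix C = X_std' Y_std / (n - 1).

    Columns are centered and scaled to unit variance; zero-variance
    columns contribute zero rows/columns. Entries lie in [-1, 1].
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise PLSError(f"row mismatch: {X.shape[0]} vs {Y.shape[0]}")
    n = X.shape[0]
    if n < 3:
        raise PLSError("need at least 3 rows")
    Xs, _ = _standardize(X)
    Ys, _ = _standardize(Y)
    return np.clip(Xs.T @ Ys / (n - 1), -1.0, 1.0)


def soft_threshold(C: np.ndarray, lambda_: float) -> np.ndarray:
    """Lasso shrinkage: sign(c) * max(|c| - lambda, 0), elementwise."""
    if lambda_ < 0:
        raise PLSError("lambda must be non-negative")
    C = np.asarray(C, dtype=float)
    return np.sign(C) * np.maximum(np.abs(C) - lambda_, 0.0)


def _leading_triple(C: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    p, q = C.shape
    if p + q <= DENSE_SVD_LIMIT:
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        return U[:, 0], float(s[0]), Vt[0]
    # seeded power iteration on C'C for very wide problems
    rng = np.random.default_rng(0)
    v = rng.standard_normal(q)
    v /= np.linalg.norm(v)
    for _ in range(10_000):
        w = C.T @ (C @ v)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        if np.linalg.norm(w - v) < 1e-12:
            v = w
            break
        v = w
    u = C @ v
    d = float(np.linalg.norm(u))
    u = u / d if d > 0 else u
    return u, d, v


@dataclass
class PLSFit:
    """First paired axes of the thresholded cross-correlation matrix.

    ``u`` (genetic loadings) and ``v`` (phenotypic loadings) are unit
    vectors unless the penalty saturates, in which case both are zero and
    r2 = 0. Sign convention: the largest-|entry| of v is positive. ``b``
    is the least-squares regression of centered shapes on the genotype
    score ``scores_t``, on the original coordinate scale.
    """

    lambda_: float
    u: np.ndarray
    v: np.ndarray
    d: float
    scores_t: np.ndarray
    b: np.ndarray
    r2: float
    x_standardization: Standardization
    y_standardization: Standardization
    x_labels: list = field(default_factory=list)

    @property
    def saturated(self) -> bool:
        return self.d == 0.0

    def gene_loading_norms(self) -> dict[str, float]:
        """Per-gene importance: Euclidean norm of the 8 founder loadings."""
        if not self.x_labels:
            raise PLSError("fit carries no column labels")
        norms: dict[str, float] = {}
        for (gene, _founder), ui in zip(self.x_labels, self.u):
            norms[gene] = norms.get(gene, 0.0) + float(ui) ** 2
        return {g: float(np.sqrt(s)) for g, s in norms.items()}

    def to_json(self, path=None) -> str:
        doc = {
            "lambda": self.lambda_,
            "d": self.d,
            "r2": self.r2,
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "b": self.b.tolist(),
            "scores_t": self.scores_t.tolist(),
            "x_means": self.x_standardization.means.tolist(),
            "x_scales": self.x_standardization.scales.tolist(),
            "y_means": self.y_standardization.means.tolist(),
            "y_scales": self.y_standardization.scales.tolist(),
            "x_labels": [list(lab) for lab in self.x_labels],
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PLSFit":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(
            lambda_=doc["lambda"],
            u=np.asarray(doc["u"]),
            v=np.asarray(doc["v"]),
            d=doc["d"],
            scores_t=np.asarray(doc["scores_t"]),
            b=np.asarray(doc["b"]),
            r2=doc["r2"],
            x_standardization=Standardization(
                np.asarray(doc["x_means"]), np.asarray(doc["x_scales"])
            ),
            y_standardization=Standardization(
                np.asarray(doc["y_means"]), np.asarray(doc["y_scales"])
            ),
            x_labels=[tuple(lab) for lab in doc["x_labels"]],
        )


def _extract_x(X) -> tuple[np.ndarray, list]:
    if hasattr(X, "X") and hasattr(X, "columns"):  # GenotypeBlock duck-type
        return np.asarray(X.X, dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), []


def _fit_core(
    Xs: np.ndarray, Yc: np.ndarray, C: np.ndarray, lambda_: float
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Shared fitting path: threshold, SVD, scores, shape regression."""
    Cl = soft_threshold(C, lambda_)
    p, q = Cl.shape
    if not Cl.any():
        return (np.zeros(p), np.zeros(q), 0.0,
                np.zeros(Xs.shape[0]), np.zeros(q))
    u, d, v = _leading_triple(Cl)
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        u, v = -u, -v
    t = Xs @ u
    tt = float(t @ t)
    b = Yc.T @ t / tt if tt > 0 else np.zeros(q)
    return u, v, d, t, b


def fit_spls(X, Y: np.ndarray, lambda_: float) -> PLSFit:
    """Fit the first regularized PLS axis pair of genotype block X vs shapes Y.

    ``X`` may be a GenotypeBlock (column labels are kept for per-gene
    loading summaries) or a plain matrix. Raises on negative lambda or
    non-finite input; a penalty at or above max|C| yields the saturated
    zero fit with r2 = 0.
    """
    if lambda_ < 0:
        raise PLSError("lambda must be non-negative")
    Xm, labels = _extract_x(X)
    Y = np.asarray(Y, dtype=float)
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(Y))):
        raise PLSError("non-finite values in input blocks")
    if Xm.shape[0] != Y.shape[0]:
        raise PLSError("specimen count differs between blocks")
    n = Xm.shape[0]
    if n < 10:
        import warnings

        warnings.warn(f"n = {n} is small for a stable PLS fit", stacklevel=2)
    Xs, x_std = _standardize(Xm)
    Ys, y_std = _standardize(Y)
    C = np.clip(Xs.T @ Ys / (n - 1), -1.0, 1.0)
    Yc = Y - y_std.means
    u, v, d, t, b = _fit_core(Xs, Yc, C, lambda_)
    fit = PLSFit(
        lambda_=float(lambda_), u=u, v=v, d=d, scores_t=t, b=b, r2=0.0,
        x_standardization=x_std, y_standardization=y_std, x_labels=labels,
    )
    fit.r2 = variance_explained(fit, Y)
    return fit


def predict_shapes(fit: PLSFit, X) -> np.ndarray:
    """Predicted shapes: score times shape regression plus training means."""
    Xm, labels = _extract_x(X)
    if Xm.shape[1] != len(fit.x_standardization.means):
        raise PLSError("column count does not match the fit's genotype block")
    if labels and fit.x_labels and labels != fit.x_labels:
        raise PLSError("genotype column labels do not match the fit")
    t = fit.x_standardization.apply(Xm) @ fit.u
    return np.outer(t, fit.b) + fit.y_standardization.means


def variance_explained(fit: PLSFit, Y: np.ndarray) -> float:
    """Trace ratio R^2: trace(cov(Yhat)) / trace(cov(Y)), over specimens."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != len(fit.b):
        raise PLSError("Y dimensionality does not match the fit")
    Yc = Y - Y.mean(axis=0)
    denom = float((Yc ** 2).sum())
    if denom <= 0:
        raise DegenerateDataError("phenotype block has zero variance")
    t = fit.scores_t
    tc = t - t.mean()
    num = float(tc @ tc) * float(fit.b @ fit.b)
    return min(num / denom, 1.0)


@dataclass
class CVResult:
    lambda_grid: list[float]
    mean_error: np.ndarray
    fold_errors: np.ndarray
    chosen_lambda: float


def cross_validate(
    X, Y: np.ndarray, lambda_grid: list[float], k: int = 10, seed: int = 0
) -> CVResult:
    """k-fold CV of held-out shape prediction error over a lambda grid.

    Folds come from a seeded specimen shuffle; standardization is
    re-estimated on each training portion. Error is the mean squared
    held-out deviation on the original coordinate scale. The chosen
    lambda minimizes mean error, ties resolved toward the larger (more
    interpretable) penalty.
    """
    Xm, _ = _extract_x(X)
    Y = np.asarray(Y, dtype=float)
    n = Xm.shape[0]
    if not lambda_grid:
        raise PLSError("empty lambda grid")
    if k > n:
        raise PLSError(f"k = {k} folds exceed n = {n} specimens")
    grid = [float(l) for l in lambda_grid]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    fold_errors = np.empty((k, len(grid)))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        Xtr, Ytr = Xm[train_idx], Y[train_idx]
        Xte, Yte = Xm[test_idx], Y[test_idx]
        Xs, x_std = _standardize(Xtr)
        Ys, y_std = _standardize(Ytr)
        C = np.clip(Xs.T @ Ys / (len(train_idx) - 1), -1.0, 1.0)
        Yc = Ytr - y_std.means
        Xte_s = x_std.apply(Xte)
        for li, lam in enumerate(grid):
            u, v, d, t, b = _fit_core(Xs, Yc, C, lam)
            pred = np.outer(Xte_s @ u, b) + y_std.means
            fold_errors[fi, li] = float(((pred - Yte) ** 2).mean())
    mean_error = fold_errors.mean(axis=0)
    best = mean_error.min()
    chosen = max(lam for lam, err in zip(grid, mean_error) if err == best)
    return CVResult(grid, mean_error, fold_errors, float(chosen))
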