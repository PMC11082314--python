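"""Covariance-based gesture decoding on the SPD manifold.

This module implements the two Riemannian pipelines:

* *Covariance*: OAS-shrunk channel covariance of each epoch, projected onto
  the tangent space at the Fréchet mean of the training covariances, then a
  one-vs-rest L2 logistic regression.
* *xDAWN covariance*: each epoch is first augmented by stacking the
  xDAWN-filtered class prototypes on top of the xDAWN-filtered epoch, and
  the same covariance -> tangent-space -> logistic machinery is applied to
  the augmented (2KF x S) matrix.

xDAWN spatial filters maximize the signal-to-signal-plus-noise ratio
(SSNR): for class k with prototype P^(k) (the class-mean epoch) and the
concatenation of all epochs as the noise term, each filter w solves

    max_w  (w' P^(k) P^(k)' w) / (w' D w),      D = sum_i X_i X_i',

a generalized symmetric eigenproblem. The top-F eigenvectors per class are
kept and concatenated into W (E x KF).

The affine-invariant metric is used throughout: distances, the Karcher
(Fréchet) mean flow, and the tangent projection at a reference point R,

    phi(Sigma) = logm(R^{-1/2} Sigma R^{-1/2}),

vectorized over the upper triangle with sqrt(2) weight on off-diagonal
entries so the Euclidean norm of the vector equals the affine-invariant
distance d(R, Sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.covariance import oas as _sk_oas
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier


# ---------------------------------------------------------------------------
# SPD primitives
# ---------------------------------------------------------------------------

def check_spd(mat: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Validate symmetry (to ``tol``) and positive definiteness."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(mat - mat.T)) > tol:
        raise ValueError("matrix is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() <= 0:
        raise ValueError("matrix is not positive definite")
    return mat


def _eig_fun(mats: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of stacked symmetric matrices."""
    w, v = np.linalg.eigh(mats)
    return (v * fun(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def logm_spd(mat: np.ndarray) -> np.ndarray:
    return _eig_fun(np.asarray(mat, float), np.log)


def expm_sym(mat: np.ndarray) -> np.ndarray:
    return _eig_fun(np.asarray(mat, float), np.exp)


def sqrtm_spd(mat: np.ndarray) -> np.ndarray:
    return _eig_fun(np.asarray(mat, float), np.sqrt)


def invsqrtm_spd(mat: np.ndarray) -> np.ndarray:
    return _eig_fun(np.asarray(mat, float), lambda w: 1.0 / np.sqrt(w))


def airm_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance sqrt(sum log^2 eig(a^{-1} b))."""
    w = scipy.linalg.eigh(b, a, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def oas_covariance(epoch: np.ndarray, center: bool = True) -> np.ndarray:
    """OAS-shrunk covariance of one (E, S) epoch.

    Rows are mean-centered by default (the covariance model assumes
    zero-mean channels). The OAS estimator returns the convex combination
    (1 - rho) * S + rho * (tr(S)/d) * I with the Oracle Approximating
    Shrinkage weight, which is positive definite whenever tr(S) > 0.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("expected an E x S matrix")
    e, s = epoch.shape
    if s <= 1:
        raise ValueError("need more than one sample per epoch")
    x = epoch - epoch.mean(axis=1, keepdims=True) if center else epoch
    cov, _ = _sk_oas(x.T, assume_centered=True)
    return cov


def oas_covariances(data: np.ndarray, center: bool = True) -> np.ndarray:
    """Stacked OAS covariances for an (N, E, S) epoch array."""
    data = np.asarray(data, dtype=float)
    return np.stack([oas_covariance(ep, center=center) for ep in data])


class FrechetConvergenceError(RuntimeError):
    def __init__(self, msg: str, last: np.ndarray):
        super().__init__(msg)
        self.last = last


def frechet_mean(
    mats, tol: float = 1e-8, max_iter: int = 50, step: float = 1.0
) -> np.ndarray:
    """Karcher flow for the Fréchet mean under the affine-invariant metric.

    Initialized at the arithmetic mean; each iteration whitens the set at
    the current iterate, averages the matrix logs, and retracts. Converged
    when the Frobenius norm of the mean log (the Riemannian gradient) drops
    below ``tol``.
    """
    stack = np.asarray(mats, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("empty set")
    if stack.shape[0] == 1:
        return stack[0].copy()
    mean = stack.mean(axis=0)
    nu = step
    prev_norm = np.inf
    for _ in range(max_iter):
        isq = invsqrtm_spd(mean)
        sq = sqrtm_spd(mean)
        whitened = isq @ stack @ isq
        grad = logm_spd(whitened).mean(axis=0)
        norm = np.linalg.norm(grad)
        if norm < tol:
            return mean
        # step-halving keeps the flow stable on ill-conditioned sets
        if norm > prev_norm:
            nu *= 0.5
        prev_norm = norm
        mean = sq @ expm_sym(nu * grad) @ sq
        mean = 0.5 * (mean + mean.T)
    isq = invsqrtm_spd(mean)
    grad = logm_spd(isq @ stack @ isq).mean(axis=0)
    if np.linalg.norm(grad) < tol:
        return mean
    raise FrechetConvergenceError(
        f"Karcher flow did not converge in {max_iter} iterations "
        f"(gradient norm {np.linalg.norm(grad):.3g})",
        last=mean,
    )


def tangent_project(sigma: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Tangent-space vector of ``sigma`` at reference point ``ref``.

    Upper triangle of logm(ref^{-1/2} sigma ref^{-1/2}), off-diagonal
    entries weighted sqrt(2) (norm-preserving convention: the Euclidean
    norm of the result equals the affine-invariant distance d(ref, sigma)).
    """
    sigma = check_spd(sigma)
    ref = check_spd(ref)
    isq = invsqrtm_spd(ref)
    return _upper_vec(logm_spd(isq @ sigma @ isq))


def _upper_vec(mats: np.ndarray) -> np.ndarray:
    """sqrt(2)-weighted upper-triangle vectorization (batched)."""
    mats = np.asarray(mats)
    d = mats.shape[-1]
    iu, ju = np.triu_indices(d)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return mats[..., iu, ju] * weights


def tangent_dim(d: int) -> int:
    return d * (d + 1) // 2


# ---------------------------------------------------------------------------
# xDAWN spatial filtering
# ---------------------------------------------------------------------------

@dataclass
class XdawnModel:
    """Per-class prototypes and SSNR-maximizing spatial filters."""

    classes: np.ndarray
    n_filters: int
    prototypes: dict
    filters: dict          # class -> (E, F) eigenvectors, leading first
    eigenvalues: dict      # class -> (F,) generalized eigenvalues
    total_cov: np.ndarray  # D = sum_i X_i X_i'

    @property
    def stacked_filters(self) -> np.ndarray:
        """W = [W^(1) ... W^(K)], shape (E, K*F)."""
        return np.concatenate([self.filters[k] for k in self.classes], axis=1)


def ssnr(w: np.ndarray, prototype: np.ndarray, total_cov: np.ndarray) -> float:
    """Signal-to-signal-plus-noise ratio of a spatial filter."""
    w = np.asarray(w, float).ravel()
    num = w @ (prototype @ prototype.T) @ w
    den = w @ total_cov @ w
    return float(num / den)


def fit_xdawn(data: np.ndarray, labels: np.ndarray, n_filters: int = 4) -> XdawnModel:
    """Fit xDAWN filters from labeled epochs (N, E, S).

    For each class the prototype is the class-mean epoch; the filters are
    the leading generalized eigenvectors of (P P', D) with D the
    second-moment matrix of the concatenation of all epochs. A singular D
    is regularized with a trace-scaled jitter (logged).
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if data.ndim != 3:
        raise ValueError("expected N x E x S epochs")
    n, e, _ = data.shape
    if n_filters < 1 or n_filters > e:
        raise ValueError("n_filters must be in [1, E]")
    classes = np.unique(labels)
    d_total = np.einsum("nes,nfs->ef", data, data)
    prototypes, filters, eigenvalues = {}, {}, {}
    for k in classes:
        mask = labels == k
        if mask.sum() < 2:
            raise ValueError(f"class {k!r} has fewer than 2 epochs")
        p = data[mask].mean(axis=0)
        num = p @ p.T
        try:
            w, v = scipy.linalg.eigh(num, d_total)
        except scipy.linalg.LinAlgError:
            jitter = 1e-10 * np.trace(d_total) / e
            warnings.warn(f"singular denominator; adding jitter {jitter:.3g}")
            w, v = scipy.linalg.eigh(num, d_total + jitter * np.eye(e))
        order = np.argsort(w)[::-1][:n_filters]
        prototypes[k] = p
        filters[k] = v[:, order]
        eigenvalues[k] = w[order]
    return XdawnModel(
        classes=classes,
        n_filters=n_filters,
        prototypes=prototypes,
        filters=filters,
        eigenvalues=eigenvalues,
        total_cov=d_total,
    )


def apply_xdawn(model: XdawnModel, epoch: np.ndarray) -> np.ndarray:
    """Augmented epoch (2KF, S): filtered prototypes over filtered signal.

    Rows 1..KF are the stacked filtered prototypes W^(k)' P^(k) — identical
    for every epoch — and rows KF+1..2KF are W' X.
    """
    epoch = np.asarray(epoch, dtype=float)
    e = next(iter(model.prototypes.values())).shape[0]
    if epoch.ndim != 2 or epoch.shape[0] != e:
        raise ValueError("epoch shape does not match the fitted model")
    upper = np.concatenate(
        [model.filters[k].T @ model.prototypes[k] for k in model.classes]
    )
    lower = model.stacked_filters.T @ epoch
    return np.concatenate([upper, lower])


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class XdawnAugment(BaseEstimator, TransformerMixin):
    """Transformer: (N, E, S) epochs -> (N, 2KF, S) xDAWN-augmented epochs."""

    def __init__(self, n_filters: int = 4):
        self.n_filters = n_filters

    def fit(self, X, y):
        self.model_ = fit_xdawn(X, y, n_filters=self.n_filters)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([apply_xdawn(self.model_, ep) for ep in X])


class Covariances(BaseEstimator, TransformerMixin):
    """Transformer: (N, E, S) epochs -> (N, E, E) OAS covariance stack."""

    def __init__(self, center: bool = True):
        self.center = center

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return oas_covariances(X, center=self.center)


class TangentSpace(BaseEstimator, TransformerMixin):
    """Transformer: SPD stack -> tangent vectors at the training Fréchet mean.

    The reference point is fit on training covariances only, so per-fold
    refitting keeps test data out of the reference.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        try:
            self.reference_ = frechet_mean(X, tol=self.tol, max_iter=self.max_iter)
        except FrechetConvergenceError as err:
            warnings.warn(f"Karcher flow not fully converged: {err}")
            self.reference_ = err.last
        self.inv_sqrt_ref_ = invsqrtm_spd(self.reference_)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        whitened = self.inv_sqrt_ref_ @ X @ self.inv_sqrt_ref_
        return _upper_vec(logm_spd(whitened))


class LinearGestureClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest L2 logistic regression (liblinear).

    The penalty uses a per-sample convention: the underlying liblinear C
    is ``reg_c / n_samples``, so duplicating every training point leaves
    the decision function unchanged. The default budget of a few hundred
    recovers the conventional C ~ 1 at the training-set sizes a guided
    session produces. ``predict_proba`` renormalizes the one-vs-rest
    probabilities across classes.
    """

    def __init__(self, reg_c: float = 500.0):
        self.reg_c = reg_c

    def fit(self, X, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes")
        # liblinear's default penalty is L2; C is per-sample scaled
        base = LogisticRegression(solver="liblinear", C=self.reg_c / len(y))
        self.ovr_ = OneVsRestClassifier(base).fit(X, y)
        self.classes_ = self.ovr_.classes_
        return self

    def predict_proba(self, X):
        return self.ovr_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
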