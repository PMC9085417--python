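"""xDAWN spatial filtering and Riemannian tangent-space features.

The single-trial feature chain: each epoch is projected through two
class-specific xDAWN filter banks (5 filters per class), stacked with the
equally filtered class prototypes (grand averages) into a 20 x T matrix,
summarised as a 20 x 20 shrinkage covariance, mapped to the tangent space of
the SPD manifold at the Karcher mean of the training covariances
(affine-invariant metric), L1-normalised, and compressed by PCA keeping 99 %
of the training variance.  Everything is fit on training data only; the
chain is deterministic given data and configuration.

xDAWN here uses the least-squares evoked estimate over the epoch window,
which for isolated, non-overlapping events reduces to the class average; the
filters maximise the generalized Rayleigh quotient
(w' S_evoked w) / (w' S_data w).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.covariance import LedoitWolf
from sklearn.decomposition import PCA

from ernbci.io_core import EpochSet, ValidationError

logger = logging.getLogger("ernbci")


# ---------------------------------------------------------------------------
# xDAWN
# ---------------------------------------------------------------------------


def fit_xdawn(epochs: np.ndarray, labels: np.ndarray, target: str,
              n_filters: int = 5, reg: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Spatial filters maximising evoked-to-total variance for one class.

    Parameters
    ----------
    epochs : ndarray (n_epochs, n_channels, n_times)
    labels : ndarray (n_epochs,)
    target : class whose evoked response the filters enhance.
    n_filters : number of leading generalized eigenvectors to keep.

    Returns
    -------
    filters : ndarray (n_filters, n_channels), unit-norm rows, ordered by
        decreasing generalized eigenvalue, sign fixed so each row's
        largest-magnitude weight is positive.
    eigenvalues : ndarray (n_filters,), non-increasing.
    """
    epochs = np.asarray(epochs, float)
    mask = np.asarray(labels) == target
    if mask.sum() < 2:
        raise ValidationError(f"need >= 2 epochs of class {target!r}")
    n_ch = epochs.shape[1]
    evoked = epochs[mask].mean(axis=0)                    # (ch, T)
    sigma_e = evoked @ evoked.T / evoked.shape[1]
    x = np.concatenate(list(epochs), axis=1)              # (ch, n*T)
    sigma_x = x @ x.T / x.shape[1]

    if np.linalg.matrix_rank(sigma_x) < n_ch:
        warnings.warn("rank-deficient data covariance; applying diagonal "
                      "loading", stacklevel=2)
    sigma_x = sigma_x + reg * np.trace(sigma_x) / n_ch * np.eye(n_ch)

    eigvals, eigvecs = scipy.linalg.eigh(sigma_e, sigma_x)
    order = np.argsort(eigvals)[::-1][:n_filters]
    filters = eigvecs[:, order].T
    eigvals = eigvals[order]
    # deterministic output: unit norm, dominant weight positive
    filters /= np.linalg.norm(filters, axis=1, keepdims=True)
    for row in filters:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return filters, eigvals


@dataclass
class SpatialFilterBank:
    """Per-class xDAWN filters with their generalized eigenvalues."""

    filters: dict[str, np.ndarray]      # class -> (n_filters, n_channels)
    eigenvalues: dict[str, np.ndarray]
    classes: tuple[str, str]

    def __post_init__(self):
        for cls in self.classes:
            ev = self.eigenvalues[cls]
            if np.any(np.diff(ev) > 1e-12):
                raise ValidationError(f"{cls}: eigenvalues not non-increasing")


def fit_filter_bank(epochs: np.ndarray, labels: np.ndarray,
                    classes: tuple[str, str], n_filters: int = 5) -> SpatialFilterBank:
    filters, eigvals = {}, {}
    for cls in classes:
        filters[cls], eigvals[cls] = fit_xdawn(epochs, labels, cls, n_filters)
    return SpatialFilterBank(filters, eigvals, classes)


def project(epoch: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Apply both filter banks; rows ordered first class 1-5, second 6-10."""
    epoch = np.asarray(epoch, float)
    stacked = np.vstack([bank.filters[c] for c in bank.classes])
    if stacked.shape[1] != epoch.shape[0]:
        raise ValidationError(
            f"filters expect {stacked.shape[1]} channels, epoch has "
            f"{epoch.shape[0]}")
    return stacked @ epoch


def augment(projected_epoch: np.ndarray, projected_prototypes: np.ndarray) -> np.ndarray:
    """Stack filtered prototypes (rows 1-10) over the filtered epoch (11-20)."""
    if projected_epoch.shape[1] != projected_prototypes.shape[1]:
        raise ValidationError("epoch and prototype lengths differ")
    if projected_prototypes.shape[0] != projected_epoch.shape[0]:
        raise ValidationError("prototype and epoch row counts differ")
    return np.vstack([projected_prototypes, projected_epoch])


# ---------------------------------------------------------------------------
# SPD covariance and tangent space
# ---------------------------------------------------------------------------


def covariance(augmented: np.ndarray, spd_floor: float = 1e-8) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance (rows = variables) with an SPD floor.

    T = 125 samples for 20 variables is marginal for a sample covariance,
    hence the analytic shrinkage toward a scaled identity; eigenvalues are
    additionally floored at ``spd_floor * trace / dim``.
    """
    augmented = np.asarray(augmented, float)
    if not np.isfinite(augmented).all():
        raise ValidationError("non-finite values in augmented epoch")
    if augmented.shape[1] < 2:
        raise ValidationError("need more than one sample to estimate covariance")
    x = augmented - augmented.mean(axis=1, keepdims=True)
    cov = LedoitWolf(assume_centered=True).fit(x.T).covariance_
    cov = 0.5 * (cov + cov.T)
    dim = cov.shape[0]
    floor = spd_floor * np.trace(cov) / dim
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] < floor:
        eigvals = np.maximum(eigvals, floor)
        cov = (eigvecs * eigvals) @ eigvecs.T
    return cov


def _check_spd(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    mat = np.asarray(mat, float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(mat)[0] <= 0:
        raise ValidationError(f"{name} is not positive definite")
    return mat


def _sqrtm_inv_sqrtm(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eigvals, eigvecs = np.linalg.eigh(mat)
    s = np.sqrt(eigvals)
    return (eigvecs * s) @ eigvecs.T, (eigvecs / s) @ eigvecs.T


def _logm(mat: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(mat)
    return (eigvecs * np.log(eigvals)) @ eigvecs.T


def _expm(mat: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(mat)
    return (eigvecs * np.exp(eigvals)) @ eigvecs.T


def riemannian_mean(mats: list[np.ndarray], tol: float = 1e-8,
                    max_iter: int = 50) -> np.ndarray:
    """Karcher mean under the affine-invariant metric.

    Fixed-point iteration: average the matrix logarithms of the whitened
    inputs in the tangent space at the current estimate, then map back with
    the exponential.  Converged when the tangent-mean (gradient) Frobenius
    norm drops below ``tol``.
    """
    if not mats:
        raise ValidationError("need at least one matrix")
    mats = [_check_spd(m, f"matrix {i}") for i, m in enumerate(mats)]
    if len(mats) == 1:
        return mats[0].copy()
    return _batch_riemannian_mean(np.stack(mats), tol=tol, max_iter=max_iter)


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant distance: ||log(eigvals of B^-1 A)||_2."""
    eigvals = scipy.linalg.eigh(a, b, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(eigvals) ** 2)))


def tangent_map(spd: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorised tangent-space projection at the reference point.

    Computes ``log(R^{-1/2} S R^{-1/2})`` and returns the upper triangle
    (row-major) with off-diagonal entries scaled by sqrt(2), so the vector's
    Euclidean norm equals the affine-invariant distance delta(S, R).  For
    20 x 20 inputs the vector has 20*21/2 = 210 entries.
    """
    spd = _check_spd(spd, "S")
    reference = _check_spd(reference, "R")
    _, inv_sqrt_r = _sqrtm_inv_sqrtm(reference)
    w = _logm(inv_sqrt_r @ spd @ inv_sqrt_r)
    dim = w.shape[0]
    iu = np.triu_indices(dim)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return w[iu] * weights


# ---------------------------------------------------------------------------
# Normalisation and PCA
# ---------------------------------------------------------------------------


def l1_normalize(vector: np.ndarray) -> np.ndarray:
    vector = np.asarray(vector, float)
    norm = np.abs(vector).sum()
    if norm == 0:
        raise ValidationError("cannot L1-normalise the zero vector")
    return vector / norm


def fit_pca(train_vectors: np.ndarray, retain: float = 0.99) -> PCA:
    """PCA keeping the smallest k with cumulative explained variance >= retain."""
    train_vectors = np.asarray(train_vectors, float)
    if train_vectors.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 training vectors")
    pca = PCA(n_components=retain, svd_solver="full")
    pca.fit(train_vectors)
    return pca


def apply_pca(pca: PCA, vectors: np.ndarray) -> np.ndarray:
    return pca.transform(np.atleast_2d(vectors))


# ---------------------------------------------------------------------------
# Batched kernels (vectorised equivalents of the per-matrix operations;
# equality with the reference implementations is covered by tests)
# ---------------------------------------------------------------------------


def _batch_covariance(augmented: np.ndarray, spd_floor: float = 1e-8) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance for a stack of (p, T) matrices."""
    x = np.asarray(augmented, float)
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in augmented epochs")
    n, p, t = x.shape
    x = x - x.mean(axis=2, keepdims=True)
    s = np.einsum("npt,nqt->npq", x, x) / t
    mu = np.trace(s, axis1=1, axis2=2) / p
    eye = np.eye(p)
    frob_s = np.einsum("npq,npq->n", s, s)
    d2 = (frob_s - p * mu ** 2) / p
    sq_norms = np.einsum("npt,npt->nt", x, x)          # ||x_t||^2 per sample
    b2 = (np.sum(sq_norms ** 2, axis=1) / t ** 2 - frob_s / t) / p
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(d2 > 0, np.minimum(b2 / d2, 1.0), 1.0)
    shrunk = ((1.0 - rho)[:, None, None] * s
              + (rho * mu)[:, None, None] * eye)
    # SPD floor, batched
    eigvals, eigvecs = np.linalg.eigh(shrunk)
    floor = (spd_floor * np.trace(shrunk, axis1=1, axis2=2) / p)[:, None]
    eigvals = np.maximum(eigvals, floor)
    return np.einsum("nij,nj,nkj->nik", eigvecs, eigvals, eigvecs)


def _batch_logm(mats: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(mats)
    return np.einsum("nij,nj,nkj->nik", eigvecs, np.log(eigvals), eigvecs)


def _batch_riemannian_mean(covs: np.ndarray, tol: float = 1e-8,
                           max_iter: int = 100) -> np.ndarray:
    """Karcher mean of a stack of SPD matrices.

    Fixed-point iteration with an adaptive step size: the step is halved
    whenever the tangent-gradient norm stops decreasing, which restores
    convergence for very ill-conditioned inputs where the full step
    oscillates.
    """
    if len(covs) == 1:
        return covs[0].copy()
    mean = covs.mean(axis=0)
    tau, prev_norm = 1.0, np.inf
    for _ in range(max_iter):
        sqrt_m, inv_sqrt_m = _sqrtm_inv_sqrtm(mean)
        whitened = inv_sqrt_m @ covs @ inv_sqrt_m
        log_mean = _batch_logm(whitened).mean(axis=0)
        norm = np.linalg.norm(log_mean, "fro")
        if norm < tol:
            return mean
        if norm >= prev_norm:
            tau = max(tau * 0.5, 1e-4)
        prev_norm = norm
        mean = sqrt_m @ _expm(tau * log_mean) @ sqrt_m
    warnings.warn("Karcher mean did not converge; returning last iterate",
                  stacklevel=2)
    return mean


def _batch_tangent(covs: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Stacked tangent-space vectors at the reference (sqrt-2 off-diagonals)."""
    _, inv_sqrt_r = _sqrtm_inv_sqrtm(reference)
    logs = _batch_logm(inv_sqrt_r @ covs @ inv_sqrt_r)
    p = logs.shape[-1]
    iu = np.triu_indices(p)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return logs[:, iu[0], iu[1]] * weights


# ---------------------------------------------------------------------------
# Fitted end-to-end chain
# ---------------------------------------------------------------------------


@dataclass
class FeatureChain:
    """The full epoch -> feature-vector map, fit on training data only."""

    classes: tuple[str, str] = ("ERN", "CRA")
    n_filters: int = 5
    pca_retain: float = 0.99
    bank: SpatialFilterBank | None = None
    prototypes: np.ndarray | None = None       # filtered prototypes (10, T)
    reference: np.ndarray | None = None        # Karcher mean of train covs
    pca: PCA | None = None

    def fit(self, epochs: np.ndarray, labels: np.ndarray) -> "FeatureChain":
        epochs = np.asarray(epochs, float)
        labels = np.asarray(labels)
        self.bank = fit_filter_bank(epochs, labels, self.classes, self.n_filters)
        # each class prototype (grand average) through its own filter bank
        self.prototypes = np.vstack([
            self.bank.filters[cls] @ epochs[labels == cls].mean(axis=0)
            for cls in self.classes
        ])
        covs = self._epoch_covs(epochs)
        self.reference = _batch_riemannian_mean(covs)
        vectors = self._vectorize(covs)
        self.pca = fit_pca(vectors, self.pca_retain)
        logger.info("FeatureChain.fit: %d epochs -> %d PCA components",
                    len(epochs), self.pca.n_components_)
        return self

    def _epoch_covs(self, epochs: np.ndarray) -> np.ndarray:
        stacked = np.vstack([self.bank.filters[c] for c in self.classes])
        projected = np.einsum("fc,nct->nft", stacked, epochs)
        protos = np.broadcast_to(
            self.prototypes, (len(epochs),) + self.prototypes.shape)
        return _batch_covariance(np.concatenate([protos, projected], axis=1))

    def _vectorize(self, covs: np.ndarray) -> np.ndarray:
        vectors = _batch_tangent(covs, self.reference)
        norms = np.abs(vectors).sum(axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValidationError("cannot L1-normalise a zero tangent vector")
        return vectors / norms

    def transform(self, epochs: np.ndarray) -> np.ndarray:
        if self.pca is None:
            raise ValidationError("chain is not fitted")
        epochs = np.asarray(epochs, float)
        vectors = self._vectorize(self._epoch_covs(epochs))
        return apply_pca(self.pca, vectors)

    def fit_transform(self, epochs: np.ndarray, labels: np.ndarray) -> np.ndarray:
        return self.fit(epochs, labels).transform(epochs)


def epochs_to_arrays(epoch_set: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (epochs, labels) arrays from an :class:`EpochSet`."""
    return epoch_set.epochs, epoch_set.labels
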