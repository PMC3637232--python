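"""Blind feature extraction: PCA truncation + FastICA on image patches.

Training patches (flattened row-major to length ``p = S*S`` vectors) are
column-centered, reduced to ``q < p`` dimensions by PCA with whitening, and
rotated by symmetric fixed-point FastICA with the log-cosh contrast.  The
combined basis

    ``W_T = K_pca.T @ W``        (p x q)

maps a centered patch to its q coefficients, ``s = (x - mean) @ W_T``, and a
patch is reconstructed (up to the discarded PCA residual) as
``mean + s @ pinv(W_T)``.  Because FastICA is an orthogonal rotation of the
whitened PCA subspace, reconstruction through the ICA basis coincides with
the rank-q PCA reconstruction; what ICA changes is the coordinate system the
classifiers see.

ICA components have no intrinsic order or sign; for reproducibility the
fitted basis orders them by descending |excess kurtosis| of the extracted
coefficients and fixes each sign so the coefficient skewness is positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ICABasis:
    """A learned patch-feature extractor.

    Attributes
    ----------
    p, q : input dimension (S*S) and number of components.
    mean : length-p vector of training column means.
    K_pca : (q, p) whitening matrix (eigenvector rows scaled by 1/sqrt(eigval)).
    W : (q, q) orthogonal ICA rotation in the whitened space.
    W_T : (p, q) combined basis, K_pca.T @ W.
    eigvals : descending covariance eigenvalues of the kept components.
    """

    p: int
    q: int
    mean: np.ndarray
    K_pca: np.ndarray
    W: np.ndarray
    W_T: np.ndarray
    eigvals: np.ndarray

    @property
    def patch_side(self) -> int:
        side = int(round(np.sqrt(self.p)))
        if side * side != self.p:
            raise ValueError("basis input dimension is not a perfect square")
        return side


@dataclass
class FeatureMatrix:
    """Per-prototype coefficient vectors with aligned metadata."""

    X: np.ndarray           # (N, q)
    y: np.ndarray           # 1 = mass, 0 = normal
    pathology: np.ndarray
    site: np.ndarray

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.pathology) == len(self.site) == n):
            raise ValueError("metadata not aligned with feature rows")


def center_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the mean of each column; returns (centered X, mean vector)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to center")
    mean = X.mean(axis=0)
    return X - mean, mean


def pca_reduce(Xc: np.ndarray, q: int,
               whiten: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Top-q PCA of centered data; returns (K_pca, eigvals).

    Rows of ``K_pca`` are covariance eigenvectors in descending eigenvalue
    order (sample covariance with N-1 denominator); with ``whiten`` each row
    is scaled by 1/sqrt(eigval) so projected components have unit variance.
    Sign convention: the largest-magnitude entry of each eigenvector is
    positive.
    """
    Xc = np.asarray(Xc, dtype=float)
    N, p = Xc.shape
    if not (1 <= q <= min(N - 1, p)):
        raise ValueError(f"q={q} outside [1, min(N-1, p)]")
    # economy SVD avoids forming the p x p covariance
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = svals**2 / (N - 1)
    comps = Vt[:q]
    flip = np.sign(comps[np.arange(q), np.abs(comps).argmax(axis=1)])
    comps = comps * flip[:, None]
    eigvals = eigvals[:q]
    if whiten:
        tol = max(N, p) * np.finfo(float).eps * max(eigvals[0], 1.0)
        if eigvals.min() <= tol:
            raise ValueError("degenerate component: eigenvalue ~ 0 with whitening")
        comps = comps / np.sqrt(eigvals)[:, None]
    return comps, eigvals


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W  (symmetric orthogonalization)."""
    evals, evecs = np.linalg.eigh(W @ W.T)
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T @ W


def fastica(Z: np.ndarray, tol: float = 1e-4, max_iter: int = 400,
            seed: int = 0) -> tuple[np.ndarray, bool]:
    """Symmetric fixed-point FastICA with the log-cosh contrast.

    ``Z`` is (q, N) whitened data.  Each row update is
    ``w <- E[z g(w.z)] - E[g'(w.z)] w`` with ``g = tanh``, followed by
    symmetric decorrelation; iteration stops when
    ``max_i |1 - |<w_i_new, w_i_old>||`` < tol.  Returns ``(W, converged)``;
    non-convergence warns and returns the current estimate.
    """
    Z = np.asarray(Z, dtype=float)
    q, n = Z.shape
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((q, q)))
    converged = False
    for _ in range(max_iter):
        WZ = W @ Z
        G = np.tanh(WZ)
        g_prime_mean = (1.0 - G**2).mean(axis=1)
        W_new = _sym_decorrelate(G @ Z.T / n - g_prime_mean[:, None] * W)
        delta = np.max(np.abs(1.0 - np.abs(np.einsum("ij,ij->i", W_new, W))))
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("FastICA did not converge within max_iter", RuntimeWarning)
    return W, converged


def build_basis(mean: np.ndarray, K_pca: np.ndarray, W: np.ndarray,
                eigvals: np.ndarray) -> ICABasis:
    """Assemble an :class:`ICABasis`, materializing ``W_T = K_pca.T @ W``."""
    mean = np.asarray(mean, dtype=float)
    K_pca = np.asarray(K_pca, dtype=float)
    W = np.asarray(W, dtype=float)
    eigvals = np.asarray(eigvals, dtype=float)
    q, p = K_pca.shape
    if W.shape != (q, q) or mean.shape != (p,) or eigvals.shape != (q,):
        raise ValueError("inconsistent shapes for ICA basis")
    return ICABasis(p=p, q=q, mean=mean, K_pca=K_pca, W=W,
                    W_T=K_pca.T @ W, eigvals=eigvals)


def fit_ica_basis(patches: "Sequence[np.ndarray] | np.ndarray", q: int,
                  seed: int = 0, tol: float = 1e-4,
                  max_iter: int = 400) -> ICABasis:
    """Learn an ICA basis from square training patches.

    center -> PCA truncate+whiten to q -> FastICA rotation; component order
    and sign are then fixed by |kurtosis| / positive skewness of the
    extracted coefficients.  The rotation stored in the basis is oriented so
    the extracted coefficients ``(x - mean) @ W_T`` are the FastICA sources.
    """
    X = np.asarray(patches, dtype=float)
    if X.ndim == 3:  # stack of S x S patches, flattened row-major
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise ValueError("patches must be an (N, S, S) stack or (N, p) matrix")
    Xc, mean = center_columns(X)
    K_pca, eigvals = pca_reduce(Xc, q, whiten=True)
    Z = K_pca @ Xc.T
    W_unmix, _ = fastica(Z, tol=tol, max_iter=max_iter, seed=seed)
    # Feature j is the column W[:, j] applied to whitened data; store the
    # unmixing transposed so features coincide with the FastICA sources.
    W = W_unmix.T
    S = W.T @ Z  # (q, N): row j = coefficient j across training patches
    order = np.argsort(-np.abs(stats.kurtosis(S, axis=1, fisher=True)),
                       kind="stable")
    W = W[:, order]
    S = S[order]
    sign = np.where(stats.skew(S, axis=1) < 0, -1.0, 1.0)
    W = W * sign[None, :]
    return build_basis(mean, K_pca, W, eigvals)


def extract_features(patch: np.ndarray, basis: ICABasis) -> np.ndarray:
    """Project one patch to its q ICA coefficients, ``(x - mean) @ W_T``.

    The patch is flattened row-major; a pre-flattened length-p vector is
    also accepted.
    """
    arr = np.asarray(patch, dtype=float)
    if arr.size != basis.p or arr.ndim not in (1, 2):
        raise ValueError(f"patch size does not match basis dimension p={basis.p}")
    return (arr.ravel() - basis.mean) @ basis.W_T


def features_for(prototypes: Sequence, basis: ICABasis) -> FeatureMatrix:
    """Featurize a list of prototypes into an aligned :class:`FeatureMatrix`."""
    X = np.stack([extract_features(pt.patch, basis) for pt in prototypes])
    y = np.array([1 if pt.label == "mass" else 0 for pt in prototypes])
    pathology = np.array([pt.pathology for pt in prototypes])
    site = np.array([pt.site for pt in prototypes])
    return FeatureMatrix(X=X, y=y, pathology=pathology, site=site)


def reconstruct(s: np.ndarray, basis: ICABasis) -> np.ndarray:
    """Rebuild an S x S patch from its coefficients (rank-q approximation)."""
    s = np.asarray(s, dtype=float)
    if s.shape != (basis.q,):
        raise ValueError(f"coefficient vector must have length q={basis.q}")
    side = basis.patch_side
    flat = basis.mean + s @ np.linalg.pinv(basis.W_T)
    return flat.reshape(side, side)


def save_basis(path: "str | Path", basis: ICABasis,
               provenance: dict | None = None) -> None:
    """Serialize a basis to an .npz archive with a JSON provenance header."""
    header = json.dumps({"p": basis.p, "q": basis.q,
                         **(provenance or {})})
    np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
             mean=basis.mean, K_pca=basis.K_pca, W=basis.W, W_T=basis.W_T,
             eigvals=basis.eigvals)


def load_basis(path: "str | Path") -> ICABasis:
    with np.load(path) as z:
        return build_basis(z["mean"], z["K_pca"], z["W"], z["eigvals"])
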