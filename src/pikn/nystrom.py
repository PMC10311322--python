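"""Nystrom kernel layer: projection onto the span of trainable anchor points.

Given a pathway kernel K and q anchor points z_1..z_q living in the
pathway's input space, a sample x is embedded as

    psi(x) = (K_ZZ + eps I)^{-1/2} K_Z(x),

where K_ZZ is the anchor Gram matrix and K_Z(x) = [K(x, z_1)..K(x, z_q)].
This is the explicit parametrization of the orthogonal projection of
phi(x) onto span(phi(z_1)..phi(z_q)) in the kernel's RKHS, so inner
products of embeddings approximate kernel values and are exact on the
anchors themselves when K_ZZ is nonsingular and eps = 0.

The anchors are model parameters.  Training therefore needs the derivative
of the inverse square root of the Gram matrix; this module implements the
standard eigendecomposition backward rule for symmetric matrix functions
and exposes analytic gradients with respect to both the anchors and the
inputs.  All math is float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .kernel import PathwayKernel
from .pathways import LaplacianMatrix

__all__ = [
    "NystromLayer",
    "init_anchors_kmeanspp",
    "gram_inverse_sqrt",
    "project",
    "forward_batch",
]

#: default ridge on the anchor Gram before the inverse square root, as a
#: fraction of the mean Gram eigenvalue (trace/q).  The ridge keeps the
#: whitening well-posed while anchors drift during training, and shrinks
#: low-variance kernel directions whose whitened coordinates would otherwise
#: be pure amplified noise.  A scale-free fraction is used because the raw
#: bilinear kernel has no intrinsic scale.
DEFAULT_EPSILON = 0.1
#: absolute floor on the ridge so a degenerate (all-zero) Gram stays regular
EPSILON_FLOOR = 1e-8
#: eigenvalues below REL_EIG_THRESHOLD * max eigenvalue are pseudo-inverted to 0
REL_EIG_THRESHOLD = 1e-6


def init_anchors_kmeanspp(X_restricted: np.ndarray, q: int, seed: int) -> np.ndarray:
    """k-means cluster centers (k-means++ seeding) of pathway-restricted samples.

    Deterministic given ``seed``.  When q exceeds the number of samples the
    centers are the samples cycled with a small seeded Gaussian jitter
    (1e-3 of the per-column spread) so the layer stays usable on tiny data.
    """
    X = np.asarray(X_restricted, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("anchor initialization needs a non-empty 2-D sample matrix")
    if q < 1:
        raise ValueError("q must be >= 1")
    n = X.shape[0]
    if q > n:
        rng = np.random.default_rng(seed)
        reps = X[np.arange(q) % n]
        scale = 1e-3 * np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        return reps + rng.standard_normal(reps.shape) * scale
    km = KMeans(n_clusters=q, init="k-means++", n_init=1, max_iter=300, tol=1e-4,
                random_state=seed)
    km.fit(X)
    return km.cluster_centers_.astype(np.float64)


def _invsqrt_eig(S: np.ndarray, rel_threshold: float = REL_EIG_THRESHOLD):
    """Eigendecomposition-based pseudo inverse square root with backward cache."""
    lam, Q = np.linalg.eigh(S)
    thr = max(lam.max(), 0.0) * rel_threshold if lam.size else 0.0
    keep = lam > thr
    g = np.where(keep, 1.0 / np.sqrt(np.where(keep, lam, 1.0)), 0.0)
    M = (Q * g) @ Q.T
    return M, (lam, Q, g, keep)


def _invsqrt_backward(cache, dM: np.ndarray) -> np.ndarray:
    """Adjoint of S -> S^{-1/2} through the eigendecomposition.

    Uses the Daleckii-Krein formula: with S = Q diag(lam) Q^T and
    g(lam) = lam^{-1/2} on the retained spectrum, the adjoint is
    Q (F o (Q^T dM Q)) Q^T with F_ij the divided difference of g.
    """
    lam, Q, g, keep = cache
    dM = 0.5 * (dM + dM.T)
    inner = Q.T @ dM @ Q
    dl = lam[:, None] - lam[None, :]
    gdiff = g[:, None] - g[None, :]
    gprime = np.where(keep, -0.5 * np.where(keep, lam, 1.0) ** -1.5, 0.0)
    near = np.abs(dl) < 1e-12 * max(1.0, np.abs(lam).max())
    F = np.where(near, 0.5 * (gprime[:, None] + gprime[None, :]),
                 gdiff / np.where(near, 1.0, dl))
    dS = Q @ (F * inner) @ Q.T
    return 0.5 * (dS + dS.T)


def gram_inverse_sqrt(K_ZZ: np.ndarray, epsilon: float = 0.0,
                      rel_threshold: float = REL_EIG_THRESHOLD) -> np.ndarray:
    """(Pseudo-)inverse square root of a regularized PSD Gram matrix.

    Eigenvalues of ``K_ZZ + epsilon I`` below ``rel_threshold`` times the
    largest eigenvalue are zeroed (pseudo-inverse); the rest are inverted
    after the square root.  The result M is symmetric and satisfies
    M (K_ZZ + eps I) M = I on the retained eigenspace.
    """
    K = np.asarray(K_ZZ, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"Gram matrix must be square, got {K.shape}")
    if np.abs(K - K.T).max() > 1e-6:
        raise ValueError("Gram matrix is not symmetric")
    S = 0.5 * (K + K.T) + epsilon * np.eye(K.shape[0])
    M, _ = _invsqrt_eig(S, rel_threshold)
    return M


@dataclass
class NystromLayer:
    """Per-pathway Nystrom projection with trainable anchors.

    Attributes
    ----------
    laplacian : the pathway's graph Laplacian (fixed)
    anchors : (q, d) matrix of anchor points (trainable)
    epsilon : ridge on the anchor Gram before the inverse square root
    """

    laplacian: LaplacianMatrix
    anchors: Optional[np.ndarray] = None
    q: int = 30
    epsilon: float = DEFAULT_EPSILON  # ridge as a fraction of mean Gram eigenvalue
    _eval_cache: Optional[tuple] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.anchors is not None:
            self.anchors = np.asarray(self.anchors, dtype=np.float64)
            if self.anchors.shape[1] != self.laplacian.size:
                raise ValueError(
                    f"pathway {self.pathway_id!r}: anchors have "
                    f"{self.anchors.shape[1]} coordinates, Laplacian has {self.laplacian.size}"
                )
            self.q = self.anchors.shape[0]
        if not np.isfinite(self.epsilon) or self.epsilon < 0:
            raise ValueError("epsilon must be finite and >= 0")

    @property
    def pathway_id(self) -> str:
        return self.laplacian.pathway_id

    @property
    def kernel(self) -> PathwayKernel:
        return PathwayKernel(self.laplacian)

    def init_anchors(self, X_restricted: np.ndarray, seed: int) -> None:
        self.anchors = init_anchors_kmeanspp(X_restricted, self.q, seed)
        self._eval_cache = None

    def invalidate_cache(self) -> None:
        self._eval_cache = None

    def _machinery(self, training: bool):
        """LZ^T, the regularized Gram and its inverse square root (cached in eval mode)."""
        if not training and self._eval_cache is not None:
            return self._eval_cache
        Z = self.anchors
        L = self.laplacian.matrix
        LZt = L @ Z.T                                  # (d, q)
        KZZ = Z @ LZt                                  # (q, q)
        KZZ = 0.5 * (KZZ + KZZ.T)
        # scale-free ridge: epsilon is a fraction of the mean Gram eigenvalue
        ridge = self.epsilon * max(np.trace(KZZ), 0.0) / self.q + EPSILON_FLOOR
        S = KZZ + ridge * np.eye(self.q)
        M, eig_cache = _invsqrt_eig(S)
        out = (LZt, M, eig_cache)
        if not training:
            self._eval_cache = out
        return out

    def forward(self, X_restricted: np.ndarray, training: bool = False):
        """Embed restricted samples; returns (Psi, cache) with Psi of shape (n, q)."""
        if self.anchors is None:
            raise RuntimeError(f"pathway {self.pathway_id!r}: anchors not initialized")
        X = np.asarray(X_restricted, dtype=np.float64)
        if X.shape[1] != self.laplacian.size:
            raise ValueError(
                f"pathway {self.pathway_id!r}: input has {X.shape[1]} coordinates, "
                f"expected {self.laplacian.size}"
            )
        LZt, M, eig_cache = self._machinery(training)
        Kx = X @ LZt                                   # (n, q)
        Psi = Kx @ M                                   # M symmetric
        cache = (X, Kx, LZt, M, eig_cache)
        return Psi, cache

    def backward(self, cache, dPsi: np.ndarray, need_dx: bool = False):
        """Gradients of a scalar loss w.r.t. anchors (and optionally inputs).

        ``dPsi`` is the upstream gradient of shape (n, q).  Returns
        (dZ, dX) with dX None unless requested.
        """
        X, Kx, LZt, M, eig_cache = cache
        L = self.laplacian.matrix
        dKx = dPsi @ M
        dM = Kx.T @ dPsi
        dS = _invsqrt_backward(eig_cache, dM)          # symmetric
        # S = K_ZZ + (eps/q) tr(K_ZZ) I: the ridge contributes through the trace
        dK = dS + (self.epsilon / self.q) * np.trace(dS) * np.eye(self.q)
        # K_ZZ = Z L Z^T: dZ gets (dK + dK^T) Z L = 2 dK Z L since dK symmetric
        dZ = 2.0 * (dK @ (LZt.T))                      # LZt.T = Z L (L symmetric)
        # K_Z(x) = X L Z^T: contribution dKx^T X L
        dZ += dKx.T @ (X @ L)
        dX = dKx @ LZt.T if need_dx else None
        return dZ, dX


def project(x_restricted: np.ndarray, layer: NystromLayer) -> np.ndarray:
    """Embedding psi(x) of a single restricted sample (length q)."""
    x = np.atleast_2d(np.asarray(x_restricted, dtype=np.float64))
    Psi, _ = layer.forward(x, training=False)
    return Psi[0]


def forward_batch(X: np.ndarray, feature_names, layers, restrictions=None,
                  training: bool = False) -> list[np.ndarray]:
    """Restrict then project a batch through every pathway layer.

    Returns one (n, q) embedding matrix per pathway.  ``restrictions`` may
    carry precomputed column maps (see pathways.build_restriction); they are
    built on the fly otherwise.
    """
    from .pathways import build_restriction

    X = np.asarray(X, dtype=np.float64)
    out = []
    for k, layer in enumerate(layers):
        restr = (restrictions[k] if restrictions is not None
                 else build_restriction(feature_names, layer.laplacian.node_names))
        Psi, _ = layer.forward(restr.apply(X), training=training)
        out.append(Psi)
    return out
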