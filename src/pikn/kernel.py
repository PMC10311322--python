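"""The pathway-induced kernel: a Laplacian bilinear form.

For a pathway with normalized graph Laplacian ``L_sym`` and two molecular
measures restricted to that pathway's nodes, the kernel is

    K(x, z) = x^T L_sym z.

Because L_sym is symmetric positive semi-definite, K is a valid (PSD)
kernel; its RKHS rewards agreement of the two measures along the pathway's
interaction structure.  Note the kernel is only PSD, not PD: directions in
the Laplacian's null space (e.g. the constant vector on a regular connected
graph) carry no similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pathways import LaplacianMatrix

__all__ = ["PathwayKernel", "kernel_value", "gram_matrix"]


@dataclass
class PathwayKernel:
    """Bilinear kernel induced by one pathway's graph Laplacian."""

    laplacian: LaplacianMatrix

    @property
    def pathway_id(self) -> str:
        return self.laplacian.pathway_id

    @property
    def dim(self) -> int:
        return self.laplacian.size

    def __call__(self, x, z) -> float:
        return kernel_value(x, z, self)


def _check_dim(v: np.ndarray, K: PathwayKernel, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != K.dim:
        raise ValueError(
            f"pathway {K.pathway_id!r}: {name} has {v.shape[-1]} coordinates, "
            f"kernel expects {K.dim}"
        )
    return v


def kernel_value(x, z, K: PathwayKernel) -> float:
    """Evaluate K(x, z) = x^T L_sym z for one pair of restricted measures."""
    x = _check_dim(np.atleast_1d(x), K, "x")
    z = _check_dim(np.atleast_1d(z), K, "z")
    return float(x @ K.laplacian.matrix @ z)


def gram_matrix(A, B, K: PathwayKernel) -> np.ndarray:
    """Cross-Gram matrix: entry (i, j) is K(A_i, B_j), computed as A L B^T."""
    A = _check_dim(np.atleast_2d(A), K, "A")
    B = _check_dim(np.atleast_2d(B), K, "B")
    return A @ K.laplacian.matrix @ B.T
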