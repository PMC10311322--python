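"""Pathway subnetworks and their graph Laplacians.

A pathway is modelled as an undirected weighted graph over named molecular
features (genes, probes, ...).  The similarity structure the kernel layer
uses is the symmetric normalized graph Laplacian

    L_sym = D^{-1/2} (D - W) D^{-1/2},

a positive semi-definite matrix with eigenvalues in [0, 2].  Isolated
(degree-0) nodes use the pseudo-inverse convention D^{-1/2}_ii = 0, so they
contribute nothing to the induced kernel.

Pathway definitions come either from GMT gene-set files (membership only,
edges defaulting to a unit-weight clique), from per-pathway edge lists, or
from precomputed Laplacian matrices in delimited text form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PathwaySubnetwork",
    "LaplacianMatrix",
    "degree_matrix",
    "unnormalized_laplacian",
    "normalized_laplacian",
    "load_pathways",
    "load_laplacian_matrix",
    "write_laplacian_matrix",
    "restrict_to_pathway",
    "build_restriction",
]

#: symmetry tolerance for matrices loaded from files
SYMMETRY_TOL = 1e-8
#: most negative eigenvalue accepted as "PSD up to round-off"
PSD_TOL = -1e-6


def _check_weight_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    asym = np.abs(W - W.T)
    if asym.size and asym.max() > 0:
        i, j = np.unravel_index(np.argmax(asym), W.shape)
        raise ValueError(
            f"weight matrix is not symmetric: W[{i},{j}]={W[i, j]!r} != W[{j},{i}]={W[j, i]!r}"
        )
    if W.size and W.min() < 0:
        i, j = np.unravel_index(np.argmin(W), W.shape)
        raise ValueError(f"edge weights must be nonnegative: W[{i},{j}]={W[i, j]!r}")
    return W


@dataclass
class PathwaySubnetwork:
    """Weighted undirected graph restricted to one pathway's member features."""

    pathway_id: str
    node_names: list[str]
    weight_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.node_names = [str(n).strip() for n in self.node_names]
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError(f"pathway {self.pathway_id!r}: duplicate node names")
        W = _check_weight_matrix(self.weight_matrix)
        if W.shape[0] != len(self.node_names):
            raise ValueError(
                f"pathway {self.pathway_id!r}: {len(self.node_names)} nodes but "
                f"weight matrix of shape {W.shape}"
            )
        np.fill_diagonal(W, 0.0)
        self.weight_matrix = W

    @property
    def size(self) -> int:
        return len(self.node_names)


@dataclass
class LaplacianMatrix:
    """A validated (symmetric PSD) pathway graph Laplacian."""

    pathway_id: str
    node_names: list[str]
    matrix: np.ndarray
    kind: str = "normalized"  # {"unnormalized", "normalized"}

    def __post_init__(self) -> None:
        self.node_names = [str(n).strip() for n in self.node_names]
        M = np.asarray(self.matrix, dtype=np.float64)
        if M.shape != (len(self.node_names),) * 2:
            raise ValueError(
                f"Laplacian {self.pathway_id!r}: shape {M.shape} does not match "
                f"{len(self.node_names)} node names"
            )
        if self.kind not in ("unnormalized", "normalized"):
            raise ValueError(f"unknown Laplacian kind {self.kind!r}")
        self.matrix = M

    @property
    def size(self) -> int:
        return len(self.node_names)

    def validate(self, psd_tol: float = PSD_TOL) -> "LaplacianMatrix":
        """Check symmetry and positive semi-definiteness; raise on violation."""
        M = self.matrix
        if M.size and np.abs(M - M.T).max() > SYMMETRY_TOL:
            raise ValueError(f"Laplacian {self.pathway_id!r} is asymmetric beyond {SYMMETRY_TOL}")
        if M.size:
            evals = np.linalg.eigvalsh(0.5 * (M + M.T))
            if evals.min() < psd_tol:
                raise ValueError(
                    f"Laplacian {self.pathway_id!r} is not PSD "
                    f"(smallest eigenvalue {evals.min():.3e})"
                )
        return self


def degree_matrix(W: np.ndarray) -> np.ndarray:
    """Diagonal degree matrix D with d_i = sum_j w_ij."""
    W = _check_weight_matrix(W)
    return np.diag(W.sum(axis=1))


def unnormalized_laplacian(W: np.ndarray, pathway_id: str = "", node_names=None) -> LaplacianMatrix:
    """Unnormalized graph Laplacian L = D - W (row sums exactly zero)."""
    W = _check_weight_matrix(W)
    L = np.diag(W.sum(axis=1)) - W
    names = list(node_names) if node_names is not None else [f"n{i}" for i in range(W.shape[0])]
    return LaplacianMatrix(pathway_id, names, L, kind="unnormalized")


def normalized_laplacian(W: np.ndarray, pathway_id: str = "", node_names=None) -> LaplacianMatrix:
    """Symmetric normalized Laplacian L_sym = D^{-1/2} (D - W) D^{-1/2}.

    Degree-0 nodes use the pseudo-inverse convention: their rows and columns
    of L_sym are identically zero.
    """
    W = _check_weight_matrix(W)
    d = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.diag(d) - W
    Lsym = (dinv_sqrt[:, None] * L) * dinv_sqrt[None, :]
    Lsym = 0.5 * (Lsym + Lsym.T)  # kill round-off asymmetry
    names = list(node_names) if node_names is not None else [f"n{i}" for i in range(W.shape[0])]
    return LaplacianMatrix(pathway_id, names, Lsym, kind="normalized")


def pathway_laplacian(pw: PathwaySubnetwork, kind: str = "normalized") -> LaplacianMatrix:
    """Laplacian of a pathway subnetwork, carrying its id and node order."""
    fn = normalized_laplacian if kind == "normalized" else unnormalized_laplacian
    return fn(pw.weight_matrix, pathway_id=pw.pathway_id, node_names=pw.node_names)


# ---------------------------------------------------------------------------
# file formats


def _read_edge_list(path, members: list[str]) -> np.ndarray:
    """Weight matrix over `members` from a 3-column (a, b, weight) TSV.

    Edges touching identifiers outside the member set are ignored; members
    absent from the file stay isolated.
    """
    pos = {m: i for i, m in enumerate(members)}
    W = np.zeros((len(members), len(members)))
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "w"], comment="#")
    for a, b, w in df.itertuples(index=False):
        a, b = str(a).strip(), str(b).strip()
        if a in pos and b in pos and a != b:
            W[pos[a], pos[b]] = W[pos[b], pos[a]] = float(w)
    return W


def load_pathways(
    gmt_path,
    edge_weight_policy: str = "clique-unit-weights",
    edge_dir=None,
) -> list[PathwaySubnetwork]:
    """Parse a GMT gene-set file into pathway subnetworks.

    GMT lines are ``name<TAB>description<TAB>member1<TAB>member2...``.  Under
    ``clique-unit-weights`` every pathway becomes a unit-weight clique over
    its members (GMT carries no topology).  Under ``external-edge-list`` the
    weights of pathway ``pw`` are read from ``<edge_dir>/<pw>.tsv``; members
    missing from the edge file become isolated nodes.
    """
    if edge_weight_policy not in ("clique-unit-weights", "external-edge-list"):
        raise ValueError(f"unknown edge_weight_policy {edge_weight_policy!r}")
    if edge_weight_policy == "external-edge-list" and edge_dir is None:
        raise ValueError("edge_weight_policy='external-edge-list' requires edge_dir")

    pathways: list[PathwaySubnetwork] = []
    with open(gmt_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                warnings.warn(f"{gmt_path}: skipping empty line {lineno}")
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 3:
                warnings.warn(
                    f"{gmt_path}: line {lineno} ({parts[0]!r}) has no members, skipping"
                )
                continue
            name, _desc, raw_members = parts[0], parts[1], parts[2:]
            members: list[str] = []
            seen = set()
            for m in raw_members:
                if not m:
                    continue
                if m in seen:
                    warnings.warn(f"pathway {name!r}: duplicate member {m!r} dropped")
                    continue
                seen.add(m)
                members.append(m)
            if not members:
                warnings.warn(f"pathway {name!r}: no members after cleanup, skipping")
                continue
            d = len(members)
            if edge_weight_policy == "clique-unit-weights":
                W = np.ones((d, d)) - np.eye(d)
            else:
                edge_path = Path(edge_dir) / f"{name}.tsv"
                if not edge_path.exists():
                    raise FileNotFoundError(
                        f"pathway {name!r}: edge file {edge_path} not found"
                    )
                W = _read_edge_list(edge_path, members)
            pathways.append(PathwaySubnetwork(name, members, W))
    return pathways


def write_gmt(pathways: list[PathwaySubnetwork], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, description, *pw.node_names]) + "\n")


def write_edge_list(pw: PathwaySubnetwork, path) -> None:
    W = pw.weight_matrix
    with open(path, "w") as fh:
        for i in range(pw.size):
            for j in range(i + 1, pw.size):
                if W[i, j] != 0:
                    fh.write(f"{pw.node_names[i]}\t{pw.node_names[j]}\t{W[i, j]:g}\n")


def load_laplacian_matrix(path, pathway_id: str | None = None) -> LaplacianMatrix:
    """Load and validate a Laplacian from a TSV with node-name header and index.

    The kind is inferred: eigenvalues within [0, 2] (up to round-off) mean
    normalized, anything larger unnormalized.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    names = [str(c).strip() for c in df.columns]
    idx = [str(i).strip() for i in df.index]
    if names != idx:
        raise ValueError(f"{path}: header and index node names disagree")
    M = df.to_numpy(dtype=np.float64)
    if M.size and np.abs(M - M.T).max() > SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetric beyond {SYMMETRY_TOL}")
    M = 0.5 * (M + M.T)
    evals = np.linalg.eigvalsh(M) if M.size else np.zeros(0)
    if evals.size and evals.min() < PSD_TOL:
        raise ValueError(f"{path}: negative eigenvalue {evals.min():.3e}, not a Laplacian")
    kind = "normalized" if (not evals.size or evals.max() <= 2 + 1e-6) else "unnormalized"
    pid = pathway_id if pathway_id is not None else Path(path).stem
    return LaplacianMatrix(pid, names, M, kind=kind).validate()


def write_laplacian_matrix(lap: LaplacianMatrix, path) -> None:
    pd.DataFrame(lap.matrix, index=lap.node_names, columns=lap.node_names).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# feature restriction


@dataclass
class Restriction:
    """Precomputed column mapping from a feature space onto pathway node order."""

    indices: np.ndarray  # position in X's columns, -1 for missing nodes
    present: np.ndarray  # boolean mask over pathway nodes
    node_names: list[str] = field(default_factory=list)

    def apply(self, X: np.ndarray) -> np.ndarray:
        Xr = X[:, np.where(self.indices >= 0, self.indices, 0)].astype(np.float64, copy=True)
        Xr[:, ~self.present] = 0.0
        return Xr


def build_restriction(feature_names: list[str], node_names: list[str]) -> Restriction:
    pos = {str(f).strip(): i for i, f in enumerate(feature_names)}
    idx = np.array([pos.get(str(n).strip(), -1) for n in node_names], dtype=np.int64)
    return Restriction(indices=idx, present=idx >= 0, node_names=list(node_names))


def restrict_to_pathway(
    X: np.ndarray,
    feature_names: list[str],
    pathway,
    missing_policy: str = "zero-fill",
):
    """Select (and order) the columns of X belonging to one pathway.

    Parameters
    ----------
    X : (n_samples, n_features) matrix
    feature_names : column names of X (unique)
    pathway : PathwaySubnetwork or LaplacianMatrix supplying the node order
    missing_policy : "zero-fill" keeps the pathway dimension fixed and fills
        absent nodes with constant-zero columns; "drop-node" removes absent
        nodes and returns a correspondingly reduced pathway object (for a
        precomputed Laplacian the principal submatrix is taken).

    Returns
    -------
    (X_restricted, pathway_out) where pathway_out equals the input pathway
    under zero-fill and a reduced copy under drop-node.
    """
    if missing_policy not in ("zero-fill", "drop-node"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if len(set(feature_names)) != len(feature_names):
        raise ValueError("feature names must be unique")
    X = np.asarray(X, dtype=np.float64)
    restr = build_restriction(feature_names, pathway.node_names)
    if not restr.present.any():
        raise ValueError(
            f"pathway {pathway.pathway_id!r} shares no features with the dataset"
        )
    if missing_policy == "zero-fill":
        return restr.apply(X), pathway
    keep = np.where(restr.present)[0]
    kept_names = [pathway.node_names[i] for i in keep]
    Xr = X[:, restr.indices[keep]]
    if isinstance(pathway, PathwaySubnetwork):
        reduced = PathwaySubnetwork(
            pathway.pathway_id, kept_names, pathway.weight_matrix[np.ix_(keep, keep)]
        )
    else:
        reduced = LaplacianMatrix(
            pathway.pathway_id, kept_names, pathway.matrix[np.ix_(keep, keep)], pathway.kind
        )
    return Xr, reduced
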