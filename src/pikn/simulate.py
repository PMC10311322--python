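"""Synthetic pathway-structured (multi-)omics data with known ground truth.

The generator builds p disjoint pathway subnetworks over named features and
draws a labelled expression matrix in which a chosen subset of pathways is
"informative": member features of informative pathways receive a
class-conditional mean shift (in units of the noise standard deviation) for
positive samples, on top of equicorrelated Gaussian within-pathway noise.
An optional second modality emulates copy-number-alteration calls: mostly
exact zeros, otherwise integer shifts in {-2,-1,1,2} whose sign is biased
by the label on informative pathways.

Topology matters more than it may appear: for a regular graph (e.g. a
clique) the constant vector is exactly the null direction of the normalized
Laplacian, so a uniform mean shift across a pathway would be invisible to
the pathway-induced kernel, and even near-regular graphs annihilate most of
it.  Random trees are therefore grown by preferential attachment: their
scale-free, hub-dominated degree distribution both matches the canonical
picture of molecular interaction networks and keeps a substantial part of
the class shift outside the Laplacian's null space.

Everything is deterministic given the seed, which makes these datasets the
statistical ground truth for the parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .data import OmicsDataset
from .pathways import PathwaySubnetwork, write_edge_list, write_gmt

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_pathways",
    "simulate_expression",
    "simulate_multiomics",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator (defaults define the study conditions)."""

    n_samples: int = 500
    n_pathways: int = 10
    pathway_size_range: tuple = (10, 30)
    informative_set: tuple = (0, 1)
    effect_size: float = 1.5              # class mean shift in noise-sd units
    within_pathway_correlation: float = 0.3
    label_balance: float = 0.5            # positive fraction
    sparsity: float = 0.9                 # exact-zero fraction of the CNA-like modality
    sign_bias: float = 0.8                # P(positive shift) on informative features of positives
    topology: str = "random-tree"
    seed: int = 0

    def __post_init__(self) -> None:
        inf = tuple(int(i) for i in self.informative_set)
        if any(i < 0 or i >= self.n_pathways for i in inf):
            raise ValueError("informative_set must index pathways in [0, n_pathways)")
        self.informative_set = inf
        if not (0.0 < self.label_balance < 1.0):
            raise ValueError("label_balance must lie strictly between 0 and 1")
        if not (0.0 <= self.within_pathway_correlation < 1.0):
            raise ValueError("within_pathway_correlation must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.sparsity <= 1.0):
            raise ValueError("sparsity must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """Generated modalities plus the ground truth behind them."""

    modalities: dict[str, OmicsDataset]
    pathways: list[PathwaySubnetwork]
    informative_set: tuple
    config: SimulationConfig

    @property
    def labels(self) -> np.ndarray:
        return next(iter(self.modalities.values())).labels

    @property
    def informative_ids(self) -> list[str]:
        return [self.pathways[i].pathway_id for i in self.informative_set]

    def write(self, outdir) -> None:
        """Write matrices (TSV), labels (TSV), pathways (GMT + edge lists) and manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mod, ds in self.modalities.items():
            ds.write_tsv(outdir / f"{mod}.tsv")
        ds0 = next(iter(self.modalities.values()))
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("sample_id\tlabel\n")
            for sid, y in zip(ds0.sample_ids, ds0.labels):
                fh.write(f"{sid}\t{int(y)}\n")
        write_gmt(self.pathways, outdir / "pathways.gmt")
        edge_dir = outdir / "edges"
        edge_dir.mkdir(exist_ok=True)
        for pw in self.pathways:
            write_edge_list(pw, edge_dir / f"{pw.pathway_id}.tsv")
        manifest = {"informative_pathways": self.informative_ids,
                    "config": asdict(self.config)}
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def _pathway_graph(size: int, topology: str, rng: np.random.Generator) -> np.ndarray:
    if size == 1:
        return np.zeros((1, 1))
    if topology == "clique":
        return np.ones((size, size)) - np.eye(size)
    if topology == "random-tree":
        # preferential-attachment tree: scale-free degree distribution
        g = nx.barabasi_albert_graph(size, 1, seed=int(rng.integers(2**31 - 1)))
    elif topology == "erdos-renyi":
        g = nx.gnp_random_graph(size, p=min(1.0, 2.0 / size + 0.2),
                                seed=int(rng.integers(2**31 - 1)))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    W = nx.to_numpy_array(g, nodelist=sorted(g.nodes()))
    return W


def simulate_pathways(p: int, size_range, topology: str = "random-tree",
                      seed: int = 0) -> list[PathwaySubnetwork]:
    """p disjoint-feature pathway subnetworks with unit edge weights."""
    import warnings

    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 1:
        raise ValueError("pathway sizes must be >= 1")
    if lo == 1:
        warnings.warn("pathways of size 1 have an all-zero Laplacian")
    rng = np.random.default_rng(seed)
    pathways = []
    gene = 0
    for r in range(p):
        size = int(rng.integers(lo, hi + 1))
        names = [f"g{gene + i:04d}" for i in range(size)]
        gene += size
        W = _pathway_graph(size, topology, rng)
        pathways.append(PathwaySubnetwork(f"pw{r:02d}", names, W))
    return pathways


def _equicorrelated_noise(n: int, d: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """n x d Gaussian noise, unit variance, pairwise correlation rho within the block."""
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, d))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep


def simulate_expression(cfg: SimulationConfig, pathways: list[PathwaySubnetwork],
                        modality: str = "expression") -> SyntheticDataset:
    """Labelled expression matrix over the pathways' features.

    Noise is equicorrelated Gaussian (sd 1, correlation rho) within each
    pathway and independent across pathways.  Features of informative
    pathways get mean +effect_size for positive samples, 0 otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = (rng.random(cfg.n_samples) < cfg.label_balance).astype(np.int64)
    blocks, names = [], []
    informative = set(cfg.informative_set)
    for r, pw in enumerate(pathways):
        block = _equicorrelated_noise(cfg.n_samples, pw.size,
                                      cfg.within_pathway_correlation, rng)
        if r in informative:
            block = block + cfg.effect_size * labels[:, None]
        blocks.append(block)
        names.extend(pw.node_names)
    X = np.hstack(blocks)
    ds = OmicsDataset(X=X, feature_names=names,
                      sample_ids=[f"s{i:05d}" for i in range(cfg.n_samples)],
                      labels=labels, modality=modality)
    return SyntheticDataset(modalities={modality: ds}, pathways=list(pathways),
                            informative_set=cfg.informative_set, config=cfg)


def simulate_multiomics(cfg_expression: SimulationConfig,
                        cfg_sparse: SimulationConfig | None = None,
                        shared_labels: bool = True,
                        seed: int | None = None) -> SyntheticDataset:
    """Two-modality dataset: dense expression plus a sparse CNA-like matrix.

    The sparse modality is spike-and-slab: exact zero with probability
    ``sparsity``, otherwise an integer shift in {-2,-1,1,2}.  On informative
    pathways the sign of a positive sample's nonzero entries is positive
    with probability ``sign_bias``; everywhere else signs are fair coins.
    Labels are shared between modalities (the only supported contract).
    """
    if cfg_sparse is None:
        cfg_sparse = cfg_expression
    if cfg_sparse.n_samples != cfg_expression.n_samples:
        raise ValueError("both modalities need the same number of samples")
    if not shared_labels:
        raise ValueError("modalities must share labels; independent labels are unsupported")
    if seed is None:
        seed = cfg_expression.seed

    rng = np.random.default_rng(seed)
    pathways = simulate_pathways(cfg_expression.n_pathways,
                                 cfg_expression.pathway_size_range,
                                 topology=cfg_expression.topology,
                                 seed=int(rng.integers(2**31 - 1)))
    expr = simulate_expression(cfg_expression, pathways, modality="expression")
    labels = expr.labels

    n = cfg_sparse.n_samples
    informative = set(cfg_sparse.informative_set)
    blocks = []
    for r, pw in enumerate(pathways):
        nonzero = rng.random((n, pw.size)) >= cfg_sparse.sparsity
        magnitude = rng.integers(1, 3, size=(n, pw.size)).astype(np.float64)
        p_pos = np.full((n, pw.size), 0.5)
        if r in informative:
            p_pos[labels == 1, :] = cfg_sparse.sign_bias
        sign = np.where(rng.random((n, pw.size)) < p_pos, 1.0, -1.0)
        blocks.append(np.where(nonzero, sign * magnitude, 0.0))
    names = [name for pw in pathways for name in pw.node_names]
    cna = OmicsDataset(X=np.hstack(blocks), feature_names=names,
                       sample_ids=[f"s{i:05d}" for i in range(n)],
                       labels=labels.copy(), modality="cna")
    return SyntheticDataset(
        modalities={"expression": expr.modalities["expression"], "cna": cna},
        pathways=pathways, informative_set=cfg_expression.informative_set,
        config=cfg_expression)
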