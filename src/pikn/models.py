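"""Interpretable prediction heads over pathway kernel embeddings.

Two head families sit on top of the per-pathway Nystrom embeddings
psi_1..psi_p (one length-q vector per pathway):

* pooling head (globally interpretable): each embedding is max-pooled to a
  single activation A_r = max(psi_r), and the prediction is the strictly
  linear weighted sum  y = sum_r w_r A_r.  The sign and magnitude of w_r
  say how, and how strongly, pathway r drives the prediction for every
  sample.

* gated-attention head (locally interpretable): the embeddings form a bag
  of p instances of a multiple-instance-learning problem; attention weights
    a_r = softmax_r( w^T (tanh(V psi_r) . sigmoid(U psi_r)) )
  aggregate the bag into psi~ = sum_r a_r psi_r, classified by a strictly
  linear layer.  The a_r are input-specific pathway importances.

A multi-omics composite first max-pools each modality's pathway embeddings
into a modality vector, projects each to a common width, and fuses the
modality vectors with gated attention before the linear classifier.

Model classes own their Nystrom layers and parameters and implement both
the forward pass and analytic backpropagation; there is no autodiff
framework underneath, which keeps the models dependency-light and exactly
reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .data import OmicsDataset, Standardizer
from .nystrom import DEFAULT_EPSILON, NystromLayer
from .pathways import LaplacianMatrix, Restriction, build_restriction

__all__ = [
    "PoolingHeadParams",
    "AttentionParams",
    "PredictionRecord",
    "max_pool_activation",
    "pooling_forward",
    "attention_weights",
    "attention_pool",
    "attention_forward",
    "multiomics_forward",
    "PoolingKernelNet",
    "AttentionKernelNet",
    "MultiOmicsKernelNet",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# functional ops (single sample / single bag), used directly and as oracles


@dataclass
class PoolingHeadParams:
    """Signed per-pathway weights of the strictly linear pooling head."""

    weights: np.ndarray
    bias: float = 0.0
    use_bias: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()


@dataclass
class AttentionParams:
    """Parameters of the (gated) attention MIL pooling layer.

    w is (l,), V and U are (l, m) with m the instance dimension; U is only
    used when ``gated``.
    """

    w: np.ndarray
    V: np.ndarray
    U: Optional[np.ndarray] = None
    gated: bool = True

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        self.V = np.asarray(self.V, dtype=np.float64)
        l, m = self.V.shape
        if self.w.shape[0] != l:
            raise ValueError(f"w has length {self.w.shape[0]}, V has {l} rows")
        if self.gated:
            if self.U is None:
                raise ValueError("gated attention requires U")
            self.U = np.asarray(self.U, dtype=np.float64)
            if self.U.shape != (l, m):
                raise ValueError(f"U shape {self.U.shape} != V shape {(l, m)}")

    @property
    def attention_dim(self) -> int:
        return self.V.shape[0]

    @property
    def instance_dim(self) -> int:
        return self.V.shape[1]

    @classmethod
    def random_init(cls, attention_dim: int, instance_dim: int, gated: bool,
                    rng: np.random.Generator) -> "AttentionParams":
        def glorot(shape):
            s = np.sqrt(2.0 / sum(shape))
            return rng.standard_normal(shape) * s
        return cls(
            w=glorot((attention_dim, 1)).ravel(),
            V=glorot((attention_dim, instance_dim)),
            U=glorot((attention_dim, instance_dim)) if gated else None,
            gated=gated,
        )


@dataclass
class PredictionRecord:
    """One sample's prediction plus its interpretation payload.

    ``per_pathway`` holds the pooled activations A_r for pooling heads and
    the attention weights a_r for attention heads (modality-level attention
    for the multi-omics composite).
    """

    score: float
    per_pathway: np.ndarray
    pathway_ids: list[str]
    sample_id: str = ""

    @property
    def probability(self) -> float:
        return float(expit(self.score))


def max_pool_activation(psi: np.ndarray) -> float:
    """A_r = max over the q entries of one pathway embedding."""
    psi = np.asarray(psi, dtype=np.float64).ravel()
    if psi.size == 0:
        raise ValueError("cannot max-pool an empty embedding")
    return float(psi.max())


def pooling_forward(embeddings, head: PoolingHeadParams,
                    pathway_ids=None, sample_id: str = "") -> PredictionRecord:
    """Strictly linear pooled prediction  y = sum_r w_r max(psi_r)."""
    p = len(embeddings)
    if p != head.weights.shape[0]:
        raise ValueError(f"{p} embeddings for {head.weights.shape[0]} head weights")
    A = np.array([max_pool_activation(psi) for psi in embeddings])
    score = float(head.weights @ A) + (head.bias if head.use_bias else 0.0)
    ids = list(pathway_ids) if pathway_ids is not None else [f"pw{i}" for i in range(p)]
    return PredictionRecord(score=score, per_pathway=A, pathway_ids=ids, sample_id=sample_id)


def attention_weights(bag: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Softmax-normalized (gated) attention weights over the p instances of a bag."""
    H = np.atleast_2d(np.asarray(bag, dtype=np.float64))
    if H.shape[1] != params.instance_dim:
        raise ValueError(
            f"instances of dimension {H.shape[1]}, attention expects {params.instance_dim}"
        )
    t = np.tanh(H @ params.V.T)                    # (p, l)
    if params.gated:
        t = t * expit(H @ params.U.T)
    logits = t @ params.w                          # (p,)
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def attention_pool(bag: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Bag representation psi~ = sum_r a_r psi_r."""
    H = np.atleast_2d(np.asarray(bag, dtype=np.float64))
    a = np.asarray(a, dtype=np.float64).ravel()
    if a.shape[0] != H.shape[0]:
        raise ValueError(f"{a.shape[0]} weights for {H.shape[0]} instances")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError("attention weights must sum to 1")
    return a @ H


def attention_forward(embeddings, att: AttentionParams, classifier_weights,
                      pathway_ids=None, sample_id: str = "") -> PredictionRecord:
    """Attention-MIL prediction for one sample's bag of pathway embeddings."""
    H = np.vstack([np.asarray(e, dtype=np.float64).ravel() for e in embeddings])
    a = attention_weights(H, att)
    pooled = attention_pool(H, a)
    c = np.asarray(classifier_weights, dtype=np.float64).ravel()
    if c.shape[0] != pooled.shape[0]:
        raise ValueError(f"classifier of length {c.shape[0]} for bag dim {pooled.shape[0]}")
    ids = list(pathway_ids) if pathway_ids is not None else [f"pw{i}" for i in range(len(a))]
    return PredictionRecord(score=float(c @ pooled), per_pathway=a,
                            pathway_ids=ids, sample_id=sample_id)


def multiomics_forward(per_modality_embeddings: dict, per_modality_projections: dict,
                       fusion: AttentionParams, classifier_weights,
                       sample_id: str = "") -> PredictionRecord:
    """Single-sample multi-omics fusion.

    Each modality's list of pathway embeddings is max-pooled into a vector
    of activations, linearly projected to the common fusion width, and the
    per-modality vectors are fused by gated attention then classified
    linearly.  ``per_modality_projections[mod]`` is the (m_f, p_mod)
    projection matrix.
    """
    if not per_modality_embeddings:
        raise ValueError("at least one modality is required")
    modalities = sorted(per_modality_embeddings)
    rows = []
    for mod in modalities:
        A = np.array([max_pool_activation(psi) for psi in per_modality_embeddings[mod]])
        P = np.asarray(per_modality_projections[mod], dtype=np.float64)
        rows.append(P @ A)
    H = np.vstack(rows)                            # (n_modalities, m_f)
    a = attention_weights(H, fusion)
    pooled = attention_pool(H, a)
    c = np.asarray(classifier_weights, dtype=np.float64).ravel()
    return PredictionRecord(score=float(c @ pooled), per_pathway=a,
                            pathway_ids=modalities, sample_id=sample_id)


# ---------------------------------------------------------------------------
# batched softmax attention with backward (shared by the model classes)


def _attention_batch_forward(Psis: list[np.ndarray], att: AttentionParams):
    """Vectorized attention over n bags, each with p instances of dim m.

    Psis is a list of p arrays of shape (n, m).  Returns attention weights
    (n, p), pooled bags (n, m) and a backward cache.
    """
    H = np.stack(Psis, axis=1)                     # (n, p, m)
    T = np.tanh(H @ att.V.T)                       # (n, p, l)
    if att.gated:
        Sg = expit(H @ att.U.T)
        G = T * Sg
    else:
        Sg = None
        G = T
    logits = G @ att.w                             # (n, p)
    logits = logits - logits.max(axis=1, keepdims=True)
    E = np.exp(logits)
    A = E / E.sum(axis=1, keepdims=True)           # (n, p)
    pooled = np.einsum("np,npm->nm", A, H)
    return A, pooled, (H, T, Sg, G, A)


def _attention_batch_backward(cache, att: AttentionParams, dA_extra, dpooled):
    """Backward through attention pooling.

    dA_extra is any upstream gradient landing directly on the attention
    weights (usually zero), dpooled the gradient on the pooled bags.
    Returns (dH, dw, dV, dU).
    """
    H, T, Sg, G, A = cache
    dA = dA_extra + np.einsum("nm,npm->np", dpooled, H)
    dH = A[:, :, None] * dpooled[:, None, :]
    # softmax backward
    dlogits = A * (dA - (dA * A).sum(axis=1, keepdims=True))   # (n, p)
    dG = dlogits[:, :, None] * att.w[None, None, :]            # (n, p, l)
    dw = np.einsum("npl,np->l", G, dlogits)
    if att.gated:
        dT = dG * Sg
        dSg = dG * T
        dpre_s = dSg * Sg * (1.0 - Sg)
        dU = np.einsum("npl,npm->lm", dpre_s, H)
        dH += dpre_s @ att.U
    else:
        dT = dG
        dU = None
    dpre_t = dT * (1.0 - T * T)
    dV = np.einsum("npl,npm->lm", dpre_t, H)
    dH += dpre_t @ att.V
    return dH, dw, dV, dU


def _maxpool_batch(Psi: np.ndarray):
    idx = Psi.argmax(axis=1)
    return Psi[np.arange(Psi.shape[0]), idx], idx


def _maxpool_backward(shape, idx, dA_col):
    dPsi = np.zeros(shape)
    dPsi[np.arange(shape[0]), idx] = dA_col
    return dPsi


# ---------------------------------------------------------------------------
# model classes


class _KernelNetBase:
    """Shared plumbing: Nystrom layers, feature restriction, standardization."""

    def __init__(self, laplacians: list[LaplacianMatrix], q: int, epsilon: float):
        self.layers = [NystromLayer(laplacian=lap, q=q, epsilon=epsilon) for lap in laplacians]
        self.q = q
        self.epsilon = epsilon
        self.scaler: Optional[Standardizer] = None
        self._restr_cache: dict = {}

    @property
    def pathway_ids(self) -> list[str]:
        return [layer.pathway_id for layer in self.layers]

    @property
    def n_pathways(self) -> int:
        return len(self.layers)

    def _restrictions(self, feature_names) -> list[Restriction]:
        key = tuple(feature_names)
        if key not in self._restr_cache:
            self._restr_cache[key] = [
                build_restriction(feature_names, layer.laplacian.node_names)
                for layer in self.layers
            ]
        return self._restr_cache[key]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return self.scaler.transform(X) if self.scaler is not None else X

    def init_anchors(self, dataset: OmicsDataset, seed: int) -> None:
        """k-means++ anchor initialization on the (standardized) restricted data."""
        X = self._prepare(dataset.X)
        restrs = self._restrictions(dataset.feature_names)
        for k, layer in enumerate(self.layers):
            layer.init_anchors(restrs[k].apply(X), seed + k)

    def embeddings(self, dataset: OmicsDataset, training: bool = False):
        X = self._prepare(dataset.X)
        restrs = self._restrictions(dataset.feature_names)
        out, caches = [], []
        for k, layer in enumerate(self.layers):
            Psi, cache = layer.forward(restrs[k].apply(X), training=training)
            out.append(Psi)
            caches.append(cache)
        return out, caches

    def invalidate_caches(self) -> None:
        for layer in self.layers:
            layer.invalidate_cache()


class PoolingKernelNet(_KernelNetBase):
    """Globally interpretable model: Nystrom layers + max pooling + linear head."""

    kind = "pooling"

    def __init__(self, laplacians: list[LaplacianMatrix], q: int = 30,
                 epsilon: float = DEFAULT_EPSILON, init_seed: int = 0,
                 zero_init_head: bool = False):
        super().__init__(laplacians, q, epsilon)
        rng = np.random.default_rng(init_seed)
        w = (np.zeros(self.n_pathways) if zero_init_head
             else rng.standard_normal(self.n_pathways) * 0.1)
        self.head = PoolingHeadParams(weights=w)

    # parameter dict interface used by the optimizer
    def parameters(self) -> dict[str, np.ndarray]:
        params = {f"anchors/{k}": layer.anchors for k, layer in enumerate(self.layers)}
        params["head/w"] = self.head.weights
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for k, layer in enumerate(self.layers):
            layer.anchors = np.asarray(params[f"anchors/{k}"], dtype=np.float64)
        self.head.weights = np.asarray(params["head/w"], dtype=np.float64)
        self.invalidate_caches()

    def forward_scores(self, dataset: OmicsDataset, training: bool = False):
        Psis, layer_caches = self.embeddings(dataset, training=training)
        A = np.empty((dataset.n_samples, self.n_pathways))
        idxs = []
        for r, Psi in enumerate(Psis):
            A[:, r], idx = _maxpool_batch(Psi)
            idxs.append(idx)
        scores = A @ self.head.weights
        return scores, (Psis, layer_caches, A, idxs)

    def backward(self, cache, dscores: np.ndarray) -> dict[str, np.ndarray]:
        Psis, layer_caches, A, idxs = cache
        grads = {"head/w": A.T @ dscores}
        for r, layer in enumerate(self.layers):
            dA_col = dscores * self.head.weights[r]
            dPsi = _maxpool_backward(Psis[r].shape, idxs[r], dA_col)
            dZ, _ = layer.backward(layer_caches[r], dPsi)
            grads[f"anchors/{r}"] = dZ
        return grads

    def predict(self, dataset: OmicsDataset) -> list[PredictionRecord]:
        scores, (Psis, _, A, _) = self.forward_scores(dataset, training=False)
        return [
            PredictionRecord(score=float(scores[i]), per_pathway=A[i].copy(),
                             pathway_ids=self.pathway_ids, sample_id=dataset.sample_ids[i])
            for i in range(dataset.n_samples)
        ]

    def predict_scores(self, dataset: OmicsDataset) -> np.ndarray:
        return self.forward_scores(dataset, training=False)[0]


class AttentionKernelNet(_KernelNetBase):
    """Locally interpretable model: Nystrom layers + gated-attention MIL head."""

    kind = "attention"

    def __init__(self, laplacians: list[LaplacianMatrix], q: int = 30,
                 attention_dim: int = 128, gated: bool = True,
                 epsilon: float = DEFAULT_EPSILON, init_seed: int = 0):
        super().__init__(laplacians, q, epsilon)
        rng = np.random.default_rng(init_seed)
        self.att = AttentionParams.random_init(attention_dim, q, gated, rng)
        self.classifier = rng.standard_normal(q) * 0.1

    def parameters(self) -> dict[str, np.ndarray]:
        params = {f"anchors/{k}": layer.anchors for k, layer in enumerate(self.layers)}
        params["att/w"] = self.att.w
        params["att/V"] = self.att.V
        if self.att.gated:
            params["att/U"] = self.att.U
        params["classifier"] = self.classifier
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for k, layer in enumerate(self.layers):
            layer.anchors = np.asarray(params[f"anchors/{k}"], dtype=np.float64)
        self.att.w = np.asarray(params["att/w"], dtype=np.float64)
        self.att.V = np.asarray(params["att/V"], dtype=np.float64)
        if self.att.gated:
            self.att.U = np.asarray(params["att/U"], dtype=np.float64)
        self.classifier = np.asarray(params["classifier"], dtype=np.float64)
        self.invalidate_caches()

    def forward_scores(self, dataset: OmicsDataset, training: bool = False):
        Psis, layer_caches = self.embeddings(dataset, training=training)
        A, pooled, att_cache = _attention_batch_forward(Psis, self.att)
        scores = pooled @ self.classifier
        return scores, (Psis, layer_caches, att_cache, pooled, A)

    def backward(self, cache, dscores: np.ndarray) -> dict[str, np.ndarray]:
        Psis, layer_caches, att_cache, pooled, A = cache
        n, p = A.shape
        dpooled = dscores[:, None] * self.classifier[None, :]
        dH, dw, dV, dU = _attention_batch_backward(
            att_cache, self.att, np.zeros((n, p)), dpooled)
        grads = {"att/w": dw, "att/V": dV, "classifier": pooled.T @ dscores}
        if self.att.gated:
            grads["att/U"] = dU
        for r, layer in enumerate(self.layers):
            dZ, _ = layer.backward(layer_caches[r], dH[:, r, :])
            grads[f"anchors/{r}"] = dZ
        return grads

    def predict(self, dataset: OmicsDataset) -> list[PredictionRecord]:
        scores, (_, _, _, _, A) = self.forward_scores(dataset, training=False)
        return [
            PredictionRecord(score=float(scores[i]), per_pathway=A[i].copy(),
                             pathway_ids=self.pathway_ids, sample_id=dataset.sample_ids[i])
            for i in range(dataset.n_samples)
        ]

    def predict_scores(self, dataset: OmicsDataset) -> np.ndarray:
        return self.forward_scores(dataset, training=False)[0]


class MultiOmicsKernelNet:
    """Multi-omics composite: per-modality pooled kernel embeddings fused by attention.

    Each modality owns its pathway set and Nystrom layers.  The modality
    vector is the concatenation of its pooled activations A_r, linearly
    projected to the fusion width; modality vectors form the bag of a gated
    attention layer whose output is classified by a strictly linear layer.
    """

    kind = "multiomics"

    def __init__(self, laplacians_by_modality: dict[str, list[LaplacianMatrix]],
                 q: int = 30, fusion_dim: int = 16, fusion_attention_dim: int = 4,
                 gated: bool = True, epsilon: float = DEFAULT_EPSILON, init_seed: int = 0):
        if not laplacians_by_modality:
            raise ValueError("at least one modality is required")
        self.modalities = sorted(laplacians_by_modality)
        self.q = q
        self.fusion_dim = fusion_dim
        self.branches = {
            mod: _KernelNetBase(laplacians_by_modality[mod], q, epsilon)
            for mod in self.modalities
        }
        rng = np.random.default_rng(init_seed)
        # projections start as (padded) identity maps so the fusion attention
        # initially sees the raw pooled pathway activations of each modality
        self.projections = {}
        for mod in self.modalities:
            p_mod = self.branches[mod].n_pathways
            P = np.zeros((fusion_dim, p_mod))
            k = min(fusion_dim, p_mod)
            P[np.arange(k), np.arange(k)] = 1.0
            self.projections[mod] = P
        self.att = AttentionParams.random_init(fusion_attention_dim, fusion_dim, gated, rng)
        self.classifier = rng.standard_normal(fusion_dim) * 0.1

    @property
    def pathway_ids(self) -> list[str]:
        # modality-level ids: the fusion attention is over modalities
        return list(self.modalities)

    def init_anchors(self, datasets: dict[str, OmicsDataset], seed: int) -> None:
        for i, mod in enumerate(self.modalities):
            self.branches[mod].init_anchors(datasets[mod], seed + 1000 * i)

    def invalidate_caches(self) -> None:
        for br in self.branches.values():
            br.invalidate_caches()

    def parameters(self) -> dict[str, np.ndarray]:
        params = {}
        for mod in self.modalities:
            for k, layer in enumerate(self.branches[mod].layers):
                params[f"anchors/{mod}/{k}"] = layer.anchors
            params[f"proj/{mod}"] = self.projections[mod]
        params["att/w"] = self.att.w
        params["att/V"] = self.att.V
        if self.att.gated:
            params["att/U"] = self.att.U
        params["classifier"] = self.classifier
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for mod in self.modalities:
            for k, layer in enumerate(self.branches[mod].layers):
                layer.anchors = np.asarray(params[f"anchors/{mod}/{k}"], dtype=np.float64)
            self.projections[mod] = np.asarray(params[f"proj/{mod}"], dtype=np.float64)
        self.att.w = np.asarray(params["att/w"], dtype=np.float64)
        self.att.V = np.asarray(params["att/V"], dtype=np.float64)
        if self.att.gated:
            self.att.U = np.asarray(params["att/U"], dtype=np.float64)
        self.classifier = np.asarray(params["classifier"], dtype=np.float64)
        self.invalidate_caches()

    def forward_scores(self, datasets: dict[str, OmicsDataset], training: bool = False):
        n = next(iter(datasets.values())).n_samples
        mod_vecs, mod_caches = [], {}
        for mod in self.modalities:
            br = self.branches[mod]
            Psis, layer_caches = br.embeddings(datasets[mod], training=training)
            A = np.empty((n, br.n_pathways))
            idxs = []
            for r, Psi in enumerate(Psis):
                A[:, r], idx = _maxpool_batch(Psi)
                idxs.append(idx)
            mod_vecs.append(A @ self.projections[mod].T)       # (n, m_f)
            mod_caches[mod] = (Psis, layer_caches, A, idxs)
        Aw, pooled, att_cache = _attention_batch_forward(mod_vecs, self.att)
        scores = pooled @ self.classifier
        return scores, (mod_caches, att_cache, pooled, Aw)

    def backward(self, cache, dscores: np.ndarray) -> dict[str, np.ndarray]:
        mod_caches, att_cache, pooled, Aw = cache
        n, n_mod = Aw.shape
        dpooled = dscores[:, None] * self.classifier[None, :]
        dH, dw, dV, dU = _attention_batch_backward(
            att_cache, self.att, np.zeros((n, n_mod)), dpooled)
        grads = {"att/w": dw, "att/V": dV, "classifier": pooled.T @ dscores}
        if self.att.gated:
            grads["att/U"] = dU
        for i, mod in enumerate(self.modalities):
            Psis, layer_caches, A, idxs = mod_caches[mod]
            dvec = dH[:, i, :]                                  # (n, m_f)
            grads[f"proj/{mod}"] = dvec.T @ A
            dA = dvec @ self.projections[mod]                   # (n, p_mod)
            for r, layer in enumerate(self.branches[mod].layers):
                dPsi = _maxpool_backward(Psis[r].shape, idxs[r], dA[:, r])
                dZ, _ = layer.backward(layer_caches[r], dPsi)
                grads[f"anchors/{mod}/{r}"] = dZ
        return grads

    def predict(self, datasets: dict[str, OmicsDataset]) -> list[PredictionRecord]:
        scores, (_, _, _, Aw) = self.forward_scores(datasets, training=False)
        sample_ids = next(iter(datasets.values())).sample_ids
        return [
            PredictionRecord(score=float(scores[i]), per_pathway=Aw[i].copy(),
                             pathway_ids=list(self.modalities), sample_id=sample_ids[i])
            for i in range(len(sample_ids))
        ]

    def predict_scores(self, datasets: dict[str, OmicsDataset]) -> np.ndarray:
        return self.forward_scores(datasets, training=False)[0]


# ---------------------------------------------------------------------------
# checkpoint archive: one zip with a JSON config block and one .npy per tensor


def _model_config(model) -> dict:
    cfg = {"kind": model.kind, "q": model.q}
    if model.kind in ("pooling", "attention"):
        cfg["pathways"] = [
            {"pathway_id": layer.pathway_id, "node_names": layer.laplacian.node_names,
             "lap_kind": layer.laplacian.kind}
            for layer in model.layers
        ]
        cfg["epsilon"] = model.epsilon
        if model.kind == "attention":
            cfg["attention_dim"] = model.att.attention_dim
            cfg["gated"] = model.att.gated
        cfg["standardized"] = model.scaler is not None
    else:
        cfg["modalities"] = {
            mod: [
                {"pathway_id": layer.pathway_id, "node_names": layer.laplacian.node_names,
                 "lap_kind": layer.laplacian.kind}
                for layer in model.branches[mod].layers
            ]
            for mod in model.modalities
        }
        cfg["fusion_dim"] = model.fusion_dim
        cfg["fusion_attention_dim"] = model.att.attention_dim
        cfg["gated"] = model.att.gated
        cfg["standardized"] = {mod: model.branches[mod].scaler is not None
                               for mod in model.modalities}
    return cfg


def _iter_tensors(model):
    yield from model.parameters().items()
    if model.kind in ("pooling", "attention"):
        for k, layer in enumerate(model.layers):
            yield f"laplacian/{k}", layer.laplacian.matrix
        if model.scaler is not None:
            yield "scaler/mean", model.scaler.mean
            yield "scaler/scale", model.scaler.scale
    else:
        for mod in model.modalities:
            br = model.branches[mod]
            for k, layer in enumerate(br.layers):
                yield f"laplacian/{mod}/{k}", layer.laplacian.matrix
            if br.scaler is not None:
                yield f"scaler/{mod}/mean", br.scaler.mean
                yield f"scaler/{mod}/scale", br.scaler.scale


def save_checkpoint(model, path) -> None:
    """Write the model to a single zip archive: config.json + one .npy per tensor."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("config.json", json.dumps(_model_config(model), indent=1))
        for name, arr in _iter_tensors(model):
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr))
            zf.writestr(name.replace("/", "__") + ".npy", buf.getvalue())


def load_checkpoint(path):
    """Reconstruct a model (pooling, attention or multi-omics) from an archive."""
    with zipfile.ZipFile(path) as zf:
        cfg = json.loads(zf.read("config.json"))
        tensors = {}
        for info in zf.infolist():
            if info.filename.endswith(".npy"):
                key = info.filename[:-4].replace("__", "/")
                tensors[key] = np.load(io.BytesIO(zf.read(info.filename)))

    def lap(meta, key):
        return LaplacianMatrix(meta["pathway_id"], meta["node_names"],
                               tensors[key], meta["lap_kind"])

    kind = cfg["kind"]
    if kind in ("pooling", "attention"):
        laps = [lap(meta, f"laplacian/{k}") for k, meta in enumerate(cfg["pathways"])]
        if kind == "pooling":
            model = PoolingKernelNet(laps, q=cfg["q"], epsilon=cfg["epsilon"])
        else:
            model = AttentionKernelNet(laps, q=cfg["q"], epsilon=cfg["epsilon"],
                                       attention_dim=cfg["attention_dim"], gated=cfg["gated"])
        model.set_parameters({k: v for k, v in tensors.items()
                              if k in model.parameters()})
        if cfg["standardized"]:
            model.scaler = Standardizer(mean=tensors["scaler/mean"],
                                        scale=tensors["scaler/scale"])
    else:
        laps_by_mod = {
            mod: [lap(meta, f"laplacian/{mod}/{k}") for k, meta in enumerate(metas)]
            for mod, metas in cfg["modalities"].items()
        }
        model = MultiOmicsKernelNet(laps_by_mod, q=cfg["q"], fusion_dim=cfg["fusion_dim"],
                                    fusion_attention_dim=cfg["fusion_attention_dim"],
                                    gated=cfg["gated"])
        model.set_parameters({k: v for k, v in tensors.items()
                              if k in model.parameters()})
        for mod, used in cfg["standardized"].items():
            if used:
                model.branches[mod].scaler = Standardizer(
                    mean=tensors[f"scaler/{mod}/mean"], scale=tensors[f"scaler/{mod}/scale"])
    return model
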