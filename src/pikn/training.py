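"""End-to-end training, evaluation metrics and the cross-validation harness.

Training follows the study configuration these models were designed around:
Adam, 200 epochs, batch size 32, and a class-balanced binary cross-entropy
in which each class c is weighted by the inverse "effective number of
samples" (1 - beta^{n_c}) / (1 - beta).  Anchors are initialized with
k-means++ and then optimized jointly with every other parameter.

Everything is deterministic given the two seeds in TrainConfig: `seed`
drives batching and parameter initialization, `anchor_init_seed` the
k-means++ anchor draw.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .data import OmicsDataset, Standardizer
from .models import AttentionKernelNet, MultiOmicsKernelNet, PoolingKernelNet

__all__ = [
    "TrainConfig",
    "CVResult",
    "class_balanced_weights",
    "loss",
    "train",
    "cross_validate",
    "auroc",
    "runtime_scaling_experiment",
    "Adam",
]


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta: float = 0.999           # class-balance hyperparameter
    weight_decay: float = 1e-3    # L2 on all parameters; omics n is small vs parameter count
    seed: int = 0
    anchor_init_seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.beta < 1.0):
            raise ValueError("beta must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def class_balanced_weights(class_counts, beta: float) -> np.ndarray:
    """Per-class weights from the effective number of samples.

    weight_c is proportional to (1 - beta) / (1 - beta^{n_c}), normalized so
    the weights average to 1 over classes.  beta = 0 recovers the unweighted
    loss; beta -> 1 approaches inverse-frequency weighting.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("class counts must be >= 1")
    if not (0.0 <= beta < 1.0):
        raise ValueError("beta must lie in [0, 1)")
    if beta == 0.0:
        w = np.ones_like(counts)
    else:
        eff = (1.0 - np.power(beta, counts)) / (1.0 - beta)
        w = 1.0 / eff
    return w * (len(counts) / w.sum())


def loss(scores, labels, class_weights) -> float:
    """Weighted binary cross-entropy on logits, averaged over the batch."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be in {0, 1}")
    w = np.asarray(class_weights, dtype=np.float64)[labels.astype(int)]
    # log(1 + e^s) - y*s, computed stably
    per = np.logaddexp(0.0, scores) - labels * scores
    return float(np.mean(w * per))


def _loss_grad(scores, labels, class_weights) -> np.ndarray:
    w = np.asarray(class_weights, dtype=np.float64)[np.asarray(labels).astype(int)]
    return w * (expit(scores) - labels) / scores.shape[0]


class Adam:
    """Plain Adam on a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> dict:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _as_modalities(dataset) -> dict[str, OmicsDataset]:
    if isinstance(dataset, dict):
        return dataset
    return {dataset.modality: dataset}


def train(model, dataset, cfg: TrainConfig):
    """Train a model end to end; returns (model, per-epoch mean loss history).

    `dataset` is an OmicsDataset for single-omics models or a dict
    modality -> OmicsDataset (shared labels) for the multi-omics composite.
    epochs=0 leaves the model at its initialization (anchors included).
    """
    datasets = _as_modalities(dataset)
    labels = None
    for ds in datasets.values():
        if ds.labels is None:
            raise ValueError(f"modality {ds.modality!r} has no labels")
        if labels is None:
            labels = ds.labels
        elif not np.array_equal(labels, ds.labels):
            raise ValueError("modalities must share one label vector")
    n = len(labels)

    multi = isinstance(model, MultiOmicsKernelNet)
    if cfg.standardize:
        if multi:
            for mod in model.modalities:
                model.branches[mod].scaler = Standardizer().fit(datasets[mod].X)
        else:
            model.scaler = Standardizer().fit(next(iter(datasets.values())).X)

    if multi:
        model.init_anchors(datasets, cfg.anchor_init_seed)
    else:
        model.init_anchors(next(iter(datasets.values())), cfg.anchor_init_seed)

    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("training data must contain both classes")
    cls_w = class_balanced_weights(counts, cfg.beta)

    params = {k: v.copy() for k, v in model.parameters().items()}
    model.set_parameters(params)
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []

    def fwd(idx):
        if multi:
            batch = {mod: datasets[mod].subset(idx) for mod in model.modalities}
        else:
            batch = next(iter(datasets.values())).subset(idx)
        return batch, labels[idx]

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch, y = fwd(idx)
            scores, cache = model.forward_scores(batch, training=True)
            batch_loss = loss(scores, y, cls_w)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}; "
                    "consider a smaller learning rate or larger epsilon"
                )
            grads = model.backward(cache, _loss_grad(scores, y, cls_w))
            if cfg.weight_decay:
                for k in grads:
                    grads[k] = grads[k] + cfg.weight_decay * params[k]
            params = opt.step(params, grads)
            model.set_parameters(params)
            epoch_losses.append(batch_loss)
        history.append(float(np.mean(epoch_losses)))
    return model, history


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CVResult:
    """Repeated stratified k-fold cross-validation scores."""

    fold_scores: pd.DataFrame            # columns: repeat, fold, auroc
    config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def per_repeat_mean(self) -> np.ndarray:
        return self.fold_scores.groupby("repeat")["auroc"].mean().to_numpy()

    @property
    def mean_auroc(self) -> float:
        return float(self.per_repeat_mean.mean())

    def write_csv(self, path) -> None:
        self.fold_scores.to_csv(path, index=False)

    def summary(self) -> dict:
        pr = self.per_repeat_mean
        return {"mean_auroc": float(pr.mean()), "std_over_repeats": float(pr.std()),
                "per_repeat_mean": [float(v) for v in pr],
                "n_repeats": int(len(pr)),
                "n_folds": int(self.fold_scores["fold"].nunique())}


def cross_validate(model_factory, dataset, cfg: TrainConfig, folds: int = 10,
                   repeats: int = 10, eval_seed: int = 0) -> CVResult:
    """Repeated stratified k-fold CV; a fresh model per fold via `model_factory`.

    The factory takes no arguments and returns an untrained model matching
    the dataset.  Per-repeat mean validation auROC follows the usual
    repeated-CV reporting convention.
    """
    datasets = _as_modalities(dataset)
    labels = next(iter(datasets.values())).labels
    if labels is None:
        raise ValueError("cross-validation needs labels")
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=eval_seed + rep)
        for fold, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            if len(np.unique(labels[tr])) < 2:
                raise ValueError(f"repeat {rep} fold {fold}: training split lost a class")
            model = model_factory()
            fold_cfg = replace(cfg, seed=cfg.seed + 97 * rep + fold,
                               anchor_init_seed=cfg.anchor_init_seed + 97 * rep + fold)
            multi = isinstance(model, MultiOmicsKernelNet)
            tr_ds = ({m: d.subset(tr) for m, d in datasets.items()} if multi
                     else next(iter(datasets.values())).subset(tr))
            va_ds = ({m: d.subset(va) for m, d in datasets.items()} if multi
                     else next(iter(datasets.values())).subset(va))
            model, _ = train(model, tr_ds, fold_cfg)
            score = auroc(model.predict_scores(va_ds), labels[va])
            rows.append({"repeat": rep, "fold": fold, "auroc": score})
    return CVResult(fold_scores=pd.DataFrame(rows), config=cfg)


def runtime_scaling_experiment(sizes, cfg: TrainConfig,
                               batch_policy: str = "fixed-32",
                               repetitions: int = 5,
                               model_types=("pooling", "attention"),
                               n_pathways: int = 10,
                               pathway_size_range=(10, 30),
                               q: int = 30,
                               seed: int = 0) -> pd.DataFrame:
    """Mean wall-clock training time versus sample size on simulated data.

    Emulates the scaling-study design: several dataset sizes, both model
    families, and either a fixed batch of 32 or an adaptive batch of 1% of
    the sample count.  Absolute times are hardware-dependent; the useful
    outputs are the per-epoch times and their ratios across sizes.
    """
    from .pathways import pathway_laplacian
    from .simulate import SimulationConfig, simulate_expression, simulate_pathways

    if batch_policy not in ("fixed-32", "one-percent"):
        raise ValueError(f"unknown batch_policy {batch_policy!r}")
    pathways = simulate_pathways(n_pathways, pathway_size_range, seed=seed)
    laps = [pathway_laplacian(pw) for pw in pathways]
    rows = []
    for n in sizes:
        sim = SimulationConfig(n_samples=int(n), n_pathways=n_pathways,
                               pathway_size_range=pathway_size_range,
                               informative_set=(0, 1), seed=seed + int(n))
        ds = simulate_expression(sim, pathways).modalities["expression"]
        bs = 32 if batch_policy == "fixed-32" else max(1, int(round(0.01 * n)))
        run_cfg = replace(cfg, batch_size=bs)
        for model_type in model_types:
            times = []
            for rep in range(repetitions):
                if model_type == "pooling":
                    model = PoolingKernelNet(laps, q=q, init_seed=rep)
                else:
                    model = AttentionKernelNet(laps, q=q, init_seed=rep)
                t0 = time.perf_counter()
                train(model, ds, replace(run_cfg, seed=rep, anchor_init_seed=rep))
                times.append(time.perf_counter() - t0)
            rows.append({
                "model_type": model_type, "n_samples": int(n),
                "batch_policy": batch_policy, "batch_size": bs,
                "epochs": cfg.epochs,
                "mean_train_time_s": float(np.mean(times)),
                "mean_epoch_time_s": float(np.mean(times) / max(cfg.epochs, 1)),
                "repetitions": repetitions,
            })
    return pd.DataFrame(rows)
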