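"""Global pathway-weight signatures and local per-sample attention maps.

Pooling models carry one signed weight per pathway: the global signature.
A positive weight ties high pathway activation to the positive class, a
negative one to the negative class, and |w_r| ranks pathway importance.
Attention models instead yield a per-sample distribution over pathways (the
attention weights), answering why one particular sample was scored the way
it was.  Both are exported as plain CSV/JSON; a small matplotlib helper
renders attention maps as one-row heat strips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import OmicsDataset
from .models import AttentionKernelNet, PoolingKernelNet, PredictionRecord

__all__ = [
    "PathwaySignature",
    "AttentionMap",
    "global_signature",
    "local_attention",
    "signature_stability",
    "export_interpretation",
    "import_interpretation",
    "plot_attention_maps",
]


@dataclass
class PathwaySignature:
    """Signed per-pathway weights of a trained pooling model."""

    pathway_ids: list[str]
    weights: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if len(self.pathway_ids) != self.weights.shape[0]:
            raise ValueError("one weight per pathway required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("signature weights must be finite")

    def ranking(self) -> list[str]:
        """Pathway ids sorted by decreasing |weight|."""
        order = np.argsort(-np.abs(self.weights))
        return [self.pathway_ids[i] for i in order]


@dataclass
class AttentionMap:
    """Per-sample attention distribution over pathways."""

    sample_id: str
    pathway_ids: list[str]
    attention: np.ndarray
    score: float = 0.0
    predicted_label: Optional[int] = None
    true_label: Optional[int] = None

    def __post_init__(self) -> None:
        self.attention = np.asarray(self.attention, dtype=np.float64).ravel()
        if len(self.pathway_ids) != self.attention.shape[0]:
            raise ValueError("one attention weight per pathway required")
        if np.any(self.attention < -1e-12) or abs(self.attention.sum() - 1.0) > 1e-6:
            raise ValueError("attention must be nonnegative and sum to 1")


def global_signature(model, model_id: str = "") -> PathwaySignature:
    """Read the pooling head's signed pathway weights (a pure read)."""
    if not isinstance(model, PoolingKernelNet):
        raise TypeError(
            "global signatures exist only for pooling models; "
            "use local_attention for attention models"
        )
    return PathwaySignature(pathway_ids=list(model.pathway_ids),
                            weights=model.head.weights.copy(), model_id=model_id)


def local_attention(model, dataset: OmicsDataset) -> list[AttentionMap]:
    """Forward the samples and capture per-pathway attention plus predictions."""
    if not isinstance(model, AttentionKernelNet):
        raise TypeError(
            "attention maps exist only for attention models; "
            "use global_signature for pooling models"
        )
    records: list[PredictionRecord] = model.predict(dataset)
    maps = []
    for i, rec in enumerate(records):
        maps.append(AttentionMap(
            sample_id=rec.sample_id,
            pathway_ids=list(rec.pathway_ids),
            attention=rec.per_pathway,
            score=rec.score,
            predicted_label=int(rec.score > 0),
            true_label=None if dataset.labels is None else int(dataset.labels[i]),
        ))
    return maps


def signature_stability(signatures: list[PathwaySignature]) -> dict:
    """Pairwise Spearman correlations and per-pathway weight spread.

    This is the tabular content behind a stability boxplot: how similar the
    learned pathway signatures are across datasets or seeds, and how widely
    each pathway's weight varies.
    """
    if len(signatures) < 2:
        raise ValueError("stability needs at least two signatures")
    ids = signatures[0].pathway_ids
    for sig in signatures[1:]:
        if sig.pathway_ids != ids:
            raise ValueError("signatures must cover identical pathway sets in one order")
    W = np.vstack([sig.weights for sig in signatures])        # (n_sig, p)
    n_sig = W.shape[0]
    corr = np.ones((n_sig, n_sig))
    for i in range(n_sig):
        for j in range(i + 1, n_sig):
            corr[i, j] = corr[j, i] = float(spearmanr(W[i], W[j]).statistic)
    pairs = corr[np.triu_indices(n_sig, k=1)]
    spread = pd.DataFrame({
        "pathway_id": ids,
        "min": W.min(axis=0), "median": np.median(W, axis=0), "max": W.max(axis=0),
    })
    return {"pairwise_spearman": corr, "median_pairwise_spearman": float(np.median(pairs)),
            "per_pathway_spread": spread}


# ---------------------------------------------------------------------------
# export / import (schemas documented in the README)


def _signature_frame(sig: PathwaySignature) -> pd.DataFrame:
    return pd.DataFrame({"pathway_id": sig.pathway_ids, "weight": sig.weights})


def _maps_frame(maps: list[AttentionMap]) -> pd.DataFrame:
    rows = []
    for m in maps:
        for pid, a in zip(m.pathway_ids, m.attention):
            rows.append({"sample_id": m.sample_id, "pathway_id": pid, "attention": a,
                         "score": m.score, "predicted_label": m.predicted_label,
                         "true_label": m.true_label})
    return pd.DataFrame(rows)


def export_interpretation(obj, path, format: str = "csv") -> None:
    """Write a signature or list of attention maps losslessly to CSV or JSON."""
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}")
    if isinstance(obj, PathwaySignature):
        if format == "csv":
            _signature_frame(obj).to_csv(path, index=False, float_format="%.17g")
        else:
            payload = {"type": "pathway_signature", "model_id": obj.model_id,
                       "pathway_ids": obj.pathway_ids,
                       "weights": [float(w) for w in obj.weights]}
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
    elif isinstance(obj, list) and all(isinstance(m, AttentionMap) for m in obj):
        if format == "csv":
            _maps_frame(obj).to_csv(path, index=False, float_format="%.17g")
        else:
            payload = {"type": "attention_maps", "maps": [
                {"sample_id": m.sample_id, "pathway_ids": m.pathway_ids,
                 "attention": [float(a) for a in m.attention], "score": m.score,
                 "predicted_label": m.predicted_label, "true_label": m.true_label}
                for m in obj]}
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
    else:
        raise TypeError("expected a PathwaySignature or a list of AttentionMap")


def import_interpretation(path, format: str = "csv"):
    """Inverse of export_interpretation (used by the round-trip tests)."""
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        if payload["type"] == "pathway_signature":
            return PathwaySignature(payload["pathway_ids"], np.array(payload["weights"]),
                                    payload.get("model_id", ""))
        return [AttentionMap(m["sample_id"], m["pathway_ids"], np.array(m["attention"]),
                             m.get("score", 0.0), m.get("predicted_label"),
                             m.get("true_label"))
                for m in payload["maps"]]
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    if set(df.columns) == {"pathway_id", "weight"}:
        return PathwaySignature(df["pathway_id"].tolist(), df["weight"].to_numpy())
    maps = []
    for sid, grp in df.groupby("sample_id", sort=False):
        first = grp.iloc[0]
        maps.append(AttentionMap(
            str(sid), grp["pathway_id"].tolist(), grp["attention"].to_numpy(),
            float(first["score"]),
            None if pd.isna(first["predicted_label"]) else int(first["predicted_label"]),
            None if pd.isna(first["true_label"]) else int(first["true_label"])))
    return maps


def plot_attention_maps(maps: list[AttentionMap], path) -> None:
    """Render attention maps as one heat strip per sample (optional helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = np.vstack([m.attention for m in maps])
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * M.shape[1]), 0.6 * len(maps) + 1.2))
    im = ax.imshow(M, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(maps)), [m.sample_id for m in maps])
    ax.set_xticks(range(M.shape[1]), maps[0].pathway_ids, rotation=90, fontsize=6)
    ax.set_xlabel("pathway")
    fig.colorbar(im, ax=ax, label="attention")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
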