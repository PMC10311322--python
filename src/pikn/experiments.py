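"""Canned simulation studies: recovery, null control, multi-omics, scaling.

These functions reproduce the package's headline property checks end to end
from a single seed: they generate data with the synthetic generator's
default study conditions, train models with the default training
configuration, and measure recovery/performance quantities.  Both the test
suite and the reproduction script call them, so the numbers reported in
either place come from the same code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .interpret import global_signature, local_attention
from .models import AttentionKernelNet, MultiOmicsKernelNet, PoolingKernelNet
from .pathways import pathway_laplacian
from .simulate import SimulationConfig, simulate_expression, simulate_multiomics, simulate_pathways
from .training import TrainConfig, auroc, cross_validate, runtime_scaling_experiment, train

__all__ = [
    "recovery_study",
    "null_control_study",
    "multiomics_study",
    "scaling_study",
]

#: study conditions of the parameter-recovery experiment
RECOVERY_CONDITIONS = dict(n_samples=500, n_pathways=10, n_informative=2,
                           effect_size=1.5, q=30, attention_dim=128)


def _holdout_split(n: int, seed: int, holdout_fraction: float = 0.2):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_test = int(round(holdout_fraction * n))
    return idx[n_test:], idx[:n_test]


def recovery_study(seed: int = 0, n_runs: int = 10, epochs: int = 200) -> dict:
    """Informative-pathway recovery under the default study conditions.

    For each of ``n_runs`` seeded replicates: draw a fresh dataset with
    p=10 pathways of which k=2 are informative (class mean shift 1.5 noise
    sd, n=500), train a pooling and an attention model on 80% of the
    samples, and measure (i) whether the two largest |w_r| of the pooling
    head sit on the informative pathways, (ii) held-out auROC of both
    models, and (iii) the fraction of correctly classified positive held-out
    samples whose largest attention weight sits on an informative pathway.
    """
    c = RECOVERY_CONDITIONS
    top2_hits = 0
    pool_aucs, att_aucs = [], []
    loc_ok = loc_tot = 0
    for run in range(n_runs):
        run_seed = seed + 101 * run
        sim = SimulationConfig(n_samples=c["n_samples"], n_pathways=c["n_pathways"],
                               informative_set=tuple(range(c["n_informative"])),
                               effect_size=c["effect_size"], seed=run_seed)
        pathways = simulate_pathways(c["n_pathways"], sim.pathway_size_range,
                                     topology=sim.topology, seed=run_seed)
        data = simulate_expression(sim, pathways)
        ds = data.modalities["expression"]
        laps = [pathway_laplacian(pw) for pw in pathways]
        tr, te = _holdout_split(ds.n_samples, run_seed)
        tr_ds, te_ds = ds.subset(tr), ds.subset(te)
        cfg = TrainConfig(epochs=epochs, seed=run_seed, anchor_init_seed=run_seed)
        informative = set(data.informative_ids)

        pool = PoolingKernelNet(laps, q=c["q"], init_seed=run_seed)
        pool, _ = train(pool, tr_ds, cfg)
        pool_aucs.append(auroc(pool.predict_scores(te_ds), ds.labels[te]))
        top2_hits += set(global_signature(pool).ranking()[:c["n_informative"]]) == informative

        att = AttentionKernelNet(laps, q=c["q"], attention_dim=c["attention_dim"],
                                 init_seed=run_seed)
        att, _ = train(att, tr_ds, cfg)
        att_aucs.append(auroc(att.predict_scores(te_ds), ds.labels[te]))
        for amap in local_attention(att, te_ds):
            if amap.true_label == 1 and amap.predicted_label == 1:
                loc_tot += 1
                loc_ok += amap.pathway_ids[int(np.argmax(amap.attention))] in informative
    return {
        "n_runs": n_runs,
        "pooling_top2_recovery_rate": top2_hits / n_runs,
        "pooling_heldout_auroc": float(np.mean(pool_aucs)),
        "pooling_heldout_aurocs": pool_aucs,
        "attention_heldout_auroc": float(np.mean(att_aucs)),
        "attention_heldout_aurocs": att_aucs,
        "attention_localization_rate": (loc_ok / loc_tot) if loc_tot else float("nan"),
        "attention_localization_counts": (loc_ok, loc_tot),
    }


def null_control_study(seed: int = 0, n_samples: int = 200, folds: int = 10,
                       epochs: int = 200) -> dict:
    """Label-permutation null: 10-fold CV auROC should hover around chance."""
    sim = SimulationConfig(n_samples=n_samples, seed=seed)
    pathways = simulate_pathways(sim.n_pathways, sim.pathway_size_range,
                                 topology=sim.topology, seed=seed)
    data = simulate_expression(sim, pathways)
    ds = data.modalities["expression"]
    rng = np.random.default_rng(seed + 1)
    ds.labels = rng.permutation(ds.labels)          # break any label-feature link
    laps = [pathway_laplacian(pw) for pw in pathways]

    def factory():
        return PoolingKernelNet(laps, q=30, init_seed=seed)

    cfg = TrainConfig(epochs=epochs, seed=seed, anchor_init_seed=seed)
    result = cross_validate(factory, ds, cfg, folds=folds, repeats=1, eval_seed=seed)
    return {"null_cv_mean_auroc": result.mean_auroc,
            "fold_aurocs": result.fold_scores["auroc"].tolist()}


def multiomics_study(seed: int = 0, n_seeds: int = 5, n_samples: int = 1980,
                     epochs: int = 200) -> dict:
    """Dense + 90%-sparse two-modality integration versus the dense model alone.

    The default sample size matches the scale of the multi-omics breast
    cancer cohort this study stands in for (1980 patients).  Also exercises
    the degenerate single-modality composite, whose softmax over one
    instance must give attention weight exactly 1.
    """
    dense_aucs, combined_aucs = [], []
    for run in range(n_seeds):
        run_seed = seed + 211 * run
        sim = SimulationConfig(n_samples=n_samples, seed=run_seed)
        data = simulate_multiomics(sim)
        laps = {mod: [pathway_laplacian(pw) for pw in data.pathways]
                for mod in data.modalities}
        expr = data.modalities["expression"]
        tr, te = _holdout_split(n_samples, run_seed)
        cfg = TrainConfig(epochs=epochs, seed=run_seed, anchor_init_seed=run_seed)

        dense = PoolingKernelNet(laps["expression"], q=30, init_seed=run_seed)
        dense, _ = train(dense, expr.subset(tr), cfg)
        dense_aucs.append(auroc(dense.predict_scores(expr.subset(te)), expr.labels[te]))

        combo = MultiOmicsKernelNet(laps, q=30, init_seed=run_seed)
        tr_map = {m: d.subset(tr) for m, d in data.modalities.items()}
        te_map = {m: d.subset(te) for m, d in data.modalities.items()}
        combo, _ = train(combo, tr_map, cfg)
        combined_aucs.append(auroc(combo.predict_scores(te_map), expr.labels[te]))

    # degenerate single-modality composite: attention over a singleton bag
    sim = SimulationConfig(n_samples=60, seed=seed)
    data = simulate_multiomics(sim)
    laps1 = {"expression": [pathway_laplacian(pw) for pw in data.pathways]}
    single = MultiOmicsKernelNet(laps1, q=5, init_seed=seed)
    expr = data.modalities["expression"]
    single, _ = train(single, {"expression": expr},
                      replace(TrainConfig(seed=seed, anchor_init_seed=seed), epochs=2))
    att_weights = np.array([rec.per_pathway[0] for rec in
                            single.predict({"expression": expr})])
    return {
        "dense_only_heldout_auroc": float(np.mean(dense_aucs)),
        "multiomics_heldout_auroc": float(np.mean(combined_aucs)),
        "dense_only_aurocs": dense_aucs,
        "multiomics_aurocs": combined_aucs,
        "single_modality_attention_weight": float(att_weights.min()),
        "n_seeds": n_seeds,
    }


def scaling_study(seed: int = 0, sizes=(100, 1000, 5000), epochs: int = 3,
                  repetitions: int = 3) -> dict:
    """Per-epoch training time versus n under a fixed batch of 32.

    Absolute times are hardware-dependent; the reported quantities are the
    per-epoch times, whether they are non-decreasing in n, and the
    largest/middle size ratio (a linearity check: step count scales with n).
    """
    cfg = TrainConfig(epochs=epochs, seed=seed, anchor_init_seed=seed)
    table = runtime_scaling_experiment(list(sizes), cfg, batch_policy="fixed-32",
                                       repetitions=repetitions, seed=seed)
    out = {"table": table}
    for model_type in table["model_type"].unique():
        sub = table[table["model_type"] == model_type].sort_values("n_samples")
        times = sub["mean_epoch_time_s"].to_numpy()
        out[f"{model_type}_epoch_times_s"] = times.tolist()
        out[f"{model_type}_monotone"] = bool(np.all(np.diff(times) >= 0))
        t_by_n = dict(zip(sub["n_samples"], times))
        out[f"{model_type}_epoch_time_ratio_{sizes[-1]}_vs_{sizes[-2]}"] = (
            float(t_by_n[sizes[-1]] / t_by_n[sizes[-2]]))
    return out
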