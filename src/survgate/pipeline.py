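"""End-to-end orchestration: simulate / fit / evaluate / crossval / cluster.

Each ``run_*`` function is the library-level body of one CLI subcommand: it
takes plain Python arguments, writes its artifacts as JSON/TSV under an
output directory and returns the report dictionary it wrote.  All file
writes are atomic (temp file + rename) and all randomness is derived from
the single ``seed`` argument, so identical inputs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from . import cluster as cl
from . import evaluate as ev
from . import network as net
from .features import FeatureSet, chi2_scores, select_features
from .io import ClinicalTable, ExpressionMatrix, align_cohort, normalize_expression
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("survgate")

TRAIN_FRACTION = 0.7  # 70/30 train/test split of the fitting cohort


def _atomic_write(path, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_json(path, obj) -> None:
    _atomic_write(path, json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_expression_tsv(path, expr: ExpressionMatrix) -> None:
    _atomic_write(path, expr.to_frame().to_csv(sep="\t", lineterminator="\n"))


def write_clinical_tsv(path, clin: ClinicalTable) -> None:
    _atomic_write(
        path, clin.data.reset_index().to_csv(sep="\t", index=False, lineterminator="\n")
    )


def stratified_split(labels: np.ndarray, train_fraction: float, seed: int):
    """Per-class random split so both classes appear on both sides."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train_idx = []
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        perm = rng.permutation(idx)
        n_tr = max(1, int(round(train_fraction * len(idx))))
        train_idx.append(perm[:n_tr])
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(len(labels)), train)
    return train, test


def run_simulate(out_dir, config: SimulationConfig) -> dict:
    """Write expression.tsv, clinical.tsv and truth.json for one cohort."""
    cohort = simulate_cohort(config)
    write_expression_tsv(os.path.join(out_dir, "expression.tsv"), cohort.expr)
    write_clinical_tsv(os.path.join(out_dir, "clinical.tsv"), cohort.clin)
    _write_json(os.path.join(out_dir, "truth.json"), _jsonable(cohort.truth))
    summary = {
        "n_samples": cohort.expr.n_samples,
        "n_genes": cohort.expr.n_genes,
        "n_events": int(cohort.clin.os_event.sum()),
        "n_adverse": int((cohort.truth["subgroup"] == 2).sum()),
        "config": asdict(config),
    }
    _write_json(os.path.join(out_dir, "simulate_summary.json"), _jsonable(summary))
    return summary


def select_and_group(expr_norm: ExpressionMatrix, labels: np.ndarray,
                     fdr_threshold: float = 0.05, seed: int = 0) -> FeatureSet:
    """Chi-square screen at the FDR threshold, then 2-group k-means of the genes."""
    scores = chi2_scores(expr_norm, labels)
    selected = select_features(scores, fdr_threshold)
    if len(selected) < 2:
        raise ValueError(
            f"only {len(selected)} gene(s) passed FDR<{fdr_threshold}; "
            "raise the threshold or check the cohort"
        )
    sub = expr_norm.subset_genes([s.gene_id for s in selected])
    return cl.cluster_features(sub, selected, seed=seed)


def _metrics_block(y_true, probs, times, events, horizons, threshold) -> dict:
    preds = net.classify(probs, threshold)
    counts = ev.ConfusionCounts.from_predictions(y_true, preds)
    block = {
        "confusion": {"TP": counts.TP, "FP": counts.FP, "TN": counts.TN, "FN": counts.FN},
        **ev.confusion_metrics(counts),
        "auc": net._safe_auc(y_true, probs),
    }
    if times is not None:
        for h in horizons:
            try:
                block[f"troc_auc_{int(h)}"] = ev.time_dependent_roc(probs, times, events, h).auc
            except ValueError as exc:
                logger.warning("tROC at %s skipped: %s", h, exc)
                block[f"troc_auc_{int(h)}"] = float("nan")
    return block


def run_fit(out_dir, expr: ExpressionMatrix, clin: ClinicalTable,
            fdr_threshold: float = 0.05, net_config: net.NetworkConfig | None = None,
            horizons=ev.DEFAULT_HORIZONS, seed: int = 0,
            features: FeatureSet | None = None) -> dict:
    """Normalize, screen, group, train on a 70% split, report on both splits.

    A precomputed ``features`` set (e.g. from another cohort or an external
    screen) skips the chi-square stage.
    """
    expr, clin = align_cohort(expr, clin)
    expr_n = normalize_expression(expr)
    labels = clin.os_event

    ss = np.random.SeedSequence(seed)
    group_seed, split_seed, train_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    )
    if features is None:
        features = select_and_group(expr_n, labels, fdr_threshold, seed=group_seed)
    tr, te = stratified_split(labels, TRAIN_FRACTION, split_seed)
    expr_tr = expr_n.subset_samples([expr_n.sample_ids[i] for i in tr])
    expr_te = expr_n.subset_samples([expr_n.sample_ids[i] for i in te])

    cfg = net_config or net.NetworkConfig(d1=1, d2=1)
    cfg = replace(cfg, seed=train_seed)
    params, hist = net.train(expr_tr, features, labels[tr], cfg)

    report = {"seed": seed, "fdr_threshold": fdr_threshold,
              "n_selected": len(features.scores),
              "group_sizes": {g: len(features.genes_in_group(g)) for g in (1, 2)},
              "n_train": len(tr), "n_test": len(te)}
    for name, idx, sub in (("train", tr, expr_tr), ("test", te, expr_te)):
        probs = net.predict_proba(params, sub, features)
        report[name] = _metrics_block(
            labels[idx], probs, clin.os_time[idx], clin.os_event[idx],
            horizons, cfg.threshold)

    net.save_params(os.path.join(out_dir, "model.json"),
                    params, replace(cfg, d1=len(features.genes_in_group(1)),
                                    d2=len(features.genes_in_group(2))),
                    feature_set=features)
    _write_json(os.path.join(out_dir, "features.json"), _jsonable(features.to_dict()))
    _write_json(os.path.join(out_dir, "history.json"), _jsonable(asdict(hist)))
    _write_json(os.path.join(out_dir, "fit_report.json"), _jsonable(report))
    return report


def run_evaluate(out_dir, model_path, expr: ExpressionMatrix, clin: ClinicalTable,
                 horizons=ev.DEFAULT_HORIZONS, seed: int = 0) -> dict:
    """Apply a saved model to a cohort: classification, survival and Cox reports."""
    params, cfg, feat_doc = net.load_params(model_path)
    if feat_doc is None:
        raise ValueError(f"model file {model_path} carries no feature set")
    features = FeatureSet.from_dict(feat_doc)
    missing = [g for g in features.gene_ids if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"cohort lacks {len(missing)} model genes, e.g. {missing[:5]}")
    expr, clin = align_cohort(expr, clin)
    expr_n = normalize_expression(expr)
    probs = net.predict_proba(params, expr_n, features)
    labels = clin.os_event

    report = {"n_samples": expr_n.n_samples,
              "metrics": _metrics_block(labels, probs, clin.os_time, clin.os_event,
                                        horizons, cfg.threshold)}

    # patient subgrouping on the model's genes + survival contrast
    sub = expr_n.subset_genes(features.gene_ids)
    groups = cl.cluster_patients(sub, clin, k=2, seed=seed)
    lr = ev.logrank_test(clin.os_time, clin.os_event, groups.labels)
    report["subgroups"] = {
        "sizes": {int(g): int((groups.labels == g).sum()) for g in (1, 2)},
        "logrank": lr,
    }

    # Cox: binarized clinical covariates + the binarized probability risk
    cov = clin.covariates.copy()
    cov["prob_risk"] = net.classify(probs, cfg.threshold)
    cov = cov.loc[:, [c for c in cov.columns if cov[c].nunique() > 1]]
    try:
        cox = ev.cox_screen(clin.os_time, clin.os_event, cov.astype(float))
        report["cox"] = {
            "univariable": {k: _jsonable({
                "beta": v.beta[0], "HR": v.hazard_ratios[0], "p": v.p_values[0]})
                for k, v in cox["univariable"].items()},
            "selected": cox["selected"],
            "multivariable": (None if cox["multivariable"] is None else
                              _jsonable(cox["multivariable"].summary().to_dict())),
        }
    except (ValueError, RuntimeError) as exc:
        logger.warning("Cox analysis skipped: %s", exc)
        report["cox"] = None

    _write_json(os.path.join(out_dir, "evaluate_report.json"), _jsonable(report))
    return report


def run_crossval(out_dir, expr: ExpressionMatrix, clin: ClinicalTable,
                 fdr_threshold: float = 0.05, net_config: net.NetworkConfig | None = None,
                 folds: int = 10, repeats: int = 20,
                 horizons=ev.DEFAULT_HORIZONS, seed: int = 0,
                 features: FeatureSet | None = None) -> dict:
    """Repeated stratified k-fold CV; writes per-fold CSV and mean +- sd JSON."""
    expr, clin = align_cohort(expr, clin)
    expr_n = normalize_expression(expr)
    labels = clin.os_event
    ss = np.random.SeedSequence(seed)
    group_seed, cv_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    if features is None:
        features = select_and_group(expr_n, labels, fdr_threshold, seed=group_seed)
    cfg = net_config or net.NetworkConfig(d1=1, d2=1)
    res = ev.cross_validate(expr_n, features, labels, cfg,
                            times=clin.os_time, events=clin.os_event,
                            folds=folds, repeats=repeats,
                            horizons=horizons, seed=cv_seed)
    _atomic_write(os.path.join(out_dir, "crossval_folds.csv"),
                  res.folds.to_csv(index=False, lineterminator="\n"))
    summary = {
        col: {"mean": float(res.folds[col].mean()), "sd": float(res.folds[col].std())}
        for col in res.folds.columns if col not in ("repeat", "fold")
    }
    report = {"seed": seed, "folds": folds, "repeats": repeats,
              "n_selected": len(features.scores), "summary": summary,
              "best_test_auc": res.best_auc}
    _write_json(os.path.join(out_dir, "crossval_report.json"), _jsonable(report))
    return report


def run_cluster(out_dir, expr: ExpressionMatrix, clin: ClinicalTable,
                fdr_threshold: float = 0.05, k_range=(2, 3, 4, 5),
                reps: int = 1000, seed: int = 0) -> dict:
    """Consensus-cluster patients on the selected genes; survival contrast at best k=2."""
    expr, clin = align_cohort(expr, clin)
    expr_n = normalize_expression(expr)
    features = select_and_group(expr_n, clin.os_event, fdr_threshold, seed=seed)
    sub = expr_n.subset_genes(features.gene_ids)
    cons = cl.consensus_cluster(sub.values.T, k_range=k_range, reps=reps, seed=seed)
    groups = cl.cluster_patients(sub, clin, k=2, seed=seed)
    lr = ev.logrank_test(clin.os_time, clin.os_event, groups.labels)
    report = {
        "best_k": cons.best_k,
        "delta_area": {int(k): v for k, v in cons.delta_area.items()},
        "subgroup_sizes": {int(g): int((groups.labels == g).sum()) for g in (1, 2)},
        "logrank": lr,
        "labels": {s: int(l) for s, l in zip(sub.sample_ids, groups.labels)},
    }
    _write_json(os.path.join(out_dir, "cluster_report.json"), _jsonable(report))
    return report
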