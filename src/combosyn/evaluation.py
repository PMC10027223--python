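"""Cross-validation protocols and regression / classification metrics.

Four split strategies probe different generalization questions:

* ``stratified_kfold`` — random k-fold, stratified so each fold holds a
  near-equal share of every (cell line x class) stratum: interpolation
  within the measured drug-pair space.
* ``leave_one_drug_out`` — every record containing the held-out drug is
  test: generalization to unseen drugs.
* ``leave_one_cell_line_out`` — all records of one cell line are test:
  generalization to unseen cellular contexts.
* ``leave_drug_pairs_out`` — unordered drug pairs are split into k groups;
  a fold's pairs are held out across all cell lines: generalization to
  unseen combinations.

Regression is scored with MSE (plus a t-interval over fold MSEs), RMSE and
Pearson correlation; classification (synergistic vs rest) with AUC, AUPR,
accuracy, F1 and Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (accuracy_score, average_precision_score,
                             cohen_kappa_score, f1_score, roc_auc_score)

from .data import FingerprintMatrix, Label, SynergyDataset
from .embedding import MultiChannelGraphAutoencoder
from .predictor import FeatureAssembler, SynergyPredictor

__all__ = ["SplitPlan", "stratified_kfold", "leave_out_split",
           "regression_metrics", "classification_metrics",
           "run_cross_validation"]


@dataclass
class SplitPlan:
    strategy: str
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train indices, test indices)
    seed: int
    fold_names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.folds)


def stratified_kfold(dataset: SynergyDataset, k: int = 10,
                     seed: int = 0) -> SplitPlan:
    """k-fold CV stratified by (cell line, class).

    Within every cell line, each of the three classes is shuffled and dealt
    round-robin into k subsets, so per-stratum test counts across folds
    differ by at most one. Strata smaller than k trigger a warning but are
    still dealt round-robin.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(dataset.records)
    assignment = np.empty(n, dtype=int)
    for cell in dataset.cell_lines:
        for label in Label:
            stratum = [i for i in dataset.records_in(cell)
                       if dataset.records[i].label == label]
            if not stratum:
                continue
            if len(stratum) < k:
                warnings.warn(
                    f"stratum ({cell}, {label.name}) has {len(stratum)} < k={k} "
                    "records; assigning round-robin")
            order = rng.permutation(len(stratum))
            for pos, rec in enumerate(np.asarray(stratum)[order]):
                assignment[rec] = pos % k
    folds = []
    all_idx = np.arange(n)
    for f in range(k):
        test = all_idx[assignment == f]
        folds.append((all_idx[assignment != f], test))
    return SplitPlan("stratified_kfold", folds, seed,
                     [f"fold{f}" for f in range(k)])


def leave_out_split(dataset: SynergyDataset, mode: str, k_pairs: int = 10,
                    seed: int = 0) -> SplitPlan:
    """Entity-exclusion splits: one fold per held-out drug / cell line / pair group."""
    if not dataset.records:
        raise ValueError("empty dataset")
    all_idx = np.arange(len(dataset.records))
    folds, names = [], []
    if mode == "drug":
        for drug in dataset.drugs:
            test = np.array([i for i in all_idx
                             if drug in (dataset.records[i].drug_a,
                                         dataset.records[i].drug_b)])
            folds.append((np.setdiff1d(all_idx, test), test))
            names.append(drug)
    elif mode == "cell_line":
        for cell in dataset.cell_lines:
            test = np.array(dataset.records_in(cell))
            folds.append((np.setdiff1d(all_idx, test), test))
            names.append(cell)
    elif mode == "drug_pairs":
        pairs = sorted({dataset.records[i].pair() for i in all_idx})
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(pairs))
        group = {pairs[j]: pos % k_pairs for pos, j in enumerate(order)}
        for f in range(k_pairs):
            test = np.array([i for i in all_idx
                             if group[dataset.records[i].pair()] == f])
            folds.append((np.setdiff1d(all_idx, test), test))
            names.append(f"pairs{f}")
    else:
        raise ValueError(f"unknown leave-out mode {mode!r}")
    strategy = {"drug": "leave_one_drug_out", "cell_line": "leave_one_cell_line_out",
                "drug_pairs": "leave_drug_pairs_out"}[mode]
    return SplitPlan(strategy, folds, seed, names)


def regression_metrics(y_true, y_pred, fold_mses=None,
                       ci_method: str = "t") -> dict:
    """MSE, RMSE and Pearson r; optional 95% CI over supplied fold MSEs."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    mse = float(np.mean((y_true - y_pred) ** 2))
    out = {"mse": mse, "rmse": float(np.sqrt(mse))}
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        warnings.warn("zero variance: Pearson correlation undefined")
        out["pcc"] = float("nan")
    else:
        out["pcc"] = float(stats.pearsonr(y_true, y_pred)[0])
    if fold_mses is not None:
        fm = np.asarray(fold_mses, dtype=float)
        k = fm.size
        half = fm.std(ddof=1) / np.sqrt(k)
        crit = (stats.t.ppf(0.975, k - 1) if ci_method == "t"
                else stats.norm.ppf(0.975))
        out["mse_ci95"] = (float(fm.mean() - crit * half),
                           float(fm.mean() + crit * half))
    return out


def classification_metrics(y_true, scores, threshold: float = 0.5) -> dict:
    """AUC/AUPR from score ranking; ACC, F1, Cohen's kappa at the threshold."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    labels = (scores >= threshold).astype(int)
    out = {"acc": float(accuracy_score(y_true, labels)),
           "f1": float(f1_score(y_true, labels, zero_division=0)),
           "kappa": float(cohen_kappa_score(y_true, labels))}
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class truth: AUC/AUPR undefined")
        out["auc"] = out["aupr"] = float("nan")
    else:
        out["auc"] = float(roc_auc_score(y_true, scores))
        out["aupr"] = float(average_precision_score(y_true, scores))
    return out


def _fold_targets(dataset: SynergyDataset, idx, task: str) -> np.ndarray:
    if task == "classification":
        return np.array([float(dataset.records[i].label == Label.SYNERGISTIC)
                         for i in idx])
    return np.array([dataset.records[i].score for i in idx])


def run_cross_validation(dataset: SynergyDataset,
                         plan: SplitPlan,
                         fingerprints: FingerprintMatrix,
                         cell_features: "dict[str, np.ndarray] | None" = None,
                         embed_config: dict | None = None,
                         predictor_config: dict | None = None,
                         feature_mask: str = "all",
                         task: str = "regression",
                         per_cell_line: bool = False) -> dict:
    """Run the full pipeline per fold and aggregate metrics.

    Per fold: graphs and embeddings are trained from the fold's training
    records only, the predictor is fit on both drug orderings of the
    training pairs, and the held-out records are scored. The report holds
    per-fold metrics, their mean +/- sd, and pooled metrics over the
    concatenated test predictions.
    """
    embed_config = dict(embed_config or {})
    predictor_config = dict(predictor_config or {})
    predictor_config.setdefault("task", task)
    report = {"strategy": plan.strategy, "task": task, "folds": [],
              "incomplete_folds": []}
    pooled_true, pooled_pred, pooled_cells = [], [], []
    for f, (train_idx, test_idx) in enumerate(plan.folds):
        name = plan.fold_names[f] if plan.fold_names else f"fold{f}"
        if len(test_idx) == 0 or len(train_idx) == 0:
            report["incomplete_folds"].append({"fold": name, "error": "empty split"})
            continue
        try:
            gae = MultiChannelGraphAutoencoder(**embed_config)
            gae.fit(dataset, fingerprints, train_records=train_idx)
            assembler = FeatureAssembler(gae.embeddings_, fingerprints,
                                         cell_features, mask=feature_mask)
            train_cells = sorted({dataset.records[i].cell_line for i in train_idx})
            assembler.fit(train_cells)

            def triples(idx):
                return [(dataset.records[i].drug_a, dataset.records[i].drug_b,
                         dataset.records[i].cell_line) for i in idx]

            Xtr = assembler.transform_pairs(triples(train_idx), dataset,
                                            both_orders=True)
            ytr = np.concatenate([_fold_targets(dataset, train_idx, task)] * 2)
            model = SynergyPredictor(**predictor_config)
            model.fit(Xtr, ytr)
            Xte = assembler.transform_pairs(triples(test_idx), dataset,
                                            both_orders=True)
            pred = model.predict_pairs(Xte)
            ytest = _fold_targets(dataset, test_idx, task)
        except Exception as exc:  # noqa: BLE001 — a fold failure must not kill the run
            report["incomplete_folds"].append({"fold": name, "error": str(exc)})
            continue
        if task == "classification":
            m = classification_metrics(ytest, pred)
        else:
            m = regression_metrics(ytest, pred)
        m["fold"] = name
        m["n_test"] = int(len(test_idx))
        report["folds"].append(m)
        pooled_true.append(ytest)
        pooled_pred.append(pred)
        pooled_cells.extend(dataset.records[i].cell_line for i in test_idx)

    if pooled_true:
        yt = np.concatenate(pooled_true)
        yp = np.concatenate(pooled_pred)
        if task == "classification":
            report["pooled"] = classification_metrics(yt, yp)
        else:
            fold_mses = [m["mse"] for m in report["folds"]]
            report["pooled"] = regression_metrics(
                yt, yp, fold_mses=fold_mses if len(fold_mses) > 1 else None)
        keys = [k for k in report["folds"][0]
                if k not in ("fold", "n_test", "mse_ci95")]
        report["mean"] = {k: float(np.nanmean([m[k] for m in report["folds"]]))
                          for k in keys}
        report["sd"] = {k: float(np.nanstd([m[k] for m in report["folds"]], ddof=0))
                        for k in keys}
        if per_cell_line and task == "regression":
            cells = np.asarray(pooled_cells)
            table = {}
            for cell in sorted(set(pooled_cells)):
                sel = cells == cell
                if sel.sum() >= 2:
                    table[cell] = regression_metrics(yt[sel], yp[sel])
                    table[cell]["n"] = int(sel.sum())
            report["per_cell_line"] = table
    return report
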