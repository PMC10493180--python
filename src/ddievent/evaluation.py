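"""Fold construction, cross-validation, metrics, and ranked false positives.

Metric conventions
------------------
* ``acc`` — mean per-fold accuracy for CV runs (plain accuracy otherwise).
* precision / recall / F — micro-averaged one-vs-rest over events, pooled
  over all test predictions. In single-label multiclass these three coincide.
* AUROC / AUPR — per-event one-vs-rest curves, averaged over events weighted
  by support (``auc_average="macro"`` switches to an unweighted mean).
* ``fp_total`` / ``fn_total`` — summed over events and folds, i.e. the
  whole-dataset misclassification count (each error is one FP for the
  predicted event and one FN for the true event, so the two totals are equal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import DatasetBundle, PairDataset
from .ddi_net import MLPClassifier, ModelConfig, build_model, predict_event
from .pair_features import concat_similarities, encode_pairs
from .similarity import similarity_matrix

__all__ = [
    "FoldSplit",
    "EvalReport",
    "CVResult",
    "stratified_kfold",
    "compute_metrics",
    "cross_validate",
    "nested_cv",
    "top_false_positives",
    "feature_rows",
]


@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray  # fold index per pair record
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.assignments.min() < 0 or self.assignments.max() >= self.k:
            raise ValueError("fold assignment out of range")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class EvalReport:
    """The six headline metrics plus error totals and a per-event table."""

    acc: float
    aupr: float
    auroc: float
    f_score: float
    precision: float
    recall: float
    fp_total: int
    fn_total: int
    per_event: pd.DataFrame = field(repr=False)
    auc_average: str = "weighted"
    extras: dict = field(default_factory=dict, repr=False)

    def metric_row(self) -> dict:
        return {
            "acc": self.acc,
            "aupr": self.aupr,
            "auroc": self.auroc,
            "f_score": self.f_score,
            "precision": self.precision,
            "recall": self.recall,
            "fp_total": self.fp_total,
            "fn_total": self.fn_total,
        }


@dataclass
class CVResult:
    """Pooled report plus everything needed for downstream ranking/analysis."""

    report: EvalReport
    fold_reports: list[EvalReport]
    split: FoldSplit
    y_true: np.ndarray
    probas: np.ndarray  # aligned to the pair record order
    extras: dict = field(default_factory=dict)


def _stratified_assignments(y: np.ndarray, n_events: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(y), dtype=np.int64)
    offset = 0
    for event in range(n_events):
        idx = np.flatnonzero(y == event)
        rng.shuffle(idx)
        for pos, rec in enumerate(idx):
            assignments[rec] = (offset + pos) % k
        offset = (offset + len(idx)) % k
    return assignments


def stratified_kfold(pairs: PairDataset, k: int, seed: int) -> FoldSplit:
    """Per-event round-robin fold assignment after a seeded shuffle.

    Events with fewer than k records land in a subset of folds' test sets.
    A rotating fold offset across events keeps overall fold sizes balanced.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > pairs.n_records:
        raise ValueError(f"k={k} exceeds the number of records ({pairs.n_records})")
    y = pairs.y()
    assignments = _stratified_assignments(y, pairs.n_events, k, seed)
    return FoldSplit(k=k, assignments=assignments, stratified=True, seed=seed)


def compute_metrics(
    y_true: np.ndarray,
    probas: np.ndarray,
    n_events: int | None = None,
    event_labels: list[str] | None = None,
    auc_average: str = "weighted",
) -> EvalReport:
    """Score one set of predictions against true event indices."""
    y_true = np.asarray(y_true, dtype=np.int64)
    probas = np.asarray(probas, dtype=np.float64)
    if probas.ndim != 2 or probas.shape[0] != len(y_true):
        raise ValueError("probas must be (n_rows, n_events) matching y_true")
    if auc_average not in ("weighted", "macro"):
        raise ValueError("auc_average must be 'weighted' or 'macro'")
    n = n_events if n_events is not None else probas.shape[1]
    y_pred = predict_event(probas)

    support = np.bincount(y_true, minlength=n)
    tp = np.zeros(n, dtype=np.int64)
    fp = np.zeros(n, dtype=np.int64)
    fn = np.zeros(n, dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t == p:
            tp[t] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    micro = tp.sum() / len(y_true) if len(y_true) else 0.0

    aurocs = np.full(n, np.nan)
    auprs = np.full(n, np.nan)
    for event in range(n):
        pos = support[event]
        if pos == 0 or pos == len(y_true):
            if pos == 0:
                warnings.warn(
                    f"event {event} absent from y_true; excluded from curve averaging",
                    stacklevel=2,
                )
            continue
        binary = (y_true == event).astype(int)
        aurocs[event] = roc_auc_score(binary, probas[:, event])
        auprs[event] = average_precision_score(binary, probas[:, event])

    usable = ~np.isnan(aurocs)
    if usable.any():
        if auc_average == "weighted":
            w = support[usable] / support[usable].sum()
            auroc = float(np.sum(aurocs[usable] * w))
            aupr = float(np.sum(auprs[usable] * w))
        else:
            auroc = float(np.mean(aurocs[usable]))
            aupr = float(np.mean(auprs[usable]))
    else:
        auroc = aupr = float("nan")

    with np.errstate(invalid="ignore", divide="ignore"):
        prec_e = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec_e = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
        f_e = np.where(prec_e + rec_e > 0, 2 * prec_e * rec_e / np.maximum(prec_e + rec_e, 1e-300), 0.0)
    labels = event_labels if event_labels is not None else [str(e) for e in range(n)]
    per_event = pd.DataFrame(
        {
            "event": labels,
            "support": support,
            "precision": prec_e,
            "recall": rec_e,
            "f_score": f_e,
            "auroc": aurocs,
            "aupr": auprs,
        }
    )
    return EvalReport(
        acc=float(micro),
        aupr=aupr,
        auroc=auroc,
        f_score=float(micro),
        precision=float(micro),
        recall=float(micro),
        fp_total=int(fp.sum()),
        fn_total=int(fn.sum()),
        per_event=per_event,
        auc_average=auc_average,
    )


def feature_rows(bundle: DatasetBundle, modalities: list[str] | None = None) -> np.ndarray:
    """Build the concatenated similarity table's row matrix for a bundle.

    ``modalities`` restricts (and orders) the similarity blocks; default is
    the bundle's full modality list.
    """
    mats = [
        similarity_matrix(fm)
        for fm in bundle.feature_matrices
        if modalities is None or fm.modality_name in modalities
    ]
    if modalities is not None:
        missing = set(modalities) - {sm.modality_name for sm in mats}
        if missing:
            raise KeyError(f"unknown modalities: {sorted(missing)}")
        order = {name: k for k, name in enumerate(modalities)}
        mats.sort(key=lambda sm: order[sm.modality_name])
    return concat_similarities(mats).values


def _pool_reports(
    fold_reports: list[EvalReport],
    y_true: np.ndarray,
    probas: np.ndarray,
    event_labels: list[str],
    auc_average: str,
) -> EvalReport:
    pooled = compute_metrics(
        y_true, probas, event_labels=event_labels, auc_average=auc_average
    )
    report = EvalReport(
        acc=float(np.mean([r.acc for r in fold_reports])),
        aupr=float(np.mean([r.aupr for r in fold_reports])),
        auroc=float(np.mean([r.auroc for r in fold_reports])),
        f_score=pooled.f_score,
        precision=pooled.precision,
        recall=pooled.recall,
        fp_total=int(sum(r.fp_total for r in fold_reports)),
        fn_total=int(sum(r.fn_total for r in fold_reports)),
        per_event=pooled.per_event,
        auc_average=auc_average,
        extras={
            "acc_pooled": pooled.acc,
            "fold_acc": [r.acc for r in fold_reports],
        },
    )
    return report


def cross_validate(
    bundle: DatasetBundle,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
    *,
    mode: str = "sum",
    rows: np.ndarray | None = None,
    modalities: list[str] | None = None,
    auc_average: str = "weighted",
    split: FoldSplit | None = None,
) -> CVResult:
    """Stratified k-fold CV of the full pipeline on one bundle.

    ``rows`` substitutes a precomputed (possibly reduced) drug-row matrix for
    the concatenated similarity table; ``modalities`` restricts the table to a
    subset of similarity blocks. Fold structure depends only on (pairs, k,
    seed), so two runs with the same seed are paired fold-for-fold.
    """
    if rows is None:
        rows = feature_rows(bundle, modalities)
    pairs = bundle.pairs
    if split is None:
        split = stratified_kfold(pairs, k, seed)
    y = pairs.y()
    ii, jj = pairs.pair_indices()
    x_all = encode_pairs(rows, ii, jj, mode)
    probas = np.full((pairs.n_records, pairs.n_events), np.nan)
    fold_reports: list[EvalReport] = []
    for fold in range(split.k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        model = build_model(config, x_all.shape[1], pairs.n_events)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # events missing from a fold's train set
            model.fit(x_all[tr], y[tr])
            probas[te] = model.predict_proba(x_all[te])
            fold_reports.append(
                compute_metrics(
                    y[te], probas[te], event_labels=pairs.event_labels, auc_average=auc_average
                )
            )
    report = _pool_reports(fold_reports, y, probas, pairs.event_labels, auc_average)
    return CVResult(report=report, fold_reports=fold_reports, split=split, y_true=y, probas=probas)


def nested_cv(
    bundle: DatasetBundle,
    grid: list[ModelConfig],
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    *,
    mode: str = "sum",
    auc_average: str = "weighted",
) -> CVResult:
    """Nested CV: inner folds select the grid config with best pooled accuracy,
    the winner is refit on the full outer-train split and scored on outer test.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    rows = feature_rows(bundle)
    pairs = bundle.pairs
    split = stratified_kfold(pairs, outer_k, seed)
    y = pairs.y()
    ii, jj = pairs.pair_indices()
    x_all = encode_pairs(rows, ii, jj, mode)
    probas = np.full((pairs.n_records, pairs.n_events), np.nan)
    fold_reports: list[EvalReport] = []
    selections: list[dict] = []
    for fold in range(split.k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        inner_assign = _stratified_assignments(
            y[tr], pairs.n_events, inner_k, seed + 1000 + fold
        )
        scores = []
        for cand in grid:
            correct = 0
            for ifold in range(inner_k):
                itr = tr[inner_assign != ifold]
                ite = tr[inner_assign == ifold]
                model = build_model(cand, x_all.shape[1], pairs.n_events)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(x_all[itr], y[itr])
                    pred = predict_event(model.predict_proba(x_all[ite]))
                correct += int(np.sum(pred == y[ite]))
            scores.append(correct / len(tr))
        best = int(np.argmax(scores))
        selections.append(
            {"outer_fold": fold, "selected": best, "inner_acc": scores}
        )
        model = build_model(grid[best], x_all.shape[1], pairs.n_events)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x_all[tr], y[tr])
            probas[te] = model.predict_proba(x_all[te])
        fold_reports.append(
            compute_metrics(
                y[te], probas[te], event_labels=pairs.event_labels, auc_average=auc_average
            )
        )
    report = _pool_reports(fold_reports, y, probas, pairs.event_labels, auc_average)
    return CVResult(
        report=report,
        fold_reports=fold_reports,
        split=split,
        y_true=y,
        probas=probas,
        extras={"selections": selections},
    )


def top_false_positives(
    y_true: np.ndarray,
    probas: np.ndarray,
    pairs: PairDataset,
    k: int = 5,
) -> pd.DataFrame:
    """The k misclassified pairs with the highest predicted-event probability.

    Sorted by that probability, descending; ties break by record index. Fewer
    than k false positives returns all of them.
    """
    y_true = np.asarray(y_true)
    y_pred = predict_event(probas)
    wrong = np.flatnonzero(y_pred != y_true)
    conf = probas[wrong, y_pred[wrong]]
    order = wrong[np.lexsort((wrong, -conf))][:k]
    rows = [
        {
            "drug_a": pairs.drug_ids[pairs.records[r][0]],
            "drug_b": pairs.drug_ids[pairs.records[r][1]],
            "recorded_event": pairs.event_labels[y_true[r]],
            "predicted_event": pairs.event_labels[y_pred[r]],
            "probability": float(probas[r, y_pred[r]]),
        }
        for r in order
    ]
    return pd.DataFrame(
        rows,
        columns=["drug_a", "drug_b", "recorded_event", "predicted_event", "probability"],
    )


def write_metrics_tsv(reports: dict[str, EvalReport], path: str | Path) -> None:
    """One row per named experiment, six metrics plus FP/FN columns."""
    rows = [{"experiment": name, **rep.metric_row()} for name, rep in reports.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_per_event_tsv(report: EvalReport, path: str | Path) -> None:
    report.per_event.to_csv(path, sep="\t", index=False)
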