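"""Feature-importance and design-variant studies over one dataset bundle.

Every variant reuses the fold split implied by (pairs, k, seed), so deltas
between variants are paired — never confounded by resplitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_io import DataValidationError, DatasetBundle
from .ddi_net import ModelConfig, build_model, predict_event
from .evaluation import (
    CVResult,
    EvalReport,
    compute_metrics,
    cross_validate,
    feature_rows,
    stratified_kfold,
    _pool_reports,
)
from .pair_features import PAIR_MODES, concat_similarities, encode_pairs
from .similarity import similarity_matrix

__all__ = [
    "AblationResult",
    "ReducedTable",
    "leave_one_feature_out",
    "feature_combinations",
    "pca_reduce",
    "compare_pair_encodings",
    "fuse_per_feature_models",
]


@dataclass
class AblationResult:
    excluded: list[str]
    included: list[str]
    report: EvalReport
    delta_acc: float  # vs the full-feature run on the same folds
    delta_errors: int  # fp_total change vs full


@dataclass
class ReducedTable:
    """A dimension-reduced drug-row matrix plus per-block component counts."""

    scenario: int
    variance_target: float
    values: np.ndarray
    component_counts: dict[str, int] = field(default_factory=dict)


def leave_one_feature_out(
    bundle: DatasetBundle,
    config: ModelConfig,
    seed: int = 0,
    k: int = 5,
) -> list[AblationResult]:
    """Drop each modality's similarity block in turn and rerun CV.

    Folds are identical across all p+1 runs (same seed), so accuracy and
    error-count deltas against the full model are paired.
    """
    names = bundle.modality_names
    if len(names) < 2:
        raise DataValidationError("ablation needs at least two modalities")
    full = cross_validate(bundle, config, k=k, seed=seed)
    results = []
    for name in names:
        kept = [x for x in names if x != name]
        res = cross_validate(bundle, config, k=k, seed=seed, modalities=kept)
        results.append(
            AblationResult(
                excluded=[name],
                included=kept,
                report=res.report,
                delta_acc=res.report.acc - full.report.acc,
                delta_errors=res.report.fp_total - full.report.fp_total,
            )
        )
    return results


def feature_combinations(
    bundle: DatasetBundle,
    config: ModelConfig,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """CV every nonempty modality subset; rows sorted by pooled accuracy."""
    names = bundle.modality_names
    if len(names) > 6:
        raise DataValidationError("subset sweep is limited to p <= 6 (2^p - 1 runs)")
    rows = []
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            res = cross_validate(bundle, config, k=k, seed=seed, modalities=list(subset))
            rows.append(
                {
                    "modalities": "+".join(subset),
                    "n_modalities": size,
                    **res.report.metric_row(),
                    "acc_pooled": res.report.extras["acc_pooled"],
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values("acc_pooled", ascending=False, kind="stable").reset_index(drop=True)


def _min_components(x: np.ndarray, variance_target: float) -> tuple[np.ndarray, int]:
    """Project mean-centered ``x`` onto the fewest principal components whose
    explained-variance ratio reaches ``variance_target``."""
    pca = PCA(svd_solver="full", random_state=0)
    with np.errstate(invalid="ignore"):  # zero-variance input yields NaN ratios
        scores = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_
    if len(ratios) == 0 or not ratios[0] > 0:  # also catches NaN (zero variance)
        raise DataValidationError("rank-0 (constant) matrix cannot be reduced")
    cum = np.cumsum(ratios)
    n_comp = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, len(ratios))
    return scores[:, :n_comp], n_comp


def pca_reduce(
    bundle: DatasetBundle,
    scenario: int,
    variance_target: float = 0.95,
) -> ReducedTable:
    """Principal-component reduction of the drug feature table.

    Scenario 1 reduces each modality's similarity matrix separately, then
    concatenates the projections; scenario 2 concatenates first and reduces
    the full table once. Columns are mean-centered, not variance-scaled
    (similarities already share the [0, 1] scale).
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    mats = [similarity_matrix(fm) for fm in bundle.feature_matrices]
    if scenario == 1:
        blocks, counts = [], {}
        for sm in mats:
            scores, n_comp = _min_components(sm.values, variance_target)
            blocks.append(scores)
            counts[sm.modality_name] = n_comp
        return ReducedTable(1, variance_target, np.hstack(blocks), counts)
    table = concat_similarities(mats)
    scores, n_comp = _min_components(table.values, variance_target)
    return ReducedTable(2, variance_target, scores, {"all": n_comp})


def compare_pair_encodings(
    bundle: DatasetBundle,
    config: ModelConfig,
    seed: int = 0,
    k: int = 5,
) -> dict[str, CVResult]:
    """CV once per pair-encoding mode (sum / concat / dot), identical folds."""
    rows = feature_rows(bundle)
    split = stratified_kfold(bundle.pairs, k, seed)
    return {
        mode: cross_validate(bundle, config, k=k, seed=seed, mode=mode, rows=rows, split=split)
        for mode in PAIR_MODES
    }


def fuse_per_feature_models(
    bundle: DatasetBundle,
    config: ModelConfig,
    mode: str = "mean",
    seed: int = 0,
    k: int = 5,
    *,
    auc_average: str = "weighted",
) -> CVResult:
    """Train one network per modality and fuse their per-pair predictions.

    ``mean`` averages the p probability rows then takes the argmax; ``vote``
    takes each model's argmax and picks the plurality event, ties resolving
    to the lowest event index.
    """
    if mode not in ("mean", "vote"):
        raise ValueError("fusion mode must be 'mean' or 'vote'")
    if bundle.n_modalities < 2:
        raise DataValidationError("fusion needs at least two modalities")
    pairs = bundle.pairs
    split = stratified_kfold(pairs, k, seed)
    y = pairs.y()
    ii, jj = pairs.pair_indices()
    per_model_x = [
        encode_pairs(similarity_matrix(fm).values, ii, jj, "sum")
        for fm in bundle.feature_matrices
    ]
    n = pairs.n_events
    fused = np.full((pairs.n_records, n), np.nan)
    fold_reports = []
    for fold in range(split.k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        model_probas = []
        for x in per_model_x:
            model = build_model(config, x.shape[1], n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x[tr], y[tr])
                model_probas.append(model.predict_proba(x[te]))
        if mode == "mean":
            fused[te] = np.mean(model_probas, axis=0)
        else:
            votes = np.zeros((len(te), n))
            for probs in model_probas:
                picks = predict_event(probs)
                votes[np.arange(len(te)), picks] += 1
            fused[te] = votes / votes.sum(axis=1, keepdims=True)
        fold_reports.append(
            compute_metrics(
                y[te], fused[te], event_labels=pairs.event_labels, auc_average=auc_average
            )
        )
    report = _pool_reports(fold_reports, y, fused, pairs.event_labels, auc_average)
    return CVResult(
        report=report,
        fold_reports=fold_reports,
        split=split,
        y_true=y,
        probas=fused,
        extras={"fusion_mode": mode},
    )
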