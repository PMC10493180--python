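import numpy as np
import pytest

from ddievent.data_io import DatasetBundle, PairDataset
from ddievent.ddi_net import ModelConfig
from ddievent.evaluation import (
    compute_metrics,
    cross_validate,
    nested_cv,
    stratified_kfold,
    top_false_positives,
    write_metrics_tsv,
)


CAPABLE = ModelConfig(hidden_sizes=[64, 32], epochs=20, batch_size=64, learning_rate=0.01, seed=0)


def oracle_confusion_metrics(y_true, y_pred, n):
    """Brute-force per-class confusion counts by direct enumeration."""
    tp = [0] * n
    fp = [0] * n
    fn = [0] * n
    for t, p in zip(y_true, y_pred):
        for event in range(n):
            if p == event and t == event:
                tp[event] += 1
            if p == event and t != event:
                fp[event] += 1
            if p != event and t == event:
                fn[event] += 1
    stp, sfp, sfn = sum(tp), sum(fp), sum(fn)
    micro_p = stp / (stp + sfp) if stp + sfp else 0.0
    micro_r = stp / (stp + sfn) if stp + sfn else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "micro_p": micro_p, "micro_r": micro_r}


def oracle_auroc(y_bin, scores):
    """Mann-Whitney pair counting."""
    pos = [s for s, y in zip(scores, y_bin) if y]
    neg = [s for s, y in zip(scores, y_bin) if not y]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def shuffle_labels(bundle: DatasetBundle, seed: int) -> DatasetBundle:
    rng = np.random.default_rng(seed)
    y = bundle.pairs.y()
    perm = rng.permutation(len(y))
    records = [
        (i, j, int(y[perm[r]])) for r, (i, j, _) in enumerate(bundle.pairs.records)
    ]
    return DatasetBundle(
        bundle.feature_matrices,
        PairDataset(bundle.pairs.drug_ids, records, bundle.pairs.event_labels),
    )


class TestStratifiedKFold:
    def test_exact_divisibility(self):
        drug_ids = [f"D{k}" for k in range(30)]
        records = []
        pairs_iter = ((i, j) for i in range(30) for j in range(i + 1, 30))
        for _ in range(100):
            i, j = next(pairs_iter)
            records.append((i, j, 0))
        pairs = PairDataset(drug_ids, records, ["e1"])
        split = stratified_kfold(pairs, 5, seed=0)
        assert np.bincount(split.assignments, minlength=5).tolist() == [20] * 5

    def test_rare_event_spreads_over_folds(self):
        drug_ids = [f"D{k}" for k in range(30)]
        records = [(i, j, 0) for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (6, 7)]]
        records += [(8 + 2 * k, 9 + 2 * k, 1) for k in range(3)]  # event with 3 records
        pairs = PairDataset(drug_ids, records, ["e1", "e2"])
        split = stratified_kfold(pairs, 5, seed=1)
        y = pairs.y()
        rare_folds = split.assignments[y == 1]
        assert len(set(rare_folds.tolist())) == 3  # one record in each of 3 folds

    def test_per_event_balance(self, learnable_bundle):
        bundle, _ = learnable_bundle
        split = stratified_kfold(bundle.pairs, 5, seed=3)
        y = bundle.pairs.y()
        for event in range(bundle.pairs.n_events):
            counts = np.bincount(split.assignments[y == event], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_partition(self, learnable_bundle):
        bundle, _ = learnable_bundle
        split = stratified_kfold(bundle.pairs, 5, seed=3)
        seen = np.concatenate([split.test_indices(f) for f in range(5)])
        assert sorted(seen.tolist()) == list(range(bundle.pairs.n_records))

    def test_determinism(self, learnable_bundle):
        bundle, _ = learnable_bundle
        a = stratified_kfold(bundle.pairs, 5, seed=9)
        b = stratified_kfold(bundle.pairs, 5, seed=9)
        assert np.array_equal(a.assignments, b.assignments)

    def test_k_too_large(self, tiny_bundle):
        with pytest.raises(ValueError, match="exceeds"):
            stratified_kfold(tiny_bundle.pairs, 100, seed=0)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1, 0])
        probas = np.eye(3)[y] * 0.94 + 0.02
        rep = compute_metrics(y, probas)
        for value in (rep.acc, rep.aupr, rep.auroc, rep.f_score, rep.precision, rep.recall):
            assert value == 1.0
        assert rep.fp_total == rep.fn_total == 0

    def test_majority_prediction_hand_count(self):
        # all rows predicted as event 0, truth uniform over 2 events
        n_rows = 40
        y = np.array([0, 1] * (n_rows // 2))
        probas = np.tile([0.9, 0.1], (n_rows, 1))
        rep = compute_metrics(y, probas)
        assert rep.acc == 0.5
        assert rep.fp_total == rep.fn_total == n_rows // 2

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_against_confusion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        rows = int(rng.integers(n, 51))
        y = rng.integers(0, n, size=rows)
        y[:n] = np.arange(n)  # every event present
        probas = rng.dirichlet(np.ones(n), size=rows)
        rep = compute_metrics(y, probas)
        y_pred = probas.argmax(axis=1)
        oracle = oracle_confusion_metrics(y.tolist(), y_pred.tolist(), n)
        assert rep.fp_total == sum(oracle["fp"])
        assert rep.fn_total == sum(oracle["fn"])
        assert rep.fp_total == rep.fn_total
        assert rep.precision == pytest.approx(oracle["micro_p"], abs=1e-12)
        assert rep.recall == pytest.approx(oracle["micro_r"], abs=1e-12)
        assert rep.precision == rep.recall == rep.f_score  # micro identity
        assert rep.acc == pytest.approx(np.mean(y_pred == y), abs=1e-12)

    def test_auroc_against_rank_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        probas = rng.dirichlet(np.ones(2), size=30)
        rep = compute_metrics(y, probas)
        auc0 = oracle_auroc((y == 0).astype(int), probas[:, 0])
        auc1 = oracle_auroc((y == 1).astype(int), probas[:, 1])
        w0 = np.mean(y == 0)
        expected = w0 * auc0 + (1 - w0) * auc1
        assert rep.auroc == pytest.approx(expected, abs=1e-12)

    def test_absent_event_warns_and_is_excluded(self):
        y = np.array([0, 0, 1, 1])
        probas = np.tile([0.5, 0.3, 0.2], (4, 1))
        with pytest.warns(UserWarning, match="event 2 absent"):
            rep = compute_metrics(y, probas)
        assert not np.isnan(rep.auroc)

    def test_macro_flag(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 20 + [1] * 5)
        probas = rng.dirichlet(np.ones(2), size=25)
        weighted = compute_metrics(y, probas, auc_average="weighted")
        macro = compute_metrics(y, probas, auc_average="macro")
        aucs = [
            oracle_auroc((y == e).astype(int), probas[:, e]) for e in range(2)
        ]
        assert macro.auroc == pytest.approx(np.mean(aucs), abs=1e-12)
        assert weighted.auroc == pytest.approx(0.8 * aucs[0] + 0.2 * aucs[1], abs=1e-12)


class TestCrossValidate:
    def test_learnable_bundle_high_accuracy(self, learnable_bundle):
        bundle, _ = learnable_bundle
        res = cross_validate(bundle, CAPABLE, k=5, seed=0)
        assert res.report.extras["acc_pooled"] >= 0.9

    def test_label_shuffle_drops_to_majority(self, learnable_bundle):
        bundle, _ = learnable_bundle
        shuffled = shuffle_labels(bundle, seed=1)
        res = cross_validate(shuffled, CAPABLE, k=5, seed=0)
        majority = np.bincount(bundle.pairs.y()).max() / bundle.pairs.n_records
        assert abs(res.report.extras["acc_pooled"] - majority) <= 0.05

    def test_every_pair_tested_once(self, learnable_bundle):
        bundle, _ = learnable_bundle
        res = cross_validate(bundle, CAPABLE, k=5, seed=0)
        assert not np.isnan(res.probas).any()  # every record predicted exactly once

    def test_determinism(self, tiny_bundle, fast_config):
        a = cross_validate(tiny_bundle, fast_config, k=2, seed=5)
        b = cross_validate(tiny_bundle, fast_config, k=2, seed=5)
        assert np.array_equal(a.probas, b.probas)
        assert a.report.metric_row() == b.report.metric_row()

    def test_fold_error_totals_sum(self, learnable_bundle):
        bundle, _ = learnable_bundle
        res = cross_validate(bundle, CAPABLE, k=5, seed=0)
        assert res.report.fp_total == sum(r.fp_total for r in res.fold_reports)
        assert res.report.fp_total == res.report.fn_total

    def test_acc_is_mean_of_fold_accs(self, learnable_bundle):
        bundle, _ = learnable_bundle
        res = cross_validate(bundle, CAPABLE, k=5, seed=0)
        assert res.report.acc == pytest.approx(
            np.mean([r.acc for r in res.fold_reports]), abs=1e-12
        )


class TestNestedCV:
    def test_single_config_grid_equals_plain_cv(self, learnable_bundle):
        bundle, _ = learnable_bundle
        plain = cross_validate(bundle, CAPABLE, k=5, seed=2)
        nested = nested_cv(bundle, [CAPABLE], outer_k=5, inner_k=3, seed=2)
        assert np.array_equal(plain.probas, nested.probas)
        assert plain.report.metric_row() == nested.report.metric_row()

    def test_selects_sane_config(self, learnable_bundle):
        bundle, _ = learnable_bundle
        absurd = ModelConfig(hidden_sizes=[1], epochs=20, batch_size=64,
                             learning_rate=0.01, seed=0)
        res = nested_cv(bundle, [CAPABLE, absurd], outer_k=5, inner_k=3, seed=2)
        picks = [s["selected"] for s in res.extras["selections"]]
        assert sum(1 for p in picks if p == 0) >= 4

    def test_determinism(self, learnable_bundle):
        bundle, _ = learnable_bundle
        absurd = ModelConfig(hidden_sizes=[1], epochs=5, batch_size=64, seed=0)
        small = ModelConfig(hidden_sizes=[16], epochs=5, batch_size=64, seed=0)
        a = nested_cv(bundle, [small, absurd], outer_k=3, inner_k=3, seed=4)
        b = nested_cv(bundle, [small, absurd], outer_k=3, inner_k=3, seed=4)
        assert [s["selected"] for s in a.extras["selections"]] == [
            s["selected"] for s in b.extras["selections"]
        ]
        assert np.array_equal(a.probas, b.probas)

    def test_empty_grid_rejected(self, tiny_bundle):
        with pytest.raises(ValueError, match="nonempty"):
            nested_cv(tiny_bundle, [], seed=0)


class TestTopFalsePositives:
    def make_pairs(self):
        drug_ids = ["A", "B", "C", "D"]
        records = [(0, 1, 0), (0, 2, 1), (0, 3, 0), (1, 2, 1)]
        return PairDataset(drug_ids, records, ["e1", "e2"])

    def test_zero_misclassifications(self):
        pairs = self.make_pairs()
        y = pairs.y()
        probas = np.eye(2)[y]
        assert len(top_false_positives(y, probas, pairs, k=5)) == 0

    def test_sort_contract(self):
        pairs = self.make_pairs()
        y = pairs.y()
        # records 0, 1, 2 misclassified with confidences 0.9, 0.8, 0.99
        probas = np.array([[0.1, 0.9], [0.8, 0.2], [0.01, 0.99], [0.3, 0.7]])
        table = top_false_positives(y, probas, pairs, k=2)
        assert table["probability"].tolist() == [0.99, 0.9]
        assert table.iloc[0]["drug_a"] == "A" and table.iloc[0]["drug_b"] == "D"

    def test_truncation(self):
        pairs = self.make_pairs()
        y = pairs.y()
        probas = np.array([[0.1, 0.9], [0.8, 0.2], [0.01, 0.99], [0.3, 0.7]])
        assert len(top_false_positives(y, probas, pairs, k=5)) == 3  # min(5, #FP)


def test_metrics_tsv_schema(tmp_path, tiny_bundle, fast_config):
    res = cross_validate(tiny_bundle, fast_config, k=2, seed=0)
    write_metrics_tsv({"run": res.report}, tmp_path / "metrics.tsv")
    header = (tmp_path / "metrics.tsv").read_text().splitlines()[0].split("\t")
    assert header == [
        "experiment", "acc", "aupr", "auroc", "f_score", "precision", "recall",
        "fp_total", "fn_total",
    ]
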