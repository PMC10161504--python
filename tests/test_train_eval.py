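"""Cropping, the training loop, and the evaluation statistics."""

import numpy as np
import pytest
from scipy import stats

from secmap._nn.autograd import Tensor
from secmap.embeddings import EmbeddingMatrix
from secmap.pairwise_encoder import ModelConfig
from secmap.seqio import DSSP3, DSSP8, ProteinRecord
from secmap.synthetic_data import SynthConfig, generate_dataset
from secmap.train_eval import (TrainConfig, class_metrics, cross_entropy,
                               dataset_accuracy, mcc, mean_difference_ci,
                               predict_sequence, random_crop, train)


def _toy_record(p=10, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACDE"), size=p))
    labels = "H" * p
    rec = ProteinRecord(id="t", sequence=seq, dssp8=labels)
    emb = EmbeddingMatrix("t", rng.normal(size=(p, 8)))
    return rec, emb


class TestRandomCrop:
    def test_short_sequence_unchanged(self):
        rec, emb = _toy_record(10)
        out_rec, out_emb = random_crop(rec, emb, 20, np.random.default_rng(0))
        assert out_rec == rec
        np.testing.assert_array_equal(out_emb.values, emb.values)

    def test_all_windows_valid_under_seed_sweep(self):
        rec, emb = _toy_record(10)
        starts = set()
        for seed in range(200):
            out_rec, out_emb = random_crop(rec, emb, 4, np.random.default_rng(seed))
            assert len(out_rec) == 4
            # find the window and check sequence/labels/embedding alignment
            start = rec.sequence.find(out_rec.sequence)
            idx = emb.values.tolist().index(out_emb.values[0].tolist())
            assert out_rec.sequence == rec.sequence[idx:idx + 4]
            assert out_rec.dssp8 == rec.dssp8[idx:idx + 4]
            np.testing.assert_array_equal(out_emb.values,
                                          emb.values[idx:idx + 4])
            assert 0 <= idx <= 6
            starts.add(idx)
        assert starts == set(range(7))  # every valid start occurs

    def test_fixed_seed_is_deterministic(self):
        rec, emb = _toy_record(30)
        a = random_crop(rec, emb, 8, np.random.default_rng(3))
        b = random_crop(rec, emb, 8, np.random.default_rng(3))
        assert a[0] == b[0]


@pytest.fixture(scope="module")
def trained(tiny_dataset):
    _, records, embeddings = tiny_dataset
    mc = ModelConfig(embed_dim=32, n_layers=1, n_heads=4,
                     detector_channels=8, head_hidden=16, n_classes=8)
    tc = TrainConfig(epochs=2, seed=5)
    model, log = train(records, embeddings, mc, tc)
    return model, log


class TestTraining:
    def test_loss_log_has_one_entry_per_epoch(self, trained):
        _, log = trained
        assert len(log.epoch_losses) == 2
        assert all(np.isfinite(log.epoch_losses))

    def test_repeat_run_reproduces_loss_curve_exactly(self, tiny_dataset):
        _, records, embeddings = tiny_dataset
        mc = ModelConfig(embed_dim=32, n_layers=1, n_heads=4,
                         detector_channels=8, head_hidden=16, n_classes=8)
        logs = [train(records, embeddings, mc, TrainConfig(epochs=1, seed=5))[1]
                for _ in range(2)]
        assert logs[0].epoch_losses == logs[1].epoch_losses

    def test_single_adam_step_reduces_loss_on_fixed_batch(self, tiny_dataset):
        from secmap._nn.layers import Adam
        from secmap.network import SecondaryStructureNet
        _, records, embeddings = tiny_dataset
        mc = ModelConfig(embed_dim=32, n_layers=1, n_heads=4,
                         detector_channels=8, head_hidden=16, n_classes=8)
        model = SecondaryStructureNet(mc, np.random.default_rng(0))
        rec = records[0]
        targets = DSSP8.encode(rec.dssp8)
        emb = Tensor(embeddings[rec.id].values)
        opt = Adam(model.parameters(), lr=1e-3)

        def loss_value():
            return float(cross_entropy(model(emb), targets).numpy())

        before = loss_value()
        opt.zero_grad()
        cross_entropy(model(emb), targets).backward()
        opt.step()
        assert loss_value() < before

    def test_prediction_shapes_labels_and_determinism(self, trained, tiny_dataset):
        model, _ = trained
        _, records, embeddings = tiny_dataset
        rec = records[0]
        labels, probs = predict_sequence(rec, embeddings[rec.id], model)
        assert len(labels) == len(rec)
        assert set(labels) <= set(DSSP8.symbols)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        labels2, probs2 = predict_sequence(rec, embeddings[rec.id], model)
        np.testing.assert_array_equal(probs, probs2)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], {}, ModelConfig(embed_dim=8, n_heads=4), TrainConfig())

    def test_missing_labels_rejected(self, tiny_dataset):
        _, records, embeddings = tiny_dataset
        unlabeled = [ProteinRecord(id=r.id, sequence=r.sequence) for r in records]
        with pytest.raises(ValueError, match="labels"):
            train(unlabeled, embeddings,
                  ModelConfig(embed_dim=32, n_heads=4), TrainConfig())

    def test_parameter_count_delta_rpe_vs_none_in_log(self, tiny_dataset):
        _, records, embeddings = tiny_dataset
        kwargs = dict(embed_dim=32, n_layers=1, n_heads=4, detector_channels=8,
                      head_hidden=16, n_classes=8)
        tc = TrainConfig(epochs=0, seed=0)
        _, log_rpe = train(records, embeddings,
                           ModelConfig(pe_mode="rpe", **kwargs), tc)
        _, log_none = train(records, embeddings,
                            ModelConfig(pe_mode="none", **kwargs), tc)
        delta = (log_rpe.parameter_counts["total"]
                 - log_none.parameter_counts["total"])
        assert delta == 16 * 4  # n_buckets * n_heads
        assert log_rpe.parameter_counts["position_bias_table"] == 64


class TestDatasetAccuracy:
    def test_sequence_averaging_rule(self):
        # two sequences with accuracies 1.0 and 0.5 average to 0.75
        assert dataset_accuracy(["HH", "HE"], ["HH", "HH"]) == pytest.approx(0.75)

    def test_perfect_predictions(self):
        assert dataset_accuracy(["HEC"], ["HEC"]) == 1.0

    def test_differs_from_residue_pooling_on_unequal_lengths(self):
        # seq A: len 2 fully correct; seq B: len 8 fully wrong
        preds = ["HH", "E" * 8]
        refs = ["HH", "H" * 8]
        assert dataset_accuracy(preds, refs) == pytest.approx(0.5)
        pooled = 2 / 10  # residue pooling would give 0.2
        assert dataset_accuracy(preds, refs) != pooled

    def test_equal_lengths_match_residue_pooling(self):
        rng = np.random.default_rng(0)
        preds = ["".join(rng.choice(list("HEC"), size=6)) for _ in range(5)]
        refs = ["".join(rng.choice(list("HEC"), size=6)) for _ in range(5)]
        pooled = np.mean([p == r for pr, rr in zip(preds, refs)
                          for p, r in zip(pr, rr)])
        assert dataset_accuracy(preds, refs) == pytest.approx(pooled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dataset_accuracy([], [])


class TestClassMetrics:
    def test_perfect_predictions_give_unit_metrics(self):
        prec, rec, f1 = class_metrics(["HEC", "CEH"], ["HEC", "CEH"], DSSP3)
        assert prec == rec == f1 == 1.0

    def test_absent_classes_count_as_zero_in_macro(self):
        # only H appears; E and C contribute zeros to the macro average
        prec, rec, f1 = class_metrics(["HHH"], ["HHH"], DSSP3)
        assert prec == pytest.approx(1 / 3)
        assert rec == pytest.approx(1 / 3)
        assert f1 == pytest.approx(1 / 3)

    def test_macro_from_explicit_confusion_matrix(self):
        # preds HHE vs refs HEE: per-class precision H=1/2, E=1, C=0
        prec, rec, f1 = class_metrics(["HHE"], ["HEE"], DSSP3)
        assert prec == pytest.approx((0.5 + 1.0 + 0.0) / 3)
        assert rec == pytest.approx((1.0 + 0.5 + 0.0) / 3)

    def test_order_invariance(self):
        a = class_metrics(["HE", "CH"], ["HH", "CC"], DSSP3)
        b = class_metrics(["CH", "HE"], ["CC", "HH"], DSSP3)
        assert a == b


class TestMcc:
    def test_perfect_multiclass_is_one(self):
        assert mcc(["HEC"], ["HEC"], DSSP3) == pytest.approx(1.0)

    def test_binary_case_matches_closed_form(self):
        # explicit 2x2 table: TP=3, FN=1, FP=2, TN=4 over H/E
        preds = ["H" * 3 + "E" * 1 + "H" * 2 + "E" * 4]
        refs = ["H" * 3 + "H" * 1 + "E" * 2 + "E" * 4]
        tp, fn, fp, tn = 3, 1, 2, 4
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert mcc(preds, refs, DSSP3) == pytest.approx(expected)

    def test_independent_predictions_near_zero(self):
        rng = np.random.default_rng(0)
        n = 20000
        refs = ["".join(rng.choice(list("HEC"), size=n))]
        preds = ["".join(rng.choice(list("HEC"), size=n))]
        assert abs(mcc(preds, refs, DSSP3)) < 0.02

    def test_degenerate_single_class_is_zero(self):
        assert mcc(["HHH"], ["HHH"], DSSP3) == 0.0


class TestMeanDifferenceCi:
    def test_identical_lists_give_degenerate_interval(self):
        mean, (lo, hi) = mean_difference_ci([0.7, 0.8], [0.7, 0.8])
        assert mean == lo == hi == 0.0

    def test_constant_differences_give_zero_width(self):
        mean, (lo, hi) = mean_difference_ci([1, 2, 3, 4], [0, 1, 2, 3])
        assert mean == pytest.approx(1.0)
        assert lo == pytest.approx(hi) == pytest.approx(1.0)

    def test_two_point_interval_matches_t_closed_form(self):
        # differences [0, 2]: mean 1, sd sqrt(2), half-width t(.975,1)*sd/sqrt(2)
        mean, (lo, hi) = mean_difference_ci([0, 2], [0, 0])
        half = stats.t.ppf(0.975, df=1) * np.sqrt(2.0) / np.sqrt(2)
        assert mean == pytest.approx(1.0)
        assert lo == pytest.approx(1.0 - half)
        assert hi == pytest.approx(1.0 + half)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            mean_difference_ci([1.0], [0.5])
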