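"""Model assembly, metrics, training and cross-validation protocol."""

import numpy as np
import pytest

from _oracles import auc_ref
from molcarc.chemio import MoleculeRecord
from molcarc.model import (CarcinogenicityModel, CarcinogenicityResults,
                           MetricsReport, TrainConfig, _Network,
                           compute_metrics, predict)
from molcarc.synthetic import SyntheticSpec, generate

FAST = TrainConfig(epochs=3, batch_size=64)


@pytest.fixture(scope="module")
def small_dataset():
    return generate(SyntheticSpec(n_molecules=90, alert_log_odds=6.0, seed=21))


class TestComputeMetrics:
    def test_perfect_classifier_on_45_55_split(self):
        labels = np.array([1] * 45 + [0] * 55)
        scores = np.where(labels == 1, 0.9, 0.1)
        m = compute_metrics(labels, labels, scores)
        assert (m.TP, m.TN, m.FP, m.FN) == (45, 55, 0, 0)
        assert m.ACC == 1.0 and m.AUC == 1.0
        assert m.n == 100

    def test_sensitivity_closed_form(self):
        labels = np.array([1] * 45 + [0] * 55)
        preds = np.array([1] * 35 + [0] * 10 + [0] * 55)
        m = compute_metrics(labels, preds, preds.astype(float))
        assert m.SE == pytest.approx(35 / 45, abs=1e-9)

    def test_auc_three_of_four_pairs(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.3, 0.8, 0.2])
        m = compute_metrics(labels, np.round(scores), scores)
        assert m.AUC == pytest.approx(0.75)

    def test_auc_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(17)
        for n in (20, 200):
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = np.round(rng.random(n), 2)  # force some ties
            m = compute_metrics(labels, (scores > 0.5).astype(int), scores)
            assert m.AUC == pytest.approx(auc_ref(labels, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(5), np.ones(5), np.ones(5))


class TestPredict:
    def test_carcinogen_capsule_wins(self):
        labels, scores = predict(np.array([[0.9, 0.1]]))
        assert labels[0] == 1 and scores[0] == 0.9

    def test_non_carcinogen_capsule_wins(self):
        labels, _ = predict(np.array([[0.1, 0.9]]))
        assert labels[0] == 0

    def test_tie_resolves_to_non_carcinogen(self):
        labels, _ = predict(np.array([[0.5, 0.5]]))
        assert labels[0] == 0


class TestNetworkContracts:
    def test_forward_outputs_two_lengths_in_unit_interval(self, small_dataset):
        model = CarcinogenicityModel(small_dataset[:16], variant="full",
                                     config=FAST)
        net = _Network(d_fp=10, variant="full", config=FAST,
                       rng=np.random.default_rng(0))
        lengths = net.forward(np.random.default_rng(1).random((4, 10)),
                              model.graphs[:4])
        assert lengths.shape == (4, 2)
        assert np.all(lengths.data >= 0) and np.all(lengths.data < 1)

    def test_missing_modality_raises(self, small_dataset):
        net = _Network(d_fp=10, variant="full", config=FAST,
                       rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            net.forward(np.zeros((2, 10)), None)
        net_of = _Network(d_fp=10, variant="OF", config=FAST,
                          rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            net_of.forward(None, None)

    def test_eval_mode_is_deterministic(self, small_dataset):
        model = CarcinogenicityModel(small_dataset, variant="OF", config=FAST)
        res = model.fit(seed=1)
        a = res.capsule_lengths(small_dataset[:5])
        b = res.capsule_lengths(small_dataset[:5])
        assert np.array_equal(a, b)

    def test_unknown_variant_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            CarcinogenicityModel(small_dataset, variant="bogus")


class TestTraining:
    def test_same_seed_reproduces_final_loss(self, small_dataset):
        model = CarcinogenicityModel(small_dataset, variant="OF", config=FAST)
        a = model.fit(seed=4)
        b = model.fit(seed=4)
        assert a.loss_history == b.loss_history

    def test_loss_decreases_on_separable_data(self, small_dataset):
        cfg = TrainConfig(epochs=10, batch_size=64)
        model = CarcinogenicityModel(small_dataset, variant="OF", config=cfg)
        res = model.fit(seed=2)
        assert res.loss_history[-1] < res.loss_history[0]

    def test_summary_mentions_variant_and_loss(self, small_dataset):
        res = CarcinogenicityModel(small_dataset, variant="OF",
                                   config=FAST).fit(seed=0)
        text = res.summary()
        assert "OF" in text and "margin loss" in text

    def test_checkpoint_roundtrip_preserves_predictions(self, small_dataset,
                                                        tmp_path):
        model = CarcinogenicityModel(small_dataset, variant="OF", config=FAST)
        res = model.fit(seed=3)
        res.save(tmp_path / "ckpt")
        back = CarcinogenicityResults.load(tmp_path / "ckpt", small_dataset)
        a = res.predict(small_dataset[:8])
        b = back.predict(small_dataset[:8])
        assert np.allclose(a["score"], b["score"])
        assert (a["predicted_label"] == b["predicted_label"]).all()


class TestCrossValidation:
    def test_every_record_validated_exactly_once_per_repeat(self, small_dataset):
        model = CarcinogenicityModel(small_dataset, variant="OF", config=FAST)
        cv = model.cross_validate(k=3, repeats=2, seed=0)
        for fold_of in cv.fold_assignments:
            assert np.all(fold_of >= 0)
            sizes = np.bincount(fold_of, minlength=3)
            assert sizes.sum() == len(small_dataset)
            assert sizes.max() - sizes.min() <= 1

    def test_repeats_use_different_splits(self, small_dataset):
        model = CarcinogenicityModel(small_dataset, variant="OF", config=FAST)
        cv = model.cross_validate(k=3, repeats=2, seed=0)
        assert not np.array_equal(cv.fold_assignments[0], cv.fold_assignments[1])

    def test_aggregations_over_folds_and_repeats(self, small_dataset):
        model = CarcinogenicityModel(small_dataset, variant="OF", config=FAST)
        cv = model.cross_validate(k=3, repeats=2, seed=0)
        df = cv.as_dataframe()
        assert len(df) == 6
        fold_agg = cv.aggregate("fold")
        rep_agg = cv.aggregate("repeat")
        assert fold_agg.loc["AUC", "mean"] == pytest.approx(df["AUC"].mean())
        assert set(rep_agg.index) == {"SE", "SP", "ACC", "AUC"}
        assert "ACC" in cv.summary()

    def test_k_below_two_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            CarcinogenicityModel(small_dataset, config=FAST).cross_validate(k=1)

    def test_too_few_minority_samples_fail_stratification(self):
        records = generate(SyntheticSpec(n_molecules=40, seed=5))
        skew = [MoleculeRecord(r.id, r.smiles, 1 if i > 1 else 0, r.source)
                for i, r in enumerate(records)]
        model = CarcinogenicityModel(skew, variant="OF", config=FAST)
        with pytest.raises(ValueError):
            model.cross_validate(k=5, seed=0)

    def test_single_class_dataset_rejected_at_construction(self, small_dataset):
        same = [MoleculeRecord(r.id, r.smiles, 1, r.source)
                for r in small_dataset]
        with pytest.raises(ValueError):
            CarcinogenicityModel(same)


def test_metrics_report_identities():
    m = MetricsReport(TP=30, TN=40, FP=10, FN=20,
                      SE=30 / 50, SP=40 / 50, ACC=70 / 100, AUC=0.8)
    assert m.SE == m.TP / (m.TP + m.FN)
    assert m.SP == m.TN / (m.TN + m.FP)
    assert m.ACC == (m.TP + m.TN) / m.n
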