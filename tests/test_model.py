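import copy
import math

import numpy as np
import pytest

from nfpscreen import model as mdl
from nfpscreen.datapipe import ScreenRecord
from nfpscreen.model import (
    TrainConfig,
    ann_forward,
    default_selection_key,
    grid_search,
    init_ann,
    load_checkpoint,
    save_checkpoint,
    train,
)
from nfpscreen.molgraph import smiles_to_graph
from nfpscreen.neuralfp import neural_fingerprint, sigmoid


TINY = dict(fp_length=8, conv_depth=1, conv_hidden_dim=6, ann_hidden=(10,),
            batch_size=4, n_epochs=3, seed=0)


def _tiny_records():
    hits = [ScreenRecord(s, -11.0, label=1, split="train")
            for s in ("N#Cc1ccccc1", "OC(=O)c1ccccc1", "Clc1ccccc1")]
    nons = [ScreenRecord(s, -5.0, label=0, split="train")
            for s in ("c1ccccc1", "CCO", "CCC", "C1CCCCC1")]
    return hits + nons


class TestForward:
    def test_zeroed_ann_outputs_half_for_any_molecule(self):
        cfg = TrainConfig(**TINY)
        m = train(_tiny_records(), [], cfg)
        for w in m.ann_params.weights:
            w[:] = 0.0
        for b in m.ann_params.biases:
            b[:] = 0.0
        for smi in ("C", "c1ccncc1"):
            assert mdl.forward(smiles_to_graph(smi), m) == 0.5

    def test_evaluation_mode_is_deterministic(self):
        cfg = TrainConfig(dropout=0.4, **TINY)
        m = train(_tiny_records(), [], cfg)
        g = smiles_to_graph("CCO")
        assert mdl.forward(g, m) == mdl.forward(g, m)

    def test_matches_hand_composed_single_hidden_layer(self):
        ann = init_ann([4, 3, 1], seed=1)
        x = np.array([0.5, 1.5, 0.25, 2.0])
        z, _ = ann_forward(x, ann, training=False)
        h = np.maximum(x @ ann.weights[0] + ann.biases[0], 0.0)
        expected = h @ ann.weights[1] + ann.biases[1]
        assert z == pytest.approx(float(expected[0]), rel=1e-12)
        prob = float(sigmoid(np.array([z]))[0])
        assert 0.0 < prob < 1.0


class TestTrain:
    def test_single_example_memorized(self):
        rec = [ScreenRecord("N#Cc1ccccc1", -11.0, label=1, split="train")]
        cfg = TrainConfig(fp_length=8, conv_depth=1, conv_hidden_dim=6,
                          ann_hidden=(10,), batch_size=1, n_epochs=200,
                          learning_rate=5e-2, seed=0)
        m = train(rec, [], cfg)
        assert m.training_history[-1]["train_loss"] < 1e-2

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        cfg = TrainConfig(learning_rate=0.0, **TINY)
        m = train(_tiny_records(), [], cfg)
        from nfpscreen.neuralfp import init_params
        fresh = init_params(cfg.conv_depth, cfg.fp_length, seed=cfg.seed,
                            hidden_dim=cfg.conv_hidden_dim)
        for (_, a), (_, b) in zip(m.fp_params.flat_parameters(),
                                  fresh.flat_parameters()):
            np.testing.assert_array_equal(a, b)

    def test_joint_training_moves_fingerprint_parameters(self):
        """End-to-end backprop: one epoch of Adam must change the
        fingerprint weights, not just the classifier head."""
        cfg = TrainConfig(**{**TINY, "n_epochs": 1})
        m = train(_tiny_records(), [], cfg)
        from nfpscreen.neuralfp import init_params
        fresh = init_params(cfg.conv_depth, cfg.fp_length, seed=cfg.seed,
                            hidden_dim=cfg.conv_hidden_dim)
        moved = any(
            not np.array_equal(a, b)
            for (_, a), (_, b) in zip(m.fp_params.flat_parameters(),
                                      fresh.flat_parameters())
        )
        assert moved

    def test_weight_decay_shrinks_parameter_norms(self):
        base = {**TINY, "n_epochs": 10}
        m0 = train(_tiny_records(), [], TrainConfig(weight_decay=0.0, **base))
        m1 = train(_tiny_records(), [], TrainConfig(weight_decay=1e-2, **base))
        def total_norm(m):
            return sum(float(np.square(a).sum())
                       for _, a in m.fp_params.flat_parameters()
                       + m.ann_params.flat_parameters())
        assert total_norm(m1) < total_norm(m0)

    def test_same_seed_reproduces_history(self):
        cfg = TrainConfig(**TINY)
        h1 = train(_tiny_records(), [], cfg).training_history
        h2 = train(_tiny_records(), [], cfg).training_history
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], [], TrainConfig(**TINY))

    def test_dropout_changes_training_forward_only(self):
        ann = init_ann([6, 20, 1], seed=0, dropout_rate=0.5)
        x = np.ones(6)
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(2)
        z1, _ = ann_forward(x, ann, training=True, rng=rng1)
        z2, _ = ann_forward(x, ann, training=True, rng=rng2)
        assert z1 != z2  # stochastic in training mode
        e1, _ = ann_forward(x, ann, training=False)
        e2, _ = ann_forward(x, ann, training=False)
        assert e1 == e2  # deterministic, rng-independent, in eval mode


class TestGridSearch:
    def test_single_combination_trains_one_model(self, small_dataset):
        recs = _tiny_records()
        ranked = grid_search({"learning_rate": [1e-3]}, recs, recs,
                             TrainConfig(**TINY))
        assert len(ranked) == 1

    def test_cartesian_product_count(self):
        recs = _tiny_records()
        cfg = TrainConfig(**{**TINY, "n_epochs": 1})
        ranked = grid_search({"learning_rate": [1e-3, 2e-3],
                              "dropout": [0.0, 0.1, 0.2]}, recs, recs, cfg)
        assert len(ranked) == 6

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown hyperparameter"):
            grid_search({"momentum": [0.9]}, _tiny_records(), _tiny_records(),
                        TrainConfig(**TINY))

    def test_ranking_matches_brute_force_sort(self):
        table = [
            {"recall": 0.9, "precision": 0.3, "mean_predicted_hit_energy": -8.0},
            {"recall": 0.9, "precision": 0.5, "mean_predicted_hit_energy": -7.0},
            {"recall": 0.9, "precision": 0.5, "mean_predicted_hit_energy": -9.0},
            {"recall": 0.95, "precision": 0.2, "mean_predicted_hit_energy": -6.0},
            {"recall": 0.7, "precision": math.nan, "mean_predicted_hit_energy": -6.0},
        ]
        ranked = sorted(table, key=default_selection_key)
        # brute force: best recall first; among equal recalls higher precision;
        # among equal both, more negative mean hit energy; NaNs last
        assert ranked[0]["recall"] == 0.95
        assert ranked[1] == table[2]
        assert ranked[2] == table[1]
        assert ranked[3] == table[0]
        assert ranked[4]["recall"] == 0.7


def test_checkpoint_roundtrip_bit_exact(tmp_path):
    cfg = TrainConfig(**TINY)
    m = train(_tiny_records(), [], cfg, energy_threshold=-9.5)
    path = tmp_path / "model.npz"
    save_checkpoint(m, path)
    m2 = load_checkpoint(path)
    assert m2.energy_threshold == -9.5
    assert m2.config == cfg
    for (_, a), (_, b) in zip(m.fp_params.flat_parameters(),
                              m2.fp_params.flat_parameters()):
        np.testing.assert_array_equal(a, b)
    g = smiles_to_graph("CCO")
    assert mdl.forward(g, m) == mdl.forward(g, m2)
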