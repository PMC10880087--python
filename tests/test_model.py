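"""Contracts of the atom-bond transformer: message passing, attention,
symmetry, determinism, serialization, and learnability."""

import numpy as np
import pytest

from pcfkit import datakit, synthdata
from pcfkit.abt_model import (
    DivergenceError,
    ModelConfig,
    TrainedModel,
    encode,
    init_params,
    make_batch,
    message_passing,
    prepare_graph,
    train,
)
from pcfkit.abt_model import _forward
from pcfkit.datakit import ChemicalRecord, Dataset, SplitSpec
from pcfkit.featurize import featurize_graph

from test_featurize import reorder_smiles

TINY = ModelConfig(hidden_dim=24, mp_iterations=2, epochs=1, seed=0, ffn_mult=2)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"mp_iterations": 0}, {"mp_iterations": 11},
        {"interatomic_scaler": 0.6}, {"dropout": 0.7},
        {"hidden_dim": 2}, {"n_encoder_blocks": 0},
    ])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)

    def test_head_dim_decoupled_from_divisibility(self):
        cfg = ModelConfig(hidden_dim=200)
        assert cfg.head_dim == 33  # six heads need not divide the width


class TestMessagePassing:
    def test_single_iteration_uses_only_initial_states(self):
        cfg = ModelConfig(hidden_dim=24, mp_iterations=1, seed=0, ffn_mult=2)
        params = init_params(cfg, 0)
        g = featurize_graph("CC")
        h = message_passing(g, cfg, params)
        # T=1 is exactly h0 = relu(W_in . concat(atom, bond))
        x = np.concatenate([g.atom_feats[g.bond_index[:, 0]], g.bond_feats], axis=1)
        h0 = np.maximum(x @ params["W_in"].data + params["b_in"].data, 0.0)
        assert np.allclose(h, h0)

    def test_path_molecule_message_flow(self):
        # propane C0-C1-C2: the bond 1->2 aggregates exactly the 0->1 state
        g = featurize_graph("CCC")
        gt = prepare_graph(g, TINY)
        bonds = list(map(tuple, g.bond_index))
        b12, b01, b21 = bonds.index((1, 2)), bonds.index((0, 1)), bonds.index((2, 1))
        row = gt.msg[b12]
        assert row[b01] == 1.0 and row.sum() == 1.0
        assert row[b21] == 0.0  # the reverse bond never feeds back

    def test_star_and_path_graphs_differ(self):
        params = init_params(TINY, 0)
        h_path = message_passing(featurize_graph("CCCC"), TINY, params)
        h_star = message_passing(featurize_graph("CC(C)C"), TINY, params)
        assert not np.allclose(sorted(h_path.sum(axis=1)), sorted(h_star.sum(axis=1)))

    def test_zero_bond_molecule_gives_empty_matrix(self):
        h = message_passing(featurize_graph("C"), TINY, init_params(TINY, 0))
        assert h.shape == (0, TINY.hidden_dim)


def _manual_model(cfg: ModelConfig, n_desc: int = 0) -> TrainedModel:
    """A TrainedModel with freshly initialized (untrained) weights."""
    if not cfg.use_descriptors:
        n_desc = 0
    else:
        from pcfkit.featurize import compute_descriptors

        n_desc = len(compute_descriptors("C").values)
    return TrainedModel(config=cfg, params=init_params(cfg, n_desc),
                        desc_mean=np.zeros(n_desc), desc_std=np.ones(n_desc))


class TestEncodeAndPredict:
    def test_attention_rows_are_stochastic(self):
        model = _manual_model(TINY)
        for smi in ["CCO", "c1ccc(CC(=O)OC)cc1", "CC(Cl)CN"]:
            for maps in model.attention(smi):
                assert np.all(maps >= 0)
                assert np.allclose(maps.sum(axis=-1), 1.0, atol=1e-5)

    def test_zero_scaler_erases_interatomic_bias(self):
        cfg = ModelConfig(hidden_dim=24, interatomic_scaler=0.0, ffn_mult=2)
        gt = prepare_graph(featurize_graph("CCOC(C)=O"), cfg)
        assert np.all(gt.attn_bias == 0)

    def test_scaler_continuity_near_zero(self):
        base = ModelConfig(hidden_dim=24, interatomic_scaler=0.0, ffn_mult=2,
                           use_descriptors=False)
        params = init_params(base, 0)
        g = featurize_graph("CCOC(C)=O")

        def value(lam):
            cfg = ModelConfig(hidden_dim=24, interatomic_scaler=lam, ffn_mult=2,
                              use_descriptors=False)
            batch = make_batch([prepare_graph(g, cfg)], None)
            return float(_forward(batch, params, cfg)[0].data[0])

        v0, v_eps, v_step = value(0.0), value(1e-6), value(0.05)
        assert abs(v_eps - v0) < 1e-4          # vanishing bias, vanishing effect
        assert abs(v_step - v0) < 10.0          # bounded response at a lattice step
        assert np.isfinite(v_step)

    def test_prediction_is_deterministic(self):
        model = _manual_model(TINY)
        values = {model.predict("CCOC(C)=O") for _ in range(10)}
        assert len(values) == 1

    def test_prediction_invariant_under_atom_reordering(self):
        model = _manual_model(TINY)
        for seed, smi in enumerate(["CCOC(C)=O", "c1ccc(O)cc1CN", "ClCCCBr"]):
            ref = model.predict(smi)
            for k in range(3):
                assert model.predict(reorder_smiles(smi, seed * 10 + k)) == \
                    pytest.approx(ref, abs=1e-5)

    def test_out_of_vocabulary_element_is_flagged(self):
        model = _manual_model(TINY)
        res = model.predict_detailed("CC[SeH]")
        assert res.out_of_vocabulary and np.isfinite(res.value)
        assert not model.predict_detailed("CCO").out_of_vocabulary

    def test_zeroed_head_predicts_the_bias(self):
        model = _manual_model(TINY)
        model.params["Wh2"].data[:] = 0.0
        model.params["bh2"].data[:] = 1.75
        for smi in ("CCO", "c1ccccc1"):
            assert model.predict(smi) == pytest.approx(1.75)

    def test_encode_returns_embedding_and_attention(self):
        g = featurize_graph("CCO")
        emb, attn = encode(g, None, ModelConfig(hidden_dim=24, ffn_mult=2,
                                                use_descriptors=False))
        assert emb.shape == (24,)
        assert attn[0].shape == (6, 3, 3)


def _tiny_training_set(n=24, seed=5):
    ds, _ = synthdata.make_dataset(synthdata.SynthConfig(n_molecules=n, noise_sd=0.1,
                                                         seed=seed))
    merged = datakit.merge_duplicates(datakit.curate(ds.records).dataset)
    k = max(2, len(merged) // 6)
    return Dataset(merged.records[:-k]), Dataset(merged.records[-k:])


class TestTraining:
    def test_same_seed_gives_identical_history(self):
        tr, va = _tiny_training_set(30)
        cfg = ModelConfig(hidden_dim=24, mp_iterations=2, epochs=3, seed=9, ffn_mult=2)
        h1 = train(tr, va, cfg).training_history
        h2 = train(tr, va, cfg).training_history
        assert h1 == h2

    def test_empty_validation_set_raises(self):
        tr, _ = _tiny_training_set(30)
        with pytest.raises(ValueError):
            train(tr, Dataset([]), TINY)

    def test_overlapping_sets_raise(self):
        tr, _ = _tiny_training_set(30)
        with pytest.raises(ValueError, match="overlap"):
            train(tr, Dataset(tr.records[:2]), TINY)

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            train(Dataset([ChemicalRecord("CCO", 1.0)] * 5),
                  Dataset([ChemicalRecord("CCN", 1.0)]), TINY)

    def test_overfits_a_small_training_set(self):
        ds, _ = synthdata.make_dataset(
            synthdata.SynthConfig(n_molecules=60, noise_sd=0.1, seed=2))
        merged = datakit.merge_duplicates(datakit.curate(ds.records).dataset)
        tr = Dataset(merged.records[:32])
        va = Dataset(merged.records[32:40])
        cfg = ModelConfig(hidden_dim=64, mp_iterations=2, epochs=60, patience=60,
                          seed=0, ffn_mult=2)
        model = train(tr, va, cfg)
        preds = model.predict_many(tr.smiles)
        train_rmse = float(np.sqrt(np.mean((preds - tr.targets) ** 2)))
        assert train_rmse < 0.5


class TestSerialization:
    def test_checkpoint_round_trip_is_bit_exact(self, tmp_path, tiny_model):
        path = tmp_path / "model.pcfkit"
        tiny_model.save(path)
        back = TrainedModel.load(path)
        assert back.config == tiny_model.config
        assert set(back.params) == set(tiny_model.params)
        for k in back.params:
            assert np.array_equal(back.params[k].data, tiny_model.params[k].data)
        for smi in ("CCO", "CCOC(C)=O"):
            assert back.predict(smi) == tiny_model.predict(smi)

    def test_history_survives_round_trip(self, tmp_path, tiny_model):
        path = tmp_path / "model.pcfkit"
        tiny_model.save(path)
        assert TrainedModel.load(path).training_history == tiny_model.training_history
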