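"""Directed message-passing network: exact contracts, oracle equivalence,
gradients and training behavior."""

import numpy as np
import pytest

from molactive import chem_data as cd
from molactive import dmpnn_model as dm
from molactive import evaluation as ev
from molactive import synthetic_data as sd
from molactive.featurization import N_DESCRIPTORS, smiles_to_graph

from oracles import oracle_forward


def zero_like(params):
    z = params.copy()
    z.Wi[:] = 0; z.Wm[:] = 0; z.Wa[:] = 0; z.ba[:] = 0
    for W in z.ffn_W:
        W[:] = 0
    for b in z.ffn_b:
        b[:] = 0
    return z


class TestBondStates:
    def test_no_bond_molecule(self, tiny_params_config):
        params, cfg = tiny_params_config
        states = dm.init_bond_states(smiles_to_graph("C"), params)
        assert states.h0.shape == (0, cfg.hidden_size)
        vec = dm.readout(smiles_to_graph("C"), states, params)
        assert vec.shape == (cfg.hidden_size,)

    def test_zero_weights_give_zero_states(self, tiny_params_config):
        params, cfg = tiny_params_config
        z = zero_like(params)
        states = dm.init_bond_states(smiles_to_graph("CCO"), z)
        assert np.all(states.h0 == 0)

    def test_ethane_messages_are_empty(self, tiny_params_config):
        # both directed bonds of CC have no second neighbor: m=0, h=tau(h0)
        params, cfg = tiny_params_config
        g = smiles_to_graph("CC")
        states = dm.init_bond_states(g, params)
        stepped = dm.message_step(g, states, params)
        assert np.all(stepped.m_t == 0)
        np.testing.assert_allclose(stepped.h_t, np.maximum(states.h0, 0))

    def test_disabled_message_pathway(self, tiny_params_config):
        params, cfg = tiny_params_config
        p = params.copy()
        p.Wm[:] = 0
        g = smiles_to_graph("CCO")
        states = dm.init_bond_states(g, p)
        for _ in range(3):
            states = dm.message_step(g, states, p)
        np.testing.assert_allclose(states.h_t, np.maximum(states.h0, 0))


class TestOracleEquivalence:
    def test_forward_matches_explicit_loops(self):
        """20 random small molecules x 5 parameter draws, tolerance 1e-6."""
        lib = [s for s in sd.generate_library(200, seed=3)
               if smiles_to_graph(s).n_atoms <= 6][:20]
        assert len(lib) == 20
        rng = np.random.default_rng(0)
        for draw in range(5):
            cfg = dm.DMPNNConfig(hidden_size=6, depth=2, ffn_depth=2, seed=draw)
            params = dm.init_params(cfg, np.random.default_rng(100 + draw))
            for smi in lib:
                desc = rng.normal(size=N_DESCRIPTORS)
                got = dm.forward(smiles_to_graph(smi), desc, params, cfg)
                want = oracle_forward(smi, desc, params, cfg)
                assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("depth", [1, 3])
    @pytest.mark.parametrize("direction", ["incoming", "outgoing"])
    def test_oracle_agreement_across_depth_and_readout(self, depth, direction):
        cfg = dm.DMPNNConfig(hidden_size=5, depth=depth, seed=0,
                             readout_direction=direction)
        params = dm.init_params(cfg, np.random.default_rng(8))
        desc = np.random.default_rng(9).normal(size=N_DESCRIPTORS)
        for smi in ["CCO", "c1ccncc1", "CC(C)Br"]:
            got = dm.forward(smiles_to_graph(smi), desc, params, cfg)
            want = oracle_forward(smi, desc, params, cfg)
            assert got == pytest.approx(want, abs=1e-6)

    def test_stepwise_unroll_matches_oracle_states(self, tiny_params_config):
        """message_step composed T times equals the batched encoder path."""
        params, cfg = tiny_params_config
        g = smiles_to_graph("CCO")
        states = dm.init_bond_states(g, params)
        for _ in range(cfg.depth):
            states = dm.message_step(g, states, params)
        enc = dm._encode(dm.BatchGraph([g]), params, cfg)
        np.testing.assert_allclose(states.h_t, enc["steps"][-1]["h"], atol=1e-12)


class TestForward:
    def test_zero_ffn_gives_half(self, tiny_params_config):
        params, cfg = tiny_params_config
        p = params.copy()
        for W in p.ffn_W:
            W[:] = 0
        for b in p.ffn_b:
            b[:] = 0
        assert dm.forward(smiles_to_graph("CCO"), np.zeros(N_DESCRIPTORS), p, cfg) == 0.5

    def test_probability_bounds(self, tiny_params_config):
        params, cfg = tiny_params_config
        rng = np.random.default_rng(5)
        for smi in sd.generate_library(100, seed=4):
            p = dm.forward(smiles_to_graph(smi), rng.normal(size=N_DESCRIPTORS), params, cfg)
            assert 0.0 < p < 1.0

    def test_atom_order_invariance(self, tiny_params_config):
        params, cfg = tiny_params_config
        desc = np.random.default_rng(1).normal(size=N_DESCRIPTORS)
        pairs = [("CCO", "OCC"), ("c1ccncc1", "n1ccccc1"), ("CC(=O)O", "OC(C)=O")]
        for a, b in pairs:
            pa = dm.forward(smiles_to_graph(a), desc, params, cfg)
            pb = dm.forward(smiles_to_graph(b), desc, params, cfg)
            assert pa == pytest.approx(pb, abs=1e-6)

    def test_wrong_descriptor_size_rejected(self, tiny_params_config):
        params, cfg = tiny_params_config
        with pytest.raises(ValueError, match="descriptor"):
            dm.forward(smiles_to_graph("CCO"), np.zeros(7), params, cfg)


class TestGradients:
    def test_backprop_matches_numerical_gradients(self):
        cfg = dm.DMPNNConfig(hidden_size=5, depth=3, ffn_depth=2, seed=3)
        rng = np.random.default_rng(3)
        params = dm.init_params(cfg, rng)
        graphs = [smiles_to_graph(s) for s in ["CCO", "c1ccncc1", "CC(=O)OC", "C"]]
        bg = dm.BatchGraph(graphs)
        desc = rng.normal(size=(4, N_DESCRIPTORS))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        out = dm._forward_batch(bg, desc, params, cfg)
        loss, dlog = dm._bce_loss_and_grad(out["logits"], y)
        grads = dm._backprop(bg, out, dlog, params, cfg)
        eps = 1e-6
        for name, arr in params.named_arrays():
            flat, g = arr.ravel(), grads[name].ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = dm._bce_loss_and_grad(dm._forward_batch(bg, desc, params, cfg)["logits"], y)
                flat[i] = orig - eps
                lm, _ = dm._bce_loss_and_grad(dm._forward_batch(bg, desc, params, cfg)["logits"], y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert g[i] == pytest.approx(num, abs=1e-6, rel=1e-4), name


class TestTraining:
    def test_learns_planted_rule(self, trained_small_model, small_task):
        model, split = trained_small_model
        _, va = split.folds[0]
        val = [small_task.records[i] for i in va]
        probs = model.predict_proba(val)
        rep = ev.metrics_report([r.label for r in val], probs)
        assert model.stopped_epoch <= 30
        assert rep.acc >= 0.85

    def test_single_class_rejected(self, desk_config):
        recs = [cd.CompoundRecord("CCO", label=1), cd.CompoundRecord("CCC", label=1)]
        with pytest.raises(ValueError, match="single class"):
            dm.train(recs, recs, desk_config)

    def test_zero_patience_stops_at_first_non_improvement(self, small_task):
        split = cd.split_dataset(len(small_task.records), 7)
        tr, va = split.folds[0]
        cfg = dm.DMPNNConfig(hidden_size=8, max_epochs=50, patience=0,
                             learning_rate=0.5, seed=0)  # large lr forces regressions
        model = dm.train(
            [small_task.records[i] for i in tr][:64],
            [small_task.records[i] for i in va][:32],
            cfg,
        )
        losses = model.history["val_loss"]
        # the run ends at the first epoch whose validation loss fails to
        # improve on the best seen so far
        first_bad = next(
            (i for i in range(1, len(losses)) if losses[i] >= min(losses[:i])),
            None,
        )
        if first_bad is not None:
            assert model.stopped_epoch == first_bad + 1
        else:
            assert model.stopped_epoch == cfg.max_epochs

    def test_seed_determinism(self, small_task):
        split = cd.split_dataset(len(small_task.records), 7)
        tr, va = split.folds[0]
        recs_tr = [small_task.records[i] for i in tr][:100]
        recs_va = [small_task.records[i] for i in va][:40]
        cfg = dm.DMPNNConfig(hidden_size=8, max_epochs=2, seed=5)
        m1 = dm.train(recs_tr, recs_va, cfg)
        m2 = dm.train(recs_tr, recs_va, cfg)
        assert m1.history["train_loss"][0] == m2.history["train_loss"][0]

    def test_beats_chance_logloss_across_seeds(self, small_task):
        """Held-out log-loss below the 0.5-probability baseline in >=4/5 seeds."""
        split = cd.split_dataset(len(small_task.records), 7)
        tr, va = split.folds[0]
        recs_tr = [small_task.records[i] for i in tr]
        recs_va = [small_task.records[i] for i in va]
        y = np.array([r.label for r in recs_va], dtype=float)
        wins = 0
        for seed in range(5):
            cfg = dm.DMPNNConfig(hidden_size=16, max_epochs=10, patience=5, seed=seed)
            model = dm.train(recs_tr, recs_va, cfg)
            p = np.clip(model.predict_proba(recs_va), 1e-12, 1 - 1e-12)
            ll = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            wins += ll < np.log(2)
        assert wins >= 4


class TestPrediction:
    def test_copies_get_identical_probabilities(self, trained_small_model):
        model, _ = trained_small_model
        recs = [cd.CompoundRecord("c1ccncc1")] * 5
        probs = model.predict_proba(recs)
        # BLAS row blocking may flip the last ulp between batch positions
        np.testing.assert_allclose(probs, probs[0], rtol=0, atol=1e-12)

    def test_batching_invariance(self, trained_small_model, small_task):
        model, _ = trained_small_model
        recs = small_task.records[:30]
        whole = model.predict_proba(recs)
        parts = np.concatenate(
            [model.predict_proba(recs[:13]), model.predict_proba(recs[13:])]
        )
        np.testing.assert_allclose(whole, parts, atol=1e-12)

    def test_matches_single_forward(self, trained_small_model):
        model, _ = trained_small_model
        rec = cd.CompoundRecord("c1ccc(Cl)nc1")
        from molactive.featurization import compute_global_descriptors
        desc = model.scaler.transform(compute_global_descriptors(rec.smiles).values)[0]
        single = dm.forward(smiles_to_graph(rec.smiles), desc, model.params, model.config)
        assert model.predict_proba([rec])[0] == pytest.approx(single, abs=1e-12)

    def test_parse_failure_handling(self, trained_small_model):
        model, _ = trained_small_model
        recs = [cd.CompoundRecord("CCO"), cd.CompoundRecord("junk")]
        with pytest.raises(ValueError):
            model.predict_proba(recs)
        probs = model.predict_proba(recs, on_error="nan")
        assert np.isfinite(probs[0]) and np.isnan(probs[1])


def test_checkpoint_round_trip(tmp_path, trained_small_model, small_task):
    model, _ = trained_small_model
    path = tmp_path / "model.json"
    model.save(path)
    back = dm.TrainedModel.load(path)
    recs = small_task.records[:10]
    np.testing.assert_allclose(
        model.predict_proba(recs), back.predict_proba(recs), atol=1e-12
    )
    assert back.stopped_epoch == model.stopped_epoch
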