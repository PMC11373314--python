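"""VAE objective: KL analytics, teacher forcing, optimization loop."""

import numpy as np
import pytest

from fraglink._autodiff import Tensor
from fraglink.decoder import STOP, apply_action, finalize, init_state
from fraglink.encoder import EncoderConfig, encode_t, init_encoder_params
from fraglink.fixtures import ToyDatasetConfig, generate_toy_dataset
from fraglink.molgraph import write_smiles
from fraglink.training import (CompiledTrajectory, DataError, TrainConfig,
                               compile_trajectory, decision_accuracy,
                               derive_trajectory, example_loss, kl_loss,
                               teacher_forced_recon_loss, train)


class TestKlLoss:
    def test_standard_normal_is_zero(self):
        assert kl_loss(np.zeros(4), np.ones(4)) == pytest.approx(0.0)

    def test_unit_mean_shift_is_half_per_dim(self):
        assert kl_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)
        assert kl_loss(np.ones(8), np.ones(8)) == pytest.approx(4.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kl_loss(np.zeros(2), np.array([1.0, 0.0]))

    def test_matches_monte_carlo_estimate(self):
        """Closed form within 3 standard errors of a 1e5-draw MC estimate."""
        rng = np.random.default_rng(0)
        mu = rng.normal(size=3)
        sigma = np.exp(rng.normal(size=3) * 0.3)
        x = mu + sigma * rng.standard_normal((100_000, 3))
        logq = (-0.5 * ((x - mu) / sigma) ** 2
                - np.log(sigma) - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        logp = (-0.5 * x ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        draws = logq - logp
        mc, se = draws.mean(), draws.std() / np.sqrt(len(draws))
        assert abs(kl_loss(mu, sigma) - mc) < 3 * se


class TestTrajectory:
    def test_replay_reconstructs_molecule(self, toy_dataset, enc_cfg, dec_cfg):
        for ex in toy_dataset[:15]:
            traj = derive_trajectory(ex, enc_cfg, dec_cfg)
            st = init_state(traj.frag1, traj.frag2, np.zeros(enc_cfg.d_z),
                            len(traj.linker_elements), enc_cfg, dec_cfg)
            for action in traj.actions:
                apply_action(st, action)
            labels = (list(st.labels[:st.n_frag_atoms])
                      + list(traj.linker_elements))
            mol = finalize(st, labels)
            assert mol.n_atoms == ex.molecule.n_atoms
            assert write_smiles(mol) == write_smiles(ex.molecule)

    def test_ends_with_all_nodes_visited(self, toy_dataset, enc_cfg, dec_cfg):
        traj = derive_trajectory(toy_dataset[0], enc_cfg, dec_cfg)
        st = init_state(traj.frag1, traj.frag2, np.zeros(enc_cfg.d_z),
                        len(traj.linker_elements), enc_cfg, dec_cfg)
        for action in traj.actions:
            apply_action(st, action)
        assert not st.queue
        assert st.visited == set(range(st.n_nodes))


class TestTeacherForcedLoss:
    def test_uniform_logits_contribute_log_k(self, toy_dataset, enc_cfg,
                                             dec_cfg, random_params):
        """Zeroed output heads make every masked softmax uniform, so the loss
        is exactly sum(ln K_step) + sum(ln K_label)."""
        params = {k: Tensor.param(p.data.copy())
                  for k, p in random_params.items()}
        for name in ("E_W2", "E_b2", "N_W2", "N_b2"):
            params[name].data[:] = 0.0
        ex = toy_dataset[0]
        traj = derive_trajectory(ex, enc_cfg, dec_cfg)
        comp = compile_trajectory(traj, enc_cfg, dec_cfg)
        loss, n_dec, _ = teacher_forced_recon_loss(
            traj, params, enc_cfg, dec_cfg, compiled=comp)
        expected = 0.0
        for st in comp.steps:
            k = sum(len(orders) for _, orders in st.cands) + 1
            expected += np.log(k)
        for row in comp.final_mask:
            expected += np.log(np.isfinite(row).sum())
        assert float(loss.data) == pytest.approx(expected, rel=1e-9)

    def test_matches_stepwise_oracle(self, toy_dataset, enc_cfg, dec_cfg,
                                     random_params):
        """Total loss equals an independently book-kept per-step replay that
        sums -log p of each forced decision."""
        from fraglink.decoder import edge_logits, node_label_logits, reencode
        from fraglink.molgraph import ATOM_VOCAB
        ex = next(e for e in toy_dataset if len(e.linker_atom_indices) == 3)
        traj = derive_trajectory(ex, enc_cfg, dec_cfg)
        z = Tensor(np.random.default_rng(5).standard_normal((1, enc_cfg.d_z)))
        loss, _, _ = teacher_forced_recon_loss(traj, random_params, enc_cfg,
                                               dec_cfg, z_seed=z)
        # oracle: own state bookkeeping around the scoring networks
        st = init_state(traj.frag1, traj.frag2, z, 3, enc_cfg, dec_cfg)
        total = 0.0
        for action in traj.actions:
            z_t = reencode(st, random_params, enc_cfg)
            acts, lp = edge_logits(st, st.queue[0], z_t, random_params,
                                   enc_cfg)
            total -= float(lp.data[0, acts.index(action)])
            apply_action(st, action)
        z_t = reencode(st, random_params, enc_cfg)
        lp = node_label_logits(st, z_t, random_params)
        vocab = {s: k for k, s in enumerate(ATOM_VOCAB)}
        for r, sym in enumerate(traj.linker_elements):
            total -= float(lp.data[r, vocab[sym]])
        assert float(loss.data) == pytest.approx(total, rel=1e-9)

    def test_fast_and_sequential_paths_agree(self, toy_dataset, enc_cfg,
                                             dec_cfg, random_params):
        for ex in toy_dataset[:5]:
            traj = derive_trajectory(ex, enc_cfg, dec_cfg)
            comp = compile_trajectory(traj, enc_cfg, dec_cfg)
            seq = CompiledTrajectory(**{**comp.__dict__, "fast": None})
            z = Tensor(np.random.default_rng(1).standard_normal((1, enc_cfg.d_z)))
            l1, n1, k1 = teacher_forced_recon_loss(
                traj, random_params, enc_cfg, dec_cfg, z_seed=z, compiled=seq)
            l2, n2, k2 = teacher_forced_recon_loss(
                traj, random_params, enc_cfg, dec_cfg, z_seed=z, compiled=comp)
            assert float(l1.data) == pytest.approx(float(l2.data), rel=1e-10)
            assert (n1, k1) == (n2, k2)

    def test_gradient_matches_finite_differences(self, toy_dataset, enc_cfg,
                                                 dec_cfg, random_params):
        """Autodiff gradient of the full example objective vs central
        differences on a handful of weight entries (1e-4 relative)."""
        params = {k: Tensor.param(p.data.copy())
                  for k, p in random_params.items()}
        traj = derive_trajectory(toy_dataset[0], enc_cfg, dec_cfg)
        comp = compile_trajectory(traj, enc_cfg, dec_cfg)
        mol = toy_dataset[0].molecule

        def loss_value():
            rng = np.random.default_rng(3)
            recon, kl, _, _ = example_loss(traj, mol, params, enc_cfg,
                                           dec_cfg, rng, train=False,
                                           compiled=comp)
            return recon + 0.01 * kl

        for p in params.values():
            p.grad = None
        loss_value().backward()
        rng = np.random.default_rng(9)
        checked = 0
        for name in ("re_W1", "E_Wsv_z", "N_W0", "W_mu_m", "W_tau"):
            p = params[name]
            idx = tuple(rng.integers(s) for s in p.data.shape)
            eps = 1e-5
            p.data[idx] += eps
            f1 = float(loss_value().data)
            p.data[idx] -= 2 * eps
            f0 = float(loss_value().data)
            p.data[idx] += eps
            fd = (f1 - f0) / (2 * eps)
            if abs(fd) > 1e-8:
                assert p.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked >= 3


class TestTrain:
    @pytest.fixture(scope="class")
    def small_dataset(self):
        return generate_toy_dataset(ToyDatasetConfig(n_examples=30, seed=2))

    def test_smoke_loss_decreases(self, small_dataset):
        res = train(small_dataset, TrainConfig(epochs=2, seed=0))
        assert len(res.history) == 2
        assert res.history[-1].total < res.history[0].total
        assert all(np.isfinite(bd.total) for bd in res.history)

    def test_kl_nonnegative_every_epoch(self, small_dataset):
        res = train(small_dataset, TrainConfig(epochs=2, seed=1))
        assert all(bd.kl >= 0 for bd in res.history)

    def test_seeded_runs_identical(self, small_dataset):
        r1 = train(small_dataset[:12], TrainConfig(epochs=2, seed=4))
        r2 = train(small_dataset[:12], TrainConfig(epochs=2, seed=4))
        assert [b.total for b in r1.history] == [b.total for b in r2.history]
        for k in r1.params:
            assert (r1.params[k].data == r2.params[k].data).all()

    def test_beta_zero_total_equals_recon(self, small_dataset):
        res = train(small_dataset[:12],
                    TrainConfig(epochs=2, seed=0, beta_final=0.0))
        for bd in res.history:
            assert bd.total == pytest.approx(bd.recon)

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train([], TrainConfig(epochs=1))

    def test_checkpoint_written(self, small_dataset, tmp_path):
        path = tmp_path / "ck.npz"
        train(small_dataset[:10], TrainConfig(epochs=1, seed=0),
              checkpoint_path=path)
        from fraglink.encoder import load_checkpoint
        params, cfg, extra = load_checkpoint(path)
        assert "decoder" in extra and params
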