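"""Graph encoders: layer semantics, invariances, latent heads, checkpoints."""

import numpy as np
import pytest

from fraglink._autodiff import Tensor
from fraglink.encoder import (EncoderConfig, censnet_edge_layer,
                              censnet_node_layer, encode, encode_fragment_pair,
                              encode_t, gcn_layer, init_encoder_params,
                              load_checkpoint, make_initial_representation,
                              node_input_features, normalized_adjacency,
                              save_checkpoint)
from fraglink.fixtures import ToyDatasetConfig, random_molecule
from fraglink.molgraph import MolGraph, parse_smiles, to_tensors


def _relabel(g: MolGraph, perm):
    """Apply a node permutation perm[old] = new."""
    inv = np.argsort(perm)
    atoms = tuple(g.atoms[inv[j]] for j in range(g.n_atoms))
    bonds = tuple(sorted((min(perm[a], perm[b]), max(perm[a], perm[b]), o)
                         for a, b, o in g.bonds))
    flags = tuple(g.attachment_flags[inv[j]] for j in range(g.n_atoms))
    return MolGraph(atoms, bonds, flags).validate()


def _random_graphs(n, seed, max_atoms=12):
    rng = np.random.default_rng(seed)
    cfg = ToyDatasetConfig(n_examples=1, seed=0, min_heavy_atoms=5,
                           max_heavy_atoms=max_atoms)
    return [random_molecule(rng, cfg) for _ in range(n)]


class TestGcnLayer:
    def test_isolated_node_identity(self):
        g = parse_smiles("C")
        t = to_tensors(g)
        h = np.array([[2.0, -1.0]])
        out = gcn_layer(t, h, Tensor.param(np.eye(2)), activation="linear")
        assert np.allclose(out.data, h)

    def test_two_node_average(self):
        t = to_tensors(parse_smiles("CC"))
        h = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = gcn_layer(t, h, Tensor.param(np.eye(2)), activation="linear")
        assert np.allclose(out.data, np.tile((h[0] + h[1]) / 2, (2, 1)))

    def test_matches_neighbor_sum_oracle(self):
        """D^-1/2 (A+I) D^-1/2 H W equals an explicit per-node loop on 50
        random graphs (tolerance 1e-6)."""
        rng = np.random.default_rng(5)
        for g in _random_graphs(50, seed=17):
            t = to_tensors(g)
            n = g.n_atoms
            h = rng.standard_normal((n, 6))
            w = rng.standard_normal((6, 4))
            out = gcn_layer(t, h, Tensor.param(w), activation="linear").data
            deg = np.zeros(n)
            adj = t.node_adjacency.sum(axis=0)
            deg = adj.sum(axis=1) + 1
            expect = np.zeros((n, 6))
            for i in range(n):
                expect[i] += h[i] / deg[i]
                for j in range(n):
                    if adj[i, j]:
                        expect[i] += h[j] / np.sqrt(deg[i] * deg[j])
            assert np.allclose(out, expect @ w, atol=1e-6)

    def test_shape_mismatch_raises(self):
        t = to_tensors(parse_smiles("CC"))
        with pytest.raises(ValueError):
            gcn_layer(t, np.ones((2, 3)), Tensor.param(np.eye(4)))


class TestCensNetLayers:
    def test_zero_edges_reduces_to_self_loop(self):
        t = to_tensors(parse_smiles("C"))
        h_v = np.array([[1.0, -2.0]])
        out = censnet_node_layer(t, h_v, np.zeros((0, 3)),
                                 Tensor.param(np.eye(2)),
                                 Tensor.param(np.zeros((3, 1))),
                                 activation="linear")
        assert np.allclose(out.data, h_v)

    def test_equal_edge_features_scale_neighbor_term(self):
        """With all edge scalars equal to c, off-diagonal aggregation is the
        GCN neighbor term scaled by c (checked explicitly on a 3-node path)."""
        t = to_tensors(parse_smiles("CCC"))
        h_v = np.random.default_rng(0).standard_normal((3, 2))
        h_e = np.ones((2, 3)) / 3.0       # equal features -> equal scalars
        p = Tensor.param(np.ones((3, 1)))  # scalar c = 1 per edge
        out = censnet_node_layer(t, h_v, h_e, Tensor.param(np.eye(2)), p,
                                 activation="linear").data
        a_hat = normalized_adjacency(t)
        tm = t.incidence
        mod = tm @ np.diag((h_e @ p.data)[:, 0]) @ tm.T + np.eye(3)
        expect = (mod * a_hat) @ h_v
        assert np.allclose(out, expect, atol=1e-10)

    def test_node_layer_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        for g in _random_graphs(20, seed=23):
            t = to_tensors(g)
            perm = rng.permutation(g.n_atoms)
            g2 = _relabel(g, perm)
            t2 = to_tensors(g2)
            h_v = node_input_features(g)
            h_v2 = node_input_features(g2)
            w = Tensor.param(rng.standard_normal((h_v.shape[1], 5)))
            p = Tensor.param(rng.standard_normal((3, 1)))
            out = censnet_node_layer(t, h_v, t.edge_features, w, p,
                                     activation="linear").data
            out2 = censnet_node_layer(t2, h_v2, t2.edge_features, w, p,
                                      activation="linear").data
            assert np.allclose(out2[perm], out, atol=1e-8)

    def test_edge_layer_single_edge_self_loop(self):
        t = to_tensors(parse_smiles("CC"))
        h_e = np.array([[1.0, 0.0, 0.0]])
        out = censnet_edge_layer(t, np.ones((2, 2)), h_e,
                                 Tensor.param(np.eye(3)),
                                 Tensor.param(np.zeros((2, 1))),
                                 activation="linear")
        # line graph has no neighbors: only the (modulated) self term remains
        assert out.data.shape == (1, 3)
        assert np.isfinite(out.data).all()

    def test_edge_layer_triangle_symmetry(self):
        t = to_tensors(parse_smiles("C1CC1"))
        h_e = np.ones((3, 3)) * 0.5
        out = censnet_edge_layer(t, np.ones((3, 2)), h_e,
                                 Tensor.param(np.eye(3)),
                                 Tensor.param(np.ones((2, 1))),
                                 activation="linear").data
        assert np.allclose(out, out[0])   # all-equal inputs, all-equal outputs


class TestEncode:
    @pytest.mark.parametrize("backbone", ["gcn", "censnet"])
    def test_permutation_invariance(self, backbone):
        cfg = EncoderConfig(backbone=backbone)
        params = init_encoder_params(cfg, np.random.default_rng(1))
        rng = np.random.default_rng(4)
        for g in _random_graphs(50, seed=31):
            e = encode(g, params, cfg)
            g2 = _relabel(g, rng.permutation(g.n_atoms))
            e2 = encode(g2, params, cfg)
            assert np.allclose(e.mu, e2.mu, atol=1e-6)
            assert np.allclose(e.sigma, e2.sigma, atol=1e-6)

    def test_sigma_positive_and_dims(self, enc_cfg, random_params):
        e = encode(parse_smiles("CC(=O)NC1CC1"), random_params, enc_cfg)
        assert e.mu.shape == (enc_cfg.d_z,)
        assert (e.sigma > 0).all()
        em = encode(parse_smiles("CC(=O)NC1CC1"), random_params, enc_cfg,
                    head="molecule")
        assert em.mu.shape == (enc_cfg.d_m,)

    def test_gradient_flow(self, enc_cfg):
        params = init_encoder_params(enc_cfg, np.random.default_rng(3))
        mu, sigma = encode_t(parse_smiles("CCOC"), params, enc_cfg)
        (mu * mu).sum().backward()
        grads = [p.grad for p in params.values() if p.grad is not None]
        assert grads and all(np.isfinite(g).all() for g in grads)


class TestInitialRepresentation:
    def test_af_zero_gives_mu_f(self, enc_cfg):
        params = init_encoder_params(enc_cfg, np.random.default_rng(0))
        params["a_f"].data = np.array(0.0)
        mu_f = np.random.default_rng(1).standard_normal(enc_cfg.d_z)
        rep = make_initial_representation(mu_f, None, params, enc_cfg,
                                          mode="generate",
                                          rng=np.random.default_rng(0))
        assert np.allclose(rep.z, mu_f)

    def test_zero_tau_weights_and_zero_zm(self, enc_cfg, fragment_pair):
        params = init_encoder_params(enc_cfg, np.random.default_rng(0))
        params["W_tau"].data[:] = 0.0
        params["b_tau"].data[:] = 0.0
        mu_f = np.zeros(enc_cfg.d_z)

        class ZeroEnc:
            mu = np.zeros(enc_cfg.d_m)
            sigma = np.zeros(enc_cfg.d_m) + 1e-12
        rep = make_initial_representation(mu_f, ZeroEnc, params, enc_cfg,
                                          mode="train",
                                          rng=np.random.default_rng(0))
        assert np.allclose(rep.z, mu_f, atol=1e-9)

    def test_seeded_determinism(self, enc_cfg):
        params = init_encoder_params(enc_cfg, np.random.default_rng(0))
        mu_f = np.ones(enc_cfg.d_z)
        r1 = make_initial_representation(mu_f, None, params, enc_cfg,
                                         rng=np.random.default_rng(42))
        r2 = make_initial_representation(mu_f, None, params, enc_cfg,
                                         rng=np.random.default_rng(42))
        assert (r1.z == r2.z).all()

    def test_train_mode_requires_molecule_encoding(self, enc_cfg):
        params = init_encoder_params(enc_cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            make_initial_representation(np.zeros(enc_cfg.d_z), None, params,
                                        enc_cfg, mode="train")


class TestCheckpoint:
    def test_bit_stable_round_trip(self, enc_cfg, random_params, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(path, random_params, enc_cfg, {"note": "x"})
        params2, cfg2, extra = load_checkpoint(path)
        assert cfg2 == enc_cfg and extra == {"note": "x"}
        assert set(params2) == set(random_params)
        for k in random_params:
            assert (params2[k].data == random_params[k].data).all()
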