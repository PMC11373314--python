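"""Sequential decoder: state machine, masking, valency, generation."""

import numpy as np
import pytest

from fraglink.decoder import (STOP, DecoderConfig, apply_action,
                              candidate_targets, decode, edge_logits,
                              finalize, generate, init_state,
                              largest_component, predict_node_labels,
                              reencode, step)
from fraglink.encoder import make_initial_representation
from fraglink.molgraph import (MAX_VALENCE, GraphError, contains_fragment,
                               parse_smiles, write_smiles)


def _fresh_state(enc_cfg, dec_cfg, n_linker=3, z=None):
    f1, f2 = parse_smiles("CC*"), parse_smiles("OC*")
    if z is None:
        z = np.zeros(enc_cfg.d_z)
    return init_state(f1, f2, z, n_linker, enc_cfg, dec_cfg)


class TestInitState:
    def test_node_counts_and_isolation(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg, n_linker=3)
        assert st.n_nodes == 4 + 3
        for i in range(st.n_frag_atoms, st.n_nodes):
            assert st.neighbors(i) == []
            assert st.budgets[i] == 4

    def test_focus_queue_seeded_with_attachments(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg)
        assert list(st.queue) == sorted(st.attach)

    def test_linker_out_of_range(self, enc_cfg, dec_cfg):
        with pytest.raises(GraphError):
            _fresh_state(enc_cfg, dec_cfg, n_linker=2)
        with pytest.raises(GraphError):
            _fresh_state(enc_cfg, dec_cfg, n_linker=13)

    def test_fragment_bonds_survive_full_generation(self, enc_cfg, dec_cfg,
                                                    random_params):
        f1, f2 = parse_smiles("CC(C)*"), parse_smiles("OCC*")
        out = generate(f1, f2, random_params, enc_cfg, dec_cfg, n_samples=10,
                       seed=5)
        for _, state in out:
            assert state.frag_bonds <= set(state.bonds)


class TestReencode:
    def test_deterministic_without_graph_change(self, enc_cfg, dec_cfg,
                                                random_params):
        st = _fresh_state(enc_cfg, dec_cfg)
        z1 = reencode(st, random_params, enc_cfg).data
        z2 = reencode(st, random_params, enc_cfg).data
        assert (z1 == z2).all()

    def test_edge_addition_changes_endpoint_embeddings(self, enc_cfg, dec_cfg,
                                                       random_params):
        st = _fresh_state(enc_cfg, dec_cfg)
        before = reencode(st, random_params, enc_cfg).data
        u = st.queue[0]
        v = st.n_frag_atoms          # first linker slot
        apply_action(st, ("edge", v, 1))
        after = reencode(st, random_params, enc_cfg).data
        assert not np.allclose(before[u], after[u])
        assert not np.allclose(before[v], after[v])


class TestEdgeLogits:
    def test_probabilities_sum_to_one(self, enc_cfg, dec_cfg, random_params):
        st = _fresh_state(enc_cfg, dec_cfg)
        z_t = reencode(st, random_params, enc_cfg)
        actions, lp = edge_logits(st, st.queue[0], z_t, random_params, enc_cfg)
        assert np.exp(lp.data).sum() == pytest.approx(1.0)
        assert actions[-1] == STOP

    def test_saturated_focus_only_stop(self, enc_cfg, dec_cfg, random_params):
        st = _fresh_state(enc_cfg, dec_cfg)
        u = st.queue[0]
        st.budgets = [0] * st.n_nodes        # everything saturated
        z_t = reencode(st, random_params, enc_cfg)
        actions, lp = edge_logits(st, u, z_t, random_params, enc_cfg)
        assert actions == [STOP]
        assert np.exp(lp.data[0, 0]) == pytest.approx(1.0)

    def test_low_budget_masks_higher_orders(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg)
        v = st.n_frag_atoms
        st.budgets[v] = 1
        cands = dict(candidate_targets(st, st.queue[0]))
        assert cands[v] == [1]

    def test_existing_bond_excluded(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg)
        u = st.queue[0]
        v = st.n_frag_atoms
        apply_action(st, ("edge", v, 1))
        assert v not in dict(candidate_targets(st, u))


class TestStep:
    def test_stop_pops_focus_and_enqueues_neighbors(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg)
        u = st.queue[0]
        v = st.n_frag_atoms
        apply_action(st, ("edge", v, 1))
        apply_action(st, STOP)
        assert u not in st.queue and u in st.visited
        assert v in st.queue

    def test_bond_addition_conserves_budget_sum(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg)
        total = sum(st.budgets)
        apply_action(st, ("edge", st.n_frag_atoms, 2))
        assert sum(st.budgets) == total - 4

    def test_infeasible_action_rejected(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg)
        st.budgets[st.queue[0]] = 0
        with pytest.raises(GraphError):
            apply_action(st, ("edge", st.n_frag_atoms, 1))

    def test_sample_policy_seeded(self, enc_cfg, dec_cfg, random_params,
                                  fragment_pair):
        f1, f2 = fragment_pair
        a = generate(f1, f2, random_params, enc_cfg, dec_cfg, n_samples=5,
                     seed=9, policy="sample")
        b = generate(f1, f2, random_params, enc_cfg, dec_cfg, n_samples=5,
                     seed=9, policy="sample")
        assert [write_smiles(m) for m, _ in a] == [write_smiles(m) for m, _ in b]


class TestNodeLabels:
    def test_bond_sum_four_forces_carbon(self, enc_cfg, dec_cfg, random_params):
        st = _fresh_state(enc_cfg, dec_cfg, n_linker=5)
        hub = st.n_frag_atoms
        st.queue.appendleft(hub)      # focus the hub slot
        for v in range(st.n_frag_atoms + 1, st.n_frag_atoms + 5):
            apply_action(st, ("edge", v, 1))
        assert st.bond_order_sum(hub) == 4
        labels = predict_node_labels(st, random_params, enc_cfg)
        assert labels[hub] == "C"

    def test_fragment_labels_unchanged(self, enc_cfg, dec_cfg, random_params):
        st = _fresh_state(enc_cfg, dec_cfg)
        labels = predict_node_labels(st, random_params, enc_cfg)
        assert labels[:st.n_frag_atoms] == list(st.labels[:st.n_frag_atoms])

    def test_all_labels_respect_valence(self, enc_cfg, dec_cfg, random_params,
                                        fragment_pair):
        f1, f2 = fragment_pair
        for mol, state in generate(f1, f2, random_params, enc_cfg, dec_cfg,
                                   n_samples=30, seed=3):
            mol.validate()   # includes the valence table


class TestFinalize:
    def test_connected_graph_fully_returned(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg)
        a1, a2 = sorted(st.attach)
        slots = list(range(st.n_frag_atoms, st.n_nodes))
        # chain a1 - s0 - s1 - s2 - a2
        chain = [a1] + slots + [a2]
        for u, v in zip(chain, chain[1:]):
            st.bonds.append((min(u, v), max(u, v), 1))
            st.budgets[u] -= 1
            st.budgets[v] -= 1
        labels = list(st.labels[:st.n_frag_atoms]) + ["C"] * st.n_linker
        mol = finalize(st, labels)
        assert mol.n_atoms == st.n_nodes

    def test_leftover_isolated_nodes_dropped(self, enc_cfg, dec_cfg):
        st = _fresh_state(enc_cfg, dec_cfg, n_linker=4)
        apply_action(st, ("edge", st.n_frag_atoms, 1))   # join one slot only
        labels = list(st.labels[:st.n_frag_atoms]) + ["C"] * 4
        mol = finalize(st, labels)
        # largest component = fragment_1 + one linker atom (3 atoms)
        assert mol.n_atoms == 3
        mol.validate()


class TestGenerate:
    def test_sample_count_and_determinism(self, enc_cfg, dec_cfg,
                                          random_params, fragment_pair):
        f1, f2 = fragment_pair
        out1 = generate(f1, f2, random_params, enc_cfg, dec_cfg,
                        n_samples=25, seed=11)
        out2 = generate(f1, f2, random_params, enc_cfg, dec_cfg,
                        n_samples=25, seed=11)
        assert len(out1) == 25
        assert ([write_smiles(m) for m, _ in out1]
                == [write_smiles(m) for m, _ in out2])

    def test_fragments_preserved_when_attachments_connected(
            self, enc_cfg, dec_cfg, random_params, fragment_pair):
        f1, f2 = fragment_pair
        for mol, state in generate(f1, f2, random_params, enc_cfg, dec_cfg,
                                   n_samples=40, seed=2):
            kept = set(_largest_component(state))
            if state.attach <= kept:
                assert contains_fragment(mol, f1)
                assert contains_fragment(mol, f2)

    def test_termination_within_max_steps(self, enc_cfg, dec_cfg,
                                          random_params, fragment_pair):
        f1, f2 = fragment_pair
        for _, state in generate(f1, f2, random_params, enc_cfg, dec_cfg,
                                 n_samples=20, seed=8):
            assert state.step_count <= state.max_steps
            assert not state.queue


def _largest_component(state):
    n = state.n_nodes
    adj = [[] for _ in range(n)]
    for a, b, _ in state.bonds:
        adj[a].append(b)
        adj[b].append(a)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], []
        seen.add(s)
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        comps.append(sorted(comp))
    a1 = min(state.attach)
    comps.sort(key=lambda c: (-len(c), 0 if a1 in c else 1, min(c)))
    return comps[0]


class TestGraphDistance:
    def test_matches_networkx_bfs_oracle(self, enc_cfg, dec_cfg):
        import networkx as nx
        rng = np.random.default_rng(21)
        for _ in range(50):
            st = _fresh_state(enc_cfg, dec_cfg,
                              n_linker=int(rng.integers(3, 9)))
            # random partial wiring
            for _ in range(int(rng.integers(0, 6))):
                cands = candidate_targets(st, int(rng.integers(st.n_nodes)))
                if cands:
                    v, orders = cands[int(rng.integers(len(cands)))]
                    u = int(rng.integers(st.n_nodes))
                    pair = dict(candidate_targets(st, u))
                    if v in pair and 1 in pair[v] and u != v:
                        st.bonds.append((min(u, v), max(u, v), 1))
            src = int(rng.integers(st.n_nodes))
            dist = st.graph_distances(src)
            g = nx.Graph()
            g.add_nodes_from(range(st.n_nodes))
            g.add_edges_from((a, b) for a, b, _ in st.bonds)
            lengths = nx.single_source_shortest_path_length(g, src)
            for v in range(st.n_nodes):
                if v in lengths:
                    assert dist[v] == lengths[v]
                else:
                    assert dist[v] == 20.0
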