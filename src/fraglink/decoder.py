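"""Sequential bond-by-bond linker construction under valency constraints.

Generation starts from the two intact fragments plus a set of isolated,
unlabeled linker nodes that all carry the broadcast seed vector z (plus a
small deterministic positional tag so they are distinguishable). A FIFO
focus queue, seeded with the two attachment atoms, drives construction:
the current partial graph is re-encoded by the backbone network at every
step, an edge-scoring MLP ranks all valence-feasible (target, bond order)
pairs plus a pseudo stop action through a masked softmax, and the chosen
edge is committed. When a focus node selects stop it is popped and its
unvisited neighbors join the queue. After the edge phase, a node-labeling
MLP assigns element symbols to linker nodes, masked to elements whose
valence can carry the realized bond-order sum, and the largest connected
component is returned — which makes every output valence-valid by
construction.

Linker nodes carry a provisional valence budget of 4 (the vocabulary
maximum) during edge placement; the element mask at labeling time
reconciles the final symbols with the realized bonds.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from ._autodiff import Tensor, concat, gather_rows, linear, log_softmax
from .encoder import (ATTACH_SLOT, EDGE_FEAT_DIM, NODE_FEAT_DIM,
                      UNLABELED_SLOT, EncoderConfig, InitialRepresentation,
                      _glorot, encode_fragment_pair,
                      make_initial_representation, init_backbone_params,
                      run_backbone)
from .molgraph import (ATOM_VOCAB, BOND_ORDERS, MAX_VALENCE, GraphError,
                       GraphTensors, MolGraph)

#: Graph-distance sentinel for disconnected node pairs (beyond any reachable
#: distance at this molecule scale).
DIST_SENTINEL = 20.0

#: Provisional valence budget for unlabeled linker nodes (vocabulary max, C).
LINKER_BUDGET = 4

STOP = ("stop",)

#: Decoder-side node features: the encoder's label layout plus the remaining
#: valence budget and realized bond-order sum (both scaled by the vocabulary
#: maximum), which the edge scorer needs to reason about saturation.
DEC_FEAT_DIM = NODE_FEAT_DIM + 2


@dataclass(frozen=True)
class DecoderConfig:
    mlp_hidden: int = 128
    label_hidden: int = 256
    min_linker: int = 3
    max_linker: int = 12


def phi_dim(enc_cfg: EncoderConfig) -> int:
    # s_u / s_v = [z^t row, label features, seed row z+tag, seed row * tag]
    s = enc_cfg.d_hidden + DEC_FEAT_DIM + 2 * enc_cfg.d_z
    return 2 * s + 1 + enc_cfg.d_z + enc_cfg.d_hidden + 2


def init_decoder_params(enc_cfg: EncoderConfig, dec_cfg: DecoderConfig, rng) -> dict:
    """Re-encoder backbone (prefix ``re_``) + MLP_E + MLP_N weights.

    The first MLP_E layer is stored as one weight block per feature segment
    of Phi = [s_u, s_v, d_uv, H0, Ht, D] (their vertical concatenation is the
    usual dense first-layer matrix); this lets the row-constant segments be
    projected once per step instead of once per candidate. To keep the Glorot
    fan-in correct the blocks are drawn as a single matrix and split.
    """
    re_cfg = replace(enc_cfg, d_in=enc_cfg.d_z + DEC_FEAT_DIM)
    p = init_backbone_params(re_cfg, rng, prefix="re_")
    h = dec_cfg.mlp_hidden
    s = enc_cfg.d_hidden + NODE_FEAT_DIM
    w0 = _glorot(rng, (phi_dim(enc_cfg), h)).data
    sizes = {"E_Wsu_z": enc_cfg.d_hidden, "E_Wsu_lab": DEC_FEAT_DIM,
             "E_Wsu_z0": enc_cfg.d_z, "E_Wsu_zp": enc_cfg.d_z,
             "E_Wsv_z": enc_cfg.d_hidden,
             "E_Wsvd": DEC_FEAT_DIM + 1,          # s_v label block + d_uv
             "E_Wsv_z0": enc_cfg.d_z, "E_Wsv_zp": enc_cfg.d_z,
             "E_WH0": enc_cfg.d_z, "E_WHt": enc_cfg.d_hidden, "E_WD": 2}
    off = 0
    for name, rows in sizes.items():
        p[name] = Tensor.param(w0[off:off + rows].copy())
        off += rows
    p["E_b0"] = Tensor.param(np.zeros(h))
    p["E_W1"], p["E_b1"] = _glorot(rng, (h, h)), Tensor.param(np.zeros(h))
    p["E_W2"], p["E_b2"] = _glorot(rng, (h, 4)), Tensor.param(np.zeros(4))
    lh = dec_cfg.label_hidden
    # label head sees [z^t row | seed row | seed*sin-tag | seed*cos-tag] —
    # the product terms act as per-slot selectors over the memorized latent
    p["N_W0"], p["N_b0"] = (_glorot(rng, (enc_cfg.d_hidden + 3 * enc_cfg.d_z, lh)),
                            Tensor.param(np.zeros(lh)))
    p["N_W1"], p["N_b1"] = _glorot(rng, (lh, lh)), Tensor.param(np.zeros(lh))
    p["N_W2"], p["N_b2"] = (_glorot(rng, (lh, len(ATOM_VOCAB))),
                            Tensor.param(np.zeros(len(ATOM_VOCAB))))
    return p


# --------------------------------------------------------------------------
# Decoder state
# --------------------------------------------------------------------------

class DecoderState:
    """Mutable partial graph during generation (see module docstring)."""

    def __init__(self, labels, attach, bonds, budgets, queue, n_frag_atoms,
                 n_linker, z0, frag_bonds, descriptor_D, max_steps,
                 tags=None):
        self.labels = labels            # element symbol or None per node
        self.attach = set(attach)       # the two attachment atom indices
        self.bonds = list(bonds)        # (i, j, order), i < j
        self.budgets = list(budgets)
        self.queue = deque(queue)
        self.visited = set()
        self.n_frag_atoms = n_frag_atoms
        self.n_linker = n_linker
        self.z0 = z0                    # Tensor, n x d_z
        self.frag_bonds = frozenset(frag_bonds)
        self.descriptor_D = np.asarray(descriptor_D, dtype=float)
        self.tags = tags if tags is not None else np.zeros(z0.shape)
        self.step_count = 0
        self.max_steps = max_steps
        self.truncated = False
        self.log = []

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def label_features(self) -> np.ndarray:
        x = np.zeros((self.n_nodes, DEC_FEAT_DIM))
        vocab = {s: k for k, s in enumerate(ATOM_VOCAB)}
        for i, lab in enumerate(self.labels):
            x[i, vocab[lab] if lab is not None else UNLABELED_SLOT] = 1.0
        for i in self.attach:
            x[i, ATTACH_SLOT] = 1.0
        for i in range(self.n_nodes):
            x[i, NODE_FEAT_DIM] = self.budgets[i] / LINKER_BUDGET
            x[i, NODE_FEAT_DIM + 1] = self.bond_order_sum(i) / LINKER_BUDGET
        return x

    def bond_order_sum(self, i: int) -> int:
        return sum(o for a, b, o in self.bonds if i in (a, b))

    def neighbors(self, i: int):
        return sorted(b if a == i else a for a, b, o in self.bonds if i in (a, b))

    def has_bond(self, i: int, j: int) -> bool:
        key = (min(i, j), max(i, j))
        return any((a, b) == key for a, b, _ in self.bonds)

    def graph_distances(self, source: int) -> np.ndarray:
        dist = np.full(self.n_nodes, DIST_SENTINEL)
        dist[source] = 0
        adj = [[] for _ in range(self.n_nodes)]
        for a, b, _ in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        queue = [source]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] >= DIST_SENTINEL:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        return dist


def positional_tags(n_linker: int, d: int) -> np.ndarray:
    """Deterministic sinusoidal tags distinguishing linker nodes (unit
    amplitude: isolated slots are only separable through these)."""
    k = np.arange(1, n_linker + 1)[:, None]
    j = np.arange(1, d + 1)[None, :]
    return np.sin(k * j)


def positional_tags_cos(n_linker: int, d: int) -> np.ndarray:
    """Quadrature companion of :func:`positional_tags`; together the two
    give each slot a rank-2 selector key for the label head."""
    k = np.arange(1, n_linker + 1)[:, None]
    j = np.arange(1, d + 1)[None, :]
    return np.cos(k * j)


def init_state(frag1: MolGraph, frag2: MolGraph, z, n_linker: int,
               enc_cfg: EncoderConfig, dec_cfg: DecoderConfig = DecoderConfig(),
               descriptor_D=(0.0, 0.0)) -> DecoderState:
    """Fresh decoder state: fragments intact, linker nodes isolated, focus
    queue seeded with the two attachment atoms."""
    if not dec_cfg.min_linker <= n_linker <= dec_cfg.max_linker:
        raise GraphError(
            f"n_linker {n_linker} outside [{dec_cfg.min_linker}, {dec_cfg.max_linker}]")
    for frag in (frag1, frag2):
        if len(frag.attachment_indices()) != 1:
            raise GraphError("each fragment needs exactly one attachment atom")
    n1, n2 = frag1.n_atoms, frag2.n_atoms
    n = n1 + n2 + n_linker
    labels = [sym for sym, _ in frag1.atoms] + [sym for sym, _ in frag2.atoms] \
        + [None] * n_linker
    a1 = frag1.attachment_indices()[0]
    a2 = n1 + frag2.attachment_indices()[0]
    bonds = [(a, b, o) for a, b, o in frag1.bonds]
    bonds += [(a + n1, b + n1, o) for a, b, o in frag2.bonds]
    budgets = []
    for i in range(n1):
        sym, ch = frag1.atoms[i]
        budgets.append(MAX_VALENCE[sym] - frag1.bond_order_sum(i) - abs(ch))
    for i in range(n2):
        sym, ch = frag2.atoms[i]
        budgets.append(MAX_VALENCE[sym] - frag2.bond_order_sum(i) - abs(ch))
    budgets += [LINKER_BUDGET] * n_linker
    if isinstance(z, Tensor):                      # training path: keep grads
        z0_t = Tensor(np.ones((n, 1))) @ z
    else:
        z_vec = z.z if isinstance(z, InitialRepresentation) else np.asarray(z)
        z0_t = Tensor(np.tile(z_vec, (n, 1)))
    tags = np.zeros((n, enc_cfg.d_z))
    tags[n1 + n2:] = positional_tags(n_linker, enc_cfg.d_z)
    z0_t = z0_t + Tensor(tags)
    max_steps = 2 * (n * (n - 1)) // 2
    return DecoderState(labels, {a1, a2}, bonds, budgets, [a1, a2],
                        n1 + n2, n_linker, z0_t, set(bonds), descriptor_D,
                        max_steps, tags=tags)


# --------------------------------------------------------------------------
# Tensorization of the partial graph and re-encoding
# --------------------------------------------------------------------------

def partial_graph_tensors(state: DecoderState) -> GraphTensors:
    n = state.n_nodes
    node_features = state.label_features()[:, :len(ATOM_VOCAB)]
    edges = tuple(sorted(state.bonds))
    m = len(edges)
    node_adjacency = np.zeros((3, n, n))
    edge_features = np.zeros((m, EDGE_FEAT_DIM))
    incidence = np.zeros((n, m))
    for e, (i, j, o) in enumerate(edges):
        node_adjacency[o - 1, i, j] = node_adjacency[o - 1, j, i] = 1.0
        edge_features[e, o - 1] = 1.0
        incidence[i, e] = incidence[j, e] = 1.0
    edge_adjacency = incidence.T @ incidence
    if m:
        np.fill_diagonal(edge_adjacency, 0.0)
        edge_adjacency = (edge_adjacency == 1.0).astype(float)
    return GraphTensors(node_features, node_adjacency, edge_features,
                        edge_adjacency, incidence, edges)


def reencode_core(t: GraphTensors, z0: Tensor, label_feats: np.ndarray,
                  params: dict, enc_cfg: EncoderConfig,
                  train: bool = False, rng=None) -> Tensor:
    re_cfg = replace(enc_cfg, d_in=enc_cfg.d_z + DEC_FEAT_DIM)
    feats = concat([z0, Tensor(label_feats)], axis=1)
    return run_backbone(t, feats, params, re_cfg, prefix="re_",
                        train=train, rng=rng)


def reencode(state: DecoderState, params: dict, enc_cfg: EncoderConfig,
             train: bool = False, rng=None, t: GraphTensors | None = None) -> Tensor:
    """z^t: backbone applied to [z0 | label features] over the current graph."""
    if t is None:
        t = partial_graph_tensors(state)
    return reencode_core(t, state.z0, state.label_features(), params, enc_cfg,
                         train=train, rng=rng)


# --------------------------------------------------------------------------
# Edge scoring
# --------------------------------------------------------------------------

def candidate_targets(state: DecoderState, u: int):
    """Sorted candidate nodes v and, per v, the feasible bond orders."""
    out = []
    for v in range(state.n_nodes):
        if v == u or state.has_bond(u, v):
            continue
        orders = [o for o in BOND_ORDERS
                  if state.budgets[u] >= o and state.budgets[v] >= o]
        if orders:
            out.append((v, orders))
    return out


def edge_logits_core(z_t: Tensor, z0: Tensor, u: int, cands,
                     label_feats: np.ndarray, dists: np.ndarray,
                     descriptor_D: np.ndarray, params: dict,
                     tags: np.ndarray | None = None):
    """Masked log-probabilities over (candidate v x bond order) + stop.

    Implements softmax(MLP_E([s_u, s_v, d_uv, H0, Ht, D])) with the
    first-layer product decomposed per feature segment, so the segments that
    are identical across candidate rows (s_u, H0, Ht, D) are projected once.
    Returns (actions, logprob Tensor (1 x n_actions)); actions are ordered by
    ascending (v, order) with stop last, so an argmax over the vector honors
    the lexicographic tie-break.
    """
    v_list = [v for v, _ in cands]
    nv = len(v_list)
    h0 = z0.mean(axis=0, keepdims=True)                    # 1 x d_z
    ht = z_t.mean(axis=0, keepdims=True)                   # 1 x d_hidden
    if tags is None:
        tags = np.zeros(z0.shape)
    su = gather_rows(z_t, [u])
    su_z0 = gather_rows(z0, [u])
    row_base = (linear(su, params["E_Wsu_z"])
                + linear(su_z0, params["E_Wsu_z0"])
                + linear(su_z0 * Tensor(tags[u][None, :]), params["E_Wsu_zp"])
                + linear(Tensor(label_feats[u][None, :]), params["E_Wsu_lab"])
                + linear(h0, params["E_WH0"]) + linear(ht, params["E_WHt"])
                + linear(Tensor(descriptor_D[None, :]), params["E_WD"])
                + params["E_b0"])
    if nv:
        sv = concat([gather_rows(z_t, v_list),
                     Tensor(np.zeros((1, z_t.shape[1])))], axis=0)
        sv_z0 = concat([gather_rows(z0, v_list),
                        Tensor(np.zeros((1, z0.shape[1])))], axis=0)
        sv_tags = np.vstack([tags[v_list], np.zeros((1, z0.shape[1]))])
        svd_const = np.hstack([
            np.vstack([label_feats[v_list], np.zeros((1, DEC_FEAT_DIM))]),
            np.concatenate([dists[v_list], [0.0]])[:, None]])
    else:
        sv = Tensor(np.zeros((1, z_t.shape[1])))
        sv_z0 = Tensor(np.zeros((1, z0.shape[1])))
        sv_tags = np.zeros((1, z0.shape[1]))
        svd_const = np.zeros((1, DEC_FEAT_DIM + 1))
    h1 = (linear(sv, params["E_Wsv_z"]) + linear(sv_z0, params["E_Wsv_z0"])
          + linear(sv_z0 * Tensor(sv_tags), params["E_Wsv_zp"])
          + linear(Tensor(svd_const), params["E_Wsvd"]) + row_base).relu()
    h2 = linear(h1, params["E_W1"], params["E_b1"], relu=True)
    raw = linear(h2, params["E_W2"], params["E_b2"])       # (nv+1) x 4
    flat = raw.reshape(1, -1)
    mask = np.full(4 * (nv + 1), -np.inf)
    actions = []
    flat_idx = []
    for k, (v, orders) in enumerate(cands):
        for o in orders:
            actions.append(("edge", v, o))
            flat_idx.append(4 * k + (o - 1))
    actions.append(STOP)
    flat_idx.append(4 * nv + 3)
    mask[flat_idx] = 0.0
    logprob_full = log_softmax(flat + Tensor(mask[None, :]))
    # keep only the admissible entries, in action order
    logprob = gather_rows(logprob_full.reshape(-1, 1), flat_idx).reshape(1, -1)
    return actions, logprob


def edge_logits(state: DecoderState, u: int, z_t: Tensor, params: dict,
                enc_cfg: EncoderConfig):
    """State-level wrapper around :func:`edge_logits_core`."""
    return edge_logits_core(z_t, state.z0, u, candidate_targets(state, u),
                            state.label_features(), state.graph_distances(u),
                            state.descriptor_D, params, tags=state.tags)


# --------------------------------------------------------------------------
# State transition
# --------------------------------------------------------------------------

def apply_action(state: DecoderState, action) -> None:
    """Commit one decoder decision; mirrors the focus-queue contract."""
    if not state.queue:
        raise GraphError("no focus node")
    u = state.queue[0]
    if action == STOP:
        state.queue.popleft()
        state.visited.add(u)
        for v in state.neighbors(u):
            if v not in state.visited and v not in state.queue:
                state.queue.append(v)
    else:
        _, v, order = action
        if state.has_bond(u, v) or state.budgets[u] < order or state.budgets[v] < order:
            raise GraphError(f"infeasible action {action}")
        state.bonds.append((min(u, v), max(u, v), order))
        state.budgets[u] -= order
        state.budgets[v] -= order
        if v not in state.visited and v not in state.queue:
            state.queue.append(v)
    state.step_count += 1
    state.log.append({"focus": int(u), "action": list(action)})


def step(state: DecoderState, params: dict, enc_cfg: EncoderConfig,
         policy: str = "argmax", rng=None) -> None:
    """One decode step: re-encode, score actions, select, commit."""
    if state.step_count >= state.max_steps:
        state.truncated = True
        state.queue.clear()
        return
    u = state.queue[0]
    z_t = reencode(state, params, enc_cfg)
    actions, logprob = edge_logits(state, u, z_t, params, enc_cfg)
    lp = logprob.data[0]
    if policy == "argmax":
        choice = int(np.argmax(lp))   # first max: lowest (v, order), stop last
    elif policy == "sample":
        if rng is None:
            raise ValueError("sample policy requires an rng")
        probs = np.exp(lp)
        probs /= probs.sum()
        choice = int(rng.choice(len(actions), p=probs))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    apply_action(state, actions[choice])


# --------------------------------------------------------------------------
# Node labeling and finalization
# --------------------------------------------------------------------------

def label_mask(state: DecoderState) -> np.ndarray:
    """-inf entries for elements whose valence is below the realized bond
    sum of each linker node."""
    idx = range(state.n_frag_atoms, state.n_nodes)
    mask = np.zeros((state.n_linker, len(ATOM_VOCAB)))
    for r, i in enumerate(idx):
        realized = state.bond_order_sum(i)
        for k, sym in enumerate(ATOM_VOCAB):
            if MAX_VALENCE[sym] < realized:
                mask[r, k] = -np.inf
    return mask


def node_label_logits_core(z_t: Tensor, z0: Tensor, n_frag_atoms: int,
                           n_nodes: int, mask: np.ndarray,
                           params: dict) -> Tensor:
    """MLP_N over [z^t row | seed row | seed * sin tag | seed * cos tag]."""
    idx = list(range(n_frag_atoms, n_nodes))
    n_linker = n_nodes - n_frag_atoms
    tags = positional_tags(n_linker, z0.shape[1])
    tags_c = positional_tags_cos(n_linker, z0.shape[1])
    z0_rows = gather_rows(z0, idx)
    x = concat([gather_rows(z_t, idx), z0_rows, z0_rows * Tensor(tags),
                z0_rows * Tensor(tags_c)], axis=1)
    h = linear(x, params["N_W0"], params["N_b0"], relu=True)
    h = linear(h, params["N_W1"], params["N_b1"], relu=True)
    raw = linear(h, params["N_W2"], params["N_b2"])
    return log_softmax(raw + Tensor(mask))


def node_label_logits(state: DecoderState, z_t: Tensor, params: dict):
    """Masked element log-probabilities for each linker node (n_linker x V)."""
    return node_label_logits_core(z_t, state.z0, state.n_frag_atoms,
                                  state.n_nodes, label_mask(state), params)


def predict_node_labels(state: DecoderState, params: dict,
                        enc_cfg: EncoderConfig) -> list:
    """Argmax element per linker node; fragment atoms keep their labels."""
    z_t = reencode(state, params, enc_cfg)
    lp = node_label_logits(state, z_t, params).data
    labels = list(state.labels[:state.n_frag_atoms])
    for r in range(state.n_linker):
        labels.append(ATOM_VOCAB[int(np.argmax(lp[r]))])
    return labels


def largest_component(state: DecoderState) -> list:
    """Atoms of the component finalize() will keep (largest; ties broken by
    containing the first attachment atom, then by lowest min atom index)."""
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


def finalize(state: DecoderState, labels: list) -> MolGraph:
    """Largest connected component as a MolGraph (ties: the component with
    the first fragment's attachment atom, then lowest min atom index)."""
    keep = largest_component(state)
    remap = {old: new for new, old in enumerate(keep)}
    atoms = tuple((labels[i], 0) for i in keep)
    bonds = tuple(sorted((remap[a], remap[b], o) for a, b, o in state.bonds
                         if a in remap and b in remap))
    flags = tuple(False for _ in keep)
    return MolGraph(atoms, bonds, flags).validate()


# --------------------------------------------------------------------------
# Full generation
# --------------------------------------------------------------------------

def decode(frag1: MolGraph, frag2: MolGraph, z, n_linker: int, params: dict,
           enc_cfg: EncoderConfig, dec_cfg: DecoderConfig = DecoderConfig(),
           policy: str = "argmax", rng=None,
           descriptor_D=(0.0, 0.0)) -> tuple:
    """Run one full decode; returns (MolGraph, state) for provenance."""
    state = init_state(frag1, frag2, z, n_linker, enc_cfg, dec_cfg,
                       descriptor_D)
    while state.queue:
        step(state, params, enc_cfg, policy=policy, rng=rng)
    labels = predict_node_labels(state, params, enc_cfg)
    return finalize(state, labels), state


def generate(frag1: MolGraph, frag2: MolGraph, params: dict,
             enc_cfg: EncoderConfig, dec_cfg: DecoderConfig = DecoderConfig(),
             n_samples: int = 250, seed: int = 0, n_linker: int | None = None,
             policy: str = "argmax", descriptor_D=(0.0, 0.0)) -> list:
    """Sample `n_samples` molecules for a fragment pair.

    Each sample draws z_m ~ N(0, I) (and, unless fixed, a uniform linker size
    in [min_linker, max_linker]) from a generator seeded with `seed`, so the
    output list is reproducible.
    """
    rng = np.random.default_rng(seed)
    mu_f, _, _ = encode_fragment_pair(frag1, frag2, params, enc_cfg)
    out = []
    for _ in range(n_samples):
        rep = make_initial_representation(mu_f, None, params, enc_cfg,
                                          mode="generate", rng=rng)
        nl = n_linker if n_linker is not None else int(
            rng.integers(dec_cfg.min_linker, dec_cfg.max_linker + 1))
        mol, state = decode(frag1, frag2, rep, nl, params, enc_cfg, dec_cfg,
                            policy=policy, rng=rng, descriptor_D=descriptor_D)
        out.append((mol, state))
    return out
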