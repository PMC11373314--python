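"""VAE objective and training loop with teacher forcing.

The loss is L = L_recon + beta * L_KL. The reconstruction term replays the
ground-truth edge-addition trajectory of each example through the decoder's
own state machine (breadth-first from the two attachment atoms, lower-index
targets first) and scores every masked edge/stop decision plus the final
node-label predictions by cross-entropy. The KL term is the closed-form
divergence of the molecule posterior from N(0, I), plus both fragment
posteriors at half weight. beta is warmed up linearly from 0 to 1 over the
first tenth of optimization steps — a standard stabilization for VAE
training on small datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._autodiff import (Adam, Tensor, concat, const_matmul, gather_rows,
                        layer_norm, linear, log_softmax)
from .decoder import (STOP, DecoderConfig, apply_action, candidate_targets,
                      edge_logits_core, init_decoder_params, init_state,
                      label_mask, node_label_logits_core,
                      partial_graph_tensors, reencode_core)
from .encoder import normalized_adjacency, normalized_line_adjacency
from .encoder import (EncoderConfig, encode_t, init_encoder_params,
                      make_initial_representation_t, save_checkpoint)
from .molgraph import (ATOM_VOCAB, GraphError, LinkerExample, MolGraph,
                       induced_subgraph, write_smiles)


def flag_linker_atoms(example: LinkerExample) -> MolGraph:
    """Molecule graph with the linker atoms marked in the attachment channel.

    The linker set is fully determined by the (fragment pair, molecule)
    conditioning, so flagging it adds no information beyond the example
    itself; it lets the molecule posterior concentrate on the atoms the
    decoder must actually reproduce.
    """
    mol = example.molecule
    flags = tuple(i in example.linker_atom_indices for i in range(mol.n_atoms))
    return MolGraph(mol.atoms, mol.bonds, flags)

#: Weight of each fragment's KL term relative to the molecule's.
FRAGMENT_KL_WEIGHT = 0.5


class DataError(ValueError):
    """A training example is inconsistent (bad linker set or valences)."""


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    recon: float
    kl: float
    beta: float

    def validate(self) -> "LossBreakdown":
        if not all(np.isfinite([self.total, self.recon, self.kl])):
            raise ValueError("non-finite loss")
        if self.kl < -1e-9:
            raise ValueError("negative KL")
        if abs(self.total - (self.recon + self.beta * self.kl)) > 1e-6 * max(
                1.0, abs(self.total)):
            raise ValueError("loss breakdown inconsistent")
        return self


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. The defaults are the package's canonical toy
    protocol: small batches give the many small gradient steps that
    per-example memorization needs, and the modest final KL weight keeps the
    molecule posterior informative (a full-weight KL collapses it and caps
    reconstruction accuracy)."""
    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 3e-3
    lr_final_frac: float = 0.1     # cosine decay floor (1.0 = constant lr)
    beta_final: float = 0.01
    warmup_frac: float = 0.1
    clip_norm: float = 5.0
    label_loss_weight: float = 2.0  # upweights node-label cross-entropies
    seed: int = 0
    backbone: str = "gcn"

    def validate(self) -> "TrainConfig":
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        return self


# --------------------------------------------------------------------------
# KL divergence
# --------------------------------------------------------------------------

def kl_loss(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)), summed over dims."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return float(0.5 * np.sum(mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma)))


def _kl_t(mu: Tensor, sigma: Tensor) -> Tensor:
    log_sig2 = _log(sigma * sigma)
    return (mu * mu + sigma * sigma - 1.0 - log_sig2).sum() * 0.5


def _log(t: Tensor) -> Tensor:
    out = Tensor(np.log(t.data))

    def bw(g):
        t._accumulate(g / t.data)

    return t._track(out, (t,), bw)


# --------------------------------------------------------------------------
# Ground-truth trajectory
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Decoder-frame replay of one example: fragments in decoder index
    space, the forced action sequence, and true linker-slot elements."""
    frag1: MolGraph
    frag2: MolGraph
    actions: tuple
    linker_elements: tuple
    descriptor_D: tuple


def _split_fragments(example: LinkerExample):
    """Locate the two fragment components of the molecule around the linker,
    oriented so the first matches example.fragment_1 canonically."""
    mol = example.molecule
    linker = set(example.linker_atom_indices)
    keep = [i for i in range(mol.n_atoms) if i not in linker]
    adj = {i: [] for i in keep}
    for a, b, _ in mol.bonds:
        if a in adj and b in adj:
            adj[a].append(b)
            adj[b].append(a)
    seen, comps = set(), []
    for s in keep:
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
    if len(comps) != 2:
        raise DataError(f"expected 2 fragment components, found {len(comps)}")
    exits = []
    for comp in comps:
        cset = set(comp)
        ex = sorted({a if a in cset else b for a, b, _ in mol.bonds
                     if (a in cset) != (b in cset)
                     and (a in linker or b in linker)
                     and (a in cset or b in cset)})
        if len(ex) != 1:
            raise DataError("fragment must touch the linker through one bond")
        exits.append(ex[0])
    f_a, map_a = induced_subgraph(mol, comps[0], attachment=[exits[0]])
    f_b, map_b = induced_subgraph(mol, comps[1], attachment=[exits[1]])
    want = write_smiles(example.fragment_1)
    if write_smiles(f_a) == want:
        return (f_a, map_a), (f_b, map_b)
    if write_smiles(f_b) == want:
        return (f_b, map_b), (f_a, map_a)
    raise DataError("neither component matches fragment_1")


def derive_trajectory(example: LinkerExample, enc_cfg: EncoderConfig,
                      dec_cfg: DecoderConfig = DecoderConfig()) -> Trajectory:
    """Forced action sequence reconstructing the molecule under the decoder's
    focus discipline (FIFO from the attachment atoms, ascending decoder index
    of the target, ties in bond order impossible by construction)."""
    example.validate()
    mol = example.molecule
    linker = set(example.linker_atom_indices)
    (frag1, map1), (frag2, map2) = _split_fragments(example)
    n1 = frag1.n_atoms
    dec_of_mol = {m: d for m, d in map1.items()}
    dec_of_mol.update({m: d + n1 for m, d in map2.items()})
    mol_of_dec = {d: m for m, d in dec_of_mol.items()}
    n_frag = n1 + frag2.n_atoms
    next_slot = n_frag
    # bonds still to be generated: everything touching the linker
    remaining = {(a, b, o) for a, b, o in mol.bonds
                 if a in linker or b in linker}
    state = init_state(frag1, frag2, np.zeros(enc_cfg.d_z), len(linker),
                       enc_cfg, dec_cfg)
    actions = []
    while state.queue:
        u_dec = state.queue[0]
        u_mol = mol_of_dec[u_dec]
        todo = sorted((a, b, o) for a, b, o in remaining if u_mol in (a, b))
        if not todo:
            action = STOP
        else:
            # assigned targets first (their slots are always lower than any
            # fresh slot), then unassigned ones by molecule index
            best = None
            for a, b, o in todo:
                w = b if a == u_mol else a
                key = (0, dec_of_mol[w]) if w in dec_of_mol else (1, w)
                if best is None or key < best[0]:
                    best = (key, w, o, (a, b, o))
            _, w, o, bond = best
            if w not in dec_of_mol:
                dec_of_mol[w] = next_slot
                mol_of_dec[next_slot] = w
                next_slot += 1
            action = ("edge", dec_of_mol[w], o)
            remaining.discard(bond)
        try:
            apply_action(state, action)
        except GraphError as exc:
            raise DataError(f"trajectory infeasible: {exc}") from exc
        actions.append(action)
    if remaining:
        raise DataError("molecule bonds left unplaced by the focus discipline")
    elements = tuple(mol.atoms[mol_of_dec[d]][0]
                     for d in range(n_frag, n_frag + len(linker)))
    return Trajectory(frag1, frag2, tuple(actions), elements,
                      tuple(example.descriptor_D))


# --------------------------------------------------------------------------
# Teacher-forced reconstruction loss
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _CompiledStep:
    tensors: object          # GraphTensors of the partial graph (memoized)
    label_feats: np.ndarray
    u: int
    cands: tuple
    dists: np.ndarray
    target: int              # index of the forced action


@dataclass(frozen=True)
class CompiledTrajectory:
    """Per-step constants of a forced trajectory, reusable across epochs."""
    tags: np.ndarray         # initial per-node representation offsets
    n_frag_atoms: int
    n_linker: int
    descriptor_D: np.ndarray
    steps: tuple
    final_tensors: object
    final_label_feats: np.ndarray
    final_mask: np.ndarray
    flat_label_targets: tuple
    label_targets: np.ndarray
    fast: "_FastPayload | None" = None


@dataclass(frozen=True)
class _FastPayload:
    """Block-diagonal batching of all teacher-forced steps of one example.

    Under teacher forcing every step re-encodes the same initial z over a
    known partial graph, so the T per-step graphs plus the final graph can be
    stacked into one disjoint union and pushed through the backbone in a
    single pass; candidate features are then assembled by row gathers. The
    result is numerically identical to the sequential replay (up to dropout
    draw order in train mode).
    """
    n: int                    # nodes per block
    n_steps: int
    a_big: object             # sparse normalized adjacency of the union graph
    l_big: np.ndarray         # stacked label features
    tags_big: np.ndarray
    su_idx: np.ndarray        # per candidate row, focus-node row in z_t
    sv_idx: np.ndarray        # per candidate row, target row (N -> zero row)
    sulab_const: np.ndarray
    svd_const: np.ndarray
    d_const: np.ndarray       # tiled descriptor D
    m_ht: object              # sparse per-row block-mean operator
    pad_idx: np.ndarray       # (n_steps * max_len,) into extended flat logits
    max_len: int
    sel_idx: np.ndarray       # flat index of the forced action per step
    target_pos: np.ndarray    # column of the forced action per step


def compile_trajectory(traj: Trajectory, enc_cfg: EncoderConfig,
                       dec_cfg: DecoderConfig = DecoderConfig()) -> CompiledTrajectory:
    """Replay the forced actions once, recording everything that does not
    depend on network parameters (graph tensors, candidate sets, masks)."""
    n_linker = len(traj.linker_elements)
    state = init_state(traj.frag1, traj.frag2, np.zeros(enc_cfg.d_z),
                       n_linker, enc_cfg, dec_cfg,
                       descriptor_D=traj.descriptor_D)
    tags = state.z0.data.copy()
    steps = []
    for action in traj.actions:
        u = state.queue[0]
        t = partial_graph_tensors(state)
        normalized_adjacency(t)            # prime the memo
        if enc_cfg.backbone == "censnet":
            normalized_line_adjacency(t)
        cands = tuple(candidate_targets(state, u))
        acts = [("edge", v, o) for v, orders in cands for o in orders] + [STOP]
        steps.append(_CompiledStep(t, state.label_features(), u, cands,
                                   state.graph_distances(u),
                                   acts.index(action)))
        apply_action(state, action)
    t = partial_graph_tensors(state)
    normalized_adjacency(t)
    if enc_cfg.backbone == "censnet":
        normalized_line_adjacency(t)
    vocab = {s: k for k, s in enumerate(ATOM_VOCAB)}
    flat = tuple(r * len(ATOM_VOCAB) + vocab[sym]
                 for r, sym in enumerate(traj.linker_elements))
    targets = np.array([vocab[s] for s in traj.linker_elements])
    compiled = CompiledTrajectory(tags, state.n_frag_atoms, n_linker,
                                  np.asarray(traj.descriptor_D, dtype=float),
                                  tuple(steps), t, state.label_features(),
                                  label_mask(state), flat, targets)
    if enc_cfg.backbone == "gcn":
        compiled = CompiledTrajectory(
            **{**compiled.__dict__, "fast": _build_fast_payload(compiled)})
    return compiled


def _build_fast_payload(c: CompiledTrajectory) -> _FastPayload:
    from .decoder import DEC_FEAT_DIM  # local to avoid cycle at import time
    n = c.tags.shape[0]
    t_steps = len(c.steps)
    blocks = [normalized_adjacency(st.tensors) for st in c.steps]
    blocks.append(normalized_adjacency(c.final_tensors))
    a_big = sp.block_diag(blocks, format="csr")
    l_big = np.vstack([st.label_feats for st in c.steps]
                      + [c.final_label_feats])
    tags_big = np.tile(c.tags, (t_steps + 1, 1))
    nf = DEC_FEAT_DIM
    su_idx, sv_idx, sulab, svd, ht_rows = [], [], [], [], []
    pad_rows, sel_idx, target_pos = [], [], []
    row = 0
    zero_row = n * (t_steps + 1)          # index of the appended zero row
    lens = []
    for s, st in enumerate(c.steps):
        off = s * n
        flat_ids = []
        for v, orders in st.cands:
            su_idx.append(off + st.u)
            sv_idx.append(off + v)
            sulab.append(st.label_feats[st.u])
            svd.append(np.concatenate([st.label_feats[v], [st.dists[v]]]))
            ht_rows.append(s)
            for o in orders:
                flat_ids.append(4 * row + (o - 1))
            row += 1
        # stop row: s_u with zeroed s_v and d
        su_idx.append(off + st.u)
        sv_idx.append(zero_row)
        sulab.append(st.label_feats[st.u])
        svd.append(np.zeros(nf + 1))
        ht_rows.append(s)
        flat_ids.append(4 * row + 3)
        row += 1
        pad_rows.append(flat_ids)
        target_pos.append(st.target)
        lens.append(len(flat_ids))
    n_rows = row
    max_len = max(lens)
    sentinel = 4 * n_rows                  # points at the appended -inf
    pad_idx = np.full((t_steps, max_len), sentinel, dtype=np.intp)
    for s, ids in enumerate(pad_rows):
        pad_idx[s, :len(ids)] = ids
    sel_idx = np.array([s * max_len + target_pos[s] for s in range(t_steps)],
                       dtype=np.intp)
    # per-candidate-row block-mean operator (H^t of the row's step)
    data = np.full(n_rows * n, 1.0 / n)
    cols = np.concatenate([np.arange(s * n, (s + 1) * n) for s in ht_rows])
    indptr = np.arange(0, n_rows * n + 1, n)
    m_ht = sp.csr_matrix((data, cols, indptr),
                         shape=(n_rows, n * (t_steps + 1)))
    return _FastPayload(n, t_steps, a_big, l_big, tags_big,
                        np.array(su_idx, dtype=np.intp),
                        np.array(sv_idx, dtype=np.intp),
                        np.array(sulab), np.array(svd),
                        np.tile(c.descriptor_D, (n_rows, 1)), m_ht,
                        pad_idx.ravel(), max_len, sel_idx,
                        np.array(target_pos, dtype=np.intp))


def _fast_recon_loss(c: CompiledTrajectory, z: Tensor, params: dict,
                     enc_cfg: EncoderConfig, train: bool, rng,
                     label_weight: float = 1.0):
    """Batched equivalent of the sequential teacher-forced replay.

    Returns (loss Tensor, n_decisions, n_correct) exactly as the sequential
    path does (identical numbers in eval mode; dropout draw order differs in
    train mode).
    """
    f = c.fast
    drop = enc_cfg.dropout if train else 0.0
    n_total = f.n * (f.n_steps + 1)
    z0_small = Tensor(np.ones((f.n, 1))) @ z + Tensor(c.tags)
    z0_big = Tensor(np.ones((n_total, 1))) @ z + Tensor(f.tags_big)
    # one backbone pass over the disjoint union of all step graphs
    from ._autodiff import gcn_matmul
    h = concat([z0_big, Tensor(f.l_big)], axis=1)
    for k in range(3):
        h = gcn_matmul(f.a_big, h, params[f"re_W{k}"]).relu()
        h = layer_norm(h, params[f"re_ln{k}_g"], params[f"re_ln{k}_b"])
        if drop > 0.0 and rng is not None:
            keep = (rng.random(h.shape) >= drop) / (1.0 - drop)
            h = h * Tensor(keep)
    z_t = h
    z_t_ext = concat([z_t, Tensor(np.zeros((1, z_t.shape[1])))], axis=0)
    # first MLP_E layer assembled per feature segment
    h0 = z0_small.mean(axis=0, keepdims=True)
    z0_big_ext = concat([z0_big, Tensor(np.zeros((1, z0_big.shape[1])))], axis=0)
    tags_ext = np.vstack([f.tags_big, np.zeros((1, f.tags_big.shape[1]))])
    z0p_big_ext = z0_big_ext * Tensor(tags_ext)
    h1 = (linear(gather_rows(z_t_ext, f.su_idx), params["E_Wsu_z"])
          + linear(gather_rows(z0_big_ext, f.su_idx), params["E_Wsu_z0"])
          + linear(gather_rows(z0p_big_ext, f.su_idx), params["E_Wsu_zp"])
          + linear(Tensor(f.sulab_const), params["E_Wsu_lab"])
          + linear(gather_rows(z_t_ext, f.sv_idx), params["E_Wsv_z"])
          + linear(gather_rows(z0_big_ext, f.sv_idx), params["E_Wsv_z0"])
          + linear(gather_rows(z0p_big_ext, f.sv_idx), params["E_Wsv_zp"])
          + linear(Tensor(f.svd_const), params["E_Wsvd"])
          + linear(const_matmul(f.m_ht, z_t), params["E_WHt"])
          + linear(h0, params["E_WH0"])
          + linear(Tensor(f.d_const), params["E_WD"])
          + params["E_b0"]).relu()
    h2 = linear(h1, params["E_W1"], params["E_b1"], relu=True)
    raw = linear(h2, params["E_W2"], params["E_b2"])
    flat = concat([raw.reshape(-1, 1), Tensor([[-np.inf]])], axis=0)
    padded = gather_rows(flat, f.pad_idx).reshape(f.n_steps, f.max_len)
    lp = log_softmax(padded)
    edge_loss = -(gather_rows(lp.reshape(-1, 1), f.sel_idx).sum())
    n_ok = int((np.argmax(lp.data, axis=1) == f.target_pos).sum())
    # node labeling on the final block
    linker_rows = np.arange(f.n_steps * f.n + c.n_frag_atoms,
                            f.n_steps * f.n + f.n)
    from .decoder import positional_tags, positional_tags_cos
    lab_z0 = gather_rows(z0_big, linker_rows)
    lab_tags = positional_tags(f.n - c.n_frag_atoms, z0_big.shape[1])
    lab_tags_c = positional_tags_cos(f.n - c.n_frag_atoms, z0_big.shape[1])
    lab_x = concat([gather_rows(z_t, linker_rows), lab_z0,
                    lab_z0 * Tensor(lab_tags),
                    lab_z0 * Tensor(lab_tags_c)], axis=1)
    lab_h = linear(lab_x, params["N_W0"], params["N_b0"], relu=True)
    lab_h = linear(lab_h, params["N_W1"], params["N_b1"], relu=True)
    lab_lp = log_softmax(linear(lab_h, params["N_W2"], params["N_b2"])
                         + Tensor(c.final_mask))
    label_loss = -(gather_rows(lab_lp.reshape(-1, 1),
                               list(c.flat_label_targets)).sum()) * label_weight
    n_ok += int((np.argmax(lab_lp.data, axis=1) == c.label_targets).sum())
    loss = edge_loss + label_loss
    return loss, f.n_steps + c.n_linker, n_ok


def teacher_forced_recon_loss(example_or_traj, params: dict,
                              enc_cfg: EncoderConfig,
                              dec_cfg: DecoderConfig = DecoderConfig(),
                              rng=None, train: bool = False,
                              z_seed: Tensor | None = None,
                              compiled: CompiledTrajectory | None = None,
                              label_weight: float = 1.0):
    """(loss Tensor, n_decisions, n_correct) for one example.

    `z_seed` (1 x d_z) lets the caller supply the reparameterized decoder
    seed; when omitted a zero seed is used (useful for unit analysis). The
    loss sums the cross-entropy of every masked edge/stop decision along the
    forced trajectory plus the masked node-label cross-entropies. Passing a
    precompiled trajectory skips the bookkeeping replay.
    """
    if compiled is None:
        traj = (example_or_traj if isinstance(example_or_traj, Trajectory)
                else derive_trajectory(example_or_traj, enc_cfg, dec_cfg))
        compiled = compile_trajectory(traj, enc_cfg, dec_cfg)
    c = compiled
    z = z_seed if z_seed is not None else Tensor(np.zeros((1, enc_cfg.d_z)))
    if c.fast is not None:
        return _fast_recon_loss(c, z, params, enc_cfg, train, rng,
                                label_weight=label_weight)
    n = c.tags.shape[0]
    z0 = Tensor(np.ones((n, 1))) @ z + Tensor(c.tags)
    losses = []
    n_dec = n_ok = 0
    for st in c.steps:
        z_t = reencode_core(st.tensors, z0, st.label_feats, params, enc_cfg,
                            train=train, rng=rng)
        _, logprob = edge_logits_core(z_t, z0, st.u, st.cands, st.label_feats,
                                      st.dists, c.descriptor_D, params,
                                      tags=c.tags)
        onehot = np.zeros((1, logprob.shape[1]))
        onehot[0, st.target] = 1.0
        losses.append(-(logprob * Tensor(onehot)).sum())
        n_dec += 1
        n_ok += int(np.argmax(logprob.data[0]) == st.target)
    # final re-encode of the completed graph for node labeling
    z_t = reencode_core(c.final_tensors, z0, c.final_label_feats, params,
                        enc_cfg, train=train, rng=rng)
    lp = node_label_logits_core(z_t, z0, c.n_frag_atoms, n, c.final_mask,
                                params)
    # pick the target entry per row (flat gather: -inf entries never selected)
    losses.append(-(gather_rows(lp.reshape(-1, 1),
                                list(c.flat_label_targets))).sum()
                  * label_weight)
    n_dec += c.n_linker
    n_ok += int((np.argmax(lp.data, axis=1) == c.label_targets).sum())
    total = losses[0]
    for term in losses[1:]:
        total = total + term
    return total, n_dec, n_ok


def example_loss(traj: Trajectory, molecule: MolGraph, params: dict,
                 enc_cfg: EncoderConfig, dec_cfg: DecoderConfig,
                 rng, train: bool = True,
                 compiled: CompiledTrajectory | None = None,
                 label_weight: float = 1.0):
    """Full per-example objective pieces: (recon Tensor, kl Tensor, n, ok)."""
    mu1, sig1 = encode_t(traj.frag1, params, enc_cfg, train=train, rng=rng)
    mu2, sig2 = encode_t(traj.frag2, params, enc_cfg, train=train, rng=rng)
    mu_f = (mu1 + mu2) * 0.5
    mu_m, sig_m = encode_t(molecule, params, enc_cfg, train=train, rng=rng,
                           head="molecule")
    z = make_initial_representation_t(mu_f, mu_m, sig_m, params, enc_cfg, rng)
    recon, n, ok = teacher_forced_recon_loss(traj, params, enc_cfg, dec_cfg,
                                             rng=rng, train=train, z_seed=z,
                                             compiled=compiled,
                                             label_weight=label_weight)
    kl = _kl_t(mu_m, sig_m) + (_kl_t(mu1, sig1) + _kl_t(mu2, sig2)) * FRAGMENT_KL_WEIGHT
    return recon, kl, n, ok


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    params: dict
    enc_cfg: EncoderConfig
    dec_cfg: DecoderConfig
    history: list = field(default_factory=list)   # LossBreakdown per epoch
    accuracy: list = field(default_factory=list)  # per-decision accuracy


def train(dataset, cfg: TrainConfig, enc_cfg: EncoderConfig | None = None,
          dec_cfg: DecoderConfig = DecoderConfig(),
          checkpoint_path=None, log=None) -> TrainResult:
    """Optimize the VAE objective on a list of LinkerExamples.

    Fully seeded: parameter init, batch order, dropout and reparameterization
    draws all derive from cfg.seed, so identical configs reproduce identical
    loss curves on a single thread.
    """
    cfg.validate()
    if not dataset:
        raise DataError("empty dataset")
    enc_cfg = enc_cfg or EncoderConfig(backbone=cfg.backbone)
    if enc_cfg.backbone != cfg.backbone:
        enc_cfg = EncoderConfig(backbone=cfg.backbone)
    rng = np.random.default_rng(cfg.seed)
    params = {**init_encoder_params(enc_cfg, rng),
              **init_decoder_params(enc_cfg, dec_cfg, rng)}
    trajs = [derive_trajectory(ex, enc_cfg, dec_cfg) for ex in dataset]
    compiled = [compile_trajectory(tr, enc_cfg, dec_cfg) for tr in trajs]
    flagged = [flag_linker_atoms(ex) for ex in dataset]
    opt = Adam(params, lr=cfg.learning_rate, clip_norm=cfg.clip_norm)
    n_steps_total = cfg.epochs * int(np.ceil(len(dataset) / cfg.batch_size))
    warm = max(1, int(cfg.warmup_frac * n_steps_total))
    result = TrainResult(params, enc_cfg, dec_cfg)
    step_idx = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        ep_recon = ep_kl = ep_betakl = 0.0
        ep_n = ep_ok = 0
        for start in range(0, len(dataset), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            beta = cfg.beta_final * min(1.0, step_idx / warm)
            frac = 0.5 * (1.0 + np.cos(np.pi * step_idx / max(1, n_steps_total)))
            opt.lr = cfg.learning_rate * (cfg.lr_final_frac
                                          + (1.0 - cfg.lr_final_frac) * frac)
            opt.zero_grad()
            recon_sum = kl_sum = None
            for i in batch:
                recon, kl, n, ok = example_loss(
                    trajs[i], flagged[i], params, enc_cfg, dec_cfg,
                    rng, compiled=compiled[i],
                    label_weight=cfg.label_loss_weight)
                recon_sum = recon if recon_sum is None else recon_sum + recon
                kl_sum = kl if kl_sum is None else kl_sum + kl
                ep_n += n
                ep_ok += ok
            loss = recon_sum + beta * kl_sum
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            loss.backward(np.ones_like(loss.data) / len(batch))
            opt.step()
            ep_recon += float(recon_sum.data)
            ep_kl += float(kl_sum.data)
            ep_betakl += beta * float(kl_sum.data)
            step_idx += 1
        n_ex = len(dataset)
        # effective beta so that total = recon + beta * kl holds exactly
        beta_eff = ep_betakl / ep_kl if ep_kl > 0 else beta
        bd = LossBreakdown((ep_recon + ep_betakl) / n_ex, ep_recon / n_ex,
                           ep_kl / n_ex, beta_eff).validate()
        result.history.append(bd)
        result.accuracy.append(ep_ok / ep_n)
        if log is not None:
            log(epoch, bd, ep_ok / ep_n)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, params, enc_cfg,
                        {"decoder": dec_cfg.__dict__, "train": cfg.__dict__})
    return result


def decision_accuracy(dataset, result: TrainResult) -> float:
    """Teacher-forced per-decision accuracy of a trained model, evaluated at
    the posterior mean z_m = mu_m (the canonical reconstruction seed)."""
    n = ok = 0
    rng = np.random.default_rng(0)
    for ex in dataset:
        traj = derive_trajectory(ex, result.enc_cfg, result.dec_cfg)
        mu1, _ = encode_t(traj.frag1, result.params, result.enc_cfg)
        mu2, _ = encode_t(traj.frag2, result.params, result.enc_cfg)
        mu_m, sig_m = encode_t(flag_linker_atoms(ex), result.params,
                               result.enc_cfg, head="molecule")
        zero_sig = Tensor(np.zeros_like(sig_m.data))
        z = make_initial_representation_t((mu1 + mu2) * 0.5, mu_m, zero_sig,
                                          result.params, result.enc_cfg, rng)
        _, nd, nok = teacher_forced_recon_loss(traj, result.params,
                                               result.enc_cfg, result.dec_cfg,
                                               z_seed=z)
        n += nd
        ok += nok
    return ok / n
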