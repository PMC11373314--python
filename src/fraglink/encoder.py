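"""Graph encoders producing latent Gaussians and the decoder's seed vector.

Two backbones are supported. A plain GCN propagates node features through the
symmetric-normalized adjacency with self-loops. CensNet-style layers
additionally carry edge embeddings: the node layer modulates neighbor
aggregation by a learned scalar per edge (routed through the incidence
matrix), and the edge layer propagates edge embeddings over the line graph,
modulated by endpoint node embeddings. Every layer applies layer
normalization and (in train mode) dropout.

A whole graph is encoded by mean-pooling node embeddings and projecting to
(mu, log sigma). A fragment pair is encoded per fragment and averaged. The
decoder seed is z = mu_f + a_f * [z_m, tau], where z_m is drawn from the
molecule posterior during training or from N(0, I) at generation time, and
tau is a linear lift of z_m to the remaining width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autodiff import Tensor, concat, gcn_matmul, layer_norm, linear
from .molgraph import ATOM_VOCAB, GraphError, GraphTensors, MolGraph, to_tensors

#: Node feature layout: one-hot element | "unlabeled" slot | attachment flag.
NODE_FEAT_DIM = len(ATOM_VOCAB) + 2
UNLABELED_SLOT = len(ATOM_VOCAB)
ATTACH_SLOT = len(ATOM_VOCAB) + 1
EDGE_FEAT_DIM = 3


@dataclass(frozen=True)
class LatentEncoding:
    """Diagonal Gaussian over the latent space: mu and elementwise sigma > 0."""
    mu: np.ndarray
    sigma: np.ndarray

    def validate(self) -> "LatentEncoding":
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("latent encoding must be finite")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        return self


@dataclass(frozen=True)
class InitialRepresentation:
    """Decoder seed z = mu_f + a_f * [z_m, tau] (broadcast per-node later)."""
    z: np.ndarray
    z_m: np.ndarray
    tau: np.ndarray
    a_f: float


@dataclass(frozen=True)
class EncoderConfig:
    backbone: str = "gcn"        # {"gcn", "censnet"}
    d_in: int = NODE_FEAT_DIM
    d_hidden: int = 64
    d_z: int = 32
    d_m: int = 24
    dropout: float = 0.05

    def validate(self) -> "EncoderConfig":
        if self.backbone not in ("gcn", "censnet"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not 0 < self.d_m < self.d_z:
            raise ValueError("need 0 < d_m < d_z")
        return self


# --------------------------------------------------------------------------
# Features and propagation matrices
# --------------------------------------------------------------------------

def node_input_features(g: MolGraph) -> np.ndarray:
    vocab = {s: k for k, s in enumerate(ATOM_VOCAB)}
    x = np.zeros((g.n_atoms, NODE_FEAT_DIM))
    for i, (sym, _) in enumerate(g.atoms):
        x[i, vocab[sym]] = 1.0
    for i in g.attachment_indices():
        x[i, ATTACH_SLOT] = 1.0
    return x


def normalized_adjacency(t: GraphTensors) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops, D^-1/2 (A+I) D^-1/2.

    Memoized on the (immutable) GraphTensors instance, since decoding
    re-encodes the same partial graph several times per step.
    """
    cached = t.__dict__.get("_a_hat")
    if cached is not None:
        return cached
    a = t.node_adjacency.sum(axis=0) + np.eye(t.node_features.shape[0])
    d = a.sum(axis=1)
    inv = 1.0 / np.sqrt(d)
    a_hat = a * inv[:, None] * inv[None, :]
    object.__setattr__(t, "_a_hat", a_hat)
    return a_hat


def normalized_line_adjacency(t: GraphTensors) -> np.ndarray:
    cached = t.__dict__.get("_a_e_hat")
    if cached is not None:
        return cached
    m = t.edge_adjacency.shape[0]
    a = t.edge_adjacency + np.eye(m)
    d = a.sum(axis=1)
    inv = 1.0 / np.sqrt(d)
    a_hat = a * inv[:, None] * inv[None, :]
    object.__setattr__(t, "_a_e_hat", a_hat)
    return a_hat


def _dropout(h: Tensor, rate: float, rng) -> Tensor:
    if rate <= 0.0 or rng is None:
        return h
    keep = (rng.random(h.shape) >= rate) / (1.0 - rate)
    return h * Tensor(keep)


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

def gcn_layer(t: GraphTensors, h, w: Tensor, ln: tuple | None = None,
              activation: str = "relu", dropout: float = 0.0, rng=None) -> Tensor:
    """One GCN propagation: act(D^-1/2 (A+I) D^-1/2 H W), then LN/dropout."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    if h.shape[1] != w.shape[0]:
        raise ValueError(f"shape mismatch: h {h.shape} vs w {w.shape}")
    out = gcn_matmul(normalized_adjacency(t), h, w)
    if activation == "relu":
        out = out.relu()
    if ln is not None:
        out = layer_norm(out, ln[0], ln[1])
    return _dropout(out, dropout, rng)


def censnet_node_layer(t: GraphTensors, h_v, h_e, w: Tensor, p: Tensor,
                       ln: tuple | None = None, activation: str = "relu",
                       dropout: float = 0.0, rng=None) -> Tensor:
    """Node update modulated by learned per-edge scalars s = h_e @ p:
    act(((T diag(s) T^T + I) o A_hat) H_v W). With no edges this reduces to
    the self-loop term act(H_v W) (up to normalization)."""
    h_v = h_v if isinstance(h_v, Tensor) else Tensor(h_v)
    h_e = h_e if isinstance(h_e, Tensor) else Tensor(h_e)
    if h_v.shape[1] != w.shape[0] or h_e.shape[1] != p.shape[0]:
        raise ValueError("shape mismatch in censnet node layer")
    n = h_v.shape[0]
    a_hat = Tensor(normalized_adjacency(t))
    if t.edge_features.shape[0] > 0:
        s = h_e @ p                                   # (m, 1)
        tm = Tensor(t.incidence)
        mod = (tm * _row(s)) @ Tensor(t.incidence.T) + Tensor(np.eye(n))
    else:
        mod = Tensor(np.eye(n))
    out = (mod * a_hat) @ h_v @ w
    if activation == "relu":
        out = out.relu()
    if ln is not None:
        out = layer_norm(out, ln[0], ln[1])
    return _dropout(out, dropout, rng)


def censnet_edge_layer(t: GraphTensors, h_v, h_e, w: Tensor, q: Tensor,
                       ln: tuple | None = None, activation: str = "relu",
                       dropout: float = 0.0, rng=None) -> Tensor:
    """Edge update over the line graph, modulated by endpoint node scalars
    r = h_v @ q: act(((T^T diag(r) T + I) o A_e_hat) H_e W)."""
    h_v = h_v if isinstance(h_v, Tensor) else Tensor(h_v)
    h_e = h_e if isinstance(h_e, Tensor) else Tensor(h_e)
    if h_e.shape[1] != w.shape[0] or h_v.shape[1] != q.shape[0]:
        raise ValueError("shape mismatch in censnet edge layer")
    m = h_e.shape[0]
    if m == 0:
        return h_e
    a_hat = Tensor(normalized_line_adjacency(t))
    r = h_v @ q                                       # (n, 1)
    tm = Tensor(t.incidence.T)
    mod = (tm * _row(r)) @ Tensor(t.incidence) + Tensor(np.eye(m))
    out = (mod * a_hat) @ h_e @ w
    if activation == "relu":
        out = out.relu()
    if ln is not None:
        out = layer_norm(out, ln[0], ln[1])
    return _dropout(out, dropout, rng)


def _row(v: Tensor) -> Tensor:
    """(k, 1) column tensor viewed as a broadcastable (k,) row."""
    return v.sum(axis=1)  # column vector -> 1-D, keeps gradient


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

def _glorot(rng, shape) -> Tensor:
    scale = np.sqrt(6.0 / (shape[0] + shape[1]))
    return Tensor.param(rng.uniform(-scale, scale, size=shape))


def _ln_pair(d: int) -> tuple:
    return Tensor.param(np.ones(d)), Tensor.param(np.zeros(d))


def init_backbone_params(cfg: EncoderConfig, rng, prefix: str = "") -> dict:
    """Weights for one 3-layer backbone column mapping d_in -> d_hidden."""
    h = cfg.d_hidden
    p: dict = {}
    if cfg.backbone == "gcn":
        dims = [cfg.d_in, h, h, h]
        for k in range(3):
            p[f"{prefix}W{k}"] = _glorot(rng, (dims[k], dims[k + 1]))
            p[f"{prefix}ln{k}_g"], p[f"{prefix}ln{k}_b"] = _ln_pair(dims[k + 1])
    else:  # two node layers around one edge layer
        p[f"{prefix}Wv0"] = _glorot(rng, (cfg.d_in, h))
        p[f"{prefix}p0"] = _glorot(rng, (EDGE_FEAT_DIM, 1))
        p[f"{prefix}lnv0_g"], p[f"{prefix}lnv0_b"] = _ln_pair(h)
        p[f"{prefix}We0"] = _glorot(rng, (EDGE_FEAT_DIM, h))
        p[f"{prefix}q0"] = _glorot(rng, (h, 1))
        p[f"{prefix}lne0_g"], p[f"{prefix}lne0_b"] = _ln_pair(h)
        p[f"{prefix}Wv1"] = _glorot(rng, (h, h))
        p[f"{prefix}p1"] = _glorot(rng, (h, 1))
        p[f"{prefix}lnv1_g"], p[f"{prefix}lnv1_b"] = _ln_pair(h)
    return p


def init_encoder_params(cfg: EncoderConfig, rng) -> dict:
    cfg.validate()
    p = init_backbone_params(cfg, rng)
    h = cfg.d_hidden
    p["W_mu"] = _glorot(rng, (h, cfg.d_z))
    p["b_mu"] = Tensor.param(np.zeros(cfg.d_z))
    p["W_sig"] = _glorot(rng, (h, cfg.d_z))
    p["b_sig"] = Tensor.param(np.zeros(cfg.d_z))
    # molecule head: the sampled seed z_m lives in the narrower d_m space
    p["W_mu_m"] = _glorot(rng, (h, cfg.d_m))
    p["b_mu_m"] = Tensor.param(np.zeros(cfg.d_m))
    p["W_sig_m"] = _glorot(rng, (h, cfg.d_m))
    p["b_sig_m"] = Tensor.param(np.zeros(cfg.d_m))
    p["W_tau"] = _glorot(rng, (cfg.d_m, cfg.d_z - cfg.d_m))
    p["b_tau"] = Tensor.param(np.zeros(cfg.d_z - cfg.d_m))
    p["a_f"] = Tensor.param(np.array(1.0))
    return p


def run_backbone(t: GraphTensors, x, params: dict, cfg: EncoderConfig,
                 prefix: str = "", train: bool = False, rng=None) -> Tensor:
    """Apply the configured backbone column to node inputs x; returns node
    embeddings (n x d_hidden)."""
    drop = cfg.dropout if train else 0.0
    if cfg.backbone == "gcn":
        h = x
        for k in range(3):
            h = gcn_layer(t, h, params[f"{prefix}W{k}"],
                          (params[f"{prefix}ln{k}_g"], params[f"{prefix}ln{k}_b"]),
                          dropout=drop, rng=rng)
        return h
    h_v = censnet_node_layer(t, x, Tensor(t.edge_features),
                             params[f"{prefix}Wv0"], params[f"{prefix}p0"],
                             (params[f"{prefix}lnv0_g"], params[f"{prefix}lnv0_b"]),
                             dropout=drop, rng=rng)
    h_e = censnet_edge_layer(t, h_v, Tensor(t.edge_features),
                             params[f"{prefix}We0"], params[f"{prefix}q0"],
                             (params[f"{prefix}lne0_g"], params[f"{prefix}lne0_b"]),
                             dropout=drop, rng=rng)
    return censnet_node_layer(t, h_v, h_e,
                              params[f"{prefix}Wv1"], params[f"{prefix}p1"],
                              (params[f"{prefix}lnv1_g"], params[f"{prefix}lnv1_b"]),
                              dropout=drop, rng=rng)


# --------------------------------------------------------------------------
# Graph-level encoding
# --------------------------------------------------------------------------

def encode_t(g: MolGraph, params: dict, cfg: EncoderConfig,
             train: bool = False, rng=None, head: str = "fragment") -> tuple:
    """(mu, sigma) as Tensors, for use inside the training graph.

    `head` selects the projection: fragments encode into the full d_z space,
    molecules into the narrower d_m space their sampled seed z_m lives in.
    """
    if g.n_atoms == 0:
        raise GraphError("cannot encode an empty graph")
    if head not in ("fragment", "molecule"):
        raise ValueError(f"unknown head {head!r}")
    t = to_tensors(g)
    h = run_backbone(t, Tensor(node_input_features(g)), params, cfg,
                     train=train, rng=rng)
    pooled = h.mean(axis=0, keepdims=True)            # 1 x d_hidden
    suffix = "" if head == "fragment" else "_m"
    mu = pooled @ params["W_mu" + suffix] + params["b_mu" + suffix]
    sigma = (pooled @ params["W_sig" + suffix] + params["b_sig" + suffix]).exp()
    return mu, sigma


def encode(g: MolGraph, params: dict, cfg: EncoderConfig,
           head: str = "fragment") -> LatentEncoding:
    """Deterministic graph-level diagonal Gaussian (eval mode, no dropout)."""
    mu, sigma = encode_t(g, params, cfg, head=head)
    return LatentEncoding(mu.data[0].copy(), sigma.data[0].copy()).validate()


def encode_fragment_pair(frag1: MolGraph, frag2: MolGraph, params: dict,
                         cfg: EncoderConfig) -> tuple:
    """mu_f (average of the two fragment means) plus both fragment encodings."""
    e1 = encode(frag1, params, cfg)
    e2 = encode(frag2, params, cfg)
    return 0.5 * (e1.mu + e2.mu), e1, e2


def make_initial_representation(mu_f, enc_m, params: dict, cfg: EncoderConfig,
                                mode: str = "generate",
                                rng=None) -> InitialRepresentation:
    """Decoder seed per z = mu_f + a_f * [z_m, tau(z_m)].

    In train mode z_m is a reparameterized draw from the molecule posterior
    (enc_m required); at generation time z_m ~ N(0, I). `rng` seeds the draw.
    """
    if mode not in ("train", "generate"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "train" and enc_m is None:
        raise ValueError("train mode requires the molecule encoding")
    rng = rng or np.random.default_rng()
    eps = rng.standard_normal(cfg.d_m)
    if mode == "train":
        z_m = enc_m.mu + enc_m.sigma * eps
    else:
        z_m = eps
    tau = z_m @ params["W_tau"].data + params["b_tau"].data
    a_f = float(params["a_f"].data)
    z = mu_f + a_f * np.concatenate([z_m, tau])
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite initial representation")
    return InitialRepresentation(z, z_m, tau, a_f)


def make_initial_representation_t(mu_f_t: Tensor, mu_m_t: Tensor,
                                  sigma_m_t: Tensor, params: dict,
                                  cfg: EncoderConfig, rng) -> Tensor:
    """Differentiable train-mode seed (1 x d_z Tensor)."""
    eps = Tensor(rng.standard_normal((1, cfg.d_m)))
    z_m = mu_m_t + sigma_m_t * eps
    tau = z_m @ params["W_tau"] + params["b_tau"]
    return mu_f_t + params["a_f"] * concat([z_m, tau], axis=1)


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, params: dict, cfg: EncoderConfig,
                    extra_cfg: dict | None = None) -> None:
    arrays = {k: p.data for k, p in params.items()}
    meta = {"encoder": asdict(cfg), "extra": extra_cfg or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: Tensor.param(data[k].copy()) for k in data.files
                  if k != "__meta__"}
    cfg = EncoderConfig(**meta["encoder"]).validate()
    return params, cfg, meta["extra"]
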