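"""Controllable generation: latent density, attribute classifiers, rejection.

The generative model alone samples linkers unconditionally. To steer it, an
explicit density Q(z) (a diagonal-covariance Gaussian mixture) is fitted over
the latent embeddings of known molecules, and one probabilistic binary
classifier per attribute predicts, from a latent point z together with the
encoded fragment pair mu_f, whether the decoded molecule will satisfy that
attribute's threshold. Sampling then draws z ~ Q and accepts with probability
equal to the product of the attribute scores (attributes are treated as
conditionally independent given z); only accepted latents are decoded. This
is classical rejection sampling from an approximation of p(z | all
attributes pass), and concentrates generation on promising latent regions at
the cost of extra draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.neural_network import MLPClassifier

from .decoder import DecoderConfig, decode
from .encoder import EncoderConfig, encode, encode_fragment_pair

#: Default attribute thresholds for drug-likeness, synthesizability, potency.
DEFAULT_THRESHOLDS = {"qed": (0.6, "greater"), "sa": (3.0, "less"),
                      "pic50": (6.0, "greater")}


class CGMError(ValueError):
    """Invalid controllable-generation configuration or inputs."""


# --------------------------------------------------------------------------
# Latent density
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentDensity:
    """Diagonal-covariance Gaussian mixture over the latent space."""
    weights: np.ndarray
    means: np.ndarray        # k x d
    covariances: np.ndarray  # k x d (diagonal entries)

    @property
    def k(self) -> int:
        return len(self.weights)

    def validate(self) -> "LatentDensity":
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise CGMError("mixture weights must sum to 1")
        if np.any(self.covariances <= 0):
            raise CGMError("covariances must be positive")
        return self

    def sample(self, n: int, rng) -> np.ndarray:
        """Seeded draws (component choice and normals both from `rng`)."""
        comps = rng.choice(self.k, size=n, p=self.weights)
        eps = rng.standard_normal((n, self.means.shape[1]))
        return self.means[comps] + eps * np.sqrt(self.covariances[comps])

    def log_pdf(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        d = z.shape[1]
        diff = z[:, None, :] - self.means[None, :, :]
        expo = -0.5 * (diff ** 2 / self.covariances[None]).sum(-1)
        norm = -0.5 * (d * np.log(2 * np.pi)
                       + np.log(self.covariances).sum(-1))
        comp = expo + norm[None, :] + np.log(self.weights)[None, :]
        m = comp.max(axis=1, keepdims=True)
        return (m + np.log(np.exp(comp - m).sum(axis=1, keepdims=True)))[:, 0]


def fit_density(latents: np.ndarray, k: int = 10, seed: int = 0) -> LatentDensity:
    """EM fit of a k-component diagonal Gaussian mixture, seeded.

    Near-degenerate dimensions get a stronger variance floor (with a
    warning) so EM stays stable.
    """
    latents = np.asarray(latents, dtype=float)
    if latents.shape[0] <= k:
        raise CGMError(f"need more than k={k} samples, got {latents.shape[0]}")
    reg = 1e-9
    if np.any(latents.var(axis=0) < 1e-12):
        warnings.warn("near-zero variance in latents; applying variance floor")
        reg = 1e-6
    gm = GaussianMixture(n_components=k, covariance_type="diag",
                         random_state=seed, reg_covar=reg, n_init=1,
                         max_iter=200)
    gm.fit(latents)
    return LatentDensity(gm.weights_.copy(), gm.means_.copy(),
                         gm.covariances_.copy()).validate()


def select_components_bic(latents: np.ndarray, k_max: int = 10,
                          seed: int = 0) -> int:
    """Smallest-BIC component count in 1..k_max."""
    latents = np.asarray(latents, dtype=float)
    best_k, best_bic = 1, np.inf
    for k in range(1, k_max + 1):
        if latents.shape[0] <= k:
            break
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             random_state=seed, reg_covar=1e-9).fit(latents)
        bic = gm.bic(latents)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


# --------------------------------------------------------------------------
# Attribute classifiers
# --------------------------------------------------------------------------

class FunctionClassifier:
    """Wrap an arbitrary score function z -> [0, 1] as a classifier
    (used for analytic acceptance rules and in tests)."""

    def __init__(self, fn):
        self.fn = fn

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = np.clip(np.asarray([self.fn(row) for row in np.atleast_2d(x)],
                               dtype=float), 0.0, 1.0)
        return np.column_stack([1.0 - p, p])


@dataclass(frozen=True)
class AttributeSpec:
    """One controllable attribute: name, threshold, direction, and (after
    training) the classifier scoring P(attribute satisfied | z, mu_f)."""
    name: str
    threshold: float
    direction: str                       # {"greater", "less"}
    classifier: object | None = None
    train_accuracy: float | None = None
    uses_fragment: bool = True

    def validate(self) -> "AttributeSpec":
        if self.direction not in ("greater", "less"):
            raise CGMError(f"direction must be greater/less, got {self.direction!r}")
        return self

    def passes(self, value: float) -> bool:
        return value > self.threshold if self.direction == "greater" \
            else value < self.threshold

    def score(self, z: np.ndarray, fragment_mu: np.ndarray | None) -> np.ndarray:
        if self.classifier is None:
            raise CGMError(f"attribute {self.name!r} has no trained classifier")
        z = np.atleast_2d(z)
        if self.uses_fragment and fragment_mu is not None:
            x = np.hstack([z, np.tile(np.atleast_2d(fragment_mu), (len(z), 1))])
        else:
            x = z
        return self.classifier.predict_proba(x)[:, 1]


def train_attribute_classifier(latents: np.ndarray, fragment_mus: np.ndarray,
                               labels: np.ndarray, spec: AttributeSpec,
                               family: str = "logistic",
                               seed: int = 0) -> AttributeSpec:
    """Fit a probabilistic classifier on concat(z, mu_f) -> pass/fail."""
    spec.validate()
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise CGMError(f"attribute {spec.name!r}: both classes required")
    x = np.hstack([np.asarray(latents, dtype=float),
                   np.asarray(fragment_mus, dtype=float)])
    if family == "logistic":
        clf = LogisticRegression(max_iter=2000, C=100.0, random_state=seed)
    elif family == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(32,), max_iter=1000,
                            random_state=seed)
    else:
        raise CGMError(f"unknown classifier family {family!r}")
    clf.fit(x, labels)
    acc = float((clf.predict(x) == labels).mean())
    return replace(spec, classifier=clf, train_accuracy=acc)


def acceptance_probability(z: np.ndarray, fragment_mu: np.ndarray | None,
                           specs) -> np.ndarray:
    """Product of attribute scores: P(accept | z) = prod_i q(a_i | z)."""
    specs = list(specs)
    if not specs:
        raise CGMError("at least one attribute spec required")
    p = np.ones(len(np.atleast_2d(z)))
    for spec in specs:
        p = p * spec.score(z, fragment_mu)
    return p


# --------------------------------------------------------------------------
# Rejection sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RejectionResult:
    samples: np.ndarray
    scores: np.ndarray       # acceptance probability of each accepted sample
    n_draws: int
    acceptance_rate: float
    exhausted: bool


def rejection_sample(density: LatentDensity, specs, n_accept: int,
                     seed: int = 0, max_draws: int = 100_000,
                     fragment_mu: np.ndarray | None = None,
                     chunk: int = 256) -> RejectionResult:
    """Draw z ~ Q, accept with Bernoulli(prod of attribute scores), until
    `n_accept` accepted or `max_draws` exhausted (partial result + warning)."""
    if n_accept < 1:
        raise CGMError("n_accept must be >= 1")
    rng = np.random.default_rng(seed)
    accepted, scores = [], []
    n_draws = 0
    while len(accepted) < n_accept and n_draws < max_draws:
        m = min(chunk, max_draws - n_draws)
        z = density.sample(m, rng)
        p = acceptance_probability(z, fragment_mu, specs)
        keep = rng.random(m) < p
        accepted.extend(z[keep])
        scores.extend(p[keep])
        n_draws += m
    exhausted = len(accepted) < n_accept
    if exhausted:
        warnings.warn(f"rejection sampling exhausted {max_draws} draws with "
                      f"{len(accepted)}/{n_accept} accepted")
    samples = np.array(accepted[:n_accept]) if accepted else \
        np.empty((0, density.means.shape[1]))
    scores = np.array(scores[:n_accept]) if scores else np.empty(0)
    rate = (len(accepted) / n_draws) if n_draws else 0.0
    return RejectionResult(samples, scores, n_draws, rate, exhausted)


# --------------------------------------------------------------------------
# End-to-end controlled generation
# --------------------------------------------------------------------------

def seed_from_zm(mu_f: np.ndarray, z_m: np.ndarray, params: dict,
                 enc_cfg: EncoderConfig) -> np.ndarray:
    """Decoder seed z = mu_f + a_f * [z_m, tau(z_m)] for a given latent."""
    tau = z_m @ params["W_tau"].data + params["b_tau"].data
    return mu_f + float(params["a_f"].data) * np.concatenate([z_m, tau])


def controlled_generate(frag1, frag2, params: dict, enc_cfg: EncoderConfig,
                        dec_cfg: DecoderConfig, density: LatentDensity,
                        specs, n_molecules: int, seed: int = 0,
                        max_draws: int = 100_000,
                        descriptor_D=(0.0, 0.0)) -> tuple:
    """Decode rejection-accepted latents for one fragment pair.

    Returns (molecules, provenance log): the log records, per molecule, the
    latent's acceptance score and the cumulative draw count spent."""
    specs = [s.validate() for s in specs]
    if not specs:
        raise CGMError("controlled generation requires at least one attribute"
                       " (use plain generation for random sampling)")
    mu_f, _, _ = encode_fragment_pair(frag1, frag2, params, enc_cfg)
    rej = rejection_sample(density, specs, n_molecules, seed=seed,
                           max_draws=max_draws, fragment_mu=mu_f)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2 ** 31))
    mols, log = [], []
    for i, z_m in enumerate(rej.samples):
        z = seed_from_zm(mu_f, z_m, params, enc_cfg)
        nl = int(rng.integers(dec_cfg.min_linker, dec_cfg.max_linker + 1))
        mol, state = decode(frag1, frag2, z, nl, params, enc_cfg, dec_cfg,
                            policy="argmax", descriptor_D=descriptor_D)
        mols.append(mol)
        log.append({"index": i, "acceptance_score": float(rej.scores[i]),
                    "n_linker": nl, "steps": state.step_count,
                    "truncated": state.truncated})
    meta = {"n_draws": rej.n_draws, "acceptance_rate": rej.acceptance_rate,
            "exhausted": rej.exhausted}
    return mols, {"per_molecule": log, **meta}


def build_known_molecule_table(dataset, params: dict, enc_cfg: EncoderConfig,
                               activity_fn=None) -> dict:
    """Latent/property table over the known molecules themselves.

    Each training molecule contributes its posterior-mean latent, the
    encoded fragment pair, and its true properties (stored activity label
    when present, otherwise `activity_fn`). This is the primary classifier
    training set: the latents are exactly the cloud the density model is
    fitted over, so rejection sampling evaluates the classifiers
    in-distribution.
    """
    from .metrics import chem_filters
    z = molecule_latents(dataset, params, enc_cfg)
    mu_f, qed, sa, act, smiles = [], [], [], [], []
    from .molgraph import write_smiles
    for ex in dataset:
        mu_f.append(encode_fragment_pair(ex.fragment_1, ex.fragment_2,
                                         params, enc_cfg)[0])
        cf = chem_filters(ex.molecule)
        qed.append(cf.qed)
        sa.append(cf.sa_score)
        if ex.activity is not None:
            act.append(ex.activity)
        elif activity_fn is not None:
            act.append(activity_fn(ex.molecule))
        else:
            act.append(np.nan)
        smiles.append(write_smiles(ex.molecule))
    return {"z": z, "mu_f": np.array(mu_f), "qed": np.array(qed),
            "sa": np.array(sa), "activity": np.array(act), "smiles": smiles}


def build_cgm_training_set(dataset, params: dict, enc_cfg: EncoderConfig,
                           dec_cfg: DecoderConfig, n_samples: int,
                           seed: int = 0, activity_fn=None) -> dict:
    """Latent/property table from prior-decoded samples (secondary).

    Draws (fragment pair, z_m ~ N(0, I)) combinations from the dataset's
    pairs, decodes each latent with the trained model, and records the
    decoded molecule's QED, SA score and activity. Useful for auditing the
    decode map; classifiers trained on it carry much weaker signal than the
    known-molecule table, because a linear probe rarely recovers properties
    of the nonlinear decode of an unstructured prior draw.
    """
    from .metrics import chem_filters          # local import avoids a cycle
    from .molgraph import write_smiles
    rng = np.random.default_rng(seed)
    mu_cache = {}
    rows = {"z": [], "mu_f": [], "qed": [], "sa": [], "activity": [],
            "smiles": []}
    for _ in range(n_samples):
        ex = dataset[int(rng.integers(len(dataset)))]
        key = id(ex)
        if key not in mu_cache:
            mu_cache[key] = encode_fragment_pair(ex.fragment_1, ex.fragment_2,
                                                 params, enc_cfg)[0]
        mu_f = mu_cache[key]
        z_m = rng.standard_normal(enc_cfg.d_m)
        z = seed_from_zm(mu_f, z_m, params, enc_cfg)
        nl = int(rng.integers(dec_cfg.min_linker, dec_cfg.max_linker + 1))
        mol, _ = decode(ex.fragment_1, ex.fragment_2, z, nl, params, enc_cfg,
                        dec_cfg, policy="argmax")
        cf = chem_filters(mol)
        rows["z"].append(z_m)
        rows["mu_f"].append(mu_f)
        rows["qed"].append(cf.qed)
        rows["sa"].append(cf.sa_score)
        rows["activity"].append(activity_fn(mol) if activity_fn else np.nan)
        rows["smiles"].append(write_smiles(mol))
    return {"z": np.array(rows["z"]), "mu_f": np.array(rows["mu_f"]),
            "qed": np.array(rows["qed"]), "sa": np.array(rows["sa"]),
            "activity": np.array(rows["activity"]), "smiles": rows["smiles"]}


def fit_attribute_classifiers(table: dict, specs, seed: int = 0,
                              family: str = "logistic") -> list:
    """Train one classifier per attribute from a build_cgm_training_set
    table; attribute names must be keys of the table (qed, sa, activity)."""
    fitted = []
    for spec in specs:
        key = "activity" if spec.name in ("pic50", "activity") else spec.name
        if key not in table:
            raise CGMError(f"no column {key!r} for attribute {spec.name!r}")
        values = np.asarray(table[key], dtype=float)
        labels = np.array([spec.passes(v) for v in values])
        fitted.append(train_attribute_classifier(table["z"], table["mu_f"],
                                                 labels, spec, family=family,
                                                 seed=seed))
    return fitted


def molecule_latents(dataset, params: dict, enc_cfg: EncoderConfig) -> np.ndarray:
    """Posterior means (d_m) of the training molecules — the 'known molecule'
    cloud the density model is fitted over. Molecules are encoded with their
    linker atoms flagged, exactly as during training."""
    from .training import flag_linker_atoms
    return np.vstack([encode(flag_linker_atoms(ex), params, enc_cfg,
                             head="molecule").mu
                      for ex in dataset])
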