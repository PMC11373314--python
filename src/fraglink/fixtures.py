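"""Synthetic fragment-linker datasets and a deterministic activity oracle.

Real fragment-linking corpora are built by double-cutting large libraries of
drug-like molecules and keeping linkers of 3-12 atoms. This module emulates
that structure at toy scale: random valence-respecting molecules (random
trees over a drug-like element mix, with occasional 5/6-membered ring
closures) are double-cut with :func:`fraglink.molgraph.fragment_molecule`,
and one example per parent molecule is kept. A deterministic surrogate
potency stands in for measured pIC50 labels, so that property classifiers
have a learnable, reproducible ground truth.

The defaults are deliberately heteroatom-rich so that both the drug-likeness
(QED > 0.6) and surrogate-potency (> 6) thresholds split any reasonably
sized dataset into two non-empty classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molgraph import (MAX_VALENCE, GraphError, LinkerExample, MolGraph,
                       fragment_molecule)

#: Default element sampling weights (heteroatom-rich drug-like mix).
DEFAULT_ELEMENT_WEIGHTS = {
    "C": 0.50, "N": 0.21, "O": 0.21, "F": 0.02, "S": 0.04, "Cl": 0.01, "Br": 0.01,
}


class ConfigError(ValueError):
    """Toy-dataset configuration is unsatisfiable."""


@dataclass(frozen=True)
class ToyDatasetConfig:
    n_examples: int
    seed: int = 0
    min_heavy_atoms: int = 8
    max_heavy_atoms: int = 20
    ring_closure_prob: float = 0.2
    element_weights: dict = field(default_factory=lambda: dict(DEFAULT_ELEMENT_WEIGHTS))

    def validate(self) -> "ToyDatasetConfig":
        if self.n_examples < 1:
            raise ConfigError("n_examples must be >= 1")
        if self.max_heavy_atoms < 5:
            raise ConfigError("max_heavy_atoms < 5 cannot host a 3-atom linker")
        if self.min_heavy_atoms < 5 or self.min_heavy_atoms > self.max_heavy_atoms:
            raise ConfigError("need 5 <= min_heavy_atoms <= max_heavy_atoms")
        total = sum(self.element_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"element weights sum to {total}, expected 1")
        for sym in self.element_weights:
            if sym not in MAX_VALENCE:
                raise ConfigError(f"element {sym!r} outside vocabulary")
        return self


def surrogate_activity(g: MolGraph) -> float:
    """Deterministic pseudo-pIC50 in [4, 8]: 4 + 4 * heteroatom fraction.

    Counts N and O among heavy atoms; invariant under atom relabeling, which
    makes it an exact, overfitting-free stand-in for a measured potency.
    """
    if g.n_atoms == 0:
        raise GraphError("surrogate activity undefined for an empty graph")
    het = sum(1 for sym, _ in g.atoms if sym in ("N", "O"))
    return 4.0 + 4.0 * het / g.n_atoms


def _graph_distances(n: int, bonds, source: int) -> list:
    adj = [[] for _ in range(n)]
    for a, b, _ in bonds:
        adj[a].append(b)
        adj[b].append(a)
    dist = [-1] * n
    dist[source] = 0
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        queue = nxt
    return dist


def random_molecule(rng: np.random.Generator, cfg: ToyDatasetConfig) -> MolGraph:
    """One random valence-valid molecule under the config's element mix."""
    n = int(rng.integers(cfg.min_heavy_atoms, cfg.max_heavy_atoms + 1))
    symbols = list(cfg.element_weights)
    weights = np.array([cfg.element_weights[s] for s in symbols])
    while True:
        syms = [str(s) for s in rng.choice(symbols, size=n, p=weights)]
        budget = [MAX_VALENCE[s] for s in syms]
        bonds = []
        ok = True
        for i in range(1, n):
            cands = [a for a in range(i) if budget[a] >= 1]
            if not cands or budget[i] < 1:
                ok = False
                break
            a = int(rng.choice(cands))
            bonds.append((a, i, 1))
            budget[a] -= 1
            budget[i] -= 1
        if not ok:
            continue
        # occasional 5/6-membered ring closure between distance-4/5 atoms
        if rng.random() < cfg.ring_closure_prob:
            open_atoms = [a for a in range(n) if budget[a] >= 1]
            rng.shuffle(open_atoms)
            done = False
            for x in open_atoms:
                dist = _graph_distances(n, bonds, x)
                ys = [y for y in open_atoms if dist[y] in (4, 5)]
                if ys:
                    y = min(ys)
                    bonds.append((min(x, y), max(x, y), 1))
                    budget[x] -= 1
                    budget[y] -= 1
                    done = True
                if done:
                    break
        g = MolGraph(tuple((s, 0) for s in syms), tuple(sorted(bonds)),
                     tuple(False for _ in range(n)))
        return g.validate()


def generate_toy_dataset(cfg: ToyDatasetConfig):
    """Seeded list of `cfg.n_examples` LinkerExamples with activity labels.

    One example (uniformly chosen among its double cuts) per random parent
    molecule; parents with no admissible double cut are discarded.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = []
    while len(out) < cfg.n_examples:
        mol = random_molecule(rng, cfg)
        examples = fragment_molecule(mol)
        if not examples:
            continue
        ex = examples[int(rng.integers(len(examples)))]
        ex = LinkerExample(ex.fragment_1, ex.fragment_2, ex.molecule,
                           ex.linker_atom_indices, ex.descriptor_D,
                           activity=surrogate_activity(ex.molecule))
        out.append(ex.validate())
    return out
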