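"""Molecular graph data model, SMILES I/O, tensorization and fragmentation.

`MolGraph` is the package's universal currency: a kekulized, hydrogen-implicit
labeled graph over a small drug-like element vocabulary, with per-atom
attachment flags marking fragment exit atoms (written as ``*`` dummy atoms in
SMILES). RDKit handles parsing, canonicalization and writing; everything else
(valence accounting, line-graph tensorization, double-cut fragmentation) is
explicit here because the generative model needs to manipulate these
structures incrementally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: Element vocabulary: covers most of drug-like chemical space while keeping
#: the one-hot encoding small.
ATOM_VOCAB: tuple = ("C", "N", "O", "F", "S", "Cl", "Br")

#: Maximum bond-order sum per element (neutral, organic subset; divalent S).
MAX_VALENCE: dict = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "Cl": 1, "Br": 1}

BOND_ORDERS: tuple = (1, 2, 3)

_RDKIT_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


class ParseError(ValueError):
    """SMILES string could not be parsed."""


class VocabularyError(ValueError):
    """Molecule contains an element outside the configured vocabulary."""


class GraphError(ValueError):
    """A MolGraph invariant is violated."""


@dataclass(frozen=True)
class MolGraph:
    """Labeled molecular graph with implicit hydrogens.

    atoms: per-atom (element symbol, formal charge);
    bonds: (i, j, order) with i < j, at most one bond per pair;
    attachment_flags: marks fragment exit atoms (where a bond was cut).
    """

    atoms: tuple
    bonds: tuple
    attachment_flags: tuple

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bond_order_sum(self, i: int) -> int:
        return sum(o for a, b, o in self.bonds if i in (a, b))

    def neighbors(self, i: int):
        return sorted(b if a == i else a for a, b, o in self.bonds if i in (a, b))

    def attachment_indices(self):
        return [i for i, f in enumerate(self.attachment_flags) if f]

    def validate(self) -> "MolGraph":
        n = self.n_atoms
        if len(self.attachment_flags) != n:
            raise GraphError("attachment_flags length mismatch")
        seen = set()
        for a, b, o in self.bonds:
            if a == b:
                raise GraphError(f"self-loop on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise GraphError(f"bond ({a},{b}) out of range")
            if o not in BOND_ORDERS:
                raise GraphError(f"bond order {o} not in {BOND_ORDERS}")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise GraphError(f"duplicate bond {key}")
            seen.add(key)
        for i, (sym, charge) in enumerate(self.atoms):
            if sym not in MAX_VALENCE:
                raise VocabularyError(f"element {sym!r} outside vocabulary")
            if self.bond_order_sum(i) + abs(charge) > MAX_VALENCE[sym]:
                raise GraphError(
                    f"atom {i} ({sym}) exceeds valence {MAX_VALENCE[sym]}")
        return self


@dataclass(frozen=True)
class LinkerExample:
    """One fragment-linking record: two exit-flagged fragments, the parent
    molecule, which of its atoms form the linker, and an optional 2-vector
    3D descriptor (exit-atom distance in Angstrom, exit-vector angle in rad;
    zeros when no conformer is available)."""

    fragment_1: MolGraph
    fragment_2: MolGraph
    molecule: MolGraph
    linker_atom_indices: frozenset
    descriptor_D: tuple = (0.0, 0.0)
    activity: float | None = None

    def validate(self) -> "LinkerExample":
        if len(self.fragment_1.attachment_indices()) != 1:
            raise GraphError("fragment_1 must have exactly one attachment atom")
        if len(self.fragment_2.attachment_indices()) != 1:
            raise GraphError("fragment_2 must have exactly one attachment atom")
        if not 3 <= len(self.linker_atom_indices) <= 12:
            raise GraphError("linker size must be within [3, 12]")
        n_frag = self.fragment_1.n_atoms + self.fragment_2.n_atoms
        if n_frag + len(self.linker_atom_indices) != self.molecule.n_atoms:
            raise GraphError("fragment + linker atoms must partition the molecule")
        return self


@dataclass(frozen=True)
class GraphTensors:
    """Dense tensor view of a MolGraph, including the line-graph structures
    node-edge co-embedding convolutions need. Edges are ordered as sorted
    (min, max) index pairs."""

    node_features: np.ndarray   # n_atoms x |ATOM_VOCAB| one-hot
    node_adjacency: np.ndarray  # 3 x n x n, one symmetric 0/1 matrix per order
    edge_features: np.ndarray   # n_edges x 3 one-hot over bond order
    edge_adjacency: np.ndarray  # line-graph adjacency, n_edges x n_edges
    incidence: np.ndarray       # n_atoms x n_edges membership
    edge_list: tuple            # ((i, j, order), ...) in canonical order


# --------------------------------------------------------------------------
# SMILES I/O
# --------------------------------------------------------------------------

def _from_rdkit(mol: Chem.Mol, attachment: set) -> MolGraph:
    atoms = tuple((a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = int(round(b.GetBondTypeAsDouble()))
        bonds.append((min(i, j), max(i, j), order))
    flags = tuple(i in attachment for i in range(mol.GetNumAtoms()))
    return MolGraph(atoms, tuple(sorted(bonds)), flags).validate()


def parse_smiles(smiles: str) -> MolGraph:
    """Parse a SMILES string into a kekulized MolGraph in canonical atom order.

    ``*`` dummy atoms are removed and their neighbors flagged as attachment
    points. Re-parsing the written form of the result yields the same graph.
    """
    if not smiles:
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    # drop dummy atoms, remembering their neighbors as attachment points
    rw = Chem.RWMol(mol)
    dummy = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
    attach_neighbors = set()
    for d in dummy:
        for nb in rw.GetAtomWithIdx(d).GetNeighbors():
            if nb.GetAtomicNum() != 0:
                attach_neighbors.add(nb.GetIdx())
    for d in sorted(dummy, reverse=True):
        rw.RemoveAtom(d)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Exception as exc:  # rdkit raises several sanitization types
        raise ParseError(f"cannot sanitize SMILES {smiles!r}: {exc}") from exc
    for a in mol.GetAtoms():
        if a.GetSymbol() not in MAX_VALENCE:
            raise VocabularyError(
                f"element {a.GetSymbol()!r} in {smiles!r} outside vocabulary")
    # renumber into canonical rank order so parsing is deterministic
    # (dummies shift indices, so recompute attachment set through the map)
    old_attach = {i for i, a in enumerate(mol.GetAtoms())
                  if i in _shift_indices(attach_neighbors, dummy)}
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = [0] * mol.GetNumAtoms()
    for old_idx, rank in enumerate(ranks):
        order[rank] = old_idx
    mol = Chem.RenumberAtoms(mol, order)
    new_attach = {ranks[i] for i in old_attach}
    return _from_rdkit(mol, new_attach)


def _shift_indices(indices: set, removed: list) -> set:
    removed = sorted(removed)
    out = set()
    for i in indices:
        out.add(i - sum(1 for d in removed if d < i))
    return out


def to_rdkit(g: MolGraph, with_dummies: bool = False) -> Chem.Mol:
    """Build a sanitized RDKit molecule; optionally re-attach ``*`` dummies."""
    rw = Chem.RWMol()
    for sym, charge in g.atoms:
        a = Chem.Atom(sym)
        a.SetFormalCharge(charge)
        rw.AddAtom(a)
    for i, j, o in g.bonds:
        rw.AddBond(i, j, _RDKIT_BOND[o])
    if with_dummies:
        for i in g.attachment_indices():
            d = rw.AddAtom(Chem.Atom(0))
            rw.AddBond(i, d, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _plain_rdkit(g: MolGraph) -> Chem.Mol:
    """RDKit molecule with explicit kekulized orders and no aromatic flags,
    for order-exact substructure matching."""
    rw = Chem.RWMol()
    for sym, charge in g.atoms:
        a = Chem.Atom(sym)
        a.SetFormalCharge(charge)
        rw.AddAtom(a)
    for i, j, o in g.bonds:
        rw.AddBond(i, j, _RDKIT_BOND[o])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL
                     ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
                     ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    return mol


def contains_fragment(mol: MolGraph, frag: MolGraph) -> bool:
    """True when `frag` (ignoring attachment flags) occurs in `mol` as a
    subgraph with identical elements and bond orders. Matching is performed
    on the kekulized graphs, so aromaticity perception of the assembled
    molecule cannot hide a preserved fragment."""
    return _plain_rdkit(mol).HasSubstructMatch(_plain_rdkit(frag))


def write_smiles(g: MolGraph) -> str:
    """Canonical SMILES for a MolGraph; attachment atoms written as ``*``."""
    if g.n_atoms == 0:
        raise GraphError("cannot write SMILES of an empty graph")
    return Chem.MolToSmiles(to_rdkit(g, with_dummies=True))


# --------------------------------------------------------------------------
# Tensorization
# --------------------------------------------------------------------------

def to_tensors(g: MolGraph) -> GraphTensors:
    n = g.n_atoms
    vocab_index = {s: k for k, s in enumerate(ATOM_VOCAB)}
    node_features = np.zeros((n, len(ATOM_VOCAB)))
    for i, (sym, _) in enumerate(g.atoms):
        node_features[i, vocab_index[sym]] = 1.0
    edges = tuple(sorted((min(i, j), max(i, j), o) for i, j, o in g.bonds))
    m = len(edges)
    node_adjacency = np.zeros((3, n, n))
    edge_features = np.zeros((m, 3))
    incidence = np.zeros((n, m))
    for e, (i, j, o) in enumerate(edges):
        node_adjacency[o - 1, i, j] = node_adjacency[o - 1, j, i] = 1.0
        edge_features[e, o - 1] = 1.0
        incidence[i, e] = incidence[j, e] = 1.0
    # line graph: edges adjacent iff they share exactly one endpoint
    edge_adjacency = incidence.T @ incidence
    np.fill_diagonal(edge_adjacency, 0.0)
    edge_adjacency = (edge_adjacency == 1.0).astype(float)
    return GraphTensors(node_features, node_adjacency, edge_features,
                        edge_adjacency, incidence, edges)


def valence_remaining(g: MolGraph, atom: int) -> int:
    if not 0 <= atom < g.n_atoms:
        raise GraphError(f"atom index {atom} out of range")
    sym, charge = g.atoms[atom]
    return MAX_VALENCE[sym] - g.bond_order_sum(atom) - abs(charge)


# --------------------------------------------------------------------------
# Double-cut fragmentation
# --------------------------------------------------------------------------

def _components(n: int, bonds) -> list:
    """Connected components (sorted lists) of a graph given by `bonds`."""
    adj = [[] for _ in range(n)]
    for a, b, _ in bonds:
        adj[a].append(b)
        adj[b].append(a)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _acyclic_single_bonds(g: MolGraph) -> list:
    """Single-order bonds not in any ring (i.e. bridges of the simple graph)."""
    out = []
    for idx, (a, b, o) in enumerate(g.bonds):
        if o != 1:
            continue
        remaining = [bd for k, bd in enumerate(g.bonds) if k != idx]
        comps = _components(g.n_atoms, remaining)
        if len(comps) > len(_components(g.n_atoms, g.bonds)):
            out.append(idx)
    return out


def induced_subgraph(g: MolGraph, atom_set, attachment=()):
    """Induced subgraph on `atom_set`; returns (MolGraph, old->new index map)."""
    atoms_sorted = sorted(atom_set)
    remap = {old: new for new, old in enumerate(atoms_sorted)}
    atoms = tuple(g.atoms[i] for i in atoms_sorted)
    bonds = tuple(sorted((remap[a], remap[b], o) for a, b, o in g.bonds
                         if a in remap and b in remap))
    flags = tuple(i in set(attachment) for i in atoms_sorted)
    return MolGraph(atoms, bonds, flags).validate(), remap


def fragment_molecule(g: MolGraph, min_linker: int = 3, max_linker: int = 12):
    """Enumerate double cuts of acyclic single bonds into (frag1, linker, frag2).

    Every ordered pair of distinct acyclic single bonds whose removal yields
    exactly three connected components, with the middle (linker) component of
    `min_linker`..`max_linker` atoms, produces one LinkerExample; results are
    deduplicated by the canonical SMILES of the (fragment_1, fragment_2,
    molecule) triple.
    """
    g.validate()
    cut_bonds = _acyclic_single_bonds(g)
    base_comps = len(_components(g.n_atoms, g.bonds))
    out, seen = [], set()
    for b1 in cut_bonds:
        for b2 in cut_bonds:
            if b1 == b2:
                continue
            remaining = [bd for k, bd in enumerate(g.bonds) if k not in (b1, b2)]
            comps = _components(g.n_atoms, remaining)
            if len(comps) != base_comps + 2:
                continue
            a1, c1, _ = g.bonds[b1]
            a2, c2, _ = g.bonds[b2]
            comp_of = {}
            for ci, comp in enumerate(comps):
                for at in comp:
                    comp_of[at] = ci
            # middle component touches both cut bonds
            ends1 = {comp_of[a1], comp_of[c1]}
            ends2 = {comp_of[a2], comp_of[c2]}
            middle = ends1 & ends2
            if len(middle) != 1:
                continue
            mid = middle.pop()
            linker = set(comps[mid])
            if not min_linker <= len(linker) <= max_linker:
                continue
            f1_comp = (ends1 - {mid}).pop()
            f2_comp = (ends2 - {mid}).pop()
            if f1_comp == f2_comp:
                continue
            exit1 = a1 if comp_of[a1] == f1_comp else c1
            exit2 = a2 if comp_of[a2] == f2_comp else c2
            frag1, _ = induced_subgraph(g, comps[f1_comp], attachment=[exit1])
            frag2, _ = induced_subgraph(g, comps[f2_comp], attachment=[exit2])
            ex = LinkerExample(frag1, frag2, g, frozenset(linker)).validate()
            key = (write_smiles(frag1), write_smiles(frag2), write_smiles(g))
            if key in seen:
                continue
            seen.add(key)
            out.append(ex)
    return out


# --------------------------------------------------------------------------
# Dataset files
# --------------------------------------------------------------------------

def write_dataset(examples, path) -> None:
    """Write LinkerExamples to CSV. Linker indices refer to the canonical atom
    order of the molecule SMILES, so the file round-trips exactly."""
    rows = []
    for ex in examples:
        # canonical order of a validated molecule equals its re-parse order
        mol_smi = write_smiles(ex.molecule)
        reparsed = parse_smiles(mol_smi)
        linker = _match_linker_indices(ex, reparsed)
        rows.append({
            "fragment_1_smiles": write_smiles(ex.fragment_1),
            "fragment_2_smiles": write_smiles(ex.fragment_2),
            "molecule_smiles": mol_smi,
            "linker_indices": " ".join(str(i) for i in sorted(linker)),
            "dist": ex.descriptor_D[0],
            "angle": ex.descriptor_D[1],
            "activity": "" if ex.activity is None else ex.activity,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def _match_linker_indices(ex: LinkerExample, reparsed: MolGraph) -> set:
    """Map the example's linker atom set onto the canonical re-parse order."""
    if reparsed == ex.molecule:
        return set(ex.linker_atom_indices)
    mol = to_rdkit(ex.molecule)
    target = to_rdkit(reparsed)
    match = target.GetSubstructMatch(mol)  # match[old] = new
    if len(match) != ex.molecule.n_atoms:
        raise GraphError("molecule does not map onto its canonical form")
    return {match[i] for i in ex.linker_atom_indices}


def read_dataset(path):
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        act = row.get("activity")
        ex = LinkerExample(
            fragment_1=parse_smiles(row["fragment_1_smiles"]),
            fragment_2=parse_smiles(row["fragment_2_smiles"]),
            molecule=parse_smiles(row["molecule_smiles"]),
            linker_atom_indices=frozenset(
                int(t) for t in str(row["linker_indices"]).split()),
            descriptor_D=(float(row.get("dist", 0.0)), float(row.get("angle", 0.0))),
            activity=None if pd.isna(act) else float(act),
        )
        out.append(ex.validate())
    return out
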