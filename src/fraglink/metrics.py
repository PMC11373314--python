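"""Evaluation of generated molecule sets.

Structural usefulness is measured by validity (parseable, valence-valid, and
containing both input fragments as substructures — the fragment-linking
convention), uniqueness (distinct canonical SMILES among valid molecules)
and novelty (unique valid molecules absent from the training set). Chemical
usefulness uses three filters: synthetic accessibility (Ertl
fragment-contribution SA score, pass when SA < 3), ring aromaticity (no
double bond inside a non-aromatic ring) and PAINS (no pan-assay
interference substructure match). Property pass rates report, for a set of
thresholded attributes (drug-likeness QED, SA, and an activity value from a
caller-supplied predictor), the fraction passing each condition and their
conjunction.
"""

from __future__ import annotations

import os
import sys
import warnings
from dataclasses import dataclass, field

from rdkit import Chem, RDConfig
from rdkit.Chem import QED, FilterCatalog

from .molgraph import (MolGraph, ParseError, contains_fragment, parse_smiles,
                       to_rdkit, write_smiles)

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (shipped with rdkit's Contrib tree)

_pains_params = FilterCatalog.FilterCatalogParams()
_pains_params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
_PAINS = FilterCatalog.FilterCatalog(_pains_params)

#: Default §-style property thresholds: QED > 0.6, SA < 3, activity > 6.
DEFAULT_THRESHOLDS = {"qed": (0.6, "greater"), "sa": (3.0, "less"),
                      "activity": (6.0, "greater")}


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ChemFilterResult:
    sa_score: float
    sa_pass: bool
    aromatic_ring_pass: bool
    pains_pass: bool
    qed: float


@dataclass(frozen=True)
class EvalReport:
    validity: float
    uniqueness: float
    novelty: float
    sa_pass: float
    aromatic_ring_pass: float
    pains_pass: float
    property_pass_rates: dict = field(default_factory=dict)
    n_generated: int = 0
    n_valid: int = 0

    def validate(self) -> "EvalReport":
        for name in ("validity", "uniqueness", "novelty", "sa_pass",
                     "aromatic_ring_pass", "pains_pass"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MetricsError(f"{name}={v} outside [0, 1]")
        return self


def _as_mol(m):
    if isinstance(m, Chem.Mol):
        return m
    if isinstance(m, MolGraph):
        return to_rdkit(m)
    mol = Chem.MolFromSmiles(m)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {m!r}")
    return mol


def _canonical(smiles: str) -> str | None:
    """Canonical SMILES through the package's graph model, or None if the
    string is unparseable or violates the valence table."""
    try:
        return write_smiles(parse_smiles(smiles))
    except (ParseError, ValueError):
        return None


# --------------------------------------------------------------------------
# Structural metrics
# --------------------------------------------------------------------------

def validity(generated, fragments=None) -> tuple:
    """(fraction valid, list of canonical SMILES of the valid subset).

    Valid = parseable + valence-table-valid + (when `fragments` given)
    containing both fragments as substructures.
    """
    queries = []
    if fragments is not None:
        for f in fragments:
            queries.append(f if isinstance(f, MolGraph) else parse_smiles(f))
    valid = []
    for smi in generated:
        smi = smi if isinstance(smi, str) else write_smiles(smi)
        can = _canonical(smi)
        if can is None:
            continue
        g = parse_smiles(can)
        if all(contains_fragment(g, q) for q in queries):
            valid.append(can)
    frac = len(valid) / len(generated) if generated else 0.0
    return frac, valid


def uniqueness(valid) -> float:
    """|unique canonical SMILES| / |valid|."""
    if not valid:
        raise MetricsError("uniqueness undefined for an empty set")
    return len(set(valid)) / len(valid)


def novelty(valid, training_set) -> float:
    """Fraction of unique valid molecules absent from the training set."""
    if not valid:
        raise MetricsError("novelty undefined for an empty set")
    uniq = set(valid)
    train = {(_canonical(s) or s) for s in training_set}
    if not train:
        warnings.warn("empty training set: all molecules counted novel")
        return 1.0
    return len(uniq - train) / len(uniq)


# --------------------------------------------------------------------------
# Chemical filters
# --------------------------------------------------------------------------

def aromatic_ring_pass(mol: Chem.Mol) -> bool:
    """True when no non-aromatic ring bond carries a double bond."""
    for bond in mol.GetBonds():
        if (bond.IsInRing() and not bond.GetIsAromatic()
                and bond.GetBondType() == Chem.BondType.DOUBLE):
            return False
    return True


def chem_filters(m) -> ChemFilterResult:
    """SA, QED, ring-aromaticity and PAINS assessment of one molecule."""
    mol = _as_mol(m)
    sa = float(sascorer.calculateScore(mol))
    return ChemFilterResult(
        sa_score=sa,
        sa_pass=sa < 3.0,
        aromatic_ring_pass=aromatic_ring_pass(mol),
        pains_pass=not _PAINS.HasMatch(mol),
        qed=float(QED.qed(mol)),
    )


# --------------------------------------------------------------------------
# Property pass rates
# --------------------------------------------------------------------------

def pass_rates(mols, activity_fn, thresholds: dict | None = None) -> dict:
    """Per-condition and conjunction pass fractions.

    `activity_fn` maps a MolGraph to a potency value (plug in the surrogate
    oracle or any predictor). Conditions default to QED > 0.6, SA < 3,
    activity > 6.
    """
    mols = list(mols)
    if not mols:
        raise MetricsError("pass rates undefined for an empty set")
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    def _passes(value, rule):
        cut, direction = rule
        return value > cut if direction == "greater" else value < cut

    counts = {name: 0 for name in th}
    counts["all"] = 0
    for m in mols:
        g = m if isinstance(m, MolGraph) else parse_smiles(
            m if isinstance(m, str) else write_smiles(m))
        cf = chem_filters(g)
        values = {"qed": cf.qed, "sa": cf.sa_score, "activity": activity_fn(g)}
        flags = {name: _passes(values[name], th[name]) for name in th}
        for name, ok in flags.items():
            counts[name] += ok
        counts["all"] += all(flags.values())
    return {name: c / len(mols) for name, c in counts.items()}


# --------------------------------------------------------------------------
# Full report
# --------------------------------------------------------------------------

def evaluate(generated, fragments=None, training_set=(),
             activity_fn=None, thresholds: dict | None = None) -> EvalReport:
    """Run the whole metric suite on a generated SMILES/molecule list."""
    generated = list(generated)
    frac_valid, valid = validity(generated, fragments)
    if not valid:
        return EvalReport(frac_valid, 0.0, 0.0, 0.0, 0.0, 0.0, {},
                          len(generated), 0).validate()
    uniq = uniqueness(valid)
    nov = novelty(valid, training_set) if training_set else 1.0
    filters = [chem_filters(s) for s in valid]
    n = len(filters)
    rates = {}
    if activity_fn is not None:
        rates = pass_rates(valid, activity_fn, thresholds)
    return EvalReport(
        validity=frac_valid,
        uniqueness=uniq,
        novelty=nov,
        sa_pass=sum(f.sa_pass for f in filters) / n,
        aromatic_ring_pass=sum(f.aromatic_ring_pass for f in filters) / n,
        pains_pass=sum(f.pains_pass for f in filters) / n,
        property_pass_rates=rates,
        n_generated=len(generated),
        n_valid=len(valid),
    ).validate()
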