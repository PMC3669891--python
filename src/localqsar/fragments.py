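"""Substructure descriptors with endpoint association — the activity-specific layer.

A pluggable miner interface produces SMARTS fragments annotated with a
chi-square p-value for their association with a two-class endpoint. The
default miner enumerates linear fragments (simple paths of heavy atoms,
labelled with element symbols, aromaticity and bond orders), keeps the
frequent ones, and discards those whose association with the endpoint is
not significant. Branched/ring-closure miners can plug in behind the same
dataset -> fragments-with-p-values contract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from scipy.stats import chi2

from .chem_io import NOMINAL, Compound, ToxDataset

ACTIVATING = "activating"
DEACTIVATING = "deactivating"

_BOND_SMARTS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


class MiningError(ValueError):
    """Fragment mining cannot proceed (e.g. single-class dataset)."""


@dataclass(frozen=True)
class Fragment:
    """A mined substructure with its endpoint association.

    ``weight`` is what the similarity layer uses: 1 for every retained
    fragment under binary weighting (the default; significance acts purely
    as a cutoff), or ``1 - p_value`` under continuous weighting.
    """

    smarts: str
    support_active: int
    support_inactive: int
    p_value: float
    direction: str
    weight: float = 1.0

    @property
    def support(self) -> int:
        return self.support_active + self.support_inactive


@dataclass
class FingerprintMatrix:
    """Per-compound substructure vectors aligned to an ordered fragment list."""

    fragments: list[Fragment]
    mode: str  # binary | count
    matrix: np.ndarray  # shape (n_compounds, n_fragments), integer
    compound_ids: list[str]

    @property
    def smarts(self) -> list[str]:
        return [f.smarts for f in self.fragments]

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.fragments], dtype=float)


def chi_square_association(
    n_active_with: int,
    n_active_without: int,
    n_inactive_with: int,
    n_inactive_without: int,
) -> tuple[float, float, str]:
    """Pearson chi-square on the 2x2 fragment/endpoint table.

    One degree of freedom, no continuity correction. The direction is the
    sign of observed minus expected in the (active, with-fragment) cell:
    strictly more actives among carriers than expected -> activating.

    Raises :class:`MiningError` if any table margin is zero (association
    undefined; callers must pre-filter such fragments).
    """
    a, b, c, d = n_active_with, n_active_without, n_inactive_with, n_inactive_without
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise MiningError("zero margin in 2x2 table: association undefined")
    statistic = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p_value = float(chi2.sf(statistic, df=1))
    expected_a = (a + b) * (a + c) / n
    direction = ACTIVATING if a > expected_a else DEACTIVATING
    return float(statistic), p_value, direction


# ---------------------------------------------------------------------------
# Linear fragment enumeration

def _atom_smarts(atom: Chem.Atom) -> str:
    symbol = atom.GetSymbol()
    return symbol.lower() if atom.GetIsAromatic() else symbol


def _path_smarts(mol: Chem.Mol, path: Sequence[int]) -> str:
    parts = [_atom_smarts(mol.GetAtomWithIdx(path[0]))]
    for u, v in zip(path, path[1:]):
        bond = mol.GetBondBetweenAtoms(u, v)
        parts.append(_BOND_SMARTS[bond.GetBondType()])
        parts.append(_atom_smarts(mol.GetAtomWithIdx(v)))
    return "".join(parts)


def molecule_fragments(mol: Chem.Mol, max_length: int) -> set[str]:
    """All linear fragments of ``mol`` with 1..max_length heavy atoms.

    Fragments are simple paths in the heavy-atom graph; each is rendered as
    SMARTS (element symbol, lowercase when aromatic, explicit bond order)
    and keyed by the lexicographic minimum of its two directions so each
    undirected path contributes once.
    """
    out: set[str] = set()
    n = mol.GetNumAtoms()
    adjacency = [[b.GetOtherAtomIdx(i) for b in mol.GetAtomWithIdx(i).GetBonds()] for i in range(n)]

    def extend(path: list[int], visited: set[int]) -> None:
        fwd = _path_smarts(mol, path)
        rev = _path_smarts(mol, path[::-1])
        out.add(min(fwd, rev))
        if len(path) == max_length:
            return
        for nxt in adjacency[path[-1]]:
            if nxt not in visited:
                path.append(nxt)
                visited.add(nxt)
                extend(path, visited)
                visited.remove(nxt)
                path.pop()

    for start in range(n):
        extend([start], {start})
    return out


def mine_fragments(
    train: ToxDataset,
    min_frequency: int = 5,
    max_length: int = 10,
    p_cutoff: float = 0.05,
    weighting: str = "binary",
) -> list[Fragment]:
    """Mine linear fragments significantly associated with a nominal endpoint.

    Candidate fragments occurring in at least ``min_frequency`` training
    compounds are scored with :func:`chi_square_association`; those with
    ``p_value > p_cutoff`` are discarded. Fragments present in every
    training compound carry no information (a zero table margin) and are
    dropped as well. The result is sorted by ascending p-value, ties broken
    by descending total support then lexicographic SMARTS — a deterministic
    ranking with the most endpoint-associated fragment first.
    """
    if train.endpoint_type != NOMINAL:
        raise MiningError("fragment mining requires a nominal endpoint")
    if min_frequency < 1:
        raise ValueError("min_frequency must be >= 1")
    active_label = train.active_label
    labels = set(train.activities)
    if len(labels) < 2:
        raise MiningError("training data contains a single class; association undefined")

    n_active = sum(1 for a in train.activities if a == active_label)
    n_inactive = len(train) - n_active

    support_a: dict[str, int] = {}
    support_i: dict[str, int] = {}
    for compound, activity in train.records:
        frags = molecule_fragments(compound.mol(), max_length)
        target = support_a if activity == active_label else support_i
        for smarts in frags:
            target[smarts] = target.get(smarts, 0) + 1

    fragments: list[Fragment] = []
    for smarts in set(support_a) | set(support_i):
        sa = support_a.get(smarts, 0)
        si = support_i.get(smarts, 0)
        if sa + si < min_frequency:
            continue
        if sa + si == len(train):  # present everywhere: no discrimination possible
            continue
        _, p_value, direction = chi_square_association(sa, n_active - sa, si, n_inactive - si)
        if p_value > p_cutoff:
            continue
        weight = 1.0 if weighting == "binary" else 1.0 - p_value
        fragments.append(
            Fragment(
                smarts=smarts,
                support_active=sa,
                support_inactive=si,
                p_value=p_value,
                direction=direction,
                weight=weight,
            )
        )
    fragments.sort(key=lambda f: (f.p_value, -f.support, f.smarts))
    return fragments


def compute_fingerprints(
    compounds: Sequence[Compound],
    fragments: Sequence[Fragment],
    mode: str = "binary",
) -> FingerprintMatrix:
    """Match each fragment SMARTS against each compound.

    Binary mode records presence/absence; count mode records the number of
    distinct (by atom set) substructure matches.
    """
    if not fragments:
        raise ValueError("fragment list is empty")
    if mode not in ("binary", "count"):
        raise ValueError(f"unknown fingerprint mode {mode!r}")
    patterns = []
    for frag in fragments:
        query = Chem.MolFromSmarts(frag.smarts)
        if query is None:
            raise RuntimeError(f"mined SMARTS failed to compile: {frag.smarts!r}")
        patterns.append(query)

    matrix = np.zeros((len(compounds), len(fragments)), dtype=np.int64)
    for i, compound in enumerate(compounds):
        mol = compound.mol()
        for j, query in enumerate(patterns):
            if mode == "binary":
                matrix[i, j] = int(mol.HasSubstructMatch(query))
            else:
                matrix[i, j] = len(mol.GetSubstructMatches(query, uniquify=True))
    return FingerprintMatrix(
        fragments=list(fragments), mode=mode, matrix=matrix, compound_ids=[c.id for c in compounds]
    )


def write_fragment_table(fragments: Sequence[Fragment], path: str) -> None:
    """Export mined fragments as CSV (smarts, supports, p-value, direction)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smarts", "support_active", "support_inactive", "p_value", "direction"])
        for frag in fragments:
            writer.writerow(
                [frag.smarts, frag.support_active, frag.support_inactive, frag.p_value, frag.direction]
            )


def write_smarts_list(fragments: Sequence[Fragment], path: str) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(frag.smarts + "\n")


# ---------------------------------------------------------------------------
# Physico-chemical descriptors
#
# A small named registry delegating to RDKit calculators. The endpoint never
# enters these computations, so they may be precomputed once per dataset.

PHYSCHEM_REGISTRY: dict[str, Callable[[Chem.Mol], float]] = {
    "heavy_atom_count": lambda m: float(m.GetNumHeavyAtoms()),
    "mol_weight": Descriptors.MolWt,
    "ring_count": lambda m: float(rdMolDescriptors.CalcNumRings(m)),
    "aromatic_ring_count": lambda m: float(rdMolDescriptors.CalcNumAromaticRings(m)),
    "aromatic_atom_count": lambda m: float(sum(a.GetIsAromatic() for a in m.GetAtoms())),
    "bond_count": lambda m: float(m.GetNumBonds()),
    "double_bond_count": lambda m: float(
        sum(b.GetBondType() == Chem.BondType.DOUBLE for b in m.GetBonds())
    ),
    "rotatable_bond_count": lambda m: float(Lipinski.NumRotatableBonds(m)),
    "hbond_donor_count": lambda m: float(Lipinski.NumHDonors(m)),
    "hbond_acceptor_count": lambda m: float(Lipinski.NumHAcceptors(m)),
    "carbon_count": lambda m: float(sum(a.GetSymbol() == "C" for a in m.GetAtoms())),
    "nitrogen_count": lambda m: float(sum(a.GetSymbol() == "N" for a in m.GetAtoms())),
    "oxygen_count": lambda m: float(sum(a.GetSymbol() == "O" for a in m.GetAtoms())),
    "xlogp": Crippen.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "fraction_csp3": rdMolDescriptors.CalcFractionCSP3,
}

DEFAULT_DESCRIPTORS = list(PHYSCHEM_REGISTRY)


def compute_physchem(
    compounds: Sequence[Compound], descriptor_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Numeric descriptor table (one row per compound, NaN for failures)."""
    names = list(descriptor_names) if descriptor_names is not None else DEFAULT_DESCRIPTORS
    unknown = [n for n in names if n not in PHYSCHEM_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown descriptors {unknown}; valid names: {sorted(PHYSCHEM_REGISTRY)}"
        )
    rows = []
    for compound in compounds:
        mol = compound.mol()
        row = {}
        for name in names:
            try:
                row[name] = float(PHYSCHEM_REGISTRY[name](mol))
            except Exception:  # incalculable -> explicit missing marker
                row[name] = np.nan
        rows.append(row)
    index = [c.id for c in compounds]
    return pd.DataFrame(rows, columns=names, index=index, dtype=float)
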