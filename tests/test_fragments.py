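"""Fragment mining, chi-square association, fingerprints and descriptors."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from scipy.stats import chi2_contingency

from localqsar import (
    Compound,
    canonical_smiles,
    chi_square_association,
    compute_fingerprints,
    compute_physchem,
    mine_fragments,
)
from localqsar.fragments import MiningError, molecule_fragments


def _compound(smiles):
    canon = canonical_smiles(smiles)
    return Compound(id=smiles, smiles_input=smiles, smiles_canonical=canon)


# ---------------------------------------------------------------------------
# chi-square association


@pytest.mark.parametrize(
    "table, stat, p, direction",
    [
        ((10, 0, 0, 10), 20.0, 7.744216431044465e-06, "activating"),
        ((5, 5, 5, 5), 0.0, 1.0, "deactivating"),
        ((4, 1, 1, 4), 3.6, 0.05777957112359738, "activating"),
    ],
)
def test_chi_square_reference_values(table, stat, p, direction):
    statistic, p_value, direc = chi_square_association(*table)
    assert statistic == pytest.approx(stat, rel=1e-12)
    assert p_value == pytest.approx(p, rel=1e-10)
    assert direc == direction


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.tuples(*[st.integers(0, 50)] * 4))
def test_chi_square_matches_independent_oracle(table):
    """Pearson statistic and p-value agree with the contingency-table oracle."""
    a, b, c, d = table
    if min(a + b, c + d, a + c, b + d) == 0:
        with pytest.raises(MiningError):
            chi_square_association(a, b, c, d)
        return
    statistic, p_value, _ = chi_square_association(a, b, c, d)
    ref_stat, ref_p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    assert statistic == pytest.approx(ref_stat, rel=1e-10, abs=1e-12)
    assert p_value == pytest.approx(ref_p, rel=1e-10, abs=1e-12)


def test_zero_margin_raises():
    with pytest.raises(MiningError):
        chi_square_association(0, 0, 5, 5)


# ---------------------------------------------------------------------------
# mining


def _brute_force_fragments(mol, max_length):
    """Independent path enumeration via networkx over the heavy-atom graph."""
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    bond_char = {Chem.BondType.SINGLE: "-", Chem.BondType.DOUBLE: "=",
                 Chem.BondType.TRIPLE: "#", Chem.BondType.AROMATIC: ":"}

    def smarts_of(path):
        parts = []
        for i, idx in enumerate(path):
            atom = mol.GetAtomWithIdx(idx)
            sym = atom.GetSymbol()
            parts.append(sym.lower() if atom.GetIsAromatic() else sym)
            if i + 1 < len(path):
                bond = mol.GetBondBetweenAtoms(idx, path[i + 1])
                parts.append(bond_char[bond.GetBondType()])
        return "".join(parts)

    found = {smarts_of([n]) for n in g.nodes}
    for u, v in itertools.permutations(g.nodes, 2):
        for path in nx.all_simple_paths(g, u, v, cutoff=max_length - 1):
            found.add(min(smarts_of(path), smarts_of(path[::-1])))
    return found


@pytest.mark.parametrize("smiles", ["CCO", "CC(C)N=O", "c1ccccc1", "OCC(N)CO", "C#CCO"])
def test_path_enumeration_matches_brute_force(smiles):
    """Miner fragments on <=8-heavy-atom molecules equal exhaustive enumeration."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol.GetNumHeavyAtoms() <= 8
    for max_length in (2, 4, 8):
        assert molecule_fragments(mol, max_length) == _brute_force_fragments(mol, max_length)


def test_planted_toxicophore_ranked_first(clf_dataset):
    fragments = mine_fragments(clf_dataset)
    assert fragments[0].smarts == "N=O"
    assert fragments[0].direction == "activating"
    assert fragments[0].p_value == min(f.p_value for f in fragments)


def test_min_frequency_above_dataset_size_yields_empty(clf_dataset):
    assert mine_fragments(clf_dataset, min_frequency=len(clf_dataset) + 1) == []


def test_single_class_dataset_is_fatal(clf_dataset):
    single = clf_dataset.subset(
        [i for i, a in enumerate(clf_dataset.activities) if a == "active"]
    )
    with pytest.raises(MiningError):
        mine_fragments(single)


def test_independent_fragment_discarded(clf_dataset):
    """Fragments in equal class proportions never survive any p_cutoff < 1."""
    fragments = mine_fragments(clf_dataset, p_cutoff=0.9999)
    n_active = sum(1 for a in clf_dataset.activities if a == "active")
    n_inactive = len(clf_dataset) - n_active
    for frag in fragments:
        assert frag.support_active / n_active != pytest.approx(frag.support_inactive / n_inactive)


def test_support_anti_monotone(clf_dataset):
    """A fragment never occurs in more compounds than its sub-fragments."""
    fragments = {f.smarts: f.support for f in mine_fragments(clf_dataset, p_cutoff=1.0, min_frequency=1)}
    mols = [c.mol() for c in clf_dataset.compounds]
    for smarts, support in fragments.items():
        if "-" not in smarts and "=" not in smarts and ":" not in smarts:
            continue
        # sub-fragment: strip the last atom+bond (linear SMARTS)
        for sep in "-=:#":
            smarts_trim = smarts.rsplit(sep, 1)[0]
            if smarts_trim != smarts:
                sub = Chem.MolFromSmarts(smarts_trim)
                sub_support = sum(1 for m in mols if m.HasSubstructMatch(sub))
                assert support <= sub_support


def test_mining_is_deterministic(clf_dataset):
    first = mine_fragments(clf_dataset)
    second = mine_fragments(clf_dataset)
    assert [(f.smarts, f.p_value, f.support) for f in first] == [
        (f.smarts, f.p_value, f.support) for f in second
    ]


def test_sort_order_p_then_support_then_smarts(clf_dataset):
    fragments = mine_fragments(clf_dataset, p_cutoff=1.0 - 1e-12, min_frequency=2)
    keys = [(f.p_value, -f.support, f.smarts) for f in fragments]
    assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# fingerprints


def test_fingerprint_binary_and_count_modes(clf_dataset):
    fragments = mine_fragments(clf_dataset)
    butane, nitroso = _compound("CCCC"), _compound("CCN=O")
    binary = compute_fingerprints([butane, nitroso], fragments, mode="binary")
    count = compute_fingerprints([butane, nitroso], fragments, mode="count")
    j = binary.smarts.index("N=O")
    assert binary.matrix[0, j] == 0 and binary.matrix[1, j] == 1
    assert set(np.unique(binary.matrix)) <= {0, 1}
    assert (count.matrix >= binary.matrix).all()


def test_count_mode_counts_distinct_matches():
    """CC in butane: one count per distinct bonded carbon pair (3 of them)."""
    from localqsar.fragments import Fragment

    frag = Fragment(smarts="C-C", support_active=5, support_inactive=0, p_value=0.01,
                    direction="activating")
    fp = compute_fingerprints([_compound("CCCC")], [frag], mode="count")
    assert fp.matrix[0, 0] == 3


def test_disjoint_elements_give_zero():
    from localqsar.fragments import Fragment

    frag = Fragment(smarts="N=O", support_active=5, support_inactive=0, p_value=0.01,
                    direction="activating")
    fp = compute_fingerprints([_compound("CCCC")], [frag], mode="binary")
    assert fp.matrix[0, 0] == 0


def test_empty_fragment_list_rejected():
    with pytest.raises(ValueError):
        compute_fingerprints([_compound("CCO")], [], mode="binary")


# ---------------------------------------------------------------------------
# physico-chemical descriptors


def test_physchem_hand_countable_values():
    table = compute_physchem([_compound("CCO"), _compound("c1ccccc1")],
                             ["heavy_atom_count", "ring_count"])
    assert table.loc["CCO", "heavy_atom_count"] == 3
    assert table.loc["c1ccccc1", "ring_count"] == 1
    assert table.loc["CCO", "ring_count"] == 0


def test_physchem_empty_compound_list_keeps_columns():
    table = compute_physchem([], ["heavy_atom_count", "tpsa"])
    assert list(table.columns) == ["heavy_atom_count", "tpsa"]
    assert len(table) == 0


def test_physchem_unknown_descriptor_is_fatal():
    with pytest.raises(KeyError, match="valid names"):
        compute_physchem([_compound("CCO")], ["not_a_descriptor"])
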