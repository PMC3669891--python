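"""Deterministic toy SMILES generators with planted structure-activity rules.

These stand in, at desk scale, for real mutagenicity / aquatic-toxicity
tables: each generated compound is a small scaffold (C/N/O chain, optionally
a benzene ring, <= 12 heavy atoms) that may carry a planted activating motif
(a nitroso group, N=O, by default). For classification the label is
"active" exactly when the motif is present, then flipped with a small noise
probability; for regression the activity is an affine function of motif
count and heavy-atom count plus Gaussian noise. Because the generative rule
is known exactly, miner recovery, cross-validation accuracy, and
slope-recovery tests all have closed-form ground truth.

All randomness is driven by integer choices from a seeded ``random.Random``
so a fixed seed reproduces the dataset byte-for-byte on any platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdkit import Chem

from .chem_io import NOMINAL, NUMERIC, Compound, ToxDataset, canonical_smiles

ACTIVE = "active"
INACTIVE = "inactive"

#: planted activating motif; as a mined linear SMARTS this is "N=O"
DEFAULT_TOXICOPHORE = "N=O"

#: regression generative coefficients (activity units per unit covariate)
REGRESSION_BASE = 2.0
REGRESSION_EFFECT = 1.0  # per toxicophore occurrence
REGRESSION_HEAVY_COEF = 0.05  # per heavy atom


@dataclass
class FixtureSpec:
    """Conditions for one synthetic dataset."""

    n_compounds: int = 200
    toxicophore_smarts: str = DEFAULT_TOXICOPHORE
    carrier_probability: float = 0.5
    label_noise: float = 0.05
    regression_noise_sd: float = 0.25
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (self.carrier_probability, self.label_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.regression_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


_CHAIN_ATOMS = ["C", "C", "C", "N", "O"]  # carbon-rich vocabulary


def _random_scaffold(rng: random.Random, motif_count: int) -> str:
    """A random scaffold SMILES sized so the final molecule stays <= 12 heavy atoms."""
    has_ring = rng.randrange(2) == 1
    max_chain = 12 - (6 if has_ring else 0) - 2 * motif_count
    chain_len = rng.randrange(2, max(2, max_chain) + 1)
    chain = "".join(rng.choice(_CHAIN_ATOMS) for _ in range(chain_len))
    return ("c1ccccc1" + chain) if has_ring else chain


def _attach_toxicophore(scaffold: str, count: int, rng: random.Random) -> str:
    """Attach ``count`` nitroso motifs at the scaffold's two terminal sites.

    A prefix copy (O=N-) bonds to the first scaffold atom — an aromatic ring
    carbon when a ring is present — and a suffix copy (-N=O) to the chain
    terminus. Varying the attachment point keeps any larger fragment that
    contains the motif from covering every carrier, so the bare motif is the
    unique maximal-support perfect marker.
    """
    if count == 0:
        return scaffold
    if count == 1:
        return ("O=N" + scaffold) if rng.randrange(2) == 1 else (scaffold + "N=O")
    return "O=N" + scaffold + "N=O"


def _generate_structures(spec: FixtureSpec, counts: bool) -> list[tuple[str, int]]:
    """Unique canonical structures, each with its planted motif count.

    ``counts=False`` plants 0 or 1 copies (classification carriers),
    ``counts=True`` plants 0, 1, or 2 copies (regression dose levels).
    Rejection sampling on the canonical SMILES guarantees uniqueness.
    """
    rng = random.Random(spec.seed)
    seen: set[str] = set()
    out: list[tuple[str, int]] = []
    while len(out) < spec.n_compounds:
        carrier = rng.random() < spec.carrier_probability
        if not carrier:
            k = 0
        elif counts:
            k = rng.choice([1, 1, 2])
        else:
            k = 1
        scaffold = _random_scaffold(rng, k)
        smiles = _attach_toxicophore(scaffold, k, rng)
        canon = canonical_smiles(smiles)
        if canon is None or canon in seen:
            continue
        seen.add(canon)
        out.append((canon, k))
    return out


def generate_classification_fixture(spec: FixtureSpec) -> ToxDataset:
    """Two-class dataset where activity is planted by the toxicophore.

    A compound is labelled active exactly when it carries the motif, after
    which the label is flipped with probability ``label_noise``. Metadata
    records the per-compound carrier flags so tests can audit the rule.
    """
    structures = _generate_structures(spec, counts=False)
    rng = random.Random(spec.seed + 1)  # label noise stream, independent of structures
    records = []
    carriers = []
    for i, (canon, k) in enumerate(structures):
        label = ACTIVE if k > 0 else INACTIVE
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = INACTIVE if label == ACTIVE else ACTIVE
        compound = Compound(id=f"fx{i + 1}", smiles_input=canon, smiles_canonical=canon)
        records.append((compound, label))
        carriers.append(k > 0)
    return ToxDataset(
        name=f"clf-fixture-seed{spec.seed}",
        endpoint_name="activity",
        endpoint_type=NOMINAL,
        records=records,
        class_labels=(ACTIVE, INACTIVE),
        metadata={
            "toxicophore": spec.toxicophore_smarts,
            "carriers": carriers,
            "label_noise": spec.label_noise,
            "seed": spec.seed,
        },
    )


def generate_regression_fixture(spec: FixtureSpec) -> ToxDataset:
    """Numeric dataset: activity affine in motif count and heavy-atom count.

    activity = base + effect * n_motifs + heavy_coef * n_heavy + N(0, sd)
    with the coefficients recorded in the dataset metadata.
    """
    structures = _generate_structures(spec, counts=True)
    rng = random.Random(spec.seed + 1)
    records = []
    motif_counts = []
    for i, (canon, k) in enumerate(structures):
        heavy = Chem.MolFromSmiles(canon).GetNumHeavyAtoms()
        activity = REGRESSION_BASE + REGRESSION_EFFECT * k + REGRESSION_HEAVY_COEF * heavy
        if spec.regression_noise_sd > 0:
            activity += rng.gauss(0.0, spec.regression_noise_sd)
        compound = Compound(id=f"fx{i + 1}", smiles_input=canon, smiles_canonical=canon)
        records.append((compound, float(activity)))
        motif_counts.append(k)
    return ToxDataset(
        name=f"reg-fixture-seed{spec.seed}",
        endpoint_name="log_activity",
        endpoint_type=NUMERIC,
        records=records,
        metadata={
            "toxicophore": spec.toxicophore_smarts,
            "motif_counts": motif_counts,
            "base": REGRESSION_BASE,
            "effect": REGRESSION_EFFECT,
            "heavy_coef": REGRESSION_HEAVY_COEF,
            "noise_sd": spec.regression_noise_sd,
            "seed": spec.seed,
        },
    )
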