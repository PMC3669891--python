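"""Chemical structure and dataset handling.

Structures are stored as canonical SMILES over the connectivity graph only
(no coordinates). Datasets pair each structure with a single endpoint value,
either nominal (two-class, e.g. mutagen / non-mutagen) or numeric
(e.g. log LC50). Duplicate structures are merged deterministically on load.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

NOMINAL = "nominal"
NUMERIC = "numeric"

#: labels recognised as the positive ("active") class when none is given
_ACTIVE_KEYWORDS = {"active", "mutagen", "mutagenic", "toxic", "positive", "pos", "1", "true"}


class DatasetError(ValueError):
    """Fatal problem with an input dataset (missing column, no usable records...)."""


@dataclass(frozen=True)
class Compound:
    """A canonicalized chemical structure with an opaque identifier."""

    id: str
    smiles_input: str
    smiles_canonical: str

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles_canonical)
        if m is None:  # canonical SMILES always parses; guard for corrupted state
            raise ValueError(f"invalid canonical SMILES: {self.smiles_canonical!r}")
        return m


@dataclass
class LoadReport:
    """Bookkeeping for dataset loading."""

    n_read: int = 0
    n_invalid: int = 0
    n_merged_duplicates: int = 0
    n_dropped_conflicts: int = 0


@dataclass
class ToxDataset:
    """Compounds plus one endpoint value per compound.

    ``records`` is an ordered list of ``(Compound, activity)`` where the
    activity is a class label for nominal endpoints and a float for numeric
    ones. ``class_labels`` is the ordered pair (active, inactive) and is
    only meaningful for nominal endpoints.
    """

    name: str
    endpoint_name: str
    endpoint_type: str
    records: list[tuple[Compound, object]] = field(default_factory=list)
    class_labels: tuple[str, str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.endpoint_type not in (NOMINAL, NUMERIC):
            raise DatasetError(f"unknown endpoint type {self.endpoint_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def compounds(self) -> list[Compound]:
        return [c for c, _ in self.records]

    @property
    def ids(self) -> list[str]:
        return [c.id for c, _ in self.records]

    @property
    def smiles(self) -> list[str]:
        return [c.smiles_canonical for c, _ in self.records]

    @property
    def activities(self) -> list:
        return [a for _, a in self.records]

    @property
    def active_label(self) -> str:
        if self.class_labels is None:
            raise DatasetError("dataset has no class labels (numeric endpoint?)")
        return self.class_labels[0]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "ToxDataset":
        return ToxDataset(
            name=name or f"{self.name}[subset]",
            endpoint_name=self.endpoint_name,
            endpoint_type=self.endpoint_type,
            records=[self.records[i] for i in indices],
            class_labels=self.class_labels,
            metadata=dict(self.metadata),
        )

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["smiles", self.endpoint_name])
            for compound, activity in self.records:
                writer.writerow([compound.smiles_canonical, activity])


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES of the largest covalent component, or None if unparseable.

    Salt/mixture handling: the component with the most heavy atoms is kept
    before canonicalization (standard QSAR practice).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


def _coerce_activity(raw: object, endpoint_type: str) -> object:
    if endpoint_type == NUMERIC:
        return float(raw)
    return str(raw).strip()


def _infer_class_labels(labels: set[str], active_label: str | None) -> tuple[str, str]:
    if len(labels) != 2:
        raise DatasetError(
            f"nominal endpoint must have exactly 2 classes, got {sorted(labels)}"
        )
    if active_label is not None:
        if active_label not in labels:
            raise DatasetError(f"active label {active_label!r} not among {sorted(labels)}")
        inactive = next(iter(labels - {active_label}))
        return active_label, inactive
    for lab in sorted(labels):
        if lab.lower() in _ACTIVE_KEYWORDS:
            return lab, next(iter(labels - {lab}))
    first, second = sorted(labels)
    log.warning("no recognised active label among %s; using %r as active", sorted(labels), first)
    return first, second


def _iter_csv(path: str, endpoint_name: str) -> Iterable[tuple[str, str, object]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        if "smiles" not in cols or endpoint_name not in cols:
            raise DatasetError(
                f"CSV must have 'smiles' and {endpoint_name!r} columns, found {cols}"
            )
        for i, row in enumerate(reader):
            yield f"c{i + 1}", row["smiles"], row[endpoint_name]


def _iter_sdf(path: str, endpoint_name: str) -> Iterable[tuple[str, str, object]]:
    supplier = Chem.SDMolSupplier(path, sanitize=True)
    saw_field = False
    for i, mol in enumerate(supplier):
        if mol is None:
            yield f"c{i + 1}", "", None  # counted as invalid downstream
            continue
        if not mol.HasProp(endpoint_name):
            yield f"c{i + 1}", Chem.MolToSmiles(mol), None
            continue
        saw_field = True
        yield f"c{i + 1}", Chem.MolToSmiles(mol), mol.GetProp(endpoint_name)
    if not saw_field:
        raise DatasetError(f"no SDF record carries the property field {endpoint_name!r}")


def read_dataset(
    path: str,
    format: str,
    endpoint_name: str,
    endpoint_type: str,
    name: str | None = None,
    active_label: str | None = None,
) -> tuple[ToxDataset, LoadReport]:
    """Load a structure/activity table from CSV or SDF.

    Structures are canonicalized (largest component kept); unparseable rows
    are skipped and counted. Records with identical canonical SMILES are
    merged: nominal labels must be unanimous (else the structure is dropped
    and counted as a conflict), numeric values are collapsed to the median.

    Returns the dataset together with a :class:`LoadReport`.
    """
    if format not in ("csv", "sdf"):
        raise DatasetError(f"unsupported format {format!r}")
    if endpoint_type not in (NOMINAL, NUMERIC):
        raise DatasetError(f"unknown endpoint type {endpoint_type!r}")

    rows = _iter_csv(path, endpoint_name) if format == "csv" else _iter_sdf(path, endpoint_name)

    report = LoadReport()
    groups: dict[str, dict] = {}  # canonical smiles -> {id, smiles_input, activities}
    for cid, smiles, raw_activity in rows:
        report.n_read += 1
        canon = canonical_smiles(smiles) if smiles else None
        if canon is None or raw_activity is None or str(raw_activity).strip() == "":
            report.n_invalid += 1
            log.warning("skipping unparseable/empty record %s (%r)", cid, smiles)
            continue
        try:
            activity = _coerce_activity(raw_activity, endpoint_type)
        except ValueError:
            report.n_invalid += 1
            log.warning("skipping record %s: bad activity %r", cid, raw_activity)
            continue
        group = groups.setdefault(canon, {"id": cid, "smiles_input": smiles, "activities": []})
        group["activities"].append(activity)

    records: list[tuple[Compound, object]] = []
    for canon, group in groups.items():
        acts = group["activities"]
        if len(acts) > 1:
            if endpoint_type == NOMINAL and len(set(acts)) > 1:
                report.n_dropped_conflicts += 1
                continue
            report.n_merged_duplicates += len(acts) - 1
        value = acts[0] if endpoint_type == NOMINAL else (acts[0] if len(acts) == 1 else median(acts))
        records.append(
            (Compound(id=group["id"], smiles_input=group["smiles_input"], smiles_canonical=canon), value)
        )

    if not records:
        raise DatasetError(f"no valid records in {path}")

    class_labels = None
    if endpoint_type == NOMINAL:
        class_labels = _infer_class_labels({a for _, a in records}, active_label)

    dataset = ToxDataset(
        name=name or path,
        endpoint_name=endpoint_name,
        endpoint_type=endpoint_type,
        records=records,
        class_labels=class_labels,
    )
    return dataset, report


# ---------------------------------------------------------------------------
# Prediction output


def _prediction_row(pred) -> dict:
    value = getattr(pred, "value", None)
    return {
        "id": pred.query_id,
        "smiles": getattr(pred, "query_smiles", ""),
        "predicted": "" if value is None else value,
        "confidence": f"{pred.confidence:.3f}",
        "unpredicted": pred.unpredicted,
        "n_neighbors": pred.n_neighbors,
    }


def write_predictions(predictions: Sequence, path: str, format: str = "csv") -> None:
    """Write prediction results to CSV or JSON.

    One row/object per query. JSON additionally embeds the neighbor
    provenance (id, smiles, similarity, activity per neighbor) and the
    matched activating/deactivating fragments.
    """
    if not predictions:
        raise ValueError("no predictions to write")
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["id", "smiles", "predicted", "confidence", "unpredicted", "n_neighbors"]
            )
            writer.writeheader()
            for pred in predictions:
                writer.writerow(_prediction_row(pred))
    elif format == "json":
        payload = []
        for pred in predictions:
            row = _prediction_row(pred)
            row["confidence"] = round(float(pred.confidence), 6)
            row["predicted"] = pred.value
            row["score"] = getattr(pred, "score", None)
            neighbors = getattr(pred, "neighbors", None)
            row["neighbors"] = [
                {"id": n.compound_id, "similarity": n.similarity, "activity": n.activity}
                for n in (neighbors.neighbors if neighbors is not None else [])
            ]
            row["fragments"] = [
                {"smarts": smarts, "direction": direction}
                for smarts, direction in getattr(pred, "fragments_matched", []) or []
            ]
            payload.append(row)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ValueError(f"unsupported prediction format {format!r}")
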