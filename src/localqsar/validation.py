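"""Leakage-aware k-fold cross-validation, statistics and reports.

Endpoint-supervised descriptors (mined fragments) are recomputed on each
training fold only; endpoint-blind descriptors (physico-chemical
properties) may be computed once for the whole dataset. Predictions are
pooled over folds; statistics are computed over the predicted instances,
with out-of-domain (unpredicted) queries counted separately. Performance as
a function of the confidence cutoff is emitted as a table backing
confidence-vs-statistic curves.
"""

from __future__ import annotations

import csv
import html
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .chem_io import NOMINAL, ToxDataset
from .config import ModelSpec
from .fragments import compute_physchem
from .local_models import TrainedModel, train_model
from .similarity import SVD_COSINE

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class ConfusionTable:
    """2x2 counts with the active class as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def classification_stats(confusion: ConfusionTable) -> dict[str, float | None]:
    """Accuracy, F-measure, TPR, TNR, PPV, NPV from a confusion table.

    Ratios with a zero denominator are reported as missing (None), never 0.
    """
    ct = confusion
    if ct.total == 0:
        raise ValueError("empty confusion table")
    tpr = _ratio(ct.tp, ct.tp + ct.fn)
    tnr = _ratio(ct.tn, ct.tn + ct.fp)
    ppv = _ratio(ct.tp, ct.tp + ct.fp)
    npv = _ratio(ct.tn, ct.tn + ct.fn)
    if ppv is None or tpr is None or (ppv + tpr) == 0:
        f_measure = None
    else:
        f_measure = 2 * ppv * tpr / (ppv + tpr)
    return {
        "accuracy": (ct.tp + ct.tn) / ct.total,
        "f_measure": f_measure,
        "true_positive_rate": tpr,
        "true_negative_rate": tnr,
        "positive_predictive_value": ppv,
        "negative_predictive_value": npv,
    }


def auc(scores, labels, positive_label) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = labels == positive_label
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes among the evaluated instances")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def regression_stats(predicted, actual) -> dict[str, float | None]:
    """RMSE, MAE, R², Pearson r, and Lin's concordance correlation.

    R² is 1 - SS_res/SS_tot about the actual mean (not squared Pearson r;
    the squared correlation is reported separately). The CCC uses
    population (1/n) moments:
    CCC = 2 cov(p,a) / (var(p) + var(a) + (mean p - mean a)²).
    With zero variance in the actual values the correlation-type statistics
    are missing.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("predicted/actual must be equal-length 1-d arrays of length >= 2")
    residuals = p - a
    rmse = float(np.sqrt(np.mean(residuals**2)))
    mae = float(np.mean(np.abs(residuals)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    var_p = float(p.var())
    var_a = float(a.var())
    if ss_tot == 0:
        r_squared = r = ccc = pearson_sq = None
    else:
        r_squared = 1.0 - float(np.sum(residuals**2)) / ss_tot
        cov = float(np.mean((p - p.mean()) * (a - a.mean())))
        r = cov / math.sqrt(var_p * var_a) if var_p > 0 else None
        pearson_sq = r**2 if r is not None else None
        ccc = 2 * cov / (var_p + var_a + (p.mean() - a.mean()) ** 2)
    return {
        "rmse": rmse,
        "mae": mae,
        "r_squared": r_squared,
        "sample_correlation": r,
        "pearson_r_squared": pearson_sq,
        "concordance_correlation": float(ccc) if ccc is not None else None,
    }


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class ValidationReport:
    """Pooled cross-validation outcome plus per-fold and per-prediction detail."""

    endpoint_type: str
    n_instances: int
    n_unpredicted: int
    pooled: dict
    per_fold: list[dict]
    confusion: ConfusionTable | None
    confidence_curve: list[dict]
    records: list[dict]  # id, smiles, actual, predicted, confidence, unpredicted, fold, score
    k: int = 10
    seed: int = 0
    fold_fragments: list[list] = field(default_factory=list, repr=False)


def _fold_indices(dataset: ToxDataset, k: int, seed: int):
    y = dataset.activities
    idx = np.arange(len(dataset))
    if dataset.endpoint_type == NOMINAL and k <= min(
        sum(1 for a in y if a == y_lab) for y_lab in set(y)
    ):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(idx, np.asarray(y, dtype=object)))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(idx))


def _confusion_from_records(records, active_label) -> ConfusionTable:
    tp = fp = fn = tn = 0
    for rec in records:
        if rec["unpredicted"]:
            continue
        actual_pos = rec["actual"] == active_label
        predicted_pos = rec["predicted"] == active_label
        if predicted_pos and actual_pos:
            tp += 1
        elif predicted_pos:
            fp += 1
        elif actual_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp, fp, fn, tn)


def _stats_for(records, endpoint_type, active_label) -> dict:
    predicted = [r for r in records if not r["unpredicted"]]
    if endpoint_type == NOMINAL:
        stats = classification_stats(_confusion_from_records(records, active_label))
        scored = [r for r in predicted if r.get("score") is not None]
        labels = {r["actual"] for r in scored}
        if len(labels) == 2:
            stats["auc"] = auc(
                [r["score"] for r in scored], [r["actual"] for r in scored], active_label
            )
        else:
            stats["auc"] = None
        return stats
    if len(predicted) < 2:
        return {"rmse": None, "mae": None, "r_squared": None,
                "sample_correlation": None, "pearson_r_squared": None,
                "concordance_correlation": None}
    return regression_stats([r["predicted"] for r in predicted], [r["actual"] for r in predicted])


def crossvalidate(dataset: ToxDataset, spec: ModelSpec, k: int = 10, seed: int = 0) -> ValidationReport:
    """Seeded k-fold cross-validation with per-fold fragment mining.

    Folds are stratified by class for nominal endpoints (plain random for
    numeric). For each fold a model is trained on the training part only —
    including fragment mining, so no test compound ever contributes to a
    fragment's support counts — and applied to the held-out part.
    """
    if k < 2 or k > len(dataset):
        raise ValueError(f"k must be in [2, {len(dataset)}]")
    physchem = None
    if spec.similarity == SVD_COSINE:
        # endpoint-blind descriptors: safe to compute once, globally
        physchem = compute_physchem(dataset.compounds, spec.descriptors)

    records: list[dict] = []
    per_fold: list[dict] = []
    fold_fragments: list[list] = []
    for fold_no, (train_idx, test_idx) in enumerate(_fold_indices(dataset, k, seed)):
        train = dataset.subset(train_idx, name=f"{dataset.name}/fold{fold_no}-train")
        if dataset.endpoint_type == NOMINAL and len(set(train.activities)) < 2:
            raise ValueError(
                f"training part of fold {fold_no} is single-class; reduce k or rebalance"
            )
        model = train_model(train, spec, physchem=physchem)
        fold_fragments.append(model.fragments)
        fold_records = []
        for i in test_idx:
            compound, actual = dataset.records[i]
            pred = model.predict_one(compound, seed=seed)
            fold_records.append(
                {
                    "id": compound.id,
                    "smiles": compound.smiles_canonical,
                    "actual": actual,
                    "predicted": pred.value,
                    "confidence": pred.confidence,
                    "unpredicted": pred.unpredicted,
                    "score": pred.score,
                    "n_neighbors": pred.n_neighbors,
                    "fold": fold_no,
                }
            )
        records.extend(fold_records)
        fold_stats = {"fold": fold_no, "n_test": len(test_idx),
                      "n_unpredicted": sum(r["unpredicted"] for r in fold_records)}
        try:
            fold_stats.update(_stats_for(fold_records, dataset.endpoint_type, _active(dataset)))
        except ValueError:
            pass  # tiny folds can be single-class or empty after domain filtering
        per_fold.append(fold_stats)

    active_label = _active(dataset)
    pooled = _stats_for(records, dataset.endpoint_type, active_label)
    confusion = (
        _confusion_from_records(records, active_label) if dataset.endpoint_type == NOMINAL else None
    )
    statistic = "accuracy" if dataset.endpoint_type == NOMINAL else "r_squared"
    curve = confidence_curve(records, statistic=statistic, active_label=active_label,
                             endpoint_type=dataset.endpoint_type)
    return ValidationReport(
        endpoint_type=dataset.endpoint_type,
        n_instances=len(dataset),
        n_unpredicted=sum(r["unpredicted"] for r in records),
        pooled=pooled,
        per_fold=per_fold,
        confusion=confusion,
        confidence_curve=curve,
        records=records,
        k=k,
        seed=seed,
        fold_fragments=fold_fragments,
    )


def _active(dataset: ToxDataset) -> str | None:
    return dataset.active_label if dataset.endpoint_type == NOMINAL else None


def confidence_curve(
    records,
    statistic: str = "accuracy",
    n_cutoffs: int = 20,
    active_label: str | None = None,
    endpoint_type: str = NOMINAL,
) -> list[dict]:
    """Statistic over predictions with confidence >= cutoff, per cutoff.

    Cutoffs form an even, strictly increasing grid over the observed
    confidences of predicted instances. Strata with fewer than 2 retained
    predictions report a missing value.
    """
    predicted = [r for r in records if not r["unpredicted"]]
    if not predicted:
        return []
    confidences = sorted({float(r["confidence"]) for r in predicted})
    lo, hi = confidences[0], confidences[-1]
    if lo == hi:
        cutoffs = [lo]
    else:
        cutoffs = list(np.linspace(lo, hi, n_cutoffs))
    curve = []
    for cut in cutoffs:
        stratum = [r for r in predicted if r["confidence"] >= cut]
        entry = {"cutoff": float(cut), "n_predictions": len(stratum), "value": None}
        if len(stratum) >= 2:
            try:
                entry["value"] = _stats_for(stratum, endpoint_type, active_label)[statistic]
            except ValueError:
                entry["value"] = None
        curve.append(entry)
    return curve


# ---------------------------------------------------------------------------
# Report rendering


def _round3(x):
    return None if x is None else round(float(x), 3)


def report_to_dict(report: ValidationReport) -> dict:
    out = {
        "schema_version": SCHEMA_VERSION,
        "endpoint_type": report.endpoint_type,
        "n_instances": report.n_instances,
        "n_unpredicted": report.n_unpredicted,
        "k": report.k,
        "seed": report.seed,
        "pooled": report.pooled,
        "per_fold": report.per_fold,
        "confidence_curve": report.confidence_curve,
        "records": report.records,
    }
    if report.confusion is not None:
        ct = report.confusion
        out["confusion"] = {"tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn}
    return out


def render_report(report: ValidationReport, path: str, format: str = "json") -> None:
    """Write the validation report as machine JSON, human HTML, or per-prediction CSV."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=2)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=["id", "smiles", "actual", "predicted", "confidence", "unpredicted", "fold"],
                extrasaction="ignore",
            )
            writer.writeheader()
            for rec in report.records:
                writer.writerow(rec)
    elif format == "html":
        with open(path, "w") as fh:
            fh.write(_render_html(report))
    else:
        raise ValueError(f"unsupported report format {format!r}")


def _table(rows, header) -> str:
    cells = "".join(f"<th>{html.escape(str(h))}</th>" for h in header)
    body = ""
    for row in rows:
        body += "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in row) + "</tr>"
    return f"<table border='1'><tr>{cells}</tr>{body}</table>"


def _render_html(report: ValidationReport) -> str:
    parts = [
        "<html><head><title>Validation report</title></head><body>",
        "<h1>Cross-validation report</h1>",
        f"<p>{report.k}-fold, seed {report.seed}: {report.n_instances} instances, "
        f"{report.n_unpredicted} unpredicted (outside the applicability domain).</p>",
        "<h2>Pooled statistics</h2>",
        _table([(k, _round3(v)) for k, v in report.pooled.items()], ["statistic", "value"]),
    ]
    if report.confusion is not None:
        ct = report.confusion
        parts += [
            "<h2>Confusion matrix</h2>",
            _table(
                [("predicted active", ct.tp, ct.fp), ("predicted inactive", ct.fn, ct.tn)],
                ["", "actual active", "actual inactive"],
            ),
        ]
    parts += [
        "<h2>Confidence curve</h2>",
        _table(
            [(_round3(e["cutoff"]), e["n_predictions"], _round3(e["value"])) for e in report.confidence_curve],
            ["confidence cutoff", "n predictions", "statistic"],
        ),
        "<h2>Per-prediction records</h2>",
        _table(
            [
                (r["id"], r["smiles"], r["actual"], r["predicted"], _round3(r["confidence"]),
                 r["unpredicted"], r["fold"])
                for r in report.records
            ],
            ["id", "smiles", "actual", "predicted", "confidence", "unpredicted", "fold"],
        ),
        "</body></html>",
    ]
    return "\n".join(parts)
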