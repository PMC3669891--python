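"""Cross-validation machinery, statistic suite, curves and reports."""

import itertools
import json

import numpy as np
import pytest

from localqsar import (
    ConfusionTable,
    FixtureSpec,
    ModelSpec,
    auc,
    classification_stats,
    confidence_curve,
    crossvalidate,
    generate_classification_fixture,
    regression_stats,
    render_report,
)
from localqsar.fragments import molecule_fragments
from localqsar.validation import report_to_dict


# ---------------------------------------------------------------------------
# classification statistics


def test_published_confusion_counts_reproduce_statistics():
    """Mutagenicity benchmark confusion counts give the published statistic set."""
    stats = classification_stats(ConfusionTable(tp=1799, fp=537, fn=492, tn=1229))
    assert round(stats["accuracy"], 3) == 0.746
    assert round(stats["f_measure"], 3) == 0.778
    assert round(stats["true_positive_rate"], 3) == 0.785
    assert round(stats["true_negative_rate"], 3) == 0.696
    assert round(stats["positive_predictive_value"], 3) == 0.770
    assert round(stats["negative_predictive_value"], 3) == 0.714


def test_undefined_ratios_are_missing_not_zero():
    stats = classification_stats(ConfusionTable(tp=0, fp=3, fn=0, tn=5))
    assert stats["true_positive_rate"] is None
    assert stats["f_measure"] is None


def test_perfect_predictor_scores_one():
    stats = classification_stats(ConfusionTable(tp=10, fp=0, fn=0, tn=7))
    for key in ("accuracy", "f_measure", "true_positive_rate", "true_negative_rate",
                "positive_predictive_value", "negative_predictive_value"):
        assert stats[key] == 1.0


# ---------------------------------------------------------------------------
# AUC


def _brute_force_auc(scores, labels, positive="+"):
    pairs = [
        (sp, sn)
        for sp, lp in zip(scores, labels) if lp == positive
        for sn, ln in zip(scores, labels) if ln != positive
    ]
    wins = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0 for sp, sn in pairs)
    return wins / len(pairs)


def test_auc_reference_cases():
    assert auc([0.9, 0.8, 0.2, 0.1], ["+", "+", "-", "-"], "+") == 1.0
    assert auc([0.5, 0.5, 0.5, 0.5], ["+", "+", "-", "-"], "+") == 0.5
    assert auc([0.9, 0.4, 0.6, 0.1], ["+", "+", "-", "-"], "+") == 0.75


def test_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(17)
    for n in (10, 40, 100):
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.choice(["+", "-"], size=n).tolist()
        if len(set(labels)) < 2:
            continue
        assert auc(scores, labels, "+") == pytest.approx(
            _brute_force_auc(scores, labels), abs=1e-12
        )


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        auc([0.1, 0.2], ["+", "+"], "+")


# ---------------------------------------------------------------------------
# regression statistics


def test_regression_stats_identity_limits():
    y = np.array([1.0, 2.0, 3.5, 0.2])
    stats = regression_stats(y, y)
    assert stats["rmse"] == 0 and stats["mae"] == 0
    assert stats["r_squared"] == 1 and stats["sample_correlation"] == pytest.approx(1.0)
    assert stats["concordance_correlation"] == pytest.approx(1.0)


def test_constant_mean_prediction_gives_zero_r_squared():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    stats = regression_stats(np.full_like(y, y.mean()), y)
    assert stats["r_squared"] == pytest.approx(0.0)


def test_shifted_prediction_keeps_r_but_penalizes_ccc():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    stats = regression_stats(y + 1.5, y)
    assert stats["sample_correlation"] == pytest.approx(1.0)
    assert stats["concordance_correlation"] < 1.0
    # closed form: 2*var / (2*var + shift^2)
    var = y.var()
    assert stats["concordance_correlation"] == pytest.approx(2 * var / (2 * var + 1.5**2))


def test_zero_variance_actual_gives_missing_correlations():
    stats = regression_stats([1.0, 2.0], [3.0, 3.0])
    assert stats["r_squared"] is None and stats["sample_correlation"] is None


# ---------------------------------------------------------------------------
# cross-validation


@pytest.fixture(scope="module")
def cv_report_and_dataset():
    dataset = generate_classification_fixture(FixtureSpec(n_compounds=80, seed=7))
    report = crossvalidate(dataset, ModelSpec(), k=5, seed=7)
    return report, dataset


def test_folds_are_disjoint_and_exhaustive(cv_report_and_dataset):
    report, dataset = cv_report_and_dataset
    seen = [r["id"] for r in report.records]
    assert sorted(seen) == sorted(dataset.ids)  # once each, none missing
    per_fold_ids = {}
    for rec in report.records:
        per_fold_ids.setdefault(rec["fold"], set()).add(rec["id"])
    for a, b in itertools.combinations(per_fold_ids.values(), 2):
        assert not (a & b)


def test_pooled_confusion_is_sum_of_fold_confusions(cv_report_and_dataset):
    report, dataset = cv_report_and_dataset
    from localqsar.validation import _confusion_from_records

    total = ConfusionTable(0, 0, 0, 0)
    for fold in range(report.k):
        fold_records = [r for r in report.records if r["fold"] == fold]
        total = total + _confusion_from_records(fold_records, "active")
    assert (total.tp, total.fp, total.fn, total.tn) == (
        report.confusion.tp, report.confusion.fp, report.confusion.fn, report.confusion.tn)
    assert total.total + report.n_unpredicted == report.n_instances


def test_fold_mining_has_no_test_leakage(cv_report_and_dataset):
    """Recount every mined fragment's support from the training fold only."""
    report, dataset = cv_report_and_dataset
    frag_sets = {c.id: molecule_fragments(c.mol(), 10) for c in dataset.compounds}
    label = dict(zip(dataset.ids, dataset.activities))
    for fold, fragments in enumerate(report.fold_fragments):
        test_ids = {r["id"] for r in report.records if r["fold"] == fold}
        train_ids = [cid for cid in dataset.ids if cid not in test_ids]
        for frag in fragments[:10]:
            recount_a = sum(1 for cid in train_ids
                            if frag.smarts in frag_sets[cid] and label[cid] == "active")
            recount_i = sum(1 for cid in train_ids
                            if frag.smarts in frag_sets[cid] and label[cid] == "inactive")
            assert (recount_a, recount_i) == (frag.support_active, frag.support_inactive)


def test_leave_one_out_predicts_each_compound_once():
    dataset = generate_classification_fixture(FixtureSpec(n_compounds=24, seed=3))
    report = crossvalidate(dataset, ModelSpec(), k=len(dataset), seed=3)
    assert sorted(r["id"] for r in report.records) == sorted(dataset.ids)


def test_cv_is_seed_deterministic():
    dataset = generate_classification_fixture(FixtureSpec(n_compounds=40, seed=9))
    a = crossvalidate(dataset, ModelSpec(), k=4, seed=5)
    b = crossvalidate(dataset, ModelSpec(), k=4, seed=5)
    assert a.records == b.records and a.pooled == b.pooled


def test_k_out_of_range_rejected(cv_report_and_dataset):
    _, dataset = cv_report_and_dataset
    with pytest.raises(ValueError):
        crossvalidate(dataset, ModelSpec(), k=1)
    with pytest.raises(ValueError):
        crossvalidate(dataset, ModelSpec(), k=len(dataset) + 1)


# ---------------------------------------------------------------------------
# confidence curve


def test_confidence_curve_contract(cv_report_and_dataset):
    report, _ = cv_report_and_dataset
    curve = report.confidence_curve
    cutoffs = [e["cutoff"] for e in curve]
    counts = [e["n_predictions"] for e in curve]
    assert cutoffs == sorted(cutoffs) and len(set(cutoffs)) == len(cutoffs)
    assert counts == sorted(counts, reverse=True)
    # lowest cutoff retains every predicted instance -> pooled statistic
    assert counts[0] == report.n_instances - report.n_unpredicted
    assert curve[0]["value"] == pytest.approx(report.pooled["accuracy"])


def test_cutoff_above_max_confidence_gives_missing_value():
    records = [
        {"actual": "active", "predicted": "active", "confidence": 0.5, "unpredicted": False},
        {"actual": "inactive", "predicted": "active", "confidence": 0.9, "unpredicted": False},
    ]
    curve = confidence_curve(records, statistic="accuracy", n_cutoffs=3, active_label="active")
    assert curve[-1]["n_predictions"] < 2
    assert curve[-1]["value"] is None


# ---------------------------------------------------------------------------
# reports


def test_json_report_roundtrip(tmp_path, cv_report_and_dataset):
    report, _ = cv_report_and_dataset
    path = tmp_path / "report.json"
    render_report(report, str(path), format="json")
    with open(path) as fh:
        loaded = json.load(fh)
    assert loaded == json.loads(json.dumps(report_to_dict(report)))
    assert loaded["confusion"]["tp"] == report.confusion.tp


def test_csv_report_row_count(tmp_path, cv_report_and_dataset):
    import csv

    report, dataset = cv_report_and_dataset
    path = tmp_path / "report.csv"
    render_report(report, str(path), format="csv")
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == report.n_instances


def test_html_report_sections(tmp_path, cv_report_and_dataset):
    report, _ = cv_report_and_dataset
    path = tmp_path / "report.html"
    render_report(report, str(path), format="html")
    text = path.read_text()
    assert "Confusion matrix" in text and "Confidence curve" in text


def test_regression_report_has_no_confusion_section(tmp_path, reg_dataset):
    spec = ModelSpec(endpoint_type="numeric", model="svm", similarity="svd_cosine")
    report = crossvalidate(reg_dataset, spec, k=4, seed=2)
    assert report.confusion is None
    path = tmp_path / "report.html"
    render_report(report, str(path), format="html")
    assert "Confusion matrix" not in path.read_text()
    json_path = tmp_path / "report.json"
    render_report(report, str(json_path), format="json")
    assert "confusion" not in json.loads(json_path.read_text())
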