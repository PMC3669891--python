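"""Per-query local models: weighted majority voting and local SVMs.

Instead of one global model, a dedicated model is built for every query
from its neighbors and discarded afterwards. Classification defaults to a
similarity-weighted majority vote over neighbor activities; classification
and regression can alternatively use an SVM trained on the neighbors only,
with the (C, gamma) pair selected on an 8x8 grid by inner cross-validation
over the neighbors. Each prediction carries the applicability-domain
confidence and its provenance (neighbors, matched fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVC, SVR

from .chem_io import NOMINAL, NUMERIC, Compound, ToxDataset, canonical_smiles
from .config import MAJORITY_VOTE, SVM, ModelSpec, SvmConfig
from .fragments import (
    ACTIVATING,
    DEACTIVATING,
    Fragment,
    compute_fingerprints,
    compute_physchem,
    mine_fragments,
)
from .similarity import (
    SVD_COSINE,
    WEIGHTED_TANIMOTO,
    NeighborSet,
    SvdProjection,
    confidence as neighbor_confidence,
    find_neighbors,
    fit_svd_projection,
    project_features,
)

log = logging.getLogger(__name__)

CLASSIFY = "classify"
REGRESS = "regress"


@dataclass
class Prediction:
    """Outcome for one query: value + confidence + provenance, or unpredicted."""

    query_id: str
    endpoint_type: str
    query_smiles: str = ""
    value: object | None = None
    confidence: float = 0.0
    unpredicted: bool = False
    tie: bool = False
    score: float | None = None
    n_neighbors: int = 0
    neighbors: NeighborSet | None = None
    fragments_matched: list[tuple[str, str]] = field(default_factory=list)
    error: str | None = None

    def __post_init__(self) -> None:
        assert self.unpredicted == (self.value is None), "unpredicted iff value absent"


def predict_majority_vote(
    neighbors: NeighborSet, class_labels: tuple[str, str], query_smiles: str = ""
) -> Prediction:
    """Similarity-weighted majority vote over neighbor class labels.

    The winning class is the one with the larger similarity mass; the score
    is the signed normalized margin (sum_active - sum_inactive) / total, so
    score > 0 exactly when the active class wins. An exact tie is reported
    as unpredicted (score 0) rather than broken arbitrarily.
    """
    active, inactive = class_labels
    conf = neighbor_confidence(neighbors)
    if len(neighbors) == 0:
        return Prediction(
            query_id=neighbors.query_id,
            endpoint_type=NOMINAL,
            query_smiles=query_smiles,
            unpredicted=True,
            confidence=0.0,
            neighbors=neighbors,
        )
    sum_active = sum(n.similarity for n in neighbors.neighbors if n.activity == active)
    sum_inactive = sum(n.similarity for n in neighbors.neighbors if n.activity != active)
    total = sum_active + sum_inactive
    score = (sum_active - sum_inactive) / total if total > 0 else 0.0
    if score == 0.0:
        return Prediction(
            query_id=neighbors.query_id,
            endpoint_type=NOMINAL,
            query_smiles=query_smiles,
            unpredicted=True,
            tie=True,
            score=0.0,
            confidence=conf,
            n_neighbors=len(neighbors),
            neighbors=neighbors,
        )
    value = active if score > 0 else inactive
    return Prediction(
        query_id=neighbors.query_id,
        endpoint_type=NOMINAL,
        query_smiles=query_smiles,
        value=value,
        score=score,
        confidence=conf,
        n_neighbors=len(neighbors),
        neighbors=neighbors,
    )


# ---------------------------------------------------------------------------
# Kernels


def tanimoto_kernel_matrix(fingerprints: np.ndarray) -> np.ndarray:
    """Square Tanimoto (set) kernel over binary fingerprint rows.

    Entry (i, j) = |Ai ∩ Aj| / |Ai ∪ Aj|; the diagonal is 1 by definition,
    including for empty rows.
    """
    B = (np.asarray(fingerprints) > 0).astype(float)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(K, 1.0)
    return K


def tanimoto_cross_kernel(fp_a: np.ndarray, fp_b: np.ndarray) -> np.ndarray:
    """Rectangular Tanimoto kernel between two binary fingerprint sets."""
    A = (np.atleast_2d(np.asarray(fp_a)) > 0).astype(float)
    B = (np.atleast_2d(np.asarray(fp_b)) > 0).astype(float)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return K


def _sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xx = (X**2).sum(axis=1)[:, None]
    yy = (Y**2).sum(axis=1)[None, :]
    return np.maximum(xx + yy - 2.0 * X @ Y.T, 0.0)


# ---------------------------------------------------------------------------
# Local SVM


@dataclass
class LocalSvmModel:
    """A fitted neighbor-only SVM (or the constant shortcut) for one query."""

    task: str
    kernel: str
    c: float
    gamma: float
    constant: object | None = None
    estimator: object | None = None
    train_features: np.ndarray | None = None

    def predict(self, query_features: np.ndarray) -> object:
        if self.constant is not None:
            return self.constant
        Q = np.atleast_2d(np.asarray(query_features, dtype=float))
        if self.kernel == "tanimoto":
            K = tanimoto_cross_kernel(Q, self.train_features)
        else:
            K = np.exp(-self.gamma * _sq_dists(Q, self.train_features))
        out = self.estimator.predict(K)[0]
        return float(out) if self.task == REGRESS else out

    def decision_value(self, query_features: np.ndarray) -> float | None:
        if self.constant is not None or self.task != CLASSIFY:
            return None
        Q = np.atleast_2d(np.asarray(query_features, dtype=float))
        if self.kernel == "tanimoto":
            K = tanimoto_cross_kernel(Q, self.train_features)
        else:
            K = np.exp(-self.gamma * _sq_dists(Q, self.train_features))
        return float(self.estimator.decision_function(K)[0])


def _make_estimator(task: str, c: float, epsilon: float):
    if task == REGRESS:
        return SVR(kernel="precomputed", C=c, epsilon=epsilon)
    return SVC(kernel="precomputed", C=c)


def _cv_score(K: np.ndarray, y: np.ndarray, splits, task: str, c: float, epsilon: float) -> float:
    """Inner-CV loss for one grid point: RMSE (regression) or error rate."""
    errors = []
    for train_idx, test_idx in splits:
        y_train = y[train_idx]
        if task == CLASSIFY and len(set(y_train)) == 1:
            pred = np.array([y_train[0]] * len(test_idx), dtype=object)
        elif task == REGRESS and len(set(y_train.tolist())) == 1:
            pred = np.full(len(test_idx), y_train[0])
        else:
            est = _make_estimator(task, c, epsilon)
            est.fit(K[np.ix_(train_idx, train_idx)], y_train)
            pred = est.predict(K[np.ix_(test_idx, train_idx)])
        if task == REGRESS:
            errors.append((np.asarray(pred, dtype=float) - y[test_idx].astype(float)) ** 2)
        else:
            errors.append((pred != y[test_idx]).astype(float))
    flat = np.concatenate(errors)
    return float(np.sqrt(flat.mean())) if task == REGRESS else float(flat.mean())


def grid_search_scores(
    features: np.ndarray,
    activities,
    config: SvmConfig,
    task: str,
    seed: int = 0,
) -> dict[tuple[float, float], float]:
    """Inner-CV loss for every (C, gamma) grid point (exposed for auditing).

    Loss is RMSE for regression and misclassification rate for
    classification; smaller is better for both.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(activities)
    n = len(y)
    n_splits = config.inner_folds if n >= config.inner_folds else n  # fall back to leave-one-out
    splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(splitter.split(X))
    gammas = list(config.gamma_grid) if config.kernel == "rbf" else [config.gamma_grid[0]]
    kernels: dict[float, np.ndarray] = {}
    if config.kernel == "tanimoto":
        K0 = tanimoto_kernel_matrix(X)
        kernels = {g: K0 for g in gammas}
    else:
        D = _sq_dists(X, X)
        kernels = {g: np.exp(-g * D) for g in gammas}
    scores: dict[tuple[float, float], float] = {}
    for c in config.c_grid:
        for g in gammas:
            scores[(float(c), float(g))] = _cv_score(kernels[g], y, splits, task, float(c), config.epsilon)
    return scores


def train_local_svm(
    features: np.ndarray,
    activities,
    config: SvmConfig,
    task: str,
    seed: int = 0,
) -> LocalSvmModel:
    """Fit the per-query SVM on neighbor features.

    (C, gamma) minimizes the inner-CV loss over the 8x8 grid; ties go to the
    smallest C, then the smallest gamma. If all neighbor activities are
    identical the constant model is returned without any SVM fitting. With
    fewer neighbors than inner folds the folds reduce to leave-one-out.
    For the (parameter-free) Tanimoto kernel only C is searched and the
    reported gamma is the first grid value.
    """
    if task not in (CLASSIFY, REGRESS):
        raise ValueError(f"unknown task {task!r}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(activities)
    if len(y) == 0:
        raise ValueError("cannot train a local SVM without neighbors")
    if len(set(y.tolist())) == 1:
        value = float(y[0]) if task == REGRESS else y[0]
        return LocalSvmModel(task=task, kernel=config.kernel, c=float(config.c_grid[0]),
                             gamma=float(config.gamma_grid[0]), constant=value)

    scores = grid_search_scores(X, y, config, task, seed)
    best_c, best_gamma = min(scores, key=lambda key: (scores[key], key[0], key[1]))

    if config.kernel == "tanimoto":
        K = tanimoto_kernel_matrix(X)
    else:
        K = np.exp(-best_gamma * _sq_dists(X, X))
    est = _make_estimator(task, best_c, config.epsilon)
    est.fit(K, y if task == CLASSIFY else y.astype(float))
    return LocalSvmModel(
        task=task, kernel=config.kernel, c=best_c, gamma=best_gamma,
        estimator=est, train_features=X,
    )


# ---------------------------------------------------------------------------
# The trained workflow: descriptors + similarity + local models


@dataclass
class TrainedModel:
    """Everything needed to predict without retraining.

    Holds the mined fragments (if any), the training fingerprints and/or
    projected property vectors, training activities and the configuration.
    """

    spec: ModelSpec
    endpoint_name: str
    endpoint_type: str
    train_ids: list[str]
    train_smiles: list[str]
    train_activities: list
    class_labels: tuple[str, str] | None = None
    fragments: list[Fragment] = field(default_factory=list)
    train_fingerprints: np.ndarray | None = None
    projection: SvdProjection | None = None
    train_projected: np.ndarray | None = None

    # -- descriptor computation for queries -------------------------------

    def _query_vector(self, compound: Compound) -> np.ndarray:
        if self.spec.similarity == WEIGHTED_TANIMOTO:
            fp = compute_fingerprints([compound], self.fragments, mode="binary")
            return fp.matrix[0]
        features = compute_physchem([compound], self.spec.descriptors)
        return project_features(features, self.projection)[0]

    def _train_matrix(self) -> np.ndarray:
        if self.spec.similarity == WEIGHTED_TANIMOTO:
            return self.train_fingerprints
        return self.train_projected

    def _svm_features(self) -> np.ndarray:
        if self.spec.svm.kernel == "tanimoto":
            return self.train_fingerprints
        return self.train_projected if self.train_projected is not None else self.train_fingerprints

    def _svm_query_features(self, compound: Compound, query_vector: np.ndarray) -> np.ndarray:
        # the similarity vector doubles as the SVM feature vector in every
        # supported configuration (fingerprints or projected properties)
        return query_vector

    def neighbors_of(self, compound: Compound, query_id: str, threshold: float | None = None) -> NeighborSet:
        vec = self._query_vector(compound)
        weights = (
            np.array([f.weight for f in self.fragments])
            if self.spec.similarity == WEIGHTED_TANIMOTO
            else None
        )
        return find_neighbors(
            query_id,
            vec,
            self._train_matrix(),
            self.train_ids,
            self.train_activities,
            similarity_kind=self.spec.similarity,
            threshold=self.spec.threshold if threshold is None else threshold,
            weights=weights,
            max_neighbors=self.spec.max_neighbors,
        )

    # -- prediction --------------------------------------------------------

    def predict_one(self, compound: Compound, query_id: str | None = None, seed: int = 0) -> Prediction:
        qid = query_id or compound.id
        if self.spec.similarity == WEIGHTED_TANIMOTO and not self.fragments:
            return Prediction(query_id=qid, endpoint_type=self.endpoint_type,
                              query_smiles=compound.smiles_canonical, unpredicted=True)
        vec = self._query_vector(compound)
        weights = (
            np.array([f.weight for f in self.fragments])
            if self.spec.similarity == WEIGHTED_TANIMOTO
            else None
        )
        nset = find_neighbors(
            qid, vec, self._train_matrix(), self.train_ids, self.train_activities,
            similarity_kind=self.spec.similarity, threshold=self.spec.threshold,
            weights=weights, max_neighbors=self.spec.max_neighbors,
        )
        matched = self._matched_fragments(compound) if self.fragments else []

        min_needed = (
            self.spec.min_neighbors if self.spec.model == MAJORITY_VOTE else self.spec.min_neighbors_svm
        )
        if len(nset) < min_needed:
            pred = Prediction(
                query_id=qid, endpoint_type=self.endpoint_type,
                query_smiles=compound.smiles_canonical, unpredicted=True,
                confidence=0.0 if len(nset) == 0 else neighbor_confidence(nset),
                n_neighbors=len(nset), neighbors=nset, fragments_matched=matched,
            )
        elif self.spec.model == MAJORITY_VOTE:
            pred = predict_majority_vote(nset, self.class_labels, compound.smiles_canonical)
            pred.fragments_matched = matched
        else:
            pred = self._predict_svm(compound, vec, nset, matched, seed)

        if self.spec.confidence_over == "all" and not pred.unpredicted:
            all_set = find_neighbors(
                qid, vec, self._train_matrix(), self.train_ids, self.train_activities,
                similarity_kind=self.spec.similarity, threshold=0.0, weights=weights,
            )
            pred.confidence = neighbor_confidence(all_set)
        return pred

    def _predict_svm(self, compound, query_vector, nset, matched, seed) -> Prediction:
        index = {cid: i for i, cid in enumerate(self.train_ids)}
        rows = [index[n.compound_id] for n in nset.neighbors]
        X = self._svm_features()[rows]
        y = [self.train_activities[index[n.compound_id]] for n in nset.neighbors]
        task = CLASSIFY if self.endpoint_type == NOMINAL else REGRESS
        model = train_local_svm(X, y, self.spec.svm, task, seed=seed)
        qvec = self._svm_query_features(compound, query_vector)
        value = model.predict(qvec)
        score = None
        if task == CLASSIFY:
            dv = model.decision_value(qvec)
            if dv is not None:
                sign = 1.0 if value == self.class_labels[0] else -1.0
                score = sign * min(1.0, abs(dv))
            else:
                score = 1.0 if value == self.class_labels[0] else -1.0
        return Prediction(
            query_id=nset.query_id, endpoint_type=self.endpoint_type,
            query_smiles=compound.smiles_canonical, value=value, score=score,
            confidence=neighbor_confidence(nset), n_neighbors=len(nset),
            neighbors=nset, fragments_matched=matched,
        )

    def _matched_fragments(self, compound: Compound) -> list[tuple[str, str]]:
        fp = compute_fingerprints([compound], self.fragments, mode="binary")
        return [
            (frag.smarts, frag.direction)
            for frag, present in zip(self.fragments, fp.matrix[0])
            if present
        ]

    def predict_smiles(self, smiles_list, seed: int = 0) -> list[Prediction]:
        """Batch prediction from raw SMILES; bad structures become per-query
        error records and the batch continues."""
        out = []
        for i, smiles in enumerate(smiles_list):
            qid = f"q{i + 1}"
            canon = canonical_smiles(smiles)
            if canon is None:
                out.append(
                    Prediction(query_id=qid, endpoint_type=self.endpoint_type,
                               query_smiles=smiles, unpredicted=True,
                               error=f"unparseable SMILES: {smiles!r}")
                )
                continue
            compound = Compound(id=qid, smiles_input=smiles, smiles_canonical=canon)
            out.append(self.predict_one(compound, seed=seed))
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize the full trained state to one JSON archive."""
        payload = {
            "schema_version": 1,
            "spec": self.spec.to_dict(),
            "endpoint_name": self.endpoint_name,
            "endpoint_type": self.endpoint_type,
            "class_labels": list(self.class_labels) if self.class_labels else None,
            "train_ids": self.train_ids,
            "train_smiles": self.train_smiles,
            "train_activities": self.train_activities,
            "fragments": [
                {
                    "smarts": f.smarts, "support_active": f.support_active,
                    "support_inactive": f.support_inactive, "p_value": f.p_value,
                    "direction": f.direction, "weight": f.weight,
                }
                for f in self.fragments
            ],
            "train_fingerprints": None
            if self.train_fingerprints is None
            else self.train_fingerprints.astype(int).tolist(),
            "projection": None
            if self.projection is None
            else {
                "columns": self.projection.columns,
                "centers": self.projection.centers.tolist(),
                "scales": self.projection.scales.tolist(),
                "components": self.projection.components.tolist(),
                "rank": self.projection.rank,
                "explained_variance_fraction": self.projection.explained_variance_fraction,
            },
            "train_projected": None if self.train_projected is None else self.train_projected.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        spec = ModelSpec.from_dict(payload["spec"])
        projection = None
        if payload["projection"] is not None:
            p = payload["projection"]
            projection = SvdProjection(
                columns=p["columns"],
                centers=np.array(p["centers"]),
                scales=np.array(p["scales"]),
                components=np.array(p["components"]),
                rank=p["rank"],
                explained_variance_fraction=p["explained_variance_fraction"],
            )
        return cls(
            spec=spec,
            endpoint_name=payload["endpoint_name"],
            endpoint_type=payload["endpoint_type"],
            train_ids=payload["train_ids"],
            train_smiles=payload["train_smiles"],
            train_activities=payload["train_activities"],
            class_labels=tuple(payload["class_labels"]) if payload["class_labels"] else None,
            fragments=[Fragment(**f) for f in payload["fragments"]],
            train_fingerprints=None
            if payload["train_fingerprints"] is None
            else np.array(payload["train_fingerprints"], dtype=np.int64),
            projection=projection,
            train_projected=None
            if payload["train_projected"] is None
            else np.array(payload["train_projected"], dtype=float),
        )


def train_model(
    dataset: ToxDataset,
    spec: ModelSpec,
    physchem: pd.DataFrame | None = None,
) -> TrainedModel:
    """Fit the training-time state: mine fragments and/or fit the projection.

    ``physchem`` may carry a precomputed descriptor table (rows indexed by
    compound id); since those descriptors never see the endpoint this is
    safe to share across cross-validation folds.
    """
    if spec.endpoint_type != dataset.endpoint_type:
        raise ValueError("spec endpoint_type does not match the dataset")
    needs_fragments = spec.similarity == WEIGHTED_TANIMOTO or (
        spec.model == SVM and spec.svm.kernel == "tanimoto"
    )
    needs_physchem = spec.similarity == SVD_COSINE
    if needs_fragments and dataset.endpoint_type != NOMINAL:
        raise ValueError(
            "substructure mining needs a nominal endpoint; use svd_cosine similarity for numeric data"
        )

    model = TrainedModel(
        spec=spec,
        endpoint_name=dataset.endpoint_name,
        endpoint_type=dataset.endpoint_type,
        train_ids=dataset.ids,
        train_smiles=dataset.smiles,
        train_activities=dataset.activities,
        class_labels=dataset.class_labels,
    )
    if needs_fragments:
        model.fragments = mine_fragments(
            dataset,
            min_frequency=spec.min_frequency,
            max_length=spec.max_length,
            p_cutoff=spec.p_cutoff,
            weighting=spec.weighting,
        )
        if model.fragments:
            model.train_fingerprints = compute_fingerprints(
                dataset.compounds, model.fragments, mode="binary"
            ).matrix
        else:
            log.warning("no significant fragments survived; all queries will be unpredicted")
            model.train_fingerprints = np.zeros((len(dataset), 0), dtype=np.int64)
    if needs_physchem:
        if physchem is None:
            physchem = compute_physchem(dataset.compounds, spec.descriptors)
        else:
            physchem = physchem.loc[dataset.ids]
        model.projection = fit_svd_projection(physchem, spec.variance_target)
        model.train_projected = project_features(physchem, model.projection)
    return model
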