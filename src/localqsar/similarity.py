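"""Neighbor-finding machinery and the applicability-domain confidence.

Two similarity indices are provided:

* weighted Tanimoto over binary substructure fingerprints — the weight of a
  fragment defaults to 1 (significance acting as a cutoff), so the index
  reduces to the classical Tanimoto |A∩B| / |A∪B|;
* cosine similarity between numeric property vectors after standardization
  and truncated-SVD projection (latent-semantic-indexing style), clamped
  below at zero so it behaves as a similarity in [0, 1].

The confidence of a prediction is the arithmetic mean similarity of the
neighbors actually feeding the local model; a query with no neighbors has
confidence 0 and is outside the applicability domain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WEIGHTED_TANIMOTO = "weighted_tanimoto"
SVD_COSINE = "svd_cosine"


@dataclass(frozen=True)
class Neighbor:
    compound_id: str
    similarity: float
    activity: object


@dataclass
class NeighborSet:
    """Training compounds above the similarity threshold, most similar first."""

    query_id: str
    neighbors: list[Neighbor] = field(default_factory=list)
    similarity_kind: str = WEIGHTED_TANIMOTO

    def __len__(self) -> int:
        return len(self.neighbors)

    @property
    def similarities(self) -> np.ndarray:
        return np.array([n.similarity for n in self.neighbors], dtype=float)


def weighted_tanimoto(fp_a: np.ndarray, fp_b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted Tanimoto index: weight mass of the intersection over the union.

    Count vectors are reduced to presence/absence. With unit weights this is
    the classical Tanimoto index. An empty union (both fingerprints empty,
    or all union weight zero) yields 0.
    """
    a = np.asarray(fp_a) > 0
    b = np.asarray(fp_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    w = np.ones(a.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != a.shape:
        raise ValueError("weights length mismatch")
    union = float(w[a | b].sum())
    if union == 0.0:
        return 0.0
    return float(w[a & b].sum() / union)


def _tanimoto_to_matrix(query_fp: np.ndarray, fp_matrix: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized weighted Tanimoto of one query row against a matrix of rows."""
    q = np.asarray(query_fp) > 0
    m = np.asarray(fp_matrix) > 0
    inter = (m & q) @ weights
    union = (m | q) @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return sims


# ---------------------------------------------------------------------------
# SVD-projected property similarity


@dataclass
class SvdProjection:
    """Standardization + truncated SVD fitted on training property vectors."""

    columns: list[str]
    centers: np.ndarray
    scales: np.ndarray
    components: np.ndarray  # (rank, n_kept_columns) right singular vectors
    rank: int
    explained_variance_fraction: float


def fit_svd_projection(features: pd.DataFrame, variance_target: float = 0.95) -> SvdProjection:
    """Center/scale non-constant columns, drop constant ones, truncate by SVD.

    The rank is the smallest r whose cumulative squared singular values reach
    ``variance_target`` of the total. Missing values are imputed with the
    column mean before fitting.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    if len(features) < 2:
        raise ValueError("need at least 2 rows to fit a projection")
    X = features.to_numpy(dtype=float)
    col_means = np.nanmean(X, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = col_means[nan_cols]
    stds = X.std(axis=0, ddof=0)
    keep = stds > 0
    if not keep.any():
        raise ValueError("all feature columns are constant; no usable variance")
    columns = [c for c, k in zip(features.columns, keep) if k]
    centers = col_means[keep]
    scales = stds[keep]
    Z = (X[:, keep] - centers) / scales
    _, singular_values, vt = np.linalg.svd(Z, full_matrices=False)
    energy = singular_values**2
    total = energy.sum()
    cumulative = np.cumsum(energy) / total
    rank = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    rank = min(rank, len(singular_values))
    return SvdProjection(
        columns=columns,
        centers=centers,
        scales=scales,
        components=vt[:rank],
        rank=rank,
        explained_variance_fraction=float(cumulative[rank - 1]),
    )


def project_features(features: pd.DataFrame, projection: SvdProjection) -> np.ndarray:
    """Project property vectors into the fitted latent space.

    Missing values are imputed with the training column mean (i.e. they map
    to zero after centering), so incomplete measured-property tables degrade
    gracefully instead of failing.
    """
    X = features.reindex(columns=projection.columns).to_numpy(dtype=float)
    nan_rows, nan_cols = np.nonzero(np.isnan(X))
    X[nan_rows, nan_cols] = projection.centers[nan_cols]
    Z = (X - projection.centers) / projection.scales
    return Z @ projection.components.T


def svd_cosine_similarity(
    query_features: pd.Series | pd.DataFrame,
    train_row: pd.Series | pd.DataFrame,
    projection: SvdProjection,
) -> float:
    """Cosine of the angle between two projected property vectors, clamped at 0."""
    q = project_features(_as_frame(query_features), projection)[0]
    t = project_features(_as_frame(train_row), projection)[0]
    return _cosine_clamped(q, t)


def _as_frame(row: pd.Series | pd.DataFrame) -> pd.DataFrame:
    return row.to_frame().T if isinstance(row, pd.Series) else row


def _cosine_clamped(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("zero-norm projected vector; similarity set to 0", stacklevel=2)
        return 0.0
    return float(max(0.0, np.dot(u, v) / (nu * nv)))


def _cosine_to_matrix(query_vec: np.ndarray, train_matrix: np.ndarray) -> np.ndarray:
    nq = np.linalg.norm(query_vec)
    norms = np.linalg.norm(train_matrix, axis=1)
    if nq == 0.0:
        return np.zeros(train_matrix.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (train_matrix @ query_vec) / (norms * nq)
    sims = np.where(norms > 0, sims, 0.0)
    return np.clip(sims, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Neighbor selection and confidence


def find_neighbors(
    query_id: str,
    query_vector: np.ndarray,
    train_matrix: np.ndarray,
    train_ids: Sequence[str],
    train_activities: Sequence,
    similarity_kind: str = WEIGHTED_TANIMOTO,
    threshold: float = 0.3,
    weights: np.ndarray | None = None,
    max_neighbors: int | None = None,
) -> NeighborSet:
    """Every training compound with similarity >= threshold, most similar first.

    ``query_vector``/``train_matrix`` are fingerprint rows for the Tanimoto
    kind and projected property vectors for the cosine kind. A query
    identical to a training structure simply appears as a similarity-1
    neighbor; cross-validation prevents self-matches by fold construction,
    so no self-exclusion happens here. An empty result is valid and means
    the query is outside the applicability domain.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    train_matrix = np.asarray(train_matrix)
    if similarity_kind == WEIGHTED_TANIMOTO:
        w = np.ones(train_matrix.shape[1]) if weights is None else np.asarray(weights, dtype=float)
        sims = _tanimoto_to_matrix(query_vector, train_matrix, w)
    elif similarity_kind == SVD_COSINE:
        sims = _cosine_to_matrix(np.asarray(query_vector, dtype=float), train_matrix)
    else:
        raise ValueError(f"unknown similarity kind {similarity_kind!r}")

    hits = np.nonzero(sims >= threshold)[0]
    # deterministic order: similarity desc, then id for exact ties
    order = sorted(hits, key=lambda i: (-sims[i], str(train_ids[i])))
    if max_neighbors is not None:
        order = order[:max_neighbors]
    neighbors = [
        Neighbor(compound_id=str(train_ids[i]), similarity=float(sims[i]), activity=train_activities[i])
        for i in order
    ]
    return NeighborSet(query_id=query_id, neighbors=neighbors, similarity_kind=similarity_kind)


def confidence(neighbors: NeighborSet) -> float:
    """Mean similarity of the neighbors used for the prediction; 0 if none."""
    if len(neighbors) == 0:
        return 0.0
    return float(neighbors.similarities.mean())
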