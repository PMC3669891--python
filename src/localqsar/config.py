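"""Model configuration: every tunable default lives here, in one place.

Defaults table
--------------
==========================  =========  ======================================
parameter                   default    meaning
==========================  =========  ======================================
min_frequency               5          minimum compounds a fragment occurs in
max_length                  10         max heavy atoms in a linear fragment
p_cutoff                    0.05       chi-square significance cutoff
weighting                   binary     fragment weight: binary (1) | p_value
                                       (1 - p) for the weighted Tanimoto
similarity                  weighted_  weighted_tanimoto (fingerprints) |
                            tanimoto   svd_cosine (property vectors)
threshold                   0.3        neighbor inclusion similarity
max_neighbors               None       optional cap on neighbor count
min_neighbors               1          below this: unpredicted (majority vote)
min_neighbors_svm           5          below this: unpredicted (local SVM)
confidence_over             neighbors  confidence averages supra-threshold
                                       neighbors | all training similarities
variance_target             0.95       SVD energy kept for property vectors
model                       majority_  majority_vote | svm
                            vote
svm.kernel                  rbf        rbf | tanimoto
svm.c_grid                  2^-2..2^5  8 geometric cost values
svm.gamma_grid              2^-7..2^0  8 geometric RBF width values
svm.epsilon                 0.1        SVR tube width
svm.inner_folds             5          inner CV folds for grid selection
==========================  =========  ======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .chem_io import NOMINAL, NUMERIC
from .similarity import SVD_COSINE, WEIGHTED_TANIMOTO

MAJORITY_VOTE = "majority_vote"
SVM = "svm"


def _default_c_grid() -> list[float]:
    return [float(2.0**k) for k in range(-2, 6)]


def _default_gamma_grid() -> list[float]:
    return [float(2.0**k) for k in range(-7, 1)]


@dataclass
class SvmConfig:
    """Local SVM settings: kernel plus the 8x8 (C, gamma) search grid."""

    kernel: str = "rbf"
    c_grid: list[float] = field(default_factory=_default_c_grid)
    gamma_grid: list[float] = field(default_factory=_default_gamma_grid)
    epsilon: float = 0.1
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "tanimoto"):
            raise ValueError(f"unknown SVM kernel {self.kernel!r}")
        if len(self.c_grid) != 8 or len(self.gamma_grid) != 8:
            raise ValueError("C and gamma grids must each have exactly 8 values")


@dataclass
class ModelSpec:
    """Full configuration of one local-model workflow."""

    endpoint_type: str = NOMINAL
    model: str = MAJORITY_VOTE
    similarity: str = WEIGHTED_TANIMOTO
    threshold: float = 0.3
    max_neighbors: int | None = None
    min_neighbors: int = 1
    min_neighbors_svm: int = 5
    confidence_over: str = "neighbors"
    min_frequency: int = 5
    max_length: int = 10
    p_cutoff: float = 0.05
    weighting: str = "binary"
    descriptors: list[str] | None = None
    variance_target: float = 0.95
    svm: SvmConfig = field(default_factory=SvmConfig)

    def __post_init__(self) -> None:
        if self.endpoint_type not in (NOMINAL, NUMERIC):
            raise ValueError(f"unknown endpoint type {self.endpoint_type!r}")
        if self.model not in (MAJORITY_VOTE, SVM):
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.similarity not in (WEIGHTED_TANIMOTO, SVD_COSINE):
            raise ValueError(f"unknown similarity kind {self.similarity!r}")
        if self.model == MAJORITY_VOTE and self.endpoint_type == NUMERIC:
            raise ValueError("majority vote requires a nominal endpoint; use model=svm")
        if self.confidence_over not in ("neighbors", "all"):
            raise ValueError("confidence_over must be 'neighbors' or 'all'")
        if isinstance(self.svm, dict):
            self.svm = SvmConfig(**self.svm)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        """Build a spec from a plain mapping, rejecting unknown keys."""
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        svm = out.pop("svm")
        out["svm"] = {
            "kernel": svm.kernel,
            "c_grid": list(np.asarray(svm.c_grid, dtype=float)),
            "gamma_grid": list(np.asarray(svm.gamma_grid, dtype=float)),
            "epsilon": svm.epsilon,
            "inner_folds": svm.inner_folds,
        }
        return out
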