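"""Core containers shared across the pipeline.

The pipeline clusters the *rows* of a numeric matrix (items: genes or
samples) under many (algorithm, k) candidates, scores every candidate
with validation measures, and aggregates the per-measure rankings into
one consensus ordering.  These dataclasses are the contracts between
those stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DataMatrix",
    "DistanceMatrix",
    "CandidateKey",
    "Partition",
    "AnnotationMap",
    "MeasureSpec",
    "ValidationScoreTable",
    "RankedList",
    "AggregationResult",
    "DegenerateCandidateError",
    "MEASURE_SPECS",
]


class DegenerateCandidateError(RuntimeError):
    """A candidate partition violated its contract (e.g. empty cluster).

    The orchestrator catches this and drops the candidate from every
    ranked list so that all lists rank the same candidate set.
    """


@dataclass(frozen=True)
class CandidateKey:
    """One (clustering algorithm, number of clusters) combination."""

    method: str
    k: int

    def __str__(self) -> str:  # used in report headers, e.g. "pam-3"
        return f"{self.method}-{self.k}"

    @staticmethod
    def parse(text: str) -> "CandidateKey":
        method, _, k = text.rpartition("-")
        return CandidateKey(method, int(k))


@dataclass
class DataMatrix:
    """Items x features numeric matrix with a declared value domain.

    ``domain`` is ``"continuous"`` or ``"counts"``; count matrices must
    hold non-negative integers (they feed the Poisson / negative-binomial
    mixture models).
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    domain: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"matrix must be at least 2x1, got {n}x{p}")
        if len(self.row_ids) != n or len(self.col_ids) != p:
            raise ValueError("row/col id lengths do not match matrix shape")
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids must be unique")
        if len(set(self.col_ids)) != p:
            raise ValueError("col_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        if self.domain not in ("continuous", "counts"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain == "counts":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("counts domain requires non-negative integers")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def drop_column(self, j: int) -> "DataMatrix":
        """Matrix with feature column ``j`` removed (stability reclustering)."""
        keep = [c for c in range(self.n_features) if c != j]
        return DataMatrix(
            self.values[:, keep],
            list(self.row_ids),
            [self.col_ids[c] for c in keep],
            self.domain,
        )


@dataclass
class DistanceMatrix:
    """Symmetric item-item dissimilarity matrix."""

    d: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n, m = self.d.shape
        if n != m:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.d < -1e-12):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n_items(self) -> int:
        return self.d.shape[0]


@dataclass
class Partition:
    """Item -> cluster assignment for one candidate.

    ``labels`` are integers in 1..k with every label represented.
    ``extras`` may carry medoid indices, fuzzy memberships, or the
    mixture-model fit that produced the partition.
    """

    key: CandidateKey
    labels: np.ndarray
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        k = self.key.k
        present = set(np.unique(self.labels))
        if not present <= set(range(1, k + 1)):
            raise ValueError(f"labels must lie in 1..{k}, got {sorted(present)}")
        if len(present) != k:
            raise DegenerateCandidateError(
                f"candidate {self.key}: empty cluster (only {len(present)} of {k} used)"
            )
        memb = self.extras.get("memberships")
        if memb is not None:
            memb = np.asarray(memb, dtype=float)
            if memb.shape != (len(self.labels), k):
                raise ValueError("memberships shape mismatch")
            if not np.allclose(memb.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("membership rows must sum to 1")
            self.extras["memberships"] = memb

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class AnnotationMap:
    """Item id -> set of functional-class ids (biological validation)."""

    classes: dict[str, set[str]]

    def __post_init__(self) -> None:
        for item, cls in self.classes.items():
            if not cls:
                raise ValueError(f"item {item!r} has an empty class set")

    def restrict(self, row_ids: Sequence[str]) -> tuple["AnnotationMap", int]:
        """Drop ids absent from ``row_ids``; returns (map, n_dropped)."""
        keep = {i: s for i, s in self.classes.items() if i in set(row_ids)}
        return AnnotationMap(keep), len(self.classes) - len(keep)

    def class_members(self) -> dict[str, set[str]]:
        """Invert to class id -> set of item ids."""
        out: dict[str, set[str]] = {}
        for item, cls in self.classes.items():
            for c in cls:
                out.setdefault(c, set()).add(item)
        return out


# direction is intrinsic to each measure: connectivity and the four
# stability measures are minimized, the rest maximized.
_MINIMIZE = {"connectivity", "APN", "AD", "ADM", "FOM"}
_MAXIMIZE = {"dunn", "silhouette", "BHI", "BSI"}
_TYPE = {
    "connectivity": "internal",
    "dunn": "internal",
    "silhouette": "internal",
    "APN": "stability",
    "AD": "stability",
    "ADM": "stability",
    "FOM": "stability",
    "BHI": "biological",
    "BSI": "biological",
}


@dataclass(frozen=True)
class MeasureSpec:
    name: str
    type: str
    direction: str

    def __post_init__(self) -> None:
        expected = "minimize" if self.name in _MINIMIZE else "maximize"
        if self.name not in _MINIMIZE | _MAXIMIZE:
            raise ValueError(f"unknown measure {self.name!r}")
        if self.direction != expected:
            raise ValueError(f"{self.name} must be direction={expected!r}")
        if self.type != _TYPE[self.name]:
            raise ValueError(f"{self.name} is a {_TYPE[self.name]} measure")


MEASURE_SPECS: dict[str, MeasureSpec] = {
    name: MeasureSpec(name, _TYPE[name], "minimize" if name in _MINIMIZE else "maximize")
    for name in _TYPE
}


@dataclass
class ValidationScoreTable:
    """measures x candidates score grid."""

    scores: np.ndarray
    specs: list[MeasureSpec]
    candidates: list[CandidateKey]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.specs), len(self.candidates)):
            raise ValueError("score grid shape mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("score table contains non-finite entries")

    def row(self, measure: str) -> np.ndarray:
        for i, spec in enumerate(self.specs):
            if spec.name == measure:
                return self.scores[i]
        raise KeyError(measure)


@dataclass
class RankedList:
    """Candidates ordered best-first under one validation measure."""

    order: list[CandidateKey]
    norm_scores: np.ndarray
    weight: float
    measure: str

    def __post_init__(self) -> None:
        self.norm_scores = np.asarray(self.norm_scores, dtype=float)
        if len(self.order) != len(self.norm_scores):
            raise ValueError("order / norm_scores length mismatch")
        if len(set(self.order)) != len(self.order):
            raise ValueError("order must be a permutation (duplicates found)")
        if np.any(np.diff(self.norm_scores) > 1e-12):
            raise ValueError("norm_scores must be non-increasing")
        if not (np.isfinite(self.weight) and self.weight > 0):
            raise ValueError("weight must be finite and > 0")


@dataclass
class AggregationResult:
    """Output of one rank-aggregation optimizer."""

    best_order: list[CandidateKey]
    phi: float
    method: str  # "CE" | "GA" | "brute"
    trace: list[float]
    seed: int
    converged: bool

    def __post_init__(self) -> None:
        if any(b > a + 1e-12 for a, b in zip(self.trace, self.trace[1:])):
            raise ValueError("optimizer trace must be non-increasing")
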