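"""Seeded synthetic-data generators with known ground truth.

Every generator is driven by :func:`numpy.random.default_rng` seeded
explicitly, so regeneration from the same ``(params, seed)`` pair is
bit-identical across runs and platforms.  The generators produce every
input class the pipeline consumes: continuous Gaussian clusters, count
matrices with Poisson or negative-binomial noise, cluster-aligned
functional annotations, and noisy ranked-list ensembles with a planted
consensus ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import AnnotationMap, CandidateKey, DataMatrix, RankedList

__all__ = ["SyntheticDataset", "make_gaussian", "make_counts", "make_annotation", "make_lists"]


@dataclass
class SyntheticDataset:
    matrix: DataMatrix
    true_labels: np.ndarray
    generator_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        if len(self.true_labels) != self.matrix.n_items:
            raise ValueError("true_labels length mismatch")


def _row_ids(n: int) -> list[str]:
    return [f"item{i:04d}" for i in range(n)]


def _col_ids(p: int) -> list[str]:
    return [f"feat{j:03d}" for j in range(p)]


def make_gaussian(
    k: int,
    n_per: int,
    P: int,
    separation: float,
    sigma: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Isotropic Gaussian blobs with controlled mean separation.

    Cluster means sit on the vertices of a regular simplex (the first
    ``k`` coordinate axes, scaled) so that the *nearest* pair of means is
    exactly ``separation * sigma`` apart; noise is N(0, sigma^2) in every
    coordinate.  ``separation=0`` gives fully exchangeable data.
    """
    if k < 1 or n_per < 1 or P < 1:
        raise ValueError("k, n_per and P must be positive")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if k > 1 and P < k:
        raise ValueError(f"need P >= k to place {k} simplex means in {P} dimensions")
    rng = np.random.default_rng(seed)
    means = np.zeros((k, P))
    if k > 1:
        # axis vertices are sqrt(2)*c apart; scale so that equals sep*sigma
        c = separation * sigma / np.sqrt(2.0)
        for j in range(k):
            means[j, j] = c
    labels = np.repeat(np.arange(1, k + 1), n_per)
    x = means[labels - 1] + rng.normal(0.0, sigma, size=(k * n_per, P))
    matrix = DataMatrix(x, _row_ids(k * n_per), _col_ids(P), "continuous")
    params = dict(kind="gaussian", k=k, n_per=n_per, P=P, separation=separation, sigma=sigma)
    return SyntheticDataset(matrix, labels, params, seed)


def make_counts(
    distribution: str,
    k: int,
    n_per: int,
    P: int,
    base_mean: float = 10.0,
    fold_change: float = 5.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Count clusters: cluster j elevates its own column block.

    Each cluster multiplies a distinct block of ``P // k`` columns by
    ``fold_change`` over the ``base_mean`` background.  ``poisson`` draws
    are plain Poisson; ``negbin`` draws are gamma-Poisson mixtures with
    variance mu + dispersion * mu^2.
    """
    if distribution not in ("poisson", "negbin"):
        raise ValueError(f"unknown distribution {distribution!r}")
    if base_mean <= 0:
        raise ValueError("base_mean must be > 0")
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    if distribution == "negbin" and dispersion <= 0:
        raise ValueError("negbin dispersion must be > 0")
    if k < 1 or n_per < 1 or P < k:
        raise ValueError("need k >= 1, n_per >= 1 and P >= k")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, k + 1), n_per)
    mu = np.full((k * n_per, P), float(base_mean))
    block = P // k
    for j in range(k):
        rows = labels == j + 1
        mu[np.ix_(rows, range(j * block, (j + 1) * block))] *= fold_change
    if distribution == "poisson":
        y = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
        y = rng.poisson(lam)
    matrix = DataMatrix(y.astype(float), _row_ids(k * n_per), _col_ids(P), "counts")
    params = dict(
        kind="counts", distribution=distribution, k=k, n_per=n_per, P=P,
        base_mean=base_mean, fold_change=fold_change, dispersion=dispersion,
    )
    return SyntheticDataset(matrix, labels, params, seed)


def make_annotation(
    true_labels: np.ndarray,
    n_classes: int,
    fidelity: float = 1.0,
    seed: int = 0,
    row_ids: list[str] | None = None,
) -> AnnotationMap:
    """Functional classes aligned to the true clusters.

    Class ``c`` is aligned with true cluster ``(c mod k)``; each item
    keeps its aligned class with probability ``fidelity`` and otherwise
    receives a uniformly random class.  ``fidelity = 1/n_classes`` makes
    the annotation independent of the clustering.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    true_labels = np.asarray(true_labels, dtype=int)
    n = len(true_labels)
    if row_ids is None:
        row_ids = _row_ids(n)
    rng = np.random.default_rng(seed)
    classes: dict[str, set[str]] = {}
    class_names = [f"class{c:02d}" for c in range(n_classes)]
    for i, lab in enumerate(true_labels):
        aligned = class_names[(lab - 1) % n_classes]
        if rng.random() < fidelity:
            chosen = aligned
        else:
            chosen = class_names[rng.integers(n_classes)]
        classes[row_ids[i]] = {chosen}
    return AnnotationMap(classes)


def make_lists(
    kappa: int,
    m: int,
    consensus_noise: int = 0,
    seed: int = 0,
) -> tuple[list[RankedList], list[CandidateKey]]:
    """Ranked-list ensemble with a planted consensus ordering.

    Each of the ``m`` lists is the planted order perturbed by
    ``consensus_noise`` random adjacent transpositions; weights are all
    1 and norm_scores are equally spaced from 1 down to 0.  Returns
    ``(lists, planted_order)``.
    """
    if kappa < 2:
        raise ValueError("kappa must be >= 2")
    if m < 1 or consensus_noise < 0:
        raise ValueError("need m >= 1 and consensus_noise >= 0")
    rng = np.random.default_rng(seed)
    planted = [CandidateKey(f"m{chr(ord('a') + i % 26)}{i}", 2) for i in range(kappa)]
    scores = np.linspace(1.0, 0.0, kappa)
    lists = []
    for i in range(m):
        order = list(planted)
        for _ in range(consensus_noise):
            j = int(rng.integers(kappa - 1))
            order[j], order[j + 1] = order[j + 1], order[j]
        lists.append(RankedList(order, scores.copy(), 1.0, f"measure{i}"))
    return lists, planted
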