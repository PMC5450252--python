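"""Clustering engines behind a uniform registry.

Continuous-data candidates: agglomerative hierarchical clustering
("hierarchical" and its alias "agnes", with selectable linkage), the
divisive DIANA procedure, k-means, PAM (partitioning around medoids,
build + swap), CLARA (PAM on subsamples), FANNY (fuzzy clustering on
dissimilarities), and a full-covariance Gaussian mixture ("model").
Count-data candidates ("em.poisson", ..., "sa.nbinom") dispatch to the
count-mixture module.

Every engine is deterministic given (matrix, key, seed, opts).  An
algorithm that leaves a cluster empty raises
:class:`~clustagg.datatypes.DegenerateCandidateError`; the orchestrator
treats that as candidate failure rather than silently re-running.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .datatypes import (
    CandidateKey,
    DataMatrix,
    DegenerateCandidateError,
    DistanceMatrix,
    Partition,
)

__all__ = [
    "compute_distance",
    "run_candidate",
    "hierarchical_cut",
    "diana_cut",
    "pam_cluster",
    "clara_cluster",
    "fanny_memberships",
    "kmeans_cluster",
    "gaussian_model_cluster",
    "CONTINUOUS_METHODS",
    "COUNT_METHODS",
    "registered_methods",
]

CONTINUOUS_METHODS = (
    "hierarchical", "agnes", "diana", "kmeans", "pam", "clara", "fanny", "model",
)
COUNT_METHODS = (
    "em.poisson", "da.poisson", "sa.poisson",
    "em.nbinom", "da.nbinom", "sa.nbinom",
)
_RESERVED = ("som", "sota")  # registry slots reserved, not implemented


def registered_methods() -> tuple[str, ...]:
    return CONTINUOUS_METHODS + COUNT_METHODS


# ---------------------------------------------------------------------------
# distances


def compute_distance(matrix: DataMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise row dissimilarities.

    ``correlation`` is 1 - Pearson correlation between rows and needs at
    least two features; a zero-variance row makes the correlation
    undefined and is reported by id.
    """
    x = matrix.values
    if metric == "euclidean":
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    elif metric == "manhattan":
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    elif metric == "correlation":
        if matrix.n_features < 2:
            raise ValueError("correlation metric requires at least 2 features")
        sd = x.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance row(s) under correlation metric: "
                f"{[matrix.row_ids[i] for i in bad]}"
            )
        d = 1.0 - np.corrcoef(x)
        d = np.clip(d, 0.0, None)
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # kill round-off asymmetry
    return DistanceMatrix(d, metric)


# ---------------------------------------------------------------------------
# hierarchical (agnes) and diana


_LINKAGES = {"average": "average", "complete": "complete", "single": "single", "ward": "ward"}


def hierarchical_cut(dist: DistanceMatrix, linkage_method: str, k: int) -> Partition:
    """Agglomerative clustering cut to exactly k groups (UPGMA default upstream)."""
    if linkage_method not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage_method!r}; choose from {sorted(_LINKAGES)}")
    n = dist.n_items
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must satisfy 2 <= k <= {n - 1}")
    z = linkage(squareform(dist.d, checks=False), method=_LINKAGES[linkage_method])
    raw = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise DegenerateCandidateError(
            f"hierarchical cut produced {len(np.unique(raw))} clusters instead of {k}"
        )
    return Partition(CandidateKey("hierarchical", k), _canonical_labels(raw))


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def diana_cut(dist: DistanceMatrix, k: int) -> Partition:
    """Divisive analysis: repeatedly split the largest-diameter cluster.

    The splinter group is seeded with the object of maximal average
    dissimilarity to the rest of its cluster; objects then migrate to
    the splinter while their average dissimilarity to it is smaller than
    to the remainder.
    """
    n = dist.n_items
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}")
    d = dist.d
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diameters = [d[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        target = int(np.argmax(diameters))
        if diameters[target] == 0.0 and len(clusters[target]) == 1:
            raise DegenerateCandidateError(f"diana cannot reach k={k}: no splittable cluster")
        clusters.extend(_diana_split(d, clusters.pop(target)))
    labels = np.empty(n, dtype=int)
    # label clusters by smallest member index for determinism
    for lab, c in enumerate(sorted(clusters, key=min), start=1):
        labels[c] = lab
    return Partition(CandidateKey("diana", k), _canonical_labels(labels))


def _diana_split(d: np.ndarray, cluster: list[int]) -> list[list[int]]:
    if len(cluster) == 1:
        return [cluster]
    idx = np.array(cluster)
    sub = d[np.ix_(idx, idx)]
    m = len(idx)
    avg = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg))  # ties -> lowest index via argmax
    splinter = [seed]
    remainder = [i for i in range(m) if i != seed]
    moved = True
    while moved and len(remainder) > 1:
        moved = False
        gains = []
        for i in remainder:
            a = sub[i, splinter].mean()
            others = [j for j in remainder if j != i]
            b = sub[i, others].mean()
            gains.append(b - a)
        best = int(np.argmax(gains))
        if gains[best] > 0:
            splinter.append(remainder.pop(best))
            moved = True
    return [[int(idx[i]) for i in splinter], [int(idx[i]) for i in remainder]]


# ---------------------------------------------------------------------------
# pam / clara


def _assign_to_medoids(d: np.ndarray, medoids: list[int]) -> np.ndarray:
    return np.argmin(d[:, medoids], axis=1)


def _pam_indices(d: np.ndarray, k: int) -> list[int]:
    """BUILD + SWAP on a dissimilarity matrix; first-improvement swaps
    in fixed index order for reproducibility."""
    n = d.shape[0]
    # BUILD: first medoid minimizes total dissimilarity; subsequent ones
    # maximize the total decrease in cost.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # SWAP
    improved = True
    while improved:
        improved = False
        current = d[:, medoids].min(axis=1).sum()
        for mi in range(len(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                cost = d[:, trial].min(axis=1).sum()
                if cost < current - 1e-12:
                    medoids = trial
                    improved = True
                    break
            if improved:
                break
    return sorted(medoids)


def pam_cluster(dist: DistanceMatrix, k: int) -> Partition:
    n = dist.n_items
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must satisfy 2 <= k <= {n - 1}")
    medoids = _pam_indices(dist.d, k)
    labels = _assign_to_medoids(dist.d, medoids) + 1
    part = Partition(CandidateKey("pam", k), _canonical_labels(labels))
    part.extras["medoids"] = medoids
    return part


def clara_cluster(
    matrix: DataMatrix,
    k: int,
    seed: int,
    metric: str = "euclidean",
    n_samples: int = 5,
    sample_size: int | None = None,
) -> Partition:
    """CLARA: PAM on random subsamples, best full-data assignment kept.

    With sample_size >= N this is exactly PAM on the full data.
    """
    n = matrix.n_items
    if sample_size is None:
        sample_size = min(n, 40 + 2 * k)
    full = compute_distance(matrix, metric)
    if sample_size >= n:
        part = pam_cluster(full, k)
        return Partition(CandidateKey("clara", k), part.labels, dict(part.extras))
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_medoids: list[int] | None = None
    for _ in range(n_samples):
        sample = np.sort(rng.choice(n, size=sample_size, replace=False))
        sub = DistanceMatrix(full.d[np.ix_(sample, sample)], metric)
        local = _pam_indices(sub.d, k)
        medoids = [int(sample[i]) for i in local]
        cost = full.d[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_medoids = medoids
    assert best_medoids is not None
    labels = _assign_to_medoids(full.d, best_medoids) + 1
    part = Partition(CandidateKey("clara", k), _canonical_labels(labels))
    part.extras["medoids"] = sorted(best_medoids)
    return part


# ---------------------------------------------------------------------------
# fanny


def fanny_memberships(
    dist: DistanceMatrix,
    k: int,
    fuzziness: float = 2.0,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> Partition:
    """Fuzzy clustering on dissimilarities (relational fuzzy c-means).

    Minimizes sum_v [sum_{i,j} u_iv^r u_jv^r d2_ij] / [2 sum_j u_jv^r]
    over squared dissimilarities d2 with exponent r = ``fuzziness``, by
    alternating the cluster "pull" e_iv (relational squared distance of
    item i to fuzzy cluster v) with the standard membership update
    u_iv ~ e_iv^{-1/(r-1)}.  On euclidean input this is fuzzy c-means in
    the underlying feature space.  Hard labels are the row-wise argmax;
    the membership grid is stored in extras.
    """
    if fuzziness <= 1:
        raise ValueError("fuzziness must be > 1")
    n = dist.n_items
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must satisfy 2 <= k <= {n - 1}")
    d = dist.d**2
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(k), size=n)
    r = fuzziness
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        w = u**r  # n x k
        col = w.sum(axis=0)  # per-cluster mass
        col = np.maximum(col, 1e-300)
        # relational "distance" of item i to cluster v
        dw = d @ w  # n x k
        within = np.einsum("iv,iv->v", w, dw)  # sum_{i,j} w_iv w_jv d_ij
        e = dw / col[None, :] - within[None, :] / (2.0 * col[None, :] ** 2)
        e = np.maximum(e, 1e-12)
        obj = float((within / (2.0 * col)).sum())
        u = e ** (-1.0 / (r - 1.0))
        u /= u.sum(axis=1, keepdims=True)
        if np.isfinite(prev_obj) and abs(prev_obj - obj) <= tol * max(1.0, abs(obj)):
            break
        prev_obj = obj
    else:
        raise RuntimeError(f"fanny did not converge in {max_iter} iterations")
    labels = np.argmax(u, axis=1) + 1
    labels = _canonical_labels(labels)
    # reorder membership columns to match canonical labels
    order = []
    seen: dict[int, int] = {}
    raw = np.argmax(u, axis=1)
    for lab in raw:
        if lab not in seen:
            seen[lab] = len(seen)
            order.append(lab)
    if len(order) < k:
        order += [c for c in range(k) if c not in order]
    u = u[:, order]
    u /= u.sum(axis=1, keepdims=True)
    part = Partition(CandidateKey("fanny", k), labels, {"memberships": u})
    return part


# ---------------------------------------------------------------------------
# kmeans / gaussian mixture


def kmeans_cluster(matrix: DataMatrix, k: int, seed: int, n_init: int = 10) -> Partition:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(matrix.values) + 1
    return Partition(CandidateKey("kmeans", k), _canonical_labels(raw))


def gaussian_model_cluster(
    matrix: DataMatrix, k: int, seed: int, n_init: int = 10
) -> Partition:
    """Full-covariance Gaussian mixture, EM with k-means initialization,
    best of ``n_init`` restarts by log-likelihood."""
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-6,
    )
    raw = gm.fit_predict(matrix.values) + 1
    part = Partition(CandidateKey("model", k), _canonical_labels(raw))
    part.extras["loglik"] = float(gm.score(matrix.values) * matrix.n_items)
    return part


# ---------------------------------------------------------------------------
# registry dispatch


def run_candidate(
    matrix: DataMatrix,
    key: CandidateKey,
    seed: int = 0,
    opts: dict | None = None,
) -> Partition:
    """Produce the Partition for one (method, k) candidate.

    ``opts`` keys understood here: ``metric`` (euclidean | correlation |
    manhattan), ``linkage`` (hierarchical/agnes), ``fuzziness`` (fanny),
    ``clara_samples`` / ``clara_sample_size``, and the count-mixture
    options forwarded to :func:`clustagg.count_mixture.fit_count_mixture`.
    """
    opts = dict(opts or {})
    method, k = key.method, key.k
    n = matrix.n_items
    if method in _RESERVED:
        raise NotImplementedError(
            f"method {method!r} is reserved but not implemented in this package"
        )
    if method not in registered_methods():
        raise ValueError(
            f"unknown method {method!r}; registered: {', '.join(registered_methods())}"
        )
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} invalid for N={n} (need 2 <= k <= N-1)")

    if method in COUNT_METHODS:
        if matrix.domain != "counts":
            raise ValueError(f"method {method!r} requires a counts-domain matrix")
        from . import count_mixture

        algorithm, distribution = method.split(".")
        fit = count_mixture.fit_count_mixture(
            matrix,
            distribution={"poisson": "poisson", "nbinom": "negbin"}[distribution],
            algorithm=algorithm.upper(),
            k=k,
            seed=seed,
            opts=opts,
        )
        part = count_mixture.map_partition(fit)
        part = Partition(key, part.labels, dict(part.extras))
        return part

    metric = opts.get("metric", "euclidean")
    if method in ("hierarchical", "agnes"):
        dist = compute_distance(matrix, metric)
        part = hierarchical_cut(dist, opts.get("linkage", "average"), k)
    elif method == "diana":
        part = diana_cut(compute_distance(matrix, metric), k)
    elif method == "kmeans":
        part = kmeans_cluster(matrix, k, seed)
    elif method == "pam":
        part = pam_cluster(compute_distance(matrix, metric), k)
    elif method == "clara":
        part = clara_cluster(
            matrix, k, seed, metric,
            n_samples=opts.get("clara_samples", 5),
            sample_size=opts.get("clara_sample_size"),
        )
    elif method == "fanny":
        part = fanny_memberships(
            compute_distance(matrix, metric), k, opts.get("fuzziness", 2.0), seed
        )
    elif method == "model":
        part = gaussian_model_cluster(matrix, k, seed)
    else:  # pragma: no cover - registry is exhaustive
        raise AssertionError(method)
    return Partition(key, part.labels, dict(part.extras))
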