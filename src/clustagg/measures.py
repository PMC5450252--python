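"""The nine cluster-validation measures.

Internal measures (connectivity, Dunn index, silhouette width) score a
partition against the data alone.  Stability measures (APN, AD, ADM,
FOM) compare the full-data partition to partitions refit after deleting
each feature column in turn, so they reward assignments that survive
small perturbations of the data.  Biological measures (BHI, BSI) score
agreement between clusters and an external functional annotation of the
items.

Directions: connectivity, APN, AD, ADM and FOM are minimized; Dunn,
silhouette, BHI and BSI are maximized.  All measures are invariant
under relabeling of the clusters.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    AnnotationMap,
    CandidateKey,
    DataMatrix,
    DegenerateCandidateError,
    DistanceMatrix,
    MeasureSpec,
    MEASURE_SPECS,
    Partition,
    ValidationScoreTable,
)
from .partition import compute_distance, run_candidate

__all__ = [
    "connectivity",
    "dunn",
    "silhouette",
    "stability_suite",
    "bhi",
    "bsi",
    "score_all",
]


# ---------------------------------------------------------------------------
# internal measures


def connectivity(part: Partition, dist: DistanceMatrix, L: int = 10) -> float:
    """Degree to which nearest neighbors share a cluster (minimize).

    Sum over items of 1/j for each of the L nearest neighbors (j = 1..L)
    not co-clustered with the item.  Neighbor ties break to the lower
    item index.
    """
    n = dist.n_items
    if not 1 <= L <= n - 1:
        raise ValueError(f"L must satisfy 1 <= L <= {n - 1}")
    total = 0.0
    for i in range(n):
        order = np.argsort(dist.d[i], kind="stable")
        order = order[order != i][:L]
        for j, nb in enumerate(order, start=1):
            if part.labels[nb] != part.labels[i]:
                total += 1.0 / j
    return total


def dunn(part: Partition, dist: DistanceMatrix) -> float:
    """Min inter-cluster distance over max intra-cluster diameter (maximize)."""
    labels = part.labels
    ks = np.unique(labels)
    max_diam = 0.0
    for c in ks:
        m = np.flatnonzero(labels == c)
        if len(m) > 1:
            max_diam = max(max_diam, dist.d[np.ix_(m, m)].max())
    if max_diam == 0.0:
        raise DegenerateCandidateError("Dunn undefined: every cluster has zero diameter")
    min_sep = np.inf
    for a in range(len(ks)):
        for b in range(a + 1, len(ks)):
            ma = np.flatnonzero(labels == ks[a])
            mb = np.flatnonzero(labels == ks[b])
            min_sep = min(min_sep, dist.d[np.ix_(ma, mb)].min())
    return float(min_sep / max_diam)


def silhouette(part: Partition, dist: DistanceMatrix) -> float:
    """Mean silhouette width (maximize); singleton clusters score 0."""
    labels = part.labels
    n = dist.n_items
    ks = np.unique(labels)
    if len(ks) < 2:
        raise ValueError("silhouette requires k >= 2")
    s = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero(labels == labels[i])
        if len(own) == 1:
            continue  # singleton convention s_i = 0
        a = dist.d[i, own[own != i]].mean()
        b = min(
            dist.d[i, np.flatnonzero(labels == c)].mean() for c in ks if c != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


# ---------------------------------------------------------------------------
# stability measures (leave-one-column-out reclustering)


def _deleted_partitions(
    matrix: DataMatrix, key: CandidateKey, seed: int, opts: dict | None
) -> list[Partition]:
    """Recluster after deleting each feature column, same (key, seed)."""
    if matrix.n_features < 2:
        raise ValueError("stability measures need at least 2 feature columns")
    return [
        run_candidate(matrix.drop_column(j), key, seed, opts)
        for j in range(matrix.n_features)
    ]


def stability_suite(
    matrix: DataMatrix,
    key: CandidateKey,
    seed: int = 0,
    metric: str = "euclidean",
    opts: dict | None = None,
    full_part: Partition | None = None,
    deleted: list[Partition] | None = None,
) -> dict[str, float]:
    """APN, AD, ADM and FOM for one candidate (all minimized).

    For every deleted column the remaining data are reclustered with the
    same (method, k, seed).  APN averages the proportion of each item's
    full-data cluster lost in the reduced-data partition; AD averages
    the full-data distances between the two clusters containing an item;
    ADM averages the euclidean distance between their full-data mean
    vectors; FOM is the within-cluster dispersion of the deleted column
    under the reduced-data partition, adjusted by sqrt(N/(N-k)).
    """
    opts = dict(opts or {})
    opts.setdefault("metric", metric)
    x = matrix.values
    n, p = x.shape
    if full_part is None:
        full_part = run_candidate(matrix, key, seed, opts)
    if deleted is None:
        deleted = _deleted_partitions(matrix, key, seed, opts)
    dist = compute_distance(matrix, metric)
    apn_terms, ad_terms, adm_terms, fom_terms = [], [], [], []
    for ell, red in enumerate(deleted):
        for i in range(n):
            full_c = np.flatnonzero(full_part.labels == full_part.labels[i])
            red_c = np.flatnonzero(red.labels == red.labels[i])
            inter = len(np.intersect1d(full_c, red_c, assume_unique=True))
            apn_terms.append(1.0 - inter / len(full_c))
            ad_terms.append(dist.d[np.ix_(full_c, red_c)].mean())
            adm_terms.append(
                float(np.linalg.norm(x[full_c].mean(axis=0) - x[red_c].mean(axis=0)))
            )
        # FOM on the deleted column under the reduced partition
        sq = 0.0
        for c in np.unique(red.labels):
            m = np.flatnonzero(red.labels == c)
            sq += ((x[m, ell] - x[m, ell].mean()) ** 2).sum()
        fom_terms.append(np.sqrt(sq / n) * np.sqrt(n / (n - key.k)))
    return {
        "APN": float(np.mean(apn_terms)),
        "AD": float(np.mean(ad_terms)),
        "ADM": float(np.mean(adm_terms)),
        "FOM": float(np.mean(fom_terms)),
    }


# ---------------------------------------------------------------------------
# biological measures


def bhi(part: Partition, ann: AnnotationMap, row_ids: list[str]) -> float:
    """Biological homogeneity index (maximize, in [0, 1]).

    Mean over clusters holding >= 2 annotated items of the fraction of
    ordered annotated pairs sharing at least one functional class.
    Unannotated items do not count toward cluster sizes.
    """
    cls = ann.classes
    terms = []
    for c in np.unique(part.labels):
        members = [row_ids[i] for i in part.members(c) if row_ids[i] in cls]
        if len(members) < 2:
            continue
        agree = sum(
            1
            for a in members
            for b in members
            if a != b and cls[a] & cls[b]
        )
        terms.append(agree / (len(members) * (len(members) - 1)))
    if not terms:
        raise ValueError("BHI undefined: no cluster has 2 annotated items")
    return float(np.mean(terms))


def bsi(
    matrix: DataMatrix,
    key: CandidateKey,
    ann: AnnotationMap,
    seed: int = 0,
    opts: dict | None = None,
    full_part: Partition | None = None,
    deleted: list[Partition] | None = None,
) -> float:
    """Biological stability index (maximize, in [0, 1]).

    For each deleted column and each functional class F with >= 2
    annotated items, averages |C(i,0) ∩ C(j,ell)| / |C(i,0)| over
    ordered pairs i != j in F, where C(i,0) is item i's full-data
    cluster and C(j,ell) is item j's reduced-data cluster.
    """
    opts = dict(opts or {})
    if full_part is None:
        full_part = run_candidate(matrix, key, seed, opts)
    if deleted is None:
        deleted = _deleted_partitions(matrix, key, seed, opts)
    idx = {rid: i for i, rid in enumerate(matrix.row_ids)}
    classes = {
        c: sorted(members & set(idx))
        for c, members in ann.class_members().items()
    }
    classes = {c: m for c, m in classes.items() if len(m) >= 2}
    if not classes:
        raise ValueError("BSI undefined: no annotation class has 2 items")
    terms = []
    for red in deleted:
        for members in classes.values():
            tot = 0.0
            nf = len(members)
            for a in members:
                ia = idx[a]
                full_c = np.flatnonzero(full_part.labels == full_part.labels[ia])
                full_set = set(full_c.tolist())
                for b in members:
                    if a == b:
                        continue
                    ib = idx[b]
                    red_c = np.flatnonzero(red.labels == red.labels[ib])
                    tot += len(full_set & set(red_c.tolist())) / len(full_c)
            terms.append(tot / (nf * (nf - 1)))
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# the full score table


def score_all(
    matrix: DataMatrix,
    candidates: list[CandidateKey],
    specs: list[MeasureSpec],
    ann: AnnotationMap | None = None,
    seed: int = 0,
    opts: dict | None = None,
    partitions: dict[CandidateKey, Partition] | None = None,
    warnings_out: list[str] | None = None,
) -> ValidationScoreTable:
    """Score every candidate on every requested measure.

    Candidates that fail (degenerate partition, reclustering failure,
    undefined measure) are dropped from *all* measures with a warning,
    so every ranked list covers the same candidate set.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates")
    if any(s.type == "biological" for s in specs) and ann is None:
        raise ValueError("biological measures require an annotation map")
    opts = dict(opts or {})
    metric = opts.get("metric", "euclidean")
    L = opts.get("neighb_size", 10)
    warn = warnings_out if warnings_out is not None else []
    if ann is not None:
        ann, dropped = ann.restrict(matrix.row_ids)
        if dropped:
            warn.append(f"annotation: dropped {dropped} ids absent from the matrix")
    need_stability = any(s.type == "stability" for s in specs) or any(
        s.name == "BSI" for s in specs
    )
    dist = compute_distance(matrix, metric)
    cols: dict[CandidateKey, dict[str, float]] = {}
    for key in candidates:
        try:
            part = (
                partitions[key]
                if partitions is not None and key in partitions
                else run_candidate(matrix, key, seed, opts)
            )
            deleted = _deleted_partitions(matrix, key, seed, opts) if need_stability else None
            scores: dict[str, float] = {}
            for spec in specs:
                if spec.name == "connectivity":
                    scores[spec.name] = connectivity(part, dist, L)
                elif spec.name == "dunn":
                    scores[spec.name] = dunn(part, dist)
                elif spec.name == "silhouette":
                    scores[spec.name] = silhouette(part, dist)
                elif spec.name in ("APN", "AD", "ADM", "FOM"):
                    if spec.name not in scores:
                        scores.update(
                            stability_suite(
                                matrix, key, seed, metric, opts,
                                full_part=part, deleted=deleted,
                            )
                        )
                elif spec.name == "BHI":
                    scores[spec.name] = bhi(part, ann, matrix.row_ids)
                elif spec.name == "BSI":
                    scores[spec.name] = bsi(
                        matrix, key, ann, seed, opts,
                        full_part=part, deleted=deleted,
                    )
            cols[key] = scores
        except (DegenerateCandidateError, ValueError, RuntimeError) as exc:
            warn.append(f"candidate {key} dropped: {exc}")
    if len(cols) < 2:
        raise ValueError(
            f"fewer than 2 candidates survived scoring ({len(cols)}); "
            "nothing to rank"
        )
    survivors = [key for key in candidates if key in cols]
    grid = np.array(
        [[cols[key][s.name] for key in survivors] for s in specs], dtype=float
    )
    for w in warn:
        if warnings_out is None:
            warnings.warn(w)
    return ValidationScoreTable(grid, list(specs), survivors)
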