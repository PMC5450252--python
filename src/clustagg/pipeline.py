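"""End-to-end pipeline: candidate grid -> partitions -> score table ->
ranked lists -> aggregation -> consensus choice.

The candidate universe is the cross-product of requested methods and
cluster numbers.  Candidates that fail on any measure are dropped
uniformly so that every ranked list orders the same set; the remaining
lists are aggregated into a single consensus ordering whose head is the
reported best (algorithm, k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    AggregationResult,
    AnnotationMap,
    CandidateKey,
    DataMatrix,
    MEASURE_SPECS,
    MeasureSpec,
    Partition,
    RankedList,
    ValidationScoreTable,
)
from .measures import score_all
from .partition import (
    COUNT_METHODS,
    CONTINUOUS_METHODS,
    registered_methods,
    run_candidate,
)
from .rankagg import (
    aggregate_ce,
    aggregate_ga,
    brute_force_aggregate,
    to_ranked_lists,
)

__all__ = [
    "OptClusterResult",
    "opt_cluster",
    "optimal_scores",
    "method_ranks",
    "score_ranks",
    "cluster_results",
    "measures_for_types",
]

_TYPE_MEASURES = {
    "internal": ["connectivity", "dunn", "silhouette"],
    "stability": ["APN", "AD", "ADM", "FOM"],
    "biological": ["BHI", "BSI"],
}


def measures_for_types(validation_types: list[str]) -> list[MeasureSpec]:
    specs: list[MeasureSpec] = []
    for t in validation_types:
        if t not in _TYPE_MEASURES:
            raise ValueError(f"unknown validation type {t!r}")
        specs.extend(MEASURE_SPECS[name] for name in _TYPE_MEASURES[t])
    if not specs:
        raise ValueError("no validation measures requested")
    return specs


@dataclass
class OptClusterResult:
    partitions: dict[CandidateKey, Partition]
    score_table: ValidationScoreTable
    ranked_lists: list[RankedList]
    aggregation: AggregationResult
    best: CandidateKey
    config_echo: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.best != self.aggregation.best_order[0]:
            raise ValueError("best must be the head of the aggregated ordering")


def opt_cluster(
    matrix: DataMatrix,
    methods: list[str],
    k_range: list[int],
    validation_types: list[str] = ("internal",),
    ann: AnnotationMap | None = None,
    weights: list[float] | None = None,
    distance: str = "footrule",
    weighted_distance: bool = True,
    optimizer: str = "CE",
    seed: int = 0,
    opts: dict | None = None,
) -> OptClusterResult:
    """Evaluate methods x k_range with the requested validation measures
    and aggregate the per-measure rankings into one consensus choice.

    ``weights`` gives one importance weight per measure (default equal);
    weights are normalized to sum to the number of measures so the Phi
    scale does not drift with the weighting.  ``optimizer`` is "CE"
    (cross-entropy Monte Carlo), "GA" (genetic algorithm), or "brute"
    (exact, small candidate sets only).
    """
    opts = dict(opts or {})
    methods = list(methods)
    k_range = sorted(set(int(k) for k in k_range))
    validation_types = list(validation_types)
    if not methods:
        raise ValueError("no clustering methods requested")
    unknown = [m for m in methods if m not in registered_methods()]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; registered: {', '.join(registered_methods())}"
        )
    n = matrix.n_items
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    count_m = [m for m in methods if m in COUNT_METHODS]
    cont_m = [m for m in methods if m in CONTINUOUS_METHODS]
    if count_m and matrix.domain != "counts":
        raise ValueError(f"count-data methods {count_m} require a counts-domain matrix")
    if cont_m and matrix.domain == "counts" and not opts.get("allow_counts_continuous"):
        raise ValueError(
            "continuous methods on a counts matrix: normalize first "
            "(io.normalize_library_size) or set opts['allow_counts_continuous']"
        )
    if "biological" in validation_types and ann is None:
        raise ValueError("biological validation requires an annotation map")
    specs = measures_for_types(validation_types)
    if weights is not None:
        if len(weights) != len(specs) or any(w <= 0 for w in weights):
            raise ValueError("need one positive weight per measure")
        w = np.asarray(weights, dtype=float)
        weights = list(w * len(w) / w.sum())

    candidates = [CandidateKey(m, k) for m in methods for k in k_range]
    warnings_out: list[str] = []
    partitions: dict[CandidateKey, Partition] = {}
    for key in candidates:
        try:
            partitions[key] = run_candidate(matrix, key, seed, opts)
        except Exception as exc:  # degenerate or invalid for this data
            warnings_out.append(f"candidate {key} failed: {exc}")
    table = score_all(
        matrix,
        [key for key in candidates if key in partitions],
        specs,
        ann=ann,
        seed=seed,
        opts=opts,
        partitions=partitions,
        warnings_out=warnings_out,
    )
    partitions = {key: partitions[key] for key in table.candidates}
    lists = to_ranked_lists(table, weights)
    if len(lists) == 1:
        # aggregation of a single list is its identity
        agg = AggregationResult(list(lists[0].order), 0.0, "identity", [0.0], seed, True)
    elif optimizer == "CE":
        agg = aggregate_ce(lists, distance, weighted_distance,
                           opts.get("optimizer_params"), seed)
    elif optimizer == "GA":
        agg = aggregate_ga(lists, distance, weighted_distance,
                           opts.get("optimizer_params"), seed)
    elif optimizer == "brute":
        agg = brute_force_aggregate(lists, distance, weighted_distance)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r} (CE | GA | brute)")
    config_echo = dict(
        methods=methods,
        k_range=k_range,
        validation_types=validation_types,
        weights=weights,
        distance=distance,
        weighted_distance=weighted_distance,
        optimizer=optimizer,
        seed=seed,
        opts={k: v for k, v in opts.items() if k != "optimizer_params"},
        row_ids=list(matrix.row_ids),
    )
    return OptClusterResult(
        partitions=partitions,
        score_table=table,
        ranked_lists=lists,
        aggregation=agg,
        best=agg.best_order[0],
        config_echo=config_echo,
        warnings=warnings_out,
    )


def optimal_scores(result: OptClusterResult) -> dict[str, tuple[float, CandidateKey]]:
    """Per-measure best (score, candidate), honoring each direction."""
    out = {}
    for spec, lst in zip(result.score_table.specs, result.ranked_lists):
        best_key = lst.order[0]
        j = result.score_table.candidates.index(best_key)
        out[spec.name] = (float(result.score_table.scores
                                [result.score_table.specs.index(spec), j]), best_key)
    return out


def method_ranks(result: OptClusterResult) -> list[list[CandidateKey]]:
    """measures x candidates grid of candidates, best first per measure."""
    return [list(lst.order) for lst in result.ranked_lists]


def score_ranks(result: OptClusterResult) -> list[list[float]]:
    """Raw scores aligned with :func:`method_ranks`."""
    out = []
    for i, lst in enumerate(result.ranked_lists):
        row = result.score_table.scores[i]
        idx = {key: j for j, key in enumerate(result.score_table.candidates)}
        out.append([float(row[idx[key]]) for key in lst.order])
    return out


def cluster_results(result: OptClusterResult, method: str) -> list[Partition]:
    """All partitions for one algorithm, in increasing-k order."""
    parts = sorted(
        (key for key in result.partitions if key.method == method),
        key=lambda key: key.k,
    )
    if not parts:
        raise ValueError(f"method {method!r} was not run (or all its candidates failed)")
    return [result.partitions[key] for key in parts]
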