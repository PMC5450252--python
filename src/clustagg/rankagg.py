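"""Weighted rank aggregation of validation-measure lists.

Each validation measure orders the candidate (algorithm, k) pairs into a
ranked list V_i with importance weight w_i.  The consensus ordering L*
minimizes

    Phi(L) = sum_i w_i * dist(L, V_i)

where dist is the (weighted) Spearman footrule or (weighted) Kendall tau
distance.  Optimizers: exhaustive enumeration for small candidate sets
(the oracle), a cross-entropy Monte Carlo sampler over a
position-probability matrix, and a permutation-encoded genetic
algorithm.  Weighted distances weight each rank displacement (footrule)
or discordant pair (Kendall) by the normalized-score difference the
displacement spans in V_i, so swaps between near-tied candidates cost
little.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from .datatypes import (
    AggregationResult,
    CandidateKey,
    RankedList,
    ValidationScoreTable,
)

__all__ = [
    "to_ranked_lists",
    "footrule_distance",
    "kendall_distance",
    "objective_phi",
    "brute_force_aggregate",
    "aggregate_ce",
    "aggregate_ga",
    "CE_DEFAULTS",
    "GA_DEFAULTS",
]

CE_DEFAULTS = dict(sample_size=None, rho=0.1, smoothing=0.7, conv_in=7, max_iter=1000)
GA_DEFAULTS = dict(pop_size=100, cross_prob=0.4, mut_prob=0.01, conv_in=30, max_iter=1000)


# ---------------------------------------------------------------------------
# list construction


def to_ranked_lists(
    table: ValidationScoreTable, weights: list[float] | None = None
) -> list[RankedList]:
    """One ranked list per measure, sorted by the measure's direction.

    Ties break by (method name lexicographic, then smaller k).  Scores
    are min-max normalized to [0, 1] with the best candidate at 1; a
    constant score row normalizes to all-ones with a warning.
    """
    m = len(table.specs)
    if weights is None:
        weights = [1.0] * m
    if len(weights) != m or any(w <= 0 for w in weights):
        raise ValueError("need one strictly positive weight per measure")
    if len(table.candidates) < 2:
        raise ValueError("need at least 2 candidates to rank")
    lists = []
    for i, spec in enumerate(table.specs):
        scores = table.scores[i]
        sign = -1.0 if spec.direction == "maximize" else 1.0
        order_idx = sorted(
            range(len(table.candidates)),
            key=lambda j: (sign * scores[j], table.candidates[j].method, table.candidates[j].k),
        )
        lo, hi = scores.min(), scores.max()
        if hi - lo < 1e-300:
            warnings.warn(f"measure {spec.name}: constant scores, normalizing to all 1")
            norm = np.ones(len(scores))
        elif spec.direction == "maximize":
            norm = (scores - lo) / (hi - lo)
        else:
            norm = (hi - scores) / (hi - lo)
        order = [table.candidates[j] for j in order_idx]
        lists.append(RankedList(order, norm[order_idx], float(weights[i]), spec.name))
    return lists


# ---------------------------------------------------------------------------
# vectorized distance machinery


class _ListArrays:
    """Lists compiled against a canonical key indexing for batch scoring."""

    def __init__(self, lists: list[RankedList], distance: str, weighted: bool):
        if not lists:
            raise ValueError("need at least one ranked list")
        if distance not in ("footrule", "kendall"):
            raise ValueError(f"unknown distance {distance!r}")
        self.keys = list(lists[0].order)
        keyset = set(self.keys)
        kappa = len(self.keys)
        index = {key: t for t, key in enumerate(self.keys)}
        m = len(lists)
        self.distance, self.weighted = distance, weighted
        self.weights = np.array([v.weight for v in lists])
        self.rank = np.empty((m, kappa), dtype=np.int64)  # rank_V[item], 1-based
        self.pos_scores = np.empty((m, kappa))  # s_V by position (0-based)
        for i, v in enumerate(lists):
            if set(v.order) != keyset:
                raise ValueError("ranked lists must share one candidate set")
            for pos, key in enumerate(v.order):
                self.rank[i, index[key]] = pos + 1
            self.pos_scores[i] = v.norm_scores
        if distance == "kendall":
            t_idx, u_idx = np.triu_indices(kappa, k=1)
            self.pair_t, self.pair_u = t_idx, u_idx
            dv = self.rank[:, t_idx] - self.rank[:, u_idx]  # m x pairs
            self.sign_v = np.sign(dv)
            if weighted:
                sv = np.take_along_axis(self.pos_scores, self.rank - 1, axis=1)
                self.pair_w = np.abs(sv[:, t_idx] - sv[:, u_idx])
            else:
                self.pair_w = np.ones_like(dv, dtype=float)

    @property
    def kappa(self) -> int:
        return len(self.keys)

    def perm_to_array(self, order: list[CandidateKey]) -> np.ndarray:
        index = {key: t for t, key in enumerate(self.keys)}
        if set(order) != set(self.keys) or len(order) != self.kappa:
            raise ValueError("permutation does not match the lists' candidate set")
        return np.array([index[key] for key in order], dtype=np.int64)

    def phi_batch(self, perms: np.ndarray) -> np.ndarray:
        """Phi for a batch of permutations (B x kappa, entries = canonical
        item indices in best-first order)."""
        B, kappa = perms.shape
        rank_l = np.empty((B, kappa), dtype=np.int64)
        rows = np.arange(B)[:, None]
        rank_l[rows, perms] = np.arange(1, kappa + 1)[None, :]
        total = np.zeros(B)
        if self.distance == "footrule":
            for i in range(self.rank.shape[0]):
                disp = np.abs(rank_l - self.rank[i][None, :])
                if self.weighted:
                    s = self.pos_scores[i]
                    sw = np.abs(s[self.rank[i] - 1][None, :] - s[rank_l - 1])
                    d = (sw * disp).sum(axis=1)
                else:
                    d = disp.sum(axis=1)
                total += self.weights[i] * d
        else:
            dl = rank_l[:, self.pair_t] - rank_l[:, self.pair_u]
            sign_l = np.sign(dl)
            for i in range(self.rank.shape[0]):
                disc = (sign_l * self.sign_v[i][None, :]) < 0
                total += self.weights[i] * (disc * self.pair_w[i][None, :]).sum(axis=1)
        return total


def footrule_distance(L: list[CandidateKey], V: RankedList, weighted: bool = False) -> float:
    """(Weighted) Spearman footrule between an ordering L and list V."""
    arr = _ListArrays([V], "footrule", weighted)
    return float(arr.phi_batch(arr.perm_to_array(L)[None, :])[0])


def kendall_distance(L: list[CandidateKey], V: RankedList, weighted: bool = False) -> float:
    """(Weighted) Kendall tau distance between an ordering L and list V."""
    arr = _ListArrays([V], "kendall", weighted)
    return float(arr.phi_batch(arr.perm_to_array(L)[None, :])[0])


def objective_phi(
    L: list[CandidateKey],
    lists: list[RankedList],
    distance: str = "footrule",
    weighted: bool = True,
) -> float:
    """Phi(L) = sum_i w_i * dist(L, V_i)."""
    arr = _ListArrays(lists, distance, weighted)
    return float(arr.phi_batch(arr.perm_to_array(L)[None, :])[0])


# ---------------------------------------------------------------------------
# optimizers


def brute_force_aggregate(
    lists: list[RankedList], distance: str = "footrule", weighted: bool = True
) -> AggregationResult:
    """Exact minimizer by enumerating all kappa! permutations (kappa <= 8).

    Ties break to the lexicographically first permutation in the
    canonical (first list's) ordering, for determinism.
    """
    arr = _ListArrays(lists, distance, weighted)
    kappa = arr.kappa
    if kappa > 8:
        raise ValueError(f"brute force refuses kappa={kappa} > 8")
    if kappa == 1:
        return AggregationResult(list(arr.keys), 0.0, "brute", [0.0], 0, True)
    perms = np.array(list(itertools.permutations(range(kappa))), dtype=np.int64)
    phis = arr.phi_batch(perms)
    best = int(np.argmin(phis))  # argmin returns the first = lexicographically smallest
    order = [arr.keys[t] for t in perms[best]]
    return AggregationResult(order, float(phis[best]), "brute", [float(phis[best])], 0, True)


def _check_common(lists, conv_in, max_iter):
    if len(lists) == 0:
        raise ValueError("no ranked lists supplied")
    if conv_in < 1 or max_iter < 1:
        raise ValueError("conv_in and max_iter must be >= 1")


def aggregate_ce(
    lists: list[RankedList],
    distance: str = "footrule",
    weighted: bool = True,
    params: dict | None = None,
    seed: int = 0,
) -> AggregationResult:
    """Cross-entropy Monte Carlo minimization of Phi.

    Maintains a kappa x kappa position-probability matrix (initialized
    uniform); each iteration samples permutations row-by-row without
    replacement, keeps the ceil(rho * sample_size) elite by Phi, and
    blends the elite position frequencies into the matrix with factor
    ``smoothing``.  Stops when the incumbent best Phi is unchanged for
    ``conv_in`` iterations.
    """
    p = {**CE_DEFAULTS, **(params or {})}
    arr = _ListArrays(lists, distance, weighted)
    kappa = arr.kappa
    if kappa < 2:
        raise ValueError("need at least 2 candidates")
    if not 0 < p["rho"] < 1:
        raise ValueError("rho must lie in (0, 1)")
    if not 0 < p["smoothing"] <= 1:
        raise ValueError("smoothing must lie in (0, 1]")
    _check_common(lists, p["conv_in"], p["max_iter"])
    sample_size = p["sample_size"] or 10 * kappa * kappa
    n_elite = int(np.ceil(p["rho"] * sample_size))
    rng = np.random.default_rng(seed)
    prob = np.full((kappa, kappa), 1.0 / kappa)
    # the input lists themselves join the first batch, so tied optima
    # resolve toward the observed orderings
    warm = np.array([arr.perm_to_array(v.order) for v in lists], dtype=np.int64)
    best_perm: np.ndarray | None = None
    best_phi = np.inf
    trace: list[float] = []
    stall = 0
    converged = False
    for it in range(p["max_iter"]):
        perms = _sample_perms(prob, sample_size, rng)
        if it == 0:
            perms = np.vstack([warm, perms])
        phis = arr.phi_batch(perms)
        order = np.argsort(phis, kind="stable")
        elite = perms[order[:n_elite]]
        if phis[order[0]] < best_phi - 1e-12:
            best_phi = float(phis[order[0]])
            best_perm = perms[order[0]].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_phi)
        freq = np.zeros((kappa, kappa))
        pos = np.arange(kappa)
        for e in elite:
            freq[pos, e] += 1.0
        freq /= n_elite
        prob = p["smoothing"] * freq + (1 - p["smoothing"]) * prob
        if stall >= p["conv_in"]:
            converged = True
            break
    assert best_perm is not None
    return AggregationResult(
        [arr.keys[t] for t in best_perm], best_phi, "CE", trace, seed, converged
    )


def _sample_perms(prob: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample permutations row-by-row from a position-probability matrix,
    without replacement within each permutation."""
    kappa = prob.shape[0]
    out = np.empty((size, kappa), dtype=np.int64)
    avail = np.ones((size, kappa), dtype=bool)
    rows = np.arange(size)
    for pos in range(kappa):
        w = prob[pos][None, :] * avail
        tot = w.sum(axis=1, keepdims=True)
        uniform = avail / avail.sum(axis=1, keepdims=True)
        w = np.where(tot > 1e-300, w / np.maximum(tot, 1e-300), uniform)
        u = rng.random(size)[:, None]
        choice = (w.cumsum(axis=1) < u).sum(axis=1)
        choice = np.minimum(choice, kappa - 1)
        # guard round-off: choice must be available
        bad = ~avail[rows, choice]
        if bad.any():
            for b in np.flatnonzero(bad):
                choice[b] = np.flatnonzero(avail[b])[0]
        out[:, pos] = choice
        avail[rows, choice] = False
    return out


def aggregate_ga(
    lists: list[RankedList],
    distance: str = "footrule",
    weighted: bool = True,
    params: dict | None = None,
    seed: int = 0,
) -> AggregationResult:
    """Genetic-algorithm minimization of Phi.

    Permutation-encoded population; rank-based (fitness-proportional on
    -Phi rank) parent selection; order crossover; swap mutation; elitism
    of one.  Convergence as in the cross-entropy optimizer.
    """
    p = {**GA_DEFAULTS, **(params or {})}
    arr = _ListArrays(lists, distance, weighted)
    kappa = arr.kappa
    if kappa < 2:
        raise ValueError("need at least 2 candidates")
    if not 0 < p["cross_prob"] <= 1 or not 0 <= p["mut_prob"] <= 1 or p["pop_size"] < 2:
        raise ValueError("invalid GA parameters")
    _check_common(lists, p["conv_in"], p["max_iter"])
    rng = np.random.default_rng(seed)
    pop_size = p["pop_size"]
    pop = np.array([rng.permutation(kappa) for _ in range(pop_size)], dtype=np.int64)
    # seed the population with the input lists themselves
    for i, v in enumerate(lists[: pop_size // 2]):
        pop[i] = arr.perm_to_array(v.order)
    best_perm: np.ndarray | None = None
    best_phi = np.inf
    trace: list[float] = []
    stall = 0
    converged = False
    for _ in range(p["max_iter"]):
        phis = arr.phi_batch(pop)
        order = np.argsort(phis, kind="stable")
        if phis[order[0]] < best_phi - 1e-12:
            best_phi = float(phis[order[0]])
            best_perm = pop[order[0]].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_phi)
        if stall >= p["conv_in"]:
            converged = True
            break
        # rank-based selection probabilities: best rank -> highest weight
        sel = np.empty(pop_size)
        sel[order] = np.arange(pop_size, 0, -1, dtype=float)
        sel /= sel.sum()
        parents = rng.choice(pop_size, size=(pop_size, 2), p=sel)
        children = np.empty_like(pop)
        for c in range(pop_size):
            a, b = pop[parents[c, 0]], pop[parents[c, 1]]
            if rng.random() < p["cross_prob"]:
                children[c] = _order_crossover(a, b, rng)
            else:
                children[c] = a
            for g in range(kappa):
                if rng.random() < p["mut_prob"]:
                    h = int(rng.integers(kappa))
                    children[c, [g, h]] = children[c, [h, g]]
        children[0] = best_perm  # elitism of 1
        pop = children
    assert best_perm is not None
    return AggregationResult(
        [arr.keys[t] for t in best_perm], best_phi, "GA", trace, seed, converged
    )


def _order_crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """OX1: copy a random slice of parent a, fill the rest in b's order."""
    kappa = len(a)
    i, j = sorted(rng.integers(kappa, size=2))
    child = -np.ones(kappa, dtype=np.int64)
    child[i : j + 1] = a[i : j + 1]
    used = set(child[i : j + 1].tolist())
    fill = [x for x in b if x not in used]
    idx = 0
    for pos in range(kappa):
        if child[pos] < 0:
            child[pos] = fill[idx]
            idx += 1
    return child
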