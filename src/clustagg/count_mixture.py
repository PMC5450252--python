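"""Finite mixtures of Poisson or negative-binomial distributions for
count matrices, fit by EM, deterministic annealing (DA), or simulated
annealing (SA).

Model: item i (a row of counts y_i over P features) belongs to one of k
latent clusters; within cluster c the features are independent with
cluster-specific means mu_cj.  The negative-binomial variant adds one
dispersion parameter phi_c per cluster shared across features, with
variance mu + phi * mu^2 (phi -> 0 recovers Poisson).

Fitting algorithms:

* EM — alternate responsibilities r_ic ~ pi_c f_c(y_i) with the
  closed-form M-step (pi_c = mean_i r_ic, mu_cj = weighted column mean);
  the log-likelihood trace is guaranteed non-decreasing.
* DA — tempered responsibilities r_ic ~ (pi_c f_c(y_i))^beta, beta
  annealed geometrically from beta0 up to 1 with one EM update per
  temperature, then plain EM to convergence.  beta0 = 1 reproduces EM.
* SA — classification EM with stochastic assignments drawn from
  temperature-flattened responsibilities and Metropolis acceptance on
  the classification log-likelihood; the temperature cools
  geometrically and the best state visited is kept.

All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.cluster import KMeans

from .datatypes import CandidateKey, DataMatrix, DegenerateCandidateError, Partition

__all__ = [
    "MixtureModelFit",
    "AnnealSchedule",
    "fit_count_mixture",
    "count_loglik",
    "map_partition",
    "estimate_dispersion",
]

_PHI_MIN, _PHI_MAX = 1e-8, 1e8


@dataclass
class AnnealSchedule:
    """Geometric annealing schedule.

    DA: inverse temperature beta rises from ``beta0`` by factor ``rate``
    each step until it reaches 1.  SA reuses ``steps`` as its cooling
    budget.  The schedule must reach beta = 1 within ``steps``.
    """

    beta0: float = 0.2
    rate: float = 1.2
    steps: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.beta0 <= 1:
            raise ValueError("beta0 must lie in (0, 1]")
        if self.rate <= 1:
            raise ValueError("rate must be > 1")
        if self.beta0 * self.rate**self.steps < 1.0:
            raise ValueError("schedule never reaches beta=1 within `steps`")

    def betas(self) -> list[float]:
        out, b = [], self.beta0
        while b < 1.0:
            out.append(b)
            b = min(1.0, b * self.rate)
        out.append(1.0)
        return out


@dataclass
class MixtureModelFit:
    distribution: str  # poisson | negbin
    algorithm: str  # EM | DA | SA
    k: int
    weights: np.ndarray  # pi, length k
    means: np.ndarray  # k x P
    dispersion: np.ndarray | None  # length k (negbin only)
    responsibilities: np.ndarray  # N x k
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    seed: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.responsibilities = np.asarray(self.responsibilities, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.means <= 0):
            raise ValueError("means must be strictly positive")
        if not np.allclose(self.responsibilities.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("responsibility rows must sum to 1")

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else np.nan


# ---------------------------------------------------------------------------
# log-densities


def _poisson_ll(y: np.ndarray, means: np.ndarray) -> np.ndarray:
    """N x k matrix of per-item Poisson log-densities."""
    const = gammaln(y + 1.0).sum(axis=1)
    return y @ np.log(means).T - means.sum(axis=1)[None, :] - const[:, None]


def _negbin_ll(y: np.ndarray, means: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """N x k matrix of per-item negative-binomial log-densities.

    Parameterized by mean mu and dispersion phi: size r = 1/phi,
    variance mu + phi mu^2.
    """
    n, k = y.shape[0], means.shape[0]
    out = np.empty((n, k))
    for c in range(k):
        r = 1.0 / max(phi[c], _PHI_MIN)
        mu = means[c]
        out[:, c] = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))[None, :]
            + y * np.log(mu / (r + mu))[None, :]
        ).sum(axis=1)
    return out


def _component_ll(y, means, phi, distribution):
    if distribution == "poisson":
        return _poisson_ll(y, means)
    return _negbin_ll(y, means, phi)


def count_loglik(matrix: DataMatrix, fit: MixtureModelFit) -> float:
    """Observed-data mixture log-likelihood sum_i log sum_c pi_c f_c(y_i)."""
    if matrix.n_features != fit.means.shape[1] or fit.means.shape[0] != fit.k:
        raise ValueError("fit dimensions do not match matrix")
    ll = _component_ll(matrix.values, fit.means, fit.dispersion, fit.distribution)
    return float(logsumexp(ll + np.log(fit.weights)[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# dispersion estimation


def _weighted_nb_profile_ll(y, mu, r_w, phi) -> float:
    """Responsibility-weighted NB log-likelihood of one cluster at phi."""
    r = 1.0 / max(phi, _PHI_MIN)
    ll = (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))[None, :]
        + y * np.log(mu / (r + mu))[None, :]
    ).sum(axis=1)
    return float((r_w * ll).sum())


def estimate_dispersion(
    matrix: DataMatrix, responsibilities: np.ndarray, flags: list[str] | None = None
) -> np.ndarray:
    """Per-cluster dispersion phi by weighted method of moments plus
    Newton refinement on the profile log-likelihood (in log phi).

    Under-dispersed clusters (moment estimate <= 0) are clamped to the
    lower bound 1e-8 and flagged.
    """
    y = matrix.values
    resp = np.asarray(responsibilities, dtype=float)
    if resp.shape[0] != y.shape[0]:
        raise ValueError("responsibility rows do not match matrix")
    k = resp.shape[1]
    phis = np.empty(k)
    for c in range(k):
        w = resp[:, c]
        tot = max(w.sum(), 1e-12)
        mu = np.maximum((w @ y) / tot, 1e-10)
        num = (w[:, None] * ((y - mu[None, :]) ** 2 - mu[None, :])).sum()
        den = max((w[:, None] * (mu[None, :] ** 2)).sum(), 1e-300)
        phi = num / den
        if phi <= 0:
            if flags is not None:
                flags.append(f"cluster {c + 1}: under-dispersed, phi clamped to {_PHI_MIN}")
            phis[c] = _PHI_MIN
            continue
        phi = float(np.clip(phi, _PHI_MIN, _PHI_MAX))
        # Newton on psi = log(phi); finite-difference derivatives
        psi = np.log(phi)
        h = 1e-4
        best_psi, best_ll = psi, _weighted_nb_profile_ll(y, mu, w, np.exp(psi))
        for _ in range(8):
            f0 = _weighted_nb_profile_ll(y, mu, w, np.exp(psi))
            fp = _weighted_nb_profile_ll(y, mu, w, np.exp(psi + h))
            fm = _weighted_nb_profile_ll(y, mu, w, np.exp(psi - h))
            g = (fp - fm) / (2 * h)
            hess = (fp - 2 * f0 + fm) / h**2
            if not np.isfinite(g) or not np.isfinite(hess) or hess >= 0:
                step = 0.1 * np.sign(g) if np.isfinite(g) else 0.0
            else:
                step = -g / hess
            step = float(np.clip(step, -1.0, 1.0))
            if abs(step) < 1e-8:
                break
            psi = float(np.clip(psi + step, np.log(_PHI_MIN), np.log(_PHI_MAX)))
            ll = _weighted_nb_profile_ll(y, mu, w, np.exp(psi))
            if ll > best_ll:
                best_psi, best_ll = psi, ll
        phis[c] = float(np.exp(best_psi))
    return phis


# ---------------------------------------------------------------------------
# fitting


def _init_hard(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k-means on log1p counts; returns a hard N x k responsibility grid."""
    km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    lab = km.fit_predict(np.log1p(y))
    resp = np.zeros((y.shape[0], k))
    resp[np.arange(y.shape[0]), lab] = 1.0
    return resp


def _m_step(y, resp, distribution, flags):
    tot = np.maximum(resp.sum(axis=0), 1e-12)
    pi = tot / resp.shape[0]
    pi = pi / pi.sum()
    means = np.maximum((resp.T @ y) / tot[:, None], 1e-10)
    phi = None
    return pi, means, phi, tot


def _e_step(y, pi, means, phi, distribution, beta=1.0):
    """Returns (responsibilities, observed loglik). ``beta`` tempers the
    posterior weights (pi_c f_c)^beta; the returned loglik is always the
    untempered mixture log-likelihood."""
    log_post = _component_ll(y, means, phi, distribution) + np.log(pi)[None, :]
    ll = float(logsumexp(log_post, axis=1).sum())
    t = beta * log_post
    resp = np.exp(t - logsumexp(t, axis=1, keepdims=True))
    return resp, ll


def _em_from(y, resp, distribution, tol, max_iter, flags, matrix,
             trace=None, phi_prev=None):
    """Plain EM iterations from an initial responsibility grid."""
    trace = trace if trace is not None else []
    converged = False
    pi = means = phi = None
    for _ in range(max_iter):
        pi, means, phi, tot = _m_step(y, resp, distribution, flags)
        if distribution == "negbin":
            phi_new = estimate_dispersion(matrix, resp, flags)
            # guard EM monotonicity: keep the previous phi if it scores higher
            if phi_prev is not None:
                for c in range(len(phi_new)):
                    w = resp[:, c]
                    if _weighted_nb_profile_ll(y, means[c], w, phi_prev[c]) > \
                       _weighted_nb_profile_ll(y, means[c], w, phi_new[c]):
                        phi_new[c] = phi_prev[c]
            phi = phi_new
            phi_prev = phi
        resp, ll = _e_step(y, pi, means, phi, distribution)
        if trace and abs(ll - trace[-1]) <= tol * max(1.0, abs(trace[-1])):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    return pi, means, phi, resp, trace, converged


def fit_count_mixture(
    matrix: DataMatrix,
    distribution: str,
    algorithm: str,
    k: int,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    opts: dict | None = None,
) -> MixtureModelFit:
    """Fit a k-component count mixture by EM, DA, or SA.

    ``opts``: ``tol`` (relative log-likelihood change, default 1e-6),
    ``max_iter`` (default 500), ``restarts`` (EM only, default 5; DA and
    SA use a single start — annealing replaces restarts),
    ``sa_temp`` (initial temperature, default 2.0), ``sa_cool``
    (default 0.95), ``sa_floor`` (default 1e-3).
    """
    if matrix.domain != "counts":
        raise ValueError("count mixtures require a counts-domain matrix")
    if distribution not in ("poisson", "negbin"):
        raise ValueError(f"unknown distribution {distribution!r}")
    if algorithm not in ("EM", "DA", "SA"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    y = matrix.values
    n = y.shape[0]
    if n <= k:
        raise ValueError("need more items than clusters")
    zero = np.flatnonzero(y.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(
            f"all-zero row(s): {[matrix.row_ids[i] for i in zero]} "
            "(cannot be assigned a positive mean profile)"
        )
    opts = dict(opts or {})
    tol = opts.get("tol", 1e-6)
    max_iter = opts.get("max_iter", 500)
    schedule = schedule or AnnealSchedule()
    flags: list[str] = []

    if algorithm == "EM":
        restarts = opts.get("restarts", 5)
        best = None
        for r in range(restarts):
            resp0 = _init_hard(y, k, seed + r)
            out = _em_from(y, resp0, distribution, tol, max_iter, flags, matrix)
            if best is None or out[4][-1] > best[4][-1]:
                best = out
        pi, means, phi, resp, trace, converged = best
    elif algorithm == "DA":
        resp = _init_hard(y, k, seed)
        trace: list[float] = []
        phi_prev = None
        for beta in schedule.betas()[:-1]:
            pi, means, phi, _ = _m_step(y, resp, distribution, flags)
            if distribution == "negbin":
                phi = estimate_dispersion(matrix, resp, flags)
                phi_prev = phi
            resp, ll = _e_step(y, pi, means, phi, distribution, beta=beta)
            trace.append(ll)
        pi, means, phi, resp, trace, converged = _em_from(
            y, resp, distribution, tol, max_iter, flags, matrix,
            trace=trace, phi_prev=phi_prev,
        )
    else:  # SA
        pi, means, phi, resp, trace, converged = _fit_sa(
            y, matrix, distribution, k, seed, tol, max_iter, opts, flags
        )

    fit = MixtureModelFit(
        distribution=distribution,
        algorithm=algorithm,
        k=k,
        weights=pi,
        means=means,
        dispersion=np.asarray(phi) if phi is not None else (
            np.full(k, _PHI_MIN) if distribution == "negbin" else None
        ),
        responsibilities=resp,
        loglik_trace=[float(v) for v in trace],
        converged=converged,
        seed=seed,
        flags=flags,
    )
    return fit


def _classification_ll(y, z, pi, means, phi, distribution):
    ll = _component_ll(y, means, phi, distribution)
    return float((ll[np.arange(len(z)), z] + np.log(pi)[z]).sum())


def _fit_sa(y, matrix, distribution, k, seed, tol, max_iter, opts, flags):
    """Classification EM with Metropolis-accepted stochastic assignments."""
    rng = np.random.default_rng(seed)
    temp = opts.get("sa_temp", 2.0)
    cool = opts.get("sa_cool", 0.95)
    floor = opts.get("sa_floor", 1e-3)
    n = y.shape[0]

    def params_from(z):
        resp = np.zeros((n, k))
        resp[np.arange(n), z] = 1.0
        pi, means, _, _ = _m_step(y, resp, distribution, flags)
        phi = estimate_dispersion(matrix, resp, flags) if distribution == "negbin" else None
        return resp, pi, means, phi

    z = np.argmax(_init_hard(y, k, seed), axis=1)
    resp, pi, means, phi = params_from(z)
    cur_ll = _classification_ll(y, z, pi, means, phi, distribution)
    best = (z.copy(), cur_ll)
    trace = [cur_ll]
    steps = 0
    while temp > floor and steps < max_iter:
        log_post = _component_ll(y, means, phi, distribution) + np.log(pi)[None, :]
        t = log_post / temp
        p = np.exp(t - logsumexp(t, axis=1, keepdims=True))
        # vectorized categorical draw per item
        u = rng.random(n)[:, None]
        z_new = (p.cumsum(axis=1) < u).sum(axis=1)
        z_new = np.minimum(z_new, k - 1)
        if len(np.unique(z_new)) == k:  # reject proposals that empty a cluster
            new_ll = _classification_ll(y, z_new, pi, means, phi, distribution)
            if new_ll >= cur_ll or rng.random() < np.exp((new_ll - cur_ll) / temp):
                z = z_new
                resp, pi, means, phi = params_from(z)
                cur_ll = _classification_ll(y, z, pi, means, phi, distribution)
                if cur_ll > best[1]:
                    best = (z.copy(), cur_ll)
        temp *= cool
        steps += 1
        trace.append(cur_ll)
    # keep the best state visited; report its soft fit
    resp, pi, means, phi = params_from(best[0])
    resp, ll = _e_step(y, pi, means, phi, distribution)
    trace.append(ll)
    return pi, means, phi, resp, trace, True


def map_partition(fit: MixtureModelFit) -> Partition:
    """Hard labels = argmax responsibility; ties break to the lower
    cluster index.  Raises a degenerate-candidate error if any cluster
    receives no items."""
    labels = np.argmax(fit.responsibilities, axis=1) + 1
    if len(np.unique(labels)) != fit.k:
        raise DegenerateCandidateError(
            f"count mixture (k={fit.k}): MAP assignment leaves a cluster empty"
        )
    name = {"poisson": "poisson", "negbin": "nbinom"}[fit.distribution]
    key = CandidateKey(f"{fit.algorithm.lower()}.{name}", fit.k)
    return Partition(key, labels, {"model": fit})
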