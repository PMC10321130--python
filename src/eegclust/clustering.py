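"""Six clustering algorithms sharing one centroid-set objective.

Learning-based: k-means / k-median (Lloyd iterations under an L_q
objective, q in {1, 2}) and fuzzy c-means.  Bio-inspired: cuckoo search
(Levy-flight perturbation with nest abandonment), dragonfly (swarm forces:
separation, alignment, cohesion, food attraction, enemy repulsion),
firefly (brightness-driven attraction with quadratic light absorption) and
a modified firefly whose brightest agent only takes strictly improving
steps and whose attraction scale is the intensity ratio of the two agents.

All metaheuristics optimize the same fitness -- the within-cluster sum of
squared errors (the q=2 hard-assignment objective) of the centroid set
encoded in each agent's position -- so their cluster quality is directly
comparable to k-means.  Every algorithm is bit-reproducible given
(data, config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# configs and model


@dataclass(frozen=True)
class ClusterConfig:
    """Shared configuration: k clusters, L_q exponent, iteration budget."""

    k: int
    q: int = 2
    max_iter: int = 300
    tol: float = 1e-9
    seed: int = 0
    n_init: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.q not in (1, 2):
            raise ValueError("q must be 1 or 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


@dataclass(frozen=True)
class FCMConfig:
    """Fuzzy c-means configuration: fuzzifier p > 1, threshold xi, I_max."""

    k: int
    p: float = 2.0
    xi: float = 1e-6
    i_max: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.p > 1:
            raise ValueError("fuzzifier p must be > 1")
        if self.xi <= 0:
            raise ValueError("threshold xi must be positive")


@dataclass(frozen=True)
class CuckooParams:
    n_nests: int = 15
    pa: float = 0.25
    levy_beta: float = 1.5
    step_scale: float = 0.02
    iters: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pa <= 1.0:
            raise ValueError("pa must lie in [0, 1]")
        if not 0.0 < self.levy_beta < 2.0:
            raise ValueError("levy_beta must lie in (0, 2)")
        if self.n_nests < 1 or self.iters < 1:
            raise ValueError("n_nests and iters must be >= 1")


@dataclass(frozen=True)
class DragonflyParams:
    w_sep: float = 0.1
    w_ali: float = 0.1
    w_coh: float = 0.7
    w_food: float = 1.0
    w_enemy: float = 0.1
    inertia: float = 0.9
    neighborhood_radius: float | None = None  # None: 25% of diagonal, shrinking to 5%
    n_agents: int = 15
    iters: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for w in (self.w_sep, self.w_ali, self.w_coh, self.w_food, self.w_enemy):
            if w < 0:
                raise ValueError("force weights must be nonnegative")
        if self.neighborhood_radius is not None and self.neighborhood_radius <= 0:
            raise ValueError("neighborhood_radius must be positive")


@dataclass(frozen=True)
class FireflyParams:
    n_fireflies: int = 15
    lam: float = 1.0
    alpha: float = 0.2
    alpha_decay: float = 0.97
    a0: float = 1.0
    iters: int = 200
    seed: int = 0
    s_directions: int = 10
    b0_mode: str = "unit"  # "unit" (A0=1) or "intensity_ratio" (B0 = J0'/J0)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("light absorption lam must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.s_directions < 1:
            raise ValueError("s_directions must be >= 1")
        if self.b0_mode not in ("unit", "intensity_ratio"):
            raise ValueError("b0_mode must be 'unit' or 'intensity_ratio'")


@dataclass
class ClusterModel:
    """A fitted clustering: centroids, memberships, objective and trace."""

    centroids: np.ndarray  # (k, d)
    labels: np.ndarray  # (n,) hard assignment
    objective: float
    trace: list[float] = field(default_factory=list)
    memberships: np.ndarray | None = None  # (n, k) fuzzy, rows sum to 1
    method: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(self.centroids.shape[0])


@dataclass
class AgentPopulation:
    """Metaheuristic swarm state: flattened centroid sets plus elite archive."""

    positions: np.ndarray  # (n_agents, k*d)
    velocities: np.ndarray  # (n_agents, k*d)
    fitness: np.ndarray  # (n_agents,)
    best_position: np.ndarray  # (k*d,)
    best_fitness: float


# ---------------------------------------------------------------------------
# objective


def _validate_X(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        raise ValueError("empty data matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix must be finite")
    return X


def clustering_objective(
    X: np.ndarray, centroids: np.ndarray, q: int = 2
) -> tuple[float, np.ndarray]:
    """Hard-assignment L_q clustering objective and nearest-centroid labels.

    Each point is assigned to its nearest centroid under the L_q norm
    (ties broken toward the lowest cluster index); the objective is the sum
    of q-th-power L_q distances to the assigned centroids.
    """
    X = _validate_X(X)
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if C.shape[1] != X.shape[1]:
        raise ValueError("centroid dimension mismatch")
    if q == 2:
        D = cdist(X, C, metric="sqeuclidean")
    elif q == 1:
        D = cdist(X, C, metric="cityblock")
    else:
        raise ValueError("q must be 1 or 2")
    labels = np.argmin(D, axis=1)  # argmin takes the lowest index on ties
    objective = float(D[np.arange(len(X)), labels].sum())
    return objective, labels


def _make_sse_evaluator(X: np.ndarray, k: int):
    """Fitness evaluator for flattened centroid sets (q=2 objective).

    For 1-d data the nearest-centroid partition of sorted samples is a set
    of contiguous runs split at centroid midpoints, so the SSE of one
    centroid set costs O(k log n) against precomputed prefix sums instead
    of an O(n k) distance matrix -- a large win for the per-segment
    amplitude clustering mode where thousands of evaluations occur.
    """
    d = X.shape[1]
    if d != 1:
        return lambda pos: clustering_objective(X, pos.reshape(k, d), q=2)[0]
    xs = np.sort(X[:, 0])
    n = xs.size
    c1 = np.concatenate(([0.0], np.cumsum(xs)))
    c2 = np.concatenate(([0.0], np.cumsum(xs * xs)))

    def evaluate(pos: np.ndarray) -> float:
        c = np.sort(pos)
        splits = np.searchsorted(xs, (c[:-1] + c[1:]) / 2.0)
        lo_i = np.concatenate(([0], splits))
        hi_i = np.concatenate((splits, [n]))
        cnt = hi_i - lo_i
        s1 = c1[hi_i] - c1[lo_i]
        s2 = c2[hi_i] - c2[lo_i]
        return float((s2 - 2.0 * c * s1 + cnt * c * c).sum())

    return evaluate


def _population_fitness(
    X: np.ndarray, positions: np.ndarray, k: int, evaluator=None
) -> np.ndarray:
    if evaluator is None:
        evaluator = _make_sse_evaluator(X, k)
    return np.array([evaluator(pos) for pos in positions])


# ---------------------------------------------------------------------------
# k-means / k-median


def _repair_empty_clusters(
    X: np.ndarray, centroids: np.ndarray, labels: np.ndarray, q: int
) -> np.ndarray:
    """Reseed each empty cluster at the point farthest from its centroid."""
    k = centroids.shape[0]
    counts = np.bincount(labels, minlength=k)
    if np.all(counts > 0):
        return centroids
    centroids = centroids.copy()
    metric = "sqeuclidean" if q == 2 else "cityblock"
    for kk in np.flatnonzero(counts == 0):
        D = cdist(X, centroids, metric=metric)
        point_d = D[np.arange(len(X)), labels]
        far = int(np.argmax(point_d))
        centroids[kk] = X[far]
        labels[far] = kk
    return centroids


def kmeans_cluster(X: np.ndarray, cfg: ClusterConfig) -> ClusterModel:
    """Lloyd-style hard clustering under L_q; q=2 k-means, q=1 k-median.

    Initial prototypes are k distinct data points chosen at random; the
    loop alternates nearest-centroid assignment with prototype update
    (mean for q=2, coordinate-wise median for q=1) and stops when the
    assignment repeats or ``max_iter`` is reached.  ``n_init`` restarts are
    run and the best objective kept.
    """
    X = _validate_X(X)
    n, d = X.shape
    if cfg.k > n:
        raise ValueError(f"k={cfg.k} exceeds n={n}")
    rng = np.random.default_rng(cfg.seed)
    best: ClusterModel | None = None
    for _ in range(cfg.n_init):
        model = _kmeans_single(X, cfg, rng)
        if best is None or model.objective < best.objective:
            best = model
    return best


def _kmeans_single(
    X: np.ndarray, cfg: ClusterConfig, rng: np.random.Generator
) -> ClusterModel:
    n, d = X.shape
    idx = rng.choice(n, size=cfg.k, replace=False)
    centroids = X[idx].copy()
    labels = np.full(n, -1)
    trace: list[float] = []
    for _ in range(cfg.max_iter):
        obj, new_labels = clustering_objective(X, centroids, q=cfg.q)
        centroids = _repair_empty_clusters(X, centroids, new_labels, cfg.q)
        trace.append(obj)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for kk in range(cfg.k):
            members = X[labels == kk]
            if len(members) == 0:
                continue
            if cfg.q == 2:
                centroids[kk] = members.mean(axis=0)
            else:
                centroids[kk] = np.median(members, axis=0)
    obj, labels = clustering_objective(X, centroids, q=cfg.q)
    trace.append(obj)
    method = "kmeans" if cfg.q == 2 else "kmedian"
    return ClusterModel(centroids, labels, obj, trace, method=method)


# ---------------------------------------------------------------------------
# fuzzy c-means


def fcm_objective(
    X: np.ndarray, centroids: np.ndarray, memberships: np.ndarray, p: float
) -> float:
    """Fuzzy objective H_m = sum_q sum_i z_iq^p * d_iq^2."""
    D2 = cdist(_validate_X(X), np.atleast_2d(centroids), metric="sqeuclidean")
    return float((memberships**p * D2).sum())


def _fcm_memberships(X: np.ndarray, centroids: np.ndarray, p: float) -> np.ndarray:
    D = cdist(X, centroids)  # Euclidean d_iq
    Z = np.empty_like(D)
    zero_rows = np.any(D == 0.0, axis=1)
    # coincident point: full membership to (the first) zero-distance cluster
    if np.any(zero_rows):
        Z[zero_rows] = 0.0
        first_zero = np.argmax(D[zero_rows] == 0.0, axis=1)
        Z[np.flatnonzero(zero_rows), first_zero] = 1.0
    ok = ~zero_rows
    if np.any(ok):
        # z_iq = d_iq^(-2/(p-1)) / sum_h d_ih^(-2/(p-1)), the O(nk) form of
        # the ratio update
        inv = D[ok] ** (-2.0 / (p - 1.0))
        Z[ok] = inv / inv.sum(axis=1, keepdims=True)
    return Z


def fcm_cluster(X: np.ndarray, cfg: FCMConfig) -> ClusterModel:
    """Fuzzy c-means: alternate membership and weighted-centroid updates.

    Memberships follow z_iq = 1 / sum_h (d_iq/d_hq)^(2/(p-1)); centroids
    are z^p-weighted means.  Stops when |H(t) - H(t-1)| < xi or after
    ``i_max`` iterations.
    """
    X = _validate_X(X)
    n, d = X.shape
    if cfg.k > n:
        raise ValueError(f"k={cfg.k} exceeds n={n}")
    rng = np.random.default_rng(cfg.seed)
    Z = rng.random((n, cfg.k))
    Z /= Z.sum(axis=1, keepdims=True)
    trace: list[float] = []
    prev_obj = np.inf
    centroids = np.zeros((cfg.k, d))
    for _ in range(cfg.i_max):
        Zp = Z**cfg.p
        centroids = (Zp.T @ X) / Zp.sum(axis=0)[:, None]
        obj = fcm_objective(X, centroids, Z, cfg.p)
        trace.append(obj)
        if abs(prev_obj - obj) < cfg.xi:
            break
        prev_obj = obj
        Z = _fcm_memberships(X, centroids, cfg.p)
    labels = np.argmax(Z, axis=1)
    obj = fcm_objective(X, centroids, Z, cfg.p)
    return ClusterModel(
        centroids, labels, obj, trace, memberships=Z, method="fcm"
    )


def xie_beni_index(
    X: np.ndarray, centroids: np.ndarray, memberships: np.ndarray, p: float
) -> float:
    """Xie-Beni validity: compactness over n times minimal centroid separation."""
    X = _validate_X(X)
    compactness = fcm_objective(X, centroids, memberships, p)
    sep = cdist(centroids, centroids, metric="sqeuclidean")
    np.fill_diagonal(sep, np.inf)
    min_sep = sep.min()
    if min_sep == 0.0:
        return np.inf
    return compactness / (len(X) * min_sep)


VALIDITY_INDICES: dict[str, Callable[..., float]] = {"xie_beni": xie_beni_index}


def fcm_select_k(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int | None = None,
    validity: str = "xie_beni",
    p: float = 2.0,
    seed: int = 0,
) -> int:
    """Pick the cluster count in [k_min, k_max] minimizing a validity index.

    Default search range is [2, floor(sqrt(n))].  Ties go to the smaller k.
    """
    X = _validate_X(X)
    n = len(X)
    if k_max is None:
        k_max = int(math.floor(math.sqrt(n)))
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds k_max={k_max}")
    index_fn = VALIDITY_INDICES[validity]
    best_k, best_score = k_min, np.inf
    for k in range(k_min, k_max + 1):
        model = fcm_cluster(X, FCMConfig(k=k, p=p, seed=seed))
        score = index_fn(X, model.centroids, model.memberships, p)
        if score < best_score:
            best_k, best_score = k, score
    return best_k


# ---------------------------------------------------------------------------
# shared metaheuristic helpers


def _bbox(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.tile(X.min(axis=0), k)
    hi = np.tile(X.max(axis=0), k)
    return lo, hi


def _init_positions(
    rng: np.random.Generator, n_agents: int, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    return rng.uniform(lo, hi, size=(n_agents, lo.size))


def _model_from_position(
    X: np.ndarray, position: np.ndarray, k: int, trace: list[float], method: str,
    meta: dict | None = None,
) -> ClusterModel:
    centroids = position.reshape(k, X.shape[1])
    obj, labels = clustering_objective(X, centroids, q=2)
    return ClusterModel(
        centroids, labels, obj, trace, method=method, meta=meta or {}
    )


def levy_flight_step(
    dim: int,
    beta: float = 1.5,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Heavy-tailed random step via the Mantegna construction.

    step = scale * u / |v|^(1/beta) with u ~ N(0, sigma_u^2), v ~ N(0, 1),
    giving a symmetric step whose magnitude tail follows P(|s|>t) ~ t^-beta.
    """
    if not 0.0 < beta < 2.0:
        raise ValueError("beta must lie in (0, 2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_u = (
        math.gamma(1.0 + beta)
        * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return scale * u / np.abs(v) ** (1.0 / beta)


# ---------------------------------------------------------------------------
# cuckoo search


def cuckoo_cluster(
    X: np.ndarray, cfg: ClusterConfig, params: CuckooParams | None = None
) -> ClusterModel:
    """Cuckoo-search clustering: Levy perturbation plus nest abandonment.

    Each host nest encodes a flattened centroid set.  Per generation a
    random nest is perturbed by a Levy flight and greedily replaces a
    randomly chosen nest if fitter; then the worst ``pa`` fraction of
    nests are abandoned and rebuilt at random.  The best nest ever seen is
    archived (elitism), so the best-fitness trace is non-increasing.
    """
    X = _validate_X(X)
    if cfg.k > len(X):
        raise ValueError(f"k={cfg.k} exceeds n={len(X)}")
    p = params or CuckooParams(seed=cfg.seed)
    rng = np.random.default_rng(p.seed)
    lo, hi = _bbox(X, cfg.k)
    span = float(np.linalg.norm(hi - lo))
    evaluate = _make_sse_evaluator(X, cfg.k)
    positions = _init_positions(rng, p.n_nests, lo, hi)
    fitness = _population_fitness(X, positions, cfg.k, evaluate)
    best_i = int(np.argmin(fitness))
    best_pos, best_fit = positions[best_i].copy(), float(fitness[best_i])
    trace = [best_fit]
    n_abandoned = 0
    n_abandon = int(round(p.pa * p.n_nests))
    for it in range(p.iters):
        j = rng.integers(p.n_nests)
        # new egg: Levy flight seeded between the chosen cuckoo and the best
        # nest, with a geometrically cooling scale for late refinement
        scale = p.step_scale * span * 0.98**it
        step = levy_flight_step(lo.size, p.levy_beta, scale, rng)
        origin = best_pos if rng.random() < 0.5 else positions[j]
        candidate = np.clip(origin + step, lo, hi)
        f_j = evaluate(candidate)
        i = rng.integers(p.n_nests)
        if f_j < fitness[i]:
            positions[i], fitness[i] = candidate, f_j
        if n_abandon > 0:
            worst = np.argsort(fitness)[-n_abandon:]
            positions[worst] = _init_positions(rng, len(worst), lo, hi)
            fitness[worst] = _population_fitness(X, positions[worst], cfg.k, evaluate)
            n_abandoned += len(worst)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_pos, best_fit = positions[gen_best].copy(), float(fitness[gen_best])
        trace.append(best_fit)
    return _model_from_position(
        X, best_pos, cfg.k, trace, "cuckoo", meta={"n_abandoned": n_abandoned}
    )


# ---------------------------------------------------------------------------
# dragonfly


def dragonfly_forces(
    idx: int,
    positions: np.ndarray,
    velocities: np.ndarray,
    food_pos: np.ndarray,
    enemy_pos: np.ndarray,
    radius: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Swarm forces on agent ``idx``: (Sep, Ali, Co, Food, Ene).

    Neighbors are the other agents within ``radius``.  Separation sums
    He_idx - He_l over neighbors; alignment is the mean neighbor velocity;
    cohesion points from the agent to the neighbor centroid; food
    attraction points to the best position, enemy repulsion away from the
    worst.  With no neighbors, Sep = Ali = Co = 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    he = positions[idx]
    dists = np.linalg.norm(positions - he, axis=1)
    mask = (dists <= radius) & (np.arange(len(positions)) != idx)
    zeros = np.zeros_like(he)
    if np.any(mask):
        neigh = positions[mask]
        sep = (he - neigh).sum(axis=0)
        ali = velocities[mask].mean(axis=0)
        co = neigh.mean(axis=0) - he
    else:
        sep = ali = co = zeros
    food = food_pos - he
    ene = he - enemy_pos
    return sep, ali, co, food, ene


def dragonfly_cluster(
    X: np.ndarray, cfg: ClusterConfig, params: DragonflyParams | None = None
) -> ClusterModel:
    """Dragonfly-swarm clustering with the five weighted forces.

    Step = w_s*Sep + w_a*Ali + w_c*Co + w_h*Food + w_e*Ene + inertia*step.
    Food is the best position seen so far, enemy the current worst.  The
    neighborhood radius shrinks linearly from 25% to 5% of the search-space
    diagonal unless fixed in params.  Positions are clamped to the data
    bounding box and the best solution is archived.
    """
    X = _validate_X(X)
    if cfg.k > len(X):
        raise ValueError(f"k={cfg.k} exceeds n={len(X)}")
    p = params or DragonflyParams(seed=cfg.seed)
    rng = np.random.default_rng(p.seed)
    lo, hi = _bbox(X, cfg.k)
    diagonal = float(np.linalg.norm(hi - lo))
    evaluate = _make_sse_evaluator(X, cfg.k)
    positions = _init_positions(rng, p.n_agents, lo, hi)
    steps = np.zeros_like(positions)
    fitness = _population_fitness(X, positions, cfg.k, evaluate)
    best_i = int(np.argmin(fitness))
    best_pos, best_fit = positions[best_i].copy(), float(fitness[best_i])
    trace = [best_fit]
    max_step = 0.25 * diagonal  # step clamp: centroids cannot usefully overshoot
    # degenerate config (every weight and the inertia zero) must leave the
    # swarm static: the update equation then yields a zero step
    inert_swarm = (
        p.w_sep + p.w_ali + p.w_coh + p.w_food + p.w_enemy + p.inertia
    ) == 0.0
    for it in range(p.iters):
        frac = it / max(p.iters - 1, 1)
        radius = (
            p.neighborhood_radius
            if p.neighborhood_radius is not None
            else max((0.25 - 0.20 * frac) * diagonal, 1e-12)
        )
        inertia = p.inertia * (1.0 - frac) + 0.4 * frac  # exploration -> exploitation
        enemy_i = int(np.argmax(fitness))
        enemy_pos = positions[enemy_i]
        new_steps = np.empty_like(steps)
        for j in range(p.n_agents):
            sep, ali, co, food, ene = dragonfly_forces(
                j, positions, steps, best_pos, enemy_pos, radius
            )
            has_neighbors = np.any(
                (np.linalg.norm(positions - positions[j], axis=1) <= radius)
                & (np.arange(p.n_agents) != j)
            )
            if not has_neighbors and not inert_swarm:
                # isolated agent: Levy random walk biased toward the food
                new_steps[j] = (
                    levy_flight_step(lo.size, 1.5, 0.01 * diagonal, rng)
                    + p.w_food * rng.random() * food
                )
            else:
                # stochastic force coefficients keep the swarm from
                # collapsing onto the food source in a single step
                r = rng.random(5)
                new_steps[j] = (
                    p.w_sep * r[0] * sep
                    + p.w_ali * r[1] * ali
                    + p.w_coh * r[2] * co
                    + p.w_food * r[3] * food
                    + p.w_enemy * r[4] * ene
                    + inertia * steps[j]
                )
            norm = np.linalg.norm(new_steps[j])
            if norm > max_step:
                new_steps[j] *= max_step / norm
        steps = new_steps
        positions = np.clip(positions + steps, lo, hi)
        fitness = _population_fitness(X, positions, cfg.k, evaluate)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_pos, best_fit = positions[gen_best].copy(), float(fitness[gen_best])
        trace.append(best_fit)
    return _model_from_position(X, best_pos, cfg.k, trace, "dragonfly")


# ---------------------------------------------------------------------------
# firefly


def firefly_kernel(q_dist: float, value0: float, lam: float) -> float:
    """Rational light-attenuation kernel value0 / (1 + lam * q^2)."""
    if q_dist < 0:
        raise ValueError("distance must be nonnegative")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    return value0 / (1.0 + lam * q_dist**2)


def firefly_move(
    y: np.ndarray,
    y_bright: np.ndarray,
    params: FireflyParams,
    rng_draw: np.ndarray,
    attraction: float | None = None,
    alpha: float | None = None,
) -> np.ndarray:
    """One attraction step y + A0*exp(-lam*q^2)*(y' - y) + alpha*eps.

    ``rng_draw`` is the already-scaled random vector eps; ``attraction``
    overrides A0 (used by the intensity-ratio variant).
    """
    y = np.asarray(y, dtype=float)
    y_bright = np.asarray(y_bright, dtype=float)
    q = float(np.linalg.norm(y_bright - y))
    a0 = params.a0 if attraction is None else attraction
    a = params.alpha if alpha is None else alpha
    return y + a0 * math.exp(-params.lam * q**2) * (y_bright - y) + a * rng_draw


def _intensity(fit: float) -> float:
    # lower objective = brighter source; bounded transform keeps ratios tame
    return 1.0 / (1.0 + fit)


def _firefly_loop(
    X: np.ndarray, cfg: ClusterConfig, p: FireflyParams, modified: bool
) -> ClusterModel:
    X = _validate_X(X)
    if cfg.k > len(X):
        raise ValueError(f"k={cfg.k} exceeds n={len(X)}")
    rng = np.random.default_rng(p.seed)
    lo, hi = _bbox(X, cfg.k)
    extent = hi - lo
    diagonal = float(np.linalg.norm(extent))
    # lam acts on distances normalized by the search-space diagonal so the
    # default lam=1 yields usable attraction regardless of amplitude scale
    p_move = dataclasses.replace(p, lam=p.lam / max(diagonal, 1e-12) ** 2)
    evaluate = _make_sse_evaluator(X, cfg.k)
    positions = _init_positions(rng, p.n_fireflies, lo, hi)
    fitness = _population_fitness(X, positions, cfg.k, evaluate)
    best_i = int(np.argmin(fitness))
    best_pos, best_fit = positions[best_i].copy(), float(fitness[best_i])
    trace = [best_fit]
    pop_best_trace = [float(fitness.min())]
    alpha = p.alpha

    def eval_pos(pos: np.ndarray) -> float:
        return evaluate(pos)

    for _ in range(p.iters):
        intensities = np.array([_intensity(f) for f in fitness])
        brightest = int(np.argmax(intensities))
        order = np.arange(p.n_fireflies)
        for j in order:
            if j == brightest:
                continue
            moved = positions[j].copy()
            for i in order:
                if intensities[i] <= intensities[j]:
                    continue
                eps = (rng.random(lo.size) - 0.5) * extent
                if modified:
                    if intensities[j] == 0.0:
                        raise ZeroDivisionError("zero source intensity J0")
                    attraction = intensities[i] / intensities[j]  # B0 = J0'/J0
                else:
                    attraction = p.a0
                moved = firefly_move(
                    moved, positions[i], p_move, eps, attraction=attraction, alpha=alpha
                )
            positions[j] = np.clip(moved, lo, hi)
            fitness[j] = eval_pos(positions[j])
        # brightest firefly: random walk (standard) or improving step (modified)
        if modified:
            current_fit = fitness[brightest]
            best_dir_fit, best_dir_pos = current_fit, None
            for _ in range(p.s_directions):
                v = rng.standard_normal(lo.size)
                v /= np.linalg.norm(v)
                cand = np.clip(positions[brightest] + alpha * v * extent, lo, hi)
                f = eval_pos(cand)
                if f < best_dir_fit:
                    best_dir_fit, best_dir_pos = f, cand
            if best_dir_pos is not None:  # strictly improving, else stay
                positions[brightest] = best_dir_pos
                fitness[brightest] = best_dir_fit
        else:
            eps = (rng.random(lo.size) - 0.5) * extent
            positions[brightest] = np.clip(positions[brightest] + alpha * eps, lo, hi)
            fitness[brightest] = eval_pos(positions[brightest])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_pos, best_fit = positions[gen_best].copy(), float(fitness[gen_best])
        trace.append(best_fit)
        pop_best_trace.append(float(fitness.min()))
        alpha *= p.alpha_decay
    method = "modified_firefly" if modified else "firefly"
    return _model_from_position(
        X, best_pos, cfg.k, trace, method,
        meta={"population_best_trace": pop_best_trace},
    )


def firefly_cluster(
    X: np.ndarray, cfg: ClusterConfig, params: FireflyParams | None = None
) -> ClusterModel:
    """Standard firefly clustering: each agent moves toward every brighter one.

    Brightness is 1/(1 + SSE); the brightest agent performs a random walk.
    The randomization term decays geometrically and the best-so-far
    solution is archived.
    """
    p = params or FireflyParams(seed=cfg.seed)
    return _firefly_loop(X, cfg, p, modified=False)


def modified_firefly_cluster(
    X: np.ndarray, cfg: ClusterConfig, params: FireflyParams | None = None
) -> ClusterModel:
    """Firefly variant with a guarded elite and intensity-ratio attraction.

    The brightest firefly probes ``s_directions`` random unit vectors and
    moves only along a strictly brightness-improving one (staying put
    otherwise), so its brightness never decreases; attraction scales as
    the intensity ratio B0 = J0'/J0 of the brighter over the dimmer agent.
    """
    p = params or FireflyParams(seed=cfg.seed, b0_mode="intensity_ratio")
    if p.b0_mode != "intensity_ratio":
        p = dataclasses.replace(p, b0_mode="intensity_ratio")
    return _firefly_loop(X, cfg, p, modified=True)


# ---------------------------------------------------------------------------
# dispatcher

METHODS = (
    "kmeans",
    "kmedian",
    "fcm",
    "cuckoo",
    "dragonfly",
    "firefly",
    "modified_firefly",
)


def cluster(
    X: np.ndarray,
    method: str,
    k: int,
    seed: int = 0,
    **kwargs,
) -> ClusterModel:
    """Run the named clustering algorithm with its default parameters."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "kmeans":
        return kmeans_cluster(X, ClusterConfig(k=k, q=2, seed=seed, **kwargs))
    if method == "kmedian":
        return kmeans_cluster(X, ClusterConfig(k=k, q=1, seed=seed, **kwargs))
    if method == "fcm":
        return fcm_cluster(X, FCMConfig(k=k, seed=seed, **kwargs))
    cfg = ClusterConfig(k=k, seed=seed)
    if method == "cuckoo":
        return cuckoo_cluster(X, cfg, CuckooParams(seed=seed, **kwargs))
    if method == "dragonfly":
        return dragonfly_cluster(X, cfg, DragonflyParams(seed=seed, **kwargs))
    if method == "firefly":
        return firefly_cluster(X, cfg, FireflyParams(seed=seed, **kwargs))
    return modified_firefly_cluster(X, cfg, FireflyParams(seed=seed, **kwargs))
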