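"""Frequent dense subgraph discovery across a collection of contracted CIGs.

The mining problem — find node sets that induce a dense subgraph in at least a
given fraction of the K graphs — is relaxed to a tensor-style optimization

    maximize  H(x, y) = sum_k y_k * (x^T A^(k) x) / 2
    s.t.      ||x||_p = 1,  ||y||_q = 1,  x >= 0,  y >= 0,

where x weights the N nodes and y weights the K graphs. Block updates are the
Lp power method: the y-update is the exact Hoelder maximizer given x; the
x-update is a multiplicative power step whose exponent 1/(p-1) sharpens the
node weights (p < 2 is sparsity-inducing). H is checked after every step and a
step that would decrease it is rejected, so accepted iterations are monotone.

The continuous solution is then discretized by scanning nested top-m node sets
and verifying the exact size/density/frequency thresholds, and the accepted
pattern's edges are masked from its supporting graphs so further restarts can
surface overlapping patterns living in other structures. An exponential-time
oracle (``brute_force_mine``) provides the ground truth on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DegenerateInstanceError, ValidationError
from .graphs import ContractedCIG

_EPS = 1e-300


@dataclass
class MiningParams:
    """Thresholds and optimizer knobs for frequent-cluster discovery.

    min_size / min_density / min_freq are the three mining thresholds
    (defaults 4, 0.6, 0.01). restarts is the patience: mining stops after that
    many consecutive restarts that fail to yield a new qualifying pattern.
    norm_p (> 1) is the node-weight norm — smaller is sparser; norm_q (> 1)
    is the graph-weight norm.
    """

    min_size: int = 4
    min_density: float = 0.6
    min_freq: float = 0.01
    restarts: int = 1000
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    norm_p: float = 1.5
    norm_q: float = 1.25

    def __post_init__(self):
        if self.min_size < 2:
            raise ConfigurationError("min_size must be >= 2")
        if not 0 < self.min_density <= 1:
            raise ConfigurationError("min_density must be in (0, 1]")
        if not 0 < self.min_freq <= 1:
            raise ConfigurationError("min_freq must be in (0, 1]")
        if self.norm_p <= 1 or self.norm_q <= 1:
            raise ConfigurationError("norm exponents must be > 1")


@dataclass
class CandidatePattern:
    """A mined domain set with its supporting structures and per-structure density."""

    nodes: tuple[int, ...]  # contracted node (= domain) indices, ascending
    support: np.ndarray  # indices of supporting graphs
    densities: np.ndarray  # induced density in each supporting graph
    n_graphs: int  # K, for the support fraction

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def support_fraction(self) -> float:
        return len(self.support) / self.n_graphs


def _stack(graphs) -> np.ndarray:
    """(K, N, N) float adjacency stack from ContractedCIGs or arrays."""
    mats = [g.adj if isinstance(g, ContractedCIG) else np.asarray(g) for g in graphs]
    if not mats:
        raise ValidationError("graph collection is empty")
    return np.stack([m.astype(float) for m in mats])


def tensor_objective(x: np.ndarray, y: np.ndarray, graphs) -> float:
    """H = sum_k y_k * (x^T A^(k) x) / 2 over the binary adjacencies."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("weight vectors must be nonnegative")
    A = _stack(graphs)
    if x.shape[0] != A.shape[1] or y.shape[0] != A.shape[0]:
        raise ValidationError("weight vector lengths do not match the graphs")
    return float(np.einsum("k,kij,i,j->", y, A, x, x) / 2.0)


def _normalize(v: np.ndarray, p: float) -> np.ndarray:
    nrm = float((v**p).sum()) ** (1.0 / p)
    return v / max(nrm, _EPS)


def optimize_pattern(
    graphs, params: MiningParams, rng: np.random.Generator, x0=None, y0=None
):
    """Alternating multiplicative updates from a random nonnegative start.

    ``x0``/``y0`` optionally supply the nonnegative starting node and graph
    weights (the restart loop seeds them around a randomly drawn edge and its
    graph, which steers the power iterations into local dense neighbourhoods
    instead of the global degree structure); by default the start is i.i.d.
    exponential. Returns (x*, y*, H_history). H is non-decreasing across
    accepted iterations; an update that would decrease H is reverted and
    terminates the loop. An all-zero gradient start is re-drawn a bounded
    number of times before the instance is reported degenerate.
    """
    A = graphs if isinstance(graphs, np.ndarray) else _stack(graphs)
    K, N, _ = A.shape
    AR = A.reshape(K, N * N)  # view: stays consistent with in-place masking
    inv_p = 1.0 / (params.norm_p - 1.0)
    inv_q = 1.0 / (params.norm_q - 1.0)

    def quad_forms(xv):
        """g_k = x^T A^(k) x / 2 for every graph, as one BLAS matvec."""
        xa = xv.astype(A.dtype, copy=False)
        return (AR @ np.multiply.outer(xa, xa).ravel()).astype(float) / 2.0

    def weighted_gradient(yv, xv):
        """grad_i = sum_k y_k (A^(k) x)_i, restricted to y's numerical support
        (the sharp graph norm concentrates y on few graphs)."""
        ysup = np.flatnonzero(yv > 1e-3 * yv.max())
        M = (yv[ysup].astype(A.dtype) @ AR[ysup]).reshape(N, N)
        return (M @ xv.astype(A.dtype, copy=False)).astype(float)

    for _attempt in range(10):
        if x0 is not None and _attempt == 0:
            x = _normalize(np.asarray(x0, dtype=float), params.norm_p)
        else:
            x = _normalize(rng.exponential(1.0, N), params.norm_p)
        if y0 is not None and _attempt == 0:
            # one x-update against the seeded graph weights before refitting y
            y_seed = _normalize(np.asarray(y0, dtype=float), params.norm_q)
            grad0 = weighted_gradient(y_seed, x)
            if grad0.max() > 0:
                x = _normalize(grad0**inv_p, params.norm_p)
        g = quad_forms(x)
        if g.sum() > 0:
            break
    else:
        raise DegenerateInstanceError(
            "all-zero objective gradient after 10 restarts: graphs have no "
            "edges reachable from random starts"
        )

    y = _normalize(g**inv_q, params.norm_q)
    H = float(y @ g)
    history = [H]
    for _ in range(params.max_iter):
        grad_x = weighted_gradient(y, x)
        if grad_x.max() <= 0:
            break
        x_new = _normalize(grad_x**inv_p, params.norm_p)
        g = quad_forms(x_new)
        y_new = _normalize(g**inv_q, params.norm_q) if g.sum() > 0 else y
        H_new = float(y_new @ g)
        if H_new < H * (1 - 1e-9):
            break  # reject the step; keep the last accepted iterate
        x, y = x_new, y_new
        converged = H > 0 and abs(H_new - H) / max(H, _EPS) < params.tol
        H = H_new
        history.append(H)
        if converged:
            break
    return x, y, history


def _per_graph_density(A: np.ndarray, idx: np.ndarray) -> np.ndarray:
    m = len(idx)
    sub = A[:, idx[:, None], idx[None, :]]
    return sub.sum(axis=(1, 2), dtype=np.float64) / (m * (m - 1))


def discretize(
    x: np.ndarray, y: np.ndarray, graphs, params: MiningParams
) -> CandidatePattern | None:
    """Round the continuous solution to the largest qualifying top-m node set.

    Scans S_m = top-m nodes of x for m = min_size .. m_max and keeps the
    largest m whose support fraction (graphs with induced density >=
    min_density) reaches min_freq. m_max is the weight support of x — the
    nodes holding at least 10% of the maximum weight — capped at 20 (the
    downstream 2^|D| enumeration guard): multiplicative updates decay
    geometrically off the dense core, so nodes below that cut are noise and
    admitting them would bolt spurious members onto an otherwise exact
    pattern. Ties in x are broken by ascending node index, so the output is
    stable.
    """
    A = graphs if isinstance(graphs, np.ndarray) else _stack(graphs)
    K, N, _ = A.shape
    x = np.asarray(x, dtype=float)
    order = np.lexsort((np.arange(N), -x))
    m_support = int((x > 0.10 * x.max()).sum()) if x.max() > 0 else N
    m_max = min(N, 20, max(params.min_size, m_support))
    best = None
    for m in range(params.min_size, m_max + 1):
        idx = np.sort(order[:m])
        dens = _per_graph_density(A, idx)
        supp = np.flatnonzero(dens >= params.min_density - 1e-12)
        if len(supp) / K >= params.min_freq - 1e-12:
            best = CandidatePattern(
                nodes=tuple(int(i) for i in idx),
                support=supp,
                densities=dens[supp],
                n_graphs=K,
            )
    return best


def _evaluate_nodes(
    A: np.ndarray, nodes: tuple[int, ...], params: MiningParams
) -> CandidatePattern | None:
    """Re-verify a node set against the exact thresholds on (unmasked) graphs."""
    idx = np.asarray(nodes, dtype=int)
    dens = _per_graph_density(A, idx)
    supp = np.flatnonzero(dens >= params.min_density - 1e-12)
    if len(idx) >= params.min_size and len(supp) / A.shape[0] >= params.min_freq - 1e-12:
        return CandidatePattern(tuple(map(int, idx)), supp, dens[supp], A.shape[0])
    return None


def _grow_seed(A: np.ndarray, i: int, j: int, params: MiningParams):
    """Greedily grow a seed pair into a candidate node set inside the graphs
    holding its edge.

    Starting from S = {i, j} and the holder graphs of edge (i, j), repeatedly
    add the node that keeps the induced density >= min_density in the most
    holder graphs, while that count stays above the frequency threshold
    (ties break to the lowest node index). Returns (S, supporting graph
    indices) or None when the pair cannot grow to min_size — the cheap
    failure path for scattered background contacts. Deterministic.
    """
    K, N, _ = A.shape
    holders = np.flatnonzero(A[:, i, j])
    min_count = max(2, int(np.ceil(params.min_freq * K - 1e-9)))
    if len(holders) < min_count:
        return None
    sub = A[holders]  # (h, N, N)
    S = [i, j]
    edges_S = sub[:, i, j].astype(np.float64)  # induced edges per holder graph
    while len(S) < min(20, N):
        m = len(S)
        # (h, N): edges from candidate to S
        add = sub[:, :, S].sum(axis=2, dtype=np.float64)
        dens = 2.0 * (edges_S[:, None] + add) / ((m + 1) * m)
        ok = dens >= params.min_density - 1e-12
        ok[:, S] = False
        support = ok.sum(axis=0)
        # prefer support, then edges contributed within supporting graphs,
        # then lowest index — a node adjacent to one member in every holder
        # must not beat a true member adjacent to all of them
        gain = (add * ok).sum(axis=0)
        c = int(np.lexsort((np.arange(N), -gain, -support))[0])
        if support[c] < min_count:
            break
        S.append(c)
        edges_S = edges_S + add[:, c]
    if len(S) < params.min_size:
        return None
    m = len(S)
    dens_S = 2.0 * edges_S / (m * (m - 1))
    H = holders[dens_S >= params.min_density - 1e-12]
    if len(H) < min_count:
        return None
    return S, H


def mask_and_iterate(graphs, params: MiningParams) -> list[CandidatePattern]:
    """Full pattern-set extraction: optimize, discretize, verify, mask, repeat.

    Accepted patterns are re-verified on the original (unmasked) graphs and
    their induced edges removed from the supporting graphs only, so
    overlapping patterns occurring in other structures stay discoverable.
    Restarts are seeded on the *unexplained frontier*: a contact pair not yet
    inside any accepted pattern, drawn proportional to its remaining
    occurrence count, together with one graph containing it (every tenth
    restart falls back to an unrestricted edge draw to keep generic
    exploration alive). Stops after ``params.restarts`` consecutive failures
    to produce a new qualifying pattern. Deterministic given params.seed
    (one counter-based RNG stream per restart).
    """
    A_orig = _stack(graphs)
    A_work = A_orig.astype(np.float32)  # working copy; densities sum in float64
    K, N, _ = A_work.shape
    patterns: list[CandidatePattern] = []
    seen: set[tuple[int, ...]] = set()
    explained = np.zeros((N, N), dtype=bool)  # pairs inside accepted patterns
    iu = np.triu_indices(N, 1)
    failures = 0
    counter = 0
    while failures < params.restarts:
        rng = np.random.default_rng([params.seed, counter])
        counter += 1
        # seed around a remaining edge, preferring pairs no pattern explains
        x0 = y0 = None
        pair_counts = A_work.sum(axis=0)[iu]
        frontier = pair_counts * ~explained[iu]
        screened = frontier.sum() > 0 and counter % 10 != 0
        weights = frontier if screened else pair_counts
        total = weights.sum()
        if total > 0:
            e = rng.choice(len(weights), p=weights / total)
            i, j = int(iu[0][e]), int(iu[1][e])
            if screened and params.min_size >= 3:
                # grow the pair inside its holder graphs; scattered
                # background contacts fail to grow and skip the optimization
                grown = _grow_seed(A_work, i, j, params)
                if grown is None:
                    failures += 1
                    continue
                S, H = grown
                if tuple(sorted(S)) in seen:
                    # this neighbourhood is already mined; don't pay for the
                    # optimization just to rediscover it
                    failures += 1
                    continue
                x0 = np.full(N, 1e-3)
                x0[S] = 1.0
                y0 = np.full(K, 1e-3)
                y0[H] = 1.0
            else:
                holders = np.flatnonzero(A_work[:, i, j])
                k = int(rng.choice(holders))
                x0 = np.full(N, 1e-3)
                x0[i] = x0[j] = 1.0
                y0 = np.full(K, 1e-3)
                y0[k] = 1.0
        try:
            x, y, _ = optimize_pattern(A_work, params, rng, x0=x0, y0=y0)
        except DegenerateInstanceError:
            break  # nothing left to mine
        cand = discretize(x, y, A_work, params)
        accepted = None
        if cand is not None and cand.nodes not in seen:
            accepted = _evaluate_nodes(A_orig, cand.nodes, params)
        if accepted is None:
            failures += 1
            continue
        failures = 0
        seen.add(accepted.nodes)
        patterns.append(accepted)
        idx = np.asarray(accepted.nodes)
        explained[np.ix_(idx, idx)] = True
        mask_supp = np.flatnonzero(
            _per_graph_density(A_work, idx) >= params.min_density - 1e-12
        )
        A_work[np.ix_(mask_supp, idx, idx)] = 0.0
    return patterns


def verify_patterns(patterns, graphs, params: MiningParams) -> bool:
    """Independent post-hoc check that every pattern meets all three thresholds."""
    A = _stack(graphs)
    for p in patterns:
        chk = _evaluate_nodes(A, p.nodes, params)
        if chk is None or set(chk.support) != set(p.support):
            return False
    return True


def brute_force_mine(graphs, params: MiningParams) -> list[CandidatePattern]:
    """Exhaustive oracle: all maximal node subsets meeting the thresholds.

    Guarded to N <= 15 nodes (exponential enumeration); intended for
    validation on small instances only.
    """
    A = _stack(graphs)
    K, N, _ = A.shape
    if N > 15:
        raise ValidationError(f"brute_force_mine refuses N = {N} > 15 nodes")
    qualifying: list[tuple[int, ...]] = []
    for m in range(params.min_size, N + 1):
        for combo in itertools.combinations(range(N), m):
            idx = np.asarray(combo)
            dens = _per_graph_density(A, idx)
            if (dens >= params.min_density - 1e-12).mean() >= params.min_freq - 1e-12:
                qualifying.append(combo)
    sets = [frozenset(q) for q in qualifying]
    maximal = [
        q
        for q, s in zip(qualifying, sets)
        if not any(s < t for t in sets)
    ]
    return [_evaluate_nodes(A, q, params) for q in maximal]


class FrequentClusterMiner(BaseEstimator):
    """Scikit-learn-style wrapper around the tensor miner.

    Parameters mirror :class:`MiningParams`. ``fit`` takes a collection of
    contracted CIGs (or (N, N) boolean adjacencies) and exposes the mined
    patterns as ``patterns_``.
    """

    def __init__(
        self,
        min_size: int = 4,
        min_density: float = 0.6,
        min_freq: float = 0.01,
        restarts: int = 200,
        max_iter: int = 500,
        tol: float = 1e-6,
        seed: int = 0,
        norm_p: float = 1.5,
        norm_q: float = 1.25,
    ):
        self.min_size = min_size
        self.min_density = min_density
        self.min_freq = min_freq
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.norm_p = norm_p
        self.norm_q = norm_q

    def _params(self) -> MiningParams:
        return MiningParams(**self.get_params())

    def fit(self, X, y=None):
        """Mine frequent dense patterns from the graph collection X."""
        params = self._params()
        self.n_graphs_ = len(X)
        self.patterns_ = mask_and_iterate(X, params)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).patterns_
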