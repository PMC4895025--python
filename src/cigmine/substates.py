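"""Partitioning a structure population into substates by NMF biclustering.

The binary cluster x structure occurrence matrix C is factorized as
C ~ W H (W, H >= 0) by Frobenius multiplicative updates; structure j joins
the substate argmax_h H[h, j], cluster i the substate argmax_h W[i, h].
Clusters occurring in at least a given fraction of all structures (default
10%) are removed first: prevalent clusters carry no partitioning signal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .domains import DomainTable
from .errors import ConfigurationError, ValidationError
from .isomorphism import FrequentCluster
from .population import StructurePopulation
from .spatial import rank_sum_compare

_EPS = 1e-12


def build_occurrence_matrix(
    clusters: list[FrequentCluster], K: int
) -> tuple[np.ndarray, list[str]]:
    """Binary M x K matrix of cluster occurrences, rows ordered by cluster_id."""
    ordered = sorted(clusters, key=lambda c: c.cluster_id)
    if not ordered:
        return np.zeros((0, K), dtype=np.uint8), []
    C = np.stack([c.occurrence.astype(np.uint8) for c in ordered])
    return C, [c.cluster_id for c in ordered]


def filter_prevalent(
    C: np.ndarray, row_ids: list[str], max_fraction: float = 0.10
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop rows with occurrence frequency >= max_fraction (boundary dropped).

    Returns (reduced matrix, kept ids, dropped ids); raises if nothing is left.
    """
    if not 0 < max_fraction <= 1:
        raise ConfigurationError("max_fraction must be in (0, 1]")
    freq = C.mean(axis=1)
    keep = freq < max_fraction - 1e-12
    dropped = [r for r, k in zip(row_ids, keep) if not k]
    if not keep.any():
        raise ValidationError("prevalence filter dropped every cluster")
    return C[keep], [r for r, k in zip(row_ids, keep) if k], dropped


@dataclass
class SubpopulationAssignment:
    """Hard partition of structures (and clusters) into k substates (1..k)."""

    structure_labels: np.ndarray
    cluster_labels: np.ndarray
    W: np.ndarray
    H: np.ndarray
    objective_history: list[float]
    converged: bool

    @property
    def k(self) -> int:
        return self.H.shape[0]


def _nmf_mu(
    C: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Lee-Seung multiplicative updates for min ||C - WH||_F^2; objective tracked."""
    M, K = C.shape
    scale = np.sqrt(C.mean() / k + _EPS)
    W = scale * rng.random((M, k)) + _EPS
    H = scale * rng.random((k, K)) + _EPS
    obj = [float(np.linalg.norm(C - W @ H) ** 2)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ C) / (W.T @ W @ H + _EPS)
        W *= (C @ H.T) / (W @ (H @ H.T) + _EPS)
        obj.append(float(np.linalg.norm(C - W @ H) ** 2))
        if abs(obj[-2] - obj[-1]) <= tol * max(obj[-2], _EPS):
            converged = True
            break
    return W, H, obj, converged


def nmf_bicluster(
    C: np.ndarray,
    k: int = 8,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    restarts: int = 10,
) -> SubpopulationAssignment:
    """NMF-based biclustering of the occurrence matrix into k substates.

    Best of ``restarts`` multiplicative-update runs by final Frobenius
    objective; deterministic given the seed. Ties in the argmax assignments
    resolve to the lowest substate index.
    """
    C = np.asarray(C, dtype=float)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if C.size == 0 or (C < 0).any():
        raise ValidationError("C must be nonempty and nonnegative")
    best = None
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        W, H, obj, conv = _nmf_mu(C, k, rng, max_iter, tol)
        if best is None or obj[-1] < best[2][-1]:
            best = (W, H, obj, conv)
    W, H, obj, conv = best
    if not conv:
        warnings.warn("NMF did not converge within max_iter", stacklevel=2)
    return SubpopulationAssignment(
        structure_labels=H.argmax(axis=0) + 1,
        cluster_labels=W.argmax(axis=1) + 1,
        W=W,
        H=H,
        objective_history=obj,
        converged=conv,
    )


class SubstateNMF(BaseEstimator):
    """Scikit-learn-style estimator facade over :func:`nmf_bicluster`.

    ``fit(C)`` factorizes the occurrence matrix; fitted attributes are
    ``W_``, ``H_``, ``structure_labels_``, ``cluster_labels_``,
    ``objective_history_`` and ``converged_``.
    """

    def __init__(
        self,
        k: int = 8,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-6,
        restarts: int = 10,
    ):
        self.k = k
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.restarts = restarts

    def fit(self, X, y=None):
        a = nmf_bicluster(
            X, k=self.k, seed=self.seed, max_iter=self.max_iter,
            tol=self.tol, restarts=self.restarts,
        )
        self.W_, self.H_ = a.W, a.H
        self.structure_labels_ = a.structure_labels
        self.cluster_labels_ = a.cluster_labels
        self.objective_history_ = a.objective_history
        self.converged_ = a.converged
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).structure_labels_


# ---------------------------------------------------------------------------
# substate summaries
# ---------------------------------------------------------------------------

def substate_contact_map(
    ccigs,
    assignment: SubpopulationAssignment,
    domains: DomainTable,
    quantile: float = 0.20,
) -> dict[int, pd.DataFrame]:
    """Top-quantile inter-chromosomal contact pairs per substate.

    For every substate, the contracted-level contact frequency of each
    inter-chromosomal domain pair is computed across that substate's
    structures; pairs at or above the (1 - quantile) frequency quantile are
    emitted. Substates with no structures are excluded with a warning.
    """
    if not 0 < quantile < 1:
        raise ConfigurationError("quantile must be in (0, 1)")
    L1 = domains.L1
    inter = L1[:, None] != L1[None, :]
    iu = np.triu_indices(domains.n, 1)
    inter_mask = inter[iu]
    stack = np.stack([g.adj for g in ccigs]).astype(float)
    out: dict[int, pd.DataFrame] = {}
    for s in range(1, assignment.k + 1):
        members = np.flatnonzero(assignment.structure_labels == s)
        if len(members) == 0:
            warnings.warn(f"substate {s} has no structures; excluded", stacklevel=2)
            continue
        freq = stack[members].mean(axis=0)[iu][inter_mask]
        cut = np.quantile(freq, 1 - quantile)
        sel = freq >= cut
        ii = iu[0][inter_mask][sel]
        jj = iu[1][inter_mask][sel]
        out[s] = pd.DataFrame(
            {
                "domain_a": [domains.domain_ids[i] for i in ii],
                "domain_b": [domains.domain_ids[j] for j in jj],
                "frequency": freq[sel],
            }
        ).sort_values(["domain_a", "domain_b"], ignore_index=True)
    return out


def substate_radial_comparison(
    population: StructurePopulation,
    assignment: SubpopulationAssignment,
    target_domain_ids,
    domains: DomainTable,
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Radial position of target domains per substate, plus pairwise rank tests.

    The per-structure radial position of a target is the minimum of its two
    homolog copies' distances from the nuclear centre (copies are unordered,
    so the more interior one represents "the" centromere/domain).
    """
    idx = domains.indices_of(target_domain_ids)
    radial = np.linalg.norm(population.coords[:, idx], axis=-1).min(axis=2).mean(axis=1)
    dists: dict[int, np.ndarray] = {}
    for s in range(1, assignment.k + 1):
        members = np.flatnonzero(assignment.structure_labels == s)
        if len(members):
            dists[s] = radial[members]
    rows = [
        (a, b, rank_sum_compare(dists[a], dists[b]))
        for a, b in itertools.combinations(sorted(dists), 2)
    ]
    return dists, pd.DataFrame(rows, columns=["substate_a", "substate_b", "p"])
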