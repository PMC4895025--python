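"""Regulatory-community annotation by factor-binding enrichment.

A frequent spatial cluster is a regulatory community when its member domains
are co-enriched in binding of at least one regulatory factor. Enrichment is a
one-sided permutation test: the statistic is the mean member signal, the null
draws equally many domains uniformly without replacement from the whole domain
pool, and p = (1 + #{null >= observed}) / (B + 1). q-values are
Benjamini-Hochberg adjusted; a cluster is enriched for a factor at q < alpha.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .domains import DomainTable
from .errors import ConfigurationError, ValidationError
from .isomorphism import FrequentCluster


def permutation_enrichment(
    member_idx,
    values: np.ndarray,
    B: int,
    rng: np.random.Generator,
) -> float:
    """One-sided permutation p-value for one (cluster, factor) pair.

    ``values`` is the factor's signal over all domains; ``member_idx`` indexes
    the cluster members. A constant signal column carries no rank information
    and yields p = 1 by convention.
    """
    if B < 100:
        raise ConfigurationError(f"need B >= 100 permutations, got {B}")
    values = np.asarray(values, dtype=float)
    member_idx = np.asarray(member_idx, dtype=int)
    m, n = len(member_idx), len(values)
    if m == 0 or m > n:
        raise ValidationError("cluster members must be a nonempty subset of domains")
    if values.max() == values.min():
        return 1.0
    observed = values[member_idx].mean()
    # B draws of m domains without replacement, vectorized
    u = rng.random((B, n))
    draws = np.argpartition(u, m - 1, axis=1)[:, :m]
    null = values[draws].mean(axis=1)
    return float((1 + (null >= observed - 1e-12).sum()) / (B + 1))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_clusters(
    clusters: list[FrequentCluster],
    signals: pd.DataFrame,
    domains: DomainTable,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of every cluster against every factor.

    One RNG stream per (cluster, factor), derived from the global seed, so
    results are reproducible regardless of evaluation order. BH correction is
    applied across the full (cluster x factor) table. Returns a tidy frame
    with columns cluster_id, factor, stat, p, q, enriched.
    """
    values = signals.to_numpy(float)
    factors = list(signals.columns)
    rows = []
    for ci, cluster in enumerate(clusters):
        idx = domains.indices_of(cluster.members)
        for fi, factor in enumerate(factors):
            rng = np.random.default_rng([seed, ci, fi])
            p = permutation_enrichment(idx, values[:, fi], B, rng)
            rows.append((cluster.cluster_id, factor, values[idx, fi].mean(), p))
    table = pd.DataFrame(rows, columns=["cluster_id", "factor", "stat", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["enriched"] = table["q"] < alpha
    return table


def classify_communities(
    enrichment: pd.DataFrame,
    clusters: list[FrequentCluster],
    factor_label_map: dict[str, str],
) -> pd.DataFrame:
    """Label clusters as regulatory communities from their enriched factors.

    A cluster is a community iff it is enriched for >= 1 factor; community
    labels come from the factor -> label map (e.g. RNAPII -> transcription),
    multi-label allowed. Factors in the map must exist in the enrichment table.
    """
    known = set(enrichment["factor"])
    unknown = set(factor_label_map) - known
    if unknown:
        raise ConfigurationError(
            f"labelling factors {sorted(unknown)} absent from the enrichment table"
        )
    enriched = enrichment[enrichment["enriched"].astype(bool)]
    by_cluster = enriched.groupby("cluster_id")["factor"].agg(list)
    rows = []
    for c in clusters:
        factors = by_cluster.get(c.cluster_id, [])
        labels = sorted({factor_label_map[f] for f in factors if f in factor_label_map})
        rows.append(
            (c.cluster_id, len(factors) > 0, len(factors), ";".join(labels))
        )
    return pd.DataFrame(
        rows, columns=["cluster_id", "is_community", "n_enriched_factors", "labels"]
    )


def shared_domain_tf_association(
    clusters: list[FrequentCluster], enrichment: pd.DataFrame
) -> tuple[np.ndarray, float]:
    """Association between domain sharing and shared enriched factors.

    Cross-tabulates, over all cluster pairs, whether the pair shares >= 1
    member domain against whether it shares >= 1 enriched factor; returns the
    2x2 table and the two-sided Fisher exact p.
    """
    if len(clusters) < 2:
        raise ValidationError("need at least 2 clusters")
    member_sets = {c.cluster_id: set(c.members) for c in clusters}
    enr = enrichment[enrichment["enriched"].astype(bool)]
    factor_sets = enr.groupby("cluster_id")["factor"].agg(set).to_dict()
    table = np.zeros((2, 2), dtype=int)
    for a, b in combinations(clusters, 2):
        share_dom = bool(member_sets[a.cluster_id] & member_sets[b.cluster_id])
        share_tf = bool(
            factor_sets.get(a.cluster_id, set()) & factor_sets.get(b.cluster_id, set())
        )
        table[0 if share_dom else 1, 0 if share_tf else 1] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate margins in the 2x2 table; p = 1", stacklevel=2)
        return table, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def cluster_set_overlap(set_a, set_b, threshold: float = 0.6) -> float:
    """Fraction of clusters in A whose best Jaccard match in B reaches threshold.

    Clusters are plain domain-id sets here; the >= boundary is counted as a
    match.
    """
    sets_a = [set(s) for s in set_a]
    sets_b = [set(s) for s in set_b]
    if not sets_a:
        raise ValidationError("set A is empty")
    if not sets_b:
        return 0.0
    matched = 0
    for a in sets_a:
        best = max(len(a & b) / len(a | b) for b in sets_b)
        if best >= threshold - 1e-12:
            matched += 1
    return matched / len(sets_a)
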