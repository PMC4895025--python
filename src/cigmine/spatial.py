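"""Spatial statistics: centromeric influence and TF stabilization of clusters.

Covers the strong/weak centromeric classification (weak = at most 30%
centromeric members), radial positions of clusters (nuclear-radius units),
centromere-distance comparisons with a random-structure control, rank-sum
tests, partial correlation of cluster frequency vs enriched-factor count
controlling for centromeric influence, hierarchical grouping of factors by
their enrichment profiles, sub-centromeric signal vs contact-frequency
correlation, and the per-domain occurrence-vs-centromere-distance trend.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .domains import DomainTable
from .errors import DegenerateControlError, ValidationError
from .isomorphism import FrequentCluster, enumerate_occurrences
from .population import StructurePopulation

CENTROMERIC_WEAK_MAX = 0.30  # proportion <= 0.30 -> weak influence


def centromeric_influence(
    cluster: FrequentCluster, domains: DomainTable
) -> tuple[str, float]:
    """('strong'|'weak', centromeric member proportion); boundary 0.30 is weak."""
    idx = domains.indices_of(cluster.members)
    prop = float((domains.categories[idx] == "centromeric").mean())
    return ("weak" if prop <= CENTROMERIC_WEAK_MAX else "strong"), prop


def rank_sum_compare(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def partial_correlation(x, y, z) -> tuple[float, float]:
    """First-order partial correlation r_xy.z with its t-test p-value.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2));
    p from t = r sqrt((n-3)/(1-r^2)) on n - 3 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise ValidationError("x, y, z must share length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValidationError("inputs must be finite")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise DegenerateControlError("control variable collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1 - 1e-15:
        return r, 0.0
    t = r * np.sqrt((n - 3) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return r, float(p)


# ---------------------------------------------------------------------------
# geometry per cluster
# ---------------------------------------------------------------------------

def _qualifying_assignment(
    cluster: FrequentCluster, cig, domains: DomainTable, min_density: float
) -> np.ndarray | None:
    """Copy bits realizing the cluster's signature in one structure, if any."""
    dom_idx = domains.indices_of(cluster.members)
    occ = enumerate_occurrences(dom_idx, cig, min_density, domains)
    hit = occ.get(cluster.signature)
    return None if hit is None else hit[1]


def compute_cluster_geometry(
    clusters: list[FrequentCluster],
    population: StructurePopulation,
    cigs,
    domains: DomainTable,
    min_density: float = 0.6,
) -> pd.DataFrame:
    """Radial position and centromeric influence per cluster.

    Radial position = mean over occurrence structures of the mean member-node
    distance from the nuclear centre, using the copy assignment that realizes
    the cluster's signature in each structure.
    """
    rows = []
    for cluster in clusters:
        dom_idx = domains.indices_of(cluster.members)
        radials = []
        for k in np.flatnonzero(cluster.occurrence):
            bits = _qualifying_assignment(cluster, cigs[k], domains, min_density)
            if bits is None:
                continue
            pos = population.coords[k][dom_idx, bits]
            radials.append(np.linalg.norm(pos, axis=1).mean())
        influence, prop = centromeric_influence(cluster, domains)
        rows.append(
            (
                cluster.cluster_id,
                cluster.frequency,
                float(np.mean(radials)) if radials else np.nan,
                influence,
                prop,
                cluster.n_chromosomes,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "frequency",
            "radial_position",
            "centromeric_influence",
            "centromeric_proportion",
            "n_chromosomes",
        ],
    )


# ---------------------------------------------------------------------------
# centromere distances
# ---------------------------------------------------------------------------

def _centromere_refs(chrom_l1s, domains: DomainTable) -> dict[int, int]:
    """L1 -> positional index of the centromere reference domain (or excluded)."""
    refs = {}
    chroms = domains.chroms
    for l1 in chrom_l1s:
        chrom = chroms[l1 - 1]
        try:
            refs[l1] = domains.centromere_reference_index(chrom)
        except KeyError:
            warnings.warn(
                f"chromosome {chrom} has no centromeric domain; excluded",
                stacklevel=3,
            )
    return refs


def _mean_centromere_distance(
    coords_k: np.ndarray, ref_idx: list[int]
) -> float:
    """Mean pairwise distance among centromere reference nodes in one structure.

    Copy ambiguity: per chromosome, the homolog copy minimizing the summed
    pairwise distance is used (exhaustive over the 2^c copy choices).
    """
    c = len(ref_idx)
    best = np.inf
    for bits in itertools.product((0, 1), repeat=c):
        pos = np.array([coords_k[d, b] for d, b in zip(ref_idx, bits)])
        total = pdist(pos).mean()
        best = min(best, total)
    return float(best)


def centromere_distance_groups(
    clusters: list[FrequentCluster],
    population: StructurePopulation,
    domains: DomainTable,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Three distributions of per-cluster mean centromere distances.

    'strong' and 'weak' hold, per cluster of that influence class, the mean
    (over occurrence structures) pairwise distance between the centromere
    reference domains of the chromosomes involved. 'random' holds, for each
    weak-influence cluster, the same quantity over equally many structures
    sampled from those where the cluster does NOT occur.
    """
    out = {"strong": [], "weak": [], "random": []}
    for cluster in clusters:
        l1s = sorted({domains.L1[i] for i in domains.indices_of(cluster.members)})
        refs = _centromere_refs(l1s, domains)
        if len(refs) < 2:
            continue  # no centromere pair to measure
        ref_idx = list(refs.values())
        occ = np.flatnonzero(cluster.occurrence)
        influence, _ = centromeric_influence(cluster, domains)
        dists = [
            _mean_centromere_distance(population.coords[k], ref_idx) for k in occ
        ]
        out[influence].append(float(np.mean(dists)))
        if influence == "weak":
            non_occ = np.flatnonzero(~cluster.occurrence)
            if len(non_occ) == 0:
                raise ValidationError(
                    f"cluster {cluster.cluster_id} occurs in every structure; "
                    "no control sample available"
                )
            pick = rng.choice(non_occ, size=min(len(occ), len(non_occ)), replace=False)
            ctrl = [
                _mean_centromere_distance(population.coords[k], ref_idx) for k in pick
            ]
            out["random"].append(float(np.mean(ctrl)))
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# factor grouping and signal-contact correlation
# ---------------------------------------------------------------------------

def group_factors_by_profile(
    enrichment: pd.DataFrame, n_groups: int = 4
) -> pd.Series:
    """Group factors by their binary enrichment profiles across clusters.

    Average-linkage hierarchical clustering on pairwise Jaccard distances of
    the factor x cluster enrichment indicator matrix, cut to n_groups.
    Factors never enriched carry no profile and land in residual group 0.
    """
    profile = (
        enrichment.assign(e=enrichment["enriched"].astype(int))
        .pivot_table(index="factor", columns="cluster_id", values="e", fill_value=0)
    )
    active = profile[profile.sum(axis=1) > 0]
    if len(active) < n_groups:
        raise ValidationError(
            f"need >= {n_groups} factors with at least one enrichment; "
            f"got {len(active)}"
        )
    dist = pdist(active.to_numpy(bool), metric="jaccard")
    labels = fcluster(linkage(dist, method="average"), t=n_groups, criterion="maxclust")
    groups = pd.Series(0, index=profile.index, name="group", dtype=int)
    groups.loc[active.index] = labels
    return groups


def subcentromere_contact_frequencies(
    cigs, domains: DomainTable
) -> pd.Series:
    """Contact frequency of centromere reference domains for every chromosome pair.

    Contact at the contracted level: any copy pair touching counts.
    """
    chroms = domains.chroms
    refs = _centromere_refs(range(1, len(chroms) + 1), domains)
    pairs, freqs = [], []
    for (l1a, da), (l1b, db) in itertools.combinations(sorted(refs.items()), 2):
        hits = 0
        for cig in cigs:
            block = cig.adj[2 * da : 2 * da + 2, 2 * db : 2 * db + 2]
            hits += bool(block.any())
        pairs.append((chroms[l1a - 1], chroms[l1b - 1]))
        freqs.append(hits / len(cigs))
    return pd.Series(freqs, index=pd.MultiIndex.from_tuples(pairs))


def signal_contact_correlation(
    subcentromeric_signal: pd.Series, contact_freq: pd.Series
) -> tuple[float, float]:
    """Pearson correlation between sub-centromeric signal and centromere contacts.

    ``subcentromeric_signal`` is one value per chromosome (e.g. the mean
    signal of a TF group over that chromosome's centromeric domains);
    ``contact_freq`` is indexed by chromosome pairs. The predictor for a pair
    is the mean of the two chromosomes' signals.
    """
    preds, resp = [], []
    for (ca, cb), f in contact_freq.items():
        if ca in subcentromeric_signal.index and cb in subcentromeric_signal.index:
            preds.append(0.5 * (subcentromeric_signal[ca] + subcentromeric_signal[cb]))
            resp.append(f)
    if len(preds) < 3:
        raise ValidationError("need at least 3 chromosome pairs with both values")
    r, p = stats.pearsonr(preds, resp)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# domain occurrence vs centromere distance
# ---------------------------------------------------------------------------

def domain_occurrence_profile(
    clusters: list[FrequentCluster],
    domains: DomainTable,
    n_bins: int = 6,
    inter_only: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-domain cluster participation and its trend in centromere distance.

    Counts, for every domain, the clusters containing it (inter-chromosomal
    only by default), then bins domains into ``n_bins`` equal-count groups of
    increasing linear distance to their chromosome's centromere midpoint and
    reports mean +/- sd of the counts per bin.
    """
    counts = pd.Series(0, index=domains.domain_ids, dtype=int)
    for c in clusters:
        if inter_only and not c.is_inter_chromosomal:
            continue
        for m in c.members:
            counts[m] += 1

    dist = []
    for _, row in domains.df.iterrows():
        try:
            mid = domains.centromere_midpoint(row["chrom"])
        except KeyError:
            dist.append(np.nan)
            continue
        dist.append(abs(0.5 * (row["start"] + row["end"]) - mid))
    dist = pd.Series(dist, index=domains.domain_ids)
    valid = dist.dropna().index
    order = dist[valid].sort_values(kind="stable").index
    bins = np.array_split(np.arange(len(order)), n_bins)
    rows = []
    for b, pos in enumerate(bins):
        ids = order[pos]
        rows.append(
            (
                b + 1,
                len(ids),
                float(dist[ids].mean()),
                float(counts[ids].mean()),
                float(counts[ids].std(ddof=1)) if len(ids) > 1 else 0.0,
            )
        )
    trend = pd.DataFrame(
        rows, columns=["bin", "n_domains", "mean_distance_bp", "mean_count", "sd_count"]
    )
    return counts, trend
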