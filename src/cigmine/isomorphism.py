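"""Coupled-isomorphism resolution: restore mined patterns to the diploid CIGs.

Homolog copy labels A/B are arbitrary per chromosome per structure, so two
occurrences of a domain set are equivalent ("coupled isomorphic") whenever one
maps onto the other by swapping A and B chromosome-wise. The canonical copy
signature below quotients out that symmetry: per chromosome it records only the
unordered bipartition of member domains into same-copy groups. Counting
occurrences then reduces to item counting of signatures — no general subgraph
isomorphism machinery is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .domains import DomainTable
from .errors import ValidationError
from .graphs import CIG

# 2^|D| assignments are enumerated per structure; patterns above this are implausible
MAX_PATTERN_SIZE = 20


def _canon_parts(part_a: tuple[int, ...], part_b: tuple[int, ...]) -> tuple:
    """Order the two same-copy groups canonically: non-empty before empty,
    then lexicographically smaller first."""
    a, b = tuple(sorted(part_a)), tuple(sorted(part_b))
    key = lambda t: (len(t) == 0, t)
    return tuple(sorted((a, b), key=key))


@dataclass(frozen=True)
class CopySignature:
    """Canonical per-chromosome bipartition of a pattern's domains by homolog copy.

    ``parts`` is a tuple of (L1, (G1, G2)) sorted by L1, where G1/G2 are sorted
    L2 tuples of members sharing a copy (G2 possibly empty). Invariant under
    per-chromosome A<->B swaps; encodes no cross-chromosome copy correspondence.
    """

    parts: tuple[tuple[int, tuple[tuple[int, ...], tuple[int, ...]]], ...]

    def __str__(self) -> str:
        def fmt(g):
            return ",".join(map(str, g)) if g else "-"

        return "; ".join(f"chr{L1}:[{fmt(g1)}|{fmt(g2)}]" for L1, (g1, g2) in self.parts)

    def to_json(self) -> list:
        return [[L1, [list(g1), list(g2)]] for L1, (g1, g2) in self.parts]

    @classmethod
    def from_json(cls, obj) -> "CopySignature":
        return cls(
            tuple(
                (int(L1), _canon_parts(tuple(g1), tuple(g2)))
                for L1, (g1, g2) in obj
            )
        )


def canonical_signature(node_set) -> CopySignature:
    """Signature of a set of (L1, L2, L3) nodes; L3 in {'A', 'B'}.

    Raises if two nodes share (L1, L2): contracted patterns hold one copy per
    domain, so a duplicate means the caller passed an invalid occurrence.
    """
    nodes = list(node_set)
    seen = {(l1, l2) for l1, l2, _ in nodes}
    if len(seen) != len(nodes):
        raise ValidationError("duplicate (L1, L2) in node set")
    by_chrom: dict[int, tuple[list[int], list[int]]] = {}
    for l1, l2, l3 in nodes:
        if l3 not in ("A", "B"):
            raise ValidationError(f"copy label must be A or B, got {l3!r}")
        by_chrom.setdefault(l1, ([], []))[0 if l3 == "A" else 1].append(l2)
    parts = tuple(
        (l1, _canon_parts(tuple(ab[0]), tuple(ab[1])))
        for l1, ab in sorted(by_chrom.items())
    )
    return CopySignature(parts)


def _assignment_signature(
    dom_idx: np.ndarray, bits: np.ndarray, domains: DomainTable
) -> CopySignature:
    L1, L2 = domains.L1, domains.L2
    nodes = [
        (int(L1[d]), int(L2[d]), "A" if b == 0 else "B")
        for d, b in zip(dom_idx, bits)
    ]
    return canonical_signature(nodes)


def _assignment_grid(dom_idx: np.ndarray, domains: DomainTable):
    """Precompute, for a domain set, the (2^m, m) copy-bit grid, the matching
    CIG node indices and the canonical signature of every assignment."""
    m = len(dom_idx)
    if m > MAX_PATTERN_SIZE:
        raise ValidationError(
            f"pattern of {m} domains exceeds the 2^|D| enumeration guard "
            f"({MAX_PATTERN_SIZE}); such a pattern is implausibly large"
        )
    if m < 2:
        raise ValidationError("pattern needs at least 2 domains")
    bits = np.array(list(itertools.product((0, 1), repeat=m)), dtype=int)
    node_idx = 2 * dom_idx[None, :] + bits
    sigs = [_assignment_signature(dom_idx, b, domains) for b in bits]
    return bits, node_idx, sigs


def enumerate_occurrences(
    D, cig: CIG, min_density: float, domains: DomainTable
) -> dict[CopySignature, tuple[float, np.ndarray]]:
    """All qualifying occurrences of domain set D in one CIG, grouped by signature.

    Walks the 2^|D| copy assignments, keeps those whose induced CIG density is
    >= min_density, and collapses them to canonical signatures, retaining per
    signature the best density and one best-scoring copy-bit assignment.
    """
    dom_idx = np.asarray(list(D), dtype=int)
    m = len(dom_idx)
    bits, node_idx, sigs = _assignment_grid(dom_idx, domains)
    sub = cig.adj[node_idx[:, :, None], node_idx[:, None, :]]
    dens = sub.sum(axis=(1, 2)) / (m * (m - 1))
    out: dict[CopySignature, tuple[float, np.ndarray]] = {}
    for a in np.flatnonzero(dens >= min_density - 1e-12):
        sig = sigs[a]
        best = out.get(sig)
        if best is None or dens[a] > best[0]:
            out[sig] = (float(dens[a]), bits[a].copy())
    return out


@dataclass
class FrequentCluster:
    """A frequent spatial cluster: domain set + copy signature + occurrence vector."""

    cluster_id: str
    members: tuple[str, ...]  # domain_id strings, (L1, L2)-sorted
    signature: CopySignature
    occurrence: np.ndarray  # bool, length K
    mean_density: float
    n_chromosomes: int
    centromeric_proportion: float = float("nan")

    @property
    def frequency(self) -> float:
        return float(self.occurrence.mean())

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_inter_chromosomal(self) -> bool:
        return self.n_chromosomes >= 2


def count_variants(
    candidates,
    cigs: list[CIG],
    domains: DomainTable,
    min_density: float = 0.6,
    min_freq: float = 0.01,
) -> list[FrequentCluster]:
    """Coupled-isomorphism counting of candidate patterns on the original CIGs.

    For every candidate domain set and every structure, qualifying copy
    assignments are collapsed to signatures; each (domain set, signature)
    variant gets its own occurrence vector, and only variants whose CIG-based
    frequency reaches min_freq are emitted. The frequency threshold applies
    per variant: isomorphic groups are the countable unit.
    """
    K = len(cigs)
    stack = np.stack([c.adj for c in cigs])  # (K, 2N, 2N)
    clusters: list[FrequentCluster] = []
    seen_sets = set()
    cat = domains.categories
    for cand in candidates:
        dom_idx = tuple(sorted(cand.nodes if hasattr(cand, "nodes") else cand))
        if dom_idx in seen_sets:
            continue
        seen_sets.add(dom_idx)
        arr = np.asarray(dom_idx, dtype=int)
        m = len(arr)
        bits, node_idx, sigs = _assignment_grid(arr, domains)
        # densities of every (structure, assignment) pair, chunked to bound memory
        dens = np.empty((K, len(bits)))
        for lo in range(0, len(bits), 1024):
            ni = node_idx[lo : lo + 1024]
            sub = stack[:, ni[:, :, None], ni[:, None, :]]
            dens[:, lo : lo + 1024] = sub.sum(axis=(2, 3)) / (m * (m - 1))
        qual = dens >= min_density - 1e-12
        occ: dict[CopySignature, np.ndarray] = {}
        dens_sum: dict[CopySignature, float] = {}
        # assignments sharing a signature collapse; keep the best density per structure
        sig_groups: dict[CopySignature, list[int]] = {}
        for a, sig in enumerate(sigs):
            sig_groups.setdefault(sig, []).append(a)
        for sig, cols in sig_groups.items():
            hit = qual[:, cols].any(axis=1)
            if hit.any():
                occ[sig] = hit
                dens_sum[sig] = float(dens[np.ix_(hit, cols)].max(axis=1).sum())
        members = tuple(domains.domain_ids[d] for d in dom_idx)
        n_chrom = len(set(domains.L1[list(dom_idx)]))
        cen_prop = float((cat[list(dom_idx)] == "centromeric").mean())
        for sig in sorted(occ, key=str):
            vec = occ[sig]
            n_occ = int(vec.sum())
            if n_occ / K >= min_freq - 1e-12:
                clusters.append(
                    FrequentCluster(
                        cluster_id=f"c{len(clusters):05d}",
                        members=members,
                        signature=sig,
                        occurrence=vec,
                        mean_density=dens_sum[sig] / n_occ,
                        n_chromosomes=n_chrom,
                        centromeric_proportion=cen_prop,
                    )
                )
    return clusters


def classify_span(cluster: FrequentCluster) -> tuple[str, int]:
    """('inter'|'intra', chromosome count); inter iff the cluster spans >= 2 chromosomes."""
    if cluster.size == 0:
        raise ValidationError("empty cluster has no span")
    n = cluster.n_chromosomes
    return ("inter" if n >= 2 else "intra"), n
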