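"""Chromatin interaction graphs (CIGs) and their homolog-contracted form.

A CIG has 2N nodes — one per homolog copy of each macrodomain, labelled
L1-L2-L3 — and an edge wherever two domain spheres are in spatial contact.
Contraction merges the two "twin" copies of every domain into a single node
(L1, L2); a contracted edge is present iff ANY copy pair of the two domains
was in contact. Contraction can only add induced density, never remove it,
so every pattern dense in a CIG under some copy assignment stays dense in
the cCIG — the property that lets mining run on the contracted graphs.

Node indexing convention: CIG node = 2 * domain_index + copy (0=A, 1=B),
with domain_index the (L1, L2)-sorted position in the DomainTable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import DomainTable
from .errors import ValidationError
from .population import StructurePopulation


@dataclass
class CIG:
    """Per-structure diploid contact graph as a dense boolean adjacency (2N, 2N)."""

    structure_id: str
    adj: np.ndarray

    def __post_init__(self):
        self.adj = np.asarray(self.adj, dtype=bool)
        m = self.adj.shape[0]
        if self.adj.shape != (m, m) or m % 2:
            raise ValidationError(f"CIG adjacency must be square of even size; got {self.adj.shape}")
        if self.adj.diagonal().any():
            raise ValidationError("CIG contains self-edges")
        if not np.array_equal(self.adj, self.adj.T):
            raise ValidationError("CIG adjacency not symmetric")

    @property
    def n_domains(self) -> int:
        return self.adj.shape[0] // 2


@dataclass
class ContractedCIG:
    """Twin-merged contact graph on the N domains (boolean adjacency (N, N))."""

    structure_id: str
    adj: np.ndarray

    def __post_init__(self):
        self.adj = np.asarray(self.adj, dtype=bool)

    @property
    def n_domains(self) -> int:
        return self.adj.shape[0]


def call_contacts(
    positions: np.ndarray, domains: DomainTable, contact_scale: float = 1.0
) -> np.ndarray:
    """Contact adjacency of one structure from sphere geometry.

    Two nodes i != j are in contact iff ||p_i - p_j|| <= contact_scale * (r_i + r_j):
    the spheres touch or overlap, optionally scaled. Homolog-homolog pairs of the
    same domain are included. Returns a (2N, 2N) boolean matrix.
    """
    if contact_scale <= 0:
        raise ValidationError(f"contact_scale must be > 0, got {contact_scale}")
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 3:  # (N, 2, 3) -> (2N, 3)
        pos = pos.reshape(-1, 3)
    if pos.shape != (2 * domains.n, 3):
        raise ValidationError(
            f"expected {2 * domains.n} node positions, got {pos.shape[0]}"
        )
    radii = np.repeat(domains.radii, 2)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff * diff).sum(-1))
    thresh = contact_scale * (radii[:, None] + radii[None, :])
    adj = dist <= thresh
    np.fill_diagonal(adj, False)
    return adj


def build_cigs(
    population: StructurePopulation,
    domains: DomainTable,
    contact_scale: float = 1.0,
) -> list[CIG]:
    """Transform every structure of the population into a CIG (order preserved)."""
    return [
        CIG(population.structure_ids[k], call_contacts(population.coords[k], domains, contact_scale))
        for k in range(population.K)
    ]


def contract(cig: CIG) -> ContractedCIG:
    """Merge homolog twins: edge {u, v} iff some copy pair of u and v touches.

    Twin-twin edges (the two copies of one domain) land on the diagonal and are
    dropped: a pattern never contains the same domain twice after merging.
    """
    n = cig.n_domains
    merged = cig.adj.reshape(n, 2, n, 2).any(axis=(1, 3))
    np.fill_diagonal(merged, False)
    return ContractedCIG(cig.structure_id, merged)


def edge_density(adj: np.ndarray, node_set) -> float:
    """Induced edge density 2|E(S)| / (|S| (|S|-1)) of node_set S in adjacency adj."""
    idx = np.asarray(list(node_set), dtype=int)
    m = len(idx)
    if m < 2:
        raise ValidationError(f"edge density needs |S| >= 2, got {m}")
    sub = adj[np.ix_(idx, idx)]
    return float(sub.sum()) / (m * (m - 1))


def write_contracted_edges(ccigs: list[ContractedCIG], domains: DomainTable, path) -> None:
    """TSV dump of cCIG edge lists (structure_id, L1-L2, L1-L2) for inspection."""
    L1, L2 = domains.L1, domains.L2
    with open(path, "w") as fh:
        fh.write("structure_id\tnode1\tnode2\n")
        for g in ccigs:
            ii, jj = np.nonzero(np.triu(g.adj, 1))
            for i, j in zip(ii, jj):
                fh.write(f"{g.structure_id}\t{L1[i]}-{L2[i]}\t{L1[j]}-{L2[j]}\n")
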