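"""Shared fixtures: tiny programmatic domain tables, graphs and populations."""

import numpy as np
import pandas as pd
import pytest

from cigmine.domains import DomainTable
from cigmine.graphs import CIG
from cigmine.population import StructurePopulation


def make_domain_table(n_chrom=2, per_chrom=4, radius=0.05, categories=None):
    """Small synthetic annotation with one centromeric domain per chromosome."""
    rows = []
    for c in range(1, n_chrom + 1):
        for d in range(1, per_chrom + 1):
            if categories is not None:
                cat = categories[(c - 1) * per_chrom + (d - 1)]
            else:
                cat = "centromeric" if d == per_chrom // 2 + 1 else "active"
            rows.append(
                {
                    "chrom": f"chr{c}",
                    "start": (d - 1) * 1000,
                    "end": d * 1000,
                    "domain_id": f"chr{c}_d{d}",
                    "radius": radius,
                    "category": cat,
                }
            )
    return DomainTable(pd.DataFrame(rows))


def cig_from_edges(domains, edges, structure_id="s0"):
    """CIG from edges given as ((L1, L2, 'A'|'B'), (L1, L2, 'A'|'B')) pairs."""
    n = 2 * domains.n
    adj = np.zeros((n, n), dtype=bool)
    for (l1a, l2a, ca), (l1b, l2b, cb) in edges:
        i = 2 * domains.index_of_label(l1a, l2a) + (0 if ca == "A" else 1)
        j = 2 * domains.index_of_label(l1b, l2b) + (0 if cb == "A" else 1)
        adj[i, j] = adj[j, i] = True
    return CIG(structure_id, adj)


def random_diploid_cig(rng, n_domains, edge_prob, structure_id="s0"):
    n = 2 * n_domains
    upper = np.triu(rng.random((n, n)) < edge_prob, 1)
    return CIG(structure_id, upper | upper.T)


@pytest.fixture
def domains2x4():
    return make_domain_table(2, 4)


@pytest.fixture
def domains3x3():
    return make_domain_table(3, 3)


def make_population(coords, structure_ids=None):
    return StructurePopulation(np.asarray(coords, dtype=float), structure_ids or [])
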