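"""Seeded synthetic diploid structure populations with planted ground truth.

The generator is the test substrate for every other module. It emulates the
statistical structure the analyses assume — a confined diploid sphere-chain
population with co-localizing domain clusters planted at controlled
frequency, factor signals with planted enrichment, and optional substate
structure — without attempting polymer physics.

Chromosomes are laid out as confined random chains: successive domain
centres are separated by the sum of their radii along a uniformly random
direction, reflected radially at the nuclear envelope; the two homolog
copies are generated independently. In structures selected i.i.d. at the
target frequency, a planted cluster's members (on copies matching its
signature) are repositioned around a random interior point: each member is
"attached" with probability sqrt(p_contact) — attached members land inside a
mutually-touching ball, detached members are displaced beyond contact range —
so every within-cluster pair is in contact with probability p_contact and the
expected induced density is ~p_contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import DomainTable
from .errors import ConfigurationError
from .isomorphism import CopySignature, canonical_signature
from .population import StructurePopulation

_CAT_PROBS = {"active": 0.345, "inactive": 0.386, "other": 0.269}
_DOMAIN_MB = 5_000_000  # genomic span per synthetic domain


@dataclass
class PlantedCluster:
    """A co-localizing domain set planted at a target occurrence frequency.

    ``members`` are (chrom_index, within_chrom_index) pairs (both 1-based).
    ``cross_copy`` optionally lists members placed on the opposite homolog
    copy from the rest of their chromosome's members, defining the planted
    copy signature.
    """

    members: tuple[tuple[int, int], ...]
    frequency: float = 0.06
    contact_probability: float = 0.9
    epsilon: float = 0.05  # co-localization ball radius
    cross_copy: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not 0 < self.frequency <= 1:
            raise ConfigurationError("target frequency must be in (0, 1]")
        if not 0 < self.contact_probability <= 1:
            raise ConfigurationError("contact probability must be in (0, 1]")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")


@dataclass
class SubstateSpec:
    """One planted substate: a structure fraction plus its planted-cluster subset."""

    fraction: float
    cluster_indices: tuple[int, ...]


@dataclass
class SimulationConfig:
    n_chrom: int = 3
    domains_per_chrom: int = 20
    radius: float = 0.03
    K: int = 500
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    substates: list[SubstateSpec] | None = None
    background_occurrence: float = 0.02  # out-of-substate planted frequency
    factors: tuple[str, ...] = ("TF1", "TF2", "TF3", "TF4")
    signal_mu: float = 0.0
    signal_sigma: float = 1.0
    enrichments: list[tuple[str, int, float]] = field(default_factory=list)
    centromere_bias: bool = False  # bias the first domain of each chain to the centre
    include_annotations: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.substates is not None:
            total = sum(s.fraction for s in self.substates)
            if total > 1 + 1e-9:
                raise ConfigurationError("substate fractions must sum to <= 1")


@dataclass
class GroundTruth:
    """What was actually planted, for validation against mining output."""

    member_ids: list[tuple[str, ...]]  # per planted cluster, (L1,L2)-sorted ids
    member_indices: list[np.ndarray]
    signatures: list[CopySignature]
    occurrence: list[np.ndarray]  # realized (Bernoulli) on-vector per cluster
    substate_labels: np.ndarray | None = None  # per structure, 1..S (0 = background)
    enriched: dict[str, list[int]] = field(default_factory=dict)  # factor -> clusters


# ---------------------------------------------------------------------------
# domain table
# ---------------------------------------------------------------------------

def generate_domain_table(config: SimulationConfig) -> DomainTable:
    """Synthetic annotation: equal 5-Mb domains, middle three per chromosome
    centromeric, the rest active/inactive/other at roughly genomic proportions."""
    rng = np.random.default_rng([config.seed, 101])
    n = config.domains_per_chrom
    mid = n // 2
    cen = {mid - 1, mid, mid + 1} if n >= 5 else {mid}
    rows = []
    cats = list(_CAT_PROBS)
    probs = np.array(list(_CAT_PROBS.values()))
    probs = probs / probs.sum()
    for c in range(1, config.n_chrom + 1):
        for d in range(1, n + 1):
            category = (
                "centromeric" if (d - 1) in cen else cats[rng.choice(3, p=probs)]
            )
            row = {
                "chrom": f"chr{c}",
                "start": (d - 1) * _DOMAIN_MB,
                "end": d * _DOMAIN_MB,
                "domain_id": f"chr{c}_d{d:02d}",
                "radius": config.radius,
                "category": category,
            }
            if config.include_annotations:
                row["gene_density"] = float(rng.gamma(2.0, 1.5))
                row["expression"] = float(rng.lognormal(0.0, 1.0))
            rows.append(row)
    return DomainTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _ball_point(rng, radius, centre=(0.0, 0.0, 0.0)):
    return np.asarray(centre) + radius * rng.random() ** (1 / 3) * _unit_vectors(rng, 1)[0]


def _chain(rng, n, r, centromere_bias):
    """One chromosome copy: a reflected random chain of n touching spheres."""
    start_radius = 0.3 if centromere_bias else 1.0 - r
    pos = np.empty((n, 3))
    pos[0] = _ball_point(rng, start_radius)
    dirs = _unit_vectors(rng, n - 1)
    for i in range(1, n):
        p = pos[i - 1] + 2 * r * dirs[i - 1]
        d = np.linalg.norm(p)
        if d + r > 1.0:  # radial reflection at the envelope
            p *= max(2 * (1.0 - r) - d, 0.0) / d
        pos[i] = p
    return pos


def _plant_positions(rng, coords_s, dom_idx, copies, radii, epsilon, p_contact):
    """Reposition planted members around a random interior point (see module doc)."""
    m = len(dom_idx)
    min_rsum = 2 * radii.min()
    max_rsum = 2 * radii.max()
    if epsilon < radii.max():
        raise ConfigurationError(
            "co-localization radius epsilon is smaller than a member radius"
        )
    rho = min(epsilon, 0.45 * min_rsum)
    z = _ball_point(rng, 0.5)
    attach = rng.random(m) < np.sqrt(p_contact)
    if not attach.any():
        attach[rng.integers(m)] = True
    for j in range(m):
        if attach[j]:
            p = _ball_point(rng, rho, z)
        else:
            p = z + (rho + 2 * max_rsum * (1.0 + rng.random())) * _unit_vectors(rng, 1)[0]
        coords_s[dom_idx[j], copies[j]] = p


def _planted_on_matrix(config: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray | None]:
    """(n_planted, K) boolean on-matrix, plus substate labels when configured."""
    K = len(config.planted_clusters), config.K
    on = np.zeros(K, dtype=bool)
    if config.substates is None:
        for i, pc in enumerate(config.planted_clusters):
            on[i] = rng.random(config.K) < pc.frequency
        return on, None
    # deterministic split: exact proportions, substates in declared order
    counts = [int(round(s.fraction * config.K)) for s in config.substates]
    while sum(counts) > config.K:
        counts[-1] -= 1
    labels = np.zeros(config.K, dtype=int)
    pos = 0
    for s, c in enumerate(counts, start=1):
        labels[pos : pos + c] = s
        pos += c
    owner: dict[int, set[int]] = {}
    for s, spec in enumerate(config.substates, start=1):
        for ci in spec.cluster_indices:
            owner.setdefault(ci, set()).add(s)
    overlap = [ci for ci, ss in owner.items() if len(ss) > 1]
    if overlap:
        import warnings

        warnings.warn(
            f"planted clusters {sorted(overlap)} are shared across substates",
            stacklevel=3,
        )
    for i, pc in enumerate(config.planted_clusters):
        in_state = np.isin(labels, list(owner.get(i, ())))
        prob = np.where(in_state, pc.frequency, config.background_occurrence)
        on[i] = rng.random(config.K) < prob
    return on, labels


def generate_population(
    config: SimulationConfig,
) -> tuple[StructurePopulation, DomainTable, GroundTruth]:
    """Generate a seeded population with planted clusters and full ground truth."""
    domains = generate_domain_table(config)
    N = domains.n
    rng = np.random.default_rng([config.seed, 202])
    on, substate_labels = _planted_on_matrix(config, rng)

    # resolve planted member indices once; fail fast on infeasible packing
    member_idx: list[np.ndarray] = []
    for pc in config.planted_clusters:
        idx = np.array(
            [domains.index_of_label(l1, l2) for l1, l2 in pc.members], dtype=int
        )
        if pc.epsilon < domains.radii[idx].max():
            raise ConfigurationError(
                "co-localization radius epsilon is smaller than a member radius"
            )
        member_idx.append(idx)

    coords = np.empty((config.K, N, 2, 3))
    realized_sigs: list[CopySignature | None] = [None] * len(config.planted_clusters)
    r = config.radius
    npc = config.domains_per_chrom
    for s in range(config.K):
        for c in range(config.n_chrom):
            lo = c * npc
            for copy in (0, 1):
                coords[s, lo : lo + npc, copy] = _chain(rng, npc, r, config.centromere_bias)
        for i, pc in enumerate(config.planted_clusters):
            if not on[i, s]:
                continue
            idx = member_idx[i]
            # per-chromosome orientation flip keeps A/B labels arbitrary
            flips = {l1: int(rng.integers(2)) for l1 in {m[0] for m in pc.members}}
            cross = set(pc.cross_copy)
            copies = np.array(
                [
                    flips[l1] ^ (1 if (l1, l2) in cross else 0)
                    for l1, l2 in pc.members
                ]
            )
            _plant_positions(
                rng, coords[s], idx, copies, domains.radii[idx],
                pc.epsilon, pc.contact_probability,
            )
            if realized_sigs[i] is None:
                nodes = [
                    (l1, l2, "AB"[cp])
                    for (l1, l2), cp in zip(pc.members, copies)
                ]
                realized_sigs[i] = canonical_signature(nodes)

    # clusters never switched on still get their canonical signature
    for i, pc in enumerate(config.planted_clusters):
        if realized_sigs[i] is None:
            nodes = [
                (l1, l2, "B" if (l1, l2) in set(pc.cross_copy) else "A")
                for l1, l2 in pc.members
            ]
            realized_sigs[i] = canonical_signature(nodes)

    population = StructurePopulation(coords, [f"s{k:05d}" for k in range(config.K)])
    gt = GroundTruth(
        member_ids=[
            tuple(domains.domain_ids[j] for j in sorted(idx)) for idx in member_idx
        ],
        member_indices=[np.sort(idx) for idx in member_idx],
        signatures=realized_sigs,
        occurrence=[on[i].copy() for i in range(len(config.planted_clusters))],
        substate_labels=substate_labels,
    )
    return population, domains, gt


def generate_substate_scenario(
    config: SimulationConfig,
) -> tuple[StructurePopulation, DomainTable, GroundTruth]:
    """Population whose planted clusters are substate-specific (deterministic split)."""
    if config.substates is None:
        raise ConfigurationError("config.substates must be specified")
    return generate_population(config)


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def generate_signals(
    domains: DomainTable, ground_truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Log-normal background signals with multiplicative planted enrichment.

    Each (factor, cluster, delta) entry in config.enrichments multiplies the
    signal of that planted cluster's members by delta on that factor;
    delta = 1 leaves the null intact.
    """
    rng = np.random.default_rng([config.seed, 303])
    vals = rng.lognormal(config.signal_mu, config.signal_sigma, (domains.n, len(config.factors)))
    df = pd.DataFrame(vals, index=domains.domain_ids, columns=list(config.factors))
    for factor, ci, delta in config.enrichments:
        if delta <= 0:
            raise ConfigurationError("enrichment shift delta must be > 0")
        if factor not in df.columns:
            raise ConfigurationError(f"unknown factor {factor!r}")
        idx = ground_truth.member_indices[ci]
        df.iloc[idx, df.columns.get_loc(factor)] *= delta
        ground_truth.enriched.setdefault(factor, []).append(ci)
    return df


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

def audit_planted_contacts(
    population: StructurePopulation,
    domains: DomainTable,
    ground_truth: GroundTruth,
    contact_scale: float = 1.0,
) -> list[float]:
    """Realized within-cluster pair-contact rate over each cluster's on-structures."""
    rates = []
    radii = domains.radii
    for idx, on in zip(ground_truth.member_indices, ground_truth.occurrence):
        hits = total = 0
        for k in np.flatnonzero(on):
            pos = population.coords[k][idx]  # (m, 2, 3)
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    thresh = contact_scale * (radii[idx[a]] + radii[idx[b]])
                    d = np.linalg.norm(
                        pos[a][:, None, :] - pos[b][None, :, :], axis=-1
                    ).min()
                    hits += d <= thresh
                    total += 1
        rates.append(hits / total if total else float("nan"))
    return rates
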