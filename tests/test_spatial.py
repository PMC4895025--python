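"""Centromeric influence, rank tests, partial correlation, TF grouping and trends."""

import numpy as np
import pandas as pd
import pytest

from cigmine.errors import DegenerateControlError, ValidationError
from cigmine.graphs import build_cigs
from cigmine.isomorphism import FrequentCluster, canonical_signature
from cigmine.population import StructurePopulation
from cigmine.spatial import (
    centromere_distance_groups,
    centromeric_influence,
    compute_cluster_geometry,
    domain_occurrence_profile,
    group_factors_by_profile,
    partial_correlation,
    rank_sum_compare,
    signal_contact_correlation,
    subcentromere_contact_frequencies,
)

from conftest import make_domain_table


def cluster_with(domains, member_idx, occurrence, cid="c0", sig_nodes=None):
    members = tuple(domains.domain_ids[i] for i in sorted(member_idx))
    if sig_nodes is None:
        sig_nodes = [(*domains.label_of(i), "A") for i in sorted(member_idx)]
    n_chrom = len({domains.L1[i] for i in member_idx})
    return FrequentCluster(
        cid, members, canonical_signature(sig_nodes),
        np.asarray(occurrence, dtype=bool), 1.0, n_chrom,
    )


class TestCentromericInfluence:
    @pytest.mark.parametrize(
        "cats, expected_label, expected_prop",
        [
            (["centromeric", "active", "active", "active"], "weak", 0.25),
            (["centromeric", "centromeric", "active", "active"], "strong", 0.5),
            (["active", "active", "active", "active", "inactive"], "weak", 0.0),
        ],
    )
    def test_proportion_and_boundary(self, cats, expected_label, expected_prop):
        domains = make_domain_table(1, len(cats), categories=cats)
        cluster = cluster_with(domains, range(len(cats)), [1])
        label, prop = centromeric_influence(cluster, domains)
        assert label == expected_label and prop == pytest.approx(expected_prop)

    def test_exact_boundary_is_weak(self):
        # 3 of 10 = 0.30: the boundary itself counts as weak influence
        cats = ["centromeric"] * 3 + ["active"] * 7
        domains = make_domain_table(1, 10, categories=cats)
        cluster = cluster_with(domains, range(10), [1])
        assert centromeric_influence(cluster, domains)[0] == "weak"


class TestRankSumCompare:
    def test_identical_groups(self):
        assert rank_sum_compare([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_extreme_separation_exact(self):
        # 3 vs 3, complete separation: two-sided exact p = 2/20 = 0.1
        assert rank_sum_compare([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 40)
        pvals = [
            rank_sum_compare(base, rng.normal(shift, 1, 40))
            for shift in (0.5, 1.5, 3.0)
        ]
        assert pvals[0] > pvals[1] > pvals[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_compare([], [1.0])


class TestPartialCorrelation:
    def test_perfect_correlation_with_independent_control(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        r, p = partial_correlation(x, x.copy(), z)
        assert r == pytest.approx(1.0, abs=1e-9) and p == pytest.approx(0.0, abs=1e-12)

    def test_collinear_control_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateControlError):
            partial_correlation(x, np.random.default_rng(0).normal(size=10), x)

    def test_monte_carlo_recovery(self):
        # trivariate Gaussian built so the true partial correlation is 0.30
        rng = np.random.default_rng(2)
        n = 10_000
        r_xz = r_yz = 0.5
        r_xy = 0.3 * (1 - r_xz * r_yz) + r_xz * r_yz
        cov = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1]])
        x, y, z = rng.multivariate_normal(np.zeros(3), cov, size=n).T
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(0.3, abs=0.02)

    def test_reduces_to_pearson_for_independent_control(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        y = 0.5 * x + rng.normal(size=5000)
        z = rng.normal(size=5000)
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)


def geometry_population(domains, occ_positions, far_positions, occurrence):
    """Population where centromere references co-locate in occurrence structures."""
    K = len(occurrence)
    coords = np.empty((K, domains.n, 2, 3))
    for k in range(K):
        src = occ_positions if occurrence[k] else far_positions
        coords[k] = src
    return StructurePopulation(coords)


class TestCentromereDistances:
    def build(self, seed=0, K=30):
        cats = ["centromeric", "active", "active"] * 2  # chr1: c,a,a; chr2: c,a,a
        domains = make_domain_table(2, 3, radius=0.04, categories=cats)
        rng = np.random.default_rng(seed)
        near = rng.random((domains.n, 2, 3)) * 0.08  # everything near the origin
        far = np.zeros((domains.n, 2, 3))
        far[:3] = [[-0.7, 0, 0]] * 2  # chr1 on one side
        far[3:] = [[0.7, 0, 0]] * 2  # chr2 on the other
        far += rng.random((domains.n, 2, 3)) * 0.05
        occurrence = np.zeros(K, dtype=bool)
        occurrence[: K // 3] = True
        pop = geometry_population(domains, near, far, occurrence)
        return domains, pop, occurrence

    def test_planted_geometry_orders_groups(self):
        domains, pop, occurrence = self.build()
        weak = cluster_with(domains, [1, 2, 4], occurrence, "weak1")  # 1/3 centromeric
        strong = cluster_with(domains, [0, 3, 4], occurrence, "strong1")  # 2/3
        groups = centromere_distance_groups(
            [weak, strong], pop, domains, np.random.default_rng(1)
        )
        assert groups["strong"].mean() < groups["random"].mean()
        assert groups["weak"].mean() < groups["random"].mean()

    def test_single_chromosome_cluster_excluded(self):
        domains, pop, occurrence = self.build()
        intra = cluster_with(domains, [0, 1], occurrence, "intra")
        groups = centromere_distance_groups([intra], pop, domains,
                                            np.random.default_rng(0))
        assert all(len(v) == 0 for v in groups.values())

    def test_full_occurrence_has_no_control(self):
        domains, pop, _ = self.build()
        always = cluster_with(domains, [1, 2, 4], np.ones(30), "always")
        with pytest.raises(ValidationError, match="control"):
            centromere_distance_groups([always], pop, domains,
                                       np.random.default_rng(0))


class TestGroupFactors:
    def enrichment_blocks(self, blocks, clusters_per_block=4, noise=None):
        rows = []
        for b, factors in enumerate(blocks):
            cids = [f"b{b}_c{i}" for i in range(clusters_per_block)]
            for f in factors:
                for cid in cids:
                    rows.append((cid, f, 1.0, 0.001, 0.01, True))
        df = pd.DataFrame(
            rows, columns=["cluster_id", "factor", "stat", "p", "q", "enriched"]
        )
        return df

    def test_two_block_recovery(self):
        enr = self.enrichment_blocks([["f1", "f2"], ["f3", "f4"]])
        groups = group_factors_by_profile(enr, n_groups=2)
        assert groups["f1"] == groups["f2"]
        assert groups["f3"] == groups["f4"]
        assert groups["f1"] != groups["f3"]

    def test_never_enriched_factor_in_residual_group(self):
        enr = self.enrichment_blocks([["f1", "f2"], ["f3", "f4"]])
        extra = pd.DataFrame(
            [("b0_c0", "dead", 1.0, 0.9, 0.9, False)], columns=enr.columns
        )
        groups = group_factors_by_profile(pd.concat([enr, extra]), n_groups=2)
        assert groups["dead"] == 0


class TestSignalContactCorrelation:
    def test_exact_linear_relation(self):
        signal = pd.Series({"chr1": 1.0, "chr2": 2.0, "chr3": 3.0, "chr4": 4.0})
        pairs = pd.MultiIndex.from_tuples(
            [("chr1", "chr2"), ("chr1", "chr3"), ("chr2", "chr3"),
             ("chr1", "chr4"), ("chr2", "chr4"), ("chr3", "chr4")]
        )
        pred = np.array([1.5, 2.0, 2.5, 2.5, 3.0, 3.5])
        r, p = signal_contact_correlation(signal, pd.Series(2 * pred, index=pairs))
        assert r == pytest.approx(1.0)
        r, _ = signal_contact_correlation(signal, pd.Series(-2 * pred, index=pairs))
        assert r == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        signal = pd.Series({"chr1": 1.0, "chr2": 2.0})
        pairs = pd.MultiIndex.from_tuples([("chr1", "chr2")])
        with pytest.raises(ValidationError):
            signal_contact_correlation(signal, pd.Series([0.5], index=pairs))

    def test_contact_frequencies_from_geometry(self):
        cats = ["active", "centromeric", "active"] * 2
        domains = make_domain_table(2, 3, radius=0.05, categories=cats)
        coords = np.full((4, domains.n, 2, 3), 0.5)
        coords[:, 1] = 0.0  # chr1 centromere reference at origin...
        coords[:2, 4] = 0.0  # ...meets chr2's in the first two structures
        coords[:, 0, :] = [[-0.9, 0, 0]] * 2
        coords[:, 3, :] = [[0.9, 0, 0]] * 2
        pop = StructurePopulation(coords)
        freqs = subcentromere_contact_frequencies(build_cigs(pop, domains), domains)
        assert freqs[("chr1", "chr2")] == pytest.approx(0.5)


class TestDomainOccurrenceProfile:
    def test_counts_and_planted_trend(self):
        cats = (["active"] * 3 + ["centromeric"] + ["active"] * 3) * 2
        domains = make_domain_table(2, 7, categories=cats)
        # occurrence decaying with distance from the centromeric domain (L2=4)
        clusters = []
        cid = 0
        for l1 in (1, 2):
            for l2, n_clusters in [(4, 6), (3, 4), (5, 4), (2, 2), (6, 2), (1, 0), (7, 0)]:
                i = domains.index_of_label(l1, l2)
                j = domains.index_of_label(3 - l1, 4)
                for _ in range(n_clusters):
                    clusters.append(
                        cluster_with(domains, [i, j], [1], f"c{cid}")
                    )
                    cid += 1
        counts, trend = domain_occurrence_profile(clusters, domains, n_bins=3)
        assert counts["chr1_d4"] == 6 + 18  # own clusters + partner slots
        means = trend["mean_count"].to_numpy()
        assert means[0] > means[1] > means[2]

    def test_all_zero_counts(self):
        domains = make_domain_table(2, 3)
        counts, trend = domain_occurrence_profile([], domains, n_bins=2)
        assert counts.sum() == 0 and (trend["mean_count"] == 0).all()


class TestClusterGeometry:
    def test_radial_position_uses_signature_copies(self):
        domains = make_domain_table(2, 2, radius=0.2)
        # copy A of both members near centre and touching; copy B far out
        coords = np.zeros((1, domains.n, 2, 3))
        coords[0, :, 1] = [0.0, 0.8, 0.0]
        pop = StructurePopulation(coords)
        cigs = build_cigs(pop, domains)
        cluster = cluster_with(
            domains, [0, 2], [1], "c0",
            sig_nodes=[(1, 1, "A"), (2, 1, "A")],
        )
        geo = compute_cluster_geometry([cluster], pop, cigs, domains, min_density=1.0)
        assert geo.iloc[0]["radial_position"] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self):
        domains = make_domain_table(2, 2, radius=0.1)
        rng = np.random.default_rng(9)
        coords = rng.random((3, domains.n, 2, 3)) * 0.3
        pop = StructurePopulation(coords)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = StructurePopulation(coords @ q.T)
        cluster = cluster_with(domains, [0, 2], [1, 1, 1], "c0")
        g1 = compute_cluster_geometry([cluster], pop, build_cigs(pop, domains), domains, 0.0)
        g2 = compute_cluster_geometry([cluster], rotated, build_cigs(rotated, domains), domains, 0.0)
        assert g1.iloc[0]["radial_position"] == pytest.approx(
            g2.iloc[0]["radial_position"], abs=1e-9
        )
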