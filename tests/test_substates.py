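"""Occurrence matrix, prevalence filter, NMF biclustering and substate summaries."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.base import clone
from sklearn.decomposition import NMF as SklearnNMF

from cigmine.errors import ConfigurationError, ValidationError
from cigmine.graphs import CIG, contract
from cigmine.isomorphism import FrequentCluster, canonical_signature
from cigmine.population import StructurePopulation
from cigmine.substates import (
    SubpopulationAssignment,
    SubstateNMF,
    build_occurrence_matrix,
    filter_prevalent,
    nmf_bicluster,
    substate_contact_map,
    substate_radial_comparison,
)

from conftest import make_domain_table


def matched_accuracy(labels, truth, k):
    """Best label-permutation agreement via the Hungarian assignment."""
    conf = np.zeros((k, k))
    for a, b in zip(labels, truth):
        conf[a - 1, b - 1] += 1
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(labels)


def cluster(cid, occurrence, n_chrom=2):
    return FrequentCluster(
        cid, ("a", "b", "c", "d"), canonical_signature([(1, 1, "A")]),
        np.asarray(occurrence, dtype=bool), 1.0, n_chrom,
    )


def block_matrix(rng, k=3, per_block=4, block_size=40, p_in=0.8, p_out=0.02):
    """Planted block-diagonal occurrence matrix + structure labels."""
    K = k * block_size
    M = k * per_block
    C = (rng.random((M, K)) < p_out).astype(float)
    truth = np.repeat(np.arange(1, k + 1), block_size)
    for b in range(k):
        rows = slice(b * per_block, (b + 1) * per_block)
        cols = slice(b * block_size, (b + 1) * block_size)
        C[rows, cols] = (rng.random((per_block, block_size)) < p_in).astype(float)
    return C, truth


class TestOccurrenceMatrix:
    def test_assembly_example(self):
        c1 = cluster("c1", [1, 0, 1, 0])
        c2 = cluster("c2", [0, 1, 0, 0])
        C, ids = build_occurrence_matrix([c1, c2], 4)
        np.testing.assert_array_equal(C, [[1, 0, 1, 0], [0, 1, 0, 0]])
        assert ids == ["c1", "c2"]

    def test_empty_cluster_set(self):
        C, ids = build_occurrence_matrix([], 5)
        assert C.shape == (0, 5) and ids == []

    def test_row_sums_equal_frequency_times_k(self):
        rng = np.random.default_rng(0)
        clusters = [
            cluster(f"c{i}", rng.random(20) < rng.random()) for i in range(6)
        ]
        C, ids = build_occurrence_matrix(clusters, 20)
        by_id = {c.cluster_id: c for c in clusters}
        for row, cid in zip(C, ids):
            assert row.sum() == pytest.approx(by_id[cid].frequency * 20)

    def test_reorder_commutes_with_filter(self):
        rng = np.random.default_rng(1)
        clusters = [cluster(f"c{i}", rng.random(30) < 0.05) for i in range(5)]
        clusters.append(cluster("c_prev", np.ones(30)))
        C1, ids1 = build_occurrence_matrix(clusters, 30)
        C2, ids2 = build_occurrence_matrix(clusters[::-1], 30)
        np.testing.assert_array_equal(C1, C2)
        f1 = filter_prevalent(C1, ids1, 0.5)
        f2 = filter_prevalent(C2, ids2, 0.5)
        np.testing.assert_array_equal(f1[0], f2[0])
        assert f1[1] == f2[1] and f1[2] == f2[2]


class TestFilterPrevalent:
    def test_boundary_frequency_dropped(self):
        C = np.zeros((2, 10), dtype=np.uint8)
        C[0, 0] = 1  # frequency 0.10 exactly: dropped (>= boundary)
        kept, ids, dropped = filter_prevalent(C, ["a", "b"], 0.10)
        assert dropped == ["a"] and ids == ["b"]

    def test_just_below_boundary_kept(self):
        K = 1000
        C = np.zeros((2, K), dtype=np.uint8)
        C[0, :99] = 1  # 0.099 -> kept
        C[1, :100] = 1  # 0.100 -> dropped
        kept, ids, dropped = filter_prevalent(C, ["low", "hi"], 0.10)
        assert ids == ["low"] and dropped == ["hi"]

    def test_uniform_low_frequency_unchanged(self):
        C = np.eye(4, 50, dtype=np.uint8)
        kept, ids, dropped = filter_prevalent(C, list("abcd"), 0.10)
        assert dropped == [] and kept.shape == (4, 50)

    def test_all_dropped_is_error(self):
        C = np.ones((2, 4), dtype=np.uint8)
        with pytest.raises(ValidationError):
            filter_prevalent(C, ["a", "b"], 0.10)


class TestNMF:
    def test_exact_rank_one_reconstruction(self):
        u = np.array([1.0, 2.0, 0.5, 3.0])
        v = np.array([0.2, 1.0, 0.0, 0.4, 2.0])
        C = np.outer(u, v)
        a = nmf_bicluster(C, k=2, seed=0)
        assert np.linalg.norm(C - a.W @ a.H) ** 2 < 1e-8

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(2)
        C, truth = block_matrix(rng)
        a = nmf_bicluster(C, k=3, seed=1)
        assert matched_accuracy(a.structure_labels, truth, 3) >= 0.9

    def test_same_seed_identical_factors(self):
        rng = np.random.default_rng(3)
        C, _ = block_matrix(rng, k=2)
        a = nmf_bicluster(C, k=2, seed=9)
        b = nmf_bicluster(C, k=2, seed=9)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    @pytest.mark.parametrize("seed", range(4))
    def test_objective_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        C = (rng.random((12, 40)) < 0.2).astype(float)
        a = nmf_bicluster(C, k=3, seed=seed, restarts=2)
        hist = a.objective_history
        assert all(b <= a_ + 1e-9 * max(a_, 1) for a_, b in zip(hist, hist[1:]))

    def test_assignment_is_partition(self):
        rng = np.random.default_rng(5)
        C, _ = block_matrix(rng)
        a = nmf_bicluster(C, k=3, seed=0)
        assert a.structure_labels.shape == (C.shape[1],)
        assert set(np.unique(a.structure_labels)) <= {1, 2, 3}

    def test_reconstruction_error_comparable_to_sklearn(self):
        """Independent cross-check: our MU solver lands in the same error
        regime as the library implementation on the same matrix and rank."""
        rng = np.random.default_rng(6)
        C, _ = block_matrix(rng, k=2)
        ours = nmf_bicluster(C, k=2, seed=0).objective_history[-1]
        sk = SklearnNMF(
            n_components=2, solver="mu", init="random", random_state=0,
            max_iter=500, tol=1e-6,
        )
        W = sk.fit_transform(C)
        theirs = np.linalg.norm(C - W @ sk.components_) ** 2
        assert ours <= theirs * 1.1

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            nmf_bicluster(np.ones((2, 2)), k=1, seed=0)
        with pytest.raises(ValidationError):
            nmf_bicluster(-np.ones((2, 2)), k=2, seed=0)

    def test_estimator_facade(self):
        rng = np.random.default_rng(7)
        C, truth = block_matrix(rng, k=2)
        est = SubstateNMF(k=2, seed=0)
        assert clone(est).get_params() == est.get_params()
        labels = est.fit_predict(C)
        assert matched_accuracy(labels, truth, 2) >= 0.9
        assert est.W_.shape == (C.shape[0], 2)


def assignment_for(labels, k):
    labels = np.asarray(labels)
    return SubpopulationAssignment(
        structure_labels=labels,
        cluster_labels=np.ones(1, dtype=int),
        W=np.ones((1, k)),
        H=np.ones((k, len(labels))),
        objective_history=[0.0],
        converged=True,
    )


class TestContactMap:
    def build_ccigs(self, domains, planted_pair, K):
        rng = np.random.default_rng(0)
        n = domains.n
        ccigs = []
        for k in range(K):
            upper = np.triu(rng.random((2 * n, 2 * n)) < 0.05, 1)
            adj = upper | upper.T
            i, j = planted_pair
            adj[2 * i, 2 * j] = adj[2 * j, 2 * i] = True
            np.fill_diagonal(adj, False)
            ccigs.append(contract(CIG(f"s{k}", adj)))
        return ccigs

    def test_planted_pair_always_in_top_set(self):
        domains = make_domain_table(2, 3)
        i, j = 0, domains.index_of_label(2, 1)
        ccigs = self.build_ccigs(domains, (i, j), K=20)
        maps = substate_contact_map(
            ccigs, assignment_for([1] * 10 + [2] * 10, 2), domains
        )
        for s, df in maps.items():
            pair = df[(df["domain_a"] == domains.domain_ids[i])
                      & (df["domain_b"] == domains.domain_ids[j])]
            assert len(pair) == 1 and pair.iloc[0]["frequency"] == 1.0

    def test_identical_substates_identical_maps(self):
        domains = make_domain_table(2, 3)
        ccigs = self.build_ccigs(domains, (0, 4), K=10)
        maps = substate_contact_map(
            ccigs + ccigs, assignment_for([1] * 10 + [2] * 10, 2), domains
        )
        assert maps[1].equals(maps[2])

    def test_empty_substate_warns_and_excluded(self):
        domains = make_domain_table(2, 3)
        ccigs = self.build_ccigs(domains, (0, 4), K=4)
        with pytest.warns(UserWarning, match="no structures"):
            maps = substate_contact_map(ccigs, assignment_for([1] * 4, 2), domains)
        assert set(maps) == {1}


class TestRadialComparison:
    def test_planted_shift_detected(self):
        domains = make_domain_table(1, 2, radius=0.03)
        rng = np.random.default_rng(1)
        K = 200
        coords = np.zeros((K, domains.n, 2, 3))
        radial = np.where(np.arange(K) < 100, 0.2, 0.7)  # substate 1 interior
        for k in range(K):
            direction = rng.normal(size=(domains.n, 2, 3))
            direction /= np.linalg.norm(direction, axis=-1, keepdims=True)
            coords[k] = direction * radial[k]
        pop = StructurePopulation(coords)
        labels = [1] * 100 + [2] * 100
        dists, tests = substate_radial_comparison(
            pop, assignment_for(labels, 2), ["chr1_d1"], domains
        )
        assert np.median(dists[1]) < np.median(dists[2])
        assert tests.iloc[0]["p"] < 0.05

    def test_degenerate_at_origin(self):
        domains = make_domain_table(1, 1)
        pop = StructurePopulation(np.zeros((6, 1, 2, 3)))
        dists, _ = substate_radial_comparison(
            pop, assignment_for([1, 1, 1, 2, 2, 2], 2), ["chr1_d1"], domains
        )
        assert all((v == 0).all() for v in dists.values())
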