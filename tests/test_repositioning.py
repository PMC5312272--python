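import numpy as np
import pytest
from scipy.stats import hypergeom

from sigrev.distance import DistanceMatrix
from sigrev.ranking import RankedList, reverse_signature
from sigrev.repositioning import (
    DrugNetwork,
    EnrichmentResult,
    candidate_target_genes,
    community_enrichment,
    hypergeom_upper,
    intersect_neighbor_sets,
    neighbors,
)

from .conftest import random_ranked_list
from .oracles import hypergeom_upper_enumerate


def toy_network(drug_dists, tau=0.86, communities=None):
    """Star network: one query node 'Q' at the given distances from drugs."""
    ids = ["Q", *drug_dists]
    k = len(ids)
    vals = np.ones((k, k))
    np.fill_diagonal(vals, 0.0)
    for j, d in enumerate(drug_dists, start=1):
        vals[0, j] = vals[j, 0] = drug_dists[d]
    feats = tuple(f"g{i}" for i in range(4))
    nodes = {i: RankedList(node_id=i, features=feats) for i in ids}
    labels = communities or {d: "c1" for d in drug_dists}
    dm = DistanceMatrix(node_ids=tuple(ids), values=vals, s=1)
    return DrugNetwork(nodes=nodes, dmatrix=dm, communities=labels, tau=tau)


class TestNeighbors:
    def test_threshold_filter(self):
        net = toy_network({"A": 0.5, "B": 0.8, "C": 0.9})
        assert neighbors("Q", net) == {"A", "B"}

    def test_inclusive_threshold(self):
        net = toy_network({"A": 0.86, "B": 0.8600001})
        assert neighbors("Q", net) == {"A"}

    def test_tau_two_selects_everything(self):
        net = toy_network({"A": 0.5, "B": 1.7, "C": 2.0}, tau=2.0)
        assert neighbors("Q", net) == {"A", "B", "C"}

    def test_query_nodes_never_neighbors(self):
        net = toy_network({"A": 0.5})
        net.nodes["Q2"] = net.nodes["Q"]
        ids = (*net.dmatrix.node_ids, "Q2")
        k = len(ids)
        vals = np.zeros((k, k))
        vals[: k - 1, : k - 1] = net.dmatrix.values
        vals[1, -1] = vals[-1, 1] = 1.0  # A far from Q2; Q at distance 0
        net.dmatrix = DistanceMatrix(node_ids=ids, values=vals, s=1)
        assert neighbors("Q2", net) == set()

    def test_drug_is_its_own_neighbor(self):
        net = toy_network({"A": 0.5, "B": 0.9})
        assert "A" in neighbors("A", net)

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            neighbors("missing", toy_network({"A": 0.5}))

    def test_monotone_in_tau(self):
        dists = {f"d{i}": x for i, x in enumerate(np.linspace(0.1, 1.9, 12))}
        prev = set()
        for tau in (0.5, 0.86, 1.2, 2.0):
            net = toy_network(dists, tau=tau)
            cur = neighbors("Q", net)
            assert prev <= cur
            prev = cur


class TestIntersect:
    def test_three_way(self):
        assert intersect_neighbor_sets(
            [{"A", "B", "C"}, {"B", "C", "D"}, {"C", "E"}]
        ) == ("C",)

    def test_disjoint_is_empty(self):
        assert intersect_neighbor_sets([{"A"}, {"B"}]) == ()

    def test_identical_sets(self):
        assert intersect_neighbor_sets([{"B", "A"}] * 3) == ("A", "B")

    def test_rejects_single_set(self):
        with pytest.raises(ValueError):
            intersect_neighbor_sets([{"A"}])


class TestHypergeomUpper:
    def test_k_zero_is_one(self):
        assert hypergeom_upper(0, 5, 3, 10) == 1.0

    def test_closed_form_full_overlap(self):
        assert hypergeom_upper(5, 5, 5, 10) == pytest.approx(1 / 252, abs=0)

    def test_closed_form_complement(self):
        assert hypergeom_upper(1, 2, 2, 4) == pytest.approx(5 / 6, abs=0)

    def test_exhaustive_enumeration_all_small_universes(self):
        for n_u in range(1, 9):
            for big_k in range(n_u + 1):
                for n in range(n_u + 1):
                    for k in range(min(big_k, n) + 1):
                        expected = hypergeom_upper_enumerate(k, big_k, n, n_u)
                        assert hypergeom_upper(k, big_k, n, n_u) == float(expected)

    def test_agrees_with_scipy_sf(self, rng):
        for _ in range(200):
            n_u = int(rng.integers(2, 200))
            big_k = int(rng.integers(0, n_u + 1))
            n = int(rng.integers(0, n_u + 1))
            k = int(rng.integers(0, min(big_k, n) + 1))
            assert hypergeom_upper(k, big_k, n, n_u) == pytest.approx(
                float(hypergeom.sf(k - 1, n_u, big_k, n)), rel=1e-9
            )

    def test_rejects_inconsistent(self):
        with pytest.raises(ValueError):
            hypergeom_upper(4, 3, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(1, 3, 5, 4)


class TestCommunityEnrichment:
    def two_community_net(self):
        dists = {f"a{i}": 0.5 for i in range(5)} | {f"b{i}": 1.5 for i in range(5)}
        labels = {f"a{i}": "alpha" for i in range(5)} | {
            f"b{i}": "beta" for i in range(5)
        }
        return toy_network(dists, communities=labels)

    def test_full_community_neighborhood(self):
        net = self.two_community_net()
        results = community_enrichment(neighbors("Q", net), net)
        by_label = {r.community: r for r in results}
        assert by_label["alpha"].p == pytest.approx(1 / 252, abs=0)
        assert by_label["alpha"].significant
        assert by_label["beta"].p == 1.0
        assert not by_label["beta"].significant
        assert results[0].community == "alpha"

    def test_empty_neighborhood(self):
        net = self.two_community_net()
        results = community_enrichment(set(), net)
        assert all(r.p == 1.0 and r.k == 0 and not r.significant for r in results)

    def test_every_community_reported_once_and_sizes_sum(self):
        net = self.two_community_net()
        results = community_enrichment({"a0", "b1"}, net)
        assert sorted(r.community for r in results) == ["alpha", "beta"]
        assert sum(r.K for r in results) == len(net.drug_ids)

    def test_matches_exhaustive_enumeration(self, rng):
        """p-values equal brute-force enumeration over all draws on a
        12-drug universe with three communities."""
        labels = {f"d{i}": ("x", "y", "z")[i % 3] for i in range(12)}
        dists = {d: 1.0 for d in labels}
        members = {c: {d for d, l in labels.items() if l == c} for c in "xyz"}
        for _ in range(20):
            neigh = set(rng.choice(sorted(labels), size=rng.integers(0, 13), replace=False))
            net = toy_network(dists, communities=labels)
            for r in community_enrichment(neigh, net):
                expected = hypergeom_upper_enumerate(
                    len(neigh & members[r.community]), r.K, len(neigh), 12
                )
                assert r.p == float(expected)

    def test_bh_adjustment_monotone(self):
        net = self.two_community_net()
        results = community_enrichment(neighbors("Q", net), net)
        for r in results:
            assert r.p <= r.p_adjusted <= 1.0

    def test_result_type_validates(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EnrichmentResult(community="c", k=6, K=5, n=5, N_u=10, p=0.5)


class TestCandidateGenes:
    def test_self_agreement(self, rng):
        sig = random_ranked_list(rng, 30, node_id="sig")
        up, down = candidate_target_genes(sig, sig.with_node_id("drug"), k_extreme=5)
        assert up == sig.features[:5]
        assert down == sig.features[-5:]

    def test_reversed_drug_gives_empty_lists(self, rng):
        sig = random_ranked_list(rng, 30, node_id="sig")
        up, down = candidate_target_genes(sig, reverse_signature(sig), k_extreme=5)
        assert up == () and down == ()

    def test_matches_bruteforce_intersections(self, rng):
        n, k = 100, 10
        sig = random_ranked_list(rng, n, node_id="sig")
        drug = random_ranked_list(rng, n, node_id="drug")
        up, down = candidate_target_genes(sig, drug, k_extreme=k)
        assert set(up) == set(sig.features[:k]) & set(drug.features[:k])
        assert set(down) == set(sig.features[-k:]) & set(drug.features[-k:])
        assert list(up) == sorted(up, key=sig.position)
        assert list(down) == sorted(down, key=sig.position)

    def test_rejects_universe_mismatch(self, rng):
        sig = random_ranked_list(rng, 20, node_id="sig")
        other = RankedList(node_id="o", features=tuple(f"h{i}" for i in range(20)))
        with pytest.raises(ValueError, match="universes"):
            candidate_target_genes(sig, other, k_extreme=5)
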