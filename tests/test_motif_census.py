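import itertools

import numpy as np
import pytest

from conftest import make_network, random_signed_network
from emap_motifs.motif_census import (
    enumerate_triplets,
    gene_sign_polarity,
    participation_summary,
)
from emap_motifs.network_build import SignedEdge, SignedNetwork
from oracles import brute_force_triplets


def _census_as_set(census):
    return {
        (t.genes, tuple(e.pair for e in t.edges), t.motif_class)
        for t in census.triplets
    }


class TestEnumeration:
    def test_all_negative_k4_gives_four_nnn(self):
        spec = []
        nodes = ["a", "b", "c", "d"]
        scores = iter([-1.1, -2.2, -3.3, -4.4, -5.5, -6.6])
        for x, y in itertools.combinations(nodes, 2):
            spec.append((x, y, "N", next(scores)))
        census = enumerate_triplets(make_network(spec))
        assert census.counts == {"NNN": 4, "NNP": 0, "NPP": 0, "PPP": 0}

    def test_mixed_triangle_classification_and_order(self):
        net = make_network(
            [("a", "b", "N", -3.2), ("b", "c", "N", -1.1), ("a", "c", "P", 2.5)]
        )
        census = enumerate_triplets(net)
        (t,) = census.triplets
        assert t.motif_class == "NNP"
        assert [e.s_score for e in t.edges] == [-3.2, -1.1, 2.5]

    def test_matches_triple_loop_oracle_on_random_graphs(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 13))
            net = random_signed_network(rng, n, 0.4)
            assert _census_as_set(enumerate_triplets(net)) == brute_force_triplets(net)

    def test_counts_invariant_under_relabeling(self, rng):
        net = random_signed_network(rng, 10, 0.5)
        mapping = {f"n{i:02d}": f"x{9 - i:02d}" for i in range(10)}
        relabeled = make_network(
            [
                (mapping[a], mapping[b], e.sign, e.s_score)
                for (a, b), e in net.edges.items()
            ],
            extra_nodes=[mapping[g] for g in net.nodes],
        )
        assert (
            enumerate_triplets(net).counts == enumerate_triplets(relabeled).counts
        )

    def test_sign_flip_swaps_classes_and_reverses_positions(self, rng):
        swap = {"NNN": "PPP", "PPP": "NNN", "NNP": "NPP", "NPP": "NNP"}
        for _ in range(10):
            net = random_signed_network(rng, 12, 0.4)
            flipped = make_network(
                [
                    (a, b, "P" if e.sign == "N" else "N", -e.s_score)
                    for (a, b), e in net.edges.items()
                ],
                extra_nodes=net.nodes,
            )
            orig = enumerate_triplets(net)
            flip = enumerate_triplets(flipped)
            assert flip.counts == {swap[c]: n for c, n in orig.counts.items()}
            flipped_positions = {
                t.genes: tuple(e.pair for e in t.edges) for t in flip.triplets
            }
            for t in orig.triplets:
                assert flipped_positions[t.genes] == tuple(
                    e.pair for e in reversed(t.edges)
                )

    def test_too_few_nodes_rejected(self):
        net = make_network([("a", "b", "N", -1)])
        with pytest.raises(ValueError):
            enumerate_triplets(net)


class TestParticipation:
    def test_single_nnp_triplet(self):
        net = make_network(
            [("a", "b", "N", -3.0), ("b", "c", "N", -2.0), ("a", "c", "P", 1.0)]
        )
        s = participation_summary(enumerate_triplets(net))
        assert s["defined"]
        assert s["fraction_negative"] == pytest.approx(2 / 3)
        assert s["mean_triplets_per_N_edge"] == 1.0
        assert s["mean_triplets_per_P_edge"] == 1.0

    def test_two_triangles_sharing_an_edge(self):
        # bowtie on a shared N edge: 5 unique edges, shared edge in 2 triplets
        net = make_network(
            [
                ("a", "b", "N", -5.0),
                ("a", "c", "N", -4.0),
                ("b", "c", "N", -3.0),
                ("a", "d", "N", -2.0),
                ("b", "d", "N", -1.0),
            ]
        )
        census = enumerate_triplets(net)
        assert census.counts["NNN"] == 2
        assert census.edge_participation[("a", "b")] == 2
        s = participation_summary(census)
        assert s["n_participating_edges"] == 5
        assert s["mean_triplets_per_N_edge"] == pytest.approx(6 / 5)

    def test_edge_slots_add_up(self, rng):
        for _ in range(10):
            census = enumerate_triplets(random_signed_network(rng, 12, 0.45))
            assert sum(census.edge_participation.values()) == 3 * census.n_triplets
            assert sum(census.counts.values()) == census.n_triplets

    def test_empty_census_flagged(self):
        net = make_network([("a", "b", "N", -1)], extra_nodes=["c"])
        s = participation_summary(enumerate_triplets(net))
        assert not s["defined"]
        assert np.isnan(s["fraction_negative"])


class TestPolarity:
    def test_all_negative_gene(self):
        net = make_network([("g", f"p{i}", "N", -2.0 - i) for i in range(5)])
        table = gene_sign_polarity(net).set_index("gene")
        assert table.loc["g", "fraction_negative"] == 1.0
        assert table.loc["g", "p_raw"] == pytest.approx(0.0625)  # 2 * 0.5**5

    def test_balanced_gene(self):
        spec = [("g", f"n{i}", "N", -2.0) for i in range(3)]
        spec += [("g", f"p{i}", "P", 2.0) for i in range(3)]
        table = gene_sign_polarity(make_network(spec)).set_index("gene")
        assert table.loc["g", "fraction_negative"] == 0.5
        assert table.loc["g", "p_raw"] == pytest.approx(1.0)

    def test_isolated_gene_excluded_and_bonferroni_capped(self):
        net = make_network([("a", "b", "N", -1.0)], extra_nodes=["lonely"])
        table = gene_sign_polarity(net)
        assert "lonely" not in set(table["gene"])
        assert (table["p_bonferroni"] <= 1.0).all()
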