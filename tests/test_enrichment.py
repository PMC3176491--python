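import numpy as np
import pytest

from conftest import make_network, matrix_from_pairs
from emap_motifs.annotations import AnnotationSet
from emap_motifs.enrichment import (
    ALL_PATTERNS,
    code_features,
    code_matches,
    edge_context_foldchange,
    enrichment_scan,
    fisher_cross_tab,
    position_gene_enrichment,
    profile_correlation,
)
from emap_motifs.motif_census import enumerate_triplets
from oracles import fisher_two_sided_p, hypergeom_over_p


def _nnp_net():
    # one NNP triplet: positions i=(a,b), ii=(b,c), iii=(a,c)
    return make_network(
        [("a", "b", "N", -3.0), ("b", "c", "N", -1.5), ("a", "c", "P", 2.0)]
    )


class TestCodes:
    def test_physical_only_on_positive_edge_gives_001(self):
        census = enumerate_triplets(_nnp_net())
        ann = AnnotationSet(pair_relations={"physical_interaction": {("a", "c")}})
        codes = code_features(census, ann)
        assert codes.loc[0, "code"] == "001"

    def test_shared_complex_among_all_three_gives_111(self):
        census = enumerate_triplets(_nnp_net())
        ann = AnnotationSet(
            gene_terms={"complex": {"a": {"X"}, "b": {"X"}, "c": {"X"}}}
        )
        assert code_features(census, ann).loc[0, "code"] == "111"

    def test_two_overlapping_complexes_give_110(self):
        # A,B share complex X; B,C share complex Y; A,C share none
        census = enumerate_triplets(_nnp_net())
        ann = AnnotationSet(
            gene_terms={"complex": {"a": {"X"}, "b": {"X", "Y"}, "c": {"Y"}}}
        )
        assert code_features(census, ann).loc[0, "code"] == "110"

    def test_missing_genes_code_all_zero(self):
        census = enumerate_triplets(_nnp_net())
        ann = AnnotationSet(gene_terms={"pathway": {}})
        assert code_features(census, ann).loc[0, "code"] == "000"

    def test_pattern_counts_partition_the_census(self, rng):
        from conftest import random_signed_network

        net = random_signed_network(rng, 12, 0.5)
        census = enumerate_triplets(net)
        terms = {
            g: {f"T{rng.integers(0, 3)}"} for g in net.nodes if rng.random() < 0.7
        }
        ann = AnnotationSet(gene_terms={"pathway": terms})
        codes = code_features(census, ann)
        by_pattern = codes["code"].value_counts()
        assert by_pattern.sum() == census.n_triplets
        assert set(by_pattern.index) <= set(ALL_PATTERNS)

    def test_collapse_maps_multibit_to_111(self):
        assert code_matches("110", "111", collapse=True)
        assert not code_matches("110", "110", collapse=True)
        assert code_matches("001", "any-bit-at-iii")
        assert not code_matches("110", "any-bit-at-iii")


class TestFisher:
    def test_odds_ratio_by_definition(self):
        net = _nnp_net()
        census = enumerate_triplets(net)
        ann = AnnotationSet(pair_relations={"physical_interaction": {("a", "c")}})
        codes = code_features(census, ann)
        rec = fisher_cross_tab(codes, census, "physical_interaction", "001", "NNP")
        assert (rec.a, rec.b, rec.c, rec.d) == (1, 0, 0, 0)

    def test_two_sided_p_matches_enumeration_oracle(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 26, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided_p(a, b, c, d), abs=1e-10)

    def test_haldane_correction_on_zero_cell(self):
        # a=2,b=3,c=4,d=1 -> OR (2*1)/(3*4) without correction
        from emap_motifs.enrichment import _haldane_odds_ratio

        assert _haldane_odds_ratio(2, 3, 4, 1) == pytest.approx(1 / 6)
        assert _haldane_odds_ratio(0, 3, 4, 1) == pytest.approx(
            (0.5 * 1.5) / (3.5 * 4.5)
        )

    def test_scan_bonferroni_family_and_untestable_classes(self):
        census = enumerate_triplets(_nnp_net())
        ann = AnnotationSet(pair_relations={"physical_interaction": {("a", "c")}})
        codes = code_features(census, ann)
        scan = enrichment_scan(codes, census)
        testable = scan[scan["testable"]]
        # only NNP has triplets here
        assert set(testable["class"]) == {"NNP"}
        assert (testable["p_bonf"] >= testable["p"]).all()
        assert (testable["p_bonf"] <= 1.0).all()


class TestFoldChange:
    def _net_with_baseline(self):
        # one all-N triangle + 10 disjoint baseline N edges
        spec = [
            ("a", "b", "N", -5.0), ("b", "c", "N", -4.0), ("a", "c", "N", -3.0),
        ]
        spec += [(f"u{i}", f"v{i}", "N", -2.0) for i in range(10)]
        return make_network(spec)

    def test_fold_change_arithmetic(self):
        net = self._net_with_baseline()
        census = enumerate_triplets(net)
        # 2 of 3 in-triplet edges share a phenotype, 1 of 10 baseline
        terms = {"a": {"slow"}, "b": {"slow"}, "c": {"slow"}}
        terms["u0"] = {"slow"}
        terms["v0"] = {"slow"}
        # a-b and a-c share, b-c shares too (all three share 'slow');
        # use distinct terms to control exactly which pairs share
        terms = {
            "a": {"p1", "p2"}, "b": {"p1"}, "c": {"p2"},
            "u0": {"p3"}, "v0": {"p3"},
        }
        ann = AnnotationSet(gene_terms={"phenotype": terms})
        df = edge_context_foldchange(net, census, ann, "N")
        row = df[(df["channel"] == "phenotype") & (df["category"] == "in_any_triplet")].iloc[0]
        assert row["fraction"] == pytest.approx(2 / 3)
        assert row["baseline_fraction"] == pytest.approx(1 / 10)
        assert row["fold_change"] == pytest.approx((2 / 3) / (1 / 10))

    def test_identical_composition_gives_fold_one(self):
        net = self._net_with_baseline()
        census = enumerate_triplets(net)
        # everyone shares one term: every fraction is 1
        terms = {g: {"t"} for g in net.nodes}
        ann = AnnotationSet(gene_terms={"phenotype": terms})
        df = edge_context_foldchange(net, census, ann, "N")
        assert df[df["category"] == "in_any_triplet"]["fold_change"].iloc[0] == 1.0

    def test_zero_baseline_flagged_undefined(self):
        net = self._net_with_baseline()
        census = enumerate_triplets(net)
        terms = {"a": {"t"}, "b": {"t"}}  # no baseline edge shares
        ann = AnnotationSet(gene_terms={"phenotype": terms})
        df = edge_context_foldchange(net, census, ann, "N")
        assert np.isnan(df[df["category"] == "in_any_triplet"]["fold_change"].iloc[0])

    def test_invalid_sign_rejected(self):
        net = self._net_with_baseline()
        census = enumerate_triplets(net)
        with pytest.raises(ValueError):
            edge_context_foldchange(net, census, AnnotationSet(), "X")


class TestProfileCorrelation:
    def _matrix_and_census(self, partner_scores_b):
        # matrix holds only the a-b score and the partner profiles, so
        # the common-partner set of (a, b) is exactly the 12 x-genes
        pairs = {("a", "b"): -3.0}
        for k in range(12):
            g = f"x{k:02d}"
            pairs[("a", g)] = float(k + 1)
            pairs[("b", g)] = partner_scores_b[k]
        matrix = matrix_from_pairs(pairs)
        net = make_network(
            [("a", "b", "N", -3.0), ("b", "c", "N", -2.0), ("a", "c", "P", 4.0)]
        )
        return matrix, enumerate_triplets(net)

    def test_identical_profiles_give_rho_one(self):
        matrix, census = self._matrix_and_census([float(k + 1) for k in range(12)])
        df = profile_correlation(matrix, census, "NNP").set_index("edge_sign")
        # only the a-b edge has >= 10 common partners
        assert df.loc["N", "n_edges"] == 1
        assert df.loc["N", "mean_rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self):
        matrix, census = self._matrix_and_census([float(12 - k) for k in range(12)])
        df = profile_correlation(matrix, census, "NNP").set_index("edge_sign")
        assert df.loc["N", "mean_rho"] == pytest.approx(-1.0)

    def test_matches_independent_rank_computation(self):
        # pairwise-swapped ranks: (2,1,4,3,...) against (1,2,3,4,...)
        b_scores = []
        for k in range(12):
            b_scores.append(float(k + 2) if k % 2 == 0 else float(k))
        matrix, census = self._matrix_and_census(b_scores)
        df = profile_correlation(matrix, census, "NNP").set_index("edge_sign")
        from scipy.stats import rankdata

        va = np.array([float(k + 1) for k in range(12)])
        vb = np.array(b_scores)
        expected = np.corrcoef(rankdata(va), rankdata(vb))[0, 1]
        assert df.loc["N", "mean_rho"] == pytest.approx(expected)

    def test_short_profiles_skipped(self):
        pairs = {("a", "b"): -3.0, ("b", "c"): -2.0, ("a", "c"): 4.0}
        matrix = matrix_from_pairs(pairs)
        net = make_network(
            [("a", "b", "N", -3.0), ("b", "c", "N", -2.0), ("a", "c", "P", 4.0)]
        )
        df = profile_correlation(matrix, enumerate_triplets(net), "NNP")
        assert (df["n_edges"] == 0).all()


class TestPositionEnrichment:
    def _setup(self):
        # NPP triplet: positive node is 'r' (incident to both P edges)
        net = make_network(
            [("m1", "m2", "N", -5.0), ("m1", "r", "P", 3.0), ("m2", "r", "P", 4.0)]
        )
        return enumerate_triplets(net)

    def test_hypergeometric_arithmetic(self):
        census = self._setup()
        universe = {f"g{i}" for i in range(9)} | {"r"}
        with_term = {"r", "g0", "g1", "g2", "g3"}
        ann = AnnotationSet(
            gene_terms={"go_function": {g: {"t"} for g in with_term}}
        )
        df = position_gene_enrichment(census, ann, "NPP", "positive_node",
                                      "go_function", universe)
        row = df[df["term"] == "t"].iloc[0]
        # role set = {r}: P(X >= 1) with M=10, K=5, n=1 -> 0.5
        assert row["p"] == pytest.approx(hypergeom_over_p(1, 10, 5, 1))
        assert row["fold_enrichment"] == pytest.approx((1 / 1) / (5 / 10))

    def test_textbook_hypergeometric_case(self):
        assert hypergeom_over_p(4, 10, 5, 4) == pytest.approx(5 / 210)
        from scipy.stats import hypergeom

        assert hypergeom.sf(3, 10, 5, 4) == pytest.approx(5 / 210)

    def test_absent_term_gets_fold_zero_p_one(self):
        census = self._setup()
        universe = {"r", "m1", "m2", "g0"}
        ann = AnnotationSet(gene_terms={"go_function": {"g0": {"t"}}})
        df = position_gene_enrichment(census, ann, "NPP", "positive_node",
                                      "go_function", universe)
        row = df[df["term"] == "t"].iloc[0]
        assert row["fold_enrichment"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_unknown_role_rejected(self):
        census = self._setup()
        with pytest.raises(ValueError):
            position_gene_enrichment(census, AnnotationSet(gene_terms={"go_function": {}}),
                                     "NNN", "positive_node", "go_function", {"r"})
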