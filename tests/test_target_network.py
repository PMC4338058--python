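import numpy as np
import pytest

from srna_seeker.annotation_io import AnnotatedGenome, GeneFeature, revcomp
from srna_seeker.target_network import (
    TargetEdge,
    build_network,
    cog_tally,
    coregulation_stats,
    extract_start_windows,
    predict_targets,
)


def oracle_matches(srna, window, seed_min):
    """Brute force: every (i, j, L) with srna[i:i+L] == revcomp-window[j:j+L]."""
    rc = revcomp(window)
    found = []
    for i in range(len(srna)):
        for j in range(len(rc)):
            L = 0
            while (i + L < len(srna) and j + L < len(rc)
                   and srna[i + L] == rc[j + L]):
                L += 1
            if L >= seed_min:
                # only maximal runs: skip if extendable leftwards
                if i > 0 and j > 0 and srna[i - 1] == rc[j - 1]:
                    continue
                found.append((i, j, L))
    return found


class TestPredictTargets:
    def test_planted_exact_complement_found(self):
        rng = np.random.default_rng(0)
        srna = "".join(rng.choice(list("ACGT"), size=120))
        seed = srna[30:42]
        window = "A" * 20 + revcomp(seed) + "A" * 18  # 50 nt window
        edges = predict_targets(srna, [("g1", window)], srna_id="S")
        assert len(edges) == 1
        e = edges[0]
        assert e.seed_len >= 12
        assert e.seed_start_in_srna <= 30 <= e.seed_start_in_srna + e.seed_len
        assert e.position_in_mrna == 20 - 30  # window offset 20 -> -10 from AUG
        # oracle agrees a maximal match of >= 12 exists at that spot
        assert any(L >= 12 for _, _, L in oracle_matches(srna, window, 8))

    def test_no_complementarity_no_edges(self):
        assert predict_targets("A" * 60, [("g1", "A" * 50)]) == []

    def test_eight_at_pairs_score_below_threshold(self):
        # rc(window) = T21 + AAAATTTT + T25: one maximal 8 nt A:T seed
        srna = "G" * 20 + "AAAATTTT" + "G" * 20
        window = "A" * 21 + "AAAATTTT" + "A" * 21
        # seed found but score 8 < 10
        assert predict_targets(srna, [("g1", window)]) == []
        # with a lower score threshold it appears
        edges = predict_targets(srna, [("g1", window)], score_min=8.0)
        assert edges and edges[0].hybrid_score == pytest.approx(8.0)

    def test_gc_seed_scores_two_per_pair(self):
        srna = "A" * 20 + "GCGCGCGC" + "A" * 20
        window = "A" * 21 + "GCGCGCGC" + "A" * 21  # GC run is its own revcomp
        (e,) = predict_targets(srna, [("g1", window)])
        assert e.hybrid_score == pytest.approx(16.0)

    def test_short_window_skipped(self):
        assert predict_targets("ACGTACGTACGT", [("g1", "ACGT")]) == []

    def test_best_edge_per_gene(self):
        srna = "A" * 10 + "GCGCGCGCGC" + "A" * 10 + "ATATATATAT" + "A" * 10
        window = revcomp("GCGCGCGCGC") + revcomp("ATATATATAT") + "C" * 30
        edges = predict_targets(srna, [("g1", window[:50])], score_min=8.0)
        assert len(edges) == 1
        assert edges[0].hybrid_score == pytest.approx(20.0)  # GC seed wins

    def test_matches_oracle_on_random_short_sequences(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            srna = "".join(rng.choice(list("ACGT"), size=60))
            window = "".join(rng.choice(list("ACGT"), size=50))
            edges = predict_targets(srna, [("g", window)], seed_min=6, score_min=0.0)
            oracle = oracle_matches(srna, window, 6)
            assert bool(edges) == bool(oracle)
            if edges:
                def score(i, L):
                    return sum(2.0 if b in "GC" else 1.0 for b in srna[i:i + L])
                assert edges[0].hybrid_score == pytest.approx(
                    max(score(i, L) for i, _, L in oracle)
                )


class TestStartWindows:
    def test_plus_and_minus_strand_windows(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=400))
        feats = [GeneFeature("gp", "CDS", 100, 200, "+"),
                 GeneFeature("gm", "CDS", 250, 350, "-"),
                 GeneFeature("t", "tRNA", 360, 380, "+")]
        g = AnnotatedGenome("x", seq, features=feats)
        windows = dict(extract_start_windows(g))
        assert set(windows) == {"gp", "gm"}  # CDS only
        assert windows["gp"] == seq[70:120]
        assert windows["gm"] == revcomp(seq[330:380])
        assert all(len(w) == 50 for w in windows.values())


def edge(s, g):
    return TargetEdge(s, g, 0, 10, 15.0, -5)


class TestNetworkStats:
    def test_disjoint_targets_all_degree_one(self):
        edges = [edge(f"s{i}", f"g{i}") for i in range(11)]
        net = build_network(edges)
        assert set(net.gene_in_degree.values()) == {1}
        stats = coregulation_stats(net)
        assert stats == (11, 0, 1, sorted(f"g{i}" for i in range(11)))

    def test_ftsx_like_gene_reaches_degree_four(self):
        edges = [edge(f"s{i}", "ftsX") for i in range(4)] + [edge("s0", "other")]
        stats = coregulation_stats(build_network(edges))
        assert stats.max_in_degree == 4
        assert stats.genes_at_max == ["ftsX"]

    def test_empty_network(self):
        assert coregulation_stats(build_network([])) == (0, 0, 0, [])

    def test_single_edge(self):
        assert coregulation_stats(build_network([edge("s", "g")])) == (1, 0, 1, ["g"])

    def test_constructed_276_48_fixture(self):
        # 276 targets, 48 with in-degree >= 2, one gene at degree 4
        edges = []
        genes = [f"g{i:03d}" for i in range(276)]
        for g in genes:
            edges.append(edge("s1", g))
        for g in genes[:48]:
            edges.append(edge("s2", g))
        for g in genes[:1]:  # g000 gets degree 4
            edges.append(edge("s3", g))
            edges.append(edge("s4", g))
        stats = coregulation_stats(build_network(edges))
        assert stats.n_targets == 276
        assert stats.n_coregulated_ge2 == 48
        assert stats.max_in_degree == 4
        assert stats.genes_at_max == ["g000"]

    def test_invariant_under_edge_permutation(self):
        rng = np.random.default_rng(8)
        edges = [edge(f"s{rng.integers(5)}", f"g{rng.integers(40)}")
                 for _ in range(120)]
        # drop duplicate (srna, gene) pairs as build_network collapses them
        stats1 = coregulation_stats(build_network(edges))
        perm = [edges[i] for i in rng.permutation(len(edges))]
        stats2 = coregulation_stats(build_network(perm))
        assert stats1 == stats2

    def test_degree_maps_match_adjacency_recount(self):
        rng = np.random.default_rng(3)
        pairs = {(f"s{rng.integers(6)}", f"g{rng.integers(30)}") for _ in range(80)}
        net = build_network([edge(s, g) for s, g in pairs])
        for g in net.gene_in_degree:
            assert net.gene_in_degree[g] == sum(1 for _, gg in pairs if gg == g)
        for s in net.srna_degree:
            assert net.srna_degree[s] == sum(1 for ss, _ in pairs if ss == s)


class TestExports:
    def test_edgelist_and_graphml(self, tmp_path):
        net = build_network([edge("s1", "g1"), edge("s1", "g2")])
        tsv = tmp_path / "edges.tsv"
        net.to_edgelist_tsv(tsv)
        lines = tsv.read_text().strip().split("\n")
        assert len(lines) == 3
        gml = tmp_path / "net.graphml"
        net.write_graphml(gml)
        import networkx as nx

        g = nx.read_graphml(gml)
        assert g.number_of_edges() == 2


class TestCogTally:
    def test_single_category(self):
        t = cog_tally(["g1", "g2"], {"g1": "E", "g2": "E"})
        assert t.counts == {"E": 2}
        assert (t.n_with_cog, t.n_total) == (2, 2)

    def test_no_labels(self):
        t = cog_tally(["g1"], {})
        assert t.n_with_cog == 0 and t.counts == {}

    def test_248_of_276_labeled_fixture(self):
        genes = [f"g{i}" for i in range(276)]
        labels = {g: "EG"[i % 2] for i, g in enumerate(genes[:248])}
        t = cog_tally(genes, labels)
        assert t.n_with_cog == 248 and t.n_total == 276
        assert sum(t.counts.values()) == 248

    def test_multi_letter_gene_counted_per_category(self):
        t = cog_tally(["g1"], {"g1": "EG"})
        assert t.counts == {"E": 1, "G": 1}
        assert sum(t.counts.values()) >= t.n_with_cog

    def test_unknown_letter_bucketed_as_other(self):
        t = cog_tally(["g1"], {"g1": "!"})
        assert t.counts == {"other": 1}
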