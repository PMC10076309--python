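"""Diversity statistics, haplotype networks and NJ trees against oracles."""

import itertools
import math

import numpy as np
import pytest

from ampseek import (
    FilterConfig,
    HaplotypeSet,
    PileupMatrix,
    build_network,
    consensus_from_pileup,
    diversity_stats,
    nj_tree,
    pairwise_differences,
    tajimas_d,
)
from ampseek.pileup_caller import _BASE_IDX


def brute_force_stats(seqs):
    """Independent enumeration oracle for pi, Hd, theta_W and S."""
    n = len(seqs)
    L = len(seqs[0])
    diffs = [sum(a != b for a, b in zip(s1, s2))
             for s1, s2 in itertools.combinations(seqs, 2)]
    pi = sum(diffs) / len(diffs) / L if L else 0.0
    S = sum(len({s[j] for s in seqs}) > 1 for j in range(L))
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    Hd = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts.values()))
    a1 = sum(1 / i for i in range(1, n))
    return pi, Hd, S, S / a1, len(counts)


def random_haplotype_set(rng, n, L):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 2, L)) for _ in range(n)]
    return HaplotypeSet(seqs, [f"s{i}" for i in range(n)], ["pop"] * n)


class TestConsensus:
    @staticmethod
    def _uniform_pileup(panel, amp_name, depth):
        amp = panel.get(amp_name)
        L = len(amp.reference_seq)
        counts = np.zeros((L, 5), dtype=np.int64)
        for p in range(L):
            counts[p, _BASE_IDX[amp.reference_seq[p]]] = depth
        return PileupMatrix(amp_name, "s", amp.reference_seq, counts,
                            [[] for _ in range(L)], {})

    def test_mean_depth_at_threshold_rejected(self, panel):
        p = self._uniform_pileup(panel, "ITS2", 49)
        res = consensus_from_pileup(p, min_fold=50)
        assert res.sequence is None and "mean_depth" in res.rejected_reason
        assert consensus_from_pileup(self._uniform_pileup(panel, "ITS2", 50),
                                     min_fold=50).sequence is None  # > rule, not >=

    def test_homozygous_sample_recovers_reference(self, panel):
        p = self._uniform_pileup(panel, "ITS2", 80)
        res = consensus_from_pileup(p, min_fold=50)
        assert res.sequence == panel.get("ITS2").reference_seq

    def test_zero_depth_position_is_n(self, panel):
        p = self._uniform_pileup(panel, "ITS2", 80)
        p.counts[100, :] = 0
        res = consensus_from_pileup(p, min_fold=50)
        assert res.sequence[100] == "N"

    def test_empty_pileup_rejected(self, panel):
        amp = panel.get("ITS2")
        L = len(amp.reference_seq)
        p = PileupMatrix("ITS2", "s", amp.reference_seq,
                         np.zeros((L, 5), dtype=np.int64),
                         [[] for _ in range(L)], {})
        assert consensus_from_pileup(p).rejected_reason == "empty_pileup"


class TestDiversityStats:
    def test_identical_sequences_degenerate(self):
        h = HaplotypeSet(["ACGT"] * 5, [f"s{i}" for i in range(5)], ["p"] * 5)
        st = diversity_stats(h)
        assert st.pi == 0 and st.Hd == 0 and st.S == 0
        assert st.D_undefined and math.isnan(st.D)

    def test_four_sequence_worked_example(self):
        """AAA/AAT/ATT/TTT: pairwise sums enumerated by hand."""
        h = HaplotypeSet(["AAA", "AAT", "ATT", "TTT"],
                         list("abcd"), ["p"] * 4)
        st = diversity_stats(h)
        pi, Hd, S, theta, k = brute_force_stats(["AAA", "AAT", "ATT", "TTT"])
        assert st.pi == pytest.approx(pi)          # 10/6/3
        assert st.Hd == pytest.approx(Hd)          # 4 distinct -> 1.0
        assert st.S == S == 3
        assert st.theta_w == pytest.approx(theta)
        assert st.k == 4

    def test_matches_enumeration_oracle_randomised(self):
        rng = np.random.default_rng(23)
        for _ in range(120):
            n = int(rng.integers(2, 9))
            L = int(rng.integers(1, 51))
            h = random_haplotype_set(rng, n, L)
            st = diversity_stats(h)
            pi, Hd, S, theta, k = brute_force_stats(h.sequences)
            assert st.pi == pytest.approx(pi)
            assert st.Hd == pytest.approx(Hd)
            assert st.S == S
            assert st.theta_w == pytest.approx(theta)
            assert st.k == k

    def test_pi_invariant_under_duplication_hd_closed_form(self):
        rng = np.random.default_rng(7)
        h = random_haplotype_set(rng, 6, 40)
        st = diversity_stats(h)
        h2 = HaplotypeSet(h.sequences * 2, [f"d{i}" for i in range(12)],
                          ["p"] * 12)
        st2 = diversity_stats(h2)
        n = 6
        # duplication adds zero-distance self pairs: the sample estimator
        # scales by exactly 2(n-1)/(2n-1), approaching invariance as n grows
        assert st2.pi == pytest.approx(st.pi * 2 * (n - 1) / (2 * n - 1))
        # Hd after doubling: n'=2n, haplotype freqs unchanged
        sum_p2 = 1 - st.Hd * (n - 1) / n
        expected = (2 * n) / (2 * n - 1) * (1 - sum_p2)
        assert st2.Hd == pytest.approx(expected)

    def test_masked_sites_excluded(self):
        h = HaplotypeSet(["ANGT", "AC-T", "ACGT"], list("abc"), ["p"] * 3)
        st = diversity_stats(h)
        assert st.L == 2          # positions 1 and 2 masked set-wide

    def test_tajimas_d_cross_checked_against_dendropy(self):
        """Independent oracle: dendropy's population-genetics statistics."""
        import dendropy
        from dendropy.calculate import popgenstat
        rng = np.random.default_rng(31)
        h = random_haplotype_set(rng, 8, 60)
        st = diversity_stats(h)
        if st.S == 0:
            pytest.skip("degenerate draw")
        mat = dendropy.DnaCharacterMatrix.from_dict(
            {f"t{i}": s for i, s in enumerate(h.sequences)})
        assert st.D == pytest.approx(popgenstat.tajimas_d(mat), abs=1e-9)
        assert st.pi == pytest.approx(
            popgenstat.nucleotide_diversity(mat), abs=1e-12)

    def test_neutral_singleton_scatter_keeps_d_near_zero(self):
        """Sites drawn from the neutral frequency spectrum (P(i) ∝ 1/i
        derived copies) give Tajima's D ≈ 0 on average."""
        rng = np.random.default_rng(101)
        n, S = 12, 40
        weights = np.array([1 / i for i in range(1, n)])
        weights /= weights.sum()
        ds = []
        for _ in range(30):
            cols = []
            for _s in range(S):
                i = 1 + int(rng.choice(n - 1, p=weights))
                col = np.array(["A"] * n)
                col[rng.choice(n, size=i, replace=False)] = "T"
                cols.append(col)
            seqs = ["".join(row) for row in np.array(cols).T]
            st = diversity_stats(HaplotypeSet(seqs, [f"s{i}" for i in range(n)],
                                              ["p"] * n))
            ds.append(st.D)
        assert abs(np.mean(ds)) < 0.5

    def test_fewer_than_two_sequences_error(self):
        with pytest.raises(ValueError):
            diversity_stats(HaplotypeSet(["ACGT"], ["a"], ["p"]))


class TestHaplotypeNetwork:
    def test_three_haplotypes_keeps_cheap_edges(self):
        h = HaplotypeSet(["AAAA", "AAAT", "AATT"], list("abc"), ["p"] * 3)
        net = build_network(h)
        weights = sorted(d["weight"] for _, _, d in net.graph.edges(data=True))
        assert weights == [1, 1]
        assert net.graph.number_of_edges() == net.graph.number_of_nodes() - 1

    def test_mst_weight_equals_exhaustive_spanning_tree_minimum(self):
        """Total MST weight equals the brute-force minimum over all spanning
        trees (Cayley enumeration via networkx on ≤ 7 haplotypes)."""
        import networkx as nx
        rng = np.random.default_rng(13)
        for _ in range(15):
            k = int(rng.integers(3, 8))
            seqs = []
            while len(set(seqs)) < k:
                seqs = list({
                    "".join("ACGT"[i] for i in rng.integers(0, 2, 12))
                    for _ in range(k)
                })[:k]
            h = HaplotypeSet(seqs, [f"s{i}" for i in range(len(seqs))],
                             ["p"] * len(seqs))
            net = build_network(h)
            mst_w = sum(d["weight"] for _, _, d in net.graph.edges(data=True))
            g = nx.Graph()
            labels = list(net.haplotypes)
            inv = {v: k_ for k_, v in net.haplotypes.items()}
            arr = {s: np.frombuffer(s.encode(), np.uint8) for s in net.haplotypes.values()}
            for a, b in itertools.combinations(net.haplotypes.values(), 2):
                g.add_edge(inv[a], inv[b], weight=int((arr[a] != arr[b]).sum()))
            best = min(
                sum(g[u][v]["weight"] for u, v in tree.edges())
                for tree in nx.SpanningTreeIterator(g)
            ) if g.number_of_nodes() > 1 else 0
            assert mst_w == best

    def test_shared_haplotype_counts_both_populations(self):
        h = HaplotypeSet(["AAAA", "AAAA", "AATT"], list("abc"),
                         ["ethiopia", "pakistan", "ethiopia"])
        net = build_network(h)
        node = next(n for n, d in net.graph.nodes(data=True) if d["count"] == 2)
        pops = net.graph.nodes[node]["populations"]
        assert pops == {"ethiopia": 1, "pakistan": 1}
        assert net.total_samples == 3

    def test_distinct_haplotypes_at_least_one_apart(self):
        rng = np.random.default_rng(4)
        h = random_haplotype_set(rng, 10, 15)
        net = build_network(h)
        assert all(d["weight"] >= 1 for _, _, d in net.graph.edges(data=True))
        assert net.total_samples == 10


def _newick_leaf_distances(newick, labels):
    """Leaf-to-leaf path lengths parsed with dendropy."""
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    out = {}
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


class TestNJTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = nj_tree(d, labels=["a", "b", "c"])
        dist = _newick_leaf_distances(t.newick, ["a", "b", "c"])
        assert dist[("a", "b")] == pytest.approx(5)
        assert dist[("a", "c")] == pytest.approx(9)
        assert dist[("b", "c")] == pytest.approx(10)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_distances_recovered_exactly(self, n_taxa):
        """NJ on additive tree distances reproduces every leaf-to-leaf path
        length exactly (hence topology and branch lengths)."""
        rng = np.random.default_rng(n_taxa)
        import dendropy
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
            num_extant_tips=n_taxa, rng=__import__("random").Random(7))
        for e in tree.edges():
            e.length = float(1 + rng.integers(1, 10))
        pdm = tree.phylogenetic_distance_matrix()
        labels = [t.label for t in taxa]
        D = np.zeros((n_taxa, n_taxa))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    D[i, j] = pdm.patristic_distance(a, b)
        out = nj_tree(D, labels=labels)
        got = _newick_leaf_distances(out.newick, labels)
        for (a, b), v in got.items():
            i, j = labels.index(a), labels.index(b)
            assert v == pytest.approx(D[i, j]), (a, b)

    def test_matches_scikit_bio_on_random_matrix(self):
        """Cross-check against scikit-bio's independent NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(9)
        n = 6
        labels = [f"t{i}" for i in range(n)]
        # build additive distances from a random tree so both must agree
        import dendropy
        taxa = dendropy.TaxonNamespace(labels)
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
            num_extant_tips=n, rng=__import__("random").Random(3))
        for e in tree.edges():
            e.length = float(rng.integers(1, 8))
        pdm = tree.phylogenetic_distance_matrix()
        D = np.zeros((n, n))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i != j:
                    D[i, j] = pdm.patristic_distance(a, b)
        ours = _newick_leaf_distances(nj_tree(D, labels=labels).newick, labels)
        sk_tree = skbio_nj(DistanceMatrix(D, labels))
        for (a, b), v in ours.items():
            assert v == pytest.approx(sk_tree.find(a).distance(sk_tree.find(b)))

    def test_planted_population_structure_is_monophyletic(self):
        """Two populations separated by 6 fixed differences, ≤1 within, are
        each monophyletic in the NJ tree."""
        import dendropy
        rng = np.random.default_rng(55)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        other = list(base)
        for p in range(0, 12, 2):
            other[p] = "A" if other[p] != "A" else "T"
        other = "".join(other)
        seqs, sids, pops = [], [], []
        for i in range(4):
            s = list(base)
            if i % 2:
                s[40 + i] = "A" if s[40 + i] != "A" else "G"
            seqs.append("".join(s)); sids.append(f"e{i}"); pops.append("E")
        for i in range(4):
            s = list(other)
            if i % 2:
                s[60 + i] = "A" if s[60 + i] != "A" else "G"
            seqs.append("".join(s)); sids.append(f"p{i}"); pops.append("P")
        h = HaplotypeSet(seqs, sids, pops)
        t = nj_tree(h)
        tree = dendropy.Tree.get(data=t.newick, schema="newick")
        labels_e = {f"e{i}|E" for i in range(4)}
        bipartitions = []
        for edge in tree.preorder_edge_iter():
            leaves = {l.taxon.label for l in edge.head_node.leaf_iter()}
            bipartitions.append(leaves)
        assert labels_e in bipartitions or (set(t.leaves) - labels_e) in bipartitions

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(d, labels=list("abc"))

    def test_nj_on_ultrametric_distances_matches_upgma_topology(self):
        """On clean ultrametric distances NJ recovers the UPGMA clustering."""
        from scipy.cluster.hierarchy import linkage, to_tree
        labels = list("abcde")
        # ultrametric: ((a,b):1,(c,d):2,e:4 style distances
        D = np.array([
            [0, 2, 6, 6, 8],
            [2, 0, 6, 6, 8],
            [6, 6, 0, 4, 8],
            [6, 6, 4, 0, 8],
            [8, 8, 8, 8, 0],
        ], float)
        got = _newick_leaf_distances(nj_tree(D, labels=labels).newick, labels)
        for (a, b), v in got.items():
            i, j = labels.index(a), labels.index(b)
            assert v == pytest.approx(D[i, j])   # additive => exact, same splits
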