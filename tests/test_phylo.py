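"""Distance estimators, complete deletion, and Neighbor-Joining."""

import math

import networkx as nx
import numpy as np
import pytest

from wreconserve.phylo import (
    DistanceMatrix,
    PhyloError,
    complete_deletion,
    jc_distance,
    mcl_tn93_distances,
    nj_tree,
    p_distance,
    pairwise_distances,
    parse_newick,
    tn93_distance,
    to_newick,
)
from wreconserve.promoter_io import AlignedPromoterSet


class TestCompleteDeletion:
    def test_gap_column_dropped(self):
        aligned = AlignedPromoterSet(members={"a": "AC-GT", "b": "ACAGT"})
        filtered, n = complete_deletion(aligned)
        assert n == 4
        assert filtered.members == {"a": "ACGT", "b": "ACGT"}

    def test_n_column_dropped(self):
        aligned = AlignedPromoterSet(members={"a": "ACNGT", "b": "ACAGT"})
        _, n = complete_deletion(aligned)
        assert n == 4

    def test_clean_alignment_identity(self):
        aligned = AlignedPromoterSet(members={"a": "ACGT", "b": "AGGT"})
        filtered, n = complete_deletion(aligned)
        assert n == 4 and filtered.members == aligned.members

    def test_all_columns_removed(self):
        aligned = AlignedPromoterSet(members={"a": "---", "b": "ACG"})
        with pytest.raises(PhyloError):
            complete_deletion(aligned)


class TestDistances:
    def test_identical_sequences_zero_under_every_model(self):
        aligned = AlignedPromoterSet(members={"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        for model in ("p", "jc", "tn93", "mcl-tn93"):
            dm = pairwise_distances(aligned, model=model)
            assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_jc_closed_form_at_p_ten_percent(self):
        # 1000 sites, exactly 100 differences
        s1 = "ACGT" * 250
        s2 = "TCGT" * 100 + "ACGT" * 150
        assert p_distance(s1, s2) == pytest.approx(0.1)
        d = jc_distance(p_distance(s1, s2))
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-12)
        assert d == pytest.approx(0.10733, abs=5e-6)

    def test_jc_saturation_flagged(self):
        with pytest.raises(PhyloError):
            jc_distance(0.75)
        s1 = "AAAA" * 10
        s2 = "CCCC" * 10
        dm = pairwise_distances(
            AlignedPromoterSet(members={"a": s1, "b": s2}), model="jc")
        assert math.isinf(dm.d[0, 1])
        assert dm.saturated == (("a", "b"),)

    def test_jc_monotone_and_above_p(self):
        ps = np.linspace(0.001, 0.74, 200)
        ds = [jc_distance(p) for p in ps]
        assert all(d2 > d1 for d1, d2 in zip(ds, ds[1:]))
        assert all(d >= p for d, p in zip(ds, ps))

    def test_tn93_matches_independent_reference(self):
        # fixed pair with 40 transitions + 35 transversions in 600 sites;
        # expected value frozen from R ape::dist.dna(model="TN93")
        rng = np.random.default_rng(42)
        L = 600
        bases = "ACGT"
        s1 = "".join(bases[i] for i in rng.integers(4, size=L))
        s2 = list(s1)
        sites = rng.choice(L, size=75, replace=False)
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        tv = {"A": "C", "G": "T", "C": "G", "T": "A"}
        for j, site in enumerate(sites):
            s2[site] = ts[s1[site]] if j < 40 else tv[s1[site]]
        assert tn93_distance(s1, "".join(s2)) == pytest.approx(0.137598899471, abs=1e-9)

    def test_mcl_tn93_collapses_to_jc_on_jc_patterns(self):
        # a pair whose site-pattern counts sit exactly at the JC expectation
        # (uniform composition, transitions one third of mismatches)
        s1, s2 = [], []
        for b in "ACGT":
            s1 += [b] * 270
            s2 += [b] * 270
        for a, b in [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]:
            s1 += [a] * 10
            s2 += [b] * 10
        for a, b in [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]:
            s1 += [a] * 10 + [b] * 10
            s2 += [b] * 10 + [a] * 10
        aligned = AlignedPromoterSet(members={"x": "".join(s1), "y": "".join(s2)})
        dm, params = mcl_tn93_distances(aligned)
        expected = jc_distance(p_distance("".join(s1), "".join(s2)))
        assert dm.d[0, 1] == pytest.approx(expected, abs=1e-6)
        assert params["kappa1"] == pytest.approx(1.0, abs=1e-4)
        assert params["kappa2"] == pytest.approx(1.0, abs=1e-4)

    def test_unfiltered_alignment_rejected(self):
        aligned = AlignedPromoterSet(members={"a": "AC-T", "b": "ACGT"})
        with pytest.raises(PhyloError):
            pairwise_distances(aligned, model="jc")


def _random_additive(n, rng):
    """Random binary tree via edge-splitting; distances = path lengths."""
    G = nx.Graph()
    center = "I0"
    for i in range(3):
        G.add_edge(f"T{i}", center, weight=float(rng.uniform(0.05, 1.0)))
    next_internal = 1
    for i in range(3, n):
        u, v = list(G.edges())[rng.integers(G.number_of_edges())]
        w = G[u][v]["weight"]
        G.remove_edge(u, v)
        mid = f"I{next_internal}"
        next_internal += 1
        cut = float(rng.uniform(0.2, 0.8)) * w
        G.add_edge(u, mid, weight=cut)
        G.add_edge(mid, v, weight=w - cut)
        G.add_edge(mid, f"T{i}", weight=float(rng.uniform(0.05, 1.0)))
    taxa = tuple(f"T{i}" for i in range(n))
    D = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(G))
    for i in range(n):
        for j in range(n):
            D[i, j] = paths[taxa[i]][taxa[j]]
    return DistanceMatrix(taxa=taxa, d=D, usable_sites=0)


class TestNeighborJoining:
    def test_three_taxon_worked_example(self):
        D = DistanceMatrix(taxa=("A", "B", "C"),
                           d=np.array([[0, .3, .4], [.3, 0, .5], [.4, .5, 0]]),
                           usable_sites=0)
        t = nj_tree(D)
        assert to_newick(t).strip() == "(A:0.1,B:0.2,C:0.3);"
        assert t.sum_branch_lengths == pytest.approx(0.6, abs=1e-12)

    def test_four_taxon_worked_example(self):
        D = DistanceMatrix(
            taxa=("A", "B", "C", "D"),
            d=np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                       dtype=float),
            usable_sites=0)
        t = nj_tree(D)
        assert t.sum_branch_lengths == pytest.approx(11.0, abs=1e-12)
        # AB|CD topology with branches A:1 B:2 C:3 D:4 and internal 1
        assert t.branch_length_of("A") == pytest.approx(1.0)
        assert t.branch_length_of("B") == pytest.approx(2.0)
        assert t.branch_length_of("C") == pytest.approx(3.0)
        assert t.branch_length_of("D") == pytest.approx(4.0)
        np.testing.assert_allclose(t.leaf_distances().d, D.d, atol=1e-12)

    def test_two_taxon_single_edge(self):
        D = DistanceMatrix(taxa=("A", "B"), d=np.array([[0, .4], [.4, 0]]),
                           usable_sites=0)
        t = nj_tree(D)
        assert t.sum_branch_lengths == pytest.approx(0.4)
        assert t.leaf_distances().d[0, 1] == pytest.approx(0.4)

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_additive_matrices_recovered_exactly(self, n, rng):
        for _ in range(5):
            D = _random_additive(n, rng)
            t = nj_tree(D)
            got = t.leaf_distances()
            assert got.taxa == tuple(sorted(D.taxa))
            idx = [D.taxa.index(x) for x in got.taxa]
            np.testing.assert_allclose(got.d, D.d[np.ix_(idx, idx)], atol=1e-9)

    def test_agrees_with_skbio_on_noisy_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        D = _random_additive(7, rng)
        noisy = D.d + rng.uniform(0, 0.01, size=D.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = nj_tree(DistanceMatrix(taxa=D.taxa, d=noisy, usable_sites=0))
        ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=list(D.taxa)))
        ref_d = ref.tip_tip_distances(list(mine.taxa))
        np.testing.assert_allclose(mine.leaf_distances().d, ref_d.data, atol=1e-8)

    def test_nonfinite_distances_rejected(self):
        D = DistanceMatrix(taxa=("A", "B", "C"),
                           d=np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]]),
                           usable_sites=0)
        with pytest.raises(PhyloError):
            nj_tree(D)


class TestNewick:
    def test_round_trip_preserves_metric(self, rng):
        D = _random_additive(6, rng)
        t = nj_tree(D)
        back = parse_newick(to_newick(t))
        np.testing.assert_allclose(back.leaf_distances().d, t.leaf_distances().d,
                                   atol=1e-8)

    def test_branch_length_precision(self):
        D = DistanceMatrix(taxa=("A", "B", "C"),
                           d=np.array([[0, 0.1234567, 0.4], [0.1234567, 0, 0.5],
                                       [0.4, 0.5, 0]]),
                           usable_sites=0)
        text = to_newick(nj_tree(D))
        # >= 6 significant digits survive serialization
        back = parse_newick(text)
        assert back.leaf_distances().d.max() == pytest.approx(
            nj_tree(D).leaf_distances().d.max(), abs=1e-7)

    def test_malformed_newick_rejected(self):
        with pytest.raises(PhyloError):
            parse_newick("((A:0.1,B:0.2;")
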