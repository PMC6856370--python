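"""Promoter/exon evolution simulator: marginals, determinism, ground truth."""

import math

import numpy as np
import pytest

from wreconserve.phylo import complete_deletion, nj_tree, pairwise_distances, to_newick
from wreconserve.synthetic_data import (
    PlantedSite,
    SubstitutionModel,
    simulate_exons,
    simulate_promoters,
)
from wreconserve.wre_scan import DegenerateMotif, scan_promoter

SPECIES5 = frozenset({"human", "mouse", "rat", "chicken", "zebrafish"})


class TestSimulatePromoters:
    def test_zero_branch_lengths_give_identical_sequences(self):
        tree = "((a:0.0,b:0.0):0.0,c:0.0);"
        sites = [PlantedSite(position=-50, retained=frozenset("abc"),
                             lost=frozenset())]
        recs, aligned, _ = simulate_promoters(tree=tree, length=200,
                                              planted_sites=sites, seed=1)
        seqs = {r.species: r.sequence for r in recs}
        assert len(set(seqs.values())) == 1

    def test_rat_loss_scenario_recovered(self, wre):
        from wreconserve import call_conserved, scan_species

        recs, aligned, truth = simulate_promoters(seed=11)
        clusters = call_conserved(scan_species(recs, wre), aligned, m=4)
        conserved = [c for c in clusters if c.conserved]
        assert len(conserved) == 1
        assert conserved[0].absent_species == frozenset({"rat"})
        # the rat carries the non-binding 7-mer at the orthologous spot
        rat = next(r for r in recs if r.species == "rat")
        site = truth.planted_sites[0]
        off = rat.upstream + site.position
        assert rat.sequence[off:off + 7] == site.loss_7mer

    def test_jc_branch_marginal_matches_closed_form(self):
        # one branch of length t: expected differing fraction
        # (3/4)(1 - exp(-4t/3)) = 0.09362 at t = 0.1, L = 10,000
        t, L = 0.1, 10_000
        tree = f"(a:{t},b:0.0);"
        recs, _, _ = simulate_promoters(
            tree=tree, length=L, planted_sites=[], seed=5,
            scrub_background=False)
        seqs = {r.species: r.sequence for r in recs}
        p_obs = sum(x != y for x, y in zip(seqs["a"], seqs["b"])) / L
        p_exp = 0.75 * (1 - math.exp(-4 * t / 3))
        assert p_exp == pytest.approx(0.09362, abs=5e-6)
        se = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) <= 3 * se

    def test_seed_reproducibility_byte_identical(self):
        a = simulate_promoters(seed=42)
        b = simulate_promoters(seed=42)
        assert [r.sequence for r in a[0]] == [r.sequence for r in b[0]]
        assert a[1].members == b[1].members

    def test_different_seeds_differ(self):
        a = simulate_promoters(seed=1)
        b = simulate_promoters(seed=2)
        assert [r.sequence for r in a[0]] != [r.sequence for r in b[0]]

    def test_scrubbed_background_leaves_only_planted_hits(self, wre):
        recs, _, truth = simulate_promoters(seed=3)
        planted = {s.position for s in truth.planted_sites}
        for rec in recs:
            if rec.species in truth.planted_sites[0].lost:
                continue
            positions = {h.position for h in scan_promoter(rec, wre)}
            assert positions == planted

    def test_isoform_duplicates(self):
        recs, _, _ = simulate_promoters(seed=0, n_isoforms=2, length=500,
                                        planted_sites=[])
        assert len(recs) == 10
        per_species = {}
        for r in recs:
            per_species.setdefault(r.species, []).append(r)
        for group in per_species.values():
            assert {r.isoform_id for r in group} == {"iso1", "iso2"}

    def test_overlapping_planted_sites_rejected(self):
        sites = [
            PlantedSite(position=-50, retained=SPECIES5, lost=frozenset()),
            PlantedSite(position=-47, retained=SPECIES5, lost=frozenset()),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_promoters(planted_sites=sites, seed=0)

    def test_retained_lost_must_partition_species(self):
        sites = [PlantedSite(position=-50, retained=frozenset({"human"}),
                             lost=frozenset({"rat"}))]
        with pytest.raises(ValueError, match="partition"):
            simulate_promoters(planted_sites=sites, seed=0)

    def test_decaying_mode_keeps_site_in_root_lineage(self, wre):
        # with zero branch lengths the decaying site survives unchanged
        tree = "((a:0.0,b:0.0):0.0,c:0.0);"
        sites = [PlantedSite(position=-50, retained=frozenset("abc"),
                             lost=frozenset())]
        recs, _, _ = simulate_promoters(tree=tree, length=200,
                                        planted_sites=sites, seed=9,
                                        freeze_planted=False)
        for r in recs:
            assert r.sequence[r.upstream - 50:r.upstream - 43] == "TTCAAAG"


class TestSimulateExons:
    def test_nj_recovers_true_topology(self, five_species_tree_newick):
        import dendropy

        aligned, _ = simulate_exons(length=10_000, seed=13)
        filtered, _ = complete_deletion(aligned)
        dm = pairwise_distances(filtered, model="jc")
        t = nj_tree(dm)
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=to_newick(t), schema="newick",
                              taxon_namespace=tns)
        b = dendropy.Tree.get(data=five_species_tree_newick, schema="newick",
                              taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0

    def test_gap_column_bookkeeping(self):
        L = 2000
        aligned, _ = simulate_exons(length=L, seed=5, gap_column_fraction=0.1)
        _, usable = complete_deletion(aligned)
        assert usable == L - round(0.1 * L)

    def test_n_masking_removes_columns(self):
        aligned, _ = simulate_exons(length=1000, seed=5, mask_n_fraction=0.02)
        _, usable = complete_deletion(aligned)
        assert usable < 1000

    def test_same_seed_identical(self):
        a, _ = simulate_exons(seed=7)
        b, _ = simulate_exons(seed=7)
        assert a.members == b.members


def test_tn93_model_transition_bias():
    """TN93 with high kappa produces transition-rich divergence."""
    model = SubstitutionModel("TN93", kappa1=8.0, kappa2=8.0)
    recs, _, _ = simulate_promoters(tree="(a:0.15,b:0.0);", length=20_000,
                                    model=model, planted_sites=[], seed=2,
                                    scrub_background=False)
    seqs = {r.species: r.sequence for r in recs}
    purines, pyrimidines = {"A", "G"}, {"C", "T"}
    ts = tv = 0
    for x, y in zip(seqs["a"], seqs["b"]):
        if x == y:
            continue
        if {x, y} <= purines or {x, y} <= pyrimidines:
            ts += 1
        else:
            tv += 1
    # with kappa = 8 and equal frequencies, transitions dominate (R = 4)
    assert ts / tv > 2.0
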