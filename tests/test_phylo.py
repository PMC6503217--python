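import dendropy
import numpy as np
import pytest

from rhizospecies.io_core import DistanceMatrix
from rhizospecies.phylo import (
    MarkerAlignment,
    concatenate,
    extract_markers,
    filter_markers,
    genetic_distance,
    nj_tree,
    pairwise_distance,
    rf_distance,
    trim_columns,
)
from rhizospecies.synthetic_data import evolve_collection, plant_marker_hgt, simulate_tree

from .conftest import small_sim_config


class TestTrimColumns:
    def test_gap_free_alignment_unchanged(self):
        aln = MarkerAlignment("m", {"A": "MKVLE", "B": "MKVLD"})
        out = trim_columns(aln)
        assert out.rows == aln.rows

    def test_single_gap_removes_only_its_column(self):
        aln = MarkerAlignment("m", {"A": "MKVLEAHQW", "B": "MKVLEAH-W"})
        out = trim_columns(aln)
        assert out.rows["A"] == "MKVLEAHW"
        assert out.rows["B"] == "MKVLEAHW"[:7] + "W"

    @pytest.mark.parametrize("seed", range(5))
    def test_retained_count_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 4, 60
        rows = {}
        for g in "ABCD":
            chars = rng.choice(list("ACDEF-"), size=L)
            rows[g] = "".join(chars)
        aln = MarkerAlignment("m", rows)
        expected = sum(
            1 for i in range(L) if all(rows[g][i] != "-" for g in "ABCD")
        )
        if expected == 0:
            with pytest.raises(ValueError):
                trim_columns(aln)
        else:
            assert trim_columns(aln).length == expected

    def test_all_gapped_columns_is_an_error(self):
        aln = MarkerAlignment("m", {"A": "-A", "B": "A-"})
        with pytest.raises(ValueError):
            trim_columns(aln)


class TestPairwiseDistance:
    def test_identical_rows_give_zero(self):
        sm = concatenate([MarkerAlignment("m", {"A": "MKVLE" * 10, "B": "MKVLE" * 10})])
        dm = pairwise_distance(sm)
        assert dm.get("A", "B") == 0.0

    def test_closed_forms_at_ten_percent_difference(self):
        base = "ACDEFGHIKL" * 10
        other = "M" * 10 + base[10:]  # exactly 10% differing sites
        sm = concatenate([MarkerAlignment("m", {"A": base, "B": other})])
        p = 0.1
        d_poisson = pairwise_distance(sm, "poisson").get("A", "B")
        assert d_poisson == pytest.approx(-np.log(1 - p), abs=1e-12)
        d_kimura = pairwise_distance(sm, "kimura-protein").get("A", "B")
        assert d_kimura == pytest.approx(-np.log(1 - p - p * p / 5.0), abs=1e-12)

    def test_saturated_pair_is_flagged(self):
        sm = concatenate([MarkerAlignment("m", {"A": "AAAA", "B": "CCCC"})])
        dm = pairwise_distance(sm, "poisson")
        assert dm.saturated is not None and dm.saturated[0, 1]
        assert np.isnan(dm.values[0, 1])

    def test_simulated_divergence_recovered_within_error(self, clean_collection):
        genomes, truth = clean_collection
        dm, sm = genetic_distance(genomes, model="poisson")
        iu = np.triu_indices(len(dm.labels), 1)
        est = dm.values[iu]
        true = truth.true_pairwise_distance.values[iu]
        # protein distances are a monotone transform of nucleotide divergence
        assert np.corrcoef(est, true)[0, 1] > 0.95


class TestNeighborJoining:
    def _patristic(self, tree):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        labels = ("A", "B", "C", "D")
        vals = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )  # from ((A:1,B:2):1,(C:3,D:1))
        tree = nj_tree(DistanceMatrix(labels, vals))
        dist = self._patristic(tree)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert abs(dist(a, b) - vals[labels.index(a), labels.index(b)]) < 1e-9
        ref = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        assert rf_distance(tree, ref) == 0

    def test_three_taxa_solve_the_three_point_equations(self):
        labels = ("A", "B", "C")
        vals = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, vals))
        dist = self._patristic(tree)
        assert dist("A", "B") == pytest.approx(5.0, abs=1e-9)
        assert dist("A", "C") == pytest.approx(9.0, abs=1e-9)
        assert dist("B", "C") == pytest.approx(8.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_trees_recovered(self, seed):
        model = simulate_tree(8, 1.0, seed)
        pdm = model.phylogenetic_distance_matrix()
        taxa = sorted(model.taxon_namespace, key=lambda t: t.label)
        labels = tuple(t.label for t in taxa)
        n = len(labels)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        tree = nj_tree(DistanceMatrix(labels, vals))
        assert rf_distance(tree, model) == 0
        dist = self._patristic(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert abs(dist(labels[i], labels[j]) - vals[i, j]) < 1e-9

    def test_ultrametric_matrix_reproduces_the_model_topology(self):
        model = simulate_tree(10, 1.0, 42)  # ultrametric by construction
        pdm = model.phylogenetic_distance_matrix()
        taxa = sorted(model.taxon_namespace, key=lambda t: t.label)
        labels = tuple(t.label for t in taxa)
        vals = np.array(
            [[0 if i == j else pdm.patristic_distance(taxa[i], taxa[j]) for j in range(10)] for i in range(10)]
        )
        assert rf_distance(nj_tree(DistanceMatrix(labels, vals)), model) == 0

    def test_non_finite_entries_rejected(self):
        vals = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        dm = DistanceMatrix(("A", "B", "C"), vals, saturated=np.isnan(vals))
        with pytest.raises(ValueError):
            nj_tree(dm)


class TestRobinsonFoulds:
    def test_identical_topologies_give_zero(self):
        t = simulate_tree(12, 1.0, 3)
        assert rf_distance(t, t) == 0

    def test_distinct_quartets_differ_by_two(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick", taxon_namespace=t1.taxon_namespace)
        assert rf_distance(t1, t2) == 2

    def test_mismatched_leaf_sets_rejected(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(20))
    def test_agreement_with_dendropy_on_random_trees(self, seed):
        import random
        import dendropy.calculate.treecompare as tc

        rng = random.Random(seed)
        tns = dendropy.TaxonNamespace([f"T{j}" for j in range(8)])
        a = dendropy.simulate.treesim.uniform_pure_birth_tree(tns, birth_rate=1.0, rng=rng)
        b = dendropy.simulate.treesim.uniform_pure_birth_tree(tns, birth_rate=1.0, rng=rng)
        for t in (a, b):
            t.is_rooted = False
            t.update_bipartitions()
        assert rf_distance(a, b) == tc.symmetric_difference(a, b)


class TestMarkerExtraction:
    def test_clean_simulation_keeps_every_tagged_marker(self, clean_collection):
        genomes, truth = clean_collection
        markers = extract_markers(genomes, "ribosomal")
        assert len(markers) == truth.config.n_ribosomal
        for m in markers:
            assert sorted(m.rows) == sorted(g.genome_id for g in genomes)

    def test_marker_deleted_in_one_genome_is_dropped(self, clean_collection):
        import copy

        genomes, truth = clean_collection
        genomes = copy.deepcopy(genomes)
        victim = genomes[-1]
        fam = "F_CORE_0001"  # tagged ribosomal in the default plan
        for r in victim.replicons:
            r.genes = [g for g in r.genes if g.family_truth != fam]
        markers = extract_markers(genomes, "ribosomal")
        assert len(markers) == truth.config.n_ribosomal - 1
        assert all(m.family_id != fam for m in markers)

    def test_paralogous_extra_copy_drops_the_marker(self, clean_collection):
        import copy

        genomes, truth = clean_collection
        genomes = copy.deepcopy(genomes)
        victim = genomes[-1]
        chrom = victim.chromosome
        src = next(g for g in chrom.genes if g.family_truth == "F_CORE_0002")
        dup = copy.deepcopy(src)
        dup.gene_id = src.gene_id + "_dup"
        chrom.genes.append(dup)
        markers = extract_markers(genomes, "ribosomal")
        assert all(m.family_id != "F_CORE_0002" for m in markers)
        assert len(markers) == truth.config.n_ribosomal - 1


class TestMarkerCongruenceFilter:
    @staticmethod
    def _clean_run(seed):
        # shallow enough that every marker clears the 60% identity gate,
        # with long internal edges so per-marker trees are well resolved
        nwk = "(((G1:0.6,G2:0.6):0.7,G3:1.3):0.7,((G4:0.6,G5:0.6):0.7,G6:1.3):0.7);"
        cfg = small_sim_config(
            seed=seed, tree=nwk, n_genomes=6, subs_rate=0.05,
            n_core_genes=21, n_ribosomal=21, n_accessory_pool=0,
            gain_rate=0.0, loss_rate=0.0, psym_transfer_rate=0.0,
            chromosome_len=None, mean_gene_len=150,
        )
        return evolve_collection(cfg)

    def test_all_clean_markers_are_retained(self):
        genomes, _ = self._clean_run(101)
        markers = extract_markers(genomes, "ribosomal")
        res = filter_markers(markers)
        assert res.dropped == []
        assert res.supermatrix.length == sum(m.length for m in res.retained)

    def test_planted_cross_clade_transfer_is_dropped(self):
        genomes, _ = self._clean_run(102)
        planted = plant_marker_hgt(genomes, "F_CORE_0003", "G1", "G6")
        res = filter_markers(extract_markers(planted, "ribosomal"))
        assert "F_CORE_0003" in res.dropped

    def test_min_len_above_all_markers_is_an_error(self):
        genomes, _ = self._clean_run(103)
        markers = extract_markers(genomes, "ribosomal")
        with pytest.raises(ValueError):
            filter_markers(markers, min_len=10_000)

    def test_concatenation_order_never_changes_distances(self):
        genomes, _ = self._clean_run(104)
        markers = [trim_columns(m) for m in extract_markers(genomes, "ribosomal")]
        d1 = pairwise_distance(concatenate(markers))
        d2 = pairwise_distance(concatenate(list(reversed(markers))))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)
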