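import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizospecies.orthology import (
    align_proteins,
    bdbh,
    bray_curtis,
    cluster_proteomes,
    consensus_core,
    families_from_clusters,
    map_symbiotic,
    mcl_cluster,
    order_profiles,
    pangenome_curves,
)

from .conftest import truth_partition


# --- independent full-matrix Smith-Waterman oracle -------------------------

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(a: str, b: str, open_cost: float = 11.0, extend_cost: float = 1.0) -> float:
    """Exhaustive affine-gap local alignment DP (gap of length L costs
    open + (L-1)*extend), independent of the production aligner."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]))
            Ix[i, j] = max(M[i - 1, j] - open_cost, Ix[i - 1, j] - extend_cost)
            Iy[i, j] = max(M[i, j - 1] - open_cost, Iy[i, j - 1] - extend_cost)
            best = max(best, M[i, j])
    return best


def _random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestAlignProteins:
    def test_self_alignment_is_perfect(self):
        h = align_proteins("MKVLANDE", "MKVLANDE")
        assert h.pct_identity == 100.0
        assert h.query_cov == 100.0 and h.target_cov == 100.0

    def test_textbook_pair_matches_exhaustive_dp(self):
        assert align_proteins("HEAGAWGHEE", "PAWHEAE").score == sw_oracle("HEAGAWGHEE", "PAWHEAE")

    @pytest.mark.parametrize("seed", range(8))
    def test_random_pairs_match_exhaustive_dp(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_protein(rng, int(rng.integers(10, 40)))
        b = _random_protein(rng, int(rng.integers(10, 40)))
        assert align_proteins(a, b).score == pytest.approx(sw_oracle(a, b))

    def test_no_positive_scoring_pair_gives_empty_alignment(self):
        # W vs P scores -4 in BLOSUM62; no positive cell exists
        h = align_proteins("WWWW", "PPPP")
        assert h.score == 0.0
        assert h.query_cov == 0.0

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("MKV*", "MKV")
        with pytest.raises(ValueError):
            align_proteins("", "MKV")


class TestBdbh:
    @staticmethod
    def bdbh_oracle(proteomes, min_identity, min_coverage):
        """Exhaustive reciprocal-best enumeration (independent of bdbh's
        prefilter/caching path)."""
        edges = set()
        genomes = sorted(proteomes)
        for i, ga in enumerate(genomes):
            for gb in genomes[i + 1 :]:
                def best(qid, qseq, targets):
                    ranked = []
                    for tid, tseq in sorted(targets.items()):
                        h = align_proteins(qseq, tseq, qid, tid)
                        ranked.append((-h.score, -h.pct_identity, tid, h))
                    ranked.sort()
                    return ranked[0][3] if ranked else None

                for a_id, a_seq in sorted(proteomes[ga].items()):
                    h = best(a_id, a_seq, proteomes[gb])
                    if h is None or h.score <= 0:
                        continue
                    back = best(h.target_id, proteomes[gb][h.target_id], proteomes[ga])
                    if back is None or back.target_id != a_id:
                        continue
                    if h.pct_identity >= min_identity and min(h.query_cov, h.target_cov) >= min_coverage:
                        edges.add(frozenset((a_id, h.target_id)))
        return edges

    def test_identical_proteomes_pair_perfectly(self):
        rng = np.random.default_rng(1)
        prots = {f"p{i}": _random_protein(rng, 50) for i in range(5)}
        proteomes = {"A": {f"A|{k}": v for k, v in prots.items()}, "B": {f"B|{k}": v for k, v in prots.items()}}
        g = bdbh(proteomes, use_score_floor=False)
        assert g.number_of_edges() == 5
        for u, v in g.edges:
            assert u.split("|")[1] == v.split("|")[1]

    def test_toy_proteomes_with_paralogs_match_the_oracle(self):
        rng = np.random.default_rng(5)
        fams = [_random_protein(rng, 60) for _ in range(4)]

        def mutate(p, k):
            p = list(p)
            for i in rng.choice(len(p), size=k, replace=False):
                p[i] = _random_protein(rng, 1)
            return "".join(p)

        proteomes = {}
        for gn in ("A", "B", "C"):
            prots = {f"{gn}|f{i}": mutate(f, 6) for i, f in enumerate(fams)}
            proteomes[gn] = prots
        # one paralog pair in genome A
        proteomes["A"]["A|f0b"] = mutate(fams[0], 8)
        g = bdbh(proteomes, min_identity=50, min_coverage=50, use_score_floor=False)
        got = {frozenset(e) for e in g.edges}
        assert got == self.bdbh_oracle(proteomes, 50, 50)

    def test_weak_best_hit_below_identity_gate_is_dropped(self):
        rng = np.random.default_rng(9)
        base = _random_protein(rng, 60)
        # ~40% identity copy: mutate 60% of positions
        mut = list(base)
        for i in rng.choice(60, size=36, replace=False):
            mut[i] = _random_protein(rng, 1)
        proteomes = {"A": {"A|x": base}, "B": {"B|x": "".join(mut)}}
        g = bdbh(proteomes, min_identity=50, use_score_floor=False, prefilter=False)
        assert g.number_of_edges() == 0


class TestMcl:
    def test_two_disconnected_cliques_are_two_clusters(self):
        g = nx.Graph()
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            g.add_edge(a, b, weight=1.0)
        res = mcl_cluster(g)
        assert res.converged
        assert res.clusters == [frozenset({0, 1, 2}), frozenset({3, 4, 5})]

    def test_barbell_with_weak_bridge_splits_into_triangles(self):
        g = nx.Graph()
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            g.add_edge(a, b, weight=1.0)
        g.add_edge(2, 3, weight=0.1)  # 10:1 weight ratio bridge
        res = mcl_cluster(g, inflation=1.5)
        assert res.clusters == [frozenset({0, 1, 2}), frozenset({3, 4, 5})]

    def test_single_node_is_a_singleton_cluster(self):
        g = nx.Graph()
        g.add_node("only")
        assert mcl_cluster(g).clusters == [frozenset({"only"})]

    @pytest.mark.parametrize("seed", range(10))
    def test_node_order_permutation_never_changes_the_partition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        g = nx.gnp_random_graph(n, 0.35, seed=seed)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.5, 2.0))
        base = set(mcl_cluster(g).clusters)
        perm = rng.permutation(n)
        mapping = {i: f"n{perm[i]:02d}" for i in range(n)}
        h = nx.relabel_nodes(g, mapping)
        relabeled = set(mcl_cluster(h).clusters)
        inverse = {v: k for k, v in mapping.items()}
        assert {frozenset(inverse[x] for x in c) for c in relabeled} == base


class TestFamiliesAndConsensusCore:
    def test_clean_simulation_clusters_recover_truth_exactly(self, clean_collection):
        genomes, truth = clean_collection
        proteomes = {g.genome_id: g.proteome() for g in genomes}
        ft = cluster_proteomes(proteomes, "mcl")
        assert set(ft.families.values()) == truth_partition(genomes)

    def test_consensus_core_on_clean_simulation_counts_all_plan_families(self, clean_collection):
        genomes, truth = clean_collection
        proteomes = {g.genome_id: g.proteome() for g in genomes}
        ft_mcl = cluster_proteomes(proteomes, "mcl")
        ft_bdbh = cluster_proteomes(proteomes, "bdbh")
        core = consensus_core(ft_bdbh, ft_mcl, sorted(proteomes))
        # every root-plan family is universal single-copy in a clean run
        n_plan = len(truth.family_table)
        assert core.n_families == n_plan

    def test_family_absent_from_one_genome_is_not_core(self):
        gene_genome = {"a1": "A", "b1": "B", "a2": "A"}
        full = frozenset({"a1", "b1"})
        partial = frozenset({"a2"})
        core = consensus_core([full, partial], [full, partial], ["A", "B"], gene_genome)
        assert set(core.families.values()) == {full}

    def test_family_split_differently_by_the_two_methods_is_excluded(self):
        gene_genome = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        bdbh_fams = [frozenset({"a1", "b1"}), frozenset({"a2", "b2"})]
        mcl_fams = [frozenset({"a1", "b2"}), frozenset({"a2", "b1"})]
        core = consensus_core(bdbh_fams, mcl_fams, ["A", "B"], gene_genome)
        assert core.n_families == 0


class TestPangenomeCurves:
    def test_first_point_equals_single_genome_family_count(self):
        pa = pd.DataFrame([[1, 1], [1, 0], [0, 1]], index=list("fgh"), columns=["A", "B"])
        curves = pangenome_curves(pa, n_perm=5, seed=0)
        assert curves.core_per_perm[:, 0].tolist() == curves.pan_per_perm[:, 0].tolist()

    def test_identical_genomes_flatten_both_curves(self):
        pa = pd.DataFrame(np.ones((10, 4), dtype=int), columns=list("ABCD"))
        curves = pangenome_curves(pa, n_perm=5, seed=1)
        assert np.all(curves.core_median == 10)
        assert np.all(curves.pan_median == 10)
        assert abs(curves.heaps_gamma) < 1e-9

    def test_monotone_in_every_permutation_and_open_when_gain_positive(self, sim_collection):
        genomes, _ = sim_collection
        proteomes = {g.genome_id: g.proteome() for g in genomes}
        pa = cluster_proteomes(proteomes, "mcl").presence_absence()
        curves = pangenome_curves(pa, n_perm=10, seed=2)
        assert np.all(np.diff(curves.core_per_perm, axis=1) <= 0)
        assert np.all(np.diff(curves.pan_per_perm, axis=1) >= 0)
        assert curves.heaps_gamma > 0
        assert np.all(np.diff(curves.pan_median) >= 0)

    def test_plasmid_restricted_core_smaller_than_chromosome_restricted(self, sim_collection):
        genomes, _ = sim_collection
        on_chr = set()
        on_plasmid = set()
        for g in genomes:
            for r in g.replicons:
                for gene in r.genes:
                    (on_chr if r.kind == "chromosome" else on_plasmid).add(gene.family_truth)
        # accessory turnover targets the plasmid compartment in the simulator
        proteomes = {g.genome_id: g.proteome() for g in genomes}
        ft = cluster_proteomes(proteomes, "mcl")
        pa = ft.presence_absence()
        fam_label = {fid: next(iter(genes)).split("|")[1] for fid, genes in ft.families.items()}
        chr_rows = [f for f in pa.index if fam_label[f] in on_chr and fam_label[f] not in on_plasmid]
        pl_rows = [f for f in pa.index if fam_label[f] in on_plasmid]
        core_chr = int((pa.loc[chr_rows].sum(axis=1) == pa.shape[1]).sum())
        core_pl = int((pa.loc[pl_rows].sum(axis=1) == pa.shape[1]).sum())
        frac_chr = core_chr / max(len(chr_rows), 1)
        frac_pl = core_pl / max(len(pl_rows), 1)
        assert frac_pl < frac_chr


class TestSymbioticMapping:
    def test_tagged_references_recover_truth_presence(self, sim_collection):
        genomes, truth = sim_collection
        proteomes = {g.genome_id: g.proteome() for g in genomes}
        refs = {}
        for g in genomes:
            for gene in g.genes():
                if "symbiotic" in gene.role_tags:
                    refs.setdefault(gene.family_truth, gene.protein)
        profile = map_symbiotic(proteomes, refs)
        # psym plan families are carried by every genome (transfers replace,
        # never delete, the symbiotic plasmid)
        assert profile.to_numpy().all()

    def test_duplicate_references_collapse(self):
        rng = np.random.default_rng(3)
        seq = _random_protein(rng, 60)
        other = _random_protein(rng, 60)
        proteomes = {"A": {"A|x": seq}, "B": {"B|x": seq}}
        profile = map_symbiotic(proteomes, {"r1": seq, "r2": seq, "r3": other})
        assert profile.shape[0] == 2  # r1+r2 collapse, r3 separate

    def test_reference_without_hits_gives_all_zero_row(self):
        rng = np.random.default_rng(4)
        seq = _random_protein(rng, 60)
        stranger = _random_protein(rng, 60)
        proteomes = {"A": {"A|x": seq}, "B": {"B|x": seq}}
        profile = map_symbiotic(proteomes, {"hit": seq, "miss": stranger})
        assert profile.loc["miss"].sum() == 0
        assert profile.loc["hit"].sum() == 2


class TestProfiles:
    def test_bray_curtis_hand_values(self):
        assert bray_curtis([1, 1, 0], [1, 1, 0]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0
        assert bray_curtis([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_bray_curtis_undefined_for_zero_profiles(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_identical_columns_join_first_at_height_zero(self):
        pa = pd.DataFrame(
            {"A": [1, 1, 0], "B": [1, 1, 0], "C": [0, 0, 1]}, index=list("fgh")
        )
        order, linkage = order_profiles(pa)
        assert linkage[0, 2] == 0.0  # first merge at zero dissimilarity
        ia, ib = order.index("A"), order.index("B")
        assert abs(ia - ib) == 1

    def test_two_clade_collection_orders_into_monophyletic_blocks(self):
        rng = np.random.default_rng(6)
        block = np.zeros((40, 6), dtype=int)
        block[:20, :3] = 1
        block[20:, 3:] = 1
        flip = rng.random((40, 6)) < 0.05
        pa = pd.DataFrame(np.clip(block + flip, 0, 1).astype(int), columns=["A1", "A2", "A3", "B1", "B2", "B3"])
        order, _ = order_profiles(pa)
        labels = [o[0] for o in order]
        assert labels in (["A"] * 3 + ["B"] * 3, ["B"] * 3 + ["A"] * 3)

    def test_ordering_is_stable_across_runs(self, sim_collection):
        genomes, _ = sim_collection
        proteomes = {g.genome_id: g.proteome() for g in genomes}
        pa = cluster_proteomes(proteomes, "mcl").presence_absence()
        assert order_profiles(pa)[0] == order_profiles(pa)[0]
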