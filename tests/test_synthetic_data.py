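import numpy as np
import pytest

from rhizospecies.io_core import translate_cds
from rhizospecies.ks_transfer import ks_ng86
from rhizospecies.synthetic_data import (
    SimConfig,
    count_synonymous_sites,
    evolve_cds_synonymous,
    evolve_collection,
    jc_pair,
    random_cds,
    decode_dna,
    simulate_tree,
    synonymous_cds_pair,
    yule_leaf_count,
)
from .conftest import small_sim_config


def jc_identity(d: float) -> float:
    return 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)


class TestSimulateTree:
    def test_two_leaves_form_an_ultrametric_cherry(self):
        t = simulate_tree(2, 1.0, 0)
        leaves = list(t.leaf_node_iter())
        assert len(leaves) == 2
        d = [lf.distance_from_root() for lf in leaves]
        assert abs(d[0] - d[1]) < 1e-12

    def test_determinism_given_seed(self):
        a = simulate_tree(16, 1.0, 5).as_string(schema="newick")
        b = simulate_tree(16, 1.0, 5).as_string(schema="newick")
        assert a == b

    def test_rejects_fewer_than_two_leaves(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 1.0, 0)

    def test_yule_growth_matches_exponential_expectation(self):
        # pure birth from one lineage: E[N(t)] = exp(lambda t)
        rng = np.random.default_rng(42)
        lam, t = 1.0, 1.5
        counts = [yule_leaf_count(t, lam, rng) for _ in range(1000)]
        expected = np.exp(lam * t)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se + 0.05 * expected


class TestEvolveCollection:
    def test_zero_rates_and_zero_branch_lengths_reproduce_the_root(self):
        nwk = "(A:0.0,B:0.0,C:0.0);"
        cfg = small_sim_config(seed=1, tree=nwk, n_genomes=3, gain_rate=0, loss_rate=0, psym_transfer_rate=0)
        genomes, truth = evolve_collection(cfg)
        seqs = [tuple(r.sequence for r in g.replicons) for g in genomes]
        assert seqs[0] == seqs[1] == seqs[2]
        assert np.all(truth.true_pairwise_distance.values == 0)

    def test_byte_identical_outputs_for_identical_config(self):
        g1, t1 = evolve_collection(small_sim_config(seed=77))
        g2, t2 = evolve_collection(small_sim_config(seed=77))
        for a, b in zip(g1, g2):
            assert a.genome_id == b.genome_id
            for ra, rb in zip(a.replicons, b.replicons):
                assert ra.sequence == rb.sequence
        assert t1.family_table == t2.family_table
        assert [
            (e.donor, e.recipient, e.time) for e in t1.transfer_events
        ] == [(e.donor, e.recipient, e.time) for e in t2.transfer_events]

    def test_true_distances_equal_rate_times_path_length(self, sim_collection):
        genomes, truth = sim_collection
        pdm = truth.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in truth.tree.taxon_namespace}
        ids = truth.genome_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                expected = pdm.patristic_distance(taxa[a], taxa[b]) * truth.config.subs_rate
                assert abs(truth.true_pairwise_distance.get(a, b) - expected) < 1e-12

    def test_realized_identity_matches_jc69_closed_form(self):
        d = 0.05
        a, b = jc_pair(50_000, d, 7)
        sa = np.frombuffer(a.replicons[0].sequence.encode(), np.uint8)
        sb = np.frombuffer(b.replicons[0].sequence.encode(), np.uint8)
        ident = float((sa == sb).mean())
        expected = jc_identity(d)
        # binomial error on 50 kb plus Poisson noise in the substitution count
        assert abs(ident - expected) < 4 * np.sqrt(expected * (1 - expected) / 50_000) + 0.002

    def test_no_transfers_means_psym_divergence_equals_chromosomal(self):
        cfg = small_sim_config(seed=5, psym_transfer_rate=0.0)
        _, truth = evolve_collection(cfg)
        assert truth.transfer_events == []
        np.testing.assert_allclose(
            truth.psym_distance.values, truth.true_pairwise_distance.values, atol=1e-12
        )

    def test_last_transfer_leaves_donor_and_recipient_psyms_young(self):
        # force a high transfer rate so at least one event lands
        cfg = small_sim_config(seed=3, psym_transfer_rate=1.0)
        _, truth = evolve_collection(cfg)
        assert truth.transfer_events
        last = truth.transfer_events[-1]
        depth = max(
            lf.distance_from_root() for lf in truth.tree.leaf_node_iter()
        )
        expected = 2.0 * (depth - last.time) * truth.config.subs_rate
        # every donor-descendant/recipient-descendant pair coalesced at the event
        for a in sorted(last.donor_leaves):
            for b in sorted(last.recipient_leaves):
                got = truth.psym_distance.get(a, b)
                assert got <= expected + 1e-9
        # and for at least one such pair the pSym is younger than the species split
        pairs = [(a, b) for a in last.donor_leaves for b in last.recipient_leaves]
        assert any(
            truth.psym_distance.get(a, b) < truth.true_pairwise_distance.get(a, b) - 1e-12
            for a, b in pairs
        )

    def test_accessory_content_approaches_gain_loss_equilibrium(self):
        # k* = gain*pool / (gain + loss) per genome, reached on a deep star tree
        gain, loss, pool = 0.5, 1.0, 30
        depth = 6.0
        nwk = "(" + ",".join(f"L{i}:{depth}" for i in range(6)) + ");"
        cfg = small_sim_config(
            seed=13, tree=nwk, n_genomes=6, gain_rate=gain, loss_rate=loss,
            n_accessory_pool=pool, psym_transfer_rate=0.0, subs_rate=0.001,
        )
        genomes, _ = evolve_collection(cfg)
        counts = [
            sum(1 for g in gen.genes() if g.family_truth.startswith("F_ACC")) for gen in genomes
        ]
        k_star = gain * pool / (gain + loss)
        se = np.std(counts) / np.sqrt(len(counts)) + 1e-9
        assert abs(np.mean(counts) - k_star) < max(4 * se, 0.35 * k_star)

    def test_core_genes_are_never_lost(self, sim_collection):
        genomes, truth = sim_collection
        for g in genomes:
            fams = {x.family_truth for x in g.genes()}
            assert all(f"F_CORE_{i + 1:04d}" in fams for i in range(truth.config.n_core_genes))


class TestSynonymousEvolution:
    def test_synonymous_evolution_preserves_the_protein(self):
        rng = np.random.default_rng(0)
        root = decode_dna(random_cds(200, rng))
        evolved = evolve_cds_synonymous(root, 0.5, rng)
        assert translate_cds(evolved) == translate_cds(root)

    def test_fourfold_pairs_recover_the_generating_ks(self):
        rng = np.random.default_rng(8)
        vals = [
            ks_ng86(*synonymous_cds_pair(300, 0.2, rng, fourfold_only=True)).ks for _ in range(60)
        ]
        med = float(np.median(vals))
        assert abs(med - 0.2) / 0.2 < 0.08

    def test_site_counts_positive_for_random_cds(self):
        rng = np.random.default_rng(1)
        s = count_synonymous_sites(decode_dna(random_cds(100, rng)))
        assert 40 < s < 120  # roughly 0.7 synonymous sites per sense codon


class TestConfigValidation:
    def test_invalid_configs_are_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genomes=1).validate()
        with pytest.raises(ValueError):
            SimConfig(n_core_genes=0).validate()
        with pytest.raises(ValueError):
            small_sim_config(plasmid_plan=[]).validate()
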