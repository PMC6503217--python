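import numpy as np
import pytest

from rhizospecies.synthetic_data import PlasmidPlan, SimConfig, evolve_collection


def small_sim_config(seed: int = 11, **overrides) -> SimConfig:
    """Desk-scale study conditions reused across tests: 6 genomes, short
    replicons, accessory turnover and occasional pSym transfer."""
    kwargs = dict(
        n_genomes=6,
        seed=seed,
        subs_rate=0.02,
        n_core_genes=20,
        n_ribosomal=8,
        n_accessory_pool=20,
        gain_rate=0.1,
        loss_rate=0.3,
        psym_transfer_rate=0.3,
        chromosome_len=20_000,
        mean_gene_len=150,
        plasmid_plan=[
            PlasmidPlan("plasmid", 5, 8_000),
            PlasmidPlan("psym", 10, 12_000),
        ],
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_collection():
    return evolve_collection(small_sim_config())


@pytest.fixture(scope="session")
def clean_collection():
    """No gene turnover, no transfer: family truth equals the root plan."""
    return evolve_collection(
        small_sim_config(seed=23, gain_rate=0.0, loss_rate=0.0, psym_transfer_rate=0.0)
    )


def truth_partition(genomes) -> set[frozenset]:
    """Ground-truth gene partition from the simulator's family labels."""
    part: dict[str, set] = {}
    for g in genomes:
        for gene in g.genes():
            part.setdefault(gene.family_truth, set()).add(gene.gene_id)
    return {frozenset(v) for v in part.values()}


def rng_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(master).integers(0, 2**31 - 1, size=n)]
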