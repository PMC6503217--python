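"""Genome-evolution simulator producing collections with known ground truth.

The simulator grows a clonal species tree (Yule, or user-supplied Newick),
builds a root genome (chromosome carrying core genes, several plasmids, one
symbiotic plasmid carrying nodABC/nifHDK analogs and Rep replication
proteins), and evolves it forward in time:

* nucleotide substitutions as a Poisson process, Jukes-Cantor (JC69):
  uniform sites, uniform choice among the three alternative bases, multiple
  hits allowed.  Inside annotated genes, mutations that would create an
  internal stop codon are rejected (nonsense purifying selection), so CDSs
  stay translatable.
* accessory gene gain (from a finite pool of uniquely labelled families)
  and loss as Poisson events; core and replicon-plan genes are exempt from
  loss.
* symbiotic-plasmid (pSym) transfer: at Poisson times a random donor
  lineage's entire pSym replaces a random recipient's, after which the two
  copies diverge again.

Ground truth (:class:`SimTruth`) records the tree, exact expected pairwise
distances per compartment, the gene family table, and every transfer event.
All randomness flows from a single seed; identical configs give identical
collections.
"""

from __future__ import annotations

import copy
from bisect import bisect_right
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_core import (
    DistanceMatrix,
    GeneRecord,
    GenomeRecord,
    RepliconRecord,
    get_logger,
    translate_cds,
)

_log = get_logger("synthetic_data")

# --- 2-bit DNA codec -------------------------------------------------------

_ALPHABET = "ACGT"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)

STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA (table 11)

_NONSTOP = np.array(
    [(a, b, c) for a in range(4) for b in range(4) for c in range(4) if (a, b, c) not in STOP_CODONS],
    dtype=np.uint8,
)


def encode_dna(seq: str) -> np.ndarray:
    codes = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode_dna(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random codons over the 61 sense codons (no stops)."""
    idx = rng.integers(0, len(_NONSTOP), size=n_codons)
    return _NONSTOP[idx].reshape(-1)


def random_dna(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


# --- configuration ---------------------------------------------------------


@dataclass
class PlasmidPlan:
    kind: str  # chromid | plasmid | psym
    n_genes: int
    length: int | None = None  # None: genes + 30% spacer


def default_plasmid_plan() -> list[PlasmidPlan]:
    return [
        PlasmidPlan("chromid", 12, 30_000),
        PlasmidPlan("plasmid", 10, 25_000),
        PlasmidPlan("psym", 18, 40_000),
    ]


@dataclass
class SimConfig:
    """Study conditions for one simulated collection.

    Rates are per unit branch length (the tree's time unit); ``subs_rate``
    converts branch length to expected substitutions per site.
    """

    n_genomes: int = 12
    tree: str | None = None  # Newick; when None a Yule tree is grown
    birth_rate: float = 1.0
    subs_rate: float = 0.02
    n_core_genes: int = 80
    n_ribosomal: int = 58  # core genes tagged as ribosomal markers
    n_accessory_pool: int = 100
    gain_rate: float = 0.1
    loss_rate: float = 0.3
    plasmid_plan: list[PlasmidPlan] = field(default_factory=default_plasmid_plan)
    psym_transfer_rate: float = 0.0
    mean_gene_len: int = 200  # codons
    chromosome_len: int | None = None  # None: genes + 30% spacer
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_core_genes < 1:
            raise ValueError("n_core_genes must be >= 1")
        for r in (self.subs_rate, self.gain_rate, self.loss_rate, self.psym_transfer_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        n_psym = sum(1 for p in self.plasmid_plan if p.kind == "psym")
        if n_psym != 1:
            raise ValueError(f"plasmid_plan must contain exactly one psym entry (got {n_psym})")


@dataclass
class TransferEvent:
    donor: str  # lineage label (head-node id / leaf label at event time)
    recipient: str
    time: float
    donor_leaves: frozenset[str] = frozenset()
    recipient_leaves: frozenset[str] = frozenset()


@dataclass
class SimTruth:
    tree: dendropy.Tree
    genome_ids: tuple[str, ...]
    true_pairwise_distance: DistanceMatrix  # chromosomal (species) expected subs/site
    psym_distance: DistanceMatrix | None
    family_table: dict[str, set[str]]  # family -> genomes carrying it
    transfer_events: list[TransferEvent]
    config: SimConfig


# --- Yule trees ------------------------------------------------------------


def simulate_tree(n: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with ``n`` leaves.

    The root splits at time 0; each subsequent split waits Exp(k*lambda);
    after the n-th lineage appears, a final Exp(n*lambda) stretch is added so
    leaf edges have positive length. Deterministic given the seed.
    """
    if n < 2:
        raise ValueError("need n >= 2 leaves")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    # active lineages: (parent_node, birth_time)
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(0, k))
        parent, t0 = active.pop(i)
        v = dendropy.Node()
        parent.add_child(v)
        v.edge.length = t - t0
        active.append((v, t))
        active.append((v, t))
        k += 1
    depth = t + rng.exponential(1.0 / (n * birth_rate))
    width = len(str(n))
    for j, (parent, t0) in enumerate(active):
        leaf = dendropy.Node()
        parent.add_child(leaf)
        leaf.edge.length = depth - t0
        label = f"G{j + 1:0{width}d}"
        leaf.taxon = taxon_namespace.new_taxon(label)
    return tree


def yule_leaf_count(t_max: float, birth_rate: float, rng: np.random.Generator) -> int:
    """Number of lineages at time ``t_max`` under a pure-birth process
    started from one lineage (E = exp(lambda*t))."""
    k, t = 1, 0.0
    while True:
        t += rng.exponential(1.0 / (k * birth_rate))
        if t > t_max:
            return k
        k += 1


def planted_clades_newick(
    n_clades: int, n_per_clade: int, d_within: float, d_between: float, subs_rate: float
) -> tuple[str, dict[str, str]]:
    """Multifurcating ultrametric tree with ``n_clades`` star clades.

    Every within-clade leaf pair sits at expected distance ``d_within``
    (subs/site at the given ``subs_rate``), every between-clade pair at
    ``d_between``. Returns (newick, leaf -> clade label map).
    """
    depth = d_between / (2.0 * subs_rate)
    tip = d_within / (2.0 * subs_rate)
    if tip > depth:
        raise ValueError("d_within must be <= d_between")
    clades = []
    clade_of: dict[str, str] = {}
    for c in range(n_clades):
        label = chr(ord("A") + c)
        leaves = []
        for i in range(n_per_clade):
            leaf = f"{label}{i + 1}"
            leaves.append(f"{leaf}:{tip:.10f}")
            clade_of[leaf] = label
        clades.append(f"({','.join(leaves)}):{depth - tip:.10f}")
    return f"({','.join(clades)});", clade_of


# --- internal evolving state ----------------------------------------------


@dataclass
class _GeneMeta:
    family: str
    start: int
    end: int
    tags: tuple[str, ...]
    core: bool  # exempt from loss


class _RepState:
    __slots__ = ("name", "kind", "seq", "genes")

    def __init__(self, name: str, kind: str, seq: np.ndarray, genes: list[_GeneMeta]):
        self.name = name
        self.kind = kind
        self.seq = seq
        self.genes = genes  # sorted by start, non-overlapping

    def clone(self) -> "_RepState":
        return _RepState(self.name, self.kind, self.seq.copy(), [copy.copy(g) for g in self.genes])

    def gene_at(self, pos: int) -> _GeneMeta | None:
        starts = [g.start for g in self.genes]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and self.genes[i].start <= pos < self.genes[i].end:
            return self.genes[i]
        return None

    def append_gene(self, family: str, seq: np.ndarray, tags: tuple[str, ...], core: bool) -> None:
        start = len(self.seq)
        self.seq = np.concatenate([self.seq, seq])
        self.genes.append(_GeneMeta(family, start, start + len(seq), tags, core))

    def remove_gene(self, family: str) -> None:
        for i, g in enumerate(self.genes):
            if g.family == family:
                width = g.end - g.start
                self.seq = np.concatenate([self.seq[: g.start], self.seq[g.end :]])
                del self.genes[i]
                for h in self.genes[i:]:
                    h.start -= width
                    h.end -= width
                return
        raise KeyError(family)


class _PsymNode:
    """Node in the pSym copy genealogy (created at speciations and transfers)."""

    __slots__ = ("parent", "time")

    def __init__(self, parent: "_PsymNode | None", time: float):
        self.parent = parent
        self.time = time


class _Lineage:
    __slots__ = ("reps", "accessory", "psym_node", "last_t", "label")

    def __init__(self, reps, accessory, psym_node, last_t, label):
        self.reps: list[_RepState] = reps
        self.accessory: dict[str, str] = accessory  # family -> replicon name
        self.psym_node: _PsymNode | None = psym_node
        self.last_t: float = last_t
        self.label: str = label

    def clone(self, label: str) -> "_Lineage":
        return _Lineage([r.clone() for r in self.reps], dict(self.accessory), self.psym_node, self.last_t, label)

    def rep(self, name: str) -> _RepState:
        for r in self.reps:
            if r.name == name:
                return r
        raise KeyError(name)

    def psym_rep(self) -> _RepState | None:
        for r in self.reps:
            if r.kind == "psym":
                return r
        return None


def _apply_substitutions(rep: _RepState, n: int, rng: np.random.Generator) -> None:
    if n == 0 or len(rep.seq) == 0:
        return
    positions = rng.integers(0, len(rep.seq), size=n)
    shifts = rng.integers(1, 4, size=n)
    starts = [g.start for g in rep.genes]
    for p, s in zip(positions, shifts):
        p = int(p)
        new = np.uint8((int(rep.seq[p]) + int(s)) % 4)
        i = bisect_right(starts, p) - 1
        g = rep.genes[i] if (i >= 0 and rep.genes[i].start <= p < rep.genes[i].end) else None
        if g is not None:
            off = (p - g.start) % 3
            c0 = p - off
            codon = [int(rep.seq[c0]), int(rep.seq[c0 + 1]), int(rep.seq[c0 + 2])]
            codon[off] = int(new)
            if tuple(codon) in STOP_CODONS:
                continue  # nonsense mutation rejected
        rep.seq[p] = new


# --- root genome -----------------------------------------------------------


@dataclass
class _Pool:
    families: list[str]
    sequences: dict[str, np.ndarray]


def _gene_length(mean_codons: int, rng: np.random.Generator) -> int:
    # modest size variation around the mean, >= 50 codons
    n = int(rng.normal(mean_codons, mean_codons * 0.15))
    return max(50, n)


def _layout_replicon(
    name: str,
    kind: str,
    families: list[tuple[str, tuple[str, ...], bool]],
    planned_length: int | None,
    mean_gene_len: int,
    rng: np.random.Generator,
) -> _RepState:
    """Place genes separated by neutral spacers, filling to planned_length."""
    genes_seq = [random_cds(_gene_length(mean_gene_len, rng), rng) for _ in families]
    total_genes = sum(len(s) for s in genes_seq)
    if planned_length is None:
        planned_length = int(total_genes * 1.3)
    spacer_total = max(planned_length - total_genes, len(families) + 1)
    n_gaps = len(families) + 1
    base = spacer_total // n_gaps
    extra = spacer_total - base * n_gaps
    parts: list[np.ndarray] = []
    metas: list[_GeneMeta] = []
    pos = 0
    for i, ((fam, tags, core), gseq) in enumerate(zip(families, genes_seq)):
        gap = base + (1 if i < extra else 0)
        parts.append(random_dna(gap, rng))
        pos += gap
        parts.append(gseq)
        metas.append(_GeneMeta(fam, pos, pos + len(gseq), tags, core))
        pos += len(gseq)
    parts.append(random_dna(base, rng))
    return _RepState(name, kind, np.concatenate(parts) if parts else np.zeros(0, np.uint8), metas)


_NODNIF = ("nodA", "nodB", "nodC", "nifH", "nifD", "nifK")


def _build_root(config: SimConfig, rng: np.random.Generator) -> tuple[list[_RepState], _Pool]:
    reps: list[_RepState] = []
    core_fams = []
    for i in range(config.n_core_genes):
        tags: tuple[str, ...] = ("core",)
        if i < config.n_ribosomal:
            tags = ("core", "ribosomal")
        core_fams.append((f"F_CORE_{i + 1:04d}", tags, True))
    reps.append(
        _layout_replicon("chr", "chromosome", core_fams, config.chromosome_len, config.mean_gene_len, rng)
    )
    counters = {"chromid": 0, "plasmid": 0, "psym": 0}
    for plan in config.plasmid_plan:
        counters[plan.kind] += 1
        name = plan.kind if counters[plan.kind] == 1 else f"{plan.kind}{counters[plan.kind]}"
        fams: list[tuple[str, tuple[str, ...], bool]] = [
            (f"F_{name.upper()}_repC", ("repC",), True),
            (f"F_{name.upper()}_repB", ("repB",), True),
        ]
        n_rest = plan.n_genes - 2
        if plan.kind == "psym":
            for tag in _NODNIF:
                fams.append((f"F_PSYM_{tag}", (tag, "symbiotic"), True))
            n_rest -= len(_NODNIF)
        for i in range(max(n_rest, 0)):
            tag = ("symbiotic",) if plan.kind == "psym" else ()
            fams.append((f"F_{name.upper()}_{i + 1:03d}", tag, True))
        reps.append(_layout_replicon(name, plan.kind, fams, plan.length, config.mean_gene_len, rng))
    pool_fams = [f"F_ACC_{i + 1:04d}" for i in range(config.n_accessory_pool)]
    pool = _Pool(pool_fams, {f: random_cds(_gene_length(config.mean_gene_len, rng), rng) for f in pool_fams})
    return reps, pool


def _accessory_target(reps: list[_RepState]) -> str:
    for kind in ("plasmid", "chromid", "chromosome"):
        for r in reps:
            if r.kind == kind:
                return r.name
    raise ValueError("no replicon")


# --- evolution sweep -------------------------------------------------------


def _advance(lin: _Lineage, t_to: float, rng: np.random.Generator, config: SimConfig, pool: _Pool) -> None:
    dt = t_to - lin.last_t
    if dt < -1e-12:
        raise RuntimeError("time went backwards")
    if dt <= 0:
        lin.last_t = t_to
        return
    # gain/loss intensities depend on current content, so long branches are
    # substepped to keep the per-family event probability small per step
    turnover = max(config.gain_rate, config.loss_rate)
    n_steps = max(1, int(np.ceil(dt * turnover / 0.05))) if turnover > 0 else 1
    step = dt / n_steps
    for _ in range(n_steps):
        # gains first (gained genes then accumulate substitutions over the
        # step: a mild over-divergence of very young genes)
        if config.gain_rate > 0 and pool.families:
            absent = [f for f in pool.families if f not in lin.accessory]
            n_gain = rng.poisson(config.gain_rate * len(absent) * step)
            if n_gain > 0 and absent:
                picked = rng.choice(len(absent), size=min(n_gain, len(absent)), replace=False)
                target = _accessory_target(lin.reps)
                for j in sorted(int(i) for i in picked):
                    fam = absent[j]
                    lin.rep(target).append_gene(fam, pool.sequences[fam].copy(), (), core=False)
                    lin.accessory[fam] = target
        for rep in lin.reps:
            n = rng.poisson(len(rep.seq) * config.subs_rate * step)
            _apply_substitutions(rep, n, rng)
        if config.loss_rate > 0 and lin.accessory:
            present = sorted(lin.accessory)
            n_loss = rng.poisson(config.loss_rate * len(present) * step)
            if n_loss > 0:
                picked = rng.choice(len(present), size=min(n_loss, len(present)), replace=False)
                for j in sorted(int(i) for i in picked):
                    fam = present[j]
                    lin.rep(lin.accessory[fam]).remove_gene(fam)
                    del lin.accessory[fam]
    lin.last_t = t_to


def _node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    ages: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            ages[node] = 0.0
        else:
            ages[node] = ages[node.parent_node] + (node.edge.length or 0.0)
    return ages


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def evolve_collection(config: SimConfig) -> tuple[list[GenomeRecord], SimTruth]:
    """Simulate a genome collection under ``config``; returns (genomes, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.tree is not None:
        tree = dendropy.Tree.get(data=config.tree, schema="newick")
    else:
        tree = simulate_tree(config.n_genomes, config.birth_rate, int(rng.integers(0, 2**31 - 1)))
    ages = _node_ages(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    depth = max(ages[lf] for lf in leaves)
    if any(abs(ages[lf] - depth) > 1e-9 * max(depth, 1.0) for lf in leaves):
        if config.psym_transfer_rate > 0:
            raise ValueError("psym transfers require an ultrametric tree")

    root_reps, pool = _build_root(config, rng)
    node_index = {node: i for i, node in enumerate(tree.preorder_node_iter())}

    def node_label(node: dendropy.Node) -> str:
        return node.taxon.label if node.taxon is not None else f"node{node_index[node]}"

    root = tree.seed_node
    root_psym = _PsymNode(None, 0.0) if any(r.kind == "psym" for r in root_reps) else None
    live: dict[dendropy.Node, _Lineage] = {}
    for child in root.child_nodes():
        lin = _Lineage([r.clone() for r in root_reps], {}, None, 0.0, node_label(child))
        if root_psym is not None:
            lin.psym_node = _PsymNode(root_psym, 0.0)
        live[child] = lin

    events = sorted(
        ((ages[n], node_index[n], n) for n in tree.preorder_internal_node_iter() if n is not root),
        key=lambda x: (x[0], x[1]),
    )
    transfer_events: list[TransferEvent] = []

    def do_transfers(t0: float, t1: float) -> None:
        if config.psym_transfer_rate <= 0 or len(live) < 2:
            return
        lam = config.psym_transfer_rate * len(live)
        n_ev = rng.poisson(lam * (t1 - t0))
        if n_ev == 0:
            return
        times = np.sort(rng.uniform(t0, t1, size=n_ev))
        for tau in times:
            keys = sorted(live, key=lambda n: node_index[n])
            recipient_key = keys[int(rng.integers(0, len(keys)))]
            donor_keys = [k for k in keys if k is not recipient_key]
            donor_key = donor_keys[int(rng.integers(0, len(donor_keys)))]
            donor, recipient = live[donor_key], live[recipient_key]
            _advance(donor, float(tau), rng, config, pool)
            _advance(recipient, float(tau), rng, config, pool)
            d_psym = donor.psym_rep()
            if d_psym is None:
                continue
            # wholesale replacement of the recipient's pSym by the donor's copy
            for i, r in enumerate(recipient.reps):
                if r.kind == "psym":
                    recipient.reps[i] = d_psym.clone()
                    break
            new_donor_node = _PsymNode(donor.psym_node, float(tau))
            donor.psym_node = new_donor_node
            recipient.psym_node = _PsymNode(new_donor_node, float(tau))
            transfer_events.append(
                TransferEvent(
                    donor=donor.label,
                    recipient=recipient.label,
                    time=float(tau),
                    donor_leaves=_leafset(donor_key),
                    recipient_leaves=_leafset(recipient_key),
                )
            )

    t_prev = 0.0
    for t_ev, _, node in events:
        do_transfers(t_prev, t_ev)
        lin = live.pop(node)
        _advance(lin, t_ev, rng, config, pool)
        parent_psym = lin.psym_node
        children = node.child_nodes()
        for child in children:
            clone = lin.clone(node_label(child)) if child is not children[0] else lin
            clone.label = node_label(child)
            if parent_psym is not None:
                clone.psym_node = _PsymNode(parent_psym, t_ev)
            live[child] = clone
        t_prev = t_ev
    do_transfers(t_prev, depth)
    for node in sorted(live, key=lambda n: node_index[n]):
        _advance(live[node], depth, rng, config, pool)

    # ---- materialize leaf genomes
    genomes: list[GenomeRecord] = []
    family_table: dict[str, set[str]] = {}
    psym_nodes: dict[str, _PsymNode | None] = {}
    for node in sorted(live, key=lambda n: node_label(n)):
        lin = live[node]
        gid = node_label(node)
        psym_nodes[gid] = lin.psym_node
        replicons = []
        for rep in lin.reps:
            genes = []
            seq = decode_dna(rep.seq)
            for g in sorted(rep.genes, key=lambda g: g.start):
                cds = seq[g.start : g.end]
                genes.append(
                    GeneRecord(
                        gene_id=f"{gid}|{g.family}",
                        start=g.start,
                        end=g.end,
                        strand="+",
                        cds=cds,
                        protein=translate_cds(cds),
                        role_tags=set(g.tags),
                        family_truth=g.family,
                    )
                )
                family_table.setdefault(g.family, set()).add(gid)
            replicons.append(RepliconRecord(f"{gid}_{rep.name}", rep.kind, seq, genes))
        genomes.append(GenomeRecord(genome_id=gid, status="complete", replicons=replicons))

    ids = tuple(g.genome_id for g in genomes)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    chrd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]]) * config.subs_rate
            chrd[i, j] = chrd[j, i] = d
    true_dist = DistanceMatrix(ids, chrd)

    psym_dist = None
    if all(psym_nodes.get(g) is not None for g in ids) and len(ids) > 1:
        pd = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                t_join = _psym_join_time(psym_nodes[ids[i]], psym_nodes[ids[j]], depth)
                d = 2.0 * (depth - t_join) * config.subs_rate
                pd[i, j] = pd[j, i] = d
        psym_dist = DistanceMatrix(ids, pd)

    truth = SimTruth(
        tree=tree,
        genome_ids=ids,
        true_pairwise_distance=true_dist,
        psym_distance=psym_dist,
        family_table=family_table,
        transfer_events=transfer_events,
        config=config,
    )
    _log.info(
        "evolve_collection: %d genomes, %d families, %d transfer events",
        len(genomes), len(family_table), len(transfer_events),
    )
    return genomes, truth


def _psym_join_time(a: _PsymNode, b: _PsymNode, leaf_time: float) -> float:
    """Time at which the two sampled pSym copies last shared state.

    Each node marks a copy event (speciation or transfer). Walking both
    chains to the first common node m, the copies separated at the *earlier*
    of the two copies made from m (leaf_time when a chain ends at m itself),
    so divergence is 2*(T - t_join).
    """
    chain_a: list[_PsymNode] = []
    x: _PsymNode | None = a
    while x is not None:
        chain_a.append(x)
        x = x.parent
    pos_a = {id(n): i for i, n in enumerate(chain_a)}
    prev_b: _PsymNode | None = None
    y: _PsymNode | None = b
    while y is not None:
        if id(y) in pos_a:
            i = pos_a[id(y)]
            t_a = chain_a[i - 1].time if i > 0 else leaf_time
            t_b = prev_b.time if prev_b is not None else leaf_time
            return min(t_a, t_b)
        prev_b = y
        y = y.parent
    return 0.0


# --- focused generators used by the rate and transfer analyses -------------


def jc_pair(length: int, d: float, seed: int) -> tuple[GenomeRecord, GenomeRecord]:
    """Two gene-free single-chromosome genomes at expected JC69 distance ``d``."""
    rng = np.random.default_rng(seed)
    root = random_dna(length, rng)
    out = []
    for name in ("A", "B"):
        seq = root.copy()
        rep = _RepState("chr", "chromosome", seq, [])
        _apply_substitutions(rep, rng.poisson(length * d / 2.0), rng)
        out.append(
            GenomeRecord(
                genome_id=name,
                replicons=[RepliconRecord(f"{name}_chr", "chromosome", decode_dna(rep.seq), [])],
            )
        )
    return out[0], out[1]


def divergence_ladder(n: int, d_max: float, length: int, seed: int) -> tuple[list[GenomeRecord], DistanceMatrix]:
    """Chain of genomes where consecutive neighbours differ by d_max/(n-1).

    Genome i is genome i-1 evolved further, so true pairwise distance is
    |i-j| * step — a monotone divergence ladder for correlation checks.
    """
    rng = np.random.default_rng(seed)
    step = d_max / (n - 1)
    rep = _RepState("chr", "chromosome", random_dna(length, rng), [])
    genomes = []
    width = len(str(n))
    for i in range(n):
        if i > 0:
            _apply_substitutions(rep, rng.poisson(length * step), rng)
        gid = f"L{i + 1:0{width}d}"
        genomes.append(
            GenomeRecord(genome_id=gid, replicons=[RepliconRecord(f"{gid}_chr", "chromosome", decode_dna(rep.seq), [])])
        )
    ids = tuple(g.genome_id for g in genomes)
    vals = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * step
    return genomes, DistanceMatrix(ids, vals.astype(float))


def simulate_transfer_pair(
    seed: int,
    ks_chr: float = 0.5,
    psym_relative_time: float = 1.0,
    n_chr_genes: int = 50,
    n_psym_genes: int = 25,
    mean_gene_len: int = 200,
) -> tuple[GenomeRecord, GenomeRecord]:
    """Two genomes whose chromosomal genes carry synonymous divergence
    ``ks_chr`` while their symbiotic-plasmid genes carry
    ``psym_relative_time * ks_chr``.

    Gene CDSs diverge by synonymous-only substitutions (strong purifying
    selection on the proteins, so ortholog pairing stays trivial even at
    high Ks, as for real chromosomal core genes); intergenic spacers
    diverge neutrally at the same nominal rate. ``psym_relative_time`` = 1
    is the clonal no-transfer control; values << 1 emulate a recent
    wholesale pSym replacement.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_core_genes=n_chr_genes,
        n_ribosomal=0,
        n_accessory_pool=0,
        gain_rate=0.0,
        loss_rate=0.0,
        plasmid_plan=[PlasmidPlan("psym", n_psym_genes)],
        mean_gene_len=mean_gene_len,
    )
    reps, _ = _build_root(cfg, rng)
    ks_psym = psym_relative_time * ks_chr
    out = []
    for name in ("A", "B"):
        replicons = []
        for rep in reps:
            ks = ks_chr if rep.kind == "chromosome" else ks_psym
            root_seq = decode_dna(rep.seq)
            parts: list[str] = []
            genes: list[GeneRecord] = []
            pos = 0
            for g in sorted(rep.genes, key=lambda g: g.start):
                spacer = _RepState("s", rep.kind, rep.seq[pos : g.start].copy(), [])
                _apply_substitutions(spacer, rng.poisson(len(spacer.seq) * ks / 2.0), rng)
                parts.append(decode_dna(spacer.seq))
                cds = evolve_cds_synonymous(root_seq[g.start : g.end], ks / 2.0, rng)
                parts.append(cds)
                genes.append(
                    GeneRecord(
                        gene_id=f"{name}|{g.family}",
                        start=g.start,
                        end=g.end,
                        cds=cds,
                        protein=translate_cds(cds),
                        role_tags=set(g.tags),
                        family_truth=g.family,
                    )
                )
                pos = g.end
            tail = _RepState("s", rep.kind, rep.seq[pos:].copy(), [])
            _apply_substitutions(tail, rng.poisson(len(tail.seq) * ks / 2.0), rng)
            parts.append(decode_dna(tail.seq))
            replicons.append(RepliconRecord(f"{name}_{rep.name}", rep.kind, "".join(parts), genes))
        out.append(GenomeRecord(genome_id=name, replicons=replicons))
    return out[0], out[1]


def plant_marker_hgt(
    genomes: list[GenomeRecord], family: str, donor_id: str, recipient_id: str
) -> list[GenomeRecord]:
    """Replace the recipient's copy of ``family`` with the donor's (in place
    on deep copies): a planted single-marker horizontal transfer."""
    genomes = copy.deepcopy(genomes)
    by_id = {g.genome_id: g for g in genomes}
    donor_gene = next(g for g in by_id[donor_id].genes() if g.family_truth == family)
    for repl in by_id[recipient_id].replicons:
        for gene in repl.genes:
            if gene.family_truth == family:
                if len(gene.cds) != len(donor_gene.cds):
                    raise ValueError("donor and recipient copies differ in length")
                repl.sequence = (
                    repl.sequence[: gene.start] + donor_gene.cds + repl.sequence[gene.end :]
                )
                gene.cds = donor_gene.cds
                gene.protein = donor_gene.protein
                return genomes
    raise KeyError(f"{family} not found in {recipient_id}")


# --- synonymous-only divergence (for the Ks analysis) ----------------------

_CODON_AA: dict[tuple[int, int, int], str] = {}
for _c in range(64):
    _tpl = (_c // 16, (_c // 4) % 4, _c % 4)
    _CODON_AA[_tpl] = "*" if _tpl in STOP_CODONS else translate_cds(decode_dna(np.array(_tpl, dtype=np.uint8)))

_SYN_OPTIONS: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
for _tpl, _aa in _CODON_AA.items():
    if _aa == "*":
        continue
    opts = []
    for pos in range(3):
        for nb in range(4):
            if nb == _tpl[pos]:
                continue
            alt = list(_tpl)
            alt[pos] = nb
            if _CODON_AA[tuple(alt)] == _aa:
                opts.append((pos, nb))
    _SYN_OPTIONS[_tpl] = opts


def count_synonymous_sites(cds: str) -> float:
    """NG86 synonymous site count: per position, (synonymous one-step
    changes)/3 summed over codons; changes to stops are nonsynonymous."""
    codes = encode_dna(cds)
    if len(codes) % 3:
        raise ValueError("CDS length not divisible by 3")
    s = 0.0
    for i in range(0, len(codes), 3):
        tpl = (int(codes[i]), int(codes[i + 1]), int(codes[i + 2]))
        if tpl in STOP_CODONS:
            raise ValueError("internal stop codon")
        s += len(_SYN_OPTIONS[tpl]) / 3.0
    return s


def evolve_cds_synonymous(cds: str, t: float, rng: np.random.Generator) -> str:
    """Apply synonymous-only substitutions at expected ``t`` substitutions per
    NG86 synonymous site (proposal-rejection over uniform single-base
    changes, so per-synonymous-site intensity is uniform across codons)."""
    codes = encode_dna(cds)
    n_target = rng.poisson(t * count_synonymous_sites(cds))
    applied = 0
    guard = 0
    while applied < n_target:
        guard += 1
        if guard > 1000 * max(n_target, 1) + 10000:
            raise RuntimeError("synonymous evolution failed to converge")
        p = int(rng.integers(0, len(codes)))
        nb = (int(codes[p]) + int(rng.integers(1, 4))) % 4
        c0 = p - (p % 3)
        tpl = (int(codes[c0]), int(codes[c0 + 1]), int(codes[c0 + 2]))
        if ((p % 3), nb) in _SYN_OPTIONS.get(tpl, []):
            codes[p] = nb
            applied += 1
    return decode_dna(codes)


# codon families whose third position is 4-fold degenerate and whose first
# two positions admit no synonymous change: on these, every synonymous site
# follows Jukes-Cantor dynamics exactly, so the NG86 correction is exact.
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")  # Ala Gly Pro Thr Val Ser


def random_cds_fourfold(n_codons: int, rng: np.random.Generator) -> str:
    pre = rng.integers(0, len(_FOURFOLD_PREFIXES), size=n_codons)
    third = rng.integers(0, 4, size=n_codons)
    return "".join(_FOURFOLD_PREFIXES[p] + "ACGT"[t] for p, t in zip(pre, third))


def synonymous_cds_pair(
    n_codons: int, ks: float, rng: np.random.Generator, fourfold_only: bool = False
) -> tuple[str, str]:
    """A CDS pair at expected synonymous divergence ``ks`` (half per side).

    With ``fourfold_only`` the root uses only 4-fold-degenerate codons,
    the regime where NG86's Jukes-Cantor correction is exact (closed-form
    validation); mixed random codons exercise the estimator's known mild
    saturation bias instead.
    """
    if fourfold_only:
        root = random_cds_fourfold(n_codons, rng)
    else:
        root = decode_dna(random_cds(n_codons, rng))
    a = evolve_cds_synonymous(root, ks / 2.0, rng)
    b = evolve_cds_synonymous(root, ks / 2.0, rng)
    return a, b
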