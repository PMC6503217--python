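"""Protein-level homology, ortholog clustering, and pangenome profiling.

Homology searches use Smith-Waterman local alignment (BLOSUM62, gap open 11
/ extend 1). Ortholog families come from two routes — bidirectional best
hits (BDBH) and Markov clustering (MCL) of the similarity graph — and the
*consensus core* is their intersection: families both methods delimit
identically, with exactly one member per genome. The e-value gate of a
BLAST-style search is emulated by an empirical noise floor: a Gumbel fit to
scores of shuffled-sequence alignments, thresholded at the requested tail
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.sparse.csgraph
import scipy.stats
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_core import get_logger

_log = get_logger("orthology")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    al = PairwiseAligner(mode="local")
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


@dataclass
class ProteinHit:
    query_id: str
    target_id: str
    pct_identity: float
    query_cov: float  # aligned residues / query length, %
    target_cov: float
    score: float

    @property
    def cov_largest(self) -> float:
        """Coverage relative to the larger protein (marker-extraction rule)."""
        return min(self.query_cov, self.target_cov)


def align_proteins(a: str, b: str, query_id: str = "query", target_id: str = "target") -> ProteinHit:
    """Smith-Waterman local alignment of two proteins (BLOSUM62, 11/1)."""
    for name, seq in (("query", a), ("target", b)):
        if not seq:
            raise ValueError(f"empty {name} sequence")
        bad = set(seq) - _AA_SET
        if bad:
            raise ValueError(f"illegal characters in {name}: {sorted(bad)}")
    alns = _aligner().align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return ProteinHit(query_id, target_id, 0.0, 0.0, 0.0, 0.0)
    aln = alns[0]
    counts = aln.counts()
    ncols = aln.length
    identity = 100.0 * counts.identities / ncols if ncols else 0.0
    spans = []
    for row in aln.aligned:
        spans.append(sum(int(e - s) for s, e in row))
    return ProteinHit(
        query_id,
        target_id,
        identity,
        100.0 * spans[0] / len(a),
        100.0 * spans[1] / len(b),
        float(aln.score),
    )


# --- empirical noise floor (e-value surrogate) -----------------------------


@lru_cache(maxsize=64)
def noise_score_floor(len_a: int, len_b: int, log10_p: float = -6.0, n_shuffles: int = 100) -> float:
    """Score above which a chance hit between unrelated sequences of these
    lengths has probability < 10**log10_p (Gumbel tail fitted to shuffled
    random-protein alignment scores); lengths are bucketed by caching."""
    rng = np.random.default_rng(12345 + 13 * len_a + len_b)
    aas = np.array(list(AMINO_ACIDS))
    scores = []
    for _ in range(n_shuffles):
        sa = "".join(rng.choice(aas, size=max(len_a, 10)))
        sb = "".join(rng.choice(aas, size=max(len_b, 10)))
        scores.append(_aligner().score(sa, sb))
    loc, scale = scipy.stats.gumbel_r.fit(scores)
    return float(scipy.stats.gumbel_r.ppf(1.0 - 10.0**log10_p, loc, scale))


def _bucket(n: int) -> int:
    return max(50, int(round(n / 50.0)) * 50)


# --- BDBH ------------------------------------------------------------------


def _kmer_set(seq: str, k: int = 5) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


class _HitCache:
    """Symmetric alignment cache with optional k-mer prefilter."""

    def __init__(self, sequences: dict[str, str], prefilter: bool, min_shared_kmers: int = 3):
        self.sequences = sequences
        self.prefilter = prefilter
        self.min_shared = min_shared_kmers
        self._kmers = {gid: _kmer_set(s) for gid, s in sequences.items()} if prefilter else None
        self._cache: dict[frozenset, ProteinHit | None] = {}

    def hit(self, qid: str, tid: str) -> ProteinHit | None:
        key = frozenset((qid, tid))
        if key in self._cache:
            h = self._cache[key]
        else:
            if self._kmers is not None and len(self._kmers[qid] & self._kmers[tid]) < self.min_shared:
                h = None
            else:
                h = align_proteins(self.sequences[qid], self.sequences[tid], qid, tid)
            self._cache[key] = h
        if h is None:
            return None
        if h.query_id == qid:
            return h
        return ProteinHit(qid, tid, h.pct_identity, h.target_cov, h.query_cov, h.score)


def _passes(
    hit: ProteinHit, min_identity: float, min_coverage: float, coverage_rule: str, floor: float | None
) -> bool:
    if hit.pct_identity < min_identity:
        return False
    if coverage_rule == "each":
        if min(hit.query_cov, hit.target_cov) < min_coverage:
            return False
    elif coverage_rule == "largest":
        if hit.cov_largest < min_coverage:
            return False
    else:
        raise ValueError(f"unknown coverage_rule {coverage_rule!r}")
    if floor is not None and hit.score < floor:
        return False
    return True


def bdbh(
    proteomes: dict[str, dict[str, str]],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
    coverage_rule: str = "each",
    use_score_floor: bool = True,
    prefilter: bool | None = None,
) -> nx.Graph:
    """Reciprocal-best-hit graph over per-genome protein sets.

    For every ordered genome pair each protein's best hit (highest score,
    ties by identity then lexicographic id) is found; an edge is kept iff
    the two bests are reciprocal and the hit clears the identity/coverage
    gates and the empirical noise floor. ``prefilter=None`` enables the
    k-mer prefilter automatically on large inputs (it never fires on the
    similarity levels the gates accept).
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 genomes")
    genome_of = {gid: gn for gn, prots in proteomes.items() for gid in prots}
    sequences = {gid: s for prots in proteomes.values() for gid, s in prots.items()}
    n_cross = sum(
        len(a) * len(b)
        for i, a in enumerate(proteomes.values())
        for j, b in enumerate(proteomes.values())
        if j > i
    )
    if prefilter is None:
        prefilter = n_cross > 20_000
    cache = _HitCache(sequences, prefilter)
    genomes = sorted(proteomes)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(sequences))
    floor_cache: dict[tuple[int, int], float] = {}

    def floor_for(a: str, b: str) -> float | None:
        if not use_score_floor:
            return None
        key = (_bucket(len(sequences[a])), _bucket(len(sequences[b])))
        if key not in floor_cache:
            floor_cache[key] = noise_score_floor(*key)
        return floor_cache[key]

    def best_hit(qid: str, targets: list[str]) -> ProteinHit | None:
        # highest score, ties by identity, then lexicographically smallest id
        best: ProteinHit | None = None
        for tid in targets:
            h = cache.hit(qid, tid)
            if h is None:
                continue
            if best is None:
                best = h
                continue
            kh, kb = (h.score, h.pct_identity), (best.score, best.pct_identity)
            if kh > kb or (kh == kb and h.target_id < best.target_id):
                best = h
        return best

    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            ids_a = sorted(proteomes[ga])
            ids_b = sorted(proteomes[gb])
            best_ab = {a: best_hit(a, ids_b) for a in ids_a}
            best_ba = {b: best_hit(b, ids_a) for b in ids_b}
            for a, h in best_ab.items():
                if h is None:
                    continue
                back = best_ba.get(h.target_id)
                if back is None or back.target_id != a:
                    continue
                if _passes(h, min_identity, min_coverage, coverage_rule, floor_for(a, h.target_id)):
                    graph.add_edge(a, h.target_id, score=h.score, identity=h.pct_identity)
    nx.set_node_attributes(graph, genome_of, "genome")
    _log.info("bdbh: %d genomes, %d proteins, %d edges", len(genomes), graph.number_of_nodes(), graph.number_of_edges())
    return graph


def similarity_graph(
    proteomes: dict[str, dict[str, str]],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
    coverage_rule: str = "each",
    use_score_floor: bool = True,
    prefilter: bool | None = None,
) -> nx.Graph:
    """All-vs-all (between genomes) similarity graph above the gates,
    weighted by alignment score — the MCL input."""
    genome_of = {gid: gn for gn, prots in proteomes.items() for gid in prots}
    sequences = {gid: s for prots in proteomes.values() for gid, s in prots.items()}
    n_cross = sum(len(p) for p in proteomes.values()) ** 2
    if prefilter is None:
        prefilter = n_cross > 20_000
    cache = _HitCache(sequences, prefilter)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(sequences))
    ids = sorted(sequences)
    floor_cache: dict[tuple[int, int], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if genome_of[a] == genome_of[b]:
                continue  # paralog edges are not drawn between same-genome genes
            h = cache.hit(a, b)
            if h is None:
                continue
            floor = None
            if use_score_floor:
                key = (_bucket(len(sequences[a])), _bucket(len(sequences[b])))
                if key not in floor_cache:
                    floor_cache[key] = noise_score_floor(*key)
                floor = floor_cache[key]
            if _passes(h, min_identity, min_coverage, coverage_rule, floor):
                graph.add_edge(a, b, weight=h.score)
    nx.set_node_attributes(graph, genome_of, "genome")
    return graph


# --- MCL -------------------------------------------------------------------


@dataclass
class MclResult:
    clusters: list[frozenset]
    converged: bool
    n_iter: int

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 200,
    prune_threshold: float = 1e-5,
    tol: float = 1e-9,
) -> MclResult:
    """Markov clustering: alternate expansion (matrix squaring) and
    inflation (elementwise power + column renormalisation) with pruning
    until the matrix is stable; clusters are the connected components of
    the limit matrix's support. Deterministic and node-order invariant."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return MclResult([], True, 0)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("negative edge weight")
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = w
    # self-loops at each node's max incident weight keep attractors stable
    loops = np.where(m.max(axis=0) > 0, m.max(axis=0), 1.0)
    m[np.diag_indices(n)] = loops

    def normalize(x):
        s = x.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        return x / s

    m = normalize(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = normalize(np.power(expanded, inflation))
        inflated[inflated < prune_threshold] = 0.0
        inflated = normalize(inflated)
        change = np.abs(inflated - m).max()
        m = inflated
        if change < tol:
            converged = True
            break
    if not converged:
        _log.warning("mcl_cluster: no convergence after %d iterations", max_iter)
    support = scipy.sparse.csr_matrix((m + m.T) > prune_threshold)
    n_comp, labels = scipy.sparse.csgraph.connected_components(support, directed=False)
    clusters: dict[int, set] = {}
    for v, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), set()).add(v)
    out = sorted((frozenset(c) for c in clusters.values()), key=lambda c: min(c))
    return MclResult(out, converged, it)


# --- family tables ---------------------------------------------------------


@dataclass
class FamilyTable:
    """Gene families with their genome-of-origin map and per-family flags."""

    families: dict[str, frozenset]  # family_id -> gene ids
    gene_genome: dict[str, str]
    flags: dict[str, set[str]] = field(default_factory=dict)  # family_id -> {"core","single_copy","symbiotic"}

    @property
    def n_families(self) -> int:
        return len(self.families)

    def genomes_of(self, family_id: str) -> set[str]:
        return {self.gene_genome[g] for g in self.families[family_id]}

    def presence_absence(self, genome_ids: list[str] | None = None, binary: bool = True) -> pd.DataFrame:
        if genome_ids is None:
            genome_ids = sorted(set(self.gene_genome.values()))
        fam_ids = sorted(self.families)
        mat = np.zeros((len(fam_ids), len(genome_ids)), dtype=int)
        gidx = {g: j for j, g in enumerate(genome_ids)}
        for i, f in enumerate(fam_ids):
            for gene in self.families[f]:
                j = gidx.get(self.gene_genome[gene])
                if j is not None:
                    mat[i, j] += 1
        if binary:
            mat = (mat > 0).astype(int)
        return pd.DataFrame(mat, index=fam_ids, columns=genome_ids)


def families_from_clusters(clusters, gene_genome: dict[str, str], genome_ids: list[str]) -> FamilyTable:
    """Label clusters deterministically and flag core / single-copy."""
    fams = {}
    flags = {}
    n_genomes = len(genome_ids)
    width = max(4, len(str(len(clusters))))
    for i, cl in enumerate(sorted((frozenset(c) for c in clusters), key=lambda c: min(c))):
        fid = f"FAM{i + 1:0{width}d}"
        fams[fid] = cl
        gset = {gene_genome[g] for g in cl}
        fl = set()
        if len(gset) == n_genomes:
            fl.add("core")
        if len(cl) == len(gset):
            fl.add("single_copy")
        flags[fid] = fl
    return FamilyTable(fams, dict(gene_genome), flags)


def cluster_proteomes(
    proteomes: dict[str, dict[str, str]],
    method: str = "mcl",
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
    inflation: float = 1.5,
    prefilter: bool | None = None,
) -> FamilyTable:
    """Gene families for a collection via MCL or BDBH-component clustering."""
    genome_ids = sorted(proteomes)
    gene_genome = {gid: gn for gn, prots in proteomes.items() for gid in prots}
    if method == "mcl":
        g = similarity_graph(proteomes, min_identity, min_coverage, prefilter=prefilter)
        clusters = mcl_cluster(g, inflation=inflation).clusters
    elif method == "bdbh":
        g = bdbh(proteomes, min_identity, min_coverage, prefilter=prefilter)
        clusters = [frozenset(c) for c in nx.connected_components(g)]
    else:
        raise ValueError(f"unknown method {method!r}")
    return families_from_clusters(clusters, gene_genome, genome_ids)


def consensus_core(
    bdbh_families: FamilyTable | list,
    mcl_families: FamilyTable | list,
    genome_ids: list[str],
    gene_genome: dict[str, str] | None = None,
) -> FamilyTable:
    """Families delimited identically by BDBH and MCL, one gene per genome.

    The intersection semantics are strict: a family enters the consensus
    core only when some BDBH family and some MCL cluster contain exactly
    the same gene set, and that set has one member in every genome.
    """
    def to_sets(x):
        if isinstance(x, FamilyTable):
            return set(x.families.values()), x.gene_genome
        return {frozenset(c) for c in x}, None

    sets_a, gg_a = to_sets(bdbh_families)
    sets_b, gg_b = to_sets(mcl_families)
    gene_genome = gene_genome or gg_a or gg_b
    if gene_genome is None:
        raise ValueError("gene_genome mapping required")
    shared = sets_a & sets_b
    core = []
    for fam in shared:
        genomes = [gene_genome[g] for g in fam]
        if len(fam) == len(genome_ids) and set(genomes) == set(genome_ids):
            core.append(fam)
    table = families_from_clusters(core, gene_genome, list(genome_ids))
    for fid in table.families:
        table.flags[fid] |= {"core", "single_copy"}
    _log.info("consensus_core: %d candidate intersections, %d consensus-core families", len(shared), len(core))
    return table


# --- pangenome rarefaction -------------------------------------------------


@dataclass
class PangenomeCurves:
    n: np.ndarray
    core_median: np.ndarray
    pan_median: np.ndarray
    core_per_perm: np.ndarray  # (n_perm, n_genomes)
    pan_per_perm: np.ndarray
    heaps_k: float
    heaps_gamma: float
    core_a: float
    core_tau: float
    core_c: float


def pangenome_curves(pa: pd.DataFrame, n_perm: int = 20, seed: int = 0) -> PangenomeCurves:
    """Rarefaction of core(n) and pan(n) over random genome orderings.

    pan(n) medians are fitted to Heaps' law K*n^gamma (log-log least
    squares); core(n) medians to A*exp(-n/tau) + C.
    """
    if pa.shape[1] < 2:
        raise ValueError("need at least 2 genomes")
    rng = np.random.default_rng(seed)
    mat = (pa.to_numpy() > 0)
    n_fam, n_gen = mat.shape
    cores = np.zeros((n_perm, n_gen), dtype=int)
    pans = np.zeros((n_perm, n_gen), dtype=int)
    for p in range(n_perm):
        order = rng.permutation(n_gen)
        acc_and = np.ones(n_fam, dtype=bool)
        acc_or = np.zeros(n_fam, dtype=bool)
        for i, g in enumerate(order):
            acc_and &= mat[:, g]
            acc_or |= mat[:, g]
            cores[p, i] = int(acc_and.sum())
            pans[p, i] = int(acc_or.sum())
    core_med = np.median(cores, axis=0)
    pan_med = np.median(pans, axis=0)
    n = np.arange(1, n_gen + 1)
    # Heaps fit
    if np.all(pan_med > 0):
        slope, intercept = np.polyfit(np.log(n), np.log(pan_med), 1)
        heaps_k, heaps_gamma = float(np.exp(intercept)), float(slope)
    else:
        heaps_k, heaps_gamma = float(pan_med[-1]), 0.0
    # core decay fit
    c0 = float(core_med[-1])
    a0 = max(float(core_med[0] - c0), 1e-6)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", scipy.optimize.OptimizeWarning)
            popt, _ = scipy.optimize.curve_fit(
                lambda x, a, tau, c: a * np.exp(-x / tau) + c,
                n.astype(float),
                core_med.astype(float),
                p0=(a0, max(n_gen / 4.0, 1.0), c0),
                bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10_000,
            )
        core_a, core_tau, core_c = (float(v) for v in popt)
    except Exception:
        core_a, core_tau, core_c = 0.0, np.inf, float(core_med.mean())
    return PangenomeCurves(n, core_med, pan_med, cores, pans, heaps_k, heaps_gamma, core_a, core_tau, core_c)


# --- symbiotic reference mapping -------------------------------------------


def map_symbiotic(
    proteomes: dict[str, dict[str, str]],
    symbiotic_refs: dict[str, str],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
    inflation: float = 1.5,
) -> pd.DataFrame:
    """Map a symbiotic reference protein set onto a collection.

    References are first made non-redundant by MCL at the same gates; each
    non-redundant reference is then matched to every genome by reciprocal
    best hit. Returns a binary profile (non-redundant reference x genome).
    """
    if not symbiotic_refs:
        raise ValueError("empty reference set")
    ref_prot = {"__refs__": dict(symbiotic_refs)}
    # dedup among references themselves
    ids = sorted(symbiotic_refs)
    g = nx.Graph()
    g.add_nodes_from(ids)
    cache = _HitCache(dict(symbiotic_refs), prefilter=len(ids) ** 2 > 20_000)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            h = cache.hit(a, b)
            if h is not None and _passes(h, min_identity, min_coverage, "each", None):
                g.add_edge(a, b, weight=h.score)
    nr_reps = [min(c) for c in mcl_cluster(g, inflation=inflation).clusters]
    nr_reps.sort()
    _log.info("map_symbiotic: %d references -> %d non-redundant", len(ids), len(nr_reps))

    genomes = sorted(proteomes)
    profile = pd.DataFrame(0, index=nr_reps, columns=genomes)
    for gn in genomes:
        two = {"refs": {r: symbiotic_refs[r] for r in nr_reps}, "gen": proteomes[gn]}
        rbh = bdbh(two, min_identity, min_coverage, use_score_floor=False)
        for u, v in rbh.edges:
            ref = u if u in profile.index else (v if v in profile.index else None)
            if ref is not None:
                profile.loc[ref, gn] = 1
    return profile


# --- profiles --------------------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two non-negative
    profiles; undefined (error) when both are all-zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("profiles must be non-negative")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(np.abs(x - y).sum() / denom)


def order_profiles(pa: pd.DataFrame):
    """UPGMA ordering of genome presence/absence profiles by Bray-Curtis.

    Returns (ordered genome labels, scipy linkage matrix). Columns are
    sorted by label before clustering so ties break deterministically.
    """
    if pa.shape[1] < 2:
        raise ValueError("need at least 2 genome columns")
    cols = sorted(pa.columns)
    mat = pa[cols].to_numpy(dtype=float).T  # genomes x families
    n = len(cols)
    cond = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            cond[k] = bray_curtis(mat[i], mat[j])
            k += 1
    linkage = sch.linkage(cond, method="average")
    order = sch.leaves_list(linkage)
    return [cols[i] for i in order], linkage
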