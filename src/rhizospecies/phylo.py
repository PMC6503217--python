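"""Marker phylogenetics: universal single-copy marker extraction, column
trimming, corrected pairwise distances, neighbor-joining trees,
Robinson-Foulds distances, and congruence-based marker filtering.

The distance models offered are the Poisson correction d = -ln(1-p) and the
Kimura protein correction d = -ln(1 - p - p^2/5) on the proportion of
differing sites p; saturated pairs (correction undefined) are flagged
rather than silently dropped. Tree building is classic Saitou-Nei
neighbor-joining with deterministic tie-breaking; marker filtering drops
markers whose NJ tree is topologically incongruent (high RF) with the
majority-rule consensus over all markers — a stand-in for recombination /
HGT screening of phylogenetic markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_core import DistanceMatrix, GenomeRecord, get_logger
from .orthology import align_proteins

_log = get_logger("phylo")

GAP_CHARS = frozenset("-.?X*")


@dataclass
class MarkerAlignment:
    """One marker family: an aligned row per genome (equal lengths)."""

    family_id: str
    rows: dict[str, str]  # genome_id -> aligned sequence
    column_mask: np.ndarray | None = None  # True for retained columns (set by trimming)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker {self.family_id}: unequal row lengths {lengths}")


@dataclass
class Supermatrix:
    rows: dict[str, str]
    marker_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


# --- marker extraction -----------------------------------------------------


def extract_markers(
    genomes: list[GenomeRecord],
    role_tag: str = "ribosomal",
    min_identity: float = 60.0,
    min_cov_largest: float = 60.0,
) -> list[MarkerAlignment]:
    """Universal single-copy markers tagged ``role_tag``.

    The first genome's tagged genes seed the marker set; each other genome
    contributes its best tagged hit above ``min_identity`` and
    ``min_cov_largest`` (coverage of the larger protein). Markers missing
    in any genome, or with more than one qualifying copy in some genome,
    are dropped (logged). Equal-length rows are kept as-is (the simulator
    produces gap-free markers); unequal rows are star-aligned to the seed.
    """
    if not genomes:
        raise ValueError("empty collection")
    tagged = {
        g.genome_id: sorted(
            (gene for gene in g.genes() if role_tag in gene.role_tags and gene.protein),
            key=lambda gene: gene.gene_id,
        )
        for g in genomes
    }
    ref_id = sorted(tagged)[0]
    markers: list[MarkerAlignment] = []
    n_dropped_missing = n_dropped_multi = 0
    for seed_gene in tagged[ref_id]:
        fam = seed_gene.family_truth or seed_gene.gene_id
        rows = {ref_id: seed_gene.protein}
        ok = True
        for gid in sorted(tagged):
            if gid == ref_id:
                continue
            hits = []
            for gene in tagged[gid]:
                h = align_proteins(seed_gene.protein, gene.protein)
                cov = 100.0 * min(h.query_cov * len(seed_gene.protein), h.target_cov * len(gene.protein)) / (
                    100.0 * max(len(seed_gene.protein), len(gene.protein))
                )
                if h.pct_identity >= min_identity and cov >= min_cov_largest:
                    hits.append((h.score, gene))
            if not hits:
                ok = False
                n_dropped_missing += 1
                break
            if len(hits) > 1:
                ok = False
                n_dropped_multi += 1
                break
            rows[gid] = hits[0][1].protein
        if ok:
            markers.append(_as_alignment(fam, rows))
    if not markers:
        raise ValueError(f"no universal single-copy markers with tag {role_tag!r}")
    _log.info(
        "extract_markers(%s): %d retained, %d dropped missing, %d dropped multi-copy",
        role_tag, len(markers), n_dropped_missing, n_dropped_multi,
    )
    return markers


def _as_alignment(fam: str, rows: dict[str, str]) -> MarkerAlignment:
    lengths = {len(s) for s in rows.values()}
    if len(lengths) == 1:
        return MarkerAlignment(fam, dict(rows))
    return MarkerAlignment(fam, _star_align(rows))


def _star_align(rows: dict[str, str]) -> dict[str, str]:
    """Approximate star alignment: project every row onto the longest
    sequence's coordinates via pairwise global alignment (insertions
    relative to the reference are discarded)."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    al = PairwiseAligner(mode="global")
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    ref_gid = max(sorted(rows), key=lambda g: len(rows[g]))
    ref = rows[ref_gid]
    out = {}
    for gid, seq in rows.items():
        if seq == ref:
            out[gid] = seq
            continue
        aln = al.align(ref, seq)[0]
        proj = ["-"] * len(ref)
        for (rs, re), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
            proj[rs:re] = seq[qs:qe]
        out[gid] = "".join(proj)
    return out


# --- trimming & concatenation ---------------------------------------------


def trim_columns(
    aln: MarkerAlignment, mode: str = "complete-deletion", max_gap_fraction: float = 0.0
) -> MarkerAlignment:
    """Remove alignment columns with gaps/unknowns.

    ``complete-deletion`` drops every column containing any gap or unknown
    character; ``gap-fraction`` keeps columns whose gap fraction is at most
    ``max_gap_fraction``.
    """
    aln.validate()
    genome_ids = sorted(aln.rows)
    mat = np.array([list(aln.rows[g]) for g in genome_ids])
    is_gap = np.isin(mat, list(GAP_CHARS))
    if mode == "complete-deletion":
        keep = ~is_gap.any(axis=0)
    elif mode == "gap-fraction":
        keep = is_gap.mean(axis=0) <= max_gap_fraction
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        raise ValueError(f"marker {aln.family_id}: trimming removed every column")
    rows = {g: "".join(mat[i, keep]) for i, g in enumerate(genome_ids)}
    return MarkerAlignment(aln.family_id, rows, column_mask=keep)


def concatenate(markers: list[MarkerAlignment]) -> Supermatrix:
    """Concatenate markers into a supermatrix with a per-marker coordinate
    map; every marker must cover the identical genome set."""
    if not markers:
        raise ValueError("no markers to concatenate")
    genome_ids = sorted(markers[0].rows)
    for m in markers:
        if sorted(m.rows) != genome_ids:
            raise ValueError(f"marker {m.family_id}: genome set differs")
    rows = {g: [] for g in genome_ids}
    spans = {}
    pos = 0
    for m in markers:
        spans[m.family_id] = (pos, pos + m.length)
        pos += m.length
        for g in genome_ids:
            rows[g].append(m.rows[g])
    return Supermatrix({g: "".join(parts) for g, parts in rows.items()}, spans)


# --- distances -------------------------------------------------------------


def pairwise_distance(sm: Supermatrix | MarkerAlignment, model: str = "poisson") -> DistanceMatrix:
    """Corrected pairwise distances from an (ungapped) alignment.

    poisson: d = -ln(1-p); kimura-protein: d = -ln(1 - p - p^2/5), with p
    the per-site difference proportion. Pairs whose correction argument is
    <= 0 are flagged saturated (NaN).
    """
    rows = sm.rows
    if not rows or len(next(iter(rows.values()))) == 0:
        raise ValueError("zero-length alignment")
    labels = tuple(sorted(rows))
    mat = np.array([np.frombuffer(rows[g].encode(), dtype=np.uint8) for g in labels])
    n = len(labels)
    values = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        diff = (mat[i + 1 :] != mat[i]).mean(axis=1)
        for off, p in enumerate(diff):
            j = i + 1 + off
            if model == "poisson":
                arg = 1.0 - p
            elif model == "kimura-protein":
                arg = 1.0 - p - p * p / 5.0
            else:
                raise ValueError(f"unknown model {model!r}")
            if arg <= 0:
                values[i, j] = values[j, i] = np.nan
                sat[i, j] = sat[j, i] = True
            else:
                d = -np.log(arg)
                values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, sat if sat.any() else None)


# --- neighbor joining ------------------------------------------------------


def nj_tree(d: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest label
    pair. Negative branch lengths are clamped to zero with the deficit
    moved to the sister edge (their sum is preserved).
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    values = np.asarray(d.values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite distances (saturated pairs?) cannot be joined")
    tns = taxon_namespace or dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        nodes[lab] = node

    active = list(labels)
    dist = {(a, b): values[i, j] for i, a in enumerate(labels) for j, b in enumerate(labels)}

    def dget(a, b):
        return 0.0 if a == b else dist[(a, b)]

    next_internal = 0
    while len(active) > 2:
        n = len(active)
        r = {a: sum(dget(a, b) for b in active) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * dget(a, b) - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                key = (q, pair)
                if best is None or key < best:
                    best = key
                    bi, bj = a, b
        dij = dget(bi, bj)
        li = dij / 2.0 + (r[bi] - r[bj]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = f"__nj{next_internal}"
        next_internal += 1
        unode = dendropy.Node()
        unode.add_child(nodes[bi])
        nodes[bi].edge.length = li
        unode.add_child(nodes[bj])
        nodes[bj].edge.length = lj
        nodes[u] = unode
        for c in active:
            if c in (bi, bj):
                continue
            duc = (dget(bi, c) + dget(bj, c) - dij) / 2.0
            dist[(u, c)] = dist[(c, u)] = duc
        active = [c for c in active if c not in (bi, bj)] + [u]

    a, b = active
    dab = max(dget(a, b), 0.0)
    root = dendropy.Node()
    root.add_child(nodes[a])
    nodes[a].edge.length = dab / 2.0
    root.add_child(nodes[b])
    nodes[b].edge.length = dab / 2.0
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# --- Robinson-Foulds -------------------------------------------------------


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical leaf sets (the side without the
    lexicographically smallest leaf)."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    anchor = leaves[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else all_set - below
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance: bipartitions in exactly one tree."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


# --- congruence filter -----------------------------------------------------


@dataclass
class MarkerFilterResult:
    retained: list[MarkerAlignment]
    dropped: list[str]  # family ids
    rf_to_consensus: dict[str, int]
    supermatrix: Supermatrix


def filter_markers(
    markers: list[MarkerAlignment],
    max_rf_quantile: float = 0.75,
    min_len: int = 50,
    distance_model: str = "poisson",
) -> MarkerFilterResult:
    """Congruence-based marker filtering.

    Each marker gets an NJ tree; markers whose RF distance to the
    majority-rule consensus of all marker trees exceeds the
    ``max_rf_quantile`` quantile of the RF distribution are dropped;
    survivors are concatenated into the supermatrix.
    """
    candidates = []
    for m in markers:
        t = trim_columns(m)
        if t.length >= min_len:
            candidates.append(t)
    if len(candidates) < 3:
        raise ValueError(f"fewer than 3 markers of length >= {min_len}")
    genome_ids = sorted(candidates[0].rows)
    if len(genome_ids) < 4:
        raise ValueError("need at least 4 genomes for congruence filtering")
    tns = dendropy.TaxonNamespace()
    trees = {}
    for m in candidates:
        dm = pairwise_distance(m, model=distance_model)
        if dm.saturated is not None:
            # saturated pairs cannot be joined; fall back to p-distance
            rows = m.rows
            labels = tuple(sorted(rows))
            mat = np.array([np.frombuffer(rows[g].encode(), np.uint8) for g in labels])
            p = np.zeros((len(labels),) * 2)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    p[i, j] = p[j, i] = float((mat[i] != mat[j]).mean())
            dm = DistanceMatrix(labels, p)
        trees[m.family_id] = nj_tree(dm, taxon_namespace=tns)
    tree_list = dendropy.TreeList(list(trees.values()), taxon_namespace=tns)
    consensus = tree_list.consensus(min_freq=0.5)
    rf = {fid: rf_distance(t, consensus) for fid, t in trees.items()}
    threshold = float(np.quantile(sorted(rf.values()), max_rf_quantile))
    retained = [m for m in candidates if rf[m.family_id] <= threshold]
    dropped = [m.family_id for m in candidates if rf[m.family_id] > threshold]
    if len(retained) < 3:
        raise ValueError("fewer than 3 markers survive congruence filtering")
    _log.info(
        "filter_markers: %d candidates, RF quantile %.2f -> threshold %.1f, %d retained, %d dropped",
        len(candidates), max_rf_quantile, threshold, len(retained), len(dropped),
    )
    return MarkerFilterResult(retained, dropped, rf, concatenate(retained))


def genetic_distance(
    genomes: list[GenomeRecord], role_tag: str = "ribosomal", model: str = "poisson"
) -> tuple[DistanceMatrix, Supermatrix]:
    """Convenience: extract -> trim -> concatenate -> corrected distances.

    This is the 'genetic distance' axis of the ANI-continuum analysis (the
    distance matrix underpinning a concatenated marker-protein phylogeny).
    """
    markers = [trim_columns(m) for m in extract_markers(genomes, role_tag=role_tag)]
    sm = concatenate(markers)
    return pairwise_distance(sm, model=model), sm
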