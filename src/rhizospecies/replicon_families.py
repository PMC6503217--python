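"""Plasmid/chromid family assignment from Rep replication proteins.

Rhizobial extrachromosomal replicons carry repABC replication machinery;
clustering the RepC (replication initiator) and RepB (partition) proteins
groups replicons into families that track whole-replicon conservation. A
family here *is* an MCL cluster over the Rep similarity graph; per-cluster
NJ trees are emitted for inspection, and whole-replicon conservation is
quantified as the fraction of one replicon covered by registered matches
to another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import networkx as nx

from .ani_engine import register_matches
from .io_core import GenomeRecord, RepliconRecord, get_logger
from .orthology import _HitCache, _passes, mcl_cluster
from .phylo import MarkerAlignment, nj_tree, pairwise_distance

_log = get_logger("replicon_families")

REP_TAGS = ("repC", "repB")


@dataclass
class RepFamilyAssignment:
    # replicon_id -> (repC family or None, repB family or None)
    assignment: dict[str, tuple[str | None, str | None]]
    families: dict[str, dict[str, list[str]]]  # tag -> family_id -> replicon ids
    trees: dict[str, dict[str, dendropy.Tree]] = field(default_factory=dict)  # tag -> family -> tree
    secondary: dict[str, list[str]] = field(default_factory=dict)  # multi-replicator extras

    def unassigned(self) -> list[str]:
        return sorted(r for r, (c, b) in self.assignment.items() if c is None and b is None)


def extract_rep_proteins(
    genomes: list[GenomeRecord], tags: tuple[str, ...] = REP_TAGS
) -> dict[str, dict[str, list[tuple[str, str]]]]:
    """Per-tag, per-replicon Rep proteins as (gene_id, protein) lists.

    Replicons without any Rep gene simply do not appear (they are reported
    unassigned downstream); paralogous extra copies are all returned.
    """
    out: dict[str, dict[str, list[tuple[str, str]]]] = {t: {} for t in tags}
    for g in genomes:
        for repl in g.replicons:
            for gene in repl.genes:
                for t in tags:
                    if t in gene.role_tags and gene.protein:
                        out[t].setdefault(repl.replicon_id, []).append((gene.gene_id, gene.protein))
    for t in tags:
        _log.info("extract_rep_proteins: %s on %d replicons", t, len(out[t]))
    return out


def family_clusters(
    rep_proteins: dict[str, dict[str, list[tuple[str, str]]]],
    genomes: list[GenomeRecord],
    inflation: float = 1.5,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> RepFamilyAssignment:
    """MCL families over each Rep protein similarity graph (50/50 gates),
    with a per-family NJ tree when the family has >= 3 members."""
    all_replicons = [r.replicon_id for g in genomes for r in g.replicons]
    assignment: dict[str, tuple[str | None, str | None]] = {r: (None, None) for r in all_replicons}
    families: dict[str, dict[str, list[str]]] = {}
    trees: dict[str, dict[str, dendropy.Tree]] = {}
    secondary: dict[str, list[str]] = {}
    for t_i, tag in enumerate(sorted(rep_proteins)):
        per_repl = rep_proteins[tag]
        seqs: dict[str, str] = {}
        gene_repl: dict[str, str] = {}
        for rid, genes in sorted(per_repl.items()):
            for gid, prot in sorted(genes):
                seqs[gid] = prot
                gene_repl[gid] = rid
        families[tag] = {}
        trees[tag] = {}
        if not seqs:
            continue
        graph = nx.Graph()
        graph.add_nodes_from(sorted(seqs))
        cache = _HitCache(seqs, prefilter=len(seqs) ** 2 > 20_000)
        ids = sorted(seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                h = cache.hit(a, b)
                if h is not None and _passes(h, min_identity, min_coverage, "each", None):
                    graph.add_edge(a, b, weight=h.score)
        clusters = mcl_cluster(graph, inflation=inflation).clusters
        for ci, cl in enumerate(sorted(clusters, key=lambda c: min(c))):
            fid = f"{tag}-MCL{ci + 1}"
            members = sorted({gene_repl[g] for g in cl})
            families[tag][fid] = members
            for rid in members:
                c, b = assignment[rid]
                if tag == "repC":
                    if c is None:
                        assignment[rid] = (fid, b)
                    else:
                        secondary.setdefault(rid, []).append(fid)
                else:
                    if b is None:
                        assignment[rid] = (c, fid)
                    else:
                        secondary.setdefault(rid, []).append(fid)
            if len(cl) >= 3:
                aln_rows = {g: seqs[g] for g in cl}
                if len({len(s) for s in aln_rows.values()}) == 1:
                    aln = MarkerAlignment(fid, aln_rows)
                else:
                    from .phylo import _star_align

                    aln = MarkerAlignment(fid, _star_align(aln_rows))
                from .phylo import trim_columns

                dm = pairwise_distance(trim_columns(aln))
                trees[tag][fid] = nj_tree(dm)
    n_fam = {t: len(f) for t, f in families.items()}
    _log.info("family_clusters: %s", n_fam)
    return RepFamilyAssignment(assignment, families, trees, secondary)


def replicon_conservation(
    a: RepliconRecord | str, b: RepliconRecord | str, min_match_len: int = 300
) -> float:
    """Fraction of replicon ``a`` covered by registered matches to ``b``
    (merged intervals; both strands)."""
    seq_a = a.sequence if isinstance(a, RepliconRecord) else a
    matches = register_matches(a, b, min_match_len=min_match_len)
    intervals = sorted((m.start_a, m.end_a) for m in matches)
    covered = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s
    return covered / len(seq_a) if seq_a else 0.0
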