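"""Genome inclusion criteria for a candidate collection.

A genome is kept iff it carries all of the required symbiosis genes
(nodABC and nifHDK by default) and, when it is a draft assembly, its total
length exceeds ``min_draft_length`` (6 Mb by default — complete genomes pass
on completeness alone). Presence is judged from gene ``role_tags``; for
un-annotated real data a homology mode matches each genome's proteome
against user-supplied seed proteins at the pangenome thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_core import GenomeRecord, get_logger

_log = get_logger("collection_filter")

REQUIRED_SYMBIOSIS_TAGS = frozenset({"nodA", "nodB", "nodC", "nifH", "nifD", "nifK"})
MIN_DRAFT_LENGTH = 6_000_000


@dataclass
class FilterReport:
    kept: list[str]
    excluded: list[tuple[str, str]]  # (genome_id, reason)
    thresholds: dict = field(default_factory=dict)

    def kept_genomes(self, genomes: list[GenomeRecord]) -> list[GenomeRecord]:
        keep = set(self.kept)
        return [g for g in genomes if g.genome_id in keep]


def filter_collection(
    genomes: list[GenomeRecord],
    min_draft_length: int = MIN_DRAFT_LENGTH,
    required_tags: frozenset[str] | set[str] = REQUIRED_SYMBIOSIS_TAGS,
    seed_proteins: dict[str, str] | None = None,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> FilterReport:
    """Apply the inclusion criteria; every exclusion records its reason.

    ``seed_proteins`` (tag -> protein sequence) switches gene-presence
    checking from annotation tags to homology search at the given
    identity/coverage thresholds.
    """
    if not genomes:
        raise ValueError("empty collection")
    kept: list[str] = []
    excluded: list[tuple[str, str]] = []
    for g in genomes:
        reasons = []
        if seed_proteins:
            missing = _missing_by_homology(g, required_tags, seed_proteins, min_identity, min_coverage)
        else:
            tags = g.role_tags()
            missing = sorted(set(required_tags) - tags)
        if missing:
            reasons.append("missing:" + ",".join(missing))
        if g.status == "draft" and g.total_length <= min_draft_length:
            reasons.append("length")
        if reasons:
            excluded.append((g.genome_id, ";".join(reasons)))
        else:
            kept.append(g.genome_id)
    report = FilterReport(
        kept=kept,
        excluded=excluded,
        thresholds={
            "min_draft_length": min_draft_length,
            "required_tags": sorted(required_tags),
            "mode": "homology" if seed_proteins else "tags",
        },
    )
    _log.info("filter_collection: %d in, %d kept, %d excluded", len(genomes), len(kept), len(excluded))
    return report


def _missing_by_homology(genome, required_tags, seed_proteins, min_identity, min_coverage):
    from .orthology import align_proteins

    proteome = list(genome.proteome().values())
    missing = []
    for tag in sorted(required_tags):
        seed = seed_proteins.get(tag)
        if seed is None:
            missing.append(tag)
            continue
        found = False
        for prot in proteome:
            hit = align_proteins(seed, prot)
            if hit.pct_identity >= min_identity and min(hit.query_cov, hit.target_cov) >= min_coverage:
                found = True
                break
        if not found:
            missing.append(tag)
    return missing
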