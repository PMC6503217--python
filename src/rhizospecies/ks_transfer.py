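"""Synonymous-rate contrasts between chromosome and symbiotic plasmid.

A recently transferred symbiotic plasmid (pSym) has had little time to
accumulate neutral divergence, so for a pair of strains its genes show
synonymous substitution rates (Ks) near zero while chromosomal orthologs of
the same pair are far more diverged. This module pairs orthologs per
compartment (BDBH), estimates Ks per pair with the Nei-Gojobori (1986)
method (codon-path averaged counts, Jukes-Cantor correction), and flags a
pair of genomes as a likely recent pSym transfer when the median pSym Ks is
a small fraction of the median chromosomal Ks — guarded by a minimum
chromosomal Ks so that genuinely recent strain splits (both compartments
near zero) are not called transfers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .io_core import GeneRecord, GenomeRecord, get_logger
from .orthology import bdbh
from .synthetic_data import STOP_CODONS, _CODON_AA, _SYN_OPTIONS, encode_dna

_log = get_logger("ks_transfer")


# --- NG86 ------------------------------------------------------------------


@dataclass
class KsResult:
    ks: float  # NaN when saturated
    ps: float
    syn_sites: float  # S
    syn_diffs: float  # Sd
    nonsyn_sites: float
    nonsyn_diffs: float
    saturated: bool


def _codon_tuple(codes: np.ndarray, i: int) -> tuple[int, int, int]:
    return (int(codes[i]), int(codes[i + 1]), int(codes[i + 2]))


def _count_diffs(ca: tuple, cb: tuple) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    over all mutational orderings (paths through stop codons are skipped
    unless every path hits one)."""
    positions = [p for p in range(3) if ca[p] != cb[p]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur = list(ca)
        sd = nd = 0.0
        through_stop = False
        for p in order:
            nxt = list(cur)
            nxt[p] = cb[p]
            if tuple(nxt) in STOP_CODONS:
                through_stop = True
            aa_cur = _CODON_AA[tuple(cur)]
            aa_nxt = _CODON_AA.get(tuple(nxt), "*")
            if aa_cur == aa_nxt and aa_nxt != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((through_stop, sd, nd))
    valid = [(sd, nd) for stop, sd, nd in paths if not stop]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def ks_ng86(cds_a: str, cds_b: str) -> KsResult:
    """Nei-Gojobori (1986) synonymous substitution rate for a codon-aligned
    CDS pair.

    Synonymous site counts per codon are (synonymous one-step changes)/3
    per position (changes into stops count as nonsynonymous); differences
    are averaged over mutational paths; pS = Sd/S gets the Jukes-Cantor
    correction Ks = -(3/4) ln(1 - 4 pS / 3). Pairs where the log argument
    is <= 0 are returned flagged saturated (Ks = NaN).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(f"CDS length mismatch: {len(cds_a)} vs {len(cds_b)}")
    if len(cds_a) % 3:
        raise ValueError("CDS length not divisible by 3")
    a = encode_dna(cds_a)
    b = encode_dna(cds_b)
    S = Sd = N = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = _codon_tuple(a, i), _codon_tuple(b, i)
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon at position {i}")
        sa = len(_SYN_OPTIONS[ca]) / 3.0
        sb = len(_SYN_OPTIONS[cb]) / 3.0
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _count_diffs(ca, cb)
        Sd += sd
        Nd += nd
    if S <= 0:
        raise ValueError("no synonymous sites")
    ps = Sd / S
    arg = 1.0 - 4.0 * ps / 3.0
    if arg <= 0:
        return KsResult(float("nan"), ps, S, Sd, N, Nd, True)
    return KsResult(-0.75 * float(np.log(arg)), ps, S, Sd, N, Nd, False)


def ks_third_position(cds_a: str, cds_b: str) -> float:
    """Naive variant: Jukes-Cantor-corrected p-distance over third codon
    positions only (NaN when saturated)."""
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("need equal codon-aligned CDSs")
    a = np.frombuffer(cds_a.encode(), np.uint8)[2::3]
    b = np.frombuffer(cds_b.encode(), np.uint8)[2::3]
    p = float((a != b).mean())
    arg = 1.0 - 4.0 * p / 3.0
    return float("nan") if arg <= 0 else -0.75 * float(np.log(arg))


# --- compartment pairing ---------------------------------------------------


def _compartment_genes(genome: GenomeRecord, kind: str) -> dict[str, GeneRecord]:
    out = {}
    for repl in genome.replicons:
        if repl.kind == kind:
            for gene in repl.genes:
                if gene.protein and gene.cds:
                    out[gene.gene_id] = gene
    return out


def pair_homologs_by_compartment(
    a: GenomeRecord,
    b: GenomeRecord,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> tuple[list[tuple[GeneRecord, GeneRecord]], list[tuple[GeneRecord, GeneRecord]]]:
    """BDBH ortholog pairs within each compartment (chromosome, pSym).

    BDBH is run separately per compartment, so a gene that moved between
    compartments cannot be paired across them: chromosome is compared with
    chromosome, pSym with pSym.
    """
    for g in (a, b):
        g.chromosome  # raises when absent
    if a.psym is None and b.psym is None:
        raise ValueError(f"neither genome ({a.genome_id}, {b.genome_id}) has a symbiotic plasmid")
    out = []
    for kind in ("chromosome", "psym"):
        genes_a = _compartment_genes(a, kind)
        genes_b = _compartment_genes(b, kind)
        pairs: list[tuple[GeneRecord, GeneRecord]] = []
        if genes_a and genes_b:
            graph = bdbh(
                {a.genome_id: {g: genes_a[g].protein for g in genes_a},
                 b.genome_id: {g: genes_b[g].protein for g in genes_b}},
                min_identity=min_identity,
                min_coverage=min_coverage,
                use_score_floor=False,
                prefilter=True,
            )
            for u, v in sorted(graph.edges):
                ga = genes_a.get(u) or genes_a.get(v)
                gb = genes_b.get(u) or genes_b.get(v)
                if ga is not None and gb is not None:
                    pairs.append((ga, gb))
        out.append(pairs)
    _log.info(
        "pair_homologs(%s, %s): %d chromosome pairs, %d psym pairs",
        a.genome_id, b.genome_id, len(out[0]), len(out[1]),
    )
    return out[0], out[1]


def codon_align(gene_a: GeneRecord, gene_b: GeneRecord) -> tuple[str, str]:
    """Codon-level alignment of two CDSs via their protein alignment
    (gapped columns dropped)."""
    if len(gene_a.cds) == len(gene_b.cds) and len(gene_a.protein) == len(gene_b.protein):
        return gene_a.cds, gene_b.cds
    from Bio.Align import PairwiseAligner, substitution_matrices

    al = PairwiseAligner(mode="global")
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    aln = al.align(gene_a.protein, gene_b.protein)[0]
    ca, cb = [], []
    for (as_, ae), (bs, be) in zip(aln.aligned[0], aln.aligned[1]):
        for i in range(ae - as_):
            ca.append(gene_a.cds[3 * (as_ + i) : 3 * (as_ + i) + 3])
            cb.append(gene_b.cds[3 * (bs + i) : 3 * (bs + i) + 3])
    return "".join(ca), "".join(cb)


# --- contrast --------------------------------------------------------------


@dataclass
class CompartmentContrast:
    genome_a: str
    genome_b: str
    ks_values_chromosome: list[float]
    ks_values_psym: list[float]
    n_saturated_chromosome: int
    n_saturated_psym: int
    median_ks_chr: float
    median_ks_psym: float
    ratio: float  # median_ks_psym / median_ks_chr
    transfer_flag: bool | None  # None = indeterminate (too few pairs)
    reverse_flag: bool  # pSym much *more* diverged than chromosome


def compartment_contrast(
    a: GenomeRecord,
    b: GenomeRecord,
    transfer_ratio_max: float = 0.2,
    min_chr_ks: float = 0.1,
    min_pairs: int = 10,
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> CompartmentContrast:
    """Chromosome-vs-pSym Ks contrast for one genome pair.

    transfer_flag is true when median pSym Ks / median chromosomal Ks <
    ``transfer_ratio_max`` AND the chromosomal median exceeds
    ``min_chr_ks`` (so recent strain splits with both compartments near
    zero are not flagged). The reverse pattern (pSym median more than
    1/ratio times the chromosomal median) marks compartments on dissimilar
    evolutionary lines.
    """
    chr_pairs, psym_pairs = pair_homologs_by_compartment(a, b, min_identity, min_coverage)
    values: dict[str, list[float]] = {"chromosome": [], "psym": []}
    n_sat = {"chromosome": 0, "psym": 0}
    for kind, pairs in (("chromosome", chr_pairs), ("psym", psym_pairs)):
        for ga, gb in pairs:
            ca, cb = codon_align(ga, gb)
            res = ks_ng86(ca, cb)
            if res.saturated:
                n_sat[kind] += 1
            else:
                values[kind].append(res.ks)
    med_chr = float(np.median(values["chromosome"])) if values["chromosome"] else float("nan")
    med_psym = float(np.median(values["psym"])) if values["psym"] else float("nan")
    ratio = med_psym / med_chr if med_chr and np.isfinite(med_chr) and np.isfinite(med_psym) else float("nan")
    if len(values["chromosome"]) < min_pairs or len(values["psym"]) < min_pairs:
        flag: bool | None = None
    else:
        flag = bool(np.isfinite(ratio) and ratio < transfer_ratio_max and med_chr > min_chr_ks)
    reverse = bool(
        np.isfinite(ratio) and ratio > 1.0 / transfer_ratio_max and med_psym > min_chr_ks
    )
    return CompartmentContrast(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        ks_values_chromosome=values["chromosome"],
        ks_values_psym=values["psym"],
        n_saturated_chromosome=n_sat["chromosome"],
        n_saturated_psym=n_sat["psym"],
        median_ks_chr=med_chr,
        median_ks_psym=med_psym,
        ratio=ratio,
        transfer_flag=flag,
        reverse_flag=reverse,
    )
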