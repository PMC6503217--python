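"""Pairwise average nucleotide identity (ANI), genome coverage, and
whole-replicon match registration.

ANI here is fragment-based (JSpecies/ANIb-like): the query genome is cut
into consecutive ``frag_len`` windows, each fragment is placed at its best
seed-supported location in the target (exact k-mer seeds grouped into
diagonal bands, banded edit-distance extension via edlib), and fragments
passing the identity/coverage gates are averaged. A match-length-weighted
variant ("anim-like") is reported alongside for robustness checks; the two
track each other closely on collections where both are defined.

Both directed values and their mean (the symmetric ANI used downstream) are
reported; coverage (Gcov) is query-based: retained fragment length over
query length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .io_core import GenomeRecord, RepliconRecord, get_logger
from .synthetic_data import encode_dna

_log = get_logger("ani_engine")

DEFAULT_FRAG_LEN = 1020
DEFAULT_MIN_FRAG_IDENTITY = 30.0
DEFAULT_MIN_FRAG_ALN_COV = 70.0
DEFAULT_K = 15
DEFAULT_BAND = 32
MIN_SEED_HITS = 2  # distinct seed matches required on the winning diagonal band
_MAX_KMER_HITS = 200  # repeat guard: hyper-abundant seeds are skipped


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h = h * np.uint64(4) + codes[j : j + n].astype(np.uint64)
    return h


class _RepliconIndex:
    __slots__ = ("seq", "codes", "hashes", "order", "sorted_hashes")

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.codes = encode_dna(seq) if seq else np.zeros(0, np.uint8)
        self.hashes = _kmer_hashes(self.codes, k)
        self.order = np.argsort(self.hashes, kind="stable")
        self.sorted_hashes = self.hashes[self.order]


class GenomeIndex:
    """Per-genome k-mer index reused across all pairwise comparisons."""

    def __init__(self, genome: GenomeRecord, k: int = DEFAULT_K):
        self.genome_id = genome.genome_id
        self.k = k
        self.replicons = [_RepliconIndex(r.sequence, k) for r in genome.replicons]
        self.total_length = sum(len(r.seq) for r in self.replicons)


def _best_location(frag_hashes: np.ndarray, target: "_RepliconIndex", band: int, k: int):
    """Return (support, diagonal) of the best-supported diagonal band, or None.

    Support counts *distinct* seed runs: consecutive overlapping anchors on
    one diagonal (a single chance exact match of length > k) collapse into
    one run, so spurious placements on unrelated sequence rarely reach a
    support of 2.
    """
    lo = np.searchsorted(target.sorted_hashes, frag_hashes, side="left")
    hi = np.searchsorted(target.sorted_hashes, frag_hashes, side="right")
    counts = hi - lo
    counts = np.where(counts > _MAX_KMER_HITS, 0, counts)
    total = int(counts.sum())
    if total == 0:
        return None
    reps = counts[counts > 0]
    qoff = np.repeat(np.nonzero(counts)[0], reps)
    base = np.repeat(lo[counts > 0], reps)
    local = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
    tpos = target.order[base + local]
    diag = tpos.astype(np.int64) - qoff
    bands = diag // band
    uniq, cnt = np.unique(bands, return_counts=True)
    best = int(np.argmax(cnt))  # ties: np.unique is sorted, argmax takes smallest band
    in_band = bands == uniq[best]
    q_in = np.sort(qoff[in_band])
    breaks = np.diff(q_in) >= k
    support = 1 + int(breaks.sum())
    # one *long* exact run (>= 2k+2) is itself conclusive: chance exact
    # matches extend past k only geometrically
    run_starts = np.concatenate([[0], np.nonzero(breaks)[0] + 1])
    run_ends = np.concatenate([np.nonzero(breaks)[0], [len(q_in) - 1]])
    max_run = int((q_in[run_ends] - q_in[run_starts]).max()) + k
    if support < MIN_SEED_HITS and max_run >= 2 * k + 2:
        support = MIN_SEED_HITS
    # representative diagonal: the smallest target-coordinate anchor in the band
    d = int(diag[in_band][np.argmin(tpos[in_band])])
    return support, d


@dataclass
class _DirectedAni:
    ani_pct: float
    ani_weighted_pct: float
    gcov_pct: float
    n_fragments_total: int
    n_fragments_retained: int


def _directed_ani(
    query: GenomeIndex,
    target: GenomeIndex,
    frag_len: int,
    min_frag_identity: float,
    min_frag_aln_cov: float,
    band: int,
) -> _DirectedAni:
    k = query.k
    identities: list[float] = []
    lengths: list[int] = []
    n_total = 0
    retained_len = 0
    for qrep in query.replicons:
        L = len(qrep.seq)
        if L == 0:
            continue
        if L < frag_len:
            _log.debug("replicon shorter than one fragment; single-fragment mode")
        for fs in range(0, L, frag_len):
            fe = min(fs + frag_len, L)
            n_total += 1
            if fe - fs < k:
                continue
            fh = qrep.hashes[fs : fe - k + 1]
            best = None
            for t_i, trep in enumerate(target.replicons):
                if len(trep.sorted_hashes) == 0:
                    continue
                loc = _best_location(fh, trep, band, k)
                if loc is None:
                    continue
                hits, diag = loc
                key = (-hits, t_i, diag)
                if best is None or key < best[0]:
                    best = (key, t_i, diag)
            if best is None or -best[0][0] < MIN_SEED_HITS:
                continue
            _, t_i, diag = best
            trep = target.replicons[t_i]
            flen = fe - fs
            ws = max(diag - band, 0)
            we = min(diag + flen + band, len(trep.seq))
            if we - ws < k:
                continue
            res = edlib.align(qrep.seq[fs:fe], trep.seq[ws:we], mode="HW", task="distance")
            dist = res["editDistance"]
            if dist < 0:
                continue
            identity = 100.0 * max(flen - dist, 0) / flen
            # infix alignment consumes the full query, so aligned coverage is
            # complete whenever a placement exists
            if identity >= min_frag_identity and 100.0 >= min_frag_aln_cov:
                identities.append(identity)
                lengths.append(flen)
                retained_len += flen
    if identities:
        ids = np.array(identities)
        lens = np.array(lengths, dtype=float)
        ani = float(ids.mean())
        ani_w = float((ids * lens).sum() / lens.sum())
    else:
        ani = ani_w = 0.0
    gcov = 100.0 * retained_len / query.total_length if query.total_length else 0.0
    return _DirectedAni(ani, ani_w, gcov, n_total, len(identities))


@dataclass
class AniResult:
    """Directed and symmetric ANI/Gcov for one genome pair."""

    genome_a: str
    genome_b: str
    ani_pct: float  # mean of the two directed fragment-mean values
    gcov_pct: float
    ani_ab_pct: float
    ani_ba_pct: float
    gcov_ab_pct: float
    gcov_ba_pct: float
    ani_weighted_pct: float  # match-length-weighted ("anim-like") symmetric value
    n_fragments_total: int
    n_fragments_retained: int


def compute_ani(
    a: GenomeRecord | GenomeIndex,
    b: GenomeRecord | GenomeIndex,
    frag_len: int = DEFAULT_FRAG_LEN,
    min_frag_identity: float = DEFAULT_MIN_FRAG_IDENTITY,
    min_frag_aln_cov: float = DEFAULT_MIN_FRAG_ALN_COV,
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
) -> AniResult:
    """Fragment-based ANI between two genomes (both directions + mean)."""
    if frag_len < 100:
        raise ValueError("frag_len must be >= 100")
    ia = a if isinstance(a, GenomeIndex) else GenomeIndex(a, k)
    ib = b if isinstance(b, GenomeIndex) else GenomeIndex(b, k)
    if ia.total_length == 0 or ib.total_length == 0:
        raise ValueError("empty genome")
    ab = _directed_ani(ia, ib, frag_len, min_frag_identity, min_frag_aln_cov, band)
    ba = _directed_ani(ib, ia, frag_len, min_frag_identity, min_frag_aln_cov, band)
    return AniResult(
        genome_a=ia.genome_id,
        genome_b=ib.genome_id,
        ani_pct=(ab.ani_pct + ba.ani_pct) / 2.0,
        gcov_pct=(ab.gcov_pct + ba.gcov_pct) / 2.0,
        ani_ab_pct=ab.ani_pct,
        ani_ba_pct=ba.ani_pct,
        gcov_ab_pct=ab.gcov_pct,
        gcov_ba_pct=ba.gcov_pct,
        ani_weighted_pct=(ab.ani_weighted_pct + ba.ani_weighted_pct) / 2.0,
        n_fragments_total=ab.n_fragments_total + ba.n_fragments_total,
        n_fragments_retained=ab.n_fragments_retained + ba.n_fragments_retained,
    )


def ani_matrix(
    collection: list[GenomeRecord],
    frag_len: int = DEFAULT_FRAG_LEN,
    min_frag_identity: float = DEFAULT_MIN_FRAG_IDENTITY,
    min_frag_aln_cov: float = DEFAULT_MIN_FRAG_ALN_COV,
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
    return_pairs: bool = False,
):
    """Symmetric ANI and Gcov matrices (%) over a collection.

    Diagonal is 100 by definition. With ``return_pairs`` the per-pair
    :class:`AniResult` list is returned as a third element.
    """
    if len(collection) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.genome_id for g in collection]
    indexes = [GenomeIndex(g, k) for g in collection]
    n = len(ids)
    ani = np.full((n, n), 100.0)
    gcov = np.full((n, n), 100.0)
    pairs: list[AniResult] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = compute_ani(indexes[i], indexes[j], frag_len, min_frag_identity, min_frag_aln_cov, k, band)
            except ValueError as exc:
                raise ValueError(f"ANI failed for pair ({ids[i]}, {ids[j]}): {exc}") from exc
            ani[i, j] = ani[j, i] = r.ani_pct
            gcov[i, j] = gcov[j, i] = r.gcov_pct
            pairs.append(r)
    _log.info("ani_matrix: %d genomes, %d pairs", n, len(pairs))
    ani_df = pd.DataFrame(ani, index=ids, columns=ids)
    gcov_df = pd.DataFrame(gcov, index=ids, columns=ids)
    if return_pairs:
        return ani_df, gcov_df, pairs
    return ani_df, gcov_df


# ---------------------------------------------------------------------------
# Whole-replicon match registration (MUMmer-style, > min_match_len)


@dataclass
class Match:
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    pct_identity: float
    strand: str  # + / -


@dataclass
class MatchSet:
    matches: list[Match] = field(default_factory=list)

    def __iter__(self):
        return iter(self.matches)

    def __len__(self):
        return len(self.matches)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.start_a, m.end_a, m.start_b, m.end_b, m.pct_identity, m.strand) for m in self.matches],
            columns=["start_a", "end_a", "start_b", "end_b", "pct_identity", "strand"],
        )


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].copy()


def _collect_anchors(qh: np.ndarray, tindex: _RepliconIndex) -> np.ndarray:
    """(qoff, tpos) anchor pairs for every exact shared k-mer."""
    lo = np.searchsorted(tindex.sorted_hashes, qh, side="left")
    hi = np.searchsorted(tindex.sorted_hashes, qh, side="right")
    counts = np.where(hi - lo > _MAX_KMER_HITS, 0, hi - lo)
    total = int(counts.sum())
    if total == 0:
        return np.zeros((0, 2), dtype=np.int64)
    reps = counts[counts > 0]
    qoff = np.repeat(np.nonzero(counts)[0], reps)
    base = np.repeat(lo[counts > 0], reps)
    local = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
    tpos = tindex.order[base + local]
    return np.stack([qoff, tpos.astype(np.int64)], axis=1)


def register_matches(
    replicon_a: RepliconRecord | str,
    replicon_b: RepliconRecord | str,
    min_match_len: int = 300,
    k: int = DEFAULT_K,
    max_gap: int = 200,
) -> MatchSet:
    """Seeded ungapped local matches longer than ``min_match_len``.

    Exact shared k-mers are chained along each diagonal (gaps up to
    ``max_gap`` between consecutive anchors, bridging isolated mismatches);
    chains longer than the threshold are registered with their percent
    identity, on both strands, sorted by ``start_a``.
    """
    seq_a = replicon_a.sequence if isinstance(replicon_a, RepliconRecord) else replicon_a
    seq_b = replicon_b.sequence if isinstance(replicon_b, RepliconRecord) else replicon_b
    if not seq_a or not seq_b:
        raise ValueError("empty replicon sequence")
    ca = encode_dna(seq_a)
    cb = encode_dna(seq_b)
    qh = _kmer_hashes(ca, k)
    matches: list[Match] = []
    for strand in ("+", "-"):
        cb_s = cb if strand == "+" else _revcomp_codes(cb)
        tindex = _RepliconIndex.__new__(_RepliconIndex)
        tindex.seq = ""
        tindex.codes = cb_s
        tindex.hashes = _kmer_hashes(cb_s, k)
        tindex.order = np.argsort(tindex.hashes, kind="stable")
        tindex.sorted_hashes = tindex.hashes[tindex.order]
        anchors = _collect_anchors(qh, tindex)
        if len(anchors) == 0:
            continue
        diag = anchors[:, 1] - anchors[:, 0]
        order = np.lexsort((anchors[:, 0], diag))
        anchors = anchors[order]
        diag = diag[order]
        start = 0
        for i in range(1, len(anchors) + 1):
            boundary = (
                i == len(anchors)
                or diag[i] != diag[start]
                or anchors[i, 0] - (anchors[i - 1, 0] + k) > max_gap
            )
            if not boundary:
                continue
            q0, qe = int(anchors[start, 0]), int(anchors[i - 1, 0]) + k
            if qe - q0 > min_match_len:
                d = int(diag[start])
                sub_a = ca[q0:qe]
                sub_b = cb_s[q0 + d : qe + d]
                ident = 100.0 * float((sub_a == sub_b).mean())
                if strand == "+":
                    sb, eb = q0 + d, qe + d
                else:
                    sb, eb = len(cb) - (qe + d), len(cb) - (q0 + d)
                matches.append(Match(q0, qe, sb, eb, ident, strand))
            start = i
    matches.sort(key=lambda m: (m.start_a, m.start_b, m.strand))
    return MatchSet(matches)


def ani_histogram(
    values, bin_width: float = 2.0, value_range: tuple[float, float] = (70.0, 100.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of pairwise ANI values per half-open ``bin_width``-wide bin.

    Values are clipped into the range so the total count is preserved; the
    top boundary value falls in the last bin. Returns (bin_left_edges,
    counts).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = value_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    vals = np.clip(np.asarray(list(values), dtype=float), lo, np.nextafter(hi, lo))
    if len(vals) == 0:
        return edges[:-1], np.zeros(len(edges) - 1, dtype=int)
    counts, _ = np.histogram(vals, bins=edges)
    return edges[:-1], counts
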