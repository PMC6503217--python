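"""Data model and on-disk formats shared by every analysis stage.

A genome collection is a list of :class:`GenomeRecord`, each holding one or
more :class:`RepliconRecord` (exactly one chromosome, optionally chromids and
plasmids, one of which may be the symbiotic plasmid, ``kind="psym"``), each
holding :class:`GeneRecord` objects with 0-based half-open coordinates on the
forward strand.

On disk a collection is one nucleotide FASTA per genome (one record per
replicon, with ``genome=``/``kind=``/``status=`` key=value tokens in the
description) plus a single gene table TSV. Distance and percentage matrices
are written as labelled TSV at fixed precision; trees as Newick (dendropy).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BACTERIAL_TABLE = 11

REPLICON_KINDS = ("chromosome", "chromid", "plasmid", "psym")

GENE_TABLE_COLUMNS = (
    "gene_id",
    "genome_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "role_tags",
    "family_truth",
    "cds",
)

_log = logging.getLogger("rhizospecies")
if not _log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    _log.addHandler(_h)
    _log.setLevel(logging.WARNING)


def get_logger(name: str | None = None) -> logging.Logger:
    """One structured log stream for the whole pipeline."""
    return _log if name is None else _log.getChild(name)


def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard bacterial code (table 11)."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate(table=BACTERIAL_TABLE))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GeneRecord:
    """A gene on a replicon; coordinates are 0-based half-open, forward strand.

    ``strand`` only affects CDS extraction (reverse complement for ``-``).
    ``role_tags`` carries functional labels such as ``ribosomal``,
    ``symbiotic``, ``nodC`` or ``repC``; ``family_truth`` is the simulator's
    ground-truth family label and is absent on real data.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    cds: str = ""
    protein: str = ""
    role_tags: set[str] = field(default_factory=set)
    family_truth: str | None = None

    def validate(self, replicon_length: int | None = None) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end ({self.end}) <= start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if replicon_length is not None and (self.start < 0 or self.end > replicon_length):
            raise ValueError(
                f"gene {self.gene_id}: coordinates [{self.start}, {self.end}) outside "
                f"replicon of length {replicon_length}"
            )
        if self.cds and self.protein and translate_cds(self.cds) != self.protein:
            raise ValueError(f"gene {self.gene_id}: cds does not translate to protein")


@dataclass
class RepliconRecord:
    replicon_id: str
    kind: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if self.kind not in REPLICON_KINDS:
            raise ValueError(f"replicon {self.replicon_id}: unknown kind {self.kind!r}")
        for g in self.genes:
            g.validate(len(self.sequence))
        if self.kind == "psym" and not any("nodC" in g.role_tags for g in self.genes):
            raise ValueError(f"replicon {self.replicon_id}: kind=psym but no gene tagged nodC")

    def extract_cds(self, gene: GeneRecord) -> str:
        seg = self.sequence[gene.start : gene.end]
        return revcomp(seg) if gene.strand == "-" else seg


@dataclass
class GenomeRecord:
    genome_id: str
    status: str = "complete"  # complete | draft
    replicons: list[RepliconRecord] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.replicons)

    @property
    def chromosome(self) -> RepliconRecord:
        for r in self.replicons:
            if r.kind == "chromosome":
                return r
        raise ValueError(f"genome {self.genome_id}: no chromosome")

    @property
    def psym(self) -> RepliconRecord | None:
        for r in self.replicons:
            if r.kind == "psym":
                return r
        return None

    def genes(self):
        for r in self.replicons:
            yield from r.genes

    def role_tags(self) -> set[str]:
        tags: set[str] = set()
        for g in self.genes():
            tags |= g.role_tags
        return tags

    def proteome(self) -> dict[str, str]:
        """gene_id -> protein for every gene with a protein sequence."""
        return {g.gene_id: g.protein for g in self.genes() if g.protein}

    def validate(self) -> None:
        if self.status not in ("complete", "draft"):
            raise ValueError(f"genome {self.genome_id}: bad status {self.status!r}")
        n_chr = sum(1 for r in self.replicons if r.kind == "chromosome")
        if n_chr != 1:
            raise ValueError(f"genome {self.genome_id}: {n_chr} chromosomes (need exactly 1)")
        for r in self.replicons:
            r.validate()


def validate_collection(genomes: list[GenomeRecord]) -> None:
    seen: set[str] = set()
    for g in genomes:
        if g.genome_id in seen:
            raise ValueError(f"duplicate genome_id {g.genome_id}")
        seen.add(g.genome_id)
        g.validate()


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric labelled matrix; NaN entries must be flagged saturated."""

    labels: tuple[str, ...]
    values: np.ndarray
    saturated: np.ndarray | None = None  # boolean mask, same shape

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, equal_nan=True, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        nan = np.isnan(self.values)
        if nan.any():
            # every NaN must be covered by the saturated mask
            if self.saturated is None or (nan & ~np.asarray(self.saturated, bool)).any():
                raise ValueError("NaN entries present without a saturated flag")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def write(self, path: str | Path) -> None:
        write_matrix(self, path, allow_saturated=self.saturated is not None)

    @classmethod
    def read(cls, path: str | Path) -> "DistanceMatrix":
        labels, values = read_matrix(path)
        sat = np.isnan(values) if np.isnan(values).any() else None
        return cls(labels, values, sat)


def write_matrix(m, path: str | Path, allow_saturated: bool = False) -> None:
    """Write a symmetric labelled matrix as TSV (6 fixed decimals).

    ``m`` is a :class:`DistanceMatrix` or a ``(labels, values)`` pair.
    Asymmetric input is an error; NaN entries are an error unless
    ``allow_saturated`` (they round-trip as ``nan``).
    """
    if isinstance(m, DistanceMatrix):
        labels, values = m.labels, m.values
    else:
        labels, values = m
        values = np.asarray(values, dtype=float)
    if not np.allclose(values, values.T, equal_nan=True, atol=1e-9):
        raise ValueError("refusing to write asymmetric matrix")
    if np.isnan(values).any() and not allow_saturated:
        raise ValueError("NaN entry in matrix; pass allow_saturated=True to flag saturation")
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="label")


def read_matrix(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return tuple(str(c) for c in df.columns), df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# FASTA + gene table round trip


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    records = []
    for r in genome.replicons:
        rec = SeqRecord(
            Seq(r.sequence),
            id=r.replicon_id,
            description=f"genome={genome.genome_id} kind={r.kind} status={genome.status}",
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


def write_gene_table(genomes: list[GenomeRecord], path: str | Path) -> None:
    rows = []
    for g in genomes:
        for r in g.replicons:
            for gene in r.genes:
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "genome_id": g.genome_id,
                        "replicon_id": r.replicon_id,
                        "start": gene.start,
                        "end": gene.end,
                        "strand": gene.strand,
                        "role_tags": ",".join(sorted(gene.role_tags)),
                        "family_truth": gene.family_truth or "",
                        "cds": gene.cds,
                    }
                )
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_collection(genomes: list[GenomeRecord], outdir: str | Path) -> list[Path]:
    """One FASTA per genome plus ``genes.tsv``; returns the FASTA paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in sorted(genomes, key=lambda g: g.genome_id):
        p = outdir / f"{g.genome_id}.fasta"
        write_genome_fasta(g, p)
        paths.append(p)
    write_gene_table(genomes, outdir / "genes.tsv")
    return paths


def _parse_tokens(description: str) -> dict[str, str]:
    out = {}
    for tok in description.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_genome_collection(paths: list[str | Path], gene_table: str | Path | None) -> list[GenomeRecord]:
    """Load FASTA files plus a gene table into GenomeRecords.

    Replicon ``kind`` and genome ``status`` come from header tokens
    (``kind=...``, ``status=...``, ``genome=...``); genes are attached by
    ``replicon_id``. Output is ordered by genome_id; duplicate genome ids and
    out-of-bounds gene coordinates are hard errors.
    """
    genomes: dict[str, GenomeRecord] = {}
    replicons: dict[str, tuple[str, RepliconRecord]] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            toks = _parse_tokens(rec.description)
            gid = toks.get("genome", Path(path).stem)
            kind = toks.get("kind", "chromosome")
            status = toks.get("status", "complete")
            if gid not in genomes:
                genomes[gid] = GenomeRecord(genome_id=gid, status=status, replicons=[])
            elif genomes[gid].status != status:
                raise ValueError(f"genome {gid}: conflicting status tokens")
            if rec.id in replicons:
                raise ValueError(f"duplicate replicon_id {rec.id}")
            repl = RepliconRecord(replicon_id=rec.id, kind=kind, sequence=str(rec.seq).upper())
            genomes[gid].replicons.append(repl)
            replicons[rec.id] = (gid, repl)
    # a genome id appearing in two files is a duplicate collection entry
    ids_per_file: dict[str, set] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            gid = _parse_tokens(rec.description).get("genome", Path(path).stem)
            ids_per_file.setdefault(gid, set()).add(str(path))
    for gid, files in ids_per_file.items():
        if len(files) > 1:
            raise ValueError(f"duplicate genome_id {gid} across files {sorted(files)}")

    if gene_table is not None:
        df = pd.read_csv(gene_table, sep="\t", dtype=str, keep_default_na=False)
        if len(df):
            for idx, row in df.iterrows():
                rid = row["replicon_id"]
                if rid not in replicons:
                    raise ValueError(f"gene table row {idx}: unknown replicon {rid}")
                start, end = int(row["start"]), int(row["end"])
                if end <= start:
                    raise ValueError(
                        f"gene table row {idx} (gene {row['gene_id']}): end {end} <= start {start}"
                    )
                cds = row.get("cds", "")
                gene = GeneRecord(
                    gene_id=row["gene_id"],
                    start=start,
                    end=end,
                    strand=row.get("strand", "+") or "+",
                    cds=cds,
                    protein=translate_cds(cds) if cds and len(cds) % 3 == 0 else "",
                    role_tags=set(t for t in row.get("role_tags", "").split(",") if t),
                    family_truth=row.get("family_truth") or None,
                )
                _, repl = replicons[rid]
                gene.validate(len(repl.sequence))
                repl.genes.append(gene)

    out = sorted(genomes.values(), key=lambda g: g.genome_id)
    validate_collection(out)
    n_genes = sum(1 for g in out for _ in g.genes())
    _log.info("read_genome_collection: %d genomes, %d replicons, %d genes",
              len(out), sum(len(g.replicons) for g in out), n_genes)
    return out


# ---------------------------------------------------------------------------
# Trees


def read_tree(path_or_string: str | Path, schema: str = "newick") -> dendropy.Tree:
    s = str(path_or_string)
    if s.lstrip().startswith("(") or s.rstrip().endswith(";"):
        return dendropy.Tree.get(data=s, schema=schema)
    return dendropy.Tree.get(path=s, schema=schema)


def write_tree(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(s)
    return s


def load_config(path: str | Path) -> dict:
    """Read a TOML config holding every threshold used by the pipeline."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
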