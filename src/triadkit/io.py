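"""Readers and writers for the formats the pipeline touches.

All interval logic inside the package uses a single convention: 1-based,
closed intervals (the GFF3 convention). BED input is converted at the
boundary (+1 to the start) and converted back on output. Strand is carried
on gene models but never used to flip coordinates; all downstream overlap
logic is strand-blind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("triadkit")

_DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed or contract-violating input file."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequences:
    """An ordered collection of named DNA sequences for one haplotype.

    Sequences are uppercase strings over {A,C,G,T,N}; IDs are unique and
    order is preserved from the source file.
    """

    records: list[tuple[str, str]]
    haplotype_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq_id, seq in self.records:
            if seq_id in seen:
                raise FormatError(f"duplicate sequence ID {seq_id!r}")
            seen.add(seq_id)
            if not seq:
                raise FormatError(f"empty sequence for {seq_id!r}")
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"sequence {seq_id!r} contains non-DNA symbols {sorted(bad)}"
                )

    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def get(self, seq_id: str) -> str:
        for sid, seq in self.records:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path, haplotype_label: str = "") -> GenomeSequences:
    """Read a FASTA file into a :class:`GenomeSequences`.

    The header token before the first whitespace becomes the sequence ID;
    lowercase bases are folded to uppercase. Duplicate IDs and empty
    sequences are hard errors.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records and Path(path).stat().st_size > 0:
        raise FormatError(f"{path}: not a FASTA file")
    return GenomeSequences(records=records, haplotype_label=haplotype_label)


def read_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    """Like :func:`read_fasta` but without the DNA-alphabet restriction
    (for protein FASTA); still rejects duplicate IDs and empty sequences."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(seqs: GenomeSequences | Iterable[tuple[str, str]],
                path: str | Path, width: int = 60) -> None:
    records = seqs.records if isinstance(seqs, GenomeSequences) else list(seqs)
    bio = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene: span plus the CDS segments of its primary
    transcript (the transcript with the longest summed CDS; ties broken by
    lexicographically smallest transcript ID)."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based closed
    end: int
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    protein_id: str = ""

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


def _gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in raw.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 with gene/mRNA/CDS features.

    CDS features are grouped under their parent transcript; each gene is
    represented by its primary transcript (longest total CDS, ties by
    transcript ID). A CDS whose parent cannot be resolved to a gene, or
    that falls outside its gene's span, is a hard error naming the line.
    """
    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    tx_to_gene: dict[str, str] = {}
    tx_protein: dict[str, str] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    pending_cds: list[tuple[int, str, int, int]] = []  # (lineno, parent, s, e)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
            start, end = int(start_s), int(end_s)
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end")
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                                       start=start, end=end)
                gene_order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise FormatError(f"{path}:{lineno}: mRNA without ID/Parent")
                tx_to_gene[tid] = parent
                tx_cds.setdefault(tid, [])
                if "protein_id" in attrs:
                    tx_protein[tid] = attrs["protein_id"]
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: CDS without Parent")
                pending_cds.append((lineno, parent, start, end))

    for lineno, parent, start, end in pending_cds:
        if parent in tx_to_gene:
            tx_cds[parent].append((start, end))
            tid = parent
        elif parent in genes:
            # CDS attached directly to a gene: synthesise a transcript
            tid = parent + ".t0"
            tx_to_gene.setdefault(tid, parent)
            tx_cds.setdefault(tid, []).append((start, end))
        else:
            raise FormatError(
                f"{path}:{lineno}: CDS Parent {parent!r} does not resolve to a gene"
            )
        gene = genes[tx_to_gene[tid]]
        if start < gene.start or end > gene.end:
            raise FormatError(
                f"{path}:{lineno}: CDS [{start},{end}] outside span of gene "
                f"{gene.gene_id!r} [{gene.start},{gene.end}]"
            )

    # primary transcript per gene: longest CDS sum, ties by transcript ID
    by_gene: dict[str, list[str]] = {}
    for tid, gid in tx_to_gene.items():
        by_gene.setdefault(gid, []).append(tid)
    for gid, tids in by_gene.items():
        best = min(tids, key=lambda t: (-sum(e - s + 1 for s, e in tx_cds.get(t, [])), t))
        segs = sorted(tx_cds.get(best, []))
        for (s1, e1), (s2, _e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"{path}: overlapping CDS segments in transcript {best!r}"
                )
        genes[gid].cds_segments = segs
        genes[gid].protein_id = tx_protein.get(best, best)

    return [genes[g] for g in gene_order]


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={tid};Parent={g.gene_id};protein_id={g.protein_id or tid}\n")
            for s, e in g.cds_segments:
                fh.write(f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={tid}\n")


# ---------------------------------------------------------------------------
# Similarity hit table (12-column tab-separated, BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

@dataclass
class HitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"percent_identity {self.percent_identity} outside [0,100]")
        if self.alignment_length < 1:
            raise FormatError("alignment_length must be >= 1")


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated similarity table.

    Every row is parsed; no filtering happens at read time. A row with the
    wrong column count is an error naming the line.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            hits.append(HitRecord(
                query_id=cols[0], subject_id=cols[1],
                percent_identity=float(cols[2]),
                alignment_length=int(cols[3]), mismatches=int(cols[4]),
                gap_openings=int(cols[5]),
                q_start=int(cols[6]), q_end=int(cols[7]),
                s_start=int(cols[8]), s_end=int(cols[9]),
                e_value=float(cols[10]), bit_score=float(cols[11]),
            ))
    return hits


def write_hits(hits: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, h.percent_identity,
                h.alignment_length, h.mismatches, h.gap_openings,
                h.q_start, h.q_end, h.s_start, h.s_end,
                h.e_value, h.bit_score))) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3+ intervals, returned 1-based closed: (chrom, start, end, name).

    The 0-based half-open BED convention is converted at this boundary
    (start + 1); extra columns beyond the name (e.g. BED6 strand) are
    ignored with a logged notice.
    """
    out: list[tuple[str, int, int, str]] = []
    noticed = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            start0, end0 = int(start_s), int(end_s)
            if start0 >= end0:
                raise FormatError(
                    f"{path}:{lineno}: start {start0} >= end {end0}")
            name = cols[3] if len(cols) > 3 else f"{chrom}:{start0}-{end0}"
            if len(cols) > 4 and not noticed:
                logger.info("%s: columns beyond name (BED6+) ignored", path)
                noticed = True
            out.append((chrom, start0 + 1, end0, name))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]],
              path: str | Path) -> None:
    """Write 1-based closed intervals back out as BED (start - 1)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# Counts table (featureCounts-style TSV)
# ---------------------------------------------------------------------------

@dataclass
class CountsTable:
    """Gene-level read counts with effective lengths.

    ``counts`` is a genes x samples integer DataFrame; ``lengths`` a Series
    indexed like ``counts``; ``tissues`` maps each sample label to its
    tissue tag. Sample labels follow ``<tissue>`` or ``<tissue>_<rep>``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    tissues: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene_ids: {dupes[:5]}")
        if not self.counts.index.equals(self.lengths.index):
            raise FormatError("counts and lengths indexed differently")
        if (self.lengths <= 0).any():
            raise FormatError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def tissue_of(sample_label: str) -> str:
    """Default tissue-tag convention: the token before the first underscore."""
    return sample_label.split("_")[0]


def read_counts(path: str | Path,
                tissue_tags: dict[str, str] | None = None) -> CountsTable:
    """Read a counts TSV with header ``gene_id<TAB>length<TAB><sample1>...``."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id" or df.columns[1] != "length":
        raise FormatError(
            f"{path}: header must start with gene_id<TAB>length")
    df = df.set_index("gene_id")
    lengths = df["length"].astype(int)
    counts = df.drop(columns="length").astype(int)
    tags = tissue_tags or {s: tissue_of(s) for s in counts.columns}
    return CountsTable(counts=counts, lengths=lengths, tissues=tags)


def write_counts(table: CountsTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.lengths)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
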