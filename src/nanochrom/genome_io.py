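"""Readers, writers, and whole-assembly statistics.

Coordinate convention: files speak GFF3 (1-based, inclusive at both ends);
everything computed internally is 0-based half-open.  The readers and
writers in this module are the only place the shift happens, so downstream
code never converts coordinates itself.

Only ``A C G T N`` are accepted in sequence input.  Other IUPAC ambiguity
codes are rejected rather than silently remapped, because the substitution
spectrum downstream must be able to trust every base call.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

_COV_RE = re.compile(r"\bcov=([0-9]*\.?[0-9]+)\b")


@dataclass
class SequenceRecord:
    """A contig / chromosome sequence with optional read-depth coverage."""

    id: str
    seq: str
    coverage: Optional[float] = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """Strand-aware exon/CDS structure of a single gene.

    ``exons`` are 1-based inclusive genomic intervals, sorted ascending
    regardless of strand; orientation is handled by consumers.  ``tss`` /
    ``tes`` are set only when transcript bounds extend past the CDS.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    tss: Optional[int] = None
    tes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    def introns(self) -> list[tuple[int, int]]:
        """1-based inclusive intervals between consecutive exons."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def gene_body_len(self) -> Optional[int]:
        """Start codon to stop codon, introns included."""
        if self.cds_start is None or self.cds_end is None:
            return None
        return self.cds_end - self.cds_start + 1

    @property
    def mrna_len(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    gc_fraction: float  # NaN when no non-N base exists
    n50: int
    mean_len: float
    median_len: float


@dataclass
class ExpressionRecord:
    gene_id: str
    count: Optional[int] = None
    effective_length: Optional[int] = None
    tpm: Optional[float] = None


def _validate_seq(seq: str, record_id: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"record {record_id!r}: invalid character {seq[pos]!r} at position "
            f"{pos + 1} (only A/C/G/T/N accepted)"
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA into :class:`SequenceRecord` objects.

    Sequences are uppercased; the id is the first whitespace-delimited
    header token; a ``cov=X`` tag anywhere in the header is parsed into
    ``coverage``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) < 1:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        _validate_seq(seq, rec.id)
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        m = _COV_RE.search(rec.description)
        cov = float(m.group(1)) if m else None
        records.append(SequenceRecord(id=rec.id, seq=seq, coverage=cov))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns, with a cov= header tag if set."""
    bio = []
    for r in records:
        desc = f"cov={r.coverage:g}" if r.coverage is not None else ""
        bio.append(_BioSeqRecord(Seq(r.seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def read_gff(
    path: str | Path, genome: Optional[Sequence[SequenceRecord]] = None
) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS rows of a GFF3 file into gene models.

    TSS/TES are derived from the mRNA bounds when they extend beyond the
    CDS in the gene's orientation, and left unset otherwise.  When
    ``genome`` is supplied, exon coordinates are checked against contig
    lengths.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    contig_len = {r.id: len(r.seq) for r in genome} if genome is not None else None

    # contract check: every CDS row must trace back to a gene
    for cds in db.features_of_type("CDS"):
        if not list(db.parents(cds, featuretype="gene")):
            raise ValueError(f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no parent gene")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exon_feats = sorted(
            db.children(parent, featuretype="exon"), key=lambda f: f.start
        )
        cds_feats = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
        if exon_feats:
            exons = [(f.start, f.end) for f in exon_feats]
        elif cds_feats:
            exons = [(f.start, f.end) for f in cds_feats]
        else:
            raise ValueError(f"gene {gene.id}: no exon or CDS rows")
        if contig_len is not None:
            if gene.seqid not in contig_len:
                raise ValueError(f"gene {gene.id}: unknown contig {gene.seqid!r}")
            if exons[-1][1] > contig_len[gene.seqid] or exons[0][0] < 1:
                raise ValueError(f"gene {gene.id}: exon outside contig bounds")

        cds_start = min(f.start for f in cds_feats) if cds_feats else None
        cds_end = max(f.end for f in cds_feats) if cds_feats else None
        tss = tes = None
        if cds_start is not None:
            t_start, t_end = parent.start, parent.end
            if gene.strand == "+":
                tss = t_start if t_start < cds_start else None
                tes = t_end if t_end > cds_end else None
            else:
                tss = t_end if t_end > cds_end else None
                tes = t_start if t_start < cds_start else None
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
                tss=tss,
                tes=tes,
            )
        )
    return models


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS rows (GFF3, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ex_min = g.exons[0][0]
            ex_max = g.exons[-1][1]
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.contig_id}\tnanochrom\tgene\t{ex_min}\t{ex_max}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig_id}\tnanochrom\tmRNA\t{ex_min}\t{ex_max}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig_id}\tnanochrom\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mid}\n"
                )
            if g.cds_start is not None and g.cds_end is not None:
                for s, e in g.exons:
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs <= ce:
                        fh.write(
                            f"{g.contig_id}\tnanochrom\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t"
                            f"Parent={mid}\n"
                        )


def filter_contigs(
    records: Sequence[SequenceRecord],
    min_len: int = 200,
    min_cov: float = 2.0,
) -> list[SequenceRecord]:
    """Drop contigs shorter than ``min_len`` or with coverage below ``min_cov``.

    Thresholds are strict removals (< min), so a contig at exactly the
    threshold is retained.  When ``min_cov`` is 0, records without a
    coverage value pass; otherwise they are rejected.
    """
    kept = []
    for r in records:
        if len(r.seq) < min_len:
            continue
        if min_cov > 0:
            if r.coverage is None or r.coverage < min_cov:
                continue
        kept.append(r)
    if not kept:
        raise ValueError("contig filter removed every record (empty assembly)")
    return kept


def assembly_stats(records: Sequence[SequenceRecord]) -> AssemblyStats:
    """Contig count, total size, GC over non-N bases, and N50.

    N50 is the largest length L such that contigs of length >= L cover at
    least half of the total assembly span.
    """
    if not records:
        raise ValueError("empty assembly")
    lengths = np.array([len(r.seq) for r in records])
    total = int(lengths.sum())
    gc = at = 0
    for r in records:
        gc += r.seq.count("G") + r.seq.count("C")
        at += r.seq.count("A") + r.seq.count("T")
    gc_fraction = gc / (gc + at) if (gc + at) > 0 else math.nan
    desc = np.sort(lengths)[::-1]
    csum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(csum, total / 2)])
    return AssemblyStats(
        n_contigs=len(records),
        total_bp=total,
        gc_fraction=gc_fraction,
        n50=n50,
        mean_len=float(lengths.mean()),
        median_len=float(np.median(lengths)),
    )


_COUNT_COLS = {"gene_id", "count", "effective_length"}
_TPM_COLS = {"gene_id", "tpm"}


def read_counts_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a per-gene expression TSV.

    Two layouts are accepted: ``gene_id, count, effective_length`` (raw
    counts; TPM left unset until computed) or ``gene_id, tpm``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = set(df.columns)
    if df["gene_id"].duplicated().any() if "gene_id" in cols else False:
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene_id {dup!r} in counts table")
    if _COUNT_COLS <= cols:
        if (df["count"] < 0).any():
            raise ValueError("negative count in counts table")
        return [
            ExpressionRecord(
                gene_id=str(r.gene_id),
                count=int(r.count),
                effective_length=int(r.effective_length),
            )
            for r in df.itertuples()
        ]
    if _TPM_COLS <= cols:
        return [
            ExpressionRecord(gene_id=str(r.gene_id), tpm=float(r.tpm))
            for r in df.itertuples()
        ]
    raise ValueError(
        "unrecognized counts-table layout; accepted column sets: "
        "{gene_id, count, effective_length} or {gene_id, tpm}"
    )
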