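"""Telomeric repeat detection and nanochromosome calling.

Spirotrich macronuclear chromosomes are capped by tandem C4A4 repeats:
``CCCCAAAA`` units at the 5' end of a contig and the reverse complement
``TTTTGGGG`` at the 3' end.  A contig carrying telomeres on both ends and
exactly one annotated gene is called a nanochromosome (gene-sized
chromosome).

Contigs are never auto-reoriented: the repeat orientation is fixed (unit
at 5', reverse complement at 3') and gene strand handles orientation
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_io import GeneModel, SequenceRecord

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

TELOMERE_UNIT = "CCCCAAAA"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class TelomereHit:
    end: str  # FIVE_PRIME or THREE_PRIME
    n_units: int
    offset: int  # bases between the contig terminus and the first matched unit
    span: tuple[int, int]  # matched interval, 0-based half-open


@dataclass
class ContigTelomereClass:
    contig_id: str
    n_telomeres: int
    hits: list[TelomereHit] = field(default_factory=list)

    def hit(self, end: str) -> Optional[TelomereHit]:
        for h in self.hits:
            if h.end == end:
                return h
        return None


@dataclass
class NanochromosomeCall:
    contig_id: str
    is_nanochromosome: bool
    n_genes: int


@dataclass
class TelomereSummary:
    n_contigs: int
    pct_ge1_telomere: float
    pct_two_telomere: float
    mean_two_tel_len: Optional[float]  # None when no two-telomere contig exists


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def scan_telomere(
    record: SequenceRecord,
    unit: str = TELOMERE_UNIT,
    min_units: int = 2,
    max_offset: int = 5,
    max_mismatch_per_unit: int = 0,
) -> list[TelomereHit]:
    """Find tandem telomeric repeat tracts at both contig ends.

    The 5' end is scanned for tandem copies of ``unit`` starting within
    ``max_offset`` bases of the terminus; the 3' end is scanned for the
    reverse complement ending within ``max_offset`` bases of the terminus.
    A hit extends maximally and at most one hit per end is reported
    (the longest tract; ties broken toward the terminus).
    """
    if len(unit) < 4:
        raise ValueError("telomere unit must be at least 4 bases")
    if set(unit) - set("ACGT"):
        raise ValueError(f"telomere unit {unit!r} contains non-ACGT characters")
    seq = record.seq
    u = len(unit)
    hits: list[TelomereHit] = []

    # 5' end: unit copies reading forward from the terminus
    best = None  # (n_units, offset)
    for off in range(min(max_offset, max(len(seq) - u, 0)) + 1):
        n = 0
        i = off
        while i + u <= len(seq) and _mismatches(seq[i : i + u], unit) <= max_mismatch_per_unit:
            n += 1
            i += u
        if n >= min_units and (best is None or n > best[0]):
            best = (n, off)
    if best:
        n, off = best
        hits.append(TelomereHit(FIVE_PRIME, n, off, (off, off + n * u)))

    # 3' end: reverse-complement unit copies reading back from the terminus
    rc = revcomp(unit)
    best = None
    for off in range(min(max_offset, max(len(seq) - u, 0)) + 1):
        n = 0
        i = len(seq) - off - u
        while i >= 0 and _mismatches(seq[i : i + u], rc) <= max_mismatch_per_unit:
            n += 1
            i -= u
        if n >= min_units and (best is None or n > best[0]):
            best = (n, off)
    if best:
        n, off = best
        end = len(seq) - off
        hits.append(TelomereHit(THREE_PRIME, n, off, (end - n * u, end)))
    return hits


def classify_contig(contig_id: str, hits: Sequence[TelomereHit]) -> ContigTelomereClass:
    """Count distinct telomere-bearing ends (0, 1, or 2)."""
    ends = [h.end for h in hits]
    if len(ends) != len(set(ends)):
        raise ValueError(f"contig {contig_id!r}: two hits on the same end")
    return ContigTelomereClass(contig_id=contig_id, n_telomeres=len(ends), hits=list(hits))


def classify_genome(
    records: Sequence[SequenceRecord], **scan_kwargs
) -> dict[str, ContigTelomereClass]:
    return {
        r.id: classify_contig(r.id, scan_telomere(r, **scan_kwargs)) for r in records
    }


def trim_telomeres(
    record: SequenceRecord, cls: ContigTelomereClass
) -> tuple[SequenceRecord, int, int]:
    """Remove matched telomere spans plus any terminus offset.

    Returns the trimmed record and the number of bases removed from each
    end, so downstream coordinates can be mapped back to the original.
    """
    if cls.contig_id != record.id:
        raise ValueError("telomere class does not belong to this record")
    five = cls.hit(FIVE_PRIME)
    three = cls.hit(THREE_PRIME)
    five_trim = five.span[1] if five else 0
    three_trim = len(record.seq) - three.span[0] if three else 0
    new_seq = record.seq[five_trim : len(record.seq) - three_trim]
    if not new_seq:
        raise ValueError(f"contig {record.id!r}: trimming telomeres leaves an empty sequence")
    return (
        SequenceRecord(id=record.id, seq=new_seq, coverage=record.coverage),
        five_trim,
        three_trim,
    )


def telomere_summary(
    records: Sequence[SequenceRecord], **scan_kwargs
) -> TelomereSummary:
    """Genome-level telomere statistics (percentages over all contigs)."""
    if not records:
        raise ValueError("empty genome")
    classes = classify_genome(records, **scan_kwargs)
    n = len(records)
    ge1 = sum(1 for c in classes.values() if c.n_telomeres >= 1)
    two_lens = [len(r.seq) for r in records if classes[r.id].n_telomeres == 2]
    return TelomereSummary(
        n_contigs=n,
        pct_ge1_telomere=100.0 * ge1 / n,
        pct_two_telomere=100.0 * len(two_lens) / n,
        mean_two_tel_len=float(np.mean(two_lens)) if two_lens else None,
    )


def call_nanochromosomes(
    classes: Mapping[str, ContigTelomereClass], genes: Sequence[GeneModel]
) -> tuple[list[NanochromosomeCall], Optional[float]]:
    """Call gene-sized chromosomes: two telomeres and exactly one gene.

    The returned fraction is computed over two-telomere contigs only and
    is None when the genome has none.
    """
    n_genes: dict[str, int] = {cid: 0 for cid in classes}
    for g in genes:
        if g.contig_id not in n_genes:
            raise ValueError(f"gene {g.gene_id}: unknown contig {g.contig_id!r}")
        n_genes[g.contig_id] += 1
    calls = []
    two_tel = 0
    gene_sized = 0
    for cid, cls in classes.items():
        is_nano = cls.n_telomeres == 2 and n_genes[cid] == 1
        if cls.n_telomeres == 2:
            two_tel += 1
            gene_sized += is_nano
        calls.append(
            NanochromosomeCall(contig_id=cid, is_nanochromosome=is_nano, n_genes=n_genes[cid])
        )
    fraction = gene_sized / two_tel if two_tel else None
    return calls, fraction


@dataclass
class SizeDistribution:
    values: np.ndarray  # sorted
    mean: float
    median: float

    @classmethod
    def from_values(cls, values) -> "SizeDistribution":
        v = np.sort(np.asarray(values, dtype=float))
        return cls(values=v, mean=float(v.mean()), median=float(np.median(v)))


def size_distributions(
    records: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    classes: Optional[Mapping[str, ContigTelomereClass]] = None,
    **scan_kwargs,
) -> dict[str, SizeDistribution]:
    """Empirical size distributions of the genome's compact architecture.

    Returns ``chromosome_len`` (untrimmed lengths of two-telomere contigs),
    ``gene_body_len`` (start to stop codon, introns included),
    ``intron_len``, and ``subtel5_len`` (5' subtelomeric region lengths of
    nanochromosomes).  Genes lacking a CDS are excluded with a logged count.
    """
    from .cre_motif import extract_subtelomere  # deferred: avoids an import cycle

    if classes is None:
        classes = classify_genome(records, **scan_kwargs)
    by_contig = {r.id: r for r in records}

    chrom_lens = [len(r.seq) for r in records if classes[r.id].n_telomeres == 2]

    body_lens = []
    intron_lens = []
    subtel5_lens = []
    n_no_cds = 0
    calls, _ = call_nanochromosomes(classes, genes)
    nano = {c.contig_id for c in calls if c.is_nanochromosome}
    for g in genes:
        if g.gene_body_len is None:
            n_no_cds += 1
            continue
        body_lens.append(g.gene_body_len)
        intron_lens.extend(e - s + 1 for s, e in g.introns())
        if g.contig_id in nano:
            region = extract_subtelomere(
                by_contig[g.contig_id], classes[g.contig_id], g, FIVE_PRIME
            )
            if region is not None:
                subtel5_lens.append(len(region.seq))
    if n_no_cds:
        logger.info("size_distributions: excluded %d gene(s) lacking a CDS", n_no_cds)

    out: dict[str, SizeDistribution] = {}
    for name, vals in [
        ("chromosome_len", chrom_lens),
        ("gene_body_len", body_lens),
        ("intron_len", intron_lens),
        ("subtel5_len", subtel5_lens),
    ]:
        if vals:
            out[name] = SizeDistribution.from_values(vals)
    return out
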