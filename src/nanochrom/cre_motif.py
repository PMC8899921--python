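"""Subtelomeric region extraction and AT-rich CRE motif scanning.

The short sequence between a telomere and the gene boundary is where
nanochromosomes must fit any cis-regulatory information.  This module
extracts those regions in gene orientation, profiles their AT content,
scans IUPAC consensus motifs (5': a 15-nt weak-base run with an A-W-T
core, ``W6 AWT W6``; 3': ``TTNATTTCNTTAA``), and summarizes matched
instances as a position weight matrix with per-column information
content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, SequenceRecord
from . import telomere as _tel
from .telomere import (
    FIVE_PRIME,
    THREE_PRIME,
    ContigTelomereClass,
    revcomp,
)

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B",
    "N": "N",
}

#: 5' consensus: six weak bases, an A-W-T core, six weak bases (15 nt).
FIVE_PRIME_CRE = "WWWWWWAWTWWWWWW"
#: 3' consensus (13 nt).
THREE_PRIME_CRE = "TTNATTTCNTTAA"

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class SubtelomericRegion:
    """Sequence between a telomere and the gene boundary, in gene orientation.

    ``anchor_offsets`` holds 0-based positions relative to the region
    start (which is the telomere-proximal end for the 5' side and the
    stop-codon-proximal end for the 3' side): ``start_codon`` for 5'
    regions (= region length), ``tss`` when transcript evidence exists;
    ``telomere`` (= region length) and optionally ``tes`` for 3' regions.
    """

    gene_id: str
    side: str
    seq: str
    anchor_offsets: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Motif:
    name: str
    consensus: str
    max_mismatch: int = 0

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class CREMatch:
    gene_id: str
    side: str
    offset: int  # 0-based start within the region
    mismatches: int
    rel_pos: Optional[float] = None  # match midpoint within the TSS -> ATG interval
    tss_anchored: bool = False


def compile_motif(pattern: str, max_mismatch: int = 0, name: str = "motif") -> Motif:
    """Validate an IUPAC consensus and wrap it as a :class:`Motif`."""
    if len(pattern) < 4:
        raise ValueError("motif consensus must be at least 4 characters")
    for c in pattern:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC character {c!r} in motif {pattern!r}")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be nonnegative")
    return Motif(name=name, consensus=pattern, max_mismatch=max_mismatch)


def five_prime_cre(max_mismatch: int = 0) -> Motif:
    return compile_motif(FIVE_PRIME_CRE, max_mismatch, name="cre5")


def three_prime_cre(max_mismatch: int = 0) -> Motif:
    return compile_motif(THREE_PRIME_CRE, max_mismatch, name="cre3")


def reverse_complement_motif(motif: Motif) -> Motif:
    rc = "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif.consensus))
    return Motif(name=motif.name + "_rc", consensus=rc, max_mismatch=motif.max_mismatch)


def extract_subtelomere(
    record: SequenceRecord,
    cls: ContigTelomereClass,
    gene: GeneModel,
    side: str,
) -> Optional[SubtelomericRegion]:
    """Extract the 5' or 3' subtelomeric region of a gene, 5'->3' in gene
    orientation.

    The 5' region runs from the inner edge of the gene-upstream telomere
    to the base before the start codon; the 3' region from the base after
    the stop codon to the inner edge of the gene-downstream telomere.
    Minus-strand genes yield reverse-complemented sequence.  Returns None
    when the required telomere is absent (the region is flagged absent,
    not fabricated).
    """
    if side not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"side must be {FIVE_PRIME!r} or {THREE_PRIME!r}")
    if gene.contig_id != record.id or cls.contig_id != record.id:
        raise ValueError("record, telomere class, and gene must refer to the same contig")
    if gene.cds_start is None or gene.cds_end is None:
        raise ValueError(f"gene {gene.gene_id}: no CDS; cannot anchor subtelomere")

    plus = gene.strand == "+"
    # physical contig end holding the telomere adjacent to the requested side
    want_five_phys = plus == (side == FIVE_PRIME)
    hit = cls.hit(FIVE_PRIME if want_five_phys else THREE_PRIME)
    if hit is None:
        return None

    L = len(record.seq)
    if want_five_phys:
        inner = hit.span[1]  # 0-based: first base after the telomere tract
    else:
        inner = hit.span[0]  # 0-based: first base of the telomere tract

    anchors: dict[str, int] = {}
    if side == FIVE_PRIME:
        atg0 = (gene.cds_start - 1) if plus else (gene.cds_end - 1)
        if plus:
            if atg0 < inner:
                raise ValueError(f"gene {gene.gene_id}: start codon inside the telomere span")
            seq = record.seq[inner:atg0]
            if gene.tss is not None:
                anchors["tss"] = (gene.tss - 1) - inner
        else:
            if atg0 >= inner:
                raise ValueError(f"gene {gene.gene_id}: start codon inside the telomere span")
            seq = revcomp(record.seq[atg0 + 1 : inner])
            if gene.tss is not None:
                anchors["tss"] = inner - gene.tss
        anchors["start_codon"] = len(seq)
    else:
        stop_after0 = gene.cds_end if plus else gene.cds_start - 1  # 0-based base after stop
        if plus:
            if stop_after0 > inner:
                raise ValueError(f"gene {gene.gene_id}: stop codon inside the telomere span")
            seq = record.seq[stop_after0:inner]
            if gene.tes is not None:
                anchors["tes"] = (gene.tes - 1) - stop_after0
        else:
            if stop_after0 < inner:
                raise ValueError(f"gene {gene.gene_id}: stop codon inside the telomere span")
            seq = revcomp(record.seq[inner:stop_after0])
            if gene.tes is not None:
                anchors["tes"] = (stop_after0 - 1) - (gene.tes - 1)
        anchors["telomere"] = len(seq)
    if not seq:
        logger.warning(
            "gene %s: zero-length %s subtelomeric region (gene abuts the telomere)",
            gene.gene_id,
            side,
        )
    return SubtelomericRegion(
        gene_id=gene.gene_id, side=side, seq=seq, anchor_offsets=anchors
    )


def at_profile(
    regions: Sequence[SubtelomericRegion], max_len: int, window: int = 1
) -> np.ndarray:
    """Per-position (or sliding-window) AT fraction, rows = regions.

    Position is measured from the telomere-proximal end of each region;
    positions beyond a region's length are NaN.
    """
    if not regions:
        raise ValueError("no regions supplied")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > max_len:
        raise ValueError("window exceeds max_len")
    ncols = max_len - window + 1
    mat = np.full((len(regions), ncols), np.nan)
    for i, region in enumerate(regions):
        s = region.seq if region.side == FIVE_PRIME else region.seq[::-1]
        s = s[:max_len]
        if len(s) < window:
            continue
        ind = np.frombuffer(s.encode(), dtype=np.uint8)
        is_at = ((ind == ord("A")) | (ind == ord("T"))).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(is_at)])
        vals = (csum[window:] - csum[:-window]) / window
        mat[i, : len(vals)] = vals
    return mat


def _allowed_matrix(motif: Motif) -> np.ndarray:
    """allowed[k, b] = True when base index b satisfies motif position k.

    A sequence N matches only a motif N position.
    """
    allowed = np.zeros((len(motif), 5), dtype=bool)
    for k, c in enumerate(motif.consensus):
        for b in IUPAC[c]:
            allowed[k, _BASE_IDX[b]] = True
        if c == "N":
            allowed[k, _BASE_IDX["N"]] = True
    return allowed


def _seq_indices(seq: str) -> np.ndarray:
    ind = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_IDX.items():
        out[ind == ord(base)] = idx
    return out


def scan_motif(region: SubtelomericRegion, motif: Motif) -> list[CREMatch]:
    """Report every offset where the region matches the consensus with at
    most ``motif.max_mismatch`` violating positions.

    Overlapping matches are all reported, sorted by offset.  ``rel_pos``
    is the match midpoint as a fraction of the TSS -> start-codon
    interval for 5' regions (telomere -> start codon when no TSS is
    annotated; ``tss_anchored`` distinguishes the two) and is None when
    the midpoint falls outside the interval.
    """
    m = len(motif)
    n_off = len(region.seq) - m + 1
    if n_off <= 0:
        return []
    allowed = _allowed_matrix(motif)
    idx = _seq_indices(region.seq)
    mm = np.zeros(n_off, dtype=np.int32)
    for k in range(m):
        mm += ~allowed[k][idx[k : k + n_off]]
    offsets = np.nonzero(mm <= motif.max_mismatch)[0]

    matches = []
    for off in offsets:
        rel = None
        anchored = False
        if region.side == FIVE_PRIME and "start_codon" in region.anchor_offsets:
            a0 = region.anchor_offsets.get("tss")
            anchored = a0 is not None
            a0 = a0 if anchored else 0
            a1 = region.anchor_offsets["start_codon"]
            if a1 > a0:
                mid = off + m / 2.0
                r = (mid - a0) / (a1 - a0)
                rel = r if 0.0 <= r <= 1.0 else None
        matches.append(
            CREMatch(
                gene_id=region.gene_id,
                side=region.side,
                offset=int(off),
                mismatches=int(mm[off]),
                rel_pos=rel,
                tss_anchored=anchored,
            )
        )
    return matches


def subtelomere_catalog(
    records: Sequence[SequenceRecord],
    classes: Mapping[str, ContigTelomereClass],
    genes: Sequence[GeneModel],
    side: str = FIVE_PRIME,
    restrict_to_nanochromosomes: bool = True,
) -> dict[str, SubtelomericRegion]:
    """Extract one subtelomeric region per eligible gene, keyed by gene id."""
    by_contig = {r.id: r for r in records}
    eligible: set[str]
    if restrict_to_nanochromosomes:
        calls, _ = _tel.call_nanochromosomes(classes, genes)
        eligible = {c.contig_id for c in calls if c.is_nanochromosome}
    else:
        eligible = set(by_contig)
    out: dict[str, SubtelomericRegion] = {}
    for g in genes:
        if g.contig_id not in eligible or g.cds_start is None:
            continue
        region = extract_subtelomere(by_contig[g.contig_id], classes[g.contig_id], g, side)
        if region is not None:
            out[g.gene_id] = region
    return out


def cre_presence(
    records: Sequence[SequenceRecord],
    classes: Mapping[str, ContigTelomereClass],
    genes: Sequence[GeneModel],
    motif: Motif,
    side: str = FIVE_PRIME,
    restrict_to_nanochromosomes: bool = True,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-gene CRE presence and the fraction of genes carrying a match.

    A gene has the CRE iff its region on the requested side has at least
    one consensus match.  The fraction is computed over genes whose
    region is at least as long as the motif; it is None when no gene
    qualifies.
    """
    regions = subtelomere_catalog(
        records, classes, genes, side, restrict_to_nanochromosomes
    )
    rows = []
    for gene_id, region in regions.items():
        if len(region.seq) < len(motif):
            rows.append((gene_id, len(region.seq), None))
            continue
        has = bool(scan_motif(region, motif))
        rows.append((gene_id, len(region.seq), has))
    df = pd.DataFrame(rows, columns=["gene_id", "region_len", "has_cre"])
    scored = df["has_cre"].dropna()
    fraction = float(scored.mean()) if len(scored) else None
    return df, fraction


def positional_density(
    matches: Sequence[CREMatch], n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of match midpoints over the anchored interval [0, 1]."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rel = [m.rel_pos for m in matches if m.rel_pos is not None]
    counts, edges = np.histogram(rel, bins=n_bins, range=(0.0, 1.0))
    return counts, edges


def build_pwm(
    instances: Sequence[str], pseudocount: float = 0.5
) -> tuple[pd.DataFrame, np.ndarray]:
    """Position x base frequency matrix and per-column information content.

    IC per column is 2 - H (bits); with pseudocount 0 an invariant column
    scores the full 2 bits and a uniform column scores 0.
    """
    if not instances:
        raise ValueError("no motif instances supplied")
    L = len(instances[0])
    if any(len(s) != L for s in instances):
        raise ValueError("motif instances must all have equal length")
    counts = np.zeros((L, 4))
    for s in instances:
        for k, c in enumerate(s.upper()):
            if c in "ACGT":
                counts[k, _BASE_IDX[c]] += 1
    counts += pseudocount
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return pd.DataFrame(freqs, columns=list("ACGT")), ic
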