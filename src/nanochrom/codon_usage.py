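"""Stop-codon usage and reassignment calling.

Many ciliates read the canonical stop codons TAA and TAG as sense
codons; only TGA terminates translation.  Reassignment leaves a clear
signature in translated-homology alignments: a reassigned codon occurs
*inside* aligned coding spans at an appreciable frequency, whereas a true
stop codon appears only at span ends.  This module counts in-frame
internal vs terminal occurrences of TAA/TAG/TGA within evalue-filtered
homolog hit spans and calls each codon 'stop' or 'reassigned' from its
internal frequency per kb of aligned coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genome_io import SequenceRecord

STOP_CODONS = ("TAA", "TAG", "TGA")

HITS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length",
    "qstart", "qend", "sstart", "send", "evalue", "frame",
]


@dataclass
class HomologHit:
    """One translated-homology hit on a transcript/CDS.

    ``frame`` is the reading offset on the query: codons start at
    1-based positions p with ``(p - frame) % 3 == 0``.
    """

    query_id: str
    query_start: int  # 1-based, on the query nucleotide sequence
    query_end: int
    frame: int
    evalue: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError(f"hit on {self.query_id}: query_start must precede query_end")
        if self.query_end - self.query_start + 1 < 30:
            raise ValueError(f"hit on {self.query_id}: span shorter than 30 nt")
        if self.frame not in (1, 2, 3):
            raise ValueError(f"hit on {self.query_id}: frame must be 1, 2 or 3")
        if self.evalue < 0:
            raise ValueError(f"hit on {self.query_id}: negative evalue")


@dataclass
class StopCodonUsage:
    internal: dict[str, int]
    terminal: dict[str, int]
    aligned_bp: int  # total merged span length

    def internal_freq_per_kb(self, codon: str) -> float:
        if self.aligned_bp == 0:
            return 0.0
        return self.internal[codon] / (self.aligned_bp / 1000.0)


@dataclass
class ReassignmentCall:
    calls: dict[str, str]  # codon -> 'stop' | 'reassigned'
    low_confidence: bool
    usage: StopCodonUsage


def read_hits_table(path: str | Path) -> list[HomologHit]:
    """Read a BLAST outfmt-6-like TSV with an extra trailing frame column."""
    df = pd.read_csv(path, sep="\t", names=HITS_COLUMNS, comment="#")
    return [
        HomologHit(
            query_id=str(r.qseqid),
            query_start=int(r.qstart),
            query_end=int(r.qend),
            frame=int(r.frame),
            evalue=float(r.evalue),
            subject_id=str(r.sseqid),
        )
        for r in df.itertuples()
    ]


def write_hits_table(hits: Sequence[HomologHit], path: str | Path) -> None:
    rows = [
        (
            h.query_id, h.subject_id or "subject", 95.0,
            h.query_end - h.query_start + 1,
            h.query_start, h.query_end, 1,
            (h.query_end - h.query_start + 1) // 3,
            h.evalue, h.frame,
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting 1-based inclusive intervals."""
    spans = sorted(spans)
    merged = [spans[0]]
    for s, e in spans[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def stop_codon_usage(
    transcripts: Sequence[SequenceRecord],
    hits: Sequence[HomologHit],
    max_evalue: float = 1e-5,
) -> StopCodonUsage:
    """Count in-frame internal and terminal stop-codon occurrences.

    Hits are filtered at ``max_evalue``; overlapping/abutting hits on the
    same transcript and frame are merged before counting so no codon is
    double counted.  A codon is *internal* when it lies fully inside a
    merged span, and *terminal* when it is the first in-frame codon after
    the span's 3' end.
    """
    seqs: Mapping[str, str] = {t.id: t.seq for t in transcripts}
    by_key: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        if h.query_id not in seqs:
            raise ValueError(f"hit references unknown transcript {h.query_id!r}")
        if h.query_end > len(seqs[h.query_id]):
            raise ValueError(
                f"hit on {h.query_id}: span [{h.query_start},{h.query_end}] exceeds "
                f"transcript length {len(seqs[h.query_id])}"
            )
        by_key.setdefault((h.query_id, h.frame), []).append((h.query_start, h.query_end))

    internal = {c: 0 for c in STOP_CODONS}
    terminal = {c: 0 for c in STOP_CODONS}
    aligned_bp = 0
    for (qid, frame), spans in by_key.items():
        seq = seqs[qid]
        for s, e in _merge_spans(spans):
            aligned_bp += e - s + 1
            # first in-frame codon start at or after s (1-based)
            p = s + (-(s - frame)) % 3
            last_internal = None
            while p + 2 <= e:
                codon = seq[p - 1 : p + 2]
                if codon in internal:
                    internal[codon] += 1
                last_internal = p
                p += 3
            term = (last_internal + 3) if last_internal is not None else p
            if term + 2 <= len(seq):
                codon = seq[term - 1 : term + 2]
                if codon in terminal:
                    terminal[codon] += 1
    return StopCodonUsage(internal=internal, terminal=terminal, aligned_bp=aligned_bp)


def call_reassignment(
    usage: StopCodonUsage, min_internal_per_kb: float = 1.0
) -> ReassignmentCall:
    """Call each of TAA/TAG/TGA 'reassigned' or 'stop'.

    A codon is reassigned when its internal frequency reaches
    ``min_internal_per_kb`` occurrences per kb of aligned coding
    sequence.  Usage built from under 10 kb of alignment is flagged low
    confidence.  At least one codon must remain a stop.
    """
    low_confidence = usage.aligned_bp < 10_000
    calls = {
        c: ("reassigned" if usage.internal_freq_per_kb(c) >= min_internal_per_kb else "stop")
        for c in STOP_CODONS
    }
    if all(v == "reassigned" for v in calls.values()):
        raise ValueError("all three codons called reassigned: no stop codon would remain")
    return ReassignmentCall(calls=calls, low_confidence=low_confidence, usage=usage)
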