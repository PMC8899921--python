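"""Inter-species divergence of subtelomeric regions.

Orthologous subtelomeric regions from two genomes are globally aligned
(affine gap penalties) and summarized as a 12-class directed substitution
spectrum (``AC`` = an A in the reference replaced by a C in the second
genome, and so on).  Comparing the pooled substitution rate inside called
CRE intervals against the rate over the entire region quantifies the
selective constraint on the element: a conserved CRE shows a reduced rate
and a shifted substitution-type spectrum.

The first genome is the reference for substitution direction; no outgroup
polarization or multiple-hit correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .cre_motif import SubtelomericRegion

BASES = "ACGT"
SUBSTITUTION_CLASSES = [a + b for a in BASES for b in BASES if a != b]


@dataclass
class RegionPair:
    gene_id_a: str
    gene_id_b: str
    region_a: SubtelomericRegion
    region_b: SubtelomericRegion
    cre_interval_a: Optional[tuple[int, int]] = None  # 0-based half-open, region-a coords

    def __post_init__(self) -> None:
        if self.region_a.side != self.region_b.side:
            raise ValueError("paired regions must be the same side")
        if self.cre_interval_a is not None:
            s, e = self.cre_interval_a
            if not (0 <= s < e <= len(self.region_a.seq)):
                raise ValueError(
                    f"pair {self.gene_id_a}/{self.gene_id_b}: CRE interval outside region"
                )


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


@dataclass
class SubstitutionSpectrum:
    counts: dict[str, int]
    aligned_ungapped: int

    @property
    def n_substitutions(self) -> int:
        return sum(self.counts.values())

    @property
    def rate(self) -> float:
        return self.n_substitutions / self.aligned_ungapped if self.aligned_ungapped else 0.0

    def frequencies(self) -> dict[str, float]:
        """Per-class fraction of all substitutions (zeros when none)."""
        n = self.n_substitutions
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}

    def __add__(self, other: "SubstitutionSpectrum") -> "SubstitutionSpectrum":
        return SubstitutionSpectrum(
            counts={k: self.counts[k] + other.counts[k] for k in SUBSTITUTION_CLASSES},
            aligned_ungapped=self.aligned_ungapped + other.aligned_ungapped,
        )


def empty_spectrum() -> SubstitutionSpectrum:
    return SubstitutionSpectrum(
        counts={k: 0 for k in SUBSTITUTION_CLASSES}, aligned_ungapped=0
    )


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (first gap base scores
    ``gap_open``, each additional ``gap_extend``)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    for name, s in (("a", a), ("b", b)):
        if set(s) - set("ACGTN"):
            raise ValueError(f"sequence {name} contains non-ACGTN characters")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=aln.score)


def substitution_spectrum(
    aln: PairwiseAlignment, mask: Optional[tuple[int, int]] = None
) -> SubstitutionSpectrum:
    """Count directed substitutions over the aligned, ungapped columns.

    Direction is a -> b (first row as reference).  Columns with a gap or
    an N in either row are excluded from both the counts and the
    ``aligned_ungapped`` denominator.  ``mask``, when given, restricts the
    count to columns whose *ungapped a-coordinate* (0-based half-open)
    falls inside it.
    """
    a_len = sum(1 for c in aln.aligned_a if c != "-")
    if mask is not None:
        s, e = mask
        if not (0 <= s < e <= a_len):
            raise ValueError(f"mask {mask} outside sequence a (length {a_len})")
    spec = empty_spectrum()
    a_idx = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        in_mask = mask is None or (mask[0] <= a_idx < mask[1])
        if ca != "-":
            a_idx += 1
        if ca == "-" or cb == "-" or ca == "N" or cb == "N":
            continue
        if not in_mask:
            continue
        spec.aligned_ungapped += 1
        if ca != cb:
            spec.counts[ca + cb] += 1
    return spec


def pair_regions(
    ortholog_table: pd.DataFrame,
    regions_a: Mapping[str, SubtelomericRegion],
    regions_b: Mapping[str, SubtelomericRegion],
    cre_intervals_a: Optional[Mapping[str, tuple[int, int]]] = None,
) -> tuple[list[RegionPair], int]:
    """Join an ortholog table (two gene-id columns) with extracted regions.

    Pairs lacking a region in either genome are skipped and counted; the
    CRE interval, when known for the genome-A gene, is attached.
    """
    if len(ortholog_table) == 0:
        raise ValueError("empty ortholog table")
    col_a, col_b = ortholog_table.columns[:2]
    for col in (col_a, col_b):
        if ortholog_table[col].duplicated().any():
            dup = ortholog_table.loc[ortholog_table[col].duplicated(), col].iloc[0]
            raise ValueError(f"duplicated gene id {dup!r} in ortholog column {col!r}")
    pairs: list[RegionPair] = []
    skipped = 0
    for row in ortholog_table.itertuples(index=False):
        ga, gb = str(getattr(row, col_a)), str(getattr(row, col_b))
        ra = regions_a.get(ga)
        rb = regions_b.get(gb)
        if ra is None or rb is None or not ra.seq or not rb.seq:
            skipped += 1
            continue
        cre = cre_intervals_a.get(ga) if cre_intervals_a else None
        pairs.append(
            RegionPair(
                gene_id_a=ga, gene_id_b=gb, region_a=ra, region_b=rb, cre_interval_a=cre
            )
        )
    return pairs, skipped


@dataclass
class DivergenceReport:
    rate_cre: float
    rate_region: float
    reduction: Optional[float]  # 1 - rate_cre / rate_region; None when undefined
    per_class_freq_cre: dict[str, float]
    per_class_freq_region: dict[str, float]
    spectrum_cre: SubstitutionSpectrum
    spectrum_region: SubstitutionSpectrum
    n_pairs: int
    n_pairs_with_cre: int
    per_pair_rates: pd.DataFrame = field(repr=False, default=None)


def cre_vs_region_rates(pairs: Sequence[RegionPair], **align_kwargs) -> DivergenceReport:
    """Pooled substitution rates inside CRE intervals vs entire regions.

    Rates are column-weighted (total substitutions over total ungapped
    columns per stratum) so long regions are not underweighted; per-pair
    rates are also returned for inspection.
    """
    if not any(p.cre_interval_a is not None for p in pairs):
        raise ValueError("no pair carries a CRE interval")
    pooled_region = empty_spectrum()
    pooled_cre = empty_spectrum()
    rows = []
    for p in pairs:
        aln = global_align(p.region_a.seq, p.region_b.seq, **align_kwargs)
        spec_region = substitution_spectrum(aln)
        pooled_region = pooled_region + spec_region
        rate_cre = np.nan
        if p.cre_interval_a is not None:
            spec_cre = substitution_spectrum(aln, mask=p.cre_interval_a)
            pooled_cre = pooled_cre + spec_cre
            rate_cre = spec_cre.rate
        rows.append((p.gene_id_a, p.gene_id_b, spec_region.rate, rate_cre))
    rate_region = pooled_region.rate
    rate_cre = pooled_cre.rate
    reduction = 1.0 - rate_cre / rate_region if rate_region > 0 else None
    return DivergenceReport(
        rate_cre=rate_cre,
        rate_region=rate_region,
        reduction=reduction,
        per_class_freq_cre=pooled_cre.frequencies(),
        per_class_freq_region=pooled_region.frequencies(),
        spectrum_cre=pooled_cre,
        spectrum_region=pooled_region,
        n_pairs=len(pairs),
        n_pairs_with_cre=sum(p.cre_interval_a is not None for p in pairs),
        per_pair_rates=pd.DataFrame(
            rows, columns=["gene_id_a", "gene_id_b", "rate_region", "rate_cre"]
        ),
    )
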