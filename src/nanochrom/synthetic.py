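"""Synthetic nanochromosome genomes with planted ground truth.

Every stage of the pipeline is testable without downloads: this module
generates a macronuclear genome of telomere-capped, gene-sized
chromosomes (5' telomere, short AT-rich 5' subtelomere with a planted
CRE between the simulated TSS and the start codon, a single gene with
tiny GT..AG introns, a 3' subtelomere with the 3' element, 3' telomere),
a sister genome diverged by per-site substitution with a reduced rate
and biased substitution types inside CREs, an expression table whose
active/silent status depends on CRE presence, and a translated-homology
fixture with a planted genetic code.

All draws flow from a single integer seed through per-component child
streams (numpy ``SeedSequence`` spawn keys), so outputs are
byte-reproducible and adding one component never reorders the draws of
another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    ExpressionRecord,
    GeneModel,
    SequenceRecord,
    write_fasta,
    write_gff,
)
from .telomere import TELOMERE_UNIT, revcomp
from .cre_motif import FIVE_PRIME_CRE, THREE_PRIME_CRE, IUPAC

BASES = np.array(list("ACGT"))
_B2I = {b: i for i, b in enumerate("ACGT")}

# stream keys for per-component child generators
_STREAM_GENOME = 0
_STREAM_SISTER = 1
_STREAM_EXPRESSION = 2
_STREAM_CODON = 3

#: Substitution-type weight preset reproducing an AT-ward bias inside the
#: CRE: transitions out of A/T toward G/C are suppressed, replacements of
#: G/C by A/T are elevated.
AT_WARD_BIAS = {
    "A": {"C": 1.0, "G": 0.15, "T": 1.0},
    "C": {"A": 6.0, "G": 0.5, "T": 1.0},
    "G": {"A": 1.0, "C": 0.5, "T": 6.0},
    "T": {"A": 1.0, "C": 0.15, "G": 1.0},
}

UNIFORM_BIAS = {
    a: {b: 1.0 for b in "ACGT" if b != a} for a in "ACGT"
}


@dataclass
class LengthDist:
    """Lognormal length distribution parameterized by mean/sd in bases."""

    mean: float
    sd: float
    min_len: int

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        draw = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)
        return np.maximum(np.round(draw).astype(int), self.min_len)


@dataclass
class SimSpec:
    """Generator parameters; the defaults emulate a *Pseudokeronopsis*-like
    macronuclear genome (two-telomere chromosomes averaging ~1.4 kb,
    subtelomeres of ~60 bp, introns of mean 36 nt, CRE planted on 95% of
    chromosomes, 92% of CRE+ genes active)."""

    n_chromosomes: int = 100
    telomere_units: int = 3
    class_probs: tuple[float, float, float] = (0.18, 0.42, 0.40)  # P(0/1/2 telomeres)
    subtel5_len: LengthDist = field(default_factory=lambda: LengthDist(60, 20, 40))
    subtel3_len: LengthDist = field(default_factory=lambda: LengthDist(60, 20, 36))
    cds_len: LengthDist = field(default_factory=lambda: LengthDist(1100, 350, 180))
    n_introns_mean: float = 1.5
    intron_len_mean: float = 36.0
    intron_len_sd: float = 5.0
    intron_min_len: int = 15
    at_bias: float = 0.7  # P(A or T) at a subtelomeric background position
    coding_at_bias: float = 0.6  # P(A or T) per coding position (AT-rich genome)
    p_cre5: float = 0.95
    p_cre3: float = 0.90
    cre_gc: float = 0.0  # P(C/G at a W slot of a planted CRE instance)
    p_minus: float = 0.5
    mu: float = 0.02  # sister per-site substitution probability
    rho_cre: float = 0.5  # CRE substitution-rate multiplier
    bias_inside: dict = field(default_factory=lambda: {a: dict(d) for a, d in AT_WARD_BIAS.items()})
    bias_outside: dict = field(default_factory=lambda: {a: dict(d) for a, d in UNIFORM_BIAS.items()})
    p_active_cre: float = 0.92
    p_active_nocre: float = 0.25
    tpm_meanlog: float = 3.0
    tpm_sdlog: float = 1.2
    library_size: int = 2_000_000
    silent_noise_lambda: float = 0.2
    sense_stops: tuple[str, ...] = ("TAA", "TAG")  # reassigned codons
    internal_sense_stop_rate: float = 0.05
    n_transcripts: int = 60
    transcript_codons: tuple[int, int] = (150, 400)
    hit_coverage: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_cre5, self.p_cre3, self.cre_gc, self.p_minus,
            self.p_active_cre, self.p_active_nocre, self.at_bias, self.coding_at_bias,
            self.internal_sense_stop_rate, self.hit_coverage, *self.class_probs,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("telomere class probabilities must sum to 1")
        if not (0.0 <= self.rho_cre <= 1.0):
            raise ValueError("rho_cre must lie in [0, 1]")
        if self.mu >= 0.5:
            raise ValueError("mu >= 0.5 breaks alignment identifiability")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.intron_min_len < 15:
            raise ValueError("intron_min_len must be >= 15")
        if self.subtel5_len.min_len < len(FIVE_PRIME_CRE) + 20:
            raise ValueError(
                "subtel5 minimum length cannot accommodate the 5' CRE and TSS margin"
            )
        if self.subtel3_len.min_len < len(THREE_PRIME_CRE) + 18:
            raise ValueError(
                "subtel3 minimum length cannot accommodate the 3' element and TES margin"
            )
        bad = set(self.sense_stops) - {"TAA", "TAG", "TGA"}
        if bad:
            raise ValueError(f"sense_stops must be drawn from TAA/TAG/TGA, got {bad}")
        if len(set(self.sense_stops)) == 3:
            raise ValueError("at least one of TAA/TAG/TGA must remain a stop codon")
        if self.library_size < self.n_chromosomes:
            raise ValueError("library size below the number of genes")

    @property
    def true_stops(self) -> tuple[str, ...]:
        return tuple(c for c in ("TAA", "TAG", "TGA") if c not in self.sense_stops)


@dataclass
class ChromosomeTruth:
    contig_id: str
    gene_id: str
    strand: str
    length: int
    n_telomeres: int
    tel5_span: Optional[tuple[int, int]]  # 0-based half-open, final orientation
    tel3_span: Optional[tuple[int, int]]
    subtel5_ivl: tuple[int, int]  # genomic interval of the gene's 5' subtelomere
    subtel3_ivl: tuple[int, int]
    gene_ivl: tuple[int, int]  # CDS span incl. introns, 0-based half-open
    cre5_region_ivl: Optional[tuple[int, int]]  # within the 5' region, gene orientation
    cre5_genomic_ivl: Optional[tuple[int, int]]
    cre3_genomic_ivl: Optional[tuple[int, int]]
    intron_lens: list[int]
    coverage: float
    active: Optional[bool] = None
    tpm_true: Optional[float] = None


@dataclass
class SubstitutionEvent:
    contig_id: str
    pos: int  # 0-based, final orientation of genome A
    ref: str
    alt: str
    label: str  # cre5 | cre3 | subtel5 | subtel3 | gene | other


@dataclass
class TruthManifest:
    spec: SimSpec
    chromosomes: list[ChromosomeTruth]
    substitutions: Optional[list[SubstitutionEvent]] = None

    def by_contig(self) -> dict[str, ChromosomeTruth]:
        return {c.contig_id: c for c in self.chromosomes}

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _random_seq(rng: np.random.Generator, n: int, at_bias: float) -> np.ndarray:
    """AT-biased background sequence as an index array."""
    p = np.array([at_bias / 2, (1 - at_bias) / 2, (1 - at_bias) / 2, at_bias / 2])
    return rng.choice(4, size=n, p=p)


def _realize_motif(rng: np.random.Generator, consensus: str, cre_gc: float) -> np.ndarray:
    """Draw one concrete instance of an IUPAC consensus.

    W slots may carry C/G with probability ``cre_gc`` (degenerate
    instances for divergence simulations); all other slots draw uniformly
    from their IUPAC class.
    """
    out = np.empty(len(consensus), dtype=int)
    for k, c in enumerate(consensus):
        if c == "W" and cre_gc > 0 and rng.random() < cre_gc:
            out[k] = _B2I[rng.choice(list("CG"))]
        else:
            out[k] = _B2I[rng.choice(list(IUPAC[c]))]
    return out


def _codon_pool(true_stops: Sequence[str]) -> list[str]:
    return [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in true_stops
    ]


def _flip_ivl(ivl: tuple[int, int], L: int) -> tuple[int, int]:
    s, e = ivl
    return (L - e, L - s)


def simulate_genome(
    spec: SimSpec,
) -> tuple[list[SequenceRecord], list[GeneModel], TruthManifest]:
    """Generate genome A: FASTA records, gene models, and the truth manifest.

    Deterministic given ``spec.seed``; chromosome i is built 5'->3' in
    gene orientation and reverse-complemented with probability
    ``p_minus`` (the gene is then annotated on the minus strand).
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_GENOME])
    tel5_arr = np.array([_B2I[b] for b in TELOMERE_UNIT * spec.telomere_units])
    tel3_arr = np.array([_B2I[b] for b in revcomp(TELOMERE_UNIT) * spec.telomere_units])
    cre5_len = len(FIVE_PRIME_CRE)
    cre3_len = len(THREE_PRIME_CRE)
    codons = np.array(_codon_pool(spec.true_stops))
    p_letter = {
        b: (spec.coding_at_bias / 2 if b in "AT" else (1 - spec.coding_at_bias) / 2)
        for b in "ACGT"
    }
    codon_w = np.array([np.prod([p_letter[c] for c in cod]) for cod in codons])
    codon_w /= codon_w.sum()

    records: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    truths: list[ChromosomeTruth] = []
    width = max(4, len(str(spec.n_chromosomes)))
    for i in range(spec.n_chromosomes):
        cid = f"chr{i:0{width}d}"
        gid = f"g{i:0{width}d}"
        n_tel = int(rng.choice(3, p=list(spec.class_probs)))
        if n_tel == 2:
            has5 = has3 = True
        elif n_tel == 1:
            has5 = bool(rng.random() < 0.5)
            has3 = not has5
        else:
            has5 = has3 = False

        L5 = int(spec.subtel5_len.sample(rng))
        L3 = int(spec.subtel3_len.sample(rng))
        n_cod = max(int(spec.cds_len.sample(rng)) // 3, 40)

        # --- 5' subtelomere: TSS, then optionally the CRE before the ATG
        sub5 = _random_seq(rng, L5, spec.at_bias)
        tss_off = int(rng.integers(4, max(6, L5 // 4)))  # 0-based within subtel5
        cre5_rel = None
        if rng.random() < spec.p_cre5:
            lo, hi = tss_off + 1, L5 - cre5_len - 1
            start = int(rng.integers(lo, hi + 1))
            sub5[start : start + cre5_len] = _realize_motif(rng, FIVE_PRIME_CRE, spec.cre_gc)
            cre5_rel = (start, start + cre5_len)

        # --- coding sequence with introns
        body_cod = rng.choice(codons, size=n_cod, p=codon_w)
        coding = "ATG" + "".join(body_cod) + str(rng.choice(np.array(spec.true_stops)))
        cds_len = len(coding)
        k_introns = int(rng.poisson(spec.n_introns_mean))
        max_introns = max((cds_len - 12) // 6, 0)
        k_introns = min(k_introns, max_introns)
        intron_lens = []
        intron_positions = []  # 0-based coding offsets, intron inserted before each
        if k_introns:
            pos = np.sort(
                rng.choice(np.arange(6, cds_len - 6), size=k_introns, replace=False)
            )
            # keep insertion points at least 6 bp apart so exons stay nonempty
            pos = [int(p) for j, p in enumerate(pos) if j == 0 or p - pos[j - 1] >= 6]
            for p in pos:
                l = max(int(round(rng.normal(spec.intron_len_mean, spec.intron_len_sd))),
                        spec.intron_min_len)
                intron_positions.append(p)
                intron_lens.append(l)
        gene_pieces = []
        prev = 0
        genomic_intron_ivls = []  # relative to gene start, 0-based half-open
        cursor = 0
        for p, l in zip(intron_positions, intron_lens):
            gene_pieces.append(coding[prev:p])
            cursor += p - prev
            intron_seq = "GT" + "".join(
                BASES[_random_seq(rng, l - 4, spec.at_bias)]
            ) + "AG"
            gene_pieces.append(intron_seq)
            genomic_intron_ivls.append((cursor, cursor + l))
            cursor += l
            prev = p
        gene_pieces.append(coding[prev:])
        gene_seq = "".join(gene_pieces)
        gene_len = len(gene_seq)

        # --- 3' subtelomere: element between stop and TES
        sub3 = _random_seq(rng, L3, spec.at_bias)
        tes_off = int(rng.integers(4, max(6, L3 // 4)))  # from the telomere-proximal end
        cre3_rel = None
        if rng.random() < spec.p_cre3:
            lo, hi = 1, L3 - tes_off - cre3_len - 1
            start = int(rng.integers(lo, hi + 1))
            sub3[start : start + cre3_len] = _realize_motif(rng, THREE_PRIME_CRE, 0.0)
            cre3_rel = (start, start + cre3_len)

        # --- assemble in gene orientation (0-based coordinates)
        T5 = len(tel5_arr) if has5 else 0
        T3 = len(tel3_arr) if has3 else 0
        parts = []
        if has5:
            parts.append(tel5_arr)
        parts.append(sub5)
        parts.append(np.array([_B2I[b] for b in gene_seq]))
        parts.append(sub3)
        if has3:
            parts.append(tel3_arr)
        idx_seq = np.concatenate(parts)
        L = len(idx_seq)

        g0 = T5 + L5  # 0-based gene (ATG) start
        gene_ivl = (g0, g0 + gene_len)
        subtel5_ivl = (T5, T5 + L5)
        subtel3_ivl = (g0 + gene_len, g0 + gene_len + L3)
        tel5_span = (0, T5) if has5 else None
        tel3_span = (L - T3, L) if has3 else None
        cre5_gen = (T5 + cre5_rel[0], T5 + cre5_rel[1]) if cre5_rel else None
        cre3_gen = (
            (g0 + gene_len + cre3_rel[0], g0 + gene_len + cre3_rel[1]) if cre3_rel else None
        )
        tss0 = T5 + tss_off
        tes0 = g0 + gene_len + L3 - 1 - tes_off

        # transcript exons: TSS..TES minus introns (1-based inclusive)
        intron_ivls_gen = [(g0 + s, g0 + e) for s, e in genomic_intron_ivls]
        exon_bounds_0 = [tss0] + [e for _, e in intron_ivls_gen]
        exon_ends_0 = [s - 1 for s, _ in intron_ivls_gen] + [tes0]
        exons = [(s + 1, e + 1) for s, e in zip(exon_bounds_0, exon_ends_0)]
        cds_start_1, cds_end_1 = g0 + 1, g0 + gene_len
        tss_1, tes_1 = tss0 + 1, tes0 + 1
        strand = "+"

        if rng.random() < spec.p_minus:
            strand = "-"
            idx_seq = 3 - idx_seq[::-1]  # ACGT indices complement to 3-i
            flip1 = lambda p: L - p + 1  # 1-based flip
            exons = sorted((flip1(e), flip1(s)) for s, e in exons)
            cds_start_1, cds_end_1 = flip1(cds_end_1), flip1(cds_start_1)
            tss_1, tes_1 = flip1(tss_1), flip1(tes_1)
            gene_ivl = _flip_ivl(gene_ivl, L)
            subtel5_ivl = _flip_ivl(subtel5_ivl, L)
            subtel3_ivl = _flip_ivl(subtel3_ivl, L)
            cre5_gen = _flip_ivl(cre5_gen, L) if cre5_gen else None
            cre3_gen = _flip_ivl(cre3_gen, L) if cre3_gen else None
            t5, t3 = tel5_span, tel3_span
            tel5_span = _flip_ivl(t3, L) if t3 else None
            tel3_span = _flip_ivl(t5, L) if t5 else None

        coverage = float(rng.lognormal(mean=math.log(50.0), sigma=0.5))
        seq = "".join(BASES[idx_seq])
        records.append(SequenceRecord(id=cid, seq=seq, coverage=round(coverage, 2)))
        genes.append(
            GeneModel(
                gene_id=gid,
                contig_id=cid,
                strand=strand,
                exons=exons,
                cds_start=cds_start_1,
                cds_end=cds_end_1,
                tss=tss_1,
                tes=tes_1,
            )
        )
        truths.append(
            ChromosomeTruth(
                contig_id=cid,
                gene_id=gid,
                strand=strand,
                length=L,
                n_telomeres=n_tel,
                tel5_span=tel5_span,
                tel3_span=tel3_span,
                subtel5_ivl=subtel5_ivl,
                subtel3_ivl=subtel3_ivl,
                gene_ivl=gene_ivl,
                cre5_region_ivl=cre5_rel,
                cre5_genomic_ivl=cre5_gen,
                cre3_genomic_ivl=cre3_gen,
                intron_lens=intron_lens,
                coverage=round(coverage, 2),
            )
        )
    return records, genes, TruthManifest(spec=spec, chromosomes=truths)


def _label_array(truth: ChromosomeTruth) -> np.ndarray:
    """Per-position region labels; telomeres marked so they stay untouched."""
    lab = np.full(truth.length, "other", dtype=object)
    for ivl, name in [
        (truth.subtel5_ivl, "subtel5"),
        (truth.subtel3_ivl, "subtel3"),
        (truth.gene_ivl, "gene"),
        (truth.cre5_genomic_ivl, "cre5"),
        (truth.cre3_genomic_ivl, "cre3"),
    ]:
        if ivl is not None:
            lab[ivl[0] : ivl[1]] = name
    for span in (truth.tel5_span, truth.tel3_span):
        if span is not None:
            lab[span[0] : span[1]] = "telomere"
    return lab


def simulate_sister(
    records: Sequence[SequenceRecord],
    manifest: TruthManifest,
    spec: Optional[SimSpec] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame, TruthManifest]:
    """Diverge genome A into a sister genome B by per-site substitution.

    Each non-telomeric site mutates with probability ``mu``, multiplied
    by ``rho_cre`` inside planted CRE intervals; the replacement base is
    drawn from ``bias_inside`` (CRE sites) or ``bias_outside``.
    Telomeres are preserved exactly, so coordinates and gene models carry
    over unchanged.  Returns genome B, the ortholog table, and the
    manifest with the per-site substitution log filled in.
    """
    spec = spec or manifest.spec
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_SISTER])

    def row_probs(bias: dict) -> np.ndarray:
        m = np.zeros((4, 4))
        for a, row in bias.items():
            for b, w in row.items():
                m[_B2I[a], _B2I[b]] = w
        return m / m.sum(axis=1, keepdims=True)

    p_in = row_probs(spec.bias_inside)
    p_out = row_probs(spec.bias_outside)

    truths = manifest.by_contig()
    out_records: list[SequenceRecord] = []
    events: list[SubstitutionEvent] = []
    for rec in records:
        truth = truths[rec.id]
        lab = _label_array(truth)
        idx = np.array([_B2I.get(b, -1) for b in rec.seq])
        site_mu = np.full(len(rec.seq), spec.mu)
        is_cre = (lab == "cre5") | (lab == "cre3")
        site_mu[is_cre] *= spec.rho_cre
        site_mu[lab == "telomere"] = 0.0
        site_mu[idx < 0] = 0.0  # leave N untouched
        hit = np.nonzero(rng.random(len(rec.seq)) < site_mu)[0]
        new_idx = idx.copy()
        for pos in hit:
            probs = (p_in if is_cre[pos] else p_out)[idx[pos]]
            alt = int(rng.choice(4, p=probs))
            new_idx[pos] = alt
            events.append(
                SubstitutionEvent(
                    contig_id=rec.id,
                    pos=int(pos),
                    ref="ACGT"[idx[pos]],
                    alt="ACGT"[alt],
                    label=str(lab[pos]),
                )
            )
        chars = BASES[np.clip(new_idx, 0, 3)].copy()
        chars[new_idx < 0] = "N"
        out_records.append(
            SequenceRecord(id=rec.id, seq="".join(chars), coverage=rec.coverage)
        )
    orthologs = pd.DataFrame(
        {
            "gene_id_a": [t.gene_id for t in manifest.chromosomes],
            "gene_id_b": [t.gene_id for t in manifest.chromosomes],
        }
    )
    manifest.substitutions = events
    return out_records, orthologs, manifest


def simulate_expression(
    manifest: TruthManifest, spec: Optional[SimSpec] = None
) -> tuple[pd.DataFrame, TruthManifest]:
    """Draw per-gene counts whose activity depends on 5' CRE presence.

    A gene is active with probability ``p_active_cre`` (CRE planted) or
    ``p_active_nocre``; active genes receive a lognormal transcript
    abundance converted to Poisson counts at ``library_size`` reads,
    silent genes only a small Poisson noise count.  Effective length is
    the gene's spliced (exonic CDS + UTR) length approximated by the CDS.
    """
    spec = spec or manifest.spec
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_EXPRESSION])
    n = len(manifest.chromosomes)
    has_cre = np.array([t.cre5_region_ivl is not None for t in manifest.chromosomes])
    p_active = np.where(has_cre, spec.p_active_cre, spec.p_active_nocre)
    active = rng.random(n) < p_active
    abundance = np.where(
        active, rng.lognormal(spec.tpm_meanlog, spec.tpm_sdlog, size=n), 0.0
    )
    eff_len = np.array(
        [t.gene_ivl[1] - t.gene_ivl[0] - sum(t.intron_lens) for t in manifest.chromosomes]
    )
    weights = abundance * eff_len
    total = weights.sum()
    expected = spec.library_size * weights / total if total > 0 else np.zeros(n)
    counts = rng.poisson(expected)
    counts = counts + rng.poisson(spec.silent_noise_lambda, size=n) * (~active)
    for t, a, ab in zip(manifest.chromosomes, active, abundance):
        t.active = bool(a)
        t.tpm_true = float(ab)
    df = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in manifest.chromosomes],
            "count": counts.astype(int),
            "effective_length": eff_len.astype(int),
        }
    )
    return df, manifest


def simulate_stop_codon_fixture(
    spec: SimSpec,
) -> tuple[list[SequenceRecord], list, dict[str, str]]:
    """Transcripts with planted in-frame reassigned codons plus hit spans.

    Each CDS is ATG + body + a true stop; body codons carry a codon from
    ``sense_stops`` with probability ``internal_sense_stop_rate`` and
    otherwise avoid all three canonical stops.  One frame-1 hit covers
    ``hit_coverage`` of each CDS.  Returns transcripts, hits, and the
    planted code (codon -> 'sense' | 'stop')."""
    from .codon_usage import HomologHit  # local import keeps module deps one-way

    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_CODON])
    clean_pool = np.array(_codon_pool(("TAA", "TAG", "TGA")))
    sense = np.array(spec.sense_stops) if spec.sense_stops else None
    lo, hi = spec.transcript_codons
    transcripts: list[SequenceRecord] = []
    hits: list[HomologHit] = []
    for i in range(spec.n_transcripts):
        tid = f"t{i:04d}"
        m = int(rng.integers(lo, hi + 1))
        body = rng.choice(clean_pool, size=m)
        if sense is not None and spec.internal_sense_stop_rate > 0:
            planted = rng.random(m) < spec.internal_sense_stop_rate
            body[planted] = rng.choice(sense, size=int(planted.sum()))
        seq = "ATG" + "".join(body) + str(rng.choice(np.array(spec.true_stops)))
        transcripts.append(SequenceRecord(id=tid, seq=seq))
        qend = 3 * max(int(round(spec.hit_coverage * (m + 1))), 10)
        hits.append(
            HomologHit(
                query_id=tid,
                query_start=1,
                query_end=min(qend, len(seq)),
                frame=1,
                evalue=1e-30,
                subject_id=f"prot{i:04d}",
            )
        )
    code = {c: ("sense" if c in spec.sense_stops else "stop") for c in ("TAA", "TAG", "TGA")}
    return transcripts, hits, code


def validate_manifest(
    records: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    manifest: TruthManifest,
) -> None:
    """Independent consistency pass over emitted genome A vs its manifest.

    Checks sequence lengths, telomere content at recorded spans, the ATG
    and stop codon at the CDS boundaries, and (for mutation-free CRE
    instances) the planted motif at the recorded interval.  Raises
    ``ValueError`` listing every violation found.
    """
    spec = manifest.spec
    by_rec = {r.id: r for r in records}
    by_gene = {g.gene_id: g for g in genes}
    problems: list[str] = []
    unit5 = TELOMERE_UNIT * spec.telomere_units
    for t in manifest.chromosomes:
        rec = by_rec.get(t.contig_id)
        if rec is None:
            problems.append(f"{t.contig_id}: missing from FASTA")
            continue
        if len(rec.seq) != t.length:
            problems.append(f"{t.contig_id}: length mismatch")
        for span, want_fwd in [(t.tel5_span, True), (t.tel3_span, False)]:
            if span is None:
                continue
            got = rec.seq[span[0] : span[1]]
            want = unit5 if want_fwd else revcomp(unit5)
            if got != want:
                problems.append(f"{t.contig_id}: telomere span content mismatch")
        g = by_gene.get(t.gene_id)
        if g is None:
            problems.append(f"{t.gene_id}: missing gene model")
            continue
        if g.strand == "+":
            start = rec.seq[g.cds_start - 1 : g.cds_start + 2]
            stop = rec.seq[g.cds_end - 3 : g.cds_end]
        else:
            start = revcomp(rec.seq[g.cds_end - 3 : g.cds_end])
            stop = revcomp(rec.seq[g.cds_start - 1 : g.cds_start + 2])
        if start != "ATG":
            problems.append(f"{t.gene_id}: CDS does not begin with ATG")
        if stop not in spec.true_stops:
            problems.append(f"{t.gene_id}: CDS does not end with a true stop")
        if t.cre5_genomic_ivl is not None and spec.cre_gc == 0.0:
            s, e = t.cre5_genomic_ivl
            inst = rec.seq[s:e]
            if t.strand == "-":
                inst = revcomp(inst)
            ok = all(b in IUPAC[c] for b, c in zip(inst, FIVE_PRIME_CRE))
            if not ok:
                problems.append(f"{t.gene_id}: planted 5' CRE does not match its consensus")
    if problems:
        raise ValueError("manifest validation failed:\n" + "\n".join(problems))


def write_simulation(outdir: str | Path, spec: SimSpec) -> dict[str, Path]:
    """Run the full generator and write all fixture files to ``outdir``.

    Emits genomeA.fasta/gff3, genomeB.fasta/gff3, orthologs.tsv,
    counts.tsv, transcripts.fasta, hits.tsv, and truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, genes, manifest = simulate_genome(spec)
    sister, orthologs, manifest = simulate_sister(records, manifest, spec)
    counts, manifest = simulate_expression(manifest, spec)
    transcripts, hits, code = simulate_stop_codon_fixture(spec)

    from .codon_usage import write_hits_table

    paths = {
        "genome_a": outdir / "genomeA.fasta",
        "gff_a": outdir / "genomeA.gff3",
        "genome_b": outdir / "genomeB.fasta",
        "gff_b": outdir / "genomeB.gff3",
        "orthologs": outdir / "orthologs.tsv",
        "counts": outdir / "counts.tsv",
        "transcripts": outdir / "transcripts.fasta",
        "hits": outdir / "hits.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(records, paths["genome_a"])
    write_gff(genes, paths["gff_a"])
    write_fasta(sister, paths["genome_b"])
    write_gff(genes, paths["gff_b"])
    orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
    counts.to_csv(paths["counts"], sep="\t", index=False)
    write_fasta(transcripts, paths["transcripts"])
    write_hits_table(hits, paths["hits"])
    manifest.to_json(paths["truth"])
    return paths
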