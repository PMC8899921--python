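from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import nanochrom as nc
from nanochrom.cre_motif import SubtelomericRegion
from nanochrom.divergence import (
    SUBSTITUTION_CLASSES,
    PairwiseAlignment,
    RegionPair,
    cre_vs_region_rates,
    global_align,
    pair_regions,
    substitution_spectrum,
)
from nanochrom.telomere import FIVE_PRIME
from nanochrom.synthetic import LengthDist, SimSpec


def brute_align_score(a, b, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Exhaustive search over the affine-gap alignment space (top-down,
    independent of the production aligner)."""

    @lru_cache(maxsize=None)
    def go(i, j, state):  # state: 0 after diagonal, 1 gap in b, 2 gap in a
        if i == len(a) and j == len(b):
            return 0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, (match if a[i] == b[j] else mismatch) + go(i + 1, j + 1, 0))
        if i < len(a):
            best = max(best, (gap_extend if state == 1 else gap_open) + go(i + 1, j, 1))
        if j < len(b):
            best = max(best, (gap_extend if state == 2 else gap_open) + go(i, j + 1, 2))
        return best

    return go(0, 0, 0)


def _region(seq, gene_id="g"):
    return SubtelomericRegion(gene_id=gene_id, side=FIVE_PRIME, seq=seq,
                              anchor_offsets={"start_codon": len(seq)})


# ---------------------------------------------------------------- alignment

def test_identity_alignment_scores_all_matches():
    aln = global_align("ACGT", "ACGT")
    assert aln.score == 4
    assert aln.aligned_a == aln.aligned_b == "ACGT"


def test_single_substitution_produces_one_mismatch_column():
    aln = global_align("ACGT", "AGGT")
    cols = [
        (ca, cb) for ca, cb in zip(aln.aligned_a, aln.aligned_b)
        if ca != cb and ca != "-" and cb != "-"
    ]
    assert cols == [("C", "G")]


def test_alignment_removing_gaps_recovers_inputs():
    aln = global_align("ACGTACGT", "ACGCT")
    assert aln.aligned_a.replace("-", "") == "ACGTACGT"
    assert aln.aligned_b.replace("-", "") == "ACGCT"
    assert not any(a == b == "-" for a, b in zip(aln.aligned_a, aln.aligned_b))


@given(st.integers(0, 10_000))
def test_alignment_score_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    la, lb = rng.integers(1, 9, size=2)
    a = "".join(rng.choice(list("ACGT"), la))
    b = "".join(rng.choice(list("ACGT"), lb))
    assert global_align(a, b).score == pytest.approx(brute_align_score(a, b))


def test_alignment_rejects_empty_or_invalid_input():
    with pytest.raises(ValueError):
        global_align("", "ACGT")
    with pytest.raises(ValueError, match="non-ACGTN"):
        global_align("ACGT", "ACRT")


# ---------------------------------------------------------------- spectrum

def test_spectrum_counts_single_substitution():
    aln = global_align("AAAA", "AACA")
    spec = substitution_spectrum(aln)
    assert spec.counts["AC"] == 1 and spec.n_substitutions == 1
    assert spec.aligned_ungapped == 4
    assert spec.rate == 0.25


def test_spectrum_mask_restricts_to_a_coordinates():
    aln = global_align("AAAA", "AACA")
    assert substitution_spectrum(aln, mask=(0, 2)).rate == 0.0
    masked = substitution_spectrum(aln, mask=(2, 3))
    assert masked.counts["AC"] == 1 and masked.aligned_ungapped == 1
    with pytest.raises(ValueError, match="mask"):
        substitution_spectrum(aln, mask=(0, 9))


def test_spectrum_excludes_gap_and_n_columns():
    aln = PairwiseAlignment(aligned_a="AC-GTN", aligned_b="AT-GAC", score=0)
    spec = substitution_spectrum(aln)
    assert spec.aligned_ungapped == 4  # gap column and N column dropped
    assert spec.counts["CT"] == 1 and spec.counts["TA"] == 1


def test_spectrum_of_self_alignment_is_zero():
    aln = global_align("ACGTTGCA", "ACGTTGCA")
    spec = substitution_spectrum(aln)
    assert spec.n_substitutions == 0 and spec.rate == 0.0


@given(st.integers(0, 10_000))
def test_spectrum_matches_column_walk_and_transposes_on_swap(seed):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list("ACGT"), 40))
    b = list(a)
    for i in rng.choice(40, size=6, replace=False):
        b[i] = "ACGT"[(("ACGT".index(b[i])) + int(rng.integers(1, 4))) % 4]
    b = "".join(b)
    aln = global_align(a, b)
    spec = substitution_spectrum(aln)
    # independent column walk
    walk = sum(
        1 for ca, cb in zip(aln.aligned_a, aln.aligned_b)
        if "-" not in (ca, cb) and "N" not in (ca, cb) and ca != cb
    )
    assert spec.n_substitutions == walk
    # swapping the genomes transposes every class
    spec_t = substitution_spectrum(PairwiseAlignment(aln.aligned_b, aln.aligned_a, aln.score))
    for x in "ACGT":
        for y in "ACGT":
            if x != y:
                assert spec.counts[x + y] == spec_t.counts[y + x]


# ---------------------------------------------------------------- pairing

def test_pair_regions_identity_table_and_skip_counting():
    regions_a = {"g1": _region("ACGTACGT", "g1"), "g2": _region("ACGTACGT", "g2")}
    regions_b = {"g1": _region("ACGAACGT", "g1")}
    table = pd.DataFrame({"a": ["g1", "g2", "g3"], "b": ["g1", "g2", "g3"]})
    pairs, skipped = pair_regions(table, regions_a, regions_b, {"g1": (0, 4)})
    assert len(pairs) == 1 and skipped == 2
    assert pairs[0].cre_interval_a == (0, 4)

    with pytest.raises(ValueError, match="empty"):
        pair_regions(table.iloc[:0], regions_a, regions_b, None)
    dup = pd.DataFrame({"a": ["g1", "g1"], "b": ["g1", "g2"]})
    with pytest.raises(ValueError, match="duplicated"):
        pair_regions(dup, regions_a, regions_b, None)


# ---------------------------------------------------------------- rate recovery

def _simulated_pairs(seed, rho_cre, n=120, mu=0.02, cre_gc=0.0, **kw):
    spec = SimSpec(
        n_chromosomes=n, seed=seed, class_probs=(0.0, 0.0, 1.0),
        subtel5_len=LengthDist(250, 60, 60), mu=mu, rho_cre=rho_cre,
        cre_gc=cre_gc, **kw,
    )
    records, genes, manifest = nc.simulate_genome(spec)
    sister, orth, manifest = nc.simulate_sister(records, manifest, spec)
    cls_a = nc.classify_genome(records)
    cls_b = nc.classify_genome(sister)
    regions_a = nc.subtelomere_catalog(records, cls_a, genes)
    regions_b = nc.subtelomere_catalog(sister, cls_b, genes)
    cre = {t.gene_id: t.cre5_region_ivl for t in manifest.chromosomes
           if t.cre5_region_ivl is not None}
    pairs, _ = pair_regions(orth, regions_a, regions_b, cre)
    return pairs, manifest


def test_null_multiplier_gives_no_rate_reduction():
    # ~240 expected CRE substitutions at n=800 -> SD(reduction) ~ 0.065
    pairs, _ = _simulated_pairs(seed=21, rho_cre=1.0, n=800)
    report = cre_vs_region_rates(pairs)
    assert report.reduction == pytest.approx(0.0, abs=0.15)


def test_pooled_region_rate_equals_independent_pass():
    pairs, _ = _simulated_pairs(seed=22, rho_cre=0.5, n=60)
    report = cre_vs_region_rates(pairs)
    subs = cols = 0
    for p in pairs:
        aln = global_align(p.region_a.seq, p.region_b.seq)
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if "-" in (ca, cb) or "N" in (ca, cb):
                continue
            cols += 1
            subs += ca != cb
    assert report.rate_region == pytest.approx(subs / cols)


def test_substitution_log_agrees_with_pipeline_spectrum():
    """End-to-end: generator's per-site log equals the spectrum the
    divergence module recovers from the emitted sequence pair."""
    pairs, manifest = _simulated_pairs(seed=23, rho_cre=0.5, n=80)
    report = cre_vs_region_rates(pairs)
    comp = str.maketrans("ACGT", "TGCA")
    strand = {t.contig_id: t.strand for t in manifest.chromosomes}
    logged = {k: 0 for k in SUBSTITUTION_CLASSES}
    for e in manifest.substitutions:
        if e.label in ("subtel5", "cre5"):
            # the log is genomic; regions read in gene orientation, so
            # minus-strand events appear as their complements
            key = e.ref + e.alt
            if strand[e.contig_id] == "-":
                key = key.translate(comp)
            logged[key] += 1
    assert report.spectrum_region.counts == logged


def test_rates_require_at_least_one_cre_interval():
    pairs, _ = _simulated_pairs(seed=24, rho_cre=1.0, n=10, p_cre5=0.0)
    with pytest.raises(ValueError, match="CRE"):
        cre_vs_region_rates(pairs)
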