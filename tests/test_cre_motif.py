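import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import nanochrom as nc
from nanochrom.genome_io import GeneModel, SequenceRecord
from nanochrom.telomere import FIVE_PRIME, THREE_PRIME, classify_genome, revcomp
from nanochrom.cre_motif import (
    IUPAC,
    SubtelomericRegion,
    at_profile,
    build_pwm,
    compile_motif,
    extract_subtelomere,
    five_prime_cre,
    positional_density,
    reverse_complement_motif,
    scan_motif,
    three_prime_cre,
)
from conftest import make_contig


def _region(seq, side=FIVE_PRIME, gene_id="g", anchors=None):
    anchors = anchors if anchors is not None else {"start_codon": len(seq)}
    return SubtelomericRegion(gene_id=gene_id, side=side, seq=seq, anchor_offsets=anchors)


# ---------------------------------------------------------------- extraction

def test_plus_strand_five_prime_region_coordinates():
    # 16 bp telomere at positions 1-16, start codon at 61 -> region 17-60 (44 bp)
    rec, cds_start, cds_end = make_contig(subtel5="A" * 44)
    assert cds_start == 61
    cls = classify_genome([rec])["c1"]
    gene = GeneModel("g1", "c1", "+", [(cds_start, cds_end)], cds_start, cds_end)
    region = extract_subtelomere(rec, cls, gene, FIVE_PRIME)
    assert len(region.seq) == 44
    assert region.seq == "A" * 44
    assert region.anchor_offsets["start_codon"] == 44


def test_minus_strand_region_equals_flipped_plus_strand_region():
    """Independent oracle: flip the contig by hand and extract on + strand."""
    rng = np.random.default_rng(42)
    sub5 = "".join(rng.choice(list("ACGT"), 50))
    sub3 = "".join(rng.choice(list("ACGT"), 30))
    rec, cds_start, cds_end = make_contig(subtel5=sub5, subtel3=sub3)
    plus_gene = GeneModel("g1", "c1", "+", [(cds_start, cds_end)], cds_start, cds_end)
    cls = classify_genome([rec])["c1"]
    want5 = extract_subtelomere(rec, cls, plus_gene, FIVE_PRIME).seq
    want3 = extract_subtelomere(rec, cls, plus_gene, THREE_PRIME).seq

    flipped = SequenceRecord("c1", revcomp(rec.seq))
    L = len(rec.seq)
    flip = lambda p: L - p + 1
    minus_gene = GeneModel(
        "g1", "c1", "-", [(flip(cds_end), flip(cds_start))],
        cds_start=flip(cds_end), cds_end=flip(cds_start),
    )
    cls_f = classify_genome([flipped])["c1"]
    got5 = extract_subtelomere(flipped, cls_f, minus_gene, FIVE_PRIME).seq
    got3 = extract_subtelomere(flipped, cls_f, minus_gene, THREE_PRIME).seq
    assert got5 == want5
    assert got3 == want3


def test_gene_abutting_telomere_yields_empty_region():
    rec, cds_start, cds_end = make_contig(subtel5="")
    cls = classify_genome([rec])["c1"]
    gene = GeneModel("g1", "c1", "+", [(cds_start, cds_end)], cds_start, cds_end)
    region = extract_subtelomere(rec, cls, gene, FIVE_PRIME)
    assert region.seq == ""


def test_start_codon_inside_telomere_is_an_error():
    rec, cds_start, cds_end = make_contig()
    cls = classify_genome([rec])["c1"]
    gene = GeneModel("g1", "c1", "+", [(5, cds_end)], cds_start=5, cds_end=cds_end)
    with pytest.raises(ValueError, match="telomere"):
        extract_subtelomere(rec, cls, gene, FIVE_PRIME)


def test_missing_required_telomere_flags_region_absent():
    rec, cds_start, cds_end = make_contig(has5=False)
    cls = classify_genome([rec])["c1"]
    gene = GeneModel("g1", "c1", "+", [(cds_start, cds_end)], cds_start, cds_end)
    assert extract_subtelomere(rec, cls, gene, FIVE_PRIME) is None


# ---------------------------------------------------------------- AT profile

def test_at_profile_extremes_and_padding():
    rows = at_profile([_region("ATAT"), _region("GCGC"), _region("AT")], max_len=4)
    assert rows[0].tolist() == [1, 1, 1, 1]
    assert rows[1].tolist() == [0, 0, 0, 0]
    assert rows[2][:2].tolist() == [1, 1] and np.isnan(rows[2][2:]).all()


def test_at_profile_three_prime_rows_read_from_the_telomere():
    region = _region("GGAT", side=THREE_PRIME, anchors={"telomere": 4})
    row = at_profile([region], max_len=4)[0]
    assert row.tolist() == [1, 1, 0, 0]


@given(st.integers(0, 5000))
def test_at_profile_window_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), 30))
    got = at_profile([_region(seq)], max_len=30, window=5)[0]
    want = [
        np.mean([c in "AT" for c in seq[i : i + 5]]) for i in range(len(seq) - 4)
    ]
    assert np.allclose(got, want)


def test_at_profile_validates_window():
    with pytest.raises(ValueError, match="window"):
        at_profile([_region("ACGT")], max_len=4, window=5)


# ---------------------------------------------------------------- motifs & scanning

def test_default_motifs_match_published_consensus():
    assert len(five_prime_cre().consensus) == 15
    assert five_prime_cre().consensus == "WWWWWWAWTWWWWWW"
    assert three_prime_cre().consensus == "TTNATTTCNTTAA"
    assert len(three_prime_cre()) == 13


def test_compile_motif_rejects_invalid_characters():
    with pytest.raises(ValueError, match="'Z'"):
        compile_motif("AWTZ")


def test_scan_finds_constructed_hit_and_respects_w_violation():
    region = _region("AAAAAAAATAAAAAA")
    matches = scan_motif(region, five_prime_cre())
    assert matches and matches[0].offset == 0 and matches[0].mismatches == 0
    # G at a W slot kills the zero-mismatch match
    region_g = _region("GAAAAAAATAAAAAA")
    assert all(m.offset != 0 for m in scan_motif(region_g, five_prime_cre()))
    assert scan_motif(region_g, five_prime_cre(max_mismatch=1))[0].offset == 0


def _brute_scan(seq, motif):
    out = []
    L = len(motif.consensus)
    for off in range(len(seq) - L + 1):
        mm = sum(
            1 for k in range(L)
            if seq[off + k] not in IUPAC[motif.consensus[k]]
        )
        if mm <= motif.max_mismatch:
            out.append((off, mm))
    return out


@given(st.integers(0, 5000), st.integers(0, 2))
def test_scan_matches_brute_force_iupac_check(seed, max_mm):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), 60, p=[0.4, 0.1, 0.1, 0.4]))
    motif = five_prime_cre(max_mismatch=max_mm)
    got = [(m.offset, m.mismatches) for m in scan_motif(_region(seq), motif)]
    assert got == _brute_scan(seq, motif)


@given(st.integers(0, 5000))
def test_scan_on_reverse_complement_mirrors_offsets(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), 50, p=[0.4, 0.1, 0.1, 0.4]))
    motif = three_prime_cre(max_mismatch=1)
    fwd = scan_motif(_region(seq), motif)
    rc = scan_motif(_region(revcomp(seq)), reverse_complement_motif(motif))
    L = len(seq) - len(motif)
    assert sorted(L - m.offset for m in rc) == sorted(m.offset for m in fwd)


def test_rel_pos_is_match_midpoint_within_tss_to_atg():
    # region of 40, TSS at 10, ATG at 40; match at offset 17 -> midpoint 24.5
    seq = "G" * 17 + "AAAAAAAATAAAAAA" + "G" * 8
    region = _region(seq, anchors={"tss": 10, "start_codon": 40})
    (m,) = scan_motif(region, five_prime_cre())
    assert m.tss_anchored
    assert m.rel_pos == pytest.approx((17 + 7.5 - 10) / 30)


# ---------------------------------------------------------------- presence & density

def test_cre_presence_saturates_at_planting_probability_one():
    spec = nc.SimSpec(n_chromosomes=40, seed=3, p_cre5=1.0, mu=0.0)
    records, genes, _ = nc.simulate_genome(spec)
    classes = classify_genome(records)
    _, fraction = nc.cre_presence(records, classes, genes, five_prime_cre())
    assert fraction == 1.0


def test_cre_presence_with_no_scorable_region_is_missing():
    rec, cds_start, cds_end = make_contig(subtel5="AC")  # shorter than the motif
    cls = classify_genome([rec])
    gene = GeneModel("g1", "c1", "+", [(cds_start, cds_end)], cds_start, cds_end)
    df, fraction = nc.cre_presence([rec], cls, [gene], five_prime_cre())
    assert fraction is None
    assert df["has_cre"].isna().all()


def test_positional_density_mass_and_degenerate_cases():
    from nanochrom.cre_motif import CREMatch

    mid = CREMatch("g", FIVE_PRIME, 0, 0, rel_pos=0.5)
    counts, edges = positional_density([mid], n_bins=20)
    assert counts.sum() == 1 and counts[10] == 1
    counts, _ = positional_density([], n_bins=5)
    assert counts.sum() == 0
    with pytest.raises(ValueError):
        positional_density([mid], n_bins=0)


def test_positional_density_uniform_simulation_passes_chi_square():
    from nanochrom.cre_motif import CREMatch

    rng = np.random.default_rng(9)
    matches = [
        CREMatch("g", FIVE_PRIME, 0, 0, rel_pos=float(u)) for u in rng.random(2000)
    ]
    counts, _ = positional_density(matches, n_bins=20)
    p = stats.chisquare(counts).pvalue
    assert p > 0.01


# ---------------------------------------------------------------- PWM

def test_pwm_invariant_column_has_two_bits_without_pseudocount():
    freqs, ic = build_pwm(["AAAA"] * 10, pseudocount=0.0)
    assert np.allclose(ic, 2.0)
    assert np.allclose(freqs["A"], 1.0)


def test_pwm_uniform_column_has_zero_information():
    _, ic = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
    assert ic[0] == pytest.approx(0.0)


@given(st.integers(0, 5000))
def test_pwm_information_matches_direct_entropy(seed):
    rng = np.random.default_rng(seed)
    instances = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(12)]
    freqs, ic = build_pwm(instances, pseudocount=0.5)
    assert np.allclose(freqs.sum(axis=1), 1.0)
    want = 2.0 - stats.entropy(freqs.to_numpy(), base=2, axis=1)
    assert np.allclose(ic, want)


def test_pwm_rejects_ragged_instances():
    with pytest.raises(ValueError, match="equal length"):
        build_pwm(["AAAA", "AAA"])
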