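# Methods

This note records the models, conventions, and design choices behind
`nanochrom`, in the spirit of a statistical-methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinates and sequence alphabet

Files speak GFF3 (1-based, inclusive); all internal arithmetic is
0-based half-open. The converters in `genome_io` are the only place the
shift happens. Sequence input is restricted to `A C G T N`; other IUPAC
ambiguity codes are rejected rather than remapped, because the
substitution spectrum must be able to trust every base call. Coverage is
an *input* (a `cov=` FASTA header tag or sidecar table), never computed:
read mapping is out of scope.

## Telomere detection and nanochromosome calling

Telomeres are tandem `CCCCAAAA` units at the 5′ contig end and the
reverse complement `TTTTGGGG` at the 3′ end; contigs are never
auto-reoriented (gene strand handles orientation downstream). A hit
requires at least `min_units = 2` complete units — the shortest
unambiguous tandem signal — starting within `max_offset = 5` bp of the
terminus, which tolerates ragged assembly ends. Within-tract mismatches
default to 0 (exactness for synthetic tests); a per-unit mismatch
allowance exists for real assemblies. All four knobs are exposed.
Contig filtering removes contigs shorter than 200 bp or below 2×
coverage, as strict `<` removals.

A **nanochromosome** is a contig with telomeres on both ends and exactly
one annotated gene; the gene-sized fraction is reported over two-telomere
contigs. N50 uses the cumulative-half definition (largest L such that
contigs ≥ L cover half the assembly).

## Subtelomeric regions and CRE scanning

The 5′ subtelomeric region runs from the inner edge of the gene-upstream
telomere to the base before the start codon, the 3′ region from the base
after the stop codon to the gene-downstream telomere, both read 5′→3′ in
gene orientation (minus-strand genes are reverse-complemented). A gene
abutting its telomere yields an empty region with a warning; a missing
required telomere yields an absent region, never a fabricated one.

The 5′ consensus is written `W₆ AWT W₆`: the element is 15 nt with a
centered A-W-T core, and the symmetric 6/6 split of the weak-base flanks
is the only symmetric split consistent with that length; both flank
lengths are configurable. The 3′ consensus is `TTNATTTCNTTAA`. Scanning
tests every offset and reports all matches with at most `max_mismatch`
IUPAC violations (default 0, recommended 1 on real data — the
significance threshold of a de novo motif finder cannot be recovered, so
consensus scanning with an explicit mismatch budget replaces it; matched
instances can be summarized post hoc as a PWM with per-column
information content 2 − H bits).

A match's relative position is its midpoint as a fraction of the
TSS→start-codon interval. When no transcript evidence fixes a TSS, the
interval falls back to telomere→ATG and the match is flagged
`tss_anchored=False`. Midpoints outside the interval leave `rel_pos`
unset.

## Divergence: substitution spectrum and CRE constraint

Orthologous 5′ regions are aligned globally with affine gaps (match +1,
mismatch −1, first gap base −2, each further gap base −1; Biopython's
`PairwiseAligner` with a deterministic first traceback). The
12-class directed spectrum counts substitutions a→b with the first
genome as reference — no outgroup polarization, no multiple-hit
correction, no dN/dS. Columns with a gap or an N in either row are
excluded from both the numerator and the denominator; a mask restricts
counting to the CRE interval in ungapped reference coordinates.

Rates are pooled (column-weighted: total substitutions over total
ungapped columns per stratum) so long regions are not underweighted;
per-region rates are also emitted. The constraint statistic is
`reduction = 1 − r_CRE / r_region`, with `r_region` taken over the
*entire* region (CRE included); it is undefined (reported missing) when
`r_region = 0`.

## Expression association

TPM is computed as `10⁶·(cᵢ/ℓᵢ)/Σⱼ(cⱼ/ℓⱼ)`; an all-zero counts table
yields all-zero TPM. "Active" means TPM strictly above a threshold
(default 1.0, a common convention; configurable, and the dependence can
be swept). Two tests are reported because the upstream study named
neither: a two-sided Mann–Whitney U on TPM (exact permutation
distribution when the smaller group has ≤ 8 observations and no ties;
tie-corrected normal approximation otherwise) and Fisher's exact test on
the active/silent × CRE± table (two-sided by summing hypergeometric
probabilities no larger than the observed table's; the odds ratio is the
sample odds ratio with ∞/NaN conventions on zero cells). Genes missing
from the expression table count as TPM 0 and are logged.

## Stop-codon reassignment

The cited measurement procedure is operationalized as frame-aware
counting inside evalue-filtered (≤ 1e-5) translated-homology hit spans:
overlapping or abutting same-frame hits are merged so no codon is
double-counted; a codon is *internal* when fully inside a merged span
and *terminal* when it is the first in-frame codon following a span's 3′
end. A codon is called reassigned when its internal frequency reaches 1
occurrence per kb of aligned coding sequence (configurable); fewer than
10 kb of alignment flags the call low-confidence, and a call that leaves
no stop codon at all is an error.

## The synthetic generator

Each simulated chromosome is, in gene orientation: telomere
(3 × CCCCAAAA) · 5′ subtelomere · gene · 3′ subtelomere · telomere
(3 × TTTTGGGG), then reverse-complemented with probability 0.5 so both
strands are exercised. Defaults emulate the study conditions: chromosome
telomere classes 18 / 42 / 40 % (0/1/2 telomeres, i.e. 82% with ≥ 1),
two-telomere chromosomes averaging ≈ 1.4 kb, lognormal subtelomeres of
mean 60 bp (min 40/36 so the motifs always fit), CDS of mean 1.1 kb,
Poisson(1.5) introns of length N(36, 5) truncated at 15 with GT..AG
ends, subtelomeric AT content 0.7, coding AT content 0.6 (giving a
genome GC fraction near 40%, like real spirotrich MACs), a 5′ CRE
planted between the simulated TSS and the ATG with probability 0.95 and
the 3′ element with probability 0.9, P(active | CRE±) = 0.92 / 0.25 with
lognormal abundances converted to Poisson counts at a 2 × 10⁶-read
library, and a genetic code with TAA/TAG sense and TGA the sole stop.

The sister genome mutates every non-telomeric site with probability
`mu = 0.02`, multiplied by `rho_cre = 0.5` inside planted CRE intervals;
replacement types are drawn from separate inside/outside weight
matrices, the inside default being AT-ward (A→G and T→C suppressed,
C→A and G→T elevated) and complement-symmetric, so strand flips do not
distort the observed spectrum. No indels are introduced, so gene models
carry over to the sister and alignments are effectively diagonal. Every
substitution is logged (site, from, to, region label) and the log is
checked against the spectrum recovered by the divergence module.

All draws flow from one integer seed through per-component child
streams (genome / sister / expression / codon fixture), so outputs are
byte-reproducible and adding a component never reorders another's draws.
A validator pass independently re-checks emitted files against the
manifest.

**Deliberate simplifications.** Planted CRE instances are pure A/T
(satisfying the consensus exactly) unless `cre_gc > 0`, in which case W
slots carry C/G with that probability — needed when simulating
substitution-type biases out of C sites inside the element, at the cost
of instances that no longer match at zero mismatches. The generator does
not model assembly error, sequencing reads, paralogy, indel divergence,
or MIC→MAC rearrangement; passing tests demonstrate correctness of the
measurement machinery under the planted model, not robustness to those
real-data complications.

## Experiment sizing in tests and the acceptance script

Simulation sizes were chosen by power analysis of the planted effects.
Rate-reduction recovery uses subtelomeres of mean 250 bp (the 15-nt CRE
then occupies ≈ 6 % of the region, so the planted reduction
1 − ρ/(1 − f + fρ) sits near 1 − ρ) and 2000 region pairs (≈ 300
expected CRE substitutions at μ = 0.02, ρ = 0.5, i.e. ≈ 6 % relative
standard error); these runs take CRE intervals from the truth manifest,
since zero-mismatch rescanning would both miss degenerate instances and
admit spurious AT-rich matches that dilute the planted rate contrast.
The type-bias run uses μ = 0.1 and `cre_gc = 0.25` so enough
substitutions originate from C sites inside the element. Calibration of
the Fisher test uses 1000 samples per group under the null so the exact
test's discreteness is negligible. Presence recovery pools 50 replicate
genomes of 40 chromosomes. All test seeds are fixed constants.

## Known limitations

- Telomere-calling thresholds on real assemblies likely need the
  mismatch allowance and offset relaxed; defaults favor exactness.
- Consensus scanning at 0 mismatches produces a small spurious-match
  rate in AT-rich background (the motif is weak); presence estimates are
  therefore slight overestimates of planting probability.
- The between-genome divergence design assumes one-to-one orthologs and
  no indel divergence in subtelomeres; with real diverged species the
  alignment step matters and rates are underestimates (no multiple-hit
  correction).
- The active/silent threshold (TPM > 1) is a convention; conclusions
  about the association should be checked across thresholds.
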