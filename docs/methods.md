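# Methods

## Model overview

hexatype treats a diploid genome position as carrying one of 16 genotypes
over the alphabet {A, C, G, T, X, Y}, where X and Y stand for the indel
alleles with the highest and second-highest weighted support in the pileup
column. The admissible set is the 10 substitution genotypes plus AX, CX,
GX, TX, XX and XY; genotypes pairing a base with Y (or YY) are excluded
because, by definition, X never has less support than Y — a Y-only
genotype would always be dominated by its X counterpart. The model assumes
a diploid, germline sample; multi-sample calling, somatic modes and higher
ploidy are out of scope.

## Observation weighting

Each read contributes `f(Q, M, s) = α·β·γ` to its allele's support:
α ∈ {0, 1} gates on mapping quality (only MAPQ 0 is discarded — a read
that maps ambiguously carries no positional evidence), β maps base quality
to an integer step (0 below Q10, then 1, 2, 3, 4 at Q10/Q13/Q17/Q20), and
γ = 1.375 multiplies indel observations. The γ up-weighting compensates
for aligner gap penalties: true gaps, especially near read ends, are often
realigned as mismatches or clipped, so surviving gap observations are
under-counted relative to substitutions.

Two conventions the weighting needs but that a pileup does not define by
itself:

* **Indel base quality.** An insertion carries the minimum base quality of
  its inserted bases; a deletion carries the quality of the preceding
  aligned base. Gap observations have no bases of their own, so a proxy is
  required; the minimum is the conservative choice for insertions.
* **Anchoring.** An indel is attributed to the reference position of the
  last aligned base before the event — the standard pileup convention,
  verified in the test suite against `samtools mpileup` on the same
  alignments.

Reads with zero weight (MAPQ 0, base quality < 10, or an N base call)
contribute nothing anywhere: they are excluded from the supports, the
strand tallies and the reported depth, so depth reflects the evidence the
model actually used.

When more than two distinct indel alleles occur at a site, only the top
two (by weighted support) become X and Y; further groups are dropped
entirely — they join neither the supports nor the error mass. At equal
support the ranking breaks ties by shorter allele, then lexicographically
smaller sequence, then insertion before deletion, which makes the X/Y
choice deterministic and independent of read order.

## Likelihood

Goodness of fit of the observed supports to a candidate genotype is a
product of two-tailed Fisher exact tests on 2×2 tables of the form
[[observed support, F], [expected support, F]] with F the total weighted
support at the site:

* homozygous ss: expected (1 − P_err)·F for allele s;
* heterozygous st: expected (0.5 − P_err)·F for each of s and t, the two
  p-values combined as a geometric mean (so a het genotype is not doubly
  penalised relative to the single-test hom genotypes);
* the remaining alleles' summed support is tested against P_err·F.

P_err = P_s + P_d combines a SNP error probability (P_s = 0.01) and an
indel error probability (P_d = 0.005) covering library-construction and
reference errors; base-calling and mapping errors are already handled by
the quality weighting. X and Y enter the formulas exactly as base alleles
do.

The two-sided Fisher convention is point-probability summation (the
convention of mainstream statistical software): all tables with the
observed margins whose point probability does not exceed the observed
one's, with a 1 + 1e-7 relative guard on the comparison. The
implementation delegates to `scipy.stats.fisher_exact`, which follows this
convention with log-space factorials (stable to depths ≥ 1e5), and
memoises results; the test suite pins it against an independent
hypergeometric enumeration — exhaustively for all tables with margins
≤ 30, and on random tables with totals up to 5 000 — at 1e-9 absolute.

**Rounding.** Weighted supports are real-valued (γ makes indel supports
fractional), but Fisher tables need integer cells. All four cells are
rounded half-away-from-zero at the table boundary, keeping accumulation
itself exact. **F** in every table is the total support over all six
alleles — the only reading under which all margins are coherent.

**Underflow.** At extreme depth a Fisher factor can underflow to exactly
0.0 in double precision; the posterior computation floors likelihoods at
1e-300 before taking logs, which leaves all rankings intact above the
floor.

## Prior

The prior is an unnormalized weight table anchored at 1 for the homozygous
reference genotype, built from three population-genetic rates (human
defaults; ε in particular should be changed for other species):

| parameter | meaning | default |
|---|---|---|
| θ | rate of single-nucleotide differences between two unrelated haplotypes | 0.001 |
| ω | rate of single indel differences | 0.0001 |
| ε | transition/transversion ratio | 2.1 |

For reference base R with transition partner R' (A↔G, C↔T): a het non-ref
allele costs θ (ε·θ if it is R'), halved for homozygotes (θ/2, with ε² for
R'R' since both alleles are transitions); genotypes with two non-reference
bases pay θ·θ/2 (times ε if one allele is R'). Indel-bearing genotypes pay
ω analogously: RX = ω, R'X = ω·(θ/2)·ε, transversion+X = ω·θ/2, XX = ω/2,
XY = ω·ω/2. The same formulas generalise the reference-A table to any
reference base via the transition relabeling, which the tests verify for
all four references. Priors need no normalisation because the posterior is
normalised over the 16 genotypes anyway.

The "het SNP plus het indel" configurations (CX, GX, TX for reference A)
need no extra genotype labels: they are distinguished from the
"reference plus het indel" case purely by the prior (ω·θ/2[·ε] vs ω), the
likelihood formula for all base+X genotypes being identical in form.

## Decision and quality

The call is the posterior argmax. Ties are broken deterministically:
genotypes containing the reference allele first, then fewer indel alleles,
then lexicographically smaller label. Quality is the gap between the top
two posteriors expressed on a Phred-like decibel scale,
`10·(log10 p1 − log10 p2)`, capped at 255 to fit VCF conventions; it is 0
when the top two posteriors are exactly tied and strictly increasing in
their ratio. Expressing the "distance" as a log ratio (rather than a
difference of normalised posteriors) makes quality independent of how much
mass the remaining 14 genotypes absorb. Sites with no weighted observation,
or fewer than `min_depth` of them, are no-calls.

## Input/output conventions

All user-facing coordinates are 1-based inclusive. VCF output (4.2) uses
anchored indel encoding: a deletion's REF includes the deleted bases with
the anchor base prepended; an insertion's ALT inserts after the anchor;
an XY site becomes one multi-allelic record with genotype 1/2, padding
alleles as needed when deletions of different lengths (or a SNP plus a
deletion) co-occur. No left-alignment beyond this anchoring is performed —
records are emitted at the pileup anchor position. Deletion alleles are
validated against the reference at write time; a contradiction skips the
record with a report rather than emitting an invalid line.

The pileup TSV dialect (documented in the README) exists so the model can
be exercised without alignment machinery; `write_pileup_tsv` and
`read_pileup_tsv` round-trip canonical files byte-identically.

Two per-site triage annotations are attached to emitted records: SUP3
(≥ 3 reads supporting the variant alleles) and SBOTH (variant support on
both strands). A third classical triage criterion — most supporting reads
carry no other variant within 10 bp — requires tracking reads across
sites, which the per-site architecture cannot do; it is documented as out
of scope rather than approximated.

## Simulator

The simulator generates the evidence the caller consumes — per-read
allele, base quality, mapping quality, strand — rather than full reads
through an aligner. Per site: read count ~ Poisson(depth 30 by default);
each read picks a haplotype by fair coin; base observations are then
corrupted with probability 0.01 (substitution to a uniformly different
base) or 0.005 (a random 1 bp indel; deletion errors remove the actual
next reference base so all outputs stay mutually consistent). These rates
deliberately equal the caller's default P_s and P_d, so the noise the
caller assumes is the noise it faces. Reads from an indel haplotype report
it faithfully. Qualities default to constant Q30/M60; strand is a fair
coin independent of allele. Truth SNP alleles honour the ε = 2.1 Ti/Tv
ratio (transition probability ε/(ε+1)).

Truth sites are placed on a 12 bp grid so indel footprints and flanks
never collide; the genotype-class mix defaults to hom_ref 0.40,
het_snp 0.15, hom_snp 0.10, het_ins 0.10, het_del 0.10, hom_indel 0.10,
double_indel 0.05 — deliberately variant-dense so small simulations
exercise every genotype class. Everything is deterministic given the seed
(per-site streams are seeded as (seed, site index)).

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: coverage biases and mapping-quality/allele
correlations, misalignment around repeats (the dominant source of real
indel errors), base-quality miscalibration, multi-nucleotide and clustered
variants, and reference N regions. Recovery rates on simulated stacks are
a check of the inference machinery under its own assumptions, not a
benchmark claim about sequencing data.

## Evaluation

`evaluate_vcfs` matches genotype-aware: a true positive requires contig,
position, REF, and the sorted genotype allele strings all to agree; a
genotype mismatch at a truth site counts one FP and one FN. Records are
classed as indels when any genotype allele's length differs from REF
(mixed SNP+indel records count as indels). Matching is by exact string,
which is sound here because caller and simulator share one anchored
encoder; it would need normalisation for VCFs from other tools.

## Problem sizes

The shipped test suite checks recovery on 2 000 simulated sites per
genotype class (concordance thresholds 99% for hom-ref/het-SNP/hom-SNP,
95% for the indel classes — this package's own acceptance choices) and an
end-to-end round trip over 5 000 mixed sites; `scripts/acceptance.py`
recomputes per-class concordance at 1 000 sites per class plus the same
5 000-site round trip. Measured concordance at these sizes is ≥ 99.9% for
every class, comfortably above the thresholds.
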