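# hexatype

A diploid variant caller that unifies SNP and indel detection in a single
probabilistic model. Instead of scoring SNPs and indels with separate
machinery, every pileup column is summarised over a **six-allele alphabet**
— the four bases plus `X` and `Y`, the indel alleles with the highest and
second-highest weighted read support at that site — and **16 diploid
genotypes** are scored jointly: the 10 classical substitution genotypes
(AA, AC, AG, AT, CC, CG, CT, GG, GT, TT) plus the six indel-bearing ones
(AX, CX, GX, TX, XX, XY). The combinations AY, CY, GY, TY and YY are
excluded by construction, since X always has at least Y's support. Because
all 16 genotypes compete for the same posterior mass, evidence for an indel
automatically argues against a SNP at the same position and vice versa.

The package is aimed at people studying genotype-likelihood models and at
anyone who needs a small, fully testable caller: a read-stack simulator with
known truth and a genotype-aware evaluator are part of the library, so the
whole pipeline runs end to end with no external data.

## The model

At a site with reference base ref, each allele s ∈ {A, C, G, T, X, Y}
receives a weighted support

```
F_s = Σ_i f(Q_i, M_i, s),   f = α·β·γ
```

over the reads supporting s, where α = 0 iff the mapping quality M_i is 0,
β steps 0/1/2/3/4 at base-quality thresholds 10/13/17/20, and γ = 1.375 for
indel observations (aligners penalise gaps more than mismatches, so true
indel evidence is systematically under-represented). Genotypes are ranked
by the Bayesian posterior

```
P(L | F) ∝ P(F | L) · P(L)
```

The likelihood P(F | L) is a product of two-tailed Fisher exact tests
comparing observed against expected support out of the site total F: a
homozygous allele is expected to carry (1 − P_err)·F, each heterozygous
allele (0.5 − P_err)·F (two tests combined as a geometric mean), and the
leftover alleles are tested against the error mass P_err·F, with
P_err = P_s + P_d (SNP and indel error probabilities, defaults 0.01 and
0.005). The prior P(L) encodes human-genome expectations: per-haplotype-pair
heterozygosity θ = 0.001 for SNPs and ω = 0.0001 for indels, with a Ti/Tv
ratio ε = 2.1 favouring transitions (e.g. the AG prior is θ·ε for
reference A, while AC and AT get θ). The call is the maximum-posterior
genotype; its quality is the Phred-scaled gap to the runner-up,
`10·(log10 p1 − log10 p2)`.

## Worked example

`examples/simulate_call_evaluate.py` simulates 1 000 sites at 30× coverage
with 1% substitution / 0.5% indel error injection, calls genotypes, and
scores the calls against the simulated truth:

```
simulated 1000 sites, 588 carry a variant
caller emitted 587 variant records
class         TP      FP      FN    recall  precision
SNP          253       0       1    0.9961   1.0000
indel        333       1       1    0.9970   0.9970
```

A true positive requires position, alleles and diploid genotype all to
match; recall is TP/(TP+FN) against the truth set. The other examples show
single-site posterior inspection (`score_one_site.py`) and calling from the
plain-text pileup dialect with anchored VCF indel encoding
(`call_from_pileup.py`).

## Command line

```
hexatype simulate --out-dir data --seed 7 --n-sites 1000
hexatype call --ref data/reference.fa --pileup data/pileup.tsv --out calls.vcf
hexatype call --ref ref.fa --bam sample.bam --out calls.vcf --region chr1:1-100000
hexatype evaluate calls.vcf data/truth.vcf
```

`call` accepts coordinate-sorted SAM/BAM or the pileup TSV dialect (one
line per site: contig, 1-based position, reference base, and
semicolon-separated observations `allele,baseQ,mapQ,strand` where allele is
a base, `I:<seq>` or `D:<seq>`). All model parameters (`--theta`, `--omega`,
`--epsilon`, `--ps`, `--pd`, `--gamma-indel`) are flags. Output is VCF 4.2
with anchored indel records; an XY site becomes a multi-allelic record with
genotype 1/2.

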