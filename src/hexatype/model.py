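"""The 16-genotype diploid model: priors, Fisher likelihoods, posteriors.

A diploid site is scored over 16 candidate genotypes: the 10 classical
substitution genotypes over {A, C, G, T} plus six indel-bearing ones —
AX, CX, GX, TX, XX and XY — where X and Y are the indel alleles with the
highest and second-highest weighted support at the site. AY, CY, GY, TY
and YY are excluded by construction, since X always has at least Y's
support. Each genotype L gets

    P(L | F)  ∝  P(F | L) · P(L)

where F is the weighted six-allele support vector. The likelihood is a
product of Fisher-exact goodness-of-fit factors: a homozygous genotype
expects its allele to carry (1 − P_err) of the total support, a
heterozygous genotype expects (0.5 − P_err) per allele (combined as a
geometric mean), and all remaining support is tested against the expected
error mass P_err = P_s + P_d. The prior encodes the population-genetic
expectation for a human genome: heterozygosity θ per haplotype pair for
SNPs, ω for indels, and a Ti/Tv ratio ε that favours transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .fisher import fisher_two_tailed
from .observations import SiteStack, SupportVector, accumulate_supports

__all__ = [
    "GENOTYPES",
    "TRANSITION_PARTNER",
    "ModelParams",
    "Genotype",
    "GenotypeCall",
    "prior_table",
    "hom_factor",
    "het_factor",
    "error_term",
    "genotype_likelihood",
    "posterior_distribution",
    "call_genotype",
]

#: The 16 admissible genotype labels, alleles ordered A<C<G<T<X<Y.
GENOTYPES: Tuple[str, ...] = (
    "AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT",
    "AX", "CX", "GX", "TX", "XX", "XY",
)

#: Purine<->purine and pyrimidine<->pyrimidine pairing.
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_ALLELE_ORDER = {a: i for i, a in enumerate("ACGTXY")}


@dataclass(frozen=True)
class ModelParams:
    """Model parameters and operational thresholds.

    theta : rate of single-nucleotide differences between two unrelated
        haplotypes (human default 0.001)
    omega : rate of single indel differences (default 0.0001)
    epsilon : transition/transversion ratio (human default 2.1; change for
        other species)
    p_s, p_d : SNP and indel error probabilities from library construction
        and the reference itself (defaults 0.01 and 0.005); their sum is
        the expected noise fraction P_err in every Fisher table
    gamma_indel : weight multiplier for indel observations (default 1.375)
    min_depth : minimum usable depth to emit a call
    quality_cap : ceiling on the Phred-scaled posterior-gap quality
    """

    theta: float = 0.001
    omega: float = 0.0001
    epsilon: float = 2.1
    p_s: float = 0.01
    p_d: float = 0.005
    gamma_indel: float = 1.375
    min_depth: int = 1
    quality_cap: float = 255.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0 and 0.0 < self.omega < 1.0):
            raise ValueError("theta and omega must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.0 < self.p_s + self.p_d < 0.5):
            raise ValueError("p_s + p_d must lie in (0, 0.5)")
        if self.min_depth < 1 or self.quality_cap <= 0:
            raise ValueError("bad operational thresholds")

    @property
    def p_err(self) -> float:
        return self.p_s + self.p_d


@dataclass(frozen=True)
class Genotype:
    """One of the 16 admissible diploid genotypes."""

    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        a1, a2 = sorted((self.allele1, self.allele2), key=_ALLELE_ORDER.__getitem__)
        object.__setattr__(self, "allele1", a1)
        object.__setattr__(self, "allele2", a2)
        if self.label not in GENOTYPES:
            raise ValueError(f"inadmissible genotype {self.label!r}")

    @property
    def label(self) -> str:
        return self.allele1 + self.allele2

    @classmethod
    def from_label(cls, label: str) -> "Genotype":
        return cls(label[0], label[1])

    @property
    def is_homozygous(self) -> bool:
        return self.allele1 == self.allele2

    @property
    def n_indel_alleles(self) -> int:
        return sum(a in "XY" for a in (self.allele1, self.allele2))


@dataclass
class GenotypeCall:
    """The posterior-ranked genotype decision at one site."""

    contig: str
    position: int
    ref_base: str
    support: SupportVector
    posteriors: Dict[str, float]
    l_max: Genotype
    runner_up: Genotype
    quality: float
    is_variant: bool


def _round_half_up(x: float) -> int:
    # half-away-from-zero for the non-negative supports used here
    return int(math.floor(x + 0.5))


def prior_table(ref_base: str, params: ModelParams) -> Dict[str, float]:
    """Unnormalized genotype priors P(L) for the given reference base.

    The homozygous-reference genotype anchors the scale at 1. Substitution
    genotypes pay θ (per het non-ref allele, halved when homozygous) with a
    factor ε for each transition allele relative to the reference;
    indel-bearing genotypes pay ω analogously. The table generalizes across
    reference bases through the transition pairing A<->G, C<->T.
    """
    ref = ref_base.upper()
    if ref not in "ACGT":
        raise ValueError(f"reference base must be concrete, got {ref_base!r}")
    th, om, ep = params.theta, params.omega, params.epsilon
    partner = TRANSITION_PARTNER[ref]
    priors: Dict[str, float] = {}
    for label in GENOTYPES:
        a1, a2 = label[0], label[1]
        if label == "XX":
            p = om / 2.0
        elif label == "XY":
            p = om * om / 2.0
        elif a2 == "X":  # base + indel het
            if a1 == ref:
                p = om
            elif a1 == partner:
                p = om * (th / 2.0) * ep
            else:
                p = om * (th / 2.0)
        elif a1 == a2:  # homozygous substitution
            if a1 == ref:
                p = 1.0
            elif a1 == partner:
                p = (th / 2.0) * ep * ep
            else:
                p = th / 2.0
        elif ref in (a1, a2):  # het reference + alt
            alt = a2 if a1 == ref else a1
            p = th * ep if alt == partner else th
        else:  # het of two non-reference bases
            p = th * (th / 2.0) * (ep if partner in (a1, a2) else 1.0)
        priors[label] = p
    return priors


def hom_factor(f_s: float, f_total: float, params: ModelParams) -> float:
    """Goodness of fit of allele support ``f_s`` to a homozygous genotype.

    Fisher test of [observed f_s vs total] against [expected
    (1 − P_err)·total vs total].
    """
    t = _round_half_up(f_total)
    return fisher_two_tailed(
        _round_half_up(f_s), t, _round_half_up((1.0 - params.p_err) * f_total), t
    )


def het_factor(f_i: float, f_j: float, f_total: float, params: ModelParams) -> float:
    """Fit of two allele supports to a heterozygous genotype.

    Each allele is tested against the expected (0.5 − P_err)·total and the
    two p-values are combined as a geometric mean.
    """
    t = _round_half_up(f_total)
    expected = _round_half_up((0.5 - params.p_err) * f_total)
    p_i = fisher_two_tailed(_round_half_up(f_i), t, expected, t)
    p_j = fisher_two_tailed(_round_half_up(f_j), t, expected, t)
    return math.sqrt(p_i * p_j)


def error_term(f_other_sum: float, f_total: float, params: ModelParams) -> float:
    """Fit of the unexplained allele support to the error mass P_err·total."""
    t = _round_half_up(f_total)
    return fisher_two_tailed(
        _round_half_up(f_other_sum), t, _round_half_up(params.p_err * f_total), t
    )


def genotype_likelihood(
    genotype: Genotype | str, support: SupportVector, params: ModelParams
) -> float:
    """P(F | L): the Fisher-factor likelihood of the support vector.

    Homozygous ss: hom_factor(F_s) x error_term(rest). Heterozygous st:
    het_factor(F_s, F_t) x error_term(rest). The indel alleles X and Y
    enter exactly as base alleles do.
    """
    if isinstance(genotype, str):
        genotype = Genotype.from_label(genotype)
    total = support.total
    if total <= 0.0:
        raise ValueError("cannot score a site with zero total support")
    a1, a2 = genotype.allele1, genotype.allele2
    rest = support.others_sum((a1, a2))
    if genotype.is_homozygous:
        fit = hom_factor(support.support(a1), total, params)
    else:
        fit = het_factor(support.support(a1), support.support(a2), total, params)
    return fit * error_term(rest, total, params)


def posterior_distribution(
    support: SupportVector, ref_base: str, params: ModelParams
) -> Dict[str, float]:
    """Normalized posteriors P(L | F) over the 16 genotypes.

    Computed in log space with a max-shift, then normalized with an exact
    (fsum) accumulation so the result is independent of summation order.
    """
    priors = prior_table(ref_base, params)
    # floor against underflow: at extreme depth a Fisher factor can round
    # to exactly 0.0 in double precision
    floor = 1e-300
    log_post = {
        label: math.log(priors[label])
        + math.log(max(genotype_likelihood(label, support, params), floor))
        for label in GENOTYPES
    }
    shift = max(log_post.values())
    unnorm = {label: math.exp(lp - shift) for label, lp in log_post.items()}
    z = math.fsum(unnorm.values())
    if z <= 0.0:
        raise ValueError("degenerate evidence: all genotype posteriors vanished")
    return {label: v / z for label, v in unnorm.items()}


def _argmax_rank(ref_base: str):
    # ties: genotype containing the reference allele first, then fewer
    # indel alleles, then lexicographically smaller label
    def key(item: Tuple[str, float]):
        label, post = item
        g = Genotype.from_label(label)
        return (-post, 0 if ref_base in label else 1, g.n_indel_alleles, label)

    return key


def call_genotype(stack: SiteStack, params: ModelParams = ModelParams()) -> Optional[GenotypeCall]:
    """Call the maximum-posterior genotype at one site.

    Returns ``None`` (a no-call) when the usable depth is below
    ``params.min_depth`` or no observation carries weight. Quality is the
    Phred-scaled gap between the top two posteriors,
    10·(log10 p1 − log10 p2), capped at ``params.quality_cap``.
    """
    support = accumulate_supports(stack)
    if support.raw_depth < params.min_depth or support.total <= 0.0:
        return None
    posteriors = posterior_distribution(support, stack.ref_base, params)
    ranked = sorted(posteriors.items(), key=_argmax_rank(stack.ref_base))
    (top_label, p1), (second_label, p2) = ranked[0], ranked[1]
    if p2 <= 0.0:
        quality = params.quality_cap
    else:
        quality = min(params.quality_cap, 10.0 * (math.log10(p1) - math.log10(p2)))
    l_max = Genotype.from_label(top_label)
    return GenotypeCall(
        contig=stack.contig,
        position=stack.position,
        ref_base=stack.ref_base,
        support=support,
        posteriors=posteriors,
        l_max=l_max,
        runner_up=Genotype.from_label(second_label),
        quality=max(0.0, quality),
        is_variant=top_label != stack.ref_base * 2,
    )
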