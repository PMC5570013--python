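"""Per-site read evidence and the weighted six-allele support vector.

A diploid caller that treats indels as first-class alleles needs, at every
reference position, a summary of the read stack over a six-letter alphabet:
the four bases plus ``X`` and ``Y``, the indel alleles with the highest and
second-highest weighted support at that site. Each read contributes a weight
``f(Q, M, s) = alpha * beta * gamma`` where ``alpha`` gates on mapping
quality (0 iff MAPQ = 0), ``beta`` steps through 0..4 at base-quality
thresholds 10/13/17/20, and ``gamma`` up-weights indel observations by
1.375 to counter the gap-opening penalty bias of short-read aligners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

__all__ = [
    "IndelAllele",
    "ReadObservation",
    "SiteStack",
    "SupportVector",
    "INDEL_WEIGHT",
    "weight_read",
    "accumulate_supports",
]

#: Multiplier gamma applied to indel observations.
INDEL_WEIGHT = 1.375

_BASES = frozenset("ACGT")
_OBS_CLASSES = frozenset({"A", "C", "G", "T", "N", "INDEL"})


@dataclass(frozen=True)
class IndelAllele:
    """An insertion or deletion allele.

    ``sequence`` holds the inserted bases (insertions) or the deleted
    reference bases (deletions), uppercase, non-empty.
    """

    kind: str  # "insertion" | "deletion"
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind: {self.kind!r}")
        seq = self.sequence.upper()
        if not seq or any(b not in "ACGTN" for b in seq):
            raise ValueError(f"bad indel sequence: {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sort_key(self) -> Tuple[int, str, int]:
        # deterministic tie-break: shorter, then lexicographic, then
        # insertion before deletion
        return (self.length, self.sequence, 0 if self.kind == "insertion" else 1)


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at one reference position."""

    allele_class: str  # A/C/G/T/N or INDEL
    base_quality: int
    mapping_quality: int
    strand: str = "+"  # "+" forward, "-" reverse
    indel: Optional[IndelAllele] = None

    def __post_init__(self) -> None:
        if self.allele_class not in _OBS_CLASSES:
            raise ValueError(f"bad allele class: {self.allele_class!r}")
        if (self.indel is not None) != (self.allele_class == "INDEL"):
            raise ValueError("indel payload present iff allele_class == 'INDEL'")
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def weight(self) -> float:
        kind = "indel" if self.allele_class == "INDEL" else "substitution"
        if self.allele_class == "N":
            return 0.0
        return weight_read(self.base_quality, self.mapping_quality, kind)


@dataclass
class SiteStack:
    """The column of read observations over one reference position."""

    contig: str
    position: int  # 1-based
    ref_base: str
    observations: List[ReadObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        self.ref_base = self.ref_base.upper()
        if self.ref_base not in _BASES:
            raise ValueError(f"ref_base must be concrete, got {self.ref_base!r}")


@dataclass
class SupportVector:
    """Weighted supports for the six alleles A, C, G, T, X, Y at one site."""

    f_a: float = 0.0
    f_c: float = 0.0
    f_g: float = 0.0
    f_t: float = 0.0
    f_x: float = 0.0
    f_y: float = 0.0
    raw_depth: int = 0
    x_allele: Optional[IndelAllele] = None
    y_allele: Optional[IndelAllele] = None
    strand_counts: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {s: (0, 0) for s in "ACGTXY"}
    )

    @property
    def total(self) -> float:
        return self.f_a + self.f_c + self.f_g + self.f_t + self.f_x + self.f_y

    def support(self, allele: str) -> float:
        return getattr(self, f"f_{allele.lower()}")

    def others_sum(self, kept: Tuple[str, ...]) -> float:
        return sum(self.support(s) for s in "ACGTXY" if s not in kept)


def weight_read(base_quality: int, mapping_quality: int, allele_kind: str) -> float:
    """Weight one read's observation: ``alpha * beta * gamma``.

    alpha is 0 iff mapping quality is 0; beta is the base-quality step
    (0 below Q10, then 1/2/3/4 at Q10/Q13/Q17/Q20); gamma is 1 for base
    observations and 1.375 for indels.
    """
    if base_quality < 0 or mapping_quality < 0:
        raise ValueError("qualities must be non-negative")
    if allele_kind not in ("substitution", "indel"):
        raise ValueError(f"bad allele kind: {allele_kind!r}")
    if mapping_quality == 0:
        return 0.0
    if base_quality < 10:
        beta = 0
    elif base_quality < 13:
        beta = 1
    elif base_quality < 17:
        beta = 2
    elif base_quality < 20:
        beta = 3
    else:
        beta = 4
    gamma = INDEL_WEIGHT if allele_kind == "indel" else 1.0
    return beta * gamma


def accumulate_supports(stack: SiteStack) -> SupportVector:
    """Collapse a read stack into the weighted six-allele support vector.

    Indel observations are grouped by (kind, sequence); the two groups with
    the highest weighted support become the X and Y alleles (ties broken by
    shorter allele, then lexicographic sequence, then insertion before
    deletion). Supports of any further indel groups are discarded. Only
    observations with nonzero weight count toward ``raw_depth`` and the
    per-allele strand tallies.
    """
    sv = SupportVector()
    base_sup = {b: 0.0 for b in "ACGT"}
    base_strands = {b: [0, 0] for b in "ACGT"}
    indel_sup: Dict[IndelAllele, float] = {}
    indel_strands: Dict[IndelAllele, List[int]] = {}

    for obs in stack.observations:
        w = obs.weight
        if w <= 0.0:
            continue
        sv.raw_depth += 1
        si = 0 if obs.strand == "+" else 1
        if obs.allele_class == "INDEL":
            allele = obs.indel
            indel_sup[allele] = indel_sup.get(allele, 0.0) + w
            indel_strands.setdefault(allele, [0, 0])[si] += 1
        else:
            base_sup[obs.allele_class] += w
            base_strands[obs.allele_class][si] += 1

    sv.f_a, sv.f_c, sv.f_g, sv.f_t = (base_sup[b] for b in "ACGT")
    ranked = sorted(indel_sup, key=lambda a: (-indel_sup[a],) + a.sort_key())
    if ranked:
        sv.x_allele = ranked[0]
        sv.f_x = indel_sup[ranked[0]]
    if len(ranked) > 1:
        sv.y_allele = ranked[1]
        sv.f_y = indel_sup[ranked[1]]

    counts = {b: tuple(base_strands[b]) for b in "ACGT"}
    counts["X"] = tuple(indel_strands[sv.x_allele]) if sv.x_allele else (0, 0)
    counts["Y"] = tuple(indel_strands[sv.y_allele]) if sv.y_allele else (0, 0)
    sv.strand_counts = counts
    return sv
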