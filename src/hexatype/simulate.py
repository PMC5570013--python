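"""Synthetic read-stack simulator with known truth genotypes.

Generates a random reference, plants diploid truth genotypes of seven
classes (hom-ref, het/hom SNP, het insertion, het deletion, hom indel, and
a double het indel), and simulates per-site read stacks: each read draws a
haplotype by fair coin, emits that haplotype's allele, and base
observations are then corrupted at the configured substitution and indel
error rates — the same rates the caller's noise model assumes by default.
Strand is assigned by fair coin independently of allele so strand-balance
flags have known expectations. Everything is deterministic given the seed.

The simulator works at the observation level: it emulates the evidence the
caller consumes (allele, base quality, mapping quality, strand per read)
rather than full reads through an aligner.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import TRANSITION_PARTNER, Genotype
from .observations import IndelAllele, ReadObservation, SiteStack
from .variantio import ReferenceStore, encode_site, write_pileup_tsv

__all__ = [
    "GENOTYPE_CLASSES",
    "DEFAULT_CLASS_MIX",
    "SimConfig",
    "TruthSite",
    "simulate_reference",
    "plan_sites",
    "simulate_site",
    "simulate_dataset",
]

GENOTYPE_CLASSES = (
    "hom_ref", "het_snp", "hom_snp", "het_ins", "het_del",
    "hom_indel", "double_indel",
)

#: Variant-dense default mix so that modest simulations exercise every class.
DEFAULT_CLASS_MIX: Dict[str, float] = {
    "hom_ref": 0.40, "het_snp": 0.15, "hom_snp": 0.10, "het_ins": 0.10,
    "het_del": 0.10, "hom_indel": 0.10, "double_indel": 0.05,
}

QualitySpec = Union[int, Tuple[int, int]]  # constant, or inclusive uniform range

#: Truth sites are kept at least this far apart so indel footprints and
#: their 10 bp flanks never overlap a neighbouring site.
SITE_SPACING = 12


@dataclass
class SimConfig:
    contig_length: int = 100_000
    n_sites: int = 1_000
    genotype_class_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    depth_mean: float = 30.0
    base_quality: QualitySpec = 30
    mapping_quality: QualitySpec = 60
    substitution_error_rate: float = 0.01
    indel_error_rate: float = 0.005
    ti_tv_truth: float = 2.1
    max_indel_length: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in self.genotype_class_mix if c not in GENOTYPE_CLASSES]
        if missing:
            raise ValueError(f"unknown genotype classes: {missing}")
        total = sum(self.genotype_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype_class_mix sums to {total}, expected 1")
        for rate in (self.substitution_error_rate, self.indel_error_rate):
            if not 0.0 <= rate < 0.5:
                raise ValueError("error rates must lie in [0, 0.5)")
        if self.contig_length < 2 * SITE_SPACING:
            raise ValueError("contig too short")

    def mix_vector(self) -> np.ndarray:
        return np.array(
            [self.genotype_class_mix.get(c, 0.0) for c in GENOTYPE_CLASSES]
        )


@dataclass
class TruthSite:
    contig: str
    position: int
    ref_base: str
    genotype_class: str
    genotype: Genotype
    alleles: Tuple[object, object]  # base letters and/or IndelAllele

    @property
    def is_variant(self) -> bool:
        return self.genotype_class != "hom_ref"


def simulate_reference(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA of the given length."""
    return "".join(rng.choice(list("ACGT"), size=length))


def _draw_alt_base(ref: str, rng: np.random.Generator, ti_tv: float) -> str:
    """Pick a substitution allele honouring the transition/transversion ratio."""
    if rng.random() < ti_tv / (ti_tv + 1.0):
        return TRANSITION_PARTNER[ref]
    choices = [b for b in "ACGT" if b != ref and b != TRANSITION_PARTNER[ref]]
    return str(rng.choice(choices))


def _draw_indel(
    ref_context: str, rng: np.random.Generator, max_len: int
) -> IndelAllele:
    """A random indel; deletions remove actual downstream reference bases."""
    length = int(rng.integers(1, max_len + 1))
    if rng.random() < 0.5:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        return IndelAllele("insertion", seq)
    return IndelAllele("deletion", ref_context[1 : 1 + length])


def _truth_alleles(
    cls: str, ref: str, ref_context: str, cfg: SimConfig, rng: np.random.Generator
) -> Tuple[Tuple[object, object], Genotype]:
    if cls == "hom_ref":
        return (ref, ref), Genotype(ref, ref)
    if cls == "het_snp":
        alt = _draw_alt_base(ref, rng, cfg.ti_tv_truth)
        return (ref, alt), Genotype(ref, alt)
    if cls == "hom_snp":
        alt = _draw_alt_base(ref, rng, cfg.ti_tv_truth)
        return (alt, alt), Genotype(alt, alt)
    if cls in ("het_ins", "het_del"):
        kind = "insertion" if cls == "het_ins" else "deletion"
        while True:
            indel = _draw_indel(ref_context, rng, cfg.max_indel_length)
            if indel.kind == kind:
                return (ref, indel), Genotype(ref, "X")
    if cls == "hom_indel":
        indel = _draw_indel(ref_context, rng, cfg.max_indel_length)
        return (indel, indel), Genotype("X", "X")
    if cls == "double_indel":
        first = _draw_indel(ref_context, rng, cfg.max_indel_length)
        while True:
            second = _draw_indel(ref_context, rng, cfg.max_indel_length)
            if second != first:
                break
        # X is the allele the tie-break ranks first at equal support
        a, b = sorted((first, second), key=IndelAllele.sort_key)
        return (a, b), Genotype("X", "Y")
    raise ValueError(f"unknown genotype class {cls!r}")


def plan_sites(
    cfg: SimConfig, reference: str, contig: str, rng: np.random.Generator
) -> List[TruthSite]:
    """Place truth sites on a spaced grid and draw their genotype classes."""
    grid = list(range(SITE_SPACING, len(reference) - SITE_SPACING, SITE_SPACING))
    if cfg.n_sites > len(grid):
        raise ValueError(
            f"n_sites={cfg.n_sites} does not fit contig of length "
            f"{len(reference)} at {SITE_SPACING} bp spacing"
        )
    positions = sorted(rng.choice(grid, size=cfg.n_sites, replace=False).tolist())
    classes = rng.choice(GENOTYPE_CLASSES, size=cfg.n_sites, p=cfg.mix_vector())
    sites: List[TruthSite] = []
    for pos, cls in zip(positions, classes):
        ref = reference[pos - 1]
        context = reference[pos - 1 : pos - 1 + cfg.max_indel_length + 2]
        alleles, genotype = _truth_alleles(str(cls), ref, context, cfg, rng)
        sites.append(TruthSite(contig, pos, ref, str(cls), genotype, alleles))
    return sites


def _draw_quality(spec: QualitySpec, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def simulate_site(
    truth: TruthSite,
    cfg: SimConfig,
    site_seed: Union[int, Sequence[int]],
    ref_context: str,
) -> SiteStack:
    """Simulate one read stack for a truth genotype.

    ``ref_context`` is the reference from the site position onward (at
    least two bases) so that deletion-type error observations remove real
    reference bases. Base observations are corrupted with probability
    ``substitution_error_rate`` (different uniform base) or
    ``indel_error_rate`` (random 1 bp indel); reads drawn from an indel
    haplotype report it faithfully.
    """
    rng = np.random.default_rng(site_seed)
    depth = int(rng.poisson(cfg.depth_mean))
    observations: List[ReadObservation] = []
    for _ in range(depth):
        allele = truth.alleles[int(rng.integers(0, 2))]
        strand = "+" if rng.random() < 0.5 else "-"
        mq = _draw_quality(cfg.mapping_quality, rng)
        if isinstance(allele, IndelAllele):
            bq = _draw_quality(cfg.base_quality, rng)
            observations.append(ReadObservation("INDEL", bq, mq, strand, allele))
            continue
        u = rng.random()
        if u < cfg.substitution_error_rate:
            base = str(rng.choice([b for b in "ACGT" if b != allele]))
            observations.append(
                ReadObservation(base, _draw_quality(cfg.base_quality, rng), mq, strand)
            )
        elif u < cfg.substitution_error_rate + cfg.indel_error_rate:
            if rng.random() < 0.5:
                err = IndelAllele("insertion", str(rng.choice(list("ACGT"))))
            else:
                err = IndelAllele("deletion", ref_context[1])
            observations.append(
                ReadObservation("INDEL", _draw_quality(cfg.base_quality, rng),
                                mq, strand, err)
            )
        else:
            observations.append(
                ReadObservation(str(allele), _draw_quality(cfg.base_quality, rng),
                                mq, strand)
            )
    return SiteStack(truth.contig, truth.position, truth.ref_base, observations)


def _write_truth_vcf(
    sites: Sequence[TruthSite], store: ReferenceStore, path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=hexatype-simulator\n")
        for contig in store.contigs():
            fh.write(f"##contig=<ID={contig},length={store.length(contig)}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description='
                 '"Simulated genotype class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
        for site in sites:
            if not site.is_variant:
                continue
            ref_allele, alts, gt = encode_site(
                site.contig, site.position, store, site.alleles
            )
            alt_s = ",".join(alts) if alts else "."
            gt_s = "/".join(str(i) for i in sorted(gt))
            fh.write(
                f"{site.contig}\t{site.position}\t.\t{ref_allele}\t{alt_s}\t.\t.\t"
                f"CLASS={site.genotype_class}\tGT\t{gt_s}\n"
            )


def simulate_dataset(
    cfg: SimConfig, out_dir: str, contig: str = "sim1"
) -> Dict[str, object]:
    """Simulate a mutually consistent {reference, pileup, truth VCF} trio.

    Returns a dict with the three file paths and the in-memory truth list.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    reference = simulate_reference(cfg.contig_length, rng)
    sites = plan_sites(cfg, reference, contig, rng)
    store = ReferenceStore({contig: reference})

    stacks = [
        simulate_site(
            site, cfg, (cfg.seed, i),
            reference[site.position - 1 : site.position + cfg.max_indel_length + 1],
        )
        for i, site in enumerate(sites)
    ]

    ref_path = os.path.join(out_dir, "reference.fa")
    with open(ref_path, "w") as fh:
        fh.write(f">{contig}\n")
        for off in range(0, len(reference), 70):
            fh.write(reference[off : off + 70] + "\n")
    pileup_path = os.path.join(out_dir, "pileup.tsv")
    write_pileup_tsv(stacks, pileup_path)
    truth_path = os.path.join(out_dir, "truth.vcf")
    _write_truth_vcf(sites, store, truth_path)
    return {
        "reference": ref_path,
        "pileup": pileup_path,
        "truth": truth_path,
        "sites": sites,
        "stacks": stacks,
    }
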