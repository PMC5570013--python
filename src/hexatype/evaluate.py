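"""Genotype-aware comparison of a called VCF against a truth VCF.

A called record is a true positive only when the site, the REF/ALT allele
strings, and the diploid genotype all agree with the truth record at that
position; a genotype mismatch at a truth site therefore counts as one
false positive and one false negative. Records are classified as indels
when any genotype allele differs in length from REF, otherwise as SNPs
(a mixed SNP+indel record counts as an indel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from cyvcf2 import VCF

__all__ = ["ClassCounts", "EvaluationResult", "evaluate_vcfs"]


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


@dataclass
class EvaluationResult:
    snp: ClassCounts = field(default_factory=ClassCounts)
    indel: ClassCounts = field(default_factory=ClassCounts)

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        out = {}
        for name, cc in (("snp", self.snp), ("indel", self.indel)):
            out[name] = {
                "tp": cc.tp, "fp": cc.fp, "fn": cc.fn,
                "recall": cc.recall, "precision": cc.precision,
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def format_text(self) -> str:
        lines = [f"{'class':<8}{'TP':>8}{'FP':>8}{'FN':>8}{'recall':>10}{'precision':>11}"]
        for name, cc in (("SNP", self.snp), ("indel", self.indel)):
            lines.append(
                f"{name:<8}{cc.tp:>8}{cc.fp:>8}{cc.fn:>8}"
                f"{cc.recall:>10.4f}{cc.precision:>11.4f}"
            )
        return "\n".join(lines)


GenotypeKey = Tuple[str, int, str, Tuple[str, ...]]


def _load_records(path: str) -> Tuple[Dict[Tuple[str, int], GenotypeKey], List[str]]:
    """Map (contig, pos) -> genotype key; also return header contigs."""
    vcf = VCF(path)
    contigs = list(vcf.seqnames)
    records: Dict[Tuple[str, int], GenotypeKey] = {}
    for rec in vcf:
        alleles = [rec.REF] + list(rec.ALT)
        gt = rec.genotypes[0][:2]
        gt_alleles = tuple(sorted(alleles[i] for i in gt))
        records[(rec.CHROM, rec.POS)] = (rec.CHROM, rec.POS, rec.REF, gt_alleles)
    vcf.close()
    return records, contigs


def _is_indel(key: GenotypeKey) -> bool:
    _, _, ref, gt_alleles = key
    return any(len(a) != len(ref) for a in gt_alleles)


def evaluate_vcfs(called_path: str, truth_path: str) -> EvaluationResult:
    """Compare called variants against truth with genotype-aware matching."""
    called, called_contigs = _load_records(called_path)
    truth, truth_contigs = _load_records(truth_path)
    unknown = {c for c, _ in called} - set(truth_contigs)
    if unknown:
        raise ValueError(
            f"called VCF uses contigs absent from the truth VCF: {sorted(unknown)}"
        )
    result = EvaluationResult()
    for site, key in called.items():
        cls = result.indel if _is_indel(key) else result.snp
        if truth.get(site) == key:
            cls.tp += 1
        else:
            cls.fp += 1
    for site, key in truth.items():
        if called.get(site) != key:
            cls = result.indel if _is_indel(key) else result.snp
            cls.fn += 1
    return result
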