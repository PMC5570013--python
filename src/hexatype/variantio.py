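"""Input/output: reference FASTA, read stacks, and VCF emission.

Read stacks arrive either from coordinate-sorted SAM/BAM (via pysam, with
an explicit CIGAR walk so indel anchoring is under our control) or from a
plain-text pileup dialect that makes the caller testable with no alignment
machinery at all.

Pileup TSV dialect (tab-separated, 1-based coordinates):

    contig  position  ref_base  obs[;obs...]

where each observation token is ``allele,base_qual,map_qual,strand``;
``allele`` is a single base, ``I:<seq>`` for an insertion of <seq>, or
``D:<seq>`` for a deletion of the reference bases <seq>; strand is ``+``
or ``-``. A site with no observations writes ``.`` in the fourth column.

Indels follow the standard pileup convention: an event is attributed to the
reference position of the last aligned base before it, and VCF records are
emitted at that anchor with a shared leading reference base.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO

from .model import GenotypeCall
from .observations import IndelAllele, ReadObservation, SiteStack, SupportVector

__all__ = [
    "ReferenceStore",
    "read_reference",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "stacks_from_alignments",
    "VariantRecord",
    "call_to_record",
    "annotate_confidence_flags",
    "write_vcf",
]


class ReferenceStore:
    """Uppercased, contig-indexed reference with 1-based random access."""

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def contigs(self) -> List[str]:
        return list(self._seqs)

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def base(self, contig: str, position: int) -> str:
        seq = self._seqs[contig]
        if not 1 <= position <= len(seq):
            raise IndexError(
                f"position {position} outside {contig} (length {len(seq)})"
            )
        return seq[position - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Inclusive 1-based slice."""
        seq = self._seqs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise IndexError(f"range {start}-{end} outside {contig}")
        return seq[start - 1 : end]


def read_reference(path: str) -> ReferenceStore:
    """Load a FASTA file into an in-memory reference store."""
    return ReferenceStore(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    )


# ---------------------------------------------------------------------------
# pileup TSV dialect


def _parse_obs_token(token: str, lineno: int) -> ReadObservation:
    parts = token.split(",")
    if len(parts) != 4:
        raise ValueError(f"line {lineno}: malformed observation {token!r}")
    allele, bq, mq, strand = parts
    try:
        bq_i, mq_i = int(bq), int(mq)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer quality in {token!r}") from exc
    if allele.startswith("I:"):
        return ReadObservation("INDEL", bq_i, mq_i, strand,
                               IndelAllele("insertion", allele[2:]))
    if allele.startswith("D:"):
        return ReadObservation("INDEL", bq_i, mq_i, strand,
                               IndelAllele("deletion", allele[2:]))
    if allele.upper() in "ACGTN" and len(allele) == 1:
        return ReadObservation(allele.upper(), bq_i, mq_i, strand)
    raise ValueError(f"line {lineno}: bad allele {allele!r}")


def read_pileup_tsv(path: str) -> Iterator[SiteStack]:
    """Stream SiteStacks from the pileup TSV dialect."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            contig, pos_s, ref, obs_s = fields
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad position {pos_s!r}") from exc
            obs: List[ReadObservation] = []
            if obs_s not in (".", ""):
                obs = [_parse_obs_token(t, lineno) for t in obs_s.split(";")]
            yield SiteStack(contig, pos, ref, obs)


def _obs_token(obs: ReadObservation) -> str:
    if obs.allele_class == "INDEL":
        prefix = "I:" if obs.indel.kind == "insertion" else "D:"
        allele = prefix + obs.indel.sequence
    else:
        allele = obs.allele_class
    return f"{allele},{obs.base_quality},{obs.mapping_quality},{obs.strand}"


def write_pileup_tsv(stacks: Iterable[SiteStack], path: str) -> None:
    with open(path, "w") as fh:
        for stack in stacks:
            obs_s = ";".join(_obs_token(o) for o in stack.observations) or "."
            fh.write(f"{stack.contig}\t{stack.position}\t{stack.ref_base}\t{obs_s}\n")


# ---------------------------------------------------------------------------
# SAM/BAM


def _region_parse(region: Optional[str]) -> Optional[Tuple[str, int, int]]:
    if region is None:
        return None
    if ":" in region:
        contig, span = region.split(":", 1)
        start_s, end_s = span.split("-", 1)
        return contig, int(start_s), int(end_s)
    return region, 1, sys.maxsize


def stacks_from_alignments(
    alignment_path: str,
    reference: ReferenceStore,
    region: Optional[str] = None,
) -> Iterator[SiteStack]:
    """Stream per-position SiteStacks from a coordinate-sorted SAM/BAM.

    Unmapped, secondary and supplementary records are skipped. Insertions
    carry the minimum base quality of the inserted bases; deletions carry
    the base quality of the preceding aligned base; both anchor to the last
    aligned reference position before the event. Positions whose reference
    base is not a concrete A/C/G/T are skipped.
    """
    reg = _region_parse(region)
    pending: Dict[int, List[ReadObservation]] = {}
    current_contig: Optional[str] = None
    last_start = -1

    def flush(upto: Optional[int]) -> Iterator[SiteStack]:
        assert current_contig is not None
        for pos in sorted(p for p in pending if upto is None or p < upto):
            obs = pending.pop(pos)
            if reg is not None and not (
                current_contig == reg[0] and reg[1] <= pos <= reg[2]
            ):
                continue
            ref_base = reference.base(current_contig, pos)
            if ref_base in "ACGT":
                yield SiteStack(current_contig, pos, ref_base, obs)

    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != current_contig:
                if current_contig is not None:
                    yield from flush(None)
                current_contig = read.reference_name
                last_start = -1
            if read.reference_start < last_start:
                raise ValueError(
                    f"input not coordinate-sorted: read {read.query_name!r} "
                    f"at {read.reference_name}:{read.reference_start + 1}"
                )
            last_start = read.reference_start
            yield from flush(read.reference_start + 1)
            _scatter_read(read, reference, pending)
        if current_contig is not None:
            yield from flush(None)


def _scatter_read(
    read: pysam.AlignedSegment,
    reference: ReferenceStore,
    pending: Dict[int, List[ReadObservation]],
) -> None:
    seq = read.query_sequence or ""
    quals = read.query_qualities
    if quals is None:
        quals = [0] * len(seq)
    mq = read.mapping_quality
    strand = "-" if read.is_reverse else "+"
    contig = read.reference_name
    rpos = read.reference_start  # 0-based
    qpos = 0
    anchor: Optional[Tuple[int, int]] = None  # (1-based ref pos, base qual)

    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            for i in range(ln):
                base = seq[qpos + i].upper()
                cls = base if base in "ACGT" else "N"
                pending.setdefault(rpos + i + 1, []).append(
                    ReadObservation(cls, quals[qpos + i], mq, strand)
                )
            anchor = (rpos + ln, quals[qpos + ln - 1])
            rpos += ln
            qpos += ln
        elif op == 1:  # I
            if anchor is not None:
                ins = seq[qpos : qpos + ln].upper()
                bq = min(quals[qpos : qpos + ln])
                pending.setdefault(anchor[0], []).append(
                    ReadObservation("INDEL", bq, mq, strand,
                                    IndelAllele("insertion", ins))
                )
            qpos += ln
        elif op == 2:  # D
            if anchor is not None:
                deleted = reference.slice(contig, rpos + 1, rpos + ln)
                pending.setdefault(anchor[0], []).append(
                    ReadObservation("INDEL", anchor[1], mq, strand,
                                    IndelAllele("deletion", deleted))
                )
            rpos += ln
        elif op == 3:  # N (skip)
            rpos += ln
            anchor = None
        elif op == 4:  # S
            qpos += ln
        # H (5) and P (6) consume nothing


# ---------------------------------------------------------------------------
# VCF emission


@dataclass
class VariantRecord:
    """A VCF-ready call with anchored indel encoding."""

    contig: str
    position: int
    ref_allele: str
    alt_alleles: List[str]
    genotype_indices: Tuple[int, int]
    quality: float
    depth: int
    info: Dict[str, object] = field(default_factory=dict)
    filter_flags: List[str] = field(default_factory=list)


def _concrete_alleles(call: GenotypeCall) -> List[object]:
    out: List[object] = []
    for sym in (call.l_max.allele1, call.l_max.allele2):
        if sym == "X":
            out.append(call.support.x_allele)
        elif sym == "Y":
            out.append(call.support.y_allele)
        else:
            out.append(sym)
    return out


def encode_site(
    contig: str,
    position: int,
    reference: ReferenceStore,
    alleles: Sequence[object],
) -> Tuple[str, List[str], Tuple[int, int]]:
    """Anchored REF/ALT encoding of a diploid allele pair.

    ``alleles`` holds two entries, each a base letter or an IndelAllele.
    Deletion sequences are validated against the reference; a mismatch
    raises ValueError. Returns (ref_allele, alt_alleles, genotype_indices).
    """
    anchor = reference.base(contig, position)
    deletions = [a for a in alleles if isinstance(a, IndelAllele) and a.kind == "deletion"]
    has_indel = any(isinstance(a, IndelAllele) for a in alleles)
    for d in deletions:
        span = reference.slice(contig, position + 1, position + d.length)
        if span != d.sequence:
            raise ValueError(
                f"deletion {d.sequence!r} at {contig}:{position} does not match "
                f"reference {span!r}"
            )
    suffix = max((d.sequence for d in deletions), key=len, default="")
    if not has_indel:
        ref_allele, suffix = reference.base(contig, position), ""
        pos_anchor = position
        def allele_string(a: object) -> str:
            return str(a)
    else:
        ref_allele = anchor + suffix
        def allele_string(a: object) -> str:
            if isinstance(a, IndelAllele):
                if a.kind == "insertion":
                    return anchor + a.sequence + suffix
                return anchor + suffix[a.length :]
            return str(a) + suffix

    # allele strings in genotype order; REF first in the index space
    strings = [allele_string(a) for a in alleles]
    alts: List[str] = []
    indices: List[int] = []
    for s in strings:
        if s == ref_allele:
            indices.append(0)
        else:
            if s not in alts:
                alts.append(s)
            indices.append(1 + alts.index(s))
    return ref_allele, alts, (indices[0], indices[1])


def call_to_record(call: GenotypeCall, reference: ReferenceStore) -> VariantRecord:
    """Convert a genotype call to an anchored VariantRecord."""
    ref_allele, alts, gt = encode_site(
        call.contig, call.position, reference, _concrete_alleles(call)
    )
    sv = call.support
    info: Dict[str, object] = {
        "DP": sv.raw_depth,
        "FA": round(sv.f_a, 3), "FC": round(sv.f_c, 3),
        "FG": round(sv.f_g, 3), "FT": round(sv.f_t, 3),
        "FX": round(sv.f_x, 3), "FY": round(sv.f_y, 3),
        "PP": round(call.posteriors[call.l_max.label], 6),
        "FSC": ",".join(str(sv.strand_counts[s][0]) for s in "ACGTXY"),
        "RSC": ",".join(str(sv.strand_counts[s][1]) for s in "ACGTXY"),
    }
    record = VariantRecord(
        contig=call.contig,
        position=call.position,
        ref_allele=ref_allele,
        alt_alleles=alts,
        genotype_indices=gt,
        quality=call.quality,
        depth=sv.raw_depth,
        info=info,
    )
    return annotate_confidence_flags(record, sv, call)


def annotate_confidence_flags(
    record: VariantRecord, support: SupportVector, call: Optional[GenotypeCall] = None
) -> VariantRecord:
    """Attach per-site confidence flags for variant triage.

    SUP3: at least 3 reads support the variant allele(s). SBOTH: the
    variant allele(s) are seen on both strands. A third classical triage
    criterion — no other variant within 10 bp in most supporting reads —
    needs cross-site read tracking and is deliberately not computed here.
    """
    if call is not None:
        var_syms = {
            s for s in (call.l_max.allele1, call.l_max.allele2)
            if s in "XY" or s != call.ref_base
        }
    else:
        # infer from the record: same-length alts are (padded) SNP alleles,
        # length-changing alts are the X (and possibly Y) indel alleles
        ref_len = len(record.ref_allele)
        var_syms = {a[0] for a in record.alt_alleles if len(a) == ref_len}
        n_indel_alts = sum(1 for a in record.alt_alleles if len(a) != ref_len)
        if n_indel_alts >= 1:
            var_syms.add("X")
        if n_indel_alts >= 2:
            var_syms.add("Y")
    fwd = sum(support.strand_counts[s][0] for s in var_syms)
    rev = sum(support.strand_counts[s][1] for s in var_syms)
    record.filter_flags = []
    if fwd + rev >= 3:
        record.filter_flags.append("SUP3")
    if fwd >= 1 and rev >= 1:
        record.filter_flags.append("SBOTH")
    for flag in record.filter_flags:
        record.info[flag] = True
    return record


_VCF_INFO_HEADER = """\
##INFO=<ID=DP,Number=1,Type=Integer,Description="Observations with nonzero weight">
##INFO=<ID=FA,Number=1,Type=Float,Description="Weighted support for A">
##INFO=<ID=FC,Number=1,Type=Float,Description="Weighted support for C">
##INFO=<ID=FG,Number=1,Type=Float,Description="Weighted support for G">
##INFO=<ID=FT,Number=1,Type=Float,Description="Weighted support for T">
##INFO=<ID=FX,Number=1,Type=Float,Description="Weighted support for the top indel allele X">
##INFO=<ID=FY,Number=1,Type=Float,Description="Weighted support for the second indel allele Y">
##INFO=<ID=PP,Number=1,Type=Float,Description="Posterior probability of the called genotype">
##INFO=<ID=FSC,Number=6,Type=Integer,Description="Forward-strand read counts for A,C,G,T,X,Y">
##INFO=<ID=RSC,Number=6,Type=Integer,Description="Reverse-strand read counts for A,C,G,T,X,Y">
##INFO=<ID=SUP3,Number=0,Type=Flag,Description="At least 3 reads support the variant alleles">
##INFO=<ID=SBOTH,Number=0,Type=Flag,Description="Variant alleles observed on both strands">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    calls: Iterable[GenotypeCall],
    reference: ReferenceStore,
    output_path: str,
    emit_all_sites: bool = False,
    sample_name: str = "SAMPLE",
) -> Tuple[int, int]:
    """Write genotype calls as VCF 4.2.

    By default only variant calls are emitted; with ``emit_all_sites`` the
    homozygous-reference calls appear too (ALT '.'). Records whose indel
    alleles contradict the reference are reported to stderr and skipped.
    Returns (records written, records skipped).
    """
    written = skipped = 0
    with open(output_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hexatype\n")
        for contig in reference.contigs():
            fh.write(f"##contig=<ID={contig},length={reference.length(contig)}>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        for call in calls:
            if not call.is_variant and not emit_all_sites:
                continue
            try:
                rec = call_to_record(call, reference)
            except ValueError as exc:
                print(f"[write_vcf] skipping record: {exc}", file=sys.stderr)
                skipped += 1
                continue
            alt_s = ",".join(rec.alt_alleles) if rec.alt_alleles else "."
            info_parts = []
            for key, val in rec.info.items():
                info_parts.append(key if val is True else f"{key}={val}")
            gt = "/".join(str(i) for i in sorted(rec.genotype_indices))
            fh.write(
                f"{rec.contig}\t{rec.position}\t.\t{rec.ref_allele}\t{alt_s}\t"
                f"{rec.quality:.2f}\t.\t{';'.join(info_parts)}\tGT\t{gt}\n"
            )
            written += 1
    return written, skipped
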