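"""Score a single read stack and inspect the 16 genotype posteriors.

Builds one pileup column by hand — 14 reads supporting the reference base A
and 12 reads carrying a 1 bp insertion of T — and shows how the model
distributes posterior mass over the 16 genotypes.
"""

from hexatype import IndelAllele, ReadObservation, SiteStack, call_genotype

reads = [ReadObservation("A", 30, 60, "+" if i % 2 else "-") for i in range(14)]
reads += [
    ReadObservation("INDEL", 30, 60, "+" if i % 2 else "-",
                    IndelAllele("insertion", "T"))
    for i in range(12)
]
stack = SiteStack("chr1", 1000, "A", reads)

call = call_genotype(stack)
print(f"site {stack.contig}:{stack.position} ref={stack.ref_base} "
      f"depth={call.support.raw_depth}")
print(f"weighted supports: F_A={call.support.f_a:.1f} "
      f"F_X={call.support.f_x:.2f} (X = insertion of 'T')")
for label, p in sorted(call.posteriors.items(), key=lambda kv: -kv[1])[:4]:
    print(f"  P({label} | F) = {p:.3g}")
print(f"call: {call.l_max.label} quality={call.quality:.1f}")
print("AX means one reference haplotype plus one haplotype carrying the")
print("insertion; quality is the Phred-scaled gap to the runner-up genotype.")
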