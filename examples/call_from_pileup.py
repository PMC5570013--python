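"""Call variants from the plain-text pileup dialect and print the VCF.

Writes a 3-site reference and pileup to a temporary directory — one clean
reference site, one heterozygous SNP, one homozygous deletion — then runs
the caller and shows the resulting records.
"""

import tempfile
from pathlib import Path

from hexatype import call_genotype, read_pileup_tsv, read_reference, write_vcf

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "ref.fa").write_text(">demo\nGGGGACGTGGGG\n")

    def column(pos, ref, tokens):
        return f"demo\t{pos}\t{ref}\t" + ";".join(tokens) + "\n"

    pileup = (
        column(5, "A", ["A,30,60,+"] * 10 + ["A,30,60,-"] * 10)
        + column(6, "C", ["C,30,60,+"] * 9 + ["T,30,60,-"] * 11)
        + column(7, "G", ["D:T,30,60,+"] * 8 + ["D:T,30,60,-"] * 9)
    )
    (tmp / "sites.tsv").write_text(pileup)

    reference = read_reference(tmp / "ref.fa")
    calls = [call_genotype(s) for s in read_pileup_tsv(tmp / "sites.tsv")]
    for c in calls:
        print(f"pos {c.position}: {c.l_max.label:>2}  "
              f"variant={c.is_variant}  quality={c.quality:.1f}")

    write_vcf(calls, reference, tmp / "out.vcf")
    print("\nVCF records (deletion is anchored on the preceding base):")
    for line in open(tmp / "out.vcf"):
        if not line.startswith("#"):
            print("  " + "\t".join(line.split("\t")[:7]))
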