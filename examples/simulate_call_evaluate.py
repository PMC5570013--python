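"""Full round trip: simulate truth data, call it, and score the calls.

Simulates 1 000 sites (40% homozygous reference, the rest SNPs and indels
of every class) at 30x coverage with 1% substitution and 0.5% indel error
injection, calls genotypes from the pileup, and compares against the truth
VCF with genotype-aware matching.
"""

import tempfile
from pathlib import Path

from hexatype import (
    SimConfig,
    call_genotype,
    evaluate_vcfs,
    read_pileup_tsv,
    read_reference,
    simulate_dataset,
    write_vcf,
)

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(contig_length=20_000, n_sites=1_000, seed=7)
    out = simulate_dataset(cfg, tmp)
    n_variant = sum(1 for s in out["sites"] if s.is_variant)
    print(f"simulated {len(out['sites'])} sites, {n_variant} carry a variant")

    reference = read_reference(out["reference"])
    calls = (call_genotype(s) for s in read_pileup_tsv(out["pileup"]))
    called = str(Path(tmp) / "called.vcf")
    written, _ = write_vcf((c for c in calls if c is not None), reference, called)
    print(f"caller emitted {written} variant records")

    result = evaluate_vcfs(called, out["truth"])
    print(result.format_text())
    print("recall = TP/(TP+FN) against the simulated truth; a true positive")
    print("requires position, alleles and diploid genotype all to match.")
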