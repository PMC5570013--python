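"""Independent oracles and small utilities shared by the test suite."""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy.special import gammaln

from hexatype import ModelParams, SimConfig, call_genotype, plan_sites, simulate_site
from hexatype.simulate import simulate_reference

REL_GUARD = 1.0 + 1e-7  # relative guard on the point-probability comparison


def _log_pmf(r1: int, r2: int, c1: int) -> tuple:
    """Hypergeometric log point-probabilities over all tables with the
    margins (r1, r2, c1, r1+r2-c1); returns (first support value, array)."""
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    ys = c1 - xs
    logp = (
        gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1) + gammaln(n - c1 + 1)
        - gammaln(n + 1)
        - gammaln(xs + 1) - gammaln(r1 - xs + 1)
        - gammaln(ys + 1) - gammaln(r2 - ys + 1)
    )
    return lo, np.exp(logp)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher exact p-value.

    Enumerates every table with the observed margins and sums the
    hypergeometric point probabilities not exceeding the observed table's.
    Completely independent of the package's implementation path.
    """
    if a + b + c + d == 0:
        return 1.0
    lo, probs = _log_pmf(a + b, c + d, a + c)
    p_obs = probs[a - lo]
    return float(min(1.0, probs[probs <= p_obs * REL_GUARD].sum()))


def fisher_oracle_margin(r1: int, r2: int, c1: int) -> Dict[int, float]:
    """Two-sided p-values for every table with the given margins, keyed by
    the top-left cell. One enumeration serves the whole margin family."""
    if r1 + r2 == 0:
        return {0: 1.0}
    lo, probs = _log_pmf(r1, r2, c1)
    order = np.argsort(probs)
    csum = np.cumsum(probs[order])
    sorted_probs = probs[order]
    out: Dict[int, float] = {}
    for i, p_obs in enumerate(probs):
        k = np.searchsorted(sorted_probs, p_obs * REL_GUARD, side="right")
        out[lo + i] = float(min(1.0, csum[k - 1]))
    return out


# ---------------------------------------------------------------------------
# genotype recovery


def _allele_key(a) -> tuple:
    if isinstance(a, str):
        return (0, a, "", 0)
    return (1, "", a.sequence, 0 if a.kind == "insertion" else 1, a.length)


def genotype_alleles(call) -> tuple:
    """Concrete sorted allele pair of a GenotypeCall (bases / IndelAllele)."""
    out = []
    for sym in (call.l_max.allele1, call.l_max.allele2):
        if sym == "X":
            out.append(call.support.x_allele)
        elif sym == "Y":
            out.append(call.support.y_allele)
        else:
            out.append(sym)
    return tuple(sorted(out, key=_allele_key))


def truth_alleles(site) -> tuple:
    return tuple(sorted(site.alleles, key=_allele_key))


def class_concordance(genotype_class: str, n_sites: int, seed: int,
                      params: ModelParams = ModelParams()) -> float:
    """Fraction of simulated sites of one class whose called genotype
    matches the truth exactly (alleles compared concretely)."""
    cfg = SimConfig(
        contig_length=14 * n_sites + 100,
        n_sites=n_sites,
        genotype_class_mix={genotype_class: 1.0},
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    reference = simulate_reference(cfg.contig_length, rng)
    sites = plan_sites(cfg, reference, "c", rng)
    n_ok = 0
    for i, site in enumerate(sites):
        ctx = reference[site.position - 1 : site.position + cfg.max_indel_length + 1]
        call = call_genotype(simulate_site(site, cfg, (seed, i), ctx), params)
        if call is not None and genotype_alleles(call) == truth_alleles(site):
            n_ok += 1
    return n_ok / len(sites)
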