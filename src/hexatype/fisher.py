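"""Two-tailed Fisher exact test on 2x2 integer tables.

This is the single statistical primitive behind every likelihood factor in
the genotype model: observed allele support is compared against the support
expected under a candidate genotype by placing both in a 2x2 table against
the site total and asking how surprising the observed table is under the
hypergeometric null. The two-sided p-value follows the point-probability
summation convention (the mainstream statistical-software definition): sum
the probabilities of all tables with the same margins whose point
probability does not exceed the observed one, with a 1e-7 relative guard
against floating-point equality.

Results are memoised: genotype scoring issues many repeated tables at
bounded depths, and the cache turns whole-chromosome calling from
Fisher-bound into hash-bound.
"""

from __future__ import annotations

from functools import lru_cache

from scipy.stats import fisher_exact as _scipy_fisher

__all__ = ["fisher_two_tailed"]


@lru_cache(maxsize=1_000_000)
def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    All cells must be non-negative integers. The degenerate all-zero table
    carries no evidence and is defined to return 1.0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a == 0 and b == 0 and c == 0 and d == 0:
        return 1.0
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue)
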