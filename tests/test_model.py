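"""Priors, Fisher likelihood factors, posteriors, and genotype calls."""

import math

import pytest

from hexatype import (
    GENOTYPES,
    Genotype,
    IndelAllele,
    ModelParams,
    ReadObservation,
    SiteStack,
    SupportVector,
    call_genotype,
    error_term,
    genotype_likelihood,
    het_factor,
    hom_factor,
    posterior_distribution,
    prior_table,
)
from helpers import fisher_oracle

PARAMS = ModelParams()


def _sv(**kw):
    sv = SupportVector()
    for key, val in kw.items():
        setattr(sv, key, val)
    return sv


# ---------------------------------------------------------------------------
# genotype labels


def test_sixteen_admissible_genotypes_only():
    assert len(GENOTYPES) == 16
    assert Genotype("G", "A").label == "AG"  # canonical ordering
    for bad in ("AY", "CY", "GY", "TY", "YY"):
        with pytest.raises(ValueError):
            Genotype.from_label(bad)


def test_model_params_validation():
    with pytest.raises(ValueError):
        ModelParams(theta=0.0)
    with pytest.raises(ValueError):
        ModelParams(p_s=0.4, p_d=0.2)  # error mass must stay below 0.5
    with pytest.raises(ValueError):
        ModelParams(epsilon=-1.0)


# ---------------------------------------------------------------------------
# priors


def test_prior_table_reference_a():
    th, om, ep = PARAMS.theta, PARAMS.omega, PARAMS.epsilon
    pt = prior_table("A", PARAMS)
    assert pt["AA"] == 1.0
    assert pt["AG"] == pytest.approx(th * ep)  # 0.0021
    assert pt["AG"] == pytest.approx(0.0021)
    assert pt["GG"] == pytest.approx((th / 2) * ep * ep)
    assert pt["CC"] == pt["TT"] == pytest.approx(th / 2)
    assert pt["AC"] == pt["AT"] == pytest.approx(th)
    assert pt["CG"] == pt["GT"] == pytest.approx(th * (th / 2) * ep)
    assert pt["CT"] == pytest.approx(th * (th / 2))
    assert pt["AX"] == pytest.approx(om)
    assert pt["GX"] == pytest.approx(om * (th / 2) * ep)
    assert pt["CX"] == pt["TX"] == pytest.approx(om * (th / 2))
    assert pt["XX"] == pytest.approx(om / 2)
    assert pt["XY"] == pytest.approx(om * om / 2)
    assert pt["XY"] == pytest.approx(5e-9)


@pytest.mark.parametrize("ref, partner", [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
def test_prior_table_generalizes_by_transition_pairing(ref, partner):
    pt = prior_table(ref, PARAMS)
    th, om, ep = PARAMS.theta, PARAMS.omega, PARAMS.epsilon
    assert pt[ref * 2] == 1.0
    assert pt[partner * 2] == pytest.approx((th / 2) * ep * ep)
    assert pt["".join(sorted(ref + partner))] == pytest.approx(th * ep)
    transversions = [b for b in "ACGT" if b not in (ref, partner)]
    for tv in transversions:
        assert pt[tv * 2] == pytest.approx(th / 2)
        assert pt["".join(sorted(ref + tv))] == pytest.approx(th)
        assert pt["".join(sorted(partner + tv))] == pytest.approx(th * (th / 2) * ep)
        assert pt[tv + "X"] == pytest.approx(om * (th / 2))
    assert pt["".join(sorted(transversions[0] + transversions[1]))] == \
        pytest.approx(th * (th / 2))
    assert pt[partner + "X"] == pytest.approx(om * (th / 2) * ep)
    assert pt[ref + "X"] == pytest.approx(om)


def test_prior_table_rejects_n_reference():
    with pytest.raises(ValueError):
        prior_table("N", PARAMS)


# ---------------------------------------------------------------------------
# likelihood factors


def test_hom_factor_perfect_support_is_one():
    # expected cell round(0.985 * 30) = 30 equals the observed cell
    assert hom_factor(30.0, 30.0, PARAMS) == 1.0


def test_hom_factor_penalizes_half_support():
    assert hom_factor(15.0, 30.0, PARAMS) < hom_factor(30.0, 30.0, PARAMS)


def test_hom_factor_matches_oracle_at_zero_support():
    assert hom_factor(0.0, 100.0, PARAMS) == pytest.approx(
        fisher_oracle(0, 100, 99, 100), abs=1e-9
    )


def test_het_factor_balanced_at_expectation_is_one():
    # expected cell round(0.485 * 40) = 19; observed 19 on both alleles
    assert het_factor(19.0, 19.0, 40.0, PARAMS) == 1.0


def test_het_factor_symmetric_in_alleles():
    for fi, fj in [(10.0, 30.0), (0.0, 40.0), (17.5, 21.0)]:
        assert het_factor(fi, fj, 40.0, PARAMS) == het_factor(fj, fi, 40.0, PARAMS)


def test_het_factor_prefers_balanced_split():
    assert het_factor(40.0, 0.0, 40.0, PARAMS) < het_factor(20.0, 20.0, 40.0, PARAMS)


def test_error_term_at_expected_noise_is_one():
    # observed 3 equals round(0.015 * 200)
    assert error_term(3.0, 200.0, PARAMS) == 1.0


def test_error_term_zero_noise_low_depth():
    # expected cell round(0.015 * 30) = 0: identical rows
    assert error_term(0.0, 30.0, PARAMS) == 1.0


def test_error_term_penalizes_gross_excess():
    assert error_term(100.0, 200.0, PARAMS) < error_term(3.0, 200.0, PARAMS)


# ---------------------------------------------------------------------------
# genotype likelihood


def test_pure_reference_support_maximizes_matching_homozygote():
    sv = _sv(f_a=120.0)
    lik = {g: genotype_likelihood(g, sv, PARAMS) for g in GENOTYPES}
    assert max(lik, key=lik.get) == "AA"
    assert lik["CC"] < lik["AA"]


def test_balanced_base_indel_support_favours_het():
    sv = _sv(f_a=20.0, f_x=20.0, x_allele=IndelAllele("deletion", "T"))
    ax = genotype_likelihood("AX", sv, PARAMS)
    assert ax > genotype_likelihood("AA", sv, PARAMS)
    assert ax > genotype_likelihood("XX", sv, PARAMS)


def test_zero_total_support_is_an_error():
    with pytest.raises(ValueError):
        genotype_likelihood("AA", SupportVector(), PARAMS)


# ---------------------------------------------------------------------------
# posteriors and calling


def test_posterior_normalizes_and_concentrates_on_reference():
    post = posterior_distribution(_sv(f_a=120.0), "A", PARAMS)
    assert math.fsum(post.values()) == pytest.approx(1.0, abs=1e-9)
    assert post["AA"] > 0.99


def test_posterior_ct_exchange_symmetry_for_ref_a():
    sv = _sv(f_a=40.0, f_c=24.0, f_t=8.0, f_g=4.0)
    swapped = _sv(f_a=40.0, f_c=8.0, f_t=24.0, f_g=4.0)
    post = posterior_distribution(sv, "A", PARAMS)
    post_sw = posterior_distribution(swapped, "A", PARAMS)
    exchange = {"AC": "AT", "AT": "AC", "CC": "TT", "TT": "CC",
                "CG": "GT", "GT": "CG", "CX": "TX", "TX": "CX"}
    for label, value in post.items():
        assert value == post_sw[exchange.get(label, label)]


def _stack(ref, observations):
    return SiteStack("chr1", 100, ref, observations)


def _reads(base, n, q=30, m=60):
    return [ReadObservation(base, q, m) for _ in range(n)]


def test_call_reference_stack_is_not_variant():
    call = call_genotype(_stack("A", _reads("A", 30)))
    assert call.l_max.label == "AA"
    assert not call.is_variant
    assert call.quality > 0


def test_call_balanced_het_snp():
    call = call_genotype(_stack("A", _reads("A", 15) + _reads("G", 15)))
    assert call.l_max.label == "AG"
    assert call.is_variant


def test_monotone_flip_three_points():
    for n_g, expected in [(0, "AA"), (20, "AG"), (40, "GG")]:
        call = call_genotype(_stack("A", _reads("A", 40 - n_g) + _reads("G", n_g)))
        assert call.l_max.label == expected


def test_empty_or_weightless_stack_is_no_call():
    assert call_genotype(_stack("A", [])) is None
    assert call_genotype(_stack("A", _reads("A", 5, q=5))) is None


def test_min_depth_guard():
    params = ModelParams(min_depth=10)
    assert call_genotype(_stack("A", _reads("A", 5)), params) is None
    assert call_genotype(_stack("A", _reads("A", 10)), params) is not None


def test_symmetric_posterior_tie_has_zero_quality_and_deterministic_argmax():
    # F_C == F_T with ref A makes AC and AT exactly symmetric top genotypes
    call = call_genotype(_stack("A", _reads("A", 40) + _reads("C", 20) + _reads("T", 20)))
    assert call.posteriors["AC"] == call.posteriors["AT"]
    assert {call.l_max.label, call.runner_up.label} == {"AC", "AT"}
    assert call.l_max.label == "AC"  # lexicographic tie-break
    assert call.quality == 0.0


def test_quality_grows_with_evidence():
    q_small = call_genotype(_stack("A", _reads("A", 10))).quality
    q_large = call_genotype(_stack("A", _reads("A", 40))).quality
    assert q_large > q_small


def test_quality_cap_applies():
    params = ModelParams(quality_cap=20.0)
    call = call_genotype(_stack("A", _reads("A", 60)), params)
    assert call.quality == 20.0
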