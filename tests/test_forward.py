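"""Closed-form forward model: frozen oracle values and structural invariants.

The brute-force oracle below re-derives every expectation by explicit
Poisson summation with per-family-size intervention probabilities, sharing
no code with the package's survival-function evaluation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srbsel import (
    ModelSpec,
    NaturalBirthParams,
    PeakBoundaryWarning,
    PopulationRates,
    Variant,
    apfb,
    expected_abortion_interventions,
    family_size_pmf,
    natural_srb,
    peak_over_lambda,
    predict,
    predict_stopping,
    predict_universal,
    psi_from_phi,
)

P = 0.486


def brute_prediction(lam, n, p, variant):
    """Independent oracle: explicit Poisson sums truncated at N=400."""
    e_extra = 0.0
    phi = 0.0
    pois = math.exp(-lam)  # P(N=0), updated recursively to avoid factorials
    for N in range(1, 400):
        pois *= lam / N
        if N < n:
            continue
        q = p ** (n - 1) if variant == "universal" else p ** (N - 1)
        phi += pois * q
        e_extra += pois * q * p  # forced birth displaces a girl w.p. p
    return lam * (1 - p) + e_extra, lam * p - e_extra, phi


class TestNaturalBenchmarks:
    def test_default_p_gives_946_girls_per_1000_boys(self):
        b100g, g1000b = natural_srb(NaturalBirthParams(P))
        assert round(g1000b) == 946
        assert b100g == pytest.approx(105.76, abs=0.005)

    def test_symmetric_p_gives_parity(self):
        b100g, g1000b = natural_srb(NaturalBirthParams(0.5))
        assert b100g == pytest.approx(100.0)
        assert g1000b == pytest.approx(1000.0)

    def test_representations_mutually_consistent(self):
        params = NaturalBirthParams(0.47)
        b100g, g1000b = natural_srb(params)
        assert b100g * g1000b == pytest.approx(100_000.0, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_p_outside_unit_interval_rejected(self, p):
        with pytest.raises(ValueError):
            NaturalBirthParams(p)


class TestApfb:
    @pytest.mark.parametrize("n, expected", [(1, 0.0), (2, 50.0), (4, 75.0)])
    def test_threshold_reparameterization(self, n, expected):
        assert apfb(n) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [0, -1, 1.5])
    def test_invalid_threshold_rejected(self, n):
        with pytest.raises(ValueError):
            apfb(n)


class TestFamilySizePmf:
    def test_degenerate_at_zero_fertility(self):
        pmf = family_size_pmf(PopulationRates(0.0))
        assert pmf[0] == pytest.approx(1.0)
        assert pmf[1:].sum() == pytest.approx(0.0, abs=1e-15)

    def test_childless_probability_matches_series(self):
        # e^{-1.7} recomputed by direct series summation
        series = sum((-1.7) ** k / math.factorial(k) for k in range(60))
        pmf = family_size_pmf(PopulationRates(1.7))
        assert pmf[0] == pytest.approx(series, rel=1e-12)
        assert pmf[0] == pytest.approx(0.18268352405273466, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.3, 1.7, 5.0])
    def test_mass_and_mean(self, lam):
        pmf = family_size_pmf(PopulationRates(lam))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-11)
        assert (pmf * np.arange(len(pmf))).sum() == pytest.approx(lam, rel=1e-10)

    def test_negative_fertility_rejected(self):
        with pytest.raises(ValueError):
            PopulationRates(-0.5)


class TestPredictions:
    def test_threshold_one_universal_reaches_every_parent(self):
        for lam in (0.3, 1.0, 2.5):
            pred = predict_universal(lam, 1)
            assert pred.phi == pytest.approx(-math.expm1(-lam), rel=1e-12)

    def test_childless_population_is_inert(self):
        for fn in (predict_universal, predict_stopping):
            pred = fn(0.0, 2)
            assert pred.phi == 0.0
            assert pred.e_boys == 0.0 and pred.e_girls == 0.0

    def test_stopping_partial_sum_matches_hand_derivation(self):
        # S = e^{-1}(e^{0.486} - 1 - 0.486), phi = S/p, srb from the balance
        pred = predict_stopping(1.0, 2)
        S = math.exp(-1.0) * (math.exp(0.486) - 1.0 - 0.486)
        assert S == pytest.approx(0.05142954448199804, rel=1e-12)
        assert pred.phi == pytest.approx(S / P, rel=1e-10)
        assert pred.r_b100g == pytest.approx(130.11228382012624, rel=1e-9)

    @pytest.mark.parametrize("variant", ["universal", "stopping_rule"])
    @pytest.mark.parametrize("lam", [0.3, 1.0, 1.7, 2.5, 4.0, 9.0])
    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_agrees_with_brute_force_summation(self, lam, n, variant):
        pred = predict(lam, ModelSpec(variant, n))
        eb, eg, phi = brute_prediction(lam, n, P, "universal" if variant == "universal" else "stopping")
        assert pred.e_boys == pytest.approx(eb, rel=1e-10)
        assert pred.e_girls == pytest.approx(eg, rel=1e-10)
        assert pred.phi == pytest.approx(phi, rel=1e-10)

    @pytest.mark.parametrize("variant", ["universal", "stopping_rule"])
    def test_large_threshold_recovers_natural_ratio(self, variant):
        for lam in (0.5, 2.0, 5.0):
            pred = predict(lam, ModelSpec(variant, 50))
            assert pred.phi == pytest.approx(0.0, abs=1e-8)
            assert pred.r_b100g == pytest.approx(105.76131687242798, abs=1e-8)

    @pytest.mark.parametrize("variant", ["universal", "stopping_rule"])
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_vanishing_fertility_extinguishes_intervention(self, n, variant):
        prev = None
        for lam in (1e-2, 1e-3, 1e-4):
            phi = predict(lam, ModelSpec(variant, n)).phi
            assert phi >= 0.0
            if prev is not None:
                assert phi < prev
            prev = phi
        assert prev < 1e-4

    def test_srb_and_phi_nested_in_threshold(self):
        # Fig-1-style nesting: both R and phi non-increasing in n at fixed lam
        for variant in ("universal", "stopping_rule"):
            for lam in (0.8, 1.5, 3.0):
                preds = [predict(lam, ModelSpec(variant, n)) for n in range(1, 6)]
                srbs = [p_.r_b100g for p_ in preds]
                phis = [p_.phi for p_ in preds]
                assert all(a >= b - 1e-12 for a, b in zip(srbs, srbs[1:]))
                assert all(a >= b - 1e-12 for a, b in zip(phis, phis[1:]))

    @settings(max_examples=60, derandomize=True)
    @given(
        lam=st.floats(0.01, 12.0),
        n=st.integers(1, 6),
        p=st.floats(0.3, 0.7),
        universal=st.booleans(),
    )
    def test_birth_conservation_and_fraction_bounds(self, lam, n, p, universal):
        spec = ModelSpec("universal" if universal else "stopping_rule", n)
        pred = predict(lam, spec, NaturalBirthParams(p))
        assert pred.e_boys + pred.e_girls == pytest.approx(lam, rel=1e-10)
        assert 0.0 <= pred.phi <= pred.psi <= 1.0 + 1e-12
        assert pred.psi == pytest.approx(pred.phi / -math.expm1(-lam), rel=1e-12)


class TestPsiFromPhi:
    def test_no_intervention_means_no_intervening_parents(self):
        assert psi_from_phi(0.0, 2.0) == 0.0

    def test_childlessness_vanishes_at_high_fertility(self):
        assert psi_from_phi(0.3, 50.0) == pytest.approx(0.3, rel=1e-12)

    def test_hand_computed_example(self):
        parent_frac = sum(math.exp(-2.5) * 2.5**k / math.factorial(k) for k in range(1, 80))
        assert psi_from_phi(0.1951, 2.5) == pytest.approx(0.1951 / parent_frac, rel=1e-10)
        assert psi_from_phi(0.1951, 2.5) == pytest.approx(0.2125, abs=5e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            psi_from_phi(0.1, 0.0)
        with pytest.raises(ValueError):
            psi_from_phi(0.95, 1.0)  # exceeds the parent fraction


class TestPeaks:
    def test_stopping_rule_srb_peak_location_and_height(self):
        # grid-scan oracle at fine resolution, then the package's optimizer
        lams = np.arange(0.2, 5.0, 0.0005)
        preds = [predict_stopping(l, 2) for l in lams]
        srbs = np.array([p_.r_b100g for p_ in preds])
        i = srbs.argmax()
        res = peak_over_lambda(2, quantity="srb", variant="stopping_rule")
        assert res.lam == pytest.approx(lams[i], abs=1e-3)
        assert res.value == pytest.approx(srbs[i], abs=1e-4)
        assert res.value == pytest.approx(130.6, abs=0.05)
        assert not res.at_boundary

    def test_stopping_rule_phi_peak_location_and_height(self):
        res = peak_over_lambda(2, quantity="phi", variant="stopping_rule")
        assert res.value == pytest.approx(0.195, abs=5e-4)
        assert res.lam == pytest.approx(2.49, abs=0.01)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_intervention_peak_lies_at_higher_fertility_than_srb_peak(self, n):
        srb_peak = peak_over_lambda(n, quantity="srb", variant="stopping_rule")
        phi_peak = peak_over_lambda(n, quantity="phi", variant="stopping_rule")
        assert phi_peak.lam > srb_peak.lam

    def test_monotone_quantity_reports_boundary_with_warning(self):
        # universal n=1: phi = 1 - e^{-lam} increases monotonically in lam
        with pytest.warns(PeakBoundaryWarning):
            res = peak_over_lambda(1, quantity="phi", variant="universal", lam_hi=10.0)
        assert res.at_boundary
        assert res.lam == pytest.approx(10.0, abs=0.05)


class TestAbortionEquivalent:
    def test_no_intervention_no_abortions(self):
        assert expected_abortion_interventions(0.0) == 0.0

    def test_symmetric_p_one_abortion_per_intervening_couple(self):
        assert expected_abortion_interventions(0.3, NaturalBirthParams(0.5)) == pytest.approx(0.3)

    def test_geometric_mean_monte_carlo(self, test_seed):
        # 1e6 geometric trials: abortions until a male fetus, success 1-p
        rng = np.random.default_rng(test_seed)
        draws = rng.geometric(1 - P, 1_000_000) - 1  # failures before success
        expected = expected_abortion_interventions(0.10) / 0.10
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se
        assert expected == pytest.approx(0.9455252918287938, rel=1e-12)
        assert expected_abortion_interventions(0.10) == pytest.approx(0.0946, abs=5e-5)
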