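"""USEPA risk chain: worked dose/hazard/risk values and its algebra.

The worked-value cases are the printed extreme concentrations of the
source dose/hazard tables, reproduced through the equations at 3
significant figures.
"""

import numpy as np
import pytest

from gwhazard.hhra import (
    ParameterError,
    assess_sample,
    cancer_risk,
    cdi_dermal,
    cdi_ingestion,
    classify_cr,
    classify_hq,
    hazard_index,
    hazard_quotient,
    rfd_dermal,
    sf_dermal,
    total_cancer_risk,
)
from gwhazard.registry import ELEMENTS
from gwhazard.samples import Measurement, WaterSample

REL = 5e-3  # printed values carry 3 significant figures


class TestCDIIngestion:
    @pytest.mark.parametrize("ec,cohort,expected", [
        (0.388, "adult", 1.83e-5),   # Cr max
        (4.086, "child", 2.81e-4),   # Mo max
        (0.009, "adult", 4.25e-7),   # Cr min
        (2.074, "child", 1.42e-4),   # Ni max
        (3.937, "adult", 1.86e-4),   # Pb max
    ])
    def test_reported_extremes(self, registry, ec, cohort, expected):
        assert cdi_ingestion(ec, registry.cohort(cohort)) \
            == pytest.approx(expected, rel=REL)

    def test_zero_and_negative(self, adult):
        assert cdi_ingestion(0.0, adult) == 0.0
        with pytest.raises(ParameterError):
            cdi_ingestion(-1.0, adult)

    def test_adult_closed_form(self, registry, adult):
        # adult EF*EP = LE, so CDI reduces to EC(mg/L) * DWI / BW
        assert adult.ef * adult.ep == adult.le
        ec = 1.234
        assert cdi_ingestion(ec, adult) \
            == pytest.approx(ec * 1e-3 * adult.dwi / adult.bw, rel=1e-12)


class TestCDIDermal:
    @pytest.mark.parametrize("ec,kp,cohort,expected", [
        (0.388, 0.001, "adult", 5.55e-8),    # Cr max
        (2.074, 0.0002, "child", 9.40e-8),   # Ni max
        (2.074, 0.0002, "adult", 5.93e-8),
        (4.086, 0.001, "adult", 5.84e-7),    # Mo max
    ])
    def test_reported_extremes(self, registry, ec, kp, cohort, expected):
        assert cdi_dermal(ec, kp, registry.cohort(cohort)) \
            == pytest.approx(expected, rel=REL)

    def test_invalid_kp(self, adult):
        with pytest.raises(ParameterError):
            cdi_dermal(1.0, 0.0, adult)


class TestReferenceDoses:
    @pytest.mark.parametrize("rfd,giabs,expected", [
        (0.003, 0.025, 7.5e-5),     # Cr: dermal CDI/HQ ratio
        (0.0005, 0.025, 1.25e-5),   # Cd
        (0.42, 1.0, 0.42),
    ])
    def test_dermal_rfd(self, rfd, giabs, expected):
        assert rfd_dermal(rfd, giabs) == pytest.approx(expected, rel=1e-9)

    def test_sf_dermal_division(self):
        assert sf_dermal(1.5, 0.025) == pytest.approx(60.0)
        assert sf_dermal(0.5, 1.0) == 0.5


class TestHazardQuotient:
    @pytest.mark.parametrize("cdi,rfd,expected", [
        (1.83e-5, 0.003, 6.11e-3),   # Cr adult max, ingestion
        (2.78e-5, 0.0005, 5.55e-2),  # Cd child max, ingestion
    ])
    def test_reported(self, cdi, rfd, expected):
        assert hazard_quotient(cdi, rfd) == pytest.approx(expected, rel=REL)

    def test_boundary_band(self):
        assert hazard_quotient(0.003, 0.003) == 1.0
        assert classify_hq(1.0) == "improbable adverse effects"
        assert classify_hq(1.0001) == "potential concern"


class TestAggregation:
    def test_hand_addition(self):
        hi = hazard_index({"a": 0.01, "b": 0.02}, {"a": 0.001})
        assert hi == pytest.approx((0.03, 0.001, 0.031))

    def test_single_element_identity(self):
        assert hazard_index({"a": 0.7}, {}) == (0.7, 0.0, 0.7)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, 8)
        d = dict(zip("abcdefgh", v))
        p = dict(zip("hgfedcba", v[::-1]))
        assert hazard_index(d, {})[2] == pytest.approx(hazard_index(p, {})[2])

    def test_tcr_equals_double_loop(self):
        rng = np.random.default_rng(6)
        cr_i = {el: rng.uniform(0, 1e-5) for el in ("Cr", "As", "Cd", "Pb")}
        cr_d = {el: rng.uniform(0, 1e-7) for el in cr_i}
        expected = sum(cr_i[el] + cr_d[el] for el in cr_i)
        assert total_cancer_risk(cr_i, cr_d)[2] == pytest.approx(expected)

    def test_tcr_empty_raises(self):
        with pytest.raises(ParameterError):
            total_cancer_risk({}, {})


class TestCancerRisk:
    @pytest.mark.parametrize("cdi,sf,expected,band", [
        (1.83e-5, 1.5, 2.75e-5, "lower"),       # Cr adult max
        (1.86e-4, 0.0085, 1.58e-6, "lower"),    # Pb adult max
        (0.0, 1.5, 0.0, "very low"),
    ])
    def test_reported(self, registry, cdi, sf, expected, band):
        if sf > 0 and cdi > 0:
            cr = cancer_risk(cdi, sf)
            assert cr == pytest.approx(expected, rel=REL)
            assert classify_cr(cr, registry) == band
        else:
            assert classify_cr(0.0, registry) == "very low"

    def test_band_classifier_monotone_total(self, registry):
        grid = np.logspace(-9, 0, 200)
        labels = [classify_cr(v, registry) for v in grid]
        order = ["very low", "lower", "moderate", "higher", "very high"]
        ranks = [order.index(l) for l in labels]
        assert ranks == sorted(ranks)
        assert classify_cr(1e-6, registry) == "very low"
        assert classify_cr(1.0000001e-6, registry) == "lower"


class TestAssessSample:
    def _max_sample(self):
        maxima = {"Cr": 0.388, "Ni": 2.074, "As": 0.573,
                  "Mo": 4.086, "Cd": 0.404, "Pb": 3.937}
        return WaterSample("max", {el: Measurement(v) for el, v in maxima.items()})

    def test_reported_max_rows_adult(self, registry, adult):
        r = assess_sample(self._max_sample(), registry, adult)
        assert r.cdi_ing["Cr"] == pytest.approx(1.83e-5, rel=REL)
        assert r.hq_ing["Mo"] == pytest.approx(3.86e-2, rel=REL)
        assert r.cdi_der["Cr"] == pytest.approx(5.55e-8, rel=REL)
        assert r.hq_der["Cd"] == pytest.approx(4.62e-3, rel=REL)
        assert r.cr_ing["Cr"] == pytest.approx(2.75e-5, rel=REL)
        assert r.cr_der["Cr"] == pytest.approx(8.32e-8, rel=REL)  # as-printed policy
        assert r.cr_ing["As"] == pytest.approx(1.35e-5, rel=REL)

    def test_reported_max_rows_child(self, registry, child):
        r = assess_sample(self._max_sample(), registry, child)
        assert r.cdi_ing["Mo"] == pytest.approx(2.81e-4, rel=REL)
        assert r.hq_ing["Pb"] == pytest.approx(7.73e-2, rel=REL)
        assert r.cdi_der["Ni"] == pytest.approx(9.40e-8, rel=REL)
        assert r.cr_ing["Cr"] == pytest.approx(4.00e-5, rel=REL)

    def test_dermal_slope_policies_differ_by_giabs(self, registry, adult):
        s = self._max_sample()
        printed = assess_sample(s, registry, adult, dermal_slope_policy="as_printed")
        strict = assess_sample(s, registry, adult, dermal_slope_policy="eq11")
        giabs = registry.element("Cr").giabs
        assert strict.cr_der["Cr"] == pytest.approx(printed.cr_der["Cr"] / giabs)
        # As has GIABS 1 so the policies coincide there
        assert strict.cr_der["As"] == pytest.approx(printed.cr_der["As"])

    def test_zero_sample_all_risks_zero(self, registry, adult):
        s = WaterSample("z", {el: Measurement(0.0) for el in ELEMENTS})
        r = assess_sample(s, registry, adult)
        assert r.hi_tot == 0.0 and r.tcr == 0.0
        assert all(v == 0.0 for v in r.cdi_ing.values())

    def test_linearity_in_concentration(self, registry, adult, synthetic40):
        s = synthetic40[3]
        doubled = WaterSample("d", {
            el: Measurement(2 * s.concentration(el)) for el in s.concentrations})
        base = assess_sample(s, registry, adult)
        twice = assess_sample(doubled, registry, adult)
        assert twice.hi_tot == pytest.approx(2 * base.hi_tot, rel=1e-9)
        assert twice.tcr == pytest.approx(2 * base.tcr, rel=1e-9)
        for el in s.concentrations:
            assert twice.cdi_ing[el] == pytest.approx(2 * base.cdi_ing[el], rel=1e-9)

    def test_route_decomposition_exact(self, registry, adult, synthetic40):
        for s in synthetic40[:8]:
            r = assess_sample(s, registry, adult)
            assert r.hi_tot == r.hi_ing + r.hi_der
            assert r.tcr == pytest.approx(r.tcr_ing + r.tcr_der, rel=1e-15)

    def test_carcinogen_set_excludes_ni_mo(self, registry, adult):
        r = assess_sample(self._max_sample(), registry, adult)
        assert set(r.cr_ing) == {"Cr", "As", "Cd", "Pb"}

    def test_ingestion_dominates_dermal(self, registry, synthetic40):
        for cohort in ("adult", "child"):
            exp = registry.cohort(cohort)
            for s in synthetic40[:10]:
                r = assess_sample(s, registry, exp)
                for el in r.hq_ing:
                    if s.concentration(el) > 0:
                        assert r.hq_ing[el] > r.hq_der[el]
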