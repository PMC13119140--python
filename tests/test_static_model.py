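"""Static DDI equations and the adult-to-pediatric extrapolation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pedddi import (
    CorrectionFactors,
    DomainError,
    ModelDomainError,
    NotInvertibleError,
    OutOfFractionWarning,
    StaticModelInputs,
    adult_aucr_induction,
    adult_aucr_inhibition,
    correct_cr,
    invert_to_adult,
    pediatric_aucr,
    predict,
    round_half_away,
)

# strategies confined to the model's valid domain; z is bounded away from 0,
# where the inverse mapping is ill-conditioned (the pediatric ratio collapses
# to 1 and carries vanishing information about the adult value)
aucr_adults = st.floats(min_value=0.05, max_value=20.0, allow_nan=False)
zs = st.floats(min_value=1e-3, max_value=1.061, allow_nan=False)
ws = st.floats(min_value=0.1, max_value=1.5, allow_nan=False)


def _in_domain(aucr, z, w):
    return (z / w) * (1.0 - 1.0 / aucr) < 1.0 - 1e-9


class TestAdultEquations:
    @pytest.mark.parametrize("cr, ir, expected", [(0.5, 1.0, 2.0), (0.0, 0.9, 1.0)])
    def test_inhibition_values(self, cr, ir, expected):
        assert adult_aucr_inhibition(cr, ir) == pytest.approx(expected)

    def test_complete_inhibition_refused(self):
        with pytest.raises(ModelDomainError):
            adult_aucr_inhibition(1.0, 1.0)

    @pytest.mark.parametrize(
        "cr, ic, expected", [(0.5, 1.0, 2 / 3), (0.0, 5.0, 1.0), (1.0, 0.0, 1.0)]
    )
    def test_induction_values(self, cr, ic, expected):
        assert adult_aucr_induction(cr, ic) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("cr, ir", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 1.1)])
    def test_out_of_range_fractions_rejected(self, cr, ir):
        with pytest.raises(DomainError):
            adult_aucr_inhibition(cr, ir)

    def test_inputs_require_exactly_one_potency(self):
        with pytest.raises(DomainError):
            StaticModelInputs(cr=0.5)
        with pytest.raises(DomainError):
            StaticModelInputs(cr=0.5, ir=0.5, ic=0.5)
        assert StaticModelInputs(cr=0.5, ir=1.0).adult_aucr() == pytest.approx(2.0)
        assert StaticModelInputs(cr=0.5, ic=1.0).adult_aucr() == pytest.approx(2 / 3)


class TestCorrectCr:
    @pytest.mark.parametrize(
        "cr, z, w, expected", [(0.8, 1.0, 1.0, 0.8), (0.8, 0.9, 1.0, 0.72)]
    )
    def test_values(self, cr, z, w, expected):
        assert correct_cr(cr, z, w) == pytest.approx(expected)

    def test_unclamped_result_above_one_warns(self):
        with pytest.warns(OutOfFractionWarning):
            value = correct_cr(0.8, 0.9, 0.462)
        assert value == pytest.approx(0.72 / 0.462, abs=1e-12)

    def test_non_positive_w_rejected(self):
        with pytest.raises(DomainError):
            correct_cr(0.5, 1.0, 0.0)


class TestPediatricAucr:
    def test_identity_factors_pass_through(self):
        assert pediatric_aucr(1.49, 1.0, 1.0) == pytest.approx(1.49)

    @given(z=zs, w=ws)
    def test_no_adult_interaction_means_no_pediatric_interaction(self, z, w):
        assert pediatric_aucr(1.0, z, w) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "aucr, z, w, printed",
        [
            (1.49, 0.9001, 0.4620, 2.78),  # carbamazepine-erythromycin, age 6
            (1.16, 0.9473, 0.6200, 1.27),  # cyclosporine A-norfloxacin, age 10
        ],
    )
    def test_published_rows_reproduced_at_two_decimals(self, aucr, z, w, printed):
        assert round_half_away(pediatric_aucr(aucr, z, w), 2) == printed

    def test_invalid_region_refused(self):
        # z/w large enough that corrected clearance would be non-positive
        with pytest.raises(ModelDomainError):
            pediatric_aucr(10.0, 1.061, 0.2)
        with pytest.raises(DomainError):
            pediatric_aucr(0.0, 1.0, 1.0)

    def test_inhibition_and_induction_forms_identical(self):
        """1/(1 - r*(1 - 1/a)) == 1/(1 + r*(1/a - 1)) on 10,000 random tuples."""
        rng = np.random.default_rng(20251001)
        n = 10_000
        a = rng.uniform(0.05, 20.0, n)
        z = rng.uniform(1e-9, 1.061, n)
        w = rng.uniform(0.1, 1.5, n)
        mask = (z / w) * (1.0 - 1.0 / a) < 1.0 - 1e-9
        a, z, w = a[mask], z[mask], w[mask]
        assert a.size > 5000
        inhibition_form = 1.0 / (1.0 - (z / w) * (1.0 - 1.0 / a))
        induction_form = 1.0 / (1.0 + (z / w) * (1.0 / a - 1.0))
        np.testing.assert_allclose(inhibition_form, induction_form, rtol=0, atol=1e-12)
        implemented = np.array([pediatric_aucr(*t) for t in zip(a[:200], z[:200], w[:200])])
        np.testing.assert_allclose(implemented, inhibition_form[:200], rtol=0, atol=1e-12)

    @given(
        cr=st.floats(min_value=0.01, max_value=0.99),
        ir=st.floats(min_value=0.01, max_value=1.0),
        z=zs,
        w=ws,
    )
    def test_composition_oracle(self, cr, ir, z, w):
        """Extrapolating the adult equation equals applying it with corrected CR."""
        if (z / w) * cr * ir >= 1.0 - 1e-9:
            return
        adult = adult_aucr_inhibition(cr, ir)
        expected = 1.0 / (1.0 - (z / w) * cr * ir)
        assert pediatric_aucr(adult, z, w) == pytest.approx(expected, abs=1e-10)

    @given(aucr=aucr_adults, z=zs, w=ws)
    def test_sign_preservation(self, aucr, z, w):
        if not _in_domain(aucr, z, w):
            return
        ped = pediatric_aucr(aucr, z, w)
        if aucr > 1:
            assert ped > 1
        elif aucr < 1:
            assert ped < 1

    @given(aucr=aucr_adults, z=zs, w=ws, bump=st.floats(min_value=1e-3, max_value=0.5))
    def test_monotone_in_correction_ratio(self, aucr, z, w, bump):
        z2 = z * (1.0 + bump)
        if abs(aucr - 1) < 1e-6 or not _in_domain(aucr, z2, w):
            return
        lo, hi = pediatric_aucr(aucr, z, w), pediatric_aucr(aucr, z2, w)
        if aucr > 1:
            assert hi > lo
        else:
            assert hi < lo


class TestInversion:
    @given(aucr=aucr_adults, z=zs, w=ws)
    def test_round_trip(self, aucr, z, w):
        if not _in_domain(aucr, z, w):
            return
        ped = pediatric_aucr(aucr, z, w)
        assert invert_to_adult(ped, z, w) == pytest.approx(aucr, abs=1e-9, rel=1e-9)

    def test_published_row_round_trip(self):
        ped = pediatric_aucr(1.49, 0.9001, 0.4620)
        assert invert_to_adult(ped, 0.9001, 0.4620) == pytest.approx(1.49, abs=1e-9)

    def test_identity_cases(self):
        assert invert_to_adult(1.0, 0.5, 1.0) == pytest.approx(1.0)
        assert invert_to_adult(1.7, 1.0, 1.0) == pytest.approx(1.7)

    def test_zero_ontogeny_not_invertible(self):
        with pytest.raises(NotInvertibleError):
            invert_to_adult(1.5, 0.0, 1.0)


class TestPredict:
    def test_approach_a_passes_through_without_isoform(self):
        res = predict(1.49, approach="A")
        assert res.aucr_pediatric == pytest.approx(1.49)
        assert (res.factors.z, res.factors.w) == (1.0, 1.0)

    @pytest.mark.parametrize(
        "aucr, age, approach, printed",
        [(1.49, 6, "B", 1.42), (1.49, 6, "C", 2.78), (1.15, 3, "C", 1.47)],
    )
    def test_published_cyp3a4_rows(self, aucr, age, approach, printed):
        res = predict(aucr, "CYP3A4", age, approach=approach)
        assert round_half_away(res.aucr_pediatric, 2) == printed

    def test_approach_b_requires_isoform_and_age(self):
        with pytest.raises(DomainError):
            predict(1.49, approach="B")

    def test_direction_metadata(self):
        assert predict(1.5, approach="A").direction == "inhibition"
        assert predict(0.8, approach="A").direction == "induction"
        assert predict(1.0, approach="A").direction == "none"

    def test_user_weight_overrides_weight_for_age(self):
        default = predict(1.49, "CYP3A4", 6, approach="C")
        heavier = predict(1.49, "CYP3A4", 6, approach="C", pediatric_weight_kg=40.0)
        assert heavier.weight.source == "user_supplied"
        assert heavier.aucr_pediatric < default.aucr_pediatric

    def test_approach_c_at_least_as_large_as_b_for_inhibition(self, validation_records):
        """With W < 1 the combined correction is the most conservative estimate."""
        for rec in validation_records:
            if rec.isoform.value != "CYP3A4" or rec.aucr_adult <= 1:
                continue
            age = rec.prediction_age_years
            b = predict(rec.aucr_adult, rec.isoform, age, approach="B")
            c = predict(rec.aucr_adult, rec.isoform, age, approach="C")
            assert c.factors.w < 1
            assert c.aucr_pediatric >= b.aucr_pediatric


def test_correction_factor_invariants():
    with pytest.raises(DomainError):
        CorrectionFactors(z=0.9, w=1.0, approach="A")
    with pytest.raises(DomainError):
        CorrectionFactors(z=0.9, w=0.5, approach="B")
    assert CorrectionFactors(z=0.9, w=0.5, approach="C").ratio == pytest.approx(1.8)
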