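"""Closed-form one-compartment infusion kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teicopk.model import final_model
from teicopk.pk import (
    DoseEvent, PKParams, Regimen, auc, concentration, expand_regimen,
    parse_regimen, typical_params,
)

FINAL = final_model()


class TestTypicalParams:
    @pytest.mark.parametrize(
        "cov, cl_exp, v_exp",
        [
            ({"sex": 0, "crrt": 0}, 0.98, 108.69),
            ({"sex": 1, "crrt": 0}, 0.98, 108.69 * np.exp(-1.07)),
            ({"sex": 0, "crrt": 1}, 0.98, 108.69 * np.exp(-0.71)),
            ({"sex": 1, "crrt": 1}, 0.98, 108.69 * np.exp(-1.78)),
        ],
    )
    def test_final_model_strata(self, cov, cl_exp, v_exp):
        p = typical_params(FINAL.theta, FINAL.effects, cov)
        assert p.cl == pytest.approx(cl_exp, rel=1e-12)
        assert p.v == pytest.approx(v_exp, rel=1e-12)

    def test_missing_covariate_raises(self):
        with pytest.raises(KeyError):
            typical_params(FINAL.theta, FINAL.effects, {"sex": 0})


class TestConcentration:
    P = PKParams(cl=0.98, v=108.69)
    SINGLE = [DoseEvent(0.0, 400.0, 1.0)]

    def test_no_doses_is_zero(self):
        assert concentration(self.P, [], 13.0) == 0.0

    def test_single_infusion_values(self):
        # frozen from numeric integration of dA/dt = R - ke*A
        assert concentration(self.P, self.SINGLE, 1.0) == pytest.approx(3.6636, abs=2e-4)
        assert concentration(self.P, self.SINGLE, 24.0) == pytest.approx(2.9775, abs=2e-4)

    def test_pre_dose_exclusion(self):
        doses = [DoseEvent(0.0, 400.0, 1.0), DoseEvent(24.0, 400.0, 1.0)]
        c_trough = concentration(self.P, doses, 24.0)
        assert c_trough == pytest.approx(concentration(self.P, self.SINGLE, 24.0))

    def test_continuity_at_infusion_end(self):
        eps = 1e-9
        before = concentration(self.P, self.SINGLE, 1.0 - eps)
        after = concentration(self.P, self.SINGLE, 1.0 + eps)
        assert after == pytest.approx(before, rel=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(
        cl=st.floats(0.2, 5.0), v=st.floats(10.0, 200.0),
        t=st.floats(0.0, 200.0),
        amounts=st.lists(st.floats(100.0, 1200.0), min_size=1, max_size=4),
    )
    def test_superposition(self, cl, v, t, amounts):
        """Concentration of a schedule equals the sum of its single doses."""
        p = PKParams(cl, v)
        doses = [DoseEvent(12.0 * i, a, 1.0) for i, a in enumerate(amounts)]
        total = concentration(p, doses, t)
        parts = sum(concentration(p, [d], t) for d in doses)
        assert total == pytest.approx(parts, rel=1e-12, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(cl=st.floats(0.2, 5.0), scale=st.floats(1.5, 3.0), t=st.floats(0.1, 100.0))
    def test_linearity_in_dose(self, cl, scale, t):
        p = PKParams(cl, 50.0)
        d1 = [DoseEvent(0.0, 400.0, 1.0)]
        d2 = [DoseEvent(0.0, 400.0 * scale, 1.0)]
        assert concentration(p, d2, t) == pytest.approx(
            scale * concentration(p, d1, t), rel=1e-12
        )

    def test_trough_decreases_in_cl(self):
        doses = expand_regimen(Regimen(400, 12, 3, 400, 24, 1, 168))
        troughs = [concentration(PKParams(cl, 100.0), doses, 72.0)
                   for cl in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(troughs, troughs[1:]))


class TestAuc:
    P = PKParams(cl=0.98, v=108.69)

    def test_no_doses(self):
        assert auc(self.P, [], 0.0, 24.0) == 0.0

    def test_mass_balance_single_dose(self):
        a = auc(self.P, [DoseEvent(0.0, 400.0, 1.0)], 0.0, np.inf)
        assert a == pytest.approx(400.0 / 0.98, rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(
        cl=st.floats(0.3, 4.0), v=st.floats(20.0, 150.0),
        n=st.integers(1, 5), amt=st.floats(200.0, 1000.0),
    )
    def test_mass_balance_any_schedule(self, cl, v, n, amt):
        p = PKParams(cl, v)
        doses = [DoseEvent(24.0 * i, amt, 1.0) for i in range(n)]
        assert auc(p, doses, 0.0, np.inf) == pytest.approx(n * amt / cl, rel=1e-10)

    def test_interval_additivity(self):
        doses = expand_regimen(Regimen(800, 12, 3, 600, 24, 1, 168))
        whole = auc(self.P, doses, 10.0, 100.0)
        split = auc(self.P, doses, 10.0, 47.0) + auc(self.P, doses, 47.0, 100.0)
        assert whole == pytest.approx(split, rel=1e-12)

    def test_inverted_interval_raises(self):
        with pytest.raises(ValueError):
            auc(self.P, [DoseEvent(0, 400, 1)], 10.0, 10.0)


class TestRegimen:
    def test_expand_3_loading(self):
        doses = expand_regimen(Regimen(1000, 12, 3, 1000, 24, 1, 168))
        assert [d.start_time for d in doses] == [0, 12, 24, 48, 72, 96, 120, 144, 168]
        assert all(d.amount == 1000 for d in doses)

    def test_expand_5_loading(self):
        doses = expand_regimen(Regimen(600, 12, 5, 400, 24, 1, 168))
        assert [(d.start_time, d.amount) for d in doses[:5]] == [
            (0, 600), (12, 600), (24, 600), (36, 600), (48, 600)]
        assert [(d.start_time, d.amount) for d in doses[5:]] == [
            (72, 400), (96, 400), (120, 400), (144, 400), (168, 400)]

    def test_maintenance_only(self):
        doses = expand_regimen(Regimen(400, 12, 0, 400, 24, 1, 48))
        assert [d.start_time for d in doses] == [0, 24, 48]

    def test_grammar_roundtrip(self):
        r = parse_regimen("600x3@q12h+400@q24h/1h/168h")
        assert (r.loading_dose, r.n_loading, r.loading_interval) == (600, 3, 12)
        assert (r.maintenance_dose, r.maintenance_interval) == (400, 24)
        assert (r.infusion_duration, r.horizon) == (1, 168)
        assert parse_regimen(r.label()).label() == r.label()

    def test_grammar_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_regimen("totally wrong")

    def test_invalid_dose_event(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, -5.0, 1.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, 400.0, 0.0)
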