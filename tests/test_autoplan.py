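"""Controller logic: first step, condition gating, subroutines, caps."""

import numpy as np
import pytest

from arcplan.autoplan import (
    AutoplanError,
    ConditionSet,
    ControllerConfig,
    evaluate_conditions,
    first_step,
    overcoverage_step,
    subroutine_I,
    subroutine_II,
    subroutine_III,
    subroutine_IV,
)
from arcplan.engine import OptimizeResult
from arcplan.template import default_template


def indices(v78=95.0, d2b=7900.0, v72=95.0, d1u=8000.0):
    return {
        "PTV1_V78Gy_pct": v78,
        "body_D2pct_cGy": d2b,
        "PTV2_V72Gy_pct": v72,
        "urethra_D1pct_cGy": d1u,
    }


class TestEvaluateConditions:
    def test_all_in_band_gives_empty_list(self):
        assert evaluate_conditions(indices()) == []

    def test_body_condition_suppressed_until_coverage_ok(self):
        fails = evaluate_conditions(indices(v78=90.0, d2b=8200.0))
        assert [f.condition for f in fails] == ["c1"]

    def test_body_condition_reported_once_coverage_ok(self):
        fails = evaluate_conditions(indices(v78=95.0, d2b=8200.0))
        assert [f.condition for f in fails] == ["c2"]

    def test_c3_c4_always_evaluated(self):
        fails = evaluate_conditions(indices(v78=90.0, v72=80.0, d1u=8200.0))
        assert [f.condition for f in fails] == ["c1", "c3", "c4"]

    def test_high_side_of_bands_detected(self):
        fails = evaluate_conditions(indices(v78=98.0, v72=99.0))
        assert [(f.condition, f.direction) for f in fails] == [("c1", "high"), ("c3", "high")]

    def test_missing_index_rejected(self):
        with pytest.raises(AutoplanError):
            evaluate_conditions({"PTV1_V78Gy_pct": 95.0})


class _ScriptedEngine:
    """Stand-in engine replaying scripted optimizer results."""

    def __init__(self, results):
        self.results = list(results)
        self.templates_seen = []

    def optimize(self, template, warm_start=True):
        self.templates_seen.append(template)
        return self.results.pop(0)


def scripted_result(status, isoeffects, unattainable=(), reported=None):
    return OptimizeResult(
        w=np.zeros(1),
        status=status,
        dose=None,
        isoeffects=isoeffects,
        unattainable=list(unattainable),
        unattainable_isoeffects=reported or {},
    )


class TestFirstStep:
    def _ids(self, tpl):
        probe = tpl.probe_function()
        b1, b2 = tpl.find(structure="bladder", kind="serial")
        return probe, b1, b2

    def test_probe_and_bladder_updates_are_exact(self):
        tpl = default_template()
        probe, b1, b2 = self._ids(tpl)
        eng = _ScriptedEngine(
            [
                scripted_result(
                    "unattainable",
                    {probe.id: 2400.0, b1.id: 5500.0, b2.id: 6000.0},
                    unattainable=[probe.id],
                    reported={probe.id: 2000.0},
                ),
                scripted_result(
                    "feasible",
                    {probe.id: 1750.0, b1.id: 5000.0, b2.id: 4000.0},
                ),
            ]
        )
        out, _ = first_step(tpl, eng)
        # the probe isoconstraint seen by the second optimization is e0 - 10%
        mid_probe = eng.templates_seen[1].probe_function()
        assert mid_probe.isoconstraint == pytest.approx(1800.0)
        # final: probe pinned at its isoeffect (fixed point), bladder at -40%
        assert out.probe_function().isoconstraint == pytest.approx(1750.0)
        nb1, nb2 = out.find(structure="bladder", kind="serial")
        assert nb1.isoconstraint == pytest.approx(3000.0)
        assert nb2.isoconstraint == pytest.approx(2400.0)

    def test_feasible_probe_raises_misconfiguration_error(self):
        tpl = default_template()
        probe, b1, b2 = self._ids(tpl)
        eng = _ScriptedEngine(
            [scripted_result("feasible", {probe.id: 700.0, b1.id: 5000.0, b2.id: 5000.0})]
        )
        with pytest.raises(AutoplanError, match="probe not triggered"):
            first_step(tpl, eng)


class TestSubroutineI:
    def test_phase_a_doubles_target_weights(self):
        tpl = default_template()
        out, info = subroutine_I(tpl, indices(v78=85.0))
        assert info["phase"] == "A"
        for cf in out.cost_functions:
            if cf.structure in ("PTV1", "CTV") and cf.is_target:
                assert cf.weight == 200.0

    def test_doubling_clips_at_caps(self):
        tpl = default_template()
        funcs = []
        for cf in tpl.cost_functions:
            if cf.structure in ("PTV1", "CTV") and cf.is_target:
                cf = cf.with_(weight=300.0 if cf.kind == "underdose_dvh" else 600.0)
            funcs.append(cf)
        tpl.cost_functions = funcs
        out, _ = subroutine_I(tpl, indices(v78=85.0))
        for cf in out.cost_functions:
            if cf.structure in ("PTV1", "CTV"):
                if cf.kind == "underdose_dvh":
                    assert cf.weight == 500.0  # 300 * 2 clipped at 500
                elif cf.kind == "target_penalty":
                    assert cf.weight == 1000.0  # 600 * 2 clipped at 1000

    def test_phase_b_loosens_oars_once_capped(self):
        tpl = default_template()
        funcs = []
        for cf in tpl.cost_functions:
            if cf.structure in ("PTV1", "CTV") and cf.is_target:
                cf = cf.with_(weight=500.0 if cf.kind == "underdose_dvh" else 1000.0)
            funcs.append(cf)
        tpl.cost_functions = funcs
        before_bladder = tpl.find(structure="bladder", kind="serial")
        before_patient = tpl.find(structure="patient", kind="quadratic_overdose")[0]
        out, info = subroutine_I(tpl, indices(v78=85.0))
        assert info["phase"] == "B"
        after_bladder = out.find(structure="bladder", kind="serial")
        for b0, b1 in zip(before_bladder, after_bladder):
            assert b1.weight == pytest.approx(max(1.0, b0.weight * 0.5))
            assert b1.isoconstraint == pytest.approx(b0.isoconstraint * 1.05)
            assert b1.shrink_margin_mm == pytest.approx(min(40.0, b0.shrink_margin_mm + 2.0))
        after_patient = out.find(structure="patient", kind="quadratic_overdose")[0]
        assert after_patient.isoconstraint == pytest.approx(before_patient.isoconstraint + 1.0)

    def test_rejected_when_condition_one_passes(self):
        with pytest.raises(AutoplanError):
            subroutine_I(default_template(), indices(v78=95.0))


class TestSubroutineII:
    def test_doubles_patient_maximum_dose_weight(self):
        out, _ = subroutine_II(default_template(), indices(d2b=8200.0))
        assert out.find(structure="patient", kind="maximum_dose")[0].weight == 8.0

    def test_clips_at_1000(self):
        tpl = default_template()
        cf = tpl.find(structure="patient", kind="maximum_dose")[0]
        tpl = tpl.replace_function(cf, cf.with_(weight=600.0))
        out, _ = subroutine_II(tpl, indices(d2b=8200.0))
        assert out.find(structure="patient", kind="maximum_dose")[0].weight == 1000.0

    def test_flags_exhausted_at_cap(self):
        tpl = default_template()
        cf = tpl.find(structure="patient", kind="maximum_dose")[0]
        tpl = tpl.replace_function(cf, cf.with_(weight=1000.0))
        out, info = subroutine_II(tpl, indices(d2b=8200.0))
        assert info["exhausted"] is True
        assert out.find(structure="patient", kind="maximum_dose")[0].weight == 1000.0

    def test_rejected_when_condition_two_passes(self):
        with pytest.raises(AutoplanError):
            subroutine_II(default_template(), indices())


class TestSubroutineIII:
    def test_phase_a_doubles_ptv2_weights(self):
        out, info = subroutine_III(default_template(), indices(v72=80.0))
        assert info["phase"] == "A"
        for cf in out.cost_functions:
            if cf.structure == "PTV2" and cf.is_target:
                assert cf.weight == 200.0

    def _capped(self):
        tpl = default_template()
        funcs = []
        for cf in tpl.cost_functions:
            if cf.structure == "PTV2" and cf.is_target:
                cf = cf.with_(weight=500.0 if cf.kind == "underdose_dvh" else 1000.0)
            funcs.append(cf)
        tpl.cost_functions = funcs
        return tpl

    def test_phase_b_loosens_rectal_side(self):
        tpl = self._capped()
        out, info = subroutine_III(tpl, indices(v72=80.0))
        assert info["phase"] == "B"
        probe0 = tpl.probe_function()
        assert out.probe_function().isoconstraint == pytest.approx(probe0.isoconstraint * 1.05)
        assert out.probe_function().shrink_margin_mm == pytest.approx(2.0)
        for t in (7000.0, 2340.0):
            q0 = tpl.find(structure="zRectum", kind="quadratic_overdose", threshold_cgy=t)[0]
            q1 = out.find(structure="zRectum", kind="quadratic_overdose", threshold_cgy=t)[0]
            assert q1.isoconstraint == pytest.approx(q0.isoconstraint + 2.0)
            assert q1.shrink_margin_mm == pytest.approx(q0.shrink_margin_mm + 2.0)
        od = out.find(structure="PTV2", kind="overdose_dvh")[0]
        assert od.isoconstraint == pytest.approx(65.0)

    def test_oddvh_isoconstraint_clips_at_100_percent(self):
        tpl = self._capped()
        od = tpl.find(structure="PTV2", kind="overdose_dvh")[0]
        tpl = tpl.replace_function(od, od.with_(isoconstraint=98.0))
        out, _ = subroutine_III(tpl, indices(v72=80.0))
        assert out.find(structure="PTV2", kind="overdose_dvh")[0].isoconstraint == 100.0

    def test_rejected_when_condition_three_passes(self):
        with pytest.raises(AutoplanError):
            subroutine_III(default_template(), indices())


class TestSubroutineIV:
    def test_doubles_urethra_maximum_dose_weight(self):
        out, _ = subroutine_IV(default_template(), indices(d1u=8200.0))
        assert out.find(structure="urethra", kind="maximum_dose")[0].weight == 60.0

    def test_clips_and_flags(self):
        tpl = default_template()
        cf = tpl.find(structure="urethra", kind="maximum_dose")[0]
        tpl = tpl.replace_function(cf, cf.with_(weight=800.0))
        out, info = subroutine_IV(tpl, indices(d1u=8200.0))
        assert out.find(structure="urethra", kind="maximum_dose")[0].weight == 1000.0
        assert info["exhausted"] is False
        out2, info2 = subroutine_IV(out, indices(d1u=8200.0))
        assert info2["exhausted"] is True

    def test_rejected_when_condition_four_passes(self):
        with pytest.raises(AutoplanError):
            subroutine_IV(default_template(), indices())


class TestCapEscalation:
    def test_repeated_escalation_stops_exactly_at_printed_caps(self):
        """An engineered never-satisfied case: weights must saturate at the
        500/1000 caps and never exceed them."""
        tpl = default_template()
        for _ in range(20):
            tpl, _ = subroutine_I(tpl, indices(v78=80.0))
            tpl, _ = subroutine_III(tpl, indices(v72=80.0))
            tpl, _ = subroutine_II(tpl, indices(d2b=8300.0))
            tpl, _ = subroutine_IV(tpl, indices(d1u=8300.0))
        weights = {cf.id: cf.weight for cf in tpl.cost_functions if cf.weight is not None}
        for cf in tpl.cost_functions:
            if cf.weight is None:
                continue
            if cf.kind == "underdose_dvh":
                assert cf.weight <= 500.0
            else:
                assert cf.weight <= 1000.0
        assert weights["PTV1/underdose_dvh@7800"] == 500.0
        assert weights["PTV1/target_penalty"] == 1000.0
        assert weights["PTV2/underdose_dvh@7200"] == 500.0
        assert weights["patient/maximum_dose"] == 1000.0
        assert weights["urethra/maximum_dose"] == 1000.0

    def test_loosening_never_tightens(self):
        tpl = default_template()
        trace = []
        for _ in range(15):
            tpl, _ = subroutine_III(tpl, indices(v72=80.0))
            trace.append(tpl.probe_function().isoconstraint)
        assert all(b >= a for a, b in zip(trace, trace[1:]))


class TestOvercoverage:
    def test_scales_target_weights_down_with_floor(self):
        from arcplan.autoplan import ConditionFailure

        tpl = default_template()
        out, _ = overcoverage_step(tpl, ConditionFailure("c1", "high", 98.0, 97.0))
        for cf in out.cost_functions:
            if cf.structure in ("PTV1", "CTV") and cf.is_target:
                assert cf.weight == pytest.approx(80.0)  # one 0.8 down-step
        # an explicit step factor maps to its reciprocal down-step, floored
        out2, _ = overcoverage_step(
            tpl, ConditionFailure("c3", "high", 99.0, 97.0), step_factor=2.0
        )
        for cf in out2.cost_functions:
            if cf.structure == "PTV2" and cf.is_target:
                assert cf.weight == pytest.approx(50.0)
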