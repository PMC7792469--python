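import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vffr.graph import StenosisSpec, VesselGraph, VesselNode, VesselSegment, apply_stenosis
from vffr.hemo import (
    NumericalConfig,
    TerminalOutlet,
    Waveform,
    poiseuille_conductance,
    solve_steady,
    solve_unsteady,
    total_inflow,
)
from vffr.personalize import (
    CalibrationConfig,
    PatientRecord,
    PersonalizeError,
    classify_patient,
    classify_vessel,
    compute_ffr,
    compute_ffr_steady,
    evaluate_ffr,
    induce_hyperemia,
    personalize,
    records_from_csv,
)


class TestPersonalize:
    def test_waveform_from_cohort_means(self, y_tree, table1_record):
        model = personalize(y_tree, table1_record)
        assert model.waveform.sbp == pytest.approx(133.39)
        assert model.waveform.dbp == pytest.approx(84.03)
        assert model.waveform.period == pytest.approx(60 / 65.19)

    def test_equal_terminal_diameters_equal_resistances(self, table1_record):
        nodes = [
            VesselNode("n0", "ostium", (0, 0, 0)),
            VesselNode("n1", "junction", (30, 0, 0)),
            VesselNode("n2", "terminal", (55, 10, 0)),
            VesselNode("n3", "terminal", (55, -10, 0)),
        ]
        segs = [
            VesselSegment("s0", "n0", "n1", 30, 3.5, 3.5, 12.0),
            VesselSegment("s1", "n1", "n2", 25, 2.6, 2.6, 12.0),
            VesselSegment("s2", "n1", "n3", 25, 2.6, 2.6, 12.0),
        ]
        g = VesselGraph.from_lists(nodes, segs, ["n0"])
        model = personalize(g, table1_record)
        assert model.terminals["n2"].resistance == pytest.approx(
            model.terminals["n3"].resistance, rel=1e-9
        )

    def test_baseline_flow_hits_target_fraction(self, y_tree, table1_record):
        cal = CalibrationConfig()
        model = personalize(y_tree, table1_record, cal)
        q_target = cal.coronary_flow_fraction * cal.stroke_volume_ml * table1_record.hr / 60.0
        sol = solve_steady(model.graph, model.terminals, model.waveform.mean_pressure())
        assert total_inflow(sol, model.graph) == pytest.approx(q_target, rel=1e-6)

    def test_calibration_uses_reference_network(self, y_tree, table1_record):
        # a severe stenosis must not starve the resistance calibration
        g = apply_stenosis(y_tree, StenosisSpec("s1", 0.9, 1.0))
        model = personalize(g, table1_record)
        assert all(t.resistance > 0 for t in model.terminals.values())

    def test_missing_hr_errors(self, y_tree):
        rec = PatientRecord(id="x", age=60, sbp=130, dbp=80, hr=None)
        with pytest.raises(PersonalizeError, match="hr"):
            personalize(y_tree, rec)

    def test_age_bracket_lookup(self):
        cal = CalibrationConfig()
        c_young = cal.c0_for_age(40)
        c_mid = cal.c0_for_age(55)
        c_old = cal.c0_for_age(75)
        assert c_young < c_mid < c_old


class TestHyperemia:
    def test_factor_one_is_identity(self, y_tree, table1_record):
        model = personalize(y_tree, table1_record)
        hyper = induce_hyperemia(model, 1.0)
        for nid in model.terminals:
            assert hyper.terminals[nid].resistance == pytest.approx(
                model.terminals[nid].resistance
            )

    def test_factor_divides_resistance(self):
        from vffr.personalize import PersonalizedModel

        model = PersonalizedModel(
            graph=None,
            waveform=Waveform.constant(93.0),
            terminals={"t": TerminalOutlet(70.0, 8.0)},
        )
        hyper = induce_hyperemia(model, 3.5)
        assert hyper.terminals["t"].resistance == pytest.approx(20.0)

    def test_factor_below_one_errors(self, y_tree, table1_record):
        model = personalize(y_tree, table1_record)
        with pytest.raises(PersonalizeError):
            induce_hyperemia(model, 0.9)

    def test_hyperemia_lowers_distal_pressure_ratio(self, y_tree, table1_record):
        g = apply_stenosis(y_tree, StenosisSpec("s1", 0.6, 0.5))
        baseline = evaluate_ffr(g, table1_record, hyperemia_factor=1.0, mode="steady")
        hyper = evaluate_ffr(g, table1_record, hyperemia_factor=3.5, mode="steady")
        site = "s1__sten"
        assert hyper.site_ffr[site] <= baseline.site_ffr[site]


class TestComputeFfr:
    def test_frictionless_tube_is_unity(self, single_tube):
        g = single_tube.copy()
        g.segments["s0"] = dataclasses.replace(g.segments["s0"], ffr_site=True)
        term = {"n1": TerminalOutlet(30.0, 8.0)}
        sol = solve_unsteady(
            g,
            term,
            Waveform.constant(93.0, 0.2),
            NumericalConfig(n_cycles=60, tolerance_mmhg=1e-3),
            mu=1e-9,
        )
        assert compute_ffr(sol, g, "s0") == pytest.approx(1.0, abs=0.02)

    def test_series_resistance_oracle(self):
        """Steady circuit: proximal (negligible), stenosis R_s, terminal R_t = 4 R_s."""
        d_s, l_s = 1.5, 10.0
        r_s = 1.0 / poiseuille_conductance(d_s, l_s)
        nodes = [
            VesselNode("n0", "ostium", (0, 0, 0)),
            VesselNode("n1", "internal", (20, 0, 0)),
            VesselNode("n2", "terminal", (30, 0, 0)),
        ]
        segs = [
            VesselSegment("p", "n0", "n1", 20.0, 8.0, 8.0, 12.0),  # ~zero resistance
            VesselSegment("s", "n1", "n2", l_s, 3.0, d_s, 12.0, ffr_site=True),
        ]
        g = VesselGraph.from_lists(nodes, segs, ["n0"])
        sol = solve_steady(g, {"n2": TerminalOutlet(4.0 * r_s, p_out=0.0)}, 93.0)
        assert compute_ffr_steady(sol, g, "s") == pytest.approx(0.800, abs=0.005)

    def test_sequential_stenoses_distal_not_above_proximal(self, single_tube, table1_record):
        g = apply_stenosis(single_tube, StenosisSpec("s0", 0.5, 0.2))
        g = apply_stenosis(g, StenosisSpec("s0__dist", 0.5, 0.3))
        result = evaluate_ffr(g, table1_record, mode="steady")
        assert result.site_ffr["s0__dist__sten"] <= result.site_ffr["s0__sten"] + 1e-12

    def test_unmarked_site_errors(self, single_tube):
        sol = solve_steady(single_tube, {"n1": TerminalOutlet(30.0)}, 93.0)
        with pytest.raises(PersonalizeError, match="not a marked FFR site"):
            compute_ffr_steady(sol, single_tube, "s0")

    def test_unconverged_solution_rejected(self, single_tube):
        g = single_tube.copy()
        g.segments["s0"] = dataclasses.replace(g.segments["s0"], ffr_site=True)
        term = {"n1": TerminalOutlet(30.0, 8.0)}
        sol = solve_unsteady(
            g, term, Waveform.constant(93.0, 0.05), NumericalConfig(n_cycles=1, tolerance_mmhg=1e-12)
        )
        assert not sol.converged
        with pytest.raises(PersonalizeError, match="convergence"):
            compute_ffr(sol, g, "s0")


class TestMonotonicity:
    def test_steady_ffr_decreases_with_severity(self, y_tree, table1_record):
        previous = None
        for severity in np.arange(0.0, 0.91, 0.1):
            if severity == 0.0:
                g = y_tree.copy()
                g.segments["s1"] = dataclasses.replace(g.segments["s1"], ffr_site=True)
            else:
                g = apply_stenosis(y_tree, StenosisSpec("s1", float(severity), 1.0))
            ffr = min(evaluate_ffr(g, table1_record, mode="steady").site_ffr.values())
            if previous is not None:
                assert ffr < previous
            previous = ffr

    def test_ffr_bounds(self, y_tree, table1_record):
        for severity in (0.2, 0.5, 0.8):
            g = apply_stenosis(y_tree, StenosisSpec("s1", severity, 0.5))
            for v in evaluate_ffr(g, table1_record, mode="steady").site_ffr.values():
                assert 0.0 < v <= 1.02


class TestClassification:
    def test_paper_worked_values(self):
        assert classify_vessel(0.58) is True
        assert classify_vessel(0.80) is False
        assert classify_patient([0.41, 0.88, 0.81]) is True

    def test_all_negative_patient(self):
        assert classify_patient([0.85, 0.92]) is False

    def test_empty_patient_errors(self):
        with pytest.raises(PersonalizeError):
            classify_patient([])

    @given(st.floats(0.01, 1.2))
    @settings(max_examples=80, deadline=None)
    def test_threshold_consistency(self, x):
        assert classify_vessel(x) == (x < 0.80)

    def test_out_of_range_rejected(self):
        with pytest.raises(PersonalizeError):
            classify_vessel(1.3)
        with pytest.raises(PersonalizeError):
            classify_vessel(0.0)


class TestRecordsCsv:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            "id,age,sex,height_cm,weight_kg,sbp,dbp,hr\n"
            "P1,63.6,m,170.7,81.6,133.39,84.03,65.19\n"
            "P2,47.8,f,165.0,70.0,,,\n"
        )
        records = records_from_csv(path)
        assert records[0].sbp == pytest.approx(133.39)
        assert records[0].bmi == pytest.approx(81.6 / 1.707**2)
        assert records[1].hr is None
        with pytest.raises(PersonalizeError):
            records[1].require_hemodynamics()

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(PersonalizeError, match="missing columns"):
            records_from_csv(path)
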