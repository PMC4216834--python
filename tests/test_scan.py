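"""Coupling-plane scans and calibration selection."""

import numpy as np
import pytest

from tcloop import CalibrationTarget, calibrate, scan
from tcloop.networks import three_population_network, two_population_network
from tcloop.scan import PATIENT_TARGET, run_protocol


@pytest.fixture(scope="module")
def small_grid():
    net = two_population_network(k_c=1.2, k_t=5.0, n=1000)
    return scan(
        net, ("k_cortex_to_thal", 0), np.array([1.0, 2.0]),
        ("k_thal_to_cortex", 0), np.array([2.0, 5.0]),
        engine="reduced", t_end_ms=1100.0,
    )


class TestScan:
    def test_grid_is_complete_long_format(self, small_grid):
        t = small_grid.table
        assert len(t) == 4  # 2x2 cells, one cortical band
        assert set(t.columns) >= {
            "axis1", "axis2", "population", "max_sli", "sync_duration_ms",
            "peak_frequency_hz", "osc_frequency_hz", "engine",
        }
        assert t["max_sli"].between(0, 1).all()

    def test_deterministic(self):
        net = two_population_network(k_c=1.2, k_t=5.0, n=500)
        kwargs = dict(engine="reduced", t_end_ms=600.0)
        g1 = scan(net, ("k_cortex_to_thal", 0), np.array([1.0]),
                  ("k_thal_to_cortex", 0), np.array([4.0]), **kwargs)
        g2 = scan(net, ("k_cortex_to_thal", 0), np.array([1.0]),
                  ("k_thal_to_cortex", 0), np.array([4.0]), **kwargs)
        assert g1.table.equals(g2.table)

    def test_coarse_grid_agrees_with_fine_grid_at_shared_cells(self):
        net = two_population_network(k_c=1.2, k_t=5.0, n=1000)
        fine = scan(net, ("k_cortex_to_thal", 0), np.array([1.0, 1.5, 2.0]),
                    ("k_thal_to_cortex", 0), np.array([3.0, 4.0, 5.0]),
                    engine="reduced", t_end_ms=800.0)
        coarse = scan(net, ("k_cortex_to_thal", 0), np.array([1.0, 2.0]),
                      ("k_thal_to_cortex", 0), np.array([3.0, 5.0]),
                      engine="reduced", t_end_ms=800.0)
        for _, row in coarse.table.iterrows():
            match = fine.cell(row.axis1, row.axis2)
            assert np.isclose(match.max_sli.iloc[0], row.max_sli)

    def test_reduced_engine_consistent_with_full_engine(self):
        net = two_population_network(k_c=1.2, k_t=4.0, n=1000)
        red = scan(net, ("k_cortex_to_thal", 0), np.array([1.2]),
                   ("k_thal_to_cortex", 0), np.array([4.0]),
                   engine="reduced", t_end_ms=900.0)
        full = scan(net, ("k_cortex_to_thal", 0), np.array([1.2]),
                    ("k_thal_to_cortex", 0), np.array([4.0]),
                    engine="full", t_end_ms=900.0, seed=3)
        dr = red.table.max_sli.iloc[0]
        df = full.table.max_sli.iloc[0]
        assert abs(dr - df) < 0.07  # finite-N ensemble noise

    def test_feedback_weakens_synchrony_less_than_forward_coupling(self):
        # dropping the thalamus->cortex drive hits the locking strength
        # harder than dropping the cortical feedback by the same amount
        net = two_population_network(k_c=2.0, k_t=5.0, n=1000)
        g = scan(net, ("k_cortex_to_thal", 0), np.array([1.1, 2.0]),
                 ("k_thal_to_cortex", 0), np.array([4.5, 5.0]),
                 engine="reduced", t_end_ms=1100.0)
        base = g.cell(2.0, 5.0).max_sli.iloc[0]
        drop_kc = g.cell(1.1, 5.0).max_sli.iloc[0]
        drop_kt = g.cell(2.0, 4.5).max_sli.iloc[0]
        assert (base - drop_kt) > (base - drop_kc)


class TestCalibration:
    def test_own_achieved_values_select_the_cell(self, small_grid):
        row = small_grid.cell(2.0, 5.0).iloc[0]
        target = CalibrationTarget(
            sli_targets={"theta": float(row.max_sli)},
            freq_intervals_hz={"theta": (0.0, 20.0)},
            sli_tolerance=0.001,
        )
        pts = calibrate(small_grid, target)
        assert pts and pts[0].axis_values == (2.0, 5.0)

    def test_unreachable_target_reports_empty(self, small_grid):
        target = CalibrationTarget(
            sli_targets={"theta": 0.999}, freq_intervals_hz={}, sli_tolerance=0.001,
        )
        assert calibrate(small_grid, target) == []

    def test_patient_point_exists_with_correct_phenomenology(self):
        # the feedback plane contains patient-level cells whose transients
        # collapse in the alpha band before the theta band
        net = three_population_network(2.0, 1.0, 1.0, 0.6, n=1000)
        g = scan(net, ("k_cortex_to_thal", 0), np.arange(9.4, 10.01, 0.1),
                 ("k_cortex_to_thal", 1), np.arange(3.4, 4.01, 0.1),
                 engine="reduced", t_end_ms=1600.0)
        pts = calibrate(g, PATIENT_TARGET, top_k=1)
        assert pts, "no patient-calibrated cell found"
        cell = g.cell(*pts[0].axis_values)
        dur = dict(zip(cell.population, cell.sync_duration_ms))
        assert dur["alpha"] < dur["theta"]
        assert 150.0 < dur["alpha"] < 450.0
        assert 250.0 < dur["theta"] < 600.0
        assert 5.0 < pts[0].achieved_freq_hz["theta"] < 7.0
        assert 9.0 < pts[0].achieved_freq_hz["alpha"] < 12.0

    def test_full_protocol_summary_matches_reduced_prediction(self):
        net = three_population_network(9.85, 3.8, 1.0, 0.6, n=1000)
        _, summary = run_protocol(net, t_end_ms=1100.0, seed=2)
        assert abs(summary["theta"]["max_sli"] - 0.29) < 0.08
        assert abs(summary["alpha"]["max_sli"] - 0.19) < 0.08
        assert 5.0 < summary["theta"]["osc_frequency_hz"] < 7.0
        assert 9.0 < summary["alpha"]["osc_frequency_hz"] < 12.0
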