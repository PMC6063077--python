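"""Standardization, SSE objective, Nelder-Mead fitting, goodness of fit."""

import numpy as np
import pytest

from xylosim import (
    CalibrationSpec,
    IntegrationConfig,
    SugarCurve,
    Tracheidogram,
    calibrate,
    fit_statistics,
    simulate_ring,
    sse_objective,
    standardize_tracheidogram,
)
from xylosim.errors import InvalidParameterError, LengthMismatchError


def make_tr(n, wt=None, lrd=None, la=None):
    x = np.linspace(0.0, 1.0, n)
    return Tracheidogram(
        rel_position=x,
        WT=np.full(n, 2.0) if wt is None else np.asarray(wt, float),
        LRD=np.full(n, 20.0) if lrd is None else np.asarray(lrd, float),
        LA=np.full(n, 500.0) if la is None else np.asarray(la, float),
    )


class TestStandardize:
    def test_identity_when_lengths_match(self):
        tr = make_tr(5, wt=[2, 2.5, 3, 3.5, 4])
        out = standardize_tracheidogram(tr, 5)
        np.testing.assert_allclose(out.WT, tr.WT)
        np.testing.assert_allclose(out.rel_position, tr.rel_position)

    def test_constant_series_stays_constant(self):
        out = standardize_tracheidogram(make_tr(7), 13)
        assert np.ptp(out.WT) == 0.0
        assert np.ptp(out.LA) == 0.0

    def test_linear_downsample(self):
        tr = make_tr(5, wt=[2.0, 2.5, 3.0, 3.5, 4.0])
        out = standardize_tracheidogram(tr, 3)
        np.testing.assert_allclose(out.WT, [2.0, 3.0, 4.0])

    def test_endpoints_preserved(self):
        tr = make_tr(9, la=np.linspace(900, 100, 9) ** 1.1)
        out = standardize_tracheidogram(tr, 4)
        assert out.LA[0] == pytest.approx(tr.LA[0])
        assert out.LA[-1] == pytest.approx(tr.LA[-1])

    def test_length_errors(self):
        with pytest.raises(LengthMismatchError):
            standardize_tracheidogram(make_tr(5), 1)


class TestSSEObjective:
    def test_zero_at_truth(self, larix, fast_cfg):
        p, curve = larix
        spec = CalibrationSpec(free=("a", "b", "c"), n_cells=20, integration=fast_cfg)
        obs = simulate_ring(p, curve, n_cells=20, cfg=fast_cfg).tracheidogram
        assert sse_objective([curve.a, curve.b, curve.c], spec, obs, p, curve) == pytest.approx(0.0, abs=1e-18)

    def test_hand_summed_offsets(self, larix, fast_cfg):
        """Two-cell ring with per-cell offsets dWT=0.5, dLRD=2, dLA=10."""
        p, curve = larix
        spec = CalibrationSpec(free=("a",), n_cells=2, integration=fast_cfg)
        sim = simulate_ring(p, curve, n_cells=2, cfg=fast_cfg).tracheidogram
        obs = Tracheidogram(
            rel_position=sim.rel_position,
            WT=sim.WT + 0.5,
            LRD=sim.LRD + 2.0,
            LA=sim.LA + 10.0,
        )
        expected = 2 * (0.25 + 4.0 + 100.0)
        assert sse_objective([curve.a], spec, obs, p, curve) == pytest.approx(expected, rel=1e-9)

    def test_length_mismatch_is_an_error(self, larix, fast_cfg):
        p, curve = larix
        spec = CalibrationSpec(free=("a",), n_cells=20, integration=fast_cfg)
        with pytest.raises(LengthMismatchError):
            sse_objective([curve.a], spec, make_tr(10), p, curve)

    def test_invalid_parameters_get_penalty(self, larix, fast_cfg):
        p, curve = larix
        spec = CalibrationSpec(free=("c",), n_cells=5, integration=fast_cfg)
        obs = simulate_ring(p, curve, n_cells=5, cfg=fast_cfg).tracheidogram
        assert sse_objective([-2.0], spec, obs, p, curve) >= 1e29  # negative sugar curve

    def test_identifiability_of_curve_coefficients(self, larix, fast_cfg):
        """SSE strictly increases when any coefficient moves 20% off truth."""
        p, curve = larix
        spec = CalibrationSpec(free=("a", "b", "c"), n_cells=25, integration=fast_cfg)
        obs = simulate_ring(p, curve, n_cells=25, cfg=fast_cfg).tracheidogram
        truth = np.array([curve.a, curve.b, curve.c])
        s0 = sse_objective(truth, spec, obs, p, curve)
        for i in range(3):
            for f in (0.8, 1.2):
                v = truth.copy()
                v[i] *= f
                assert sse_objective(v, spec, obs, p, curve) > s0 + 1.0


class TestCalibrate:
    def test_noiseless_recovery_abc(self, larix):
        p, curve = larix
        cfg = IntegrationConfig(dt=0.1)
        spec = CalibrationSpec(
            free=("a", "b", "c"),
            n_cells=30,
            integration=cfg,
            restarts=0,
            initial={"a": curve.a * 1.25, "b": curve.b * 0.8, "c": curve.c * 1.2},
        )
        obs = simulate_ring(p, curve, n_cells=30, cfg=cfg).tracheidogram
        res = calibrate(obs, spec, p, curve)
        for name, truth in (("a", curve.a), ("b", curve.b), ("c", curve.c)):
            assert abs(res.params[name] - truth) / abs(truth) < 0.01, res.params
        assert res.sse < 1e-6
        assert res.sse <= res.start_sse

    def test_descent_from_truth(self, larix):
        p, curve = larix
        cfg = IntegrationConfig(dt=0.15)
        spec = CalibrationSpec(free=("c",), n_cells=10, integration=cfg, restarts=0)
        obs = simulate_ring(p, curve, n_cells=10, cfg=cfg).tracheidogram
        res = calibrate(obs, spec, p, curve)
        assert res.sse <= res.start_sse
        assert res.sse == pytest.approx(0.0, abs=1e-9)

    def test_one_dimensional_vc_recovery(self, larix):
        p, curve = larix
        cfg = IntegrationConfig(dt=0.1)
        spec = CalibrationSpec(
            free=("vc",), n_cells=25, integration=cfg, restarts=0, initial={"vc": 0.39 * 1.3}
        )
        obs = simulate_ring(p, curve, n_cells=25, cfg=cfg).tracheidogram
        res = calibrate(obs, spec, p, curve)
        assert abs(res.params["vc"] - 0.39) / 0.39 < 0.01

    def test_sse_equals_component_sum(self, larix):
        p, curve = larix
        cfg = IntegrationConfig(dt=0.15)
        spec = CalibrationSpec(free=("c",), n_cells=10, integration=cfg, restarts=0,
                               initial={"c": curve.c * 1.1})
        obs = simulate_ring(p, curve, n_cells=10, cfg=cfg).tracheidogram
        res = calibrate(obs, spec, p, curve)
        assert res.sse == pytest.approx(sum(res.components.values()), rel=1e-6, abs=1e-12)

    def test_empty_free_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            CalibrationSpec(free=())

    def test_unknown_free_name_rejected(self):
        with pytest.raises(InvalidParameterError):
            CalibrationSpec(free=("vc", "bogus"))


class TestFitStatistics:
    def test_perfect_fit(self):
        tr = make_tr(5, wt=[2, 2.5, 3, 3.5, 4])
        stats = fit_statistics(tr, tr)
        assert all(v["r2"] == pytest.approx(1.0) for v in stats.values())
        assert all(v["sse"] == 0.0 for v in stats.values())

    def test_constant_prediction_scores_zero(self):
        obs = make_tr(5, wt=[2.0, 2.5, 3.0, 3.5, 4.0])
        sim = make_tr(5, wt=np.full(5, 3.0))  # the observed mean
        assert fit_statistics(obs, sim)["WT"]["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_r2(self):
        obs = make_tr(3, wt=[1.0, 2.0, 3.0])
        sim = make_tr(3, wt=[1.0, 2.0, 4.0])  # one unit error on the last cell
        # SS_res = 1, SS_tot = 2  ->  R^2 = 0.5
        out = fit_statistics(obs, sim)["WT"]
        assert out["sse"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            fit_statistics(make_tr(4), make_tr(5))
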