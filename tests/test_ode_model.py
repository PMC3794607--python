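import numpy as np
import pytest

import trmbdyn as td
from trmbdyn.core_data import DataError, KNOCKOUT, PARENT
from trmbdyn.ode_model import CalibrationError, OdeParams, _euler


def _steady_trace(m_pre, m_post, strain=PARENT):
    """A trace sitting at m_pre for the first 3 points, m_post for the rest."""
    grid = td.DESIGN_GRID
    vals = np.where(grid < 0, m_pre, m_post).astype(float)
    vals[2] = m_pre  # t=0 still pre-perturbation
    return td.TimeCourse("g", strain, grid, vals[None, :])


class TestCalibrate:
    def test_exact_recovery_of_planted_parameters(self, binding):
        k_deg, n = 0.08, 1
        k_basal, k_eff = 2.5, 3.0
        b_pre = binding.enrichment[:3].mean()
        b_post = binding.enrichment[-3:].mean()
        expr = _steady_trace((k_basal + k_eff * b_pre ** n) / k_deg,
                             (k_basal + k_eff * b_post ** n) / k_deg)
        p = td.calibrate(expr, binding, n, k_deg)
        assert p.k_basal == pytest.approx(k_basal, rel=1e-10)
        assert p.k_eff == pytest.approx(k_eff, rel=1e-10)

    def test_flat_binding_is_singular(self):
        flat = td.BindingCurve(td.DESIGN_GRID,
                               np.full(td.DESIGN_GRID.size, 2.0))
        with pytest.raises(CalibrationError, match="indistinct"):
            td.calibrate(_steady_trace(10.0, 5.0), flat, 1, 0.1)

    def test_unchanged_expression_means_no_regulation(self, binding):
        expr = _steady_trace(10.0, 10.0)
        p = td.calibrate(expr, binding, 1, 0.1)
        assert p.k_eff == pytest.approx(0.0, abs=1e-12)
        assert p.k_basal == pytest.approx(1.0, rel=1e-10)

    def test_negative_basal_rate_is_flagged_not_fatal(self, binding):
        # a strong activated gene whose expression collapses post-pulse
        expr = _steady_trace(100.0, 1.0)
        p = td.calibrate(expr, binding, 1, 0.1)
        assert p.k_basal < 0
        assert p.warnings

    def test_recovery_on_noisy_panel(self):
        # 50 direct genes, 5% measurement noise: each parameter lands
        # within 10% of truth for at least 90% of genes
        cfg = td.PanelConfig(n_activated_direct=25, n_repressed_direct=25,
                             n_ffl_target=0, n_independent_impulse=0,
                             n_no_change=0, cv=0.05, seed=2)
        panel = td.simulate_panel(cfg)
        ok_basal = ok_eff = 0
        for _, row in panel.truth.iterrows():
            tc = panel.by_gene(row.gene, PARENT)
            p = td.calibrate(tc, panel.binding, int(row.n), row.k_deg)
            ok_basal += abs(p.k_basal - row.k_basal) / row.k_basal < 0.10
            ok_eff += abs(p.k_eff - row.k_eff) / row.k_eff < 0.10
        assert ok_basal >= 45
        assert ok_eff >= 45


class TestPredict:
    def test_steady_state_is_a_fixed_point(self, binding):
        k_deg = 0.08
        b_pre = binding.enrichment[:3].mean()
        params = OdeParams(2.0, 3.0, 1, k_deg)
        m_pre = (2.0 + 3.0 * b_pre) / k_deg
        flat = td.BindingCurve.constant(b_pre)
        out = td.predict(params, flat, m_pre, td.DESIGN_GRID)
        np.testing.assert_allclose(out.values[0], m_pre, rtol=1e-6)

    def test_constant_binding_matches_closed_form(self):
        # linear ODE with constant input: m(t) = m_ss + (m0-m_ss) e^(-kt)
        k = 0.05
        params = OdeParams(3.0, 2.0, 1, k)
        b_level = 2.0
        m_ss = (3.0 + 2.0 * b_level) / k
        m0 = 1.5 * m_ss
        grid = np.arange(0.0, 361.0, 5.0)
        out = td.predict(params, td.BindingCurve.constant(b_level), m0, grid)
        closed = m_ss + (m0 - m_ss) * np.exp(-k * grid)
        np.testing.assert_allclose(out.values[0], closed, rtol=5e-3)

    def test_step_binding_matches_fine_step_oracle(self):
        params = OdeParams(3.0, 2.0, 1, 0.05)
        step = td.BindingCurve(np.array([-240., -1e-6, 0., 360.]),
                               np.array([6., 6., 1.3, 1.3]))
        m0 = (3.0 + 2.0 * 6.0) / 0.05
        t1, m1 = _euler(params, step.at, m0, -240.0, 360.0, dt=1.0)
        tf, mf = _euler(params, step.at, m0, -240.0, 360.0, dt=0.01)
        v1 = np.interp(td.DESIGN_GRID, t1, m1)
        vf = np.interp(td.DESIGN_GRID, tf, mf)
        assert np.max(np.abs(v1 - vf) / vf) < 0.01

    def test_first_order_convergence_to_fine_oracle(self, binding):
        # the 1-min explicit Euler scheme is first order: halving the
        # step roughly halves the error against a 0.01-min reference
        params = OdeParams(3.0, 2.0, 1, 0.12)
        m0 = (3.0 + 2.0 * 6.0) / 0.12
        tf, mf = _euler(params, binding.at, m0, -240.0, 360.0, dt=0.01)
        ref = np.interp(td.DESIGN_GRID, tf, mf)
        errs = []
        for dt in (1.0, 0.5):
            t, m = _euler(params, binding.at, m0, -240.0, 360.0, dt=dt)
            errs.append(np.max(np.abs(np.interp(td.DESIGN_GRID, t, m) - ref)))
        ratio = errs[1] / errs[0]
        assert 0.3 < ratio < 0.7
        assert errs[0] / ref.max() < 0.02

    def test_activation_sign_consistency(self):
        # monotone binding drop, n=+1: prediction never increases post-0
        curve = td.simulate_binding(td.BindingParams(omega=0.0))
        params = OdeParams(2.0, 3.0, 1, 0.08)
        m0 = (2.0 + 3.0 * 6.0) / 0.08
        grid = td.DESIGN_GRID[td.DESIGN_GRID >= 0]
        out = td.predict(params, curve, m0, grid)
        assert np.all(np.diff(out.values[0]) <= 1e-9)
        rep = OdeParams(2.0, 3.0, -1, 0.08)
        m0r = (2.0 + 3.0 / 6.0) / 0.08
        outr = td.predict(rep, curve, m0r, grid)
        assert np.all(np.diff(outr.values[0]) >= -1e-9)

    def test_nonpositive_initial_value_rejected(self, binding):
        with pytest.raises(DataError):
            td.predict(OdeParams(1.0, 1.0, 1, 0.1), binding, 0.0,
                       td.DESIGN_GRID)

    def test_calibration_then_prediction_reproduces_both_steady_states(
            self, binding):
        k_deg = 0.08
        expr = _steady_trace(80.0, 30.0)
        p = td.calibrate(expr, binding, 1, k_deg)
        out = td.predict(p, binding, 80.0, td.DESIGN_GRID)
        assert out.values[0, 0] == pytest.approx(80.0, rel=1e-6)
        assert out.values[0, -1] == pytest.approx(30.0, rel=1e-2)


class TestPredictKnockout:
    def test_monotone_relaxation_to_no_binding_steady_state(self):
        params = OdeParams(2.0, 3.0, 1, 0.08)
        m_ss = (2.0 + 3.0) / 0.08
        out = td.predict_knockout(params, 2 * m_ss, np.arange(0.0, 200.0, 5.0))
        diffs = np.diff(out.values[0])
        assert np.all(diffs <= 1e-9)
        assert out.values[0, -1] == pytest.approx(m_ss, rel=1e-4)
        assert out.strain == KNOCKOUT

    def test_repressed_knockout_steady_state_exceeds_parent_pre(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k_basal = rng.uniform(0.5, 5)
            k_eff = rng.uniform(0.5, 8)
            k_deg = rng.uniform(0.02, 0.2)
            b_pre = rng.uniform(2, 10)
            params = OdeParams(k_basal, k_eff, -1, k_deg)
            parent_pre = (k_basal + k_eff / b_pre) / k_deg
            assert td.knockout_steady_state(params) >= parent_pre

    def test_unregulated_gene_has_equal_steady_states(self):
        params = OdeParams(2.0, 0.0, 1, 0.08)
        b_any = 3.7
        parent_ss = (2.0 + 0.0 * b_any) / 0.08
        assert td.knockout_steady_state(params) == pytest.approx(parent_ss)


class TestResidualTrace:
    def test_direct_gene_residuals_are_small_away_from_perturbation(
            self, noiseless_panel, binding):
        # the weighted-secant derivative cannot resolve the jump at t=0
        # on the coarse design grid, so the contract holds from 20 min on
        grid = td.DESIGN_GRID
        late = grid >= 20
        for _, row in noiseless_panel.truth.iterrows():
            if row.gene_class not in ("activated_direct", "repressed_direct"):
                continue
            tc = noiseless_panel.by_gene(row.gene, PARENT)
            trace, params = td.residual_trace(tc, binding, int(row.n),
                                              row.k_deg)
            peak = np.max(np.abs(params.synthesis(binding.at(grid))))
            assert np.max(np.abs(trace.residual[late])) < 0.05 * peak

    def test_ffl_class_mean_residual_peaks_in_the_20_45_window(
            self, default_panel):
        binding = default_panel.binding
        grid = td.DESIGN_GRID
        traces = []
        for _, row in default_panel.truth.iterrows():
            if row.gene_class != "ffl_target":
                continue
            tc = default_panel.by_gene(row.gene, PARENT)
            p = td.best_sign_calibration(tc, binding, row.k_deg)
            trace, _ = td.residual_trace(tc, binding, p.n, row.k_deg)
            traces.append(trace.residual)
        mean = np.mean(traces, axis=0)
        assert 20 <= grid[int(np.argmax(mean))] <= 45

    def test_impulse_gene_residuals_similar_in_both_strains(
            self, default_panel):
        binding = default_panel.binding
        flat = td.BindingCurve.constant(1.0)
        grid = td.DESIGN_GRID
        for _, row in default_panel.truth.iterrows():
            if row.gene_class != "independent_impulse":
                continue
            par = default_panel.by_gene(row.gene, PARENT)
            ko = default_panel.by_gene(row.gene, KNOCKOUT)
            p = td.best_sign_calibration(par, binding, row.k_deg)
            tr_p, sp = td.residual_trace(par, binding, p.n, row.k_deg)
            tr_k, _ = td.residual_trace(ko, flat, p.n, row.k_deg,
                                        scaled_params=sp)
            r = np.corrcoef(tr_p.residual, tr_k.residual)[0, 1]
            assert r > 0.8
            # ... and the excursion starts immediately after t=0
            post_start = np.abs(tr_p.residual[(grid >= 5) & (grid <= 20)])
            pre = np.abs(tr_p.residual[grid < 0])
            assert post_start.max() > 3 * max(pre.max(), 1e-12)
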