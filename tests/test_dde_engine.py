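"""Integrator correctness: oracles, conservation, convergence, positivity."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lactodyn.dde_engine import dense_state, integrate_brown, integrate_mm2d
from lactodyn.model_core import (
    HistorySpec,
    RateParamsBrown,
    RateParamsMM,
    SystemState,
    Trajectory,
)


def ode12_oracle(p: RateParamsMM, init: SystemState, t_eval):
    """Independent stiff-capable ODE solve of the no-delay reduction."""

    def rhs(_t, y):
        nS, nE, nC, _ = y
        b = p.k1 * nS * nE
        r = p.k2 * nC
        u = p.k_m1 * nC
        return [u - b, u + r - b, b - r - u, r]

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])),
                    [init.nS, init.nE, init.nC, init.nP],
                    t_eval=t_eval, rtol=1e-10, atol=1e-13, method="RK45")
    assert sol.success
    return sol.y.T


class TestIntegrateMM2D:
    def test_zero_rates_constant_trajectory(self):
        p = RateParamsMM(k1=0.0, k_m1=0.0, k2=0.0, tau1=1.0, tau2=2.0)
        init = SystemState(nS=1.0, nE=0.5, nC=0.2, nP=0.1)
        traj = integrate_mm2d(p, init, t_end=5.0, step=0.1)
        assert np.allclose(traj.states, init.as_array(), atol=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_delay_matches_ode_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k1, km1, k2 = 10.0 ** rng.uniform(-1.5, -0.5, 3)
        p = RateParamsMM(k1=k1, k_m1=km1, k2=k2, tau1=0.0, tau2=0.0)
        init = SystemState(*rng.uniform(0.1, 2.0, 4))
        traj = integrate_mm2d(p, init, t_end=50.0, step=0.01)
        ref = ode12_oracle(p, init, traj.times)
        scale = np.maximum(np.abs(ref), 1e-3)
        assert np.max(np.abs(traj.states - ref) / scale) < 1e-6

    def test_enzyme_conservation_along_delayed_run(self, table2_rates, sweep_init):
        traj = integrate_mm2d(table2_rates, sweep_init, t_end=100.0, step=0.02)
        total0 = sweep_init.nE + sweep_init.nC
        drift = np.abs(traj.column("nE") + traj.column("nC") - total0)
        assert drift.max() < 1e-8 * total0

    def test_substrate_material_conservation(self, table2_rates, sweep_init):
        traj = integrate_mm2d(table2_rates, sweep_init, t_end=100.0, step=0.02)
        total0 = sweep_init.nS + sweep_init.nC + sweep_init.nP
        drift = np.abs(traj.column("nS") + traj.column("nC")
                       + traj.column("nP") - total0)
        assert drift.max() < 1e-8 * total0

    def test_step_halving_convergence(self, table2_rates, sweep_init):
        vals = [integrate_mm2d(table2_rates, sweep_init, t_end=30.0,
                               step=s).states[-1, 3]
                for s in (0.2, 0.1, 0.05)]
        e1 = abs(vals[1] - vals[0])
        e2 = abs(vals[2] - vals[1])
        assert e2 < max(0.5 * e1, 1e-12)  # at least first order observed

    @pytest.mark.parametrize("seed", range(20))
    def test_positivity_without_delays(self, seed):
        rng = np.random.default_rng(100 + seed)
        k1, km1, k2 = 10.0 ** rng.uniform(-2, 0, 3)
        p = RateParamsMM(k1=k1, k_m1=km1, k2=k2)
        init = SystemState(*rng.uniform(1e-3, 3.0, 4))
        traj = integrate_mm2d(p, init, t_end=30.0, step=0.02)
        assert traj.states.min() >= -1e-12

    def test_history_shorter_than_delay_rejected(self, table2_rates):
        init = SystemState(nS=1.0, nE=1.0)
        hist = HistorySpec(tau_max=1.0, values=init)
        with pytest.raises(ValueError):
            integrate_mm2d(table2_rates, init, hist=hist, t_end=5.0)

    def test_positivity_loss_recorded(self, table2_rates, sweep_init):
        traj = integrate_mm2d(table2_rates, sweep_init, t_end=60.0, step=0.02)
        t_neg = traj.metadata["first_negative_time"]
        assert t_neg is not None and 0 < t_neg < 60.0


class TestIntegrateBrown:
    def test_zero_kd_constant(self):
        p = RateParamsBrown(kd=0.0, a=1.0, m=0.0, tau_min=0.0)
        traj = integrate_brown(p, (1.0, 0.5, 0.1), t_end=5.0, step=0.1)
        assert np.allclose(traj.states, [1.0, 0.5, 0.1], atol=0)

    def test_substrate_decreases_product_grows(self, table1_rates):
        traj = integrate_brown(table1_rates, (1.0, 1.139071, 1e-9),
                               t_end=60.0, step=0.05)
        nS = traj.column("nS")
        nP = traj.column("nP")
        assert nS[-1] < nS[0]
        assert np.all(np.diff(nS) <= 1e-15)
        assert np.all(np.diff(nP) >= -1e-15)

    def test_point_mass_kernel_approaches_single_lag(self):
        # concentrated gamma kernel (sd 2.5e-3) vs a discrete-lag mimic of
        # the same mechanism built from the two-delay model
        pb = RateParamsBrown(kd=0.01, a=400.0, m=0.0, tau_min=1.0, c=0.95)
        tb = integrate_brown(pb, (1.0, 1.0, 0.0), t_end=50.0, step=0.01)
        pm = RateParamsMM(k1=0.01, k_m1=1e-12, k2=20.0, tau1=1.0, tau2=0.0)
        tm = integrate_mm2d(pm, SystemState(1.0, 1.0, 0.0, 0.0),
                            t_end=50.0, step=0.01)
        nP_b = tb.states[-1, tb.column_index("nP")]
        nP_m = tm.states[-1, tm.column_index("nP")]
        assert abs(nP_b - nP_m) / nP_b < 0.01

    def test_short_history_rejected(self, table1_rates):
        hist = HistorySpec(tau_max=2.0, values=SystemState(1.0, 1.0))
        with pytest.raises(ValueError):
            integrate_brown(table1_rates, (1.0, 1.0, 0.0), hist=hist, t_end=5.0)


class TestDenseState:
    def _linear_traj(self):
        t = np.linspace(0.0, 4.0, 5)
        states = np.column_stack([2 * t + 1, -t + 3, 0 * t, 0.5 * t])
        derivs = np.column_stack([np.full(5, 2.0), np.full(5, -1.0),
                                  np.zeros(5), np.full(5, 0.5)])
        return Trajectory(times=t, states=states, derivs=derivs,
                          columns=("nS", "nE", "nC", "nP"), tau_max=0.0,
                          history=states[0])

    def test_exact_at_grid_nodes(self):
        traj = self._linear_traj()
        s = dense_state(traj, 2.0)
        assert (s.nS, s.nE, s.nP) == (5.0, 1.0, 1.0)

    def test_linear_reconstruction_at_midpoints(self):
        traj = self._linear_traj()
        s = dense_state(traj, 1.5)
        assert s.nS == pytest.approx(4.0, abs=1e-14)
        assert s.nE == pytest.approx(1.5, abs=1e-14)

    def test_quadratic_reconstruction(self):
        # cubic Hermite with exact derivatives reproduces a quadratic
        t = np.linspace(0.0, 2.0, 5)
        traj = Trajectory(times=t,
                          states=np.column_stack([t ** 2] * 4),
                          derivs=np.column_stack([2 * t] * 4),
                          columns=("nS", "nE", "nC", "nP"), tau_max=0.0,
                          history=np.zeros(4))
        assert dense_state(traj, 0.75).nS == pytest.approx(0.5625, abs=1e-13)

    def test_out_of_span_rejected(self):
        traj = self._linear_traj()
        with pytest.raises(ValueError):
            dense_state(traj, 5.0)
        with pytest.raises(ValueError):
            dense_state(traj, -1.0)

    def test_negative_times_read_history(self):
        traj = self._linear_traj()
        traj.tau_max = 2.0
        s = dense_state(traj, -1.0)
        assert s.nS == traj.history[0]


def test_trajectory_csv_export(tmp_path, table2_rates, sweep_init):
    import pandas as pd

    traj = integrate_mm2d(table2_rates, sweep_init, t_end=2.0, step=0.5)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["time", "nS", "nE", "nC", "nP"]
    assert np.allclose(df["nS"].to_numpy(), traj.column("nS"))
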