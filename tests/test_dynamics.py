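"""Integration, steady states, survival classification, extinction times."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from plasmidyn import (
    ChemostatParams,
    EquilibriumReport,
    InteractionSet,
    NEUTRAL_INTERACTIONS,
    Parameterization,
    PlasmidTraits,
    SystemState,
    UndeterminedOutcome,
    classify_survival,
    extinction_times,
    integrate,
    plasmid_free_equilibrium,
    solve_steady_state,
    time_of_extinction,
)
from plasmidyn.dynamics import DEFAULT_OPTIONS


def two_plasmid_param(wx=0.9, gx=1e-12, wy=0.9, gy=1e-12, delta=1e-6,
                      inter=NEUTRAL_INTERACTIONS):
    return Parameterization(
        PlasmidTraits(wx, gx, delta), PlasmidTraits(wy, gy, delta), inter
    )


def standard_start(x0=5e5, y0=5e5):
    return SystemState(X=x0, Y=y0, resource=100.0)


class TestIntegrate:
    def test_plasmid_free_start_reaches_closed_form_equilibrium(self):
        param = two_plasmid_param()
        traj = integrate(SystemState(free=1e6, resource=100.0), param, 1e4)
        r_hat, free_hat = plasmid_free_equilibrium(param.chemostat)
        end = traj.final_state
        assert end.free == pytest.approx(free_hat, rel=1e-3)
        assert end.resource == pytest.approx(r_hat, rel=1e-3)

    def test_dense_output_matches_grid_points(self):
        param = two_plasmid_param()
        traj = integrate(standard_start(), param, 100.0)
        mid = traj.time_grid[len(traj.time_grid) // 2]
        assert np.allclose(traj(mid), traj.states[:, len(traj.time_grid) // 2])
        with pytest.raises(ValueError):
            traj(1e5)

    def test_step_halving_self_consistency(self):
        param = two_plasmid_param(wx=0.95, gx=1e-11)
        coarse = integrate(standard_start(), param, 500.0, max_step=10.0)
        fine = integrate(standard_start(), param, 500.0, max_step=5.0)
        a, b = coarse.final_state.as_array(), fine.final_state.as_array()
        scale = np.abs(b) + 1.0
        assert np.all(np.abs(a - b) / scale < 10 * DEFAULT_OPTIONS.rtol * 1e3)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            integrate(standard_start(), two_plasmid_param(), -1.0)


class TestSteadyState:
    def test_plasmid_free_equilibrium_recovered(self):
        param = two_plasmid_param()
        report = solve_steady_state(SystemState(free=1e6, resource=100.0), param)
        assert report.converged and report.stability_flag
        r_hat, free_hat = plasmid_free_equilibrium(param.chemostat)
        assert report.state.free == pytest.approx(free_hat, rel=1e-6)
        assert report.state.resource == pytest.approx(r_hat, rel=1e-6)

    def test_costly_plasmids_vanish_at_steady_state(self):
        # any fitness cost drives both plasmids below one cell per mL
        param = two_plasmid_param(wx=0.95, gx=1e-11, wy=0.9, gy=1e-12)
        report = solve_steady_state(standard_start(), param)
        assert report.converged
        sx, sy = classify_survival(report)
        assert not sx and not sy
        assert report.state.X < 1 and report.state.XY < 1

    def test_positive_epistasis_equilibrium_dominated_by_double_carriers(self):
        param = two_plasmid_param(
            wx=0.975, gx=1e-11, wy=0.975, gy=1e-11, delta=1e-8,
            inter=InteractionSet(epistasis=0.1),
        )
        report = solve_steady_state(standard_start(), param)
        sx, sy = classify_survival(report)
        assert sx and sy
        s = report.state
        assert s.XY / s.total_cells > s.X / s.total_cells
        assert s.XY / s.total_cells > s.Y / s.total_cells

    def test_non_equilibrium_report_refused(self):
        report = EquilibriumReport(
            state=SystemState(X=10.0), converged=False,
            residual_norm=1.0, stability_flag=False,
        )
        with pytest.raises(ValueError):
            classify_survival(report)

    def test_threshold_classification(self):
        report = EquilibriumReport(
            state=SystemState(free=5e7, X=0.3, Y=5e7, XY=0.2, resource=0.1),
            converged=True, residual_norm=0.0, stability_flag=True,
        )
        assert classify_survival(report) == (False, True)
        # exactly one cell per mL counts as survival
        report.state.X = 1.0
        assert classify_survival(report) == (True, True)


class TestTimeOfExtinction:
    def test_zero_when_already_below_threshold(self):
        param = two_plasmid_param()
        assert time_of_extinction(
            SystemState(X=0.0, Y=5e5, resource=100.0), param, "X"
        ) == 0

    def test_matches_fine_grid_oracle(self):
        """The integer-hour scan must agree with direct evaluation of a
        densely sampled trajectory at 0.01 h resolution."""
        cases = [
            dict(wx=0.85, gx=1e-13, wy=0.9, gy=1e-12, delta=1e-4),
            dict(wx=0.9, gx=1e-12, wy=0.9, gy=1e-12, delta=1e-6),
            dict(wx=0.95, gx=1e-11, wy=0.85, gy=1e-13, delta=1e-8),
        ]
        for case in cases:
            param = two_plasmid_param(**case)
            toe = time_of_extinction(standard_start(), param, "X")
            assert toe is not None
            traj = integrate(standard_start(), param, toe + 5.0)
            # fine grid around the crossing: no sub-integer dip precedes it
            ts = np.arange(toe - 50.0, toe + 2.0, 0.01)
            fine = traj(ts)
            fine_below = (fine[1] < 1.0) & (fine[3] < 1.0)
            assert fine_below.any() and not fine_below[0]
            # first integer hour below threshold on the dense trajectory
            ints = np.arange(float(toe - 50), float(toe + 2))
            vals = traj(ints)
            below = (vals[1] < 1.0) & (vals[3] < 1.0)
            oracle = int(ints[np.argmax(below)])
            assert toe == oracle, case

    def test_identical_plasmids_go_extinct_simultaneously(self):
        param = two_plasmid_param(wx=0.9, gx=1e-12, wy=0.9, gy=1e-12)
        toes = extinction_times(standard_start(), param)
        assert toes["X"] == toes["Y"]

    def test_budget_exhaustion_is_explicit(self):
        opts = replace(DEFAULT_OPTIONS, max_time=10.0)
        param = two_plasmid_param()
        with pytest.raises(UndeterminedOutcome):
            extinction_times(standard_start(), param, opts)


class TestModelReductions:
    def _naive_two_plasmid_rhs(self, tx, ty, chem):
        """Independent minimal implementation of the non-interacting
        two-plasmid system: no interaction code path at all."""
        psi, om, q, pi, r0 = (
            chem.growth_rate, chem.washout_rate, chem.monod_constant,
            chem.resource_per_division, chem.inflow_resource,
        )
        wx, gx, d = tx.fitness, tx.conjugation_rate, tx.loss_rate
        wy, gy = ty.fitness, ty.conjugation_rate
        wxy = wx * wy
        gxy = min(gx, gy)

        def f(t, y):
            o, x, yv, xy, r = y
            m = psi * r / (r + q)
            return [
                o * m - om * o + d * (x + yv)
                - gx * o * x - gy * o * yv - (gx + gy - gxy) * o * xy,
                x * wx * m - om * x - d * x + d * xy + gx * o * x
                + (gx - gxy) * o * xy - gy * x * yv - gy * x * xy,
                yv * wy * m - om * yv - d * yv + d * xy + gy * o * yv
                + (gy - gxy) * o * xy - gx * x * yv - gx * yv * xy,
                xy * wxy * m - om * xy - 2 * d * xy + gxy * o * xy
                + (gx + gy) * x * yv + gy * x * xy + gx * yv * xy,
                om * (r0 - r) - pi * m * (o + wx * x + wy * yv + wxy * xy),
            ]

        return f

    def test_neutral_interactions_reduce_to_plain_competition(self):
        tx = PlasmidTraits(0.95, 1e-11, 1e-6)
        ty = PlasmidTraits(0.9, 1e-12, 1e-6)
        chem = ChemostatParams()
        param = Parameterization(tx, ty, NEUTRAL_INTERACTIONS, chem)
        y0 = standard_start().as_array()
        ours = integrate(standard_start(), param, 3000.0).final_state.as_array()
        naive = solve_ivp(
            self._naive_two_plasmid_rhs(tx, ty, chem), (0, 3000.0), y0,
            method="LSODA", rtol=1e-10, atol=1e-8,
        ).y[:, -1]
        assert np.allclose(ours, naive, rtol=1e-5, atol=1e-3)

    def test_symmetric_pairing_stays_symmetric(self):
        param = two_plasmid_param(
            wx=0.9, gx=1e-11, wy=0.9, gy=1e-11, delta=1e-6,
            inter=InteractionSet(epistasis=0.05, intracellular_X=10.0,
                                 intracellular_Y=10.0, intercellular_X=1e-2,
                                 intercellular_Y=1e-2),
        )
        traj = integrate(standard_start(), param, 2000.0)
        ts = np.linspace(0, 2000.0, 40)
        vals = traj(ts)
        assert np.allclose(vals[1], vals[2], rtol=1e-7, atol=1e-6)
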