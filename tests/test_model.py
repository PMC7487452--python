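"""Core model algebra: derived rates, ODE right-hand side, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasmidyn import (
    ChemostatParams,
    InteractionSet,
    NEUTRAL_INTERACTIONS,
    Parameterization,
    PlasmidTraits,
    SystemState,
    derive_rates,
    plasmid_free_equilibrium,
    rhs,
)


def make_traits(omega=0.9, gamma=1e-12, delta=1e-6):
    return PlasmidTraits(omega, gamma, delta)


class TestDerivedRates:
    def test_positive_epistasis_can_make_double_carriers_beneficial(self):
        rates = derive_rates(
            make_traits(omega=0.975),
            make_traits(omega=0.975),
            InteractionSet(epistasis=0.1),
        )
        assert rates.fitness_XY == pytest.approx(1.050625, abs=1e-12)
        # a 0.050625 fitness benefit over plasmid-free cells
        assert rates.fitness_XY - 1.0 == pytest.approx(0.050625, abs=1e-12)

    def test_intracellular_effect_scales_transfer_from_double_carriers(self):
        rates = derive_rates(
            make_traits(gamma=1e-11),
            make_traits(gamma=1e-12),
            InteractionSet(intracellular_X=10.0),
        )
        assert rates.conj_X_from_XY == pytest.approx(1e-10)
        # co-transfer proceeds at the rate of the less efficient plasmid
        assert rates.cotransfer == pytest.approx(
            min(rates.conj_X_from_XY, rates.conj_Y_from_XY)
        )
        assert rates.cotransfer == pytest.approx(1e-12)

    def test_exclusion_override_applies_only_above_one(self):
        # inhibitory effect: transfer into single carriers keeps the
        # reduced intracellular rate
        low = derive_rates(
            make_traits(gamma=1e-11), make_traits(gamma=1e-11),
            InteractionSet(intracellular_X=1e-3),
        )
        assert low.conj_X_from_XY_to_Y == pytest.approx(1e-14)
        # facilitation is neutralized by surface exclusion in the recipient
        high = derive_rates(
            make_traits(gamma=1e-11), make_traits(gamma=1e-11),
            InteractionSet(intracellular_X=10.0),
        )
        assert high.conj_X_from_XY_to_Y == pytest.approx(1e-11)
        # the tie alpha = 1 takes the intracellular branch, numerically bare
        tie = derive_rates(
            make_traits(gamma=1e-11), make_traits(gamma=1e-11),
            NEUTRAL_INTERACTIONS,
        )
        assert tie.conj_X_from_XY_to_Y == pytest.approx(1e-11)

    def test_neutral_interactions_reduce_to_bare_rates(self):
        tx, ty = make_traits(0.9, 1e-11, 1e-6), make_traits(0.95, 1e-13, 1e-6)
        rates = derive_rates(tx, ty, NEUTRAL_INTERACTIONS)
        assert rates.fitness_XY == pytest.approx(0.9 * 0.95)
        assert rates.conj_X_from_XY == tx.conjugation_rate
        assert rates.conj_Y_from_XY == ty.conjugation_rate
        assert rates.conj_X_to_Y == tx.conjugation_rate
        assert rates.conj_Y_to_X == ty.conjugation_rate
        assert rates.cotransfer == min(tx.conjugation_rate, ty.conjugation_rate)
        assert rates.loss_from_XY == tx.loss_rate

    def test_single_transfer_rates_from_double_carriers_nonnegative(self):
        # gamma_X(Y) - gamma_XY >= 0 for every grid combination
        from plasmidyn.experiments import ALPHA_VALUES, GAMMA_VALUES

        for g_x in GAMMA_VALUES:
            for g_y in GAMMA_VALUES:
                for a in ALPHA_VALUES:
                    for inter in (
                        InteractionSet(intracellular_X=a),
                        InteractionSet(intracellular_Y=a),
                    ):
                        r = derive_rates(
                            make_traits(gamma=g_x), make_traits(gamma=g_y), inter
                        )
                        assert r.conj_X_from_XY - r.cotransfer >= 0
                        assert r.conj_Y_from_XY - r.cotransfer >= 0

    def test_invalid_parameterizations_rejected(self):
        with pytest.raises(ValueError):
            InteractionSet(loss_interference=0.0)
        with pytest.raises(ValueError):
            InteractionSet(intracellular_X=-1.0)
        with pytest.raises(ValueError):
            derive_rates(
                make_traits(omega=0.85), make_traits(omega=0.85),
                InteractionSet(epistasis=-0.7225),
            )
        with pytest.raises(ValueError):
            derive_rates(
                PlasmidTraits(0.9, 1e-12, 1e-6),
                PlasmidTraits(0.9, 1e-12, 1e-4),
                NEUTRAL_INTERACTIONS,
            )

    def test_chemostat_requires_growth_beyond_washout(self):
        with pytest.raises(ValueError):
            ChemostatParams(growth_rate=0.04, washout_rate=0.05)
        with pytest.raises(ValueError):
            ChemostatParams(monod_constant=-1.0)


traits_strategy = st.builds(
    PlasmidTraits,
    fitness=st.floats(0.5, 1.2),
    conjugation_rate=st.floats(0, 1e-10),
    loss_rate=st.sampled_from([1e-8, 1e-6, 1e-4]),
)

state_strategy = st.builds(
    SystemState,
    free=st.floats(0, 1e8),
    X=st.floats(0, 1e8),
    Y=st.floats(0, 1e8),
    XY=st.floats(0, 1e8),
    resource=st.floats(0.01, 100.0),
)

interactions_strategy = st.builds(
    InteractionSet,
    epistasis=st.floats(-0.05, 0.1),
    intracellular_X=st.sampled_from([1e-3, 1.0, 10.0]),
    intracellular_Y=st.sampled_from([1e-3, 1.0, 10.0]),
    intercellular_X=st.sampled_from([1e-2, 1.0, 10.0]),
    intercellular_Y=st.sampled_from([1e-2, 1.0, 10.0]),
    loss_interference=st.sampled_from([1.0, 10.0]),
)


class TestRightHandSide:
    @settings(max_examples=200, deadline=None)
    @given(state=state_strategy, omega=st.floats(0.5, 1.2),
           inter=interactions_strategy, delta=st.sampled_from([1e-8, 1e-6, 1e-4]),
           gx=st.floats(0, 1e-10), gy=st.floats(0, 1e-10))
    def test_bookkeeping_identity(self, state, omega, inter, delta, gx, gy):
        """Conjugation and loss only move cells between compartments: the
        total cell derivative must equal growth minus washout exactly."""
        params = ChemostatParams()
        tx = PlasmidTraits(omega, gx, delta)
        ty = PlasmidTraits(min(1.2, omega + 0.05), gy, delta)
        rates = derive_rates(tx, ty, inter)
        d = rhs(state, params, tx, ty, rates)
        total = d.free + d.X + d.Y + d.XY
        monod = params.growth_rate * state.resource / (
            state.resource + params.monod_constant
        )
        expected = monod * (
            state.free
            + tx.fitness * state.X
            + ty.fitness * state.Y
            + rates.fitness_XY * state.XY
        ) - params.washout_rate * state.total_cells
        scale = (
            abs(expected)
            + max(gx, gy) * 10 * state.total_cells ** 2
            + 1e-6
        )
        assert abs(total - expected) <= 1e-12 * scale

    def test_empty_chemostat_only_replenishes_resource(self):
        params = ChemostatParams()
        tx = make_traits()
        rates = derive_rates(tx, tx, NEUTRAL_INTERACTIONS)
        d = rhs(SystemState(resource=50.0), params, tx, tx, rates)
        assert d.free == d.X == d.Y == d.XY == 0.0
        assert d.resource == pytest.approx(0.05 * (100 - 50))

    def test_symmetric_plasmids_give_symmetric_derivatives(self):
        params = ChemostatParams()
        tx = make_traits(0.9, 1e-12, 1e-6)
        inter = InteractionSet(epistasis=0.05, intracellular_X=10,
                               intracellular_Y=10, intercellular_X=1e-2,
                               intercellular_Y=1e-2)
        rates = derive_rates(tx, tx, inter)
        state = SystemState(free=1e4, X=3e7, Y=3e7, XY=1e5, resource=2.0)
        d = rhs(state, params, tx, tx, rates)
        assert d.X == pytest.approx(d.Y, rel=1e-14)

    def test_jacobian_matches_finite_differences(self):
        param = Parameterization(
            make_traits(0.9, 1e-11, 1e-6),
            make_traits(0.95, 1e-12, 1e-6),
            InteractionSet(epistasis=0.05, intracellular_X=10.0,
                           intercellular_Y=1e-2),
        )
        y = np.array([1e6, 3e7, 2e7, 1e5, 5.0])
        J = param.jac_array(0.0, y)
        num = np.empty_like(J)
        for j in range(5):
            h = max(1e-6, 1e-7 * abs(y[j]))
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            num[:, j] = (param.rhs_array(0, yp) - param.rhs_array(0, ym)) / (2 * h)
        scale = np.abs(J).max()
        assert np.allclose(J, num, atol=1e-5 * scale, rtol=1e-5)


class TestPlasmidFreeEquilibrium:
    def test_closed_form_is_a_fixed_point(self):
        params = ChemostatParams()
        r_hat, free_hat = plasmid_free_equilibrium(params)
        assert r_hat == pytest.approx(0.123187, rel=1e-4)
        assert free_hat == pytest.approx(9.98768e7, rel=1e-4)
        tx = make_traits()
        rates = derive_rates(tx, tx, NEUTRAL_INTERACTIONS)
        d = rhs(SystemState(free=free_hat, resource=r_hat), params, tx, tx, rates)
        assert abs(d.free) < 1e-6 * free_hat
        assert abs(d.resource) < 1e-9

    def test_vanishing_washout_limit(self):
        params = ChemostatParams(washout_rate=1e-9)
        r_hat, free_hat = plasmid_free_equilibrium(params)
        assert r_hat < 1e-6
        assert free_hat == pytest.approx(
            params.inflow_resource / params.resource_per_division, rel=1e-6
        )


class TestConfigRoundTrip:
    def test_round_trip_preserves_rates(self):
        param = Parameterization(
            make_traits(0.95, 1e-11, 1e-4),
            make_traits(0.85, 1e-13, 1e-4),
            InteractionSet(epistasis=-0.05, loss_interference=10.0),
        )
        back = Parameterization.from_config(param.to_config())
        assert back.to_config() == param.to_config()
        assert back.rates == param.rates

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            Parameterization.from_config(
                {"omega_X": 0.9, "gamma_X": 1e-12, "delta": 1e-6, "bogus": 1}
            )

    def test_required_keys_enforced(self):
        with pytest.raises(ValueError):
            Parameterization.from_config({"omega_X": 0.9})
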