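"""Core two-plasmid chemostat model.

A well-mixed chemostat hosts up to four cell types that differ only in
plasmid content: plasmid-free cells (``free``), single carriers of the
focal plasmid X or the competitor plasmid Y, and double carriers XY.
Cells grow on a single limiting resource with Monod kinetics, wash out at
the chemostat turnover rate, lose plasmids segregationally, and exchange
plasmids by mass-action conjugation.  Interactions between the two
plasmids modify the joint fitness (epistasis), the conjugation rates
(intracellular and intercellular effects) and the loss rate of double
carriers (loss interference).

This module holds the parameter containers, the derived-rate algebra for
double carriers, and the ODE right-hand side together with its analytic
Jacobian.  Everything downstream (integration, steady states, grids)
builds on the :class:`Parameterization` object defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChemostatParams",
    "PlasmidTraits",
    "InteractionSet",
    "NEUTRAL_INTERACTIONS",
    "DerivedRates",
    "SystemState",
    "Parameterization",
    "derive_rates",
    "rhs",
    "jacobian",
    "plasmid_free_equilibrium",
]

_LN2 = math.log(2.0)

#: indices of the state vector (free, X, Y, XY, resource)
IDX_FREE, IDX_X, IDX_Y, IDX_XY, IDX_R = range(5)


@dataclass(frozen=True)
class ChemostatParams:
    """Constants of the chemostat environment.

    Parameters
    ----------
    washout_rate : float
        Turnover rate Omega of the vessel (h^-1).  Both cells and medium
        leave the chemostat at this rate.
    monod_constant : float
        Half-saturation constant Q of the Monod growth function (ug/mL).
    resource_per_division : float
        Resource consumed per cell division, Pi (ug).
    growth_rate : float
        Maximum growth rate psi of plasmid-free cells (h^-1).  The
        default, 3*ln(2), corresponds to three doublings per hour.
    inflow_resource : float
        Resource concentration R0 in the inflowing medium (ug/mL).
    """

    washout_rate: float = 0.05
    monod_constant: float = 5.0
    resource_per_division: float = 1e-6
    growth_rate: float = 3.0 * _LN2
    inflow_resource: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "washout_rate",
            "monod_constant",
            "resource_per_division",
            "growth_rate",
            "inflow_resource",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.growth_rate > self.washout_rate:
            raise ValueError(
                "growth_rate must exceed washout_rate, otherwise even "
                "plasmid-free cells wash out"
            )


@dataclass(frozen=True)
class PlasmidTraits:
    """Intrinsic traits of one conjugative plasmid.

    ``fitness`` is the relative fitness omega of a cell carrying the
    plasmid (dimensionless; carriers grow at psi*omega).
    ``conjugation_rate`` is the mass-action transfer rate gamma
    (mL cell^-1 h^-1) from single carriers into plasmid-free cells.
    ``loss_rate`` is the segregational loss rate delta (h^-1).
    """

    fitness: float
    conjugation_rate: float
    loss_rate: float

    def __post_init__(self) -> None:
        if not self.fitness > 0:
            raise ValueError("fitness must be strictly positive")
        if self.conjugation_rate < 0:
            raise ValueError("conjugation_rate must be non-negative")
        if self.loss_rate < 0:
            raise ValueError("loss_rate must be non-negative")


@dataclass(frozen=True)
class InteractionSet:
    """The six parameters governing what happens when two plasmids meet.

    epistasis : additive deviation epsilon of the double-carrier fitness
        from the multiplicative expectation, omega_XY = omega_X*omega_Y + eps.
    intracellular_X / intracellular_Y : multiplier alpha applied to a
        plasmid's conjugation rate when both plasmids co-reside in the
        donor cell.
    intercellular_X / intercellular_Y : multiplier xi applied to a
        plasmid's conjugation rate when the recipient carries the other
        plasmid.
    loss_interference : multiplier sigma on the loss rate of double
        carriers, delta_XY = delta*sigma.

    The neutral element (eps=0, all multipliers 1) reduces the model
    exactly to two independent, non-interacting plasmids.
    """

    epistasis: float = 0.0
    intracellular_X: float = 1.0
    intracellular_Y: float = 1.0
    intercellular_X: float = 1.0
    intercellular_Y: float = 1.0
    loss_interference: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "intracellular_X",
            "intracellular_Y",
            "intercellular_X",
            "intercellular_Y",
            "loss_interference",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def is_neutral(self) -> bool:
        return (
            self.epistasis == 0.0
            and self.intracellular_X == 1.0
            and self.intracellular_Y == 1.0
            and self.intercellular_X == 1.0
            and self.intercellular_Y == 1.0
            and self.loss_interference == 1.0
        )


NEUTRAL_INTERACTIONS = InteractionSet()


@dataclass(frozen=True)
class DerivedRates:
    """Composite rates of double carriers implied by traits + interactions.

    Attributes use the donor(resident)->recipient convention:
    ``conj_X_from_XY`` is the rate gamma_X(Y) at which XY donors transfer
    plasmid X into plasmid-free recipients; ``conj_X_to_Y`` is the rate
    gamma_X->Y at which X donors transfer into Y recipients; and so on.
    ``cotransfer`` is the rate gamma_XY of simultaneous transfer of both
    plasmids from XY donors, taken as the minimum of the two single
    rates.  ``loss_from_XY`` is the per-plasmid loss rate delta_XY of
    double carriers.
    """

    fitness_XY: float
    conj_X_from_XY: float
    conj_Y_from_XY: float
    conj_X_to_Y: float
    conj_Y_to_X: float
    conj_X_from_XY_to_Y: float
    conj_Y_from_XY_to_X: float
    cotransfer: float
    loss_from_XY: float


def derive_rates(
    traits_X: PlasmidTraits,
    traits_Y: PlasmidTraits,
    interactions: InteractionSet,
) -> DerivedRates:
    """Compute all double-carrier rates from traits and interactions.

    The joint fitness is ``omega_XY = omega_X*omega_Y + epsilon``.
    Intracellular effects rescale transfer out of XY donors,
    ``gamma_X(Y) = gamma_X*alpha_X``; intercellular effects rescale
    transfer into single carriers, ``gamma_X->Y = gamma_X*xi_X``.
    Transfer from XY donors into single carriers uses the intracellular
    rate only while the effect is inhibitory (alpha <= 1); when alpha > 1
    surface/entry exclusion by the resident copy in the recipient
    neutralizes the facilitation, so the bare rate applies.  Co-transfer
    of both plasmids proceeds at the rate of the less efficient one.

    Raises
    ------
    ValueError
        If the epistatic term drives ``omega_XY`` to zero or below, or if
        the two plasmids carry different loss rates (the double-carrier
        loss rate is defined for a shared delta only).
    """
    w_xy = traits_X.fitness * traits_Y.fitness + interactions.epistasis
    if not w_xy > 0:
        raise ValueError(
            f"epistasis {interactions.epistasis} drives the double-carrier "
            f"fitness to {w_xy} <= 0; inconsistent parameterization"
        )
    if traits_X.loss_rate != traits_Y.loss_rate:
        raise ValueError(
            "the double-carrier loss rate delta_XY = delta*sigma is defined "
            "for plasmids sharing a single loss rate delta"
        )
    g_x_from_xy = traits_X.conjugation_rate * interactions.intracellular_X
    g_y_from_xy = traits_Y.conjugation_rate * interactions.intracellular_Y
    return DerivedRates(
        fitness_XY=w_xy,
        conj_X_from_XY=g_x_from_xy,
        conj_Y_from_XY=g_y_from_xy,
        conj_X_to_Y=traits_X.conjugation_rate * interactions.intercellular_X,
        conj_Y_to_X=traits_Y.conjugation_rate * interactions.intercellular_Y,
        conj_X_from_XY_to_Y=(
            g_x_from_xy
            if interactions.intracellular_X <= 1.0
            else traits_X.conjugation_rate
        ),
        conj_Y_from_XY_to_X=(
            g_y_from_xy
            if interactions.intracellular_Y <= 1.0
            else traits_Y.conjugation_rate
        ),
        cotransfer=min(g_x_from_xy, g_y_from_xy),
        loss_from_XY=traits_X.loss_rate * interactions.loss_interference,
    )


@dataclass
class SystemState:
    """Densities of the four cell types (cells/mL) plus resource (ug/mL)."""

    free: float = 0.0
    X: float = 0.0
    Y: float = 0.0
    XY: float = 0.0
    resource: float = 100.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.free, self.X, self.Y, self.XY, self.resource], dtype=float
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(
            free=float(y[0]),
            X=float(y[1]),
            Y=float(y[2]),
            XY=float(y[3]),
            resource=float(y[4]),
        )

    @property
    def total_cells(self) -> float:
        return self.free + self.X + self.Y + self.XY


class Parameterization:
    """A fully specified model instance: chemostat + two plasmids + interactions.

    Precomputes the flat tuple of rate constants consumed by the fast ODE
    right-hand side, and exposes ``rhs_array``/``jac_array`` callables
    suitable for :func:`scipy.integrate.solve_ivp`.

    A single-plasmid population (the focal plasmid alone) is the special
    case Y(0) = XY(0) = 0: with no Y carriers present, the Y and XY
    equations stay identically zero, so the same right-hand side serves
    both the one- and two-plasmid systems.
    """

    def __init__(
        self,
        traits_X: PlasmidTraits,
        traits_Y: PlasmidTraits,
        interactions: InteractionSet = NEUTRAL_INTERACTIONS,
        chemostat: ChemostatParams | None = None,
    ) -> None:
        self.chemostat = chemostat if chemostat is not None else ChemostatParams()
        self.traits_X = traits_X
        self.traits_Y = traits_Y
        self.interactions = interactions
        self.rates = derive_rates(traits_X, traits_Y, interactions)
        c = self.chemostat
        r = self.rates
        self._c = (
            c.growth_rate,
            c.washout_rate,
            c.monod_constant,
            c.resource_per_division,
            c.inflow_resource,
            traits_X.fitness,
            traits_Y.fitness,
            r.fitness_XY,
            traits_X.conjugation_rate,
            traits_Y.conjugation_rate,
            r.conj_X_from_XY,
            r.conj_Y_from_XY,
            r.conj_X_to_Y,
            r.conj_Y_to_X,
            r.conj_X_from_XY_to_Y,
            r.conj_Y_from_XY_to_X,
            r.cotransfer,
            traits_X.loss_rate,
            r.loss_from_XY,
        )

    def rhs_array(self, t: float, y: np.ndarray) -> np.ndarray:
        """ODE right-hand side on a raw state vector (free, X, Y, XY, R)."""
        (
            psi,
            Om,
            Q,
            Pi,
            R0,
            wX,
            wY,
            wXY,
            gX,
            gY,
            gXfXY,
            gYfXY,
            gXtoY,
            gYtoX,
            gXfXYtoY,
            gYfXYtoX,
            gXY,
            delta,
            dXY,
        ) = self._c
        free, X, Y, XY, R = y
        monod = psi * R / (R + Q)
        xy_donor_total = gXfXY + gYfXY - gXY  # all transfer out of XY into free
        d_free = (
            free * monod
            - Om * free
            + delta * (X + Y)
            - gX * free * X
            - gY * free * Y
            - xy_donor_total * free * XY
        )
        d_x = (
            X * wX * monod
            - Om * X
            - delta * X
            + dXY * XY
            + gX * free * X
            + (gXfXY - gXY) * free * XY
            - gYtoX * X * Y
            - gYfXYtoX * X * XY
        )
        d_y = (
            Y * wY * monod
            - Om * Y
            - delta * Y
            + dXY * XY
            + gY * free * Y
            + (gYfXY - gXY) * free * XY
            - gXtoY * X * Y
            - gXfXYtoY * Y * XY
        )
        d_xy = (
            XY * wXY * monod
            - Om * XY
            - 2.0 * dXY * XY
            + gXY * free * XY
            + (gXtoY + gYtoX) * X * Y
            + gYfXYtoX * X * XY
            + gXfXYtoY * Y * XY
        )
        d_r = Om * (R0 - R) - Pi * monod * (free + wX * X + wY * Y + wXY * XY)
        return np.array([d_free, d_x, d_y, d_xy, d_r])

    def jac_array(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs_array` (5x5)."""
        (
            psi,
            Om,
            Q,
            Pi,
            R0,
            wX,
            wY,
            wXY,
            gX,
            gY,
            gXfXY,
            gYfXY,
            gXtoY,
            gYtoX,
            gXfXYtoY,
            gYfXYtoX,
            gXY,
            delta,
            dXY,
        ) = self._c
        free, X, Y, XY, R = y
        monod = psi * R / (R + Q)
        dmonod = psi * Q / (R + Q) ** 2
        xy_donor_total = gXfXY + gYfXY - gXY
        J = np.empty((5, 5))
        J[0, 0] = monod - Om - gX * X - gY * Y - xy_donor_total * XY
        J[0, 1] = delta - gX * free
        J[0, 2] = delta - gY * free
        J[0, 3] = -xy_donor_total * free
        J[0, 4] = free * dmonod

        J[1, 0] = gX * X + (gXfXY - gXY) * XY
        J[1, 1] = wX * monod - Om - delta + gX * free - gYtoX * Y - gYfXYtoX * XY
        J[1, 2] = -gYtoX * X
        J[1, 3] = dXY + (gXfXY - gXY) * free - gYfXYtoX * X
        J[1, 4] = X * wX * dmonod

        J[2, 0] = gY * Y + (gYfXY - gXY) * XY
        J[2, 1] = -gXtoY * Y
        J[2, 2] = wY * monod - Om - delta + gY * free - gXtoY * X - gXfXYtoY * XY
        J[2, 3] = dXY + (gYfXY - gXY) * free - gXfXYtoY * Y
        J[2, 4] = Y * wY * dmonod

        J[3, 0] = gXY * XY
        J[3, 1] = (gXtoY + gYtoX) * Y + gYfXYtoX * XY
        J[3, 2] = (gXtoY + gYtoX) * X + gXfXYtoY * XY
        J[3, 3] = (
            wXY * monod
            - Om
            - 2.0 * dXY
            + gXY * free
            + gYfXYtoX * X
            + gXfXYtoY * Y
        )
        J[3, 4] = XY * wXY * dmonod

        J[4, 0] = -Pi * monod
        J[4, 1] = -Pi * monod * wX
        J[4, 2] = -Pi * monod * wY
        J[4, 3] = -Pi * monod * wXY
        J[4, 4] = -Om - Pi * dmonod * (free + wX * X + wY * Y + wXY * XY)
        return J

    # -- flat config round trip ------------------------------------------

    def to_config(self) -> dict:
        """Serialize to a flat key-value mapping with conventional symbols."""
        return {
            "Omega": self.chemostat.washout_rate,
            "Q": self.chemostat.monod_constant,
            "Pi": self.chemostat.resource_per_division,
            "psi": self.chemostat.growth_rate,
            "R0": self.chemostat.inflow_resource,
            "omega_X": self.traits_X.fitness,
            "gamma_X": self.traits_X.conjugation_rate,
            "omega_Y": self.traits_Y.fitness,
            "gamma_Y": self.traits_Y.conjugation_rate,
            "delta": self.traits_X.loss_rate,
            "epsilon": self.interactions.epistasis,
            "alpha_X": self.interactions.intracellular_X,
            "alpha_Y": self.interactions.intracellular_Y,
            "xi_X": self.interactions.intercellular_X,
            "xi_Y": self.interactions.intercellular_Y,
            "sigma": self.interactions.loss_interference,
        }

    @classmethod
    def from_config(cls, config: dict) -> "Parameterization":
        """Build from a flat mapping; unspecified keys take the defaults.

        ``omega_Y``/``gamma_Y`` default to the focal plasmid's values
        (the competitor is made irrelevant by starting it at density 0).
        """
        defaults = ChemostatParams()
        unknown = set(config) - {
            "Omega", "Q", "Pi", "psi", "R0",
            "omega_X", "gamma_X", "omega_Y", "gamma_Y", "delta",
            "epsilon", "alpha_X", "alpha_Y", "xi_X", "xi_Y", "sigma",
            "X0", "Y0",
        }
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        chem = ChemostatParams(
            washout_rate=float(config.get("Omega", defaults.washout_rate)),
            monod_constant=float(config.get("Q", defaults.monod_constant)),
            resource_per_division=float(
                config.get("Pi", defaults.resource_per_division)
            ),
            growth_rate=float(config.get("psi", defaults.growth_rate)),
            inflow_resource=float(config.get("R0", defaults.inflow_resource)),
        )
        if "omega_X" not in config or "gamma_X" not in config or "delta" not in config:
            raise ValueError("config must define omega_X, gamma_X and delta")
        delta = float(config["delta"])
        tx = PlasmidTraits(
            fitness=float(config["omega_X"]),
            conjugation_rate=float(config["gamma_X"]),
            loss_rate=delta,
        )
        ty = PlasmidTraits(
            fitness=float(config.get("omega_Y", tx.fitness)),
            conjugation_rate=float(config.get("gamma_Y", tx.conjugation_rate)),
            loss_rate=delta,
        )
        inter = InteractionSet(
            epistasis=float(config.get("epsilon", 0.0)),
            intracellular_X=float(config.get("alpha_X", 1.0)),
            intracellular_Y=float(config.get("alpha_Y", 1.0)),
            intercellular_X=float(config.get("xi_X", 1.0)),
            intercellular_Y=float(config.get("xi_Y", 1.0)),
            loss_interference=float(config.get("sigma", 1.0)),
        )
        return cls(tx, ty, inter, chem)


def rhs(
    state: SystemState,
    params: ChemostatParams,
    traits_X: PlasmidTraits,
    traits_Y: PlasmidTraits,
    rates: DerivedRates,
) -> SystemState:
    """Evaluate the model equations at one state (derivative per hour).

    Convenience wrapper over :meth:`Parameterization.rhs_array` operating
    on :class:`SystemState` objects.
    """
    p = Parameterization.__new__(Parameterization)
    p.chemostat = params
    p._c = (
        params.growth_rate,
        params.washout_rate,
        params.monod_constant,
        params.resource_per_division,
        params.inflow_resource,
        traits_X.fitness,
        traits_Y.fitness,
        rates.fitness_XY,
        traits_X.conjugation_rate,
        traits_Y.conjugation_rate,
        rates.conj_X_from_XY,
        rates.conj_Y_from_XY,
        rates.conj_X_to_Y,
        rates.conj_Y_to_X,
        rates.conj_X_from_XY_to_Y,
        rates.conj_Y_from_XY_to_X,
        rates.cotransfer,
        traits_X.loss_rate,
        rates.loss_from_XY,
    )
    dy = p.rhs_array(0.0, state.as_array())
    return SystemState.from_array(dy)


def jacobian(
    state: SystemState,
    params: ChemostatParams,
    traits_X: PlasmidTraits,
    traits_Y: PlasmidTraits,
    rates: DerivedRates,
) -> np.ndarray:
    """Analytic Jacobian of the model equations at one state."""
    p = Parameterization.__new__(Parameterization)
    p.chemostat = params
    p._c = (
        params.growth_rate,
        params.washout_rate,
        params.monod_constant,
        params.resource_per_division,
        params.inflow_resource,
        traits_X.fitness,
        traits_Y.fitness,
        rates.fitness_XY,
        traits_X.conjugation_rate,
        traits_Y.conjugation_rate,
        rates.conj_X_from_XY,
        rates.conj_Y_from_XY,
        rates.conj_X_to_Y,
        rates.conj_Y_to_X,
        rates.conj_X_from_XY_to_Y,
        rates.conj_Y_from_XY_to_X,
        rates.cotransfer,
        traits_X.loss_rate,
        rates.loss_from_XY,
    )
    return p.jac_array(0.0, state.as_array())


def plasmid_free_equilibrium(params: ChemostatParams) -> tuple[float, float]:
    """Closed-form fixed point of the plasmid-free subsystem.

    With only plasmid-free cells present, growth balances washout when
    ``psi*R/(R+Q) = Omega``, giving ``R_hat = Q*Omega/(psi - Omega)``;
    the resource balance then fixes ``free_hat = (R0 - R_hat)/Pi``.

    Returns ``(R_hat, free_hat)``.
    """
    if not params.growth_rate > params.washout_rate:
        raise ValueError("requires growth_rate > washout_rate")
    r_hat = (
        params.monod_constant
        * params.washout_rate
        / (params.growth_rate - params.washout_rate)
    )
    free_hat = (params.inflow_resource - r_hat) / params.resource_per_division
    return r_hat, free_hat
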