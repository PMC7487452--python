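"""Numerical machinery: integration, steady states, survival, extinction times.

The decision threshold for extinction (one cell per mL) sits roughly
fourteen orders of magnitude below peak densities (~1e8 cells/mL), so
the integrator runs with a stiff-capable adaptive method (LSODA with the
model's analytic Jacobian, falling back to BDF if LSODA stalls) at
tight absolute tolerance.  Long-horizon questions (steady states,
extinction times up to ~1e5-1e6 h) are handled by a single continuous
integration whose accepted steps are monitored for a per-component
derivative criterion.

Extinction is detected on the integer-hour scale: the time of extinction
is the first non-negative integer hour at which the focal plasmid's
carrier densities are strictly below threshold (X < 1 and XY < 1 cells/mL).
The solver's own steps bracket the integer scan through its dense output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .model import Parameterization, SystemState

__all__ = [
    "SolverOptions",
    "Trajectory",
    "EquilibriumReport",
    "SolverFailure",
    "UndeterminedOutcome",
    "integrate",
    "solve_steady_state",
    "steady_state_and_extinction",
    "classify_survival",
    "time_of_extinction",
    "extinction_times",
]


class SolverFailure(RuntimeError):
    """The ODE solver broke down (step-size collapse or non-finite state)."""


class UndeterminedOutcome(RuntimeError):
    """The time budget elapsed with neither extinction nor convergence.

    Raised instead of silently coding the scenario as survival.
    """


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and budgets for all long-horizon computations.

    ``rtol``/``atol_cells``/``atol_resource`` feed the ODE solver; the
    cell-density absolute tolerance must sit far below the 1 cell/mL
    decision threshold.  Long-horizon runs stop at ``max_time`` simulated
    hours.  Steady-state convergence requires every component of the
    derivative to satisfy ``|dy_i/dt| <= ftol_abs + ftol_rel*|y_i|`` on
    ``converged_steps`` consecutive accepted steps.  ``max_lsoda_steps``
    bounds the LSODA phase before the driver falls back to BDF;
    ``max_steps`` is the hard step budget.
    """

    rtol: float = 1e-8
    atol_cells: float = 1e-6
    atol_resource: float = 1e-10
    max_time: float = 1e8
    ftol_abs: float = 1e-7
    ftol_rel: float = 1e-9
    extinction_threshold: float = 1.0
    stability_tol: float = 1e-9
    polish: bool = True
    converged_steps: int = 3
    max_lsoda_steps: int = 100_000
    max_steps: int = 1_000_000

    @property
    def atol(self) -> list[float]:
        a = self.atol_cells
        return [a, a, a, a, self.atol_resource]


DEFAULT_OPTIONS = SolverOptions()


@dataclass
class Trajectory:
    """A dense-output solution of the model over ``[t0, t_end]``.

    ``time_grid``/``states`` hold the solver's natural step points; the
    object is callable at arbitrary times within the integrated span
    (piecewise interpolation through the underlying dense output).
    """

    time_grid: np.ndarray
    states: np.ndarray  # shape (5, n), rows free/X/Y/XY/resource
    _segments: list = field(default_factory=list, repr=False)
    diagnostics: dict = field(default_factory=dict)

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((5, t_arr.size))
        for j, tj in enumerate(t_arr):
            seg = None
            for s in self._segments:
                if s.t_min - 1e-9 <= tj <= s.t_max + 1e-9:
                    seg = s
                    break
            if seg is None:
                raise ValueError(f"time {tj} outside integrated span")
            out[:, j] = seg(tj)
        return out[:, 0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    @property
    def initial_state(self) -> SystemState:
        return SystemState.from_array(self.states[:, 0])

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[:, -1])

    def to_frame(self):
        """Tidy table with columns time, free, X, Y, XY, R."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time_grid,
                "free": self.states[0],
                "X": self.states[1],
                "Y": self.states[2],
                "XY": self.states[3],
                "R": self.states[4],
            }
        )


@dataclass
class EquilibriumReport:
    """Steady state reached from a given initial condition."""

    state: SystemState
    converged: bool
    residual_norm: float
    stability_flag: bool
    max_eigenvalue_real: float = math.nan
    time_integrated: float = 0.0
    polished: bool = False


def _solve_window(param, t0, t1, y, options, max_step=np.inf):
    sol = solve_ivp(
        param.rhs_array,
        (t0, t1),
        y,
        method="LSODA",
        jac=param.jac_array,
        rtol=options.rtol,
        atol=options.atol,
        dense_output=True,
        max_step=max_step,
    )
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        raise SolverFailure(
            f"integration failed on [{t0}, {t1}]: {sol.message}; "
            f"last state {sol.y[:, -1]}"
        )
    return sol


def integrate(
    initial: SystemState,
    param: Parameterization,
    t_end: float,
    options: SolverOptions = DEFAULT_OPTIONS,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the model from ``initial`` over ``[0, t_end]``.

    Returns a dense-output :class:`Trajectory` evaluable at arbitrary
    times in the span.  Solver failures raise :class:`SolverFailure`
    with diagnostics; they are never silently truncated.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    sol = _solve_window(param, 0.0, float(t_end), initial.as_array(), options,
                        max_step=max_step)
    return Trajectory(
        time_grid=sol.t,
        states=sol.y,
        _segments=[sol.sol],
        diagnostics={"nfev": sol.nfev, "njev": sol.njev, "n_steps": len(sol.t)},
    )


def _converged(param, y, options):
    f = param.rhs_array(0.0, y)
    ok = np.all(np.abs(f) <= options.ftol_abs + options.ftol_rel * np.abs(y))
    return bool(ok), float(np.max(np.abs(f)))


def _advance(
    param: Parameterization,
    y0: np.ndarray,
    options: SolverOptions,
    track_X: bool = False,
    track_Y: bool = False,
    stop_on_toe: bool = False,
):
    """Shared long-horizon driver: step the stiff solver while scanning
    integer hours for extinction crossings and testing the steady-state
    criterion at every accepted step.

    A single continuous integration (no restarts) runs from t = 0 until
    the criterion holds on ``converged_steps`` consecutive steps, all
    tracked extinctions are resolved (when ``stop_on_toe``), or the
    ``max_time`` budget is exhausted.  If LSODA exceeds its step budget
    without finishing — its step-size heuristics can stall on the slow
    near-neutral manifolds this model produces — the run switches to BDF
    from the current state and continues.

    Returns ``(toe, y_end, t_end, converged, residual, diagnostics)``
    where ``toe`` maps 'X'/'Y' to an integer hour or None (still above
    threshold when the run stopped).
    """
    from scipy.integrate import BDF, LSODA

    thr = options.extinction_threshold
    y = np.array(y0, dtype=float)
    toe: dict[str, int | None] = {}
    scan_from: dict[str, int | None] = {}
    comp = {"X": (1, 3), "Y": (2, 3)}
    for p, tracked in (("X", track_X), ("Y", track_Y)):
        if tracked:
            toe[p] = None
            scan_from[p] = None
            i1, i2 = comp[p]
            if y[i1] < thr and y[i2] < thr:
                toe[p] = 0  # below threshold already at t = 0

    solver = LSODA(
        param.rhs_array, 0.0, y, options.max_time,
        jac=param.jac_array, rtol=options.rtol, atol=options.atol,
    )
    using_lsoda = True
    steps = 0
    switches = 0
    conv_streak = 0
    converged = False
    residual = math.inf
    while solver.status == "running":
        msg = solver.step()
        steps += 1
        if solver.status == "failed":
            raise SolverFailure(
                f"integration failed at t={solver.t:.6g}: {msg}"
            )
        t_old, t, y = solver.t_old, solver.t, solver.y
        if not np.all(np.isfinite(y)):
            raise SolverFailure(f"non-finite state at t={t:.6g}: {y}")

        # integer-hour extinction scan over the step just taken
        seg = None
        for p in toe:
            if toe[p] is not None:
                continue
            i1, i2 = comp[p]
            start = scan_from[p]
            if start is None and y[i1] < thr and y[i2] < thr:
                start = int(math.floor(t_old)) + 1  # crossed within this step
            if start is None:
                continue
            lo = max(start, int(math.floor(t_old)) + 1)
            hi = int(math.floor(t))
            if hi >= lo:
                if seg is None:
                    seg = solver.dense_output()
                ks = np.arange(lo, hi + 1, dtype=float)
                vals = seg(ks)
                below = (vals[i1] < thr) & (vals[i2] < thr)
                idx = np.nonzero(below)[0]
                if idx.size:
                    toe[p] = int(ks[idx[0]])
                    scan_from[p] = None
                    continue
                start = hi + 1
            scan_from[p] = start

        ok, residual = _converged(param, y, options)
        conv_streak = conv_streak + 1 if ok else 0
        if conv_streak >= options.converged_steps:
            converged = True
            # a plasmid sitting below threshold at the steady state keeps
            # that density forever; its pending integer is the crossing
            for p in toe:
                if toe[p] is None and scan_from[p] is not None:
                    i1, i2 = comp[p]
                    if y[i1] < thr and y[i2] < thr:
                        toe[p] = scan_from[p]
                        scan_from[p] = None
            break
        if stop_on_toe and all(v is not None for v in toe.values()):
            break
        if using_lsoda and steps >= options.max_lsoda_steps:
            solver = BDF(
                param.rhs_array, t, y, options.max_time,
                jac=param.jac_array, rtol=options.rtol, atol=options.atol,
            )
            using_lsoda = False
            switches += 1
        if steps >= options.max_steps:
            raise SolverFailure(
                f"step budget ({options.max_steps}) exhausted at t={t:.6g}"
            )

    if not converged:
        converged, residual = _converged(param, y, options)
    diagnostics = {"steps": steps, "solver_switches": switches}
    return toe, y, float(solver.t), converged, residual, diagnostics


def _polish_equilibrium(param, y, options):
    """Root-polish a near-equilibrium state; keep the integrated state on
    any sign of trouble."""
    try:
        res = optimize.root(
            lambda v: param.rhs_array(0.0, v),
            y,
            jac=lambda v: param.jac_array(0.0, v),
            method="hybr",
        )
    except Exception:
        return y, False
    if not res.success:
        return y, False
    y_new = res.x
    if not np.all(np.isfinite(y_new)):
        return y, False
    if np.any(y_new < -10 * options.atol_cells):
        return y, False
    old = np.max(np.abs(param.rhs_array(0.0, y)))
    new = np.max(np.abs(param.rhs_array(0.0, y_new)))
    if new > old:
        return y, False
    # reject a polish that jumped to a different equilibrium
    scale = 1.0 + np.abs(y)
    if np.max(np.abs(y_new - y) / scale) > 0.05:
        return y, False
    return y_new, True


def _clamp_small_negatives(y, options):
    y = np.array(y, dtype=float)
    small = (y < 0) & (y > -10 * options.atol_cells)
    y[small] = 0.0
    if np.any(y < 0):
        raise SolverFailure(f"state has significant negative components: {y}")
    return y


def _finalize_equilibrium(
    param, y, t_end, converged, options, stability_subspace=None
) -> EquilibriumReport:
    polished = False
    if converged and options.polish:
        y, polished = _polish_equilibrium(param, y, options)
    y = _clamp_small_negatives(y, options)
    residual = float(np.max(np.abs(param.rhs_array(0.0, y))))
    J = param.jac_array(0.0, y)
    if stability_subspace is not None:
        idx = np.asarray(stability_subspace, dtype=int)
        J = J[np.ix_(idx, idx)]
    eigs = np.linalg.eigvals(J)
    max_re = float(np.max(eigs.real))
    return EquilibriumReport(
        state=SystemState.from_array(y),
        converged=converged,
        residual_norm=residual,
        stability_flag=bool(max_re < options.stability_tol),
        max_eigenvalue_real=max_re,
        time_integrated=t_end,
        polished=polished,
    )


def solve_steady_state(
    initial: SystemState,
    param: Parameterization,
    options: SolverOptions = DEFAULT_OPTIONS,
) -> EquilibriumReport:
    """Find the stable steady state reached from ``initial``.

    Integrates until the per-component derivative criterion holds on
    consecutive steps, then polishes with Newton root-finding on the
    right-hand side and checks local stability through the Jacobian's
    eigenvalues.  A run that exhausts the time budget reports
    ``converged=False``; it never fabricates an equilibrium.
    """
    _, y, t_end, converged, residual, diag = _advance(
        param, initial.as_array(), options
    )
    return _finalize_equilibrium(param, y, t_end, converged, options)


def steady_state_and_extinction(
    initial: SystemState,
    param: Parameterization,
    options: SolverOptions = DEFAULT_OPTIONS,
    plasmids: tuple[str, ...] = ("X", "Y"),
    stability_subspace: tuple[int, ...] | None = None,
) -> tuple[EquilibriumReport, dict[str, int | None]]:
    """Steady state plus extinction times in a single integration pass.

    The per-scenario workhorse of the experiment engine: one continuous
    run records the integer-hour extinction crossings on the way to the
    attractor, so extinct scenarios are not integrated twice.

    ``stability_subspace`` restricts the Jacobian stability check to the
    listed state indices.  A single-plasmid study passes ``(0, 1, 4)``
    (free cells, focal carriers, resource): the competitor compartments
    are pinned at zero there, and invasion by an absent plasmid is not
    part of the question being asked.
    """
    toe, y, t_end, converged, residual, _ = _advance(
        param,
        initial.as_array(),
        options,
        track_X="X" in plasmids,
        track_Y="Y" in plasmids,
    )
    report = _finalize_equilibrium(
        param, y, t_end, converged, options, stability_subspace
    )
    return report, toe


def classify_survival(
    eq: EquilibriumReport, threshold: float = 1.0
) -> tuple[bool, bool]:
    """Survival flags for the two plasmids at a converged equilibrium.

    A plasmid survives when at least one carrier type holds ``threshold``
    (default one cell per mL) or more at the stable steady state; a
    density of exactly one cell counts as survival.  For a single-plasmid
    population the condition degenerates to X >= threshold, since XY
    never forms.  An equilibrium that is not locally stable does not
    count as survival.
    """
    if not eq.converged:
        raise ValueError("refusing to classify a non-converged equilibrium")
    s = eq.state
    if not eq.stability_flag:
        return False, False
    survival_x = s.X >= threshold or s.XY >= threshold
    survival_y = s.Y >= threshold or s.XY >= threshold
    return survival_x, survival_y


def extinction_times(
    initial: SystemState,
    param: Parameterization,
    options: SolverOptions = DEFAULT_OPTIONS,
    plasmids: tuple[str, ...] = ("X", "Y"),
) -> dict[str, int | None]:
    """Integer-hour times of extinction for the requested plasmids.

    Returns None for a plasmid that reaches a converged steady state
    while still above threshold (survival).  Raises
    :class:`UndeterminedOutcome` if the time budget runs out with
    neither extinction nor convergence.
    """
    toe, y, t_end, converged, residual, _ = _advance(
        param,
        initial.as_array(),
        options,
        track_X="X" in plasmids,
        track_Y="Y" in plasmids,
        stop_on_toe=True,
    )
    if any(v is None for v in toe.values()) and not converged:
        raise UndeterminedOutcome(
            f"no extinction and no steady state within {options.max_time} h "
            f"(residual {residual:.3g})"
        )
    if converged:
        # a plasmid extinct at the converged state must have a recorded hour
        thr = options.extinction_threshold
        comp = {"X": (1, 3), "Y": (2, 3)}
        for p, v in toe.items():
            i1, i2 = comp[p]
            if v is None and y[i1] < thr and y[i2] < thr:
                raise UndeterminedOutcome(
                    f"plasmid {p} below threshold at steady state but no "
                    "integer-hour crossing was recorded"
                )
    return toe


def time_of_extinction(
    initial: SystemState,
    param: Parameterization,
    plasmid: str = "X",
    options: SolverOptions = DEFAULT_OPTIONS,
) -> int | None:
    """Time of extinction of one plasmid (integer hours), or None.

    The smallest integer t >= 0 at which the dense trajectory has both
    carrier densities of the focal plasmid strictly below threshold;
    None when the plasmid instead survives to a converged steady state.
    """
    if plasmid not in ("X", "Y"):
        raise ValueError("plasmid must be 'X' or 'Y'")
    return extinction_times(initial, param, options, plasmids=(plasmid,))[plasmid]
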