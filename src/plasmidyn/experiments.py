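"""Parameter grids, sweep execution, and extinction-time comparisons.

The study design crosses plasmid trait values over fixed grids and
activates one (or several) interaction parameters per model family:

==========  ======================================================  ======
model id    description                                             cases
==========  ======================================================  ======
``1``       focal plasmid alone, X(0) = 5e5                            36
``1c``      control: focal plasmid alone, X(0) = 1e6                   36
``1b``      cost-free/beneficial plasmid alone (omega_X in {1,1.05})   18
``1p``      high-conjugation probe alone (gamma_X = 1e-10)             12
``2``       two non-interacting plasmids                              432
``3``       epistasis epsilon in {-0.05, 0, 0.05, 0.1}               1728
``4.1``     intracellular conjugation effect on X (alpha_X)          1296
``4.2``     intracellular conjugation effect on Y (alpha_Y)          1296
``5.1``     intercellular conjugation effect on X (xi_X)             1296
``5.2``     intercellular conjugation effect on Y (xi_Y)             1296
``6``       loss interference sigma in {1, 10}                        864
``multi``   all six interactions crossed, fixed competitor          23328
==========  ======================================================  ======

Trait grids: omega in {0.85, 0.9, 0.95, 0.975}, gamma in
{1e-13, 1e-12, 1e-11} for each plasmid, and a loss rate delta in
{1e-8, 1e-6, 1e-4} shared by both plasmids.  The ``multi`` sweep fixes
the competitor at omega_Y = 0.9, gamma_Y = 1e-12 and crosses all six
interaction parameters over the 36 focal-trait combinations.

Extinction times from an interaction model are normalized by the
matching reference run (model 1: same focal traits and loss rate;
model 2: same trait pairing) and categorized as ``increase`` (ratio
strictly above 1), ``decrease`` (below 1) or ``null`` (exact integer
tie).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .dynamics import (
    DEFAULT_OPTIONS,
    EquilibriumReport,
    SolverOptions,
    UndeterminedOutcome,
    classify_survival,
    extinction_times,
    steady_state_and_extinction,
)
from .model import (
    ChemostatParams,
    InteractionSet,
    NEUTRAL_INTERACTIONS,
    Parameterization,
    PlasmidTraits,
    SystemState,
)

__all__ = [
    "OMEGA_VALUES",
    "GAMMA_VALUES",
    "DELTA_VALUES",
    "EPSILON_VALUES",
    "ALPHA_VALUES",
    "XI_VALUES",
    "SIGMA_VALUES",
    "Scenario",
    "ModelGrid",
    "ScenarioResult",
    "build_grid",
    "run_scenario",
    "run_grid",
    "run_grid_toe",
    "results_to_frame",
    "normalize_toe",
    "summarize_outcomes",
    "summarize_survival",
    "benefit_by_interaction",
    "GridFailure",
]

OMEGA_VALUES = (0.85, 0.9, 0.95, 0.975)
GAMMA_VALUES = (1e-13, 1e-12, 1e-11)
DELTA_VALUES = (1e-8, 1e-6, 1e-4)
EPSILON_VALUES = (-0.05, 0.0, 0.05, 0.1)
ALPHA_VALUES = (1e-3, 1.0, 10.0)
XI_VALUES = (1e-2, 1.0, 10.0)
SIGMA_VALUES = (1.0, 10.0)

#: fitness values of the cost-free / beneficial single-plasmid control
BENEFIT_OMEGA_VALUES = (1.0, 1.05)
#: conjugation rate of the de-repressed-plasmid probe
PROBE_GAMMA = 1e-10

STANDARD_X0 = 5e5
CONTROL_X0 = 1e6

MODEL_IDS = ("1", "1c", "1b", "1p", "2", "3", "4.1", "4.2", "5.1", "5.2", "6", "multi")


class GridFailure(RuntimeError):
    """One or more scenarios of a grid ended undetermined."""

    def __init__(self, failures: list[tuple[str, str]]):
        self.failures = failures
        ids = ", ".join(sid for sid, _ in failures[:10])
        super().__init__(
            f"{len(failures)} scenario(s) ended undetermined: {ids}"
        )


@dataclass(frozen=True)
class Scenario:
    """One fully specified simulation case."""

    model: str
    traits_X: PlasmidTraits
    traits_Y: PlasmidTraits | None = None
    interactions: InteractionSet = NEUTRAL_INTERACTIONS
    chemostat: ChemostatParams = field(default_factory=ChemostatParams)
    x0: float = STANDARD_X0
    y0: float = 0.0
    target: str | None = None  # which plasmid an interaction acts on, if any

    @property
    def two_plasmid(self) -> bool:
        return self.traits_Y is not None

    def parameterization(self) -> Parameterization:
        # a single-plasmid population reuses the two-plasmid equations
        # with the competitor compartments pinned at zero density
        traits_y = self.traits_Y if self.traits_Y is not None else self.traits_X
        return Parameterization(
            self.traits_X, traits_y, self.interactions, self.chemostat
        )

    def initial_state(self) -> SystemState:
        return SystemState(
            free=0.0,
            X=self.x0,
            Y=self.y0,
            XY=0.0,
            resource=self.chemostat.inflow_resource,
        )

    def config(self) -> dict:
        cfg = self.parameterization().to_config()
        cfg["X0"] = self.x0
        cfg["Y0"] = self.y0
        if not self.two_plasmid:
            del cfg["omega_Y"], cfg["gamma_Y"]
        return cfg

    @property
    def scenario_id(self) -> str:
        payload = json.dumps(
            {"model": self.model, **self.config()}, sort_keys=True
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ModelGrid:
    """An enumerated set of scenarios for one model family."""

    model: str
    scenarios: list[Scenario]
    notes: str = ""

    def __len__(self) -> int:
        return len(self.scenarios)


def _focal_traits():
    for omega, gamma, delta in itertools.product(
        OMEGA_VALUES, GAMMA_VALUES, DELTA_VALUES
    ):
        yield PlasmidTraits(omega, gamma, delta)


def _trait_pairings():
    """All 432 pairings: focal x competitor traits with a shared loss rate."""
    for w_x, g_x, w_y, g_y, delta in itertools.product(
        OMEGA_VALUES, GAMMA_VALUES, OMEGA_VALUES, GAMMA_VALUES, DELTA_VALUES
    ):
        yield (
            PlasmidTraits(w_x, g_x, delta),
            PlasmidTraits(w_y, g_y, delta),
        )


def build_grid(model_id: str, chemostat: ChemostatParams | None = None) -> ModelGrid:
    """Enumerate the scenario grid for one model family (see module docs)."""
    model_id = str(model_id)
    chem = chemostat if chemostat is not None else ChemostatParams()
    scenarios: list[Scenario] = []

    if model_id == "1":
        for tx in _focal_traits():
            scenarios.append(Scenario("1", tx, chemostat=chem))
        notes = "focal plasmid alone, X(0)=5e5"
    elif model_id == "1c":
        for tx in _focal_traits():
            scenarios.append(Scenario("1c", tx, chemostat=chem, x0=CONTROL_X0))
        notes = "initial-density control of model 1, X(0)=1e6"
    elif model_id == "1b":
        for omega, gamma, delta in itertools.product(
            BENEFIT_OMEGA_VALUES, GAMMA_VALUES, DELTA_VALUES
        ):
            scenarios.append(
                Scenario("1b", PlasmidTraits(omega, gamma, delta), chemostat=chem)
            )
        notes = "cost-free/beneficial focal plasmid alone (omega_X in {1, 1.05})"
    elif model_id == "1p":
        for omega, delta in itertools.product(OMEGA_VALUES, DELTA_VALUES):
            scenarios.append(
                Scenario(
                    "1p", PlasmidTraits(omega, PROBE_GAMMA, delta), chemostat=chem
                )
            )
        notes = "high-conjugation probe alone (gamma_X = 1e-10)"
    elif model_id == "2":
        for tx, ty in _trait_pairings():
            scenarios.append(
                Scenario("2", tx, ty, chemostat=chem, y0=STANDARD_X0)
            )
        notes = "two non-interacting plasmids"
    elif model_id == "3":
        for eps in EPSILON_VALUES:
            inter = InteractionSet(epistasis=eps)
            for tx, ty in _trait_pairings():
                scenarios.append(
                    Scenario("3", tx, ty, inter, chem, y0=STANDARD_X0)
                )
        notes = "epistasis only"
    elif model_id in ("4.1", "4.2"):
        target = "X" if model_id == "4.1" else "Y"
        for alpha in ALPHA_VALUES:
            inter = (
                InteractionSet(intracellular_X=alpha)
                if target == "X"
                else InteractionSet(intracellular_Y=alpha)
            )
            for tx, ty in _trait_pairings():
                scenarios.append(
                    Scenario(
                        model_id, tx, ty, inter, chem,
                        y0=STANDARD_X0, target=target,
                    )
                )
        notes = f"intracellular conjugation effect on plasmid {target}"
    elif model_id in ("5.1", "5.2"):
        target = "X" if model_id == "5.1" else "Y"
        for xi in XI_VALUES:
            inter = (
                InteractionSet(intercellular_X=xi)
                if target == "X"
                else InteractionSet(intercellular_Y=xi)
            )
            for tx, ty in _trait_pairings():
                scenarios.append(
                    Scenario(
                        model_id, tx, ty, inter, chem,
                        y0=STANDARD_X0, target=target,
                    )
                )
        notes = f"intercellular conjugation effect on plasmid {target}"
    elif model_id == "6":
        for sigma in SIGMA_VALUES:
            inter = InteractionSet(loss_interference=sigma)
            for tx, ty in _trait_pairings():
                scenarios.append(
                    Scenario("6", tx, ty, inter, chem, y0=STANDARD_X0)
                )
        notes = "loss interference"
    elif model_id == "multi":
        for tx in _focal_traits():
            ty = PlasmidTraits(0.9, 1e-12, tx.loss_rate)
            for eps, a_x, a_y, x_x, x_y, sigma in itertools.product(
                EPSILON_VALUES,
                ALPHA_VALUES,
                ALPHA_VALUES,
                XI_VALUES,
                XI_VALUES,
                SIGMA_VALUES,
            ):
                inter = InteractionSet(
                    epistasis=eps,
                    intracellular_X=a_x,
                    intracellular_Y=a_y,
                    intercellular_X=x_x,
                    intercellular_Y=x_y,
                    loss_interference=sigma,
                )
                scenarios.append(
                    Scenario("multi", tx, ty, inter, chem, y0=STANDARD_X0)
                )
        notes = (
            "all six interaction parameters crossed; fixed competitor "
            "omega_Y=0.9, gamma_Y=1e-12"
        )
    else:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")

    return ModelGrid(model_id, scenarios, notes)


@dataclass
class ScenarioResult:
    """Outcome of one scenario: survival flags, extinction times, equilibrium."""

    scenario: Scenario
    survival_X: bool
    survival_Y: bool | None
    toe_X: int | None
    toe_Y: int | None
    equilibrium: EquilibriumReport

    @property
    def frequencies(self) -> dict[str, float]:
        s = self.equilibrium.state
        total = s.total_cells
        if total <= 0:
            return {"free": math.nan, "X": math.nan, "Y": math.nan, "XY": math.nan}
        return {
            "free": s.free / total,
            "X": s.X / total,
            "Y": s.Y / total,
            "XY": s.XY / total,
        }

    def to_row(self) -> dict:
        sc = self.scenario
        inter = sc.interactions
        eq = self.equilibrium.state
        row = {
            "scenario_id": sc.scenario_id,
            "model": sc.model,
            "omega_X": sc.traits_X.fitness,
            "gamma_X": sc.traits_X.conjugation_rate,
            "omega_Y": sc.traits_Y.fitness if sc.two_plasmid else math.nan,
            "gamma_Y": sc.traits_Y.conjugation_rate if sc.two_plasmid else math.nan,
            "delta": sc.traits_X.loss_rate,
            "epsilon": inter.epistasis,
            "alpha_X": inter.intracellular_X,
            "alpha_Y": inter.intracellular_Y,
            "xi_X": inter.intercellular_X,
            "xi_Y": inter.intercellular_Y,
            "sigma": inter.loss_interference,
            "X0": sc.x0,
            "Y0": sc.y0,
            "survival_X": self.survival_X,
            "survival_Y": self.survival_Y,
            "toe_X": self.toe_X,
            "toe_Y": self.toe_Y,
            "eq_free": eq.free,
            "eq_X": eq.X,
            "eq_Y": eq.Y,
            "eq_XY": eq.XY,
            "eq_R": eq.resource,
            "freq_free": self.frequencies["free"],
            "converged": self.equilibrium.converged,
            "stable": self.equilibrium.stability_flag,
        }
        return row


def run_scenario(
    scenario: Scenario, options: SolverOptions = DEFAULT_OPTIONS
) -> ScenarioResult:
    """Run one scenario to its steady state, recording extinction times.

    Raises :class:`UndeterminedOutcome` when the run neither converges
    nor resolves the extinction times within the time budget, and on any
    inconsistency between the steady-state classification and the
    recorded crossings.
    """
    param = scenario.parameterization()
    plasmids = ("X", "Y") if scenario.two_plasmid else ("X",)
    report, toe = steady_state_and_extinction(
        scenario.initial_state(),
        param,
        options,
        plasmids=plasmids,
        stability_subspace=None if scenario.two_plasmid else (0, 1, 4),
    )
    if not report.converged:
        raise UndeterminedOutcome(
            f"scenario {scenario.scenario_id}: no steady state within "
            f"{options.max_time} h (residual {report.residual_norm:.3g})"
        )
    survival_x, survival_y = classify_survival(
        report, options.extinction_threshold
    )
    toe_x = toe.get("X")
    toe_y = toe.get("Y") if scenario.two_plasmid else None
    if survival_x != (toe_x is None):
        raise UndeterminedOutcome(
            f"scenario {scenario.scenario_id}: steady-state survival flag for "
            f"X contradicts the recorded extinction crossing"
        )
    if scenario.two_plasmid and survival_y != (toe_y is None):
        raise UndeterminedOutcome(
            f"scenario {scenario.scenario_id}: steady-state survival flag for "
            f"Y contradicts the recorded extinction crossing"
        )
    return ScenarioResult(
        scenario=scenario,
        survival_X=survival_x,
        survival_Y=survival_y if scenario.two_plasmid else None,
        toe_X=toe_x,
        toe_Y=toe_y,
        equilibrium=report,
    )


def run_grid(
    grid: ModelGrid,
    options: SolverOptions = DEFAULT_OPTIONS,
    n_jobs: int = 1,
) -> list[ScenarioResult]:
    """Run every scenario of a grid; order and content are independent of
    ``n_jobs``.  Undetermined scenarios abort with a :class:`GridFailure`
    listing the offenders."""
    failures: list[tuple[str, str]] = []
    results: list[ScenarioResult | None] = [None] * len(grid.scenarios)

    def _one(sc: Scenario):
        try:
            return run_scenario(sc, options), None
        except UndeterminedOutcome as exc:
            return None, (sc.scenario_id, str(exc))

    if n_jobs == 1:
        outcomes = [_one(sc) for sc in grid.scenarios]
    else:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=n_jobs)(
            delayed(_one)(sc) for sc in grid.scenarios
        )
    for i, (res, err) in enumerate(outcomes):
        if err is not None:
            failures.append(err)
        else:
            results[i] = res
    if failures:
        raise GridFailure(failures)
    return results  # type: ignore[return-value]


def _scenario_param_row(sc: Scenario) -> dict:
    inter = sc.interactions
    return {
        "scenario_id": sc.scenario_id,
        "model": sc.model,
        "omega_X": sc.traits_X.fitness,
        "gamma_X": sc.traits_X.conjugation_rate,
        "omega_Y": sc.traits_Y.fitness if sc.two_plasmid else math.nan,
        "gamma_Y": sc.traits_Y.conjugation_rate if sc.two_plasmid else math.nan,
        "delta": sc.traits_X.loss_rate,
        "epsilon": inter.epistasis,
        "alpha_X": inter.intracellular_X,
        "alpha_Y": inter.intracellular_Y,
        "xi_X": inter.intercellular_X,
        "xi_Y": inter.intercellular_Y,
        "sigma": inter.loss_interference,
        "X0": sc.x0,
        "Y0": sc.y0,
    }


def run_grid_toe(
    scenarios: list[Scenario] | ModelGrid,
    options: SolverOptions = DEFAULT_OPTIONS,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Extinction times without equilibrium composition.

    Considerably cheaper than :func:`run_grid` for comparative
    extinction-time analyses: each run stops as soon as the integer-hour
    crossings of all tracked plasmids are resolved (a plasmid that
    instead converges to a steady state above threshold gets a missing
    time and ``survival=True``).
    """
    if isinstance(scenarios, ModelGrid):
        scenarios = scenarios.scenarios

    def _one(sc: Scenario):
        plasmids = ("X", "Y") if sc.two_plasmid else ("X",)
        toe = extinction_times(
            sc.initial_state(), sc.parameterization(), options, plasmids=plasmids
        )
        row = _scenario_param_row(sc)
        row["toe_X"] = toe.get("X")
        row["toe_Y"] = toe.get("Y") if sc.two_plasmid else None
        row["survival_X"] = toe.get("X") is None
        row["survival_Y"] = toe.get("Y") is None if sc.two_plasmid else None
        return row

    if n_jobs == 1:
        rows = [_one(sc) for sc in scenarios]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(_one)(sc) for sc in scenarios)
    frame = pd.DataFrame(rows)
    for col in ("toe_X", "toe_Y"):
        frame[col] = frame[col].astype("Int64")
    return frame


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy one-row-per-scenario table (extinction times as nullable ints)."""
    frame = pd.DataFrame([r.to_row() for r in results])
    for col in ("toe_X", "toe_Y"):
        frame[col] = frame[col].astype("Int64")
    return frame


_REF_KEYS = {
    1: ["omega_X", "gamma_X", "delta"],
    2: ["omega_X", "gamma_X", "omega_Y", "gamma_Y", "delta"],
}


def normalize_toe(
    frame: pd.DataFrame,
    reference_frame: pd.DataFrame,
    reference_model: int,
) -> pd.DataFrame:
    """Normalize focal-plasmid extinction times against a reference sweep.

    ``reference_model`` is 1 (focal plasmid alone; keyed on the focal
    traits and loss rate) or 2 (non-interacting pair; keyed on the full
    trait pairing).  Scenarios where either member survives carry
    ``excluded=True`` and a NaN ratio; they enter no ratio analysis.
    Categories compare exact integer extinction times.
    """
    if reference_model not in _REF_KEYS:
        raise ValueError("reference_model must be 1 or 2")
    keys = _REF_KEYS[reference_model]
    ref = reference_frame[keys + ["toe_X", "survival_X"]].rename(
        columns={"toe_X": "toe_ref", "survival_X": "survival_ref"}
    )
    if ref.duplicated(keys).any():
        raise ValueError("reference sweep has duplicate trait combinations")
    merged = frame.merge(ref, on=keys, how="left", validate="m:1")
    if merged["survival_ref"].isna().any():
        missing = merged.loc[merged["survival_ref"].isna(), keys].drop_duplicates()
        raise ValueError(
            f"missing reference pairing for {len(missing)} trait combination(s)"
        )
    merged["excluded"] = merged["survival_X"] | merged["survival_ref"].astype(bool)
    ratio = merged["toe_X"].astype(float) / merged["toe_ref"].astype(float)
    merged["ratio"] = ratio.where(~merged["excluded"])
    merged["reference_model"] = reference_model

    def _cat(row):
        if row["excluded"]:
            return pd.NA
        if row["toe_X"] > row["toe_ref"]:
            return "increase"
        if row["toe_X"] < row["toe_ref"]:
            return "decrease"
        return "null"

    merged["category"] = merged.apply(_cat, axis=1)
    return merged


def summarize_outcomes(
    records: pd.DataFrame, stratify_by: str
) -> pd.DataFrame:
    """Counts of increase/decrease/null per stratum of ``stratify_by``."""
    if records.empty:
        raise ValueError("no comparison records to summarize")
    if stratify_by not in records.columns:
        raise ValueError(f"unknown stratifier {stratify_by!r}")
    sub = records[~records["excluded"]]
    table = (
        sub.groupby(stratify_by)["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["increase", "decrease", "null"], fill_value=0)
    )
    table.columns.name = None
    return table


def summarize_survival(frame: pd.DataFrame, stratify_by: str | None = None):
    """Survivor/extinct counts of the focal plasmid, optionally per stratum."""
    if frame.empty:
        raise ValueError("no results to summarize")
    if stratify_by is None:
        n = len(frame)
        s = int(frame["survival_X"].sum())
        return pd.DataFrame(
            {"survive": [s], "extinct": [n - s]}, index=["all"]
        )
    if stratify_by not in frame.columns:
        raise ValueError(f"unknown stratifier {stratify_by!r}")
    g = frame.groupby(stratify_by)["survival_X"]
    return pd.DataFrame(
        {"survive": g.sum().astype(int), "extinct": (g.count() - g.sum()).astype(int)}
    )


#: which interaction parameter each single-interaction model varies,
#: and its neutral value
_INTERACTION_OF_MODEL = {
    "3": ("epsilon", 0.0),
    "4.1": ("alpha_X", 1.0),
    "4.2": ("alpha_Y", 1.0),
    "5.1": ("xi_X", 1.0),
    "5.2": ("xi_Y", 1.0),
    "6": ("sigma", 1.0),
}


def pooled_interaction_frame(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool the non-neutral cases of the single-interaction models 3-6.

    Input maps model id ('3', '4.1', ... '6') to its full sweep frame;
    the neutral stratum of each model (which duplicates model 2) is
    dropped, leaving each case tagged with the interaction that is
    active in it.
    """
    parts = []
    for model_id, (param, neutral) in _INTERACTION_OF_MODEL.items():
        if model_id not in frames:
            raise ValueError(f"missing sweep frame for model {model_id}")
        f = frames[model_id]
        sub = f[f[param] != neutral].copy()
        sub["interaction"] = param
        parts.append(sub)
    pooled = pd.concat(parts, ignore_index=True)
    return pooled


def benefit_by_interaction(
    pooled: pd.DataFrame, model1_frame: pd.DataFrame
) -> pd.DataFrame:
    """Benefit proportions of each interaction versus the plasmid-alone run.

    For every pooled non-neutral case the focal extinction time is
    normalized by the matching single-plasmid (model 1) value; a ratio
    strictly above 1 is a benefit.  Proportions are taken among the
    extinct cases of each interaction stratum.
    """
    records = normalize_toe(pooled, model1_frame, reference_model=1)
    rows = []
    for name, grp in records.groupby("interaction"):
        extinct = grp[~grp["excluded"]]
        n_benefit = int((extinct["ratio"] > 1).sum())
        rows.append(
            {
                "interaction": name,
                "n_cases": len(grp),
                "n_extinct": len(extinct),
                "n_benefit": n_benefit,
                "pct_benefit": 100.0 * n_benefit / len(extinct)
                if len(extinct)
                else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("interaction")
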