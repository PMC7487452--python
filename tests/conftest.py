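"""Shared fixtures: the model sweeps, computed once per session.

Every sweep is generated programmatically by the package itself; heavy
grids are session-scoped so that the acceptance checks and the
comparative analyses share a single computation.
"""

from __future__ import annotations

import pytest

from plasmidyn import (
    ChemostatParams,
    PlasmidTraits,
    build_grid,
    results_to_frame,
    run_grid,
    run_grid_toe,
)


@pytest.fixture(scope="session")
def chemostat() -> ChemostatParams:
    return ChemostatParams()


@pytest.fixture(scope="session")
def sample_traits() -> PlasmidTraits:
    return PlasmidTraits(fitness=0.9, conjugation_rate=1e-12, loss_rate=1e-6)


def _full_frame(grid):
    return results_to_frame(run_grid(grid))


@pytest.fixture(scope="session")
def model1_frame():
    """Full single-plasmid sweep (36 cases): equilibria and extinction times."""
    return _full_frame(build_grid("1"))


@pytest.fixture(scope="session")
def model1c_frame():
    """Initial-density control of model 1 (X(0)=1e6)."""
    return run_grid_toe(build_grid("1c"))


@pytest.fixture(scope="session")
def model1b_frame():
    """Cost-free/beneficial single plasmid (omega_X in {1, 1.05})."""
    return _full_frame(build_grid("1b"))


@pytest.fixture(scope="session")
def model1p_frame():
    """High-conjugation single-plasmid probe (gamma_X = 1e-10)."""
    return _full_frame(build_grid("1p"))


@pytest.fixture(scope="session")
def model2_frame():
    """Two non-interacting plasmids (432 pairings), extinction times."""
    return run_grid_toe(build_grid("2"))


@pytest.fixture(scope="session")
def model3_frame():
    """Epistasis sweep (1728 cases): equilibria and extinction times."""
    return _full_frame(build_grid("3"))


def _stratum_toe(model_id: str, param: str, value: float):
    grid = build_grid(model_id)
    subset = [
        sc for sc in grid.scenarios
        if getattr(sc.interactions, param) == value
    ]
    return run_grid_toe(subset)


@pytest.fixture(scope="session")
def model41_frames():
    """Non-neutral intracellular-effect-on-X strata (alpha_X = 1e-3 and 10)."""
    return {
        1e-3: _stratum_toe("4.1", "intracellular_X", 1e-3),
        10.0: _stratum_toe("4.1", "intracellular_X", 10.0),
    }


@pytest.fixture(scope="session")
def model42_frames():
    return {
        1e-3: _stratum_toe("4.2", "intracellular_Y", 1e-3),
        10.0: _stratum_toe("4.2", "intracellular_Y", 10.0),
    }


@pytest.fixture(scope="session")
def model51_frames():
    return {
        1e-2: _stratum_toe("5.1", "intercellular_X", 1e-2),
        10.0: _stratum_toe("5.1", "intercellular_X", 10.0),
    }


@pytest.fixture(scope="session")
def model52_frames():
    return {
        1e-2: _stratum_toe("5.2", "intercellular_Y", 1e-2),
        10.0: _stratum_toe("5.2", "intercellular_Y", 10.0),
    }


@pytest.fixture(scope="session")
def model6_sigma10_frame():
    return _stratum_toe("6", "loss_interference", 10.0)


@pytest.fixture(scope="session")
def multi_survival_subset_frame():
    """The multi-interaction cases satisfying the survival preconditions.

    The full 23328-case sweep is far beyond a test budget; the subset
    with epsilon=0.1, alpha_X=10, gamma_X=1e-11 and omega_X>0.85 (486
    cases) is where survival is at stake, and is run in full.
    """
    grid = build_grid("multi")
    subset = [
        sc for sc in grid.scenarios
        if sc.interactions.epistasis == 0.1
        and sc.interactions.intracellular_X == 10.0
        and sc.traits_X.conjugation_rate == 1e-11
        and sc.traits_X.fitness > 0.85
    ]
    return _full_frame(
        type(grid)(model="multi-survival-subset", scenarios=subset)
    )


@pytest.fixture(scope="session")
def pooled_frames(model3_frame, model41_frames, model42_frames,
                  model51_frames, model52_frames, model6_sigma10_frame,
                  model2_frame):
    """Per-model frames covering every non-neutral single-interaction case."""
    import pandas as pd

    return {
        "3": model3_frame,
        "4.1": pd.concat(model41_frames.values(), ignore_index=True),
        "4.2": pd.concat(model42_frames.values(), ignore_index=True),
        "5.1": pd.concat(model51_frames.values(), ignore_index=True),
        "5.2": pd.concat(model52_frames.values(), ignore_index=True),
        "6": model6_sigma10_frame,
    }
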