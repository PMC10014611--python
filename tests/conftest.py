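"""Shared fixtures: the printed worked-example matrices and small simulated
populations.  Expensive simulation studies are session-scoped so the
acceptance tests share one set of runs."""

from __future__ import annotations

import numpy as np
import pytest

import smoothdescent as sd

# Worked diploid example: 3 markers x 4 homologues (parent 1 = H1,H2).
EQ1_ROWS = np.array(
    [
        [1, 0, 0, 0],
        [0, 1, 1, 0],
        [0, 0, 0, 1],
    ]
)

# Worked tetraploid example: 3 markers x 8 homologues.
EQ2_ROWS = np.array(
    [
        [0, 1, 0, 1, 0, 0, 0, 0],
        [1, 0, 1, 1, 1, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 1, 1],
    ]
)


@pytest.fixture
def eq1_phase() -> sd.HomologueMatrix:
    return sd.HomologueMatrix(EQ1_ROWS, 2, 2)


@pytest.fixture
def eq2_phase() -> sd.HomologueMatrix:
    return sd.HomologueMatrix(EQ2_ROWS, 4, 4)


def make_population(
    ploidy: int,
    seed: int,
    error_rate: float = 0.0,
    n_individuals: int = 100,
    n_markers: int = 200,
) -> sd.TruthBundle:
    cfg = sd.SimConfig(
        ploidy_p1=ploidy,
        ploidy_p2=ploidy,
        n_individuals=n_individuals,
        n_markers=n_markers,
        seed=seed,
    )
    return sd.simulate_experiment(cfg, sd.ErrorProfile.uniform(error_rate), seed=seed)


@pytest.fixture(scope="session")
def diploid_clean() -> sd.TruthBundle:
    """Error-free diploid population, full study size."""
    return make_population(2, seed=101)


@pytest.fixture(scope="session")
def diploid_noisy() -> sd.TruthBundle:
    """Diploid population with 10% uniform errors."""
    return make_population(2, seed=102, error_rate=0.10)


def run_study(ploidy: int, seeds: list[int], error_rate: float = 0.10):
    """One simulation-study condition: returns per-seed metric dicts."""
    rows = []
    for s in seeds:
        bundle = make_population(ploidy, seed=s, error_rate=error_rate)
        results = sd.run_smooth_descent(
            bundle.G_observed, bundle.H, sd.SmoothDescentConfig()
        )
        prelim = sd.evaluate(results[0], bundle.G_true, bundle.positions)
        final = sd.evaluate(results[-1], bundle.G_true, bundle.positions)
        best = sd.evaluate(
            results[sd.best_iteration(results)], bundle.G_true, bundle.positions
        )
        rows.append({"prelim": prelim, "final": final, "best": best})
    return rows


@pytest.fixture(scope="session")
def sim_study():
    """Scaled replication of the 10%-error simulation study.

    Three diploid and tetraploid populations and two hexaploid ones, 100
    individuals x 200 markers each, 5 correction iterations.
    """
    return {
        2: run_study(2, [11, 12, 13]),
        4: run_study(4, [21, 22, 23]),
        6: run_study(6, [31, 32]),
    }
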