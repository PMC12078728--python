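import numpy as np
import pandas as pd
import pytest

from toxicoclust import (
    SimulationConfig,
    build_grid,
    classify_coclusters,
    cut_tree,
    agglomerate,
    generate_fcge,
    logistic_transform,
    pairwise_distance,
    rank_and_relabel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """A 4x3 labelled fold-change matrix with obvious structure."""
    return pd.DataFrame(
        [[3.0, 0.1, -0.2], [2.9, -0.1, 0.0], [-3.0, 0.2, 0.1], [-3.1, 0.0, -0.1]],
        index=["g1", "g2", "g3", "g4"],
        columns=["d1", "d2", "d3"],
    )


def run_default_pipeline(seed_or_rng, estimator="xbar_overall", mode="robust"):
    """One end-to-end run on a freshly simulated default matrix."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    f, truth = generate_fcge(SimulationConfig(), rng)
    x = logistic_transform(f) if mode == "robust" else f
    ga = cut_tree(agglomerate(pairwise_distance(x, "gene"), "ward.d2"), 4, "gene")
    da = cut_tree(agglomerate(pairwise_distance(x, "dc"), "ward.d2"), 3, "dc")
    grid = rank_and_relabel(build_grid(x, ga, da))
    grid, limits = classify_coclusters(grid, x=x, estimator=estimator)
    return f, x, truth, grid, limits


@pytest.fixture
def eq7_pipeline():
    return run_default_pipeline(7)
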