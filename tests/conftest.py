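"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from symptomnet.association import ItemResponseMatrix
from symptomnet.validation import glasso_objective, glasso_reference_solution

# the estimation stack warns about tolerance escalation on hard inputs;
# tests assert on results, not warnings
warnings.filterwarnings("ignore", message=".*loosening the dual-gap.*")

# the generic convex reference solution doubles as the unit-test oracle
glasso_oracle = glasso_reference_solution


NODE6 = [f"A{i}" for i in range(1, 4)] + [f"D{i}" for i in range(1, 4)]
COMM6 = {**{f"A{i}": "anxiety" for i in range(1, 4)},
         **{f"D{i}": "depression" for i in range(1, 4)}}


@pytest.fixture(scope="session")
def small_truth():
    """Planted 3+3 two-community network with one bridge edge of 0.3."""
    from symptomnet.simulate import make_ground_truth

    return make_ground_truth(
        p_anx=3, p_dep=3, within_density=0.2,
        bridge_spec=(("A1", "D1", 0.3),), seed=5,
    )


@pytest.fixture(scope="session")
def default_truth():
    """The default 17-node planted network with four bridge edges."""
    from symptomnet.simulate import make_ground_truth

    return make_ground_truth(seed=1)


@pytest.fixture(scope="session")
def default_data(default_truth):
    from symptomnet.simulate import sample_ordinal

    return sample_ordinal(default_truth, n=2000, seed=2)


@pytest.fixture
def toy_model():
    """3-node hand-built network: w12=0.3, w13=-0.1, w23=0."""
    from symptomnet.ggm import NetworkModel

    W = np.array([
        [0.0, 0.3, -0.1],
        [0.3, 0.0, 0.0],
        [-0.1, 0.0, 0.0],
    ])
    return NetworkModel(
        weights=W, node_labels=["X1", "X2", "X3"],
        community_of={"X1": "anxiety", "X2": "anxiety", "X3": "depression"},
        lambda_used=0.1, gamma_used=0.5,
    )


def iid_ordinal(n: int, p: int, seed: int) -> ItemResponseMatrix:
    """Independent uniform ordinal columns (true network empty)."""
    rng = np.random.default_rng(seed)
    labels = [f"A{i}" for i in range(1, p // 2 + 1)] + [
        f"D{i}" for i in range(1, p - p // 2 + 1)
    ]
    comm = {lab: ("anxiety" if lab.startswith("A") else "depression")
            for lab in labels}
    return ItemResponseMatrix(
        rng.integers(0, 4, size=(n, p)).astype(float), labels, comm
    )
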