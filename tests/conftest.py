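"""Shared fixtures: small hand-built tables and reusable simulator output."""

import numpy as np
import pytest

from rankdyn import ModelParams, RankTable, simulate


@pytest.fixture
def tiny_table() -> RankTable:
    """Two observations, three ranks: (A,B,C) -> (A,C,D)."""
    return RankTable(occupants=[["A", "B", "C"], ["A", "C", "D"]])


@pytest.fixture
def static_table() -> RankTable:
    return RankTable(occupants=[["A", "B", "C"]] * 4)


def make_random_table(seed: int, t: int = 4, n0: int = 5, pool: int = 8) -> RankTable:
    """Random valid table: each observation is a sample from a fixed id pool."""
    rng = np.random.default_rng(seed)
    ids = [f"id{i}" for i in range(pool)]
    occupants = [
        list(rng.choice(ids, size=n0, replace=False)) for _ in range(t)
    ]
    return RankTable(occupants=occupants)


@pytest.fixture(scope="session")
def sim_table_open() -> RankTable:
    """Moderately open simulated system reused across tests."""
    return simulate(ModelParams(N=150, N0=100, tau=0.1, nu=0.05, T=200, seed=11))


@pytest.fixture(scope="session")
def sim_params_open() -> ModelParams:
    return ModelParams(N=150, N0=100, tau=0.1, nu=0.05, T=200, seed=11)
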