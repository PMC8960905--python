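"""Stochastic displacement-replacement dynamics on an ordered list.

The system holds ``N`` totally ordered elements; only the top ``N0`` ranks
are observed.  Each micro-step lasts ``1/N`` time units and applies two
independent Bernoulli events:

* with probability ``tau`` a uniformly chosen element is removed and
  re-inserted at a uniformly chosen rank (elements in between shift by one);
* with probability ``nu`` a uniformly chosen element is replaced in place by
  a brand-new element, leaving all other ranks untouched.

``N`` micro-steps make up one observation interval, so over a unit of time
each element jumps with probability ``~tau/N`` per micro-step (exponential
survival ``e^{-tau t}`` in the large-N limit) and is replaced at total rate
``nu``.

Two drivers are provided: :func:`simulate` evolves the full list and records
the top-``N0`` view as a :class:`~rankdyn.rank_records.RankTable`, while
:func:`track_displacements` follows a single tagged element through its exact
marginal dynamics, vectorized over many independent realizations (the rank of
a uniformly chosen *other* element is itself uniform, so the marginal chain
closes without simulating the whole list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .observables import DisplacementHistogram
from .rank_records import RankTable

__all__ = [
    "ModelParams",
    "SystemState",
    "initial_state",
    "step",
    "simulate",
    "track_displacements",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one displacement-replacement run."""

    N: int
    N0: int
    tau: float
    nu: float
    T: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.N0 <= self.N):
            raise ValueError(f"need 1 <= N0 <= N, got N0={self.N0}, N={self.N}")
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")
        if not (0.0 <= self.nu <= 1.0):
            raise ValueError(f"nu must be in [0, 1], got {self.nu}")
        if self.T < 2:
            raise ValueError(f"need T >= 2 observations, got {self.T}")

    @property
    def p(self) -> float:
        """Relative list size N0/N."""
        return self.N0 / self.N


@dataclass
class SystemState:
    """Full ordered system: position in ``order`` equals rank - 1."""

    order: list[int]
    next_id: int
    clock: float = 0.0


def initial_state(params: ModelParams) -> SystemState:
    return SystemState(order=list(range(params.N)), next_id=params.N, clock=0.0)


def _displace(order: list[int], src: int, dst: int) -> None:
    """Move the element at 0-based position src to position dst (shift rule)."""
    el = order.pop(src)
    order.insert(dst, el)


def step(state: SystemState, params: ModelParams, rng: np.random.Generator) -> SystemState:
    """Apply one micro-step of duration 1/N in place and return the state.

    Draw order: displacement coin, (element, target) if it fires, replacement
    coin, position if it fires.  Displacement is applied before replacement
    when both fire.
    """
    N = params.N
    if rng.random() < params.tau:
        src = int(rng.integers(N))
        dst = int(rng.integers(N))
        _displace(state.order, src, dst)
    if rng.random() < params.nu:
        pos = int(rng.integers(N))
        state.order[pos] = state.next_id
        state.next_id += 1
    state.clock += 1.0 / N
    return state


def simulate(params: ModelParams) -> RankTable:
    """Run the model and return the top-N0 view at t = 0..T-1.

    Deterministic given ``params.seed``.  For speed the random variates of a
    whole observation interval are drawn as blocks (coins first, then indices),
    so the stream layout differs from repeated :func:`step` calls; the applied
    dynamics are identical.
    """
    N, N0 = params.N, params.N0
    rng = np.random.default_rng(params.seed)
    order = list(range(N))
    next_id = N

    snapshots = [order[:N0].copy()]
    for _ in range(params.T - 1):
        coins = rng.random((N, 2))
        srcs = rng.integers(0, N, size=N)
        dsts = rng.integers(0, N, size=N)
        rpos = rng.integers(0, N, size=N)
        tau_fire = coins[:, 0] < params.tau
        nu_fire = coins[:, 1] < params.nu
        for i in np.nonzero(tau_fire | nu_fire)[0]:
            if tau_fire[i]:
                _displace(order, srcs[i], dsts[i])
            if nu_fire[i]:
                order[rpos[i]] = next_id
                next_id += 1
        snapshots.append(order[:N0].copy())

    occupants = [[f"e{el}" for el in snap] for snap in snapshots]
    return RankTable(occupants=occupants, interval_length=1.0)


def track_displacements(
    params: ModelParams,
    r: float,
    lags: Iterable[int],
    n_realizations: int,
    seed: int | None = None,
) -> dict[int, DisplacementHistogram]:
    """Monte-Carlo distribution of a tagged element's rank after each lag.

    The element starts at rank ``round(r * N)``; ``r`` must be a grid point
    in {1/N, ..., 1}.  Replaced realizations stop contributing mass (they form
    the deficit); each histogram also reports the surviving fraction and the
    fraction of realizations whose tagged element never performed a jump of
    its own (both have exponential large-N limits).
    """
    N = params.N
    R0 = int(round(r * N))
    if not (1 <= R0 <= N) or abs(R0 - r * N) > 1e-9:
        raise ValueError(f"r must be one of 1/N..1 on the N={N} grid, got {r}")
    lags = sorted(set(int(t) for t in lags))
    if any(t < 0 for t in lags):
        raise ValueError("lags must be non-negative")
    if n_realizations < 1:
        raise ValueError("n_realizations must be positive")
    warning = (
        f"only {n_realizations} realizations; estimates will be noisy"
        if n_realizations < 100
        else None
    )

    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = n_realizations
    R = np.full(n, R0, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    jumped = np.zeros(n, dtype=bool)

    def snapshot(lag: int) -> DisplacementHistogram:
        counts = np.bincount(R[alive], minlength=N + 1)[1:].astype(float)
        return DisplacementHistogram(
            lag=lag,
            source_rank=R0 / N,
            grid=np.arange(1, N + 1) / N,
            dx=1.0 / N,
            mass=counts / n,
            n_tracked=n,
            survival=float(alive.mean()),
            never_jumped=float((~jumped).mean()),
            warning=warning,
        )

    out: dict[int, DisplacementHistogram] = {}
    done = 0
    for lag in lags:
        for _ in range((lag - done) * N):
            u = rng.random(n)
            pick = rng.integers(1, N + 1, size=n)
            dst = rng.integers(1, N + 1, size=n)
            v = rng.random(n)
            rpos = rng.integers(1, N + 1, size=n)

            jump = u < params.tau
            focal = jump & (pick == R)
            other = jump & ~focal
            # another element moved: removal below us pulls us down one,
            # insertion at or above our (post-removal) rank pushes us up one
            R_shift = R - (other & (pick < R))
            R_shift += other & (dst <= R_shift)
            R = np.where(focal, dst, R_shift)
            jumped |= focal
            alive &= ~((v < params.nu) & (rpos == R))
        done = lag
        out[lag] = snapshot(lag)
    return out
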