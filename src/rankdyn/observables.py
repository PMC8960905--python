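"""Empirical rank statistics: flux, turnover, rank change, displacement.

All quantities are measured directly on a :class:`~rankdyn.rank_records.RankTable`:

* rank flux ``F_t``: fraction of the list that is exchanged between
  consecutive observations, and its time average ``F``;
* rank turnover ``o_t``: cumulative count of distinct elements ever listed,
  relative to the list size, and its mean rate;
* rank change ``C(R)``: per-rank probability that the occupant of a rank cell
  differs between consecutive observations;
* displacement histograms: where the element occupying a given rank ends up
  after a fixed lag, with the mass deficit recording elements that dropped
  off the list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .rank_records import RankTable

__all__ = [
    "FluxTurnoverSummary",
    "RankChangeProfile",
    "DisplacementHistogram",
    "rank_flux",
    "rank_turnover",
    "measure_flux_turnover",
    "rank_change",
    "displacement_histogram",
    "smooth_histogram",
]


@dataclass
class FluxTurnoverSummary:
    """Flux and turnover series of one rank table.

    ``flux_series[i]`` is ``F_t`` for ``t = i + 1``; ``turnover_series[t]``
    is ``o_t = N_t / N0`` with ``N_t`` the number of distinct ids seen up to
    (and including) time ``t``.
    """

    flux_series: np.ndarray
    mean_flux: float
    new_element_counts: np.ndarray
    turnover_series: np.ndarray
    mean_turnover_rate: float


@dataclass
class RankChangeProfile:
    """Per-rank occupant-change probability C(R), R = 1..N0."""

    change_prob: np.ndarray


@dataclass
class DisplacementHistogram:
    """Estimated probability mass of normalized destination ranks at a lag.

    ``mass[i]`` is the probability that a tracked element sits in the grid
    cell centred at ``grid[i]`` (cell width ``dx``).  The total mass can be
    below one: the deficit counts tracked elements that are no longer listed.
    """

    lag: int
    source_rank: float
    grid: np.ndarray
    dx: float
    mass: np.ndarray
    n_tracked: int
    smoothed: bool = False
    survival: float | None = None
    never_jumped: float | None = None
    warning: str | None = None


def measure_flux_turnover(table: RankTable) -> FluxTurnoverSummary:
    """Compute flux and turnover series in a single pass over the table."""
    n0 = table.list_size
    T = table.n_times
    sets = [table.id_set(t) for t in range(T)]

    flux = np.empty(T - 1)
    for t in range(1, T):
        flux[t - 1] = len(sets[t] - sets[t - 1]) / n0

    counts = np.empty(T, dtype=int)
    seen: set[str] = set()
    for t in range(T):
        seen |= sets[t]
        counts[t] = len(seen)
    turnover = counts / n0
    o_dot = (turnover[-1] - turnover[0]) / (T - 1)
    return FluxTurnoverSummary(
        flux_series=flux,
        mean_flux=float(flux.mean()),
        new_element_counts=counts,
        turnover_series=turnover,
        mean_turnover_rate=float(o_dot),
    )


def rank_flux(table: RankTable) -> FluxTurnoverSummary:
    """Flux series F_t and mean flux F (full summary returned for convenience)."""
    return measure_flux_turnover(table)


def rank_turnover(table: RankTable) -> FluxTurnoverSummary:
    """Turnover series o_t and mean turnover rate (full summary returned)."""
    return measure_flux_turnover(table)


def rank_change(table: RankTable) -> RankChangeProfile:
    """Probability that the occupant of each rank cell changes per step."""
    T = table.n_times
    n0 = table.list_size
    changes = np.zeros(n0)
    for t in range(1, T):
        prev, cur = table.occupants[t - 1], table.occupants[t]
        for i in range(n0):
            if prev[i] != cur[i]:
                changes[i] += 1
    return RankChangeProfile(change_prob=changes / (T - 1))


def displacement_histogram(
    table: RankTable,
    lag: int,
    source_ranks: tuple[int, int] | None = None,
    normalization: str = "by_list_N0",
) -> DisplacementHistogram:
    """Empirical distribution of normalized rank after ``lag`` steps.

    Every (reference time, source rank) pair with the source rank inside
    ``source_ranks`` (inclusive integer bounds; default: the whole list)
    contributes one tracked element.  Elements absent at the later time are
    counted in the mass deficit.  ``normalization`` chooses the rank
    denominator: the list size ``N0`` (default) or the number of distinct
    elements ever seen (``by_system_N``), the latter matching the model's
    system-size normalization.
    """
    if lag < 0 or lag > table.n_times - 1:
        raise ValueError(f"lag must be in 0..T-1, got {lag}")
    if normalization == "by_list_N0":
        n_norm = table.list_size
    elif normalization == "by_system_N":
        n_norm = len(table.all_ids())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    n0 = table.list_size
    lo, hi = source_ranks if source_ranks is not None else (1, n0)
    if not (1 <= lo <= hi <= n0):
        raise ValueError(f"source rank bin ({lo}, {hi}) outside 1..{n0}")

    counts = np.zeros(n0)
    n_tracked = 0
    for t0 in range(table.n_times - lag):
        later = table.rank_of(t0 + lag)
        row = table.occupants[t0]
        for r in range(lo, hi + 1):
            n_tracked += 1
            dest = later.get(row[r - 1])
            if dest is not None:
                counts[dest - 1] += 1

    mass = counts / n_tracked if n_tracked else counts
    return DisplacementHistogram(
        lag=lag,
        source_rank=(lo + hi) / 2.0 / n_norm,
        grid=np.arange(1, n0 + 1) / n_norm,
        dx=1.0 / n_norm,
        mass=mass,
        n_tracked=n_tracked,
        survival=float(mass.sum()) if n_tracked else None,
        warning=None if n_tracked else "empty source bin",
    )


def smooth_histogram(
    hist: DisplacementHistogram, window: int = 11, polyorder: int = 3
) -> DisplacementHistogram:
    """Savitzky-Golay smoothing of the histogram mass (negatives clipped)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window >= len(hist.grid):
        raise ValueError(
            f"window {window} too large for grid of length {len(hist.grid)}"
        )
    smoothed = np.clip(savgol_filter(hist.mass, window, polyorder), 0.0, None)
    return replace(hist, mass=smoothed, smoothed=True)
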