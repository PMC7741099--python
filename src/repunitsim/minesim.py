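"""Duration-effect experiment: constant occupancy, shrinking use-lives.

A fixed number of production sites (copper mines) is active in every year of
a millennium-long window: whenever a mine is abandoned, a replacement is
founded immediately, so the true activity level is flat by construction.
What changes through time is only the expected use-life of an individual
mine — declining linearly from 200 years at the start of the window to 10
years at its end — with individual durations drawn from a shifted negative
binomial (the standard overdispersed waiting-time-to-failure model).

The naive archaeological count — how many distinct mines have remains that
date to a given time block, ignoring duration — rises steeply toward the
present even though true activity never changes.  That contrast is the
experiment's point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeline import BinnedSeries

__all__ = [
    "DurationModel",
    "MineRecord",
    "mean_duration",
    "draw_duration",
    "simulate_mines",
    "in_use_counts",
    "naive_mine_count",
    "mines_to_frame",
    "sample_mine_years",
    "select_mines_near",
]


@dataclass(frozen=True)
class DurationModel:
    """Expected use-life declines linearly across the window.

    ``mean_start`` years at ``t_start`` down to ``mean_end`` years at
    ``t_end``, clamped to the endpoint values outside the window.
    ``dispersion`` is the negative-binomial size parameter k (smaller k,
    more variable use-lives).
    """

    t_start: int = -1750
    t_end: int = -750
    mean_start: float = 200.0
    mean_end: float = 10.0
    dispersion: float = 2.0

    def __post_init__(self):
        if self.t_start >= self.t_end:
            raise ValueError("empty model window")
        if self.dispersion <= 0:
            raise ValueError("dispersion k must be positive")
        if min(self.mean_start, self.mean_end) < 1:
            raise ValueError("mean duration must stay >= 1 year")


def mean_duration(model: DurationModel, t) -> np.ndarray | float:
    """Expected use-life (years) for a mine founded at year ``t``."""
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - model.t_start) / (model.t_end - model.t_start), 0.0, 1.0)
    out = model.mean_start + frac * (model.mean_end - model.mean_start)
    return out if out.ndim else float(out)


def draw_duration(
    model: DurationModel, t, rng: np.random.Generator
) -> np.ndarray | int:
    """Random integer use-life (years, >= 1) for founding year(s) ``t``.

    ``X ~ NegBin(mean = mean_duration(t) - 1, size = k)`` and the draw is
    ``X + 1``, so the analytic mean is exactly ``mean_duration(t)`` and a
    zero-length use-life is impossible.
    """
    mu = np.asarray(mean_duration(model, t), dtype=float) - 1.0
    if np.any(mu < 0):
        raise ValueError("mean duration below 1 year")
    scalar = mu.ndim == 0
    mu = np.atleast_1d(mu)
    out = np.ones_like(mu, dtype=int)
    pos = mu > 0
    if pos.any():
        k = model.dispersion
        p = k / (k + mu[pos])  # NB success prob: mean = k(1-p)/p
        out[pos] = 1 + rng.negative_binomial(k, p)
    return int(out[0]) if scalar else out


@dataclass(frozen=True)
class MineRecord:
    """One mine's use-life interval ``[founded, abandoned)``."""

    id: str
    founded: int
    abandoned: int

    def __post_init__(self):
        if self.duration < 1:
            raise ValueError(f"mine {self.id!r}: duration must be >= 1 year")

    @property
    def duration(self) -> int:
        return self.abandoned - self.founded


def simulate_mines(
    n_active: int, model: DurationModel, rng: np.random.Generator
) -> list[MineRecord]:
    """Simulate the turnover process with exactly ``n_active`` mines in use.

    All ``n_active`` slots are founded at the window start (the initial age
    structure is not otherwise constrained, so every slot starts fresh; the
    resulting start-up transient in naive counts is documented and the first
    reporting bin can be discarded downstream).  Each abandonment triggers an
    immediate replacement whose duration is drawn at its founding year.
    Records open at the window end are truncated there, so the total
    mine-years always equal ``n_active * (t_end - t_start)``.
    """
    if n_active < 1:
        raise ValueError("n_active must be >= 1")
    mines: list[MineRecord] = []
    counter = 0
    for _ in range(n_active):
        t = model.t_start
        while t < model.t_end:
            dur = draw_duration(model, t, rng)
            abandoned = min(t + int(dur), model.t_end)
            mines.append(MineRecord(f"m{counter}", t, abandoned))
            counter += 1
            t = abandoned
    return mines


def in_use_counts(mines: list[MineRecord], t_start: int, t_end: int) -> np.ndarray:
    """Number of mines in use at every year of ``[t_start, t_end)``."""
    years = np.arange(t_start, t_end)
    delta = np.zeros(len(years) + 1, dtype=int)
    for m in mines:
        lo = max(m.founded, t_start) - t_start
        hi = min(m.abandoned, t_end) - t_start
        if hi > lo:
            delta[lo] += 1
            delta[hi] -= 1
    return np.cumsum(delta[:-1])


def naive_mine_count(mines: list[MineRecord], bins) -> BinnedSeries:
    """Distinct mines whose use-life intersects each bin.

    This is the count an observer makes when duration is unknown: a mine is
    tallied once in every time block its remains could date to, however
    briefly it overlapped.  Short-lived mines therefore inflate late blocks
    relative to the flat truth.
    """
    bins = np.asarray(bins, dtype=float)
    if mines:
        lo = min(m.founded for m in mines)
        hi = max(m.abandoned for m in mines)
        if lo < bins[0] or hi > bins[-1]:
            raise ValueError("bins do not cover the simulation window")
    counts = np.zeros(len(bins) - 1)
    for m in mines:
        first = int(np.searchsorted(bins, m.founded, side="right")) - 1
        last = int(np.searchsorted(bins, m.abandoned - 1, side="right")) - 1
        counts[first:last + 1] += 1
    return BinnedSeries(bins, counts)


def sample_mine_years(
    mine: MineRecord, n_dates: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_dates`` i.i.d. uniform integer calendar years within the use-life."""
    if n_dates < 1:
        raise ValueError("n_dates must be >= 1")
    return rng.integers(mine.founded, mine.abandoned, size=n_dates)


def select_mines_near(
    mines: list[MineRecord],
    target_years=(-1700, -1250, -800),
    per_target: int = 5,
) -> dict[int, list[MineRecord]]:
    """Pick the ``per_target`` mines founded nearest each target year.

    Mimics selecting dated mines from early, middle and late parts of the
    sequence.  A mine is assigned to at most one target (nearest first).
    """
    chosen: dict[int, list[MineRecord]] = {}
    used: set[str] = set()
    for ty in target_years:
        ranked = sorted(
            (m for m in mines if m.id not in used),
            key=lambda m: (abs(m.founded - ty), m.founded, m.id),
        )
        picks = ranked[:per_target]
        used.update(m.id for m in picks)
        chosen[ty] = picks
    return chosen


def mines_to_frame(mines: list[MineRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [m.id for m in mines],
            "founded": [m.founded for m in mines],
            "abandoned": [m.abandoned for m in mines],
        }
    )
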