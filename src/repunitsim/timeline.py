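"""Calendar phases and the chronological-uncertainty calculus.

Time is a signed integer axis of calendar years: BCE years are negative
(1750 BCE -> -1750) and time increases toward the present.  No year-zero
adjustment is made; the axis is purely arithmetic.  All intervals (phases,
bins, mine use-lives) are half-open ``[start, end)``.

Three layers of chronological uncertainty are modelled:

* *phase-assignment uncertainty* — an event carries a probability vector
  over candidate phases;
* *within-phase uncertainty* — the unknown position of an event inside its
  phase, modelled as uniform or as a trapezium distribution;
* *phase-boundary uncertainty* — the trapezium corners ``a <= b <= c <= d``
  may themselves be jittered between Monte Carlo repetitions.

The trapezium density rises linearly on ``[a, b]``, is flat at height
``h = 2 / ((c + d) - (a + b))`` on ``[b, c]`` and falls linearly on
``[c, d]``.  With ``a == b`` and ``c == d`` it degenerates to the uniform
distribution on ``[b, c]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Periodization",
    "TrapeziumDistribution",
    "EventSet",
    "BinnedSeries",
    "year_to_calbp",
    "calbp_to_year",
    "trapezium_pdf",
    "trapezium_cdf",
    "trapezium_ppf",
    "make_bins",
    "trapezium_interval_prob",
    "trapezium_sample",
    "jitter_boundaries",
    "sample_event_year",
    "mc_aoristic",
    "AoristicResult",
]

PHASE_PROB_TOL = 1e-9


# ---------------------------------------------------------------------------
# calendar helpers

def year_to_calbp(year):
    """Convert signed calendar year to calendar years BP (BP = 1950 - year)."""
    return 1950 - np.asarray(year)


def calbp_to_year(calbp):
    """Convert calendar years BP to a signed calendar year."""
    return 1950 - np.asarray(calbp)


# ---------------------------------------------------------------------------
# phases

@dataclass(frozen=True)
class Phase:
    """A named calendar interval ``[start, end)`` used as a reporting unit."""

    id: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"phase {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start

    def __contains__(self, year) -> bool:
        return self.start <= year < self.end


@dataclass(frozen=True)
class Periodization:
    """An ordered, non-overlapping sequence of phases.

    Contiguity (``end_i == start_{i+1}``) is required only when
    ``require_contiguous=True``; the periodization-effect experiments use
    contiguous slicings of the study window.
    """

    phases: tuple[Phase, ...]
    require_contiguous: bool = False

    def __init__(self, phases: Iterable[Phase], require_contiguous: bool = False):
        phases = tuple(sorted(phases, key=lambda p: p.start))
        if not phases:
            raise ValueError("periodization needs at least one phase")
        ids = [p.id for p in phases]
        if len(set(ids)) != len(ids):
            raise ValueError("phase ids must be unique")
        for left, right in zip(phases, phases[1:]):
            if right.start < left.end:
                raise ValueError(
                    f"phases {left.id!r} and {right.id!r} overlap"
                )
            if require_contiguous and right.start != left.end:
                raise ValueError(
                    f"gap between phases {left.id!r} and {right.id!r}"
                )
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "require_contiguous", require_contiguous)

    @property
    def start(self) -> int:
        return self.phases[0].start

    @property
    def end(self) -> int:
        return self.phases[-1].end

    def __iter__(self):
        return iter(self.phases)

    def __len__(self):
        return len(self.phases)

    def __getitem__(self, phase_id: str) -> Phase:
        for p in self.phases:
            if p.id == phase_id:
                return p
        raise KeyError(phase_id)

    def phase_of(self, year) -> Phase:
        """The unique phase containing ``year`` (half-open convention)."""
        for p in self.phases:
            if year in p:
                return p
        raise ValueError(f"year {year} falls outside all phases")

    @classmethod
    def from_csv(cls, path, require_contiguous: bool = False) -> "Periodization":
        """Read ``phase_id,start_year,end_year`` (signed years)."""
        df = pd.read_csv(path)
        required = {"phase_id", "start_year", "end_year"}
        if not required.issubset(df.columns):
            raise ValueError(f"periodization CSV needs columns {sorted(required)}")
        phases = [
            Phase(str(r.phase_id), int(r.start_year), int(r.end_year))
            for r in df.itertuples()
        ]
        return cls(phases, require_contiguous=require_contiguous)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase_id": [p.id for p in self.phases],
                "start_year": [p.start for p in self.phases],
                "end_year": [p.end for p in self.phases],
            }
        )


# ---------------------------------------------------------------------------
# trapezium distribution

@dataclass(frozen=True)
class TrapeziumDistribution:
    """Piecewise-linear density with corners ``a <= b <= c <= d``, ``d > a``.

    A degenerate trapezium with ``a == d`` (a point mass) is rejected.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(
                f"trapezium parameters must satisfy a <= b <= c <= d, "
                f"got a={self.a}, b={self.b}, c={self.c}, d={self.d}"
            )
        if not self.d > self.a:
            raise ValueError("degenerate trapezium (a == d) is not a distribution")

    @property
    def height(self) -> float:
        """Flat-top density ``h = 2 / ((c + d) - (a + b))``."""
        return 2.0 / ((self.c + self.d) - (self.a + self.b))

    @classmethod
    def uniform(cls, start: float, end: float) -> "TrapeziumDistribution":
        return cls(start, start, end, end)

    @classmethod
    def from_phase(cls, phase: Phase, widen: float = 0.0) -> "TrapeziumDistribution":
        """Trapezium whose flat top spans the phase, ramps widened by a
        fraction ``widen`` of the phase duration on each side."""
        w = widen * phase.duration
        return cls(phase.start - w, phase.start, phase.end, phase.end + w)


def trapezium_pdf(dist: TrapeziumDistribution, t) -> np.ndarray | float:
    """Density per year of the trapezium at ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    h = dist.height
    out = np.zeros_like(t)
    if dist.b > dist.a:
        rise = (t >= dist.a) & (t < dist.b)
        out = np.where(rise, h * (t - dist.a) / (dist.b - dist.a), out)
    flat = (t >= dist.b) & (t <= dist.c)
    out = np.where(flat, h, out)
    if dist.d > dist.c:
        fall = (t > dist.c) & (t <= dist.d)
        out = np.where(fall, h * (dist.d - t) / (dist.d - dist.c), out)
    return out if out.ndim else float(out)


def trapezium_cdf(dist: TrapeziumDistribution, t) -> np.ndarray | float:
    """Closed-form CDF of the trapezium."""
    t = np.asarray(t, dtype=float)
    a, b, c, d = dist.a, dist.b, dist.c, dist.d
    h = dist.height
    tc = np.clip(t, a, d)
    out = np.zeros_like(tc)
    # rising ramp: area of the partial triangle
    if b > a:
        seg = np.clip(tc, a, b)
        out += 0.5 * h * (seg - a) ** 2 / (b - a)
    # flat top
    seg = np.clip(tc, b, c)
    out += h * (seg - b)
    # falling ramp: full triangle minus the remaining tail triangle
    if d > c:
        seg = np.clip(tc, c, d)
        out += 0.5 * h * (d - c) - 0.5 * h * (d - seg) ** 2 / (d - c)
    out = np.where(t >= d, 1.0, out)
    return out if out.ndim else float(out)


def trapezium_interval_prob(dist: TrapeziumDistribution, t0: float, t1: float) -> float:
    """Exact probability that an event falls in ``[t0, t1]``."""
    if t0 > t1:
        raise ValueError(f"interval reversed: t0={t0} > t1={t1}")
    return float(trapezium_cdf(dist, t1) - trapezium_cdf(dist, t0))


def trapezium_sample(
    dist: TrapeziumDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` i.i.d. draws via inverse-CDF sampling."""
    if n < 0:
        raise ValueError("n must be non-negative")
    u = rng.random(n)
    return trapezium_ppf(dist, u)


def trapezium_ppf(dist: TrapeziumDistribution, u) -> np.ndarray:
    """Inverse CDF (quantile function) of the trapezium."""
    u = np.asarray(u, dtype=float)
    a, b, c, d = dist.a, dist.b, dist.c, dist.d
    h = dist.height
    f_b = trapezium_cdf(dist, b)  # mass of the rising ramp
    f_c = trapezium_cdf(dist, c)  # mass up to the end of the flat top
    out = np.empty_like(u)

    lo = u <= f_b
    if b > a:
        out[lo] = a + np.sqrt(2.0 * u[lo] * (b - a) / h)
    else:
        out[lo] = a

    mid = (u > f_b) & (u <= f_c)
    out[mid] = b + (u[mid] - f_b) / h

    hi = u > f_c
    if d > c:
        out[hi] = d - np.sqrt(2.0 * (1.0 - u[hi]) * (d - c) / h)
    else:
        out[hi] = d
    return out


def jitter_boundaries(
    dist: TrapeziumDistribution,
    uncertainty: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> TrapeziumDistribution:
    """Draw a new trapezium with corners perturbed inside given intervals.

    ``uncertainty`` maps any of ``'a','b','c','d'`` to a sampling interval
    ``(lo, hi)``; omitted corners stay fixed.  Draws violating
    ``a <= b <= c <= d`` are rejected and redrawn; if the intervals admit no
    valid ordering at all a ``ValueError`` is raised.
    """
    unknown = set(uncertainty) - {"a", "b", "c", "d"}
    if unknown:
        raise ValueError(f"unknown trapezium corners in uncertainty spec: {unknown}")
    base = {"a": dist.a, "b": dist.b, "c": dist.c, "d": dist.d}
    intervals = {}
    for k in "abcd":
        lo, hi = uncertainty.get(k, (base[k], base[k]))
        if lo > hi:
            raise ValueError(f"uncertainty interval for {k!r} reversed: ({lo}, {hi})")
        intervals[k] = (lo, hi)
    # feasibility: smallest achievable a..d ordering must exist
    mins = [intervals[k][0] for k in "abcd"]
    maxs = [intervals[k][1] for k in "abcd"]
    if any(mins[i] > maxs[j] for i in range(4) for j in range(i + 1, 4)):
        raise ValueError("uncertainty spec admits no ordering with a <= b <= c <= d")
    if all(lo == hi for lo, hi in intervals.values()):
        return TrapeziumDistribution(*(intervals[k][0] for k in "abcd"))
    for _ in range(max_tries):
        draw = [
            rng.uniform(*intervals[k]) if intervals[k][0] < intervals[k][1]
            else intervals[k][0]
            for k in "abcd"
        ]
        if draw[0] <= draw[1] <= draw[2] <= draw[3] and draw[3] > draw[0]:
            return TrapeziumDistribution(*draw)
    raise ValueError("could not draw a valid trapezium within the retry budget")


# ---------------------------------------------------------------------------
# events

class EventSet:
    """A collection of point events with known or uncertain timing.

    Each event has either a true calendar year (generator output), a
    phase-probability vector summing to 1 (analysis input), or both.
    ``phase_probs`` is a DataFrame with one row per event and one column per
    phase id.
    """

    def __init__(self, ids, true_years=None, phase_probs=None):
        self.ids = [str(i) for i in ids]
        n = len(self.ids)
        if true_years is None and phase_probs is None:
            raise ValueError("events need true years or phase probabilities")
        if true_years is not None:
            true_years = np.asarray(true_years, dtype=int)
            if true_years.shape != (n,):
                raise ValueError("true_years length mismatch")
        if phase_probs is not None:
            phase_probs = pd.DataFrame(phase_probs)
            if len(phase_probs) != n:
                raise ValueError("phase_probs length mismatch")
            sums = phase_probs.to_numpy(dtype=float).sum(axis=1)
            if np.any(np.abs(sums - 1.0) > PHASE_PROB_TOL):
                bad = self.ids[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValueError(f"phase probabilities of event {bad!r} do not sum to 1")
        self.true_years = true_years
        self.phase_probs = phase_probs

    def __len__(self):
        return len(self.ids)

    @classmethod
    def from_csv(cls, path) -> "EventSet":
        """Read either ``event_id,phase_id`` (point-mass labels) or the wide
        format ``event_id,p_<phase>...`` (probability vectors)."""
        df = pd.read_csv(path)
        if "event_id" not in df.columns:
            raise ValueError("event CSV needs an event_id column")
        if "phase_id" in df.columns:
            labels = df["phase_id"].astype(str)
            probs = pd.get_dummies(labels).astype(float)
            return cls(df["event_id"], phase_probs=probs)
        pcols = [c for c in df.columns if c.startswith("p_")]
        if not pcols:
            raise ValueError("event CSV needs a phase_id or p_<phase> columns")
        probs = df[pcols].astype(float)
        probs.columns = [c[2:] for c in pcols]
        return cls(df["event_id"], phase_probs=probs.reset_index(drop=True))


@dataclass(frozen=True)
class BinnedSeries:
    """Counts aggregated into half-open calendar bins."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __init__(self, bin_edges, counts):
        bin_edges = np.asarray(bin_edges, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if len(counts) != len(bin_edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(np.diff(bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", bin_edges)
        object.__setattr__(self, "counts", counts)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def make_bins(start: int, end: int, width: int) -> np.ndarray:
    """Half-open bin edges covering ``[start, end)`` in steps of ``width``."""
    edges = np.arange(start, end + width, width, dtype=float)
    if edges[-1] < end:
        edges = np.append(edges, float(end))
    return edges


# ---------------------------------------------------------------------------
# Monte Carlo aoristic redistribution

def sample_event_year(
    event_probs: Mapping[str, float],
    periodization: Periodization,
    rng: np.random.Generator,
    within_model: str = "uniform",
    trapezium_widen: float = 0.1,
) -> float:
    """Two-stage draw of one event year: phase, then position within it."""
    labels = list(event_probs.keys())
    probs = np.array([event_probs[k] for k in labels], dtype=float)
    if abs(probs.sum() - 1.0) > PHASE_PROB_TOL:
        raise ValueError("phase probabilities must sum to 1")
    phase = periodization[labels[rng.choice(len(labels), p=probs)]]
    return _draw_within(phase, 1, rng, within_model, trapezium_widen)[0]


def _draw_within(phase, n, rng, within_model, trapezium_widen):
    if within_model == "uniform":
        return rng.uniform(phase.start, phase.end, size=n)
    if within_model == "trapezium":
        dist = TrapeziumDistribution.from_phase(phase, widen=trapezium_widen)
        return trapezium_sample(dist, n, rng)
    raise ValueError(f"unknown within-phase model {within_model!r}")


@dataclass(frozen=True)
class AoristicResult:
    """Monte Carlo aoristic output: one binned series per repetition plus a
    per-bin envelope (mean and percentile band)."""

    bin_edges: np.ndarray
    matrix: np.ndarray          # n_sim x n_bins
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    percentiles: tuple[float, float]

    def envelope_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean": self.mean,
                "lo": self.lo,
                "hi": self.hi,
            }
        )


def mc_aoristic(
    events: EventSet,
    periodization: Periodization,
    bins: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
    within_model: str = "uniform",
    trapezium_widen: float = 0.1,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> AoristicResult:
    """Monte Carlo aoristic analysis.

    Each repetition re-simulates a calendar year for every event (phase drawn
    from its probability vector, year drawn from the within-phase model) and
    bins the years.  Every row of the output matrix therefore sums to the
    number of events: the redistribution conserves mass.
    """
    if events.phase_probs is None:
        raise ValueError("mc_aoristic needs phase-labelled events")
    bins = np.asarray(bins, dtype=float)
    for phase in periodization:
        if phase.start < bins[0] or phase.end > bins[-1]:
            raise ValueError(
                f"bins do not cover phase {phase.id!r} "
                f"([{phase.start}, {phase.end}) vs [{bins[0]}, {bins[-1]}))"
            )
    labels = list(events.phase_probs.columns)
    for lab in labels:
        periodization[lab]  # KeyError if a label has no phase
    probs = events.phase_probs[labels].to_numpy(dtype=float)
    n_events = len(events)
    n_bins = len(bins) - 1
    starts = np.array([periodization[lab].start for lab in labels], dtype=float)
    widths = np.array([periodization[lab].duration for lab in labels], dtype=float)

    matrix = np.empty((n_sim, n_bins), dtype=float)
    cum = np.cumsum(probs, axis=1)
    for s in range(n_sim):
        u = rng.random(n_events)
        phase_idx = (u[:, None] > cum).sum(axis=1)
        if within_model == "uniform":
            years = starts[phase_idx] + rng.random(n_events) * widths[phase_idx]
        else:
            years = np.empty(n_events)
            for j, lab in enumerate(labels):
                sel = phase_idx == j
                if sel.any():
                    years[sel] = _draw_within(
                        periodization[lab], int(sel.sum()), rng,
                        within_model, trapezium_widen,
                    )
        matrix[s], _ = np.histogram(years, bins=bins)

    lo, hi = np.percentile(matrix, percentiles, axis=0)
    return AoristicResult(
        bin_edges=bins,
        matrix=matrix,
        mean=matrix.mean(axis=0),
        lo=lo,
        hi=hi,
        percentiles=percentiles,
    )
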