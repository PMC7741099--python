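"""Radiocarbon machinery: curves, back-calibration, and span estimation.

A calibration curve maps calendar age BP to an expected radiocarbon age with
a per-point standard error; queries interpolate linearly between the
tabulated knots.  ``back_calibrate`` simulates a laboratory measurement from
a known calendar year (curve mean plus combined curve and lab noise);
``calibrate`` inverts a measurement into a posterior density over calendar
years on an integer-year grid.

``span_posterior`` is a simplified Bayesian uniform-phase model of the
elapsed time between the start and end of an episode of activity: each
date's true calendar year is assumed uniform on an unknown interval
``[s, e]``, the marginal likelihood of ``(s, e)`` is the product over dates
of the average calibration likelihood across the interval, and the posterior
is evaluated exactly on a 2-D grid (no MCMC).  The marginal over the span
``e - s`` is the quantity of interest.

A synthetic curve generator provides an identity curve (calendar age equals
radiocarbon age) and a plateau variant in which the radiocarbon age is
constant across a chosen calendar stretch — reproducing the mechanism by
which a calibration plateau (such as the one around 800-400 BCE) smears
single dates across centuries and inflates span estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .timeline import calbp_to_year, year_to_calbp

__all__ = [
    "CalibrationCurve",
    "C14Determination",
    "CalibratedDensity",
    "SpanPosterior",
    "read_curve",
    "synthetic_curve",
    "back_calibrate",
    "calibrate",
    "span_posterior",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Tabulated (calendar age BP, ¹⁴C age BP, 1σ error), linear interpolation."""

    calbp: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __init__(self, calbp, mu, sigma):
        calbp = np.asarray(calbp, dtype=float)
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if calbp.ndim != 1 or len(calbp) < 2:
            raise ValueError("curve needs at least 2 rows")
        if len(mu) != len(calbp) or len(sigma) != len(calbp):
            raise ValueError("curve columns must have equal length")
        order = np.argsort(calbp)
        calbp, mu, sigma = calbp[order], mu[order], sigma[order]
        if np.any(np.diff(calbp) <= 0):
            raise ValueError("calendar ages must be strictly monotone")
        if np.any(sigma <= 0):
            raise ValueError("curve errors must be positive")
        object.__setattr__(self, "calbp", calbp)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def calbp_min(self) -> float:
        return float(self.calbp[0])

    @property
    def calbp_max(self) -> float:
        return float(self.calbp[-1])

    def _check_domain(self, calbp):
        calbp = np.asarray(calbp, dtype=float)
        if np.any(calbp < self.calbp_min) or np.any(calbp > self.calbp_max):
            raise ValueError(
                f"query outside curve domain "
                f"[{self.calbp_min}, {self.calbp_max}] cal BP"
            )
        return calbp

    def mu_at(self, calbp):
        return np.interp(self._check_domain(calbp), self.calbp, self.mu)

    def sigma_at(self, calbp):
        return np.interp(self._check_domain(calbp), self.calbp, self.sigma)

    def year_domain(self) -> tuple[int, int]:
        """Curve domain as signed calendar years (min, max)."""
        years = calbp_to_year(self.calbp)
        return int(np.ceil(years.min())), int(np.floor(years.max()))


@dataclass(frozen=True)
class C14Determination:
    """A laboratory radiocarbon measurement: age and 1σ error, ¹⁴C years BP."""

    c14_age: float
    sigma_lab: float

    def __post_init__(self):
        if self.sigma_lab <= 0:
            raise ValueError("sigma_lab must be positive")


def read_curve(path_or_buffer, strict: bool = False) -> CalibrationCurve:
    """Read a three-column calibration-curve table.

    Lines starting with '#' are skipped; columns may be comma- or
    whitespace-separated.  Out-of-order rows are sorted by calendar age
    unless ``strict=True``, in which case they are rejected.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise ValueError(f"malformed curve line: {line!r}")
        rows.append([float(x) for x in parts[:3]])
    if len(rows) < 2:
        raise ValueError("curve file needs at least 2 data rows")
    arr = np.array(rows)
    if strict and np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError("curve rows out of order (strict mode)")
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2])


def synthetic_curve(
    kind: str = "identity",
    calbp_min: float = 2000.0,
    calbp_max: float = 4000.0,
    sigma_curve: float = 10.0,
    plateau: tuple[float, float] | None = None,
    step: float = 1.0,
) -> CalibrationCurve:
    """Build a synthetic calibration curve over ``[calbp_min, calbp_max]``.

    ``identity``: ¹⁴C age equals calendar age everywhere.  ``plateau``: the
    ¹⁴C age is constant across the calendar interval ``plateau=(lo, hi)``
    (cal BP); on the old side of the plateau the curve is the identity, and
    on the young side it is the identity shifted down by the plateau width so
    the curve stays continuous at both joins.
    """
    if calbp_min >= calbp_max:
        raise ValueError("empty curve window")
    calbp = np.arange(calbp_min, calbp_max + step, step, dtype=float)
    if kind == "identity":
        mu = calbp.copy()
    elif kind == "plateau":
        if plateau is None:
            raise ValueError("plateau curve needs plateau=(lo, hi) cal BP")
        lo, hi = sorted(float(x) for x in plateau)
        if lo < calbp_min or hi > calbp_max:
            raise ValueError("plateau interval outside the curve window")
        mu = np.where(
            calbp >= hi, calbp,                       # old side: identity
            np.where(calbp >= lo, hi,                 # plateau: constant
                     calbp + (hi - lo)),              # young side: shifted
        )
    else:
        raise ValueError(f"unknown synthetic curve kind {kind!r}")
    sigma = np.full_like(calbp, float(sigma_curve))
    return CalibrationCurve(calbp, mu, sigma)


def back_calibrate(
    cal_year: int,
    curve: CalibrationCurve,
    sigma_lab: float,
    rng: np.random.Generator,
) -> C14Determination:
    """Simulate a measured determination from a known calendar year.

    The ¹⁴C age is drawn from a Normal centred on the curve mean at that
    year with the curve and laboratory errors combined in quadrature, then
    rounded to integer ¹⁴C years.
    """
    calbp = float(year_to_calbp(cal_year))
    mu = float(curve.mu_at(calbp))
    sd = float(np.hypot(curve.sigma_at(calbp), sigma_lab))
    age = float(np.round(rng.normal(mu, sd))) if sd > 0 else float(np.round(mu))
    return C14Determination(c14_age=age, sigma_lab=sigma_lab)


@dataclass(frozen=True)
class CalibratedDensity:
    """Posterior over integer calendar years for a single determination."""

    years: np.ndarray
    probs: np.ndarray

    def mean(self) -> float:
        return float(np.sum(self.years * self.probs))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum((self.years - m) ** 2 * self.probs)))

    def mode(self) -> int:
        return int(self.years[int(np.argmax(self.probs))])

    def hpd_interval(self, level: float = 0.95) -> tuple[int, int]:
        """Smallest set of highest-density years holding ``level`` mass,
        reported as its enclosing interval."""
        order = np.argsort(self.probs)[::-1]
        cum = np.cumsum(self.probs[order])
        keep = order[: int(np.searchsorted(cum, level)) + 1]
        return int(self.years[keep].min()), int(self.years[keep].max())


def _cal_likelihood(det: C14Determination, curve: CalibrationCurve, years):
    calbp = year_to_calbp(years)
    mu = curve.mu_at(calbp)
    sd = np.hypot(curve.sigma_at(calbp), det.sigma_lab)
    return stats.norm.pdf(det.c14_age, loc=mu, scale=sd)


def calibrate(det: C14Determination, curve: CalibrationCurve) -> CalibratedDensity:
    """Single-date calibration on the curve's integer-year grid."""
    y0, y1 = curve.year_domain()
    years = np.arange(y0, y1 + 1)
    like = _cal_likelihood(det, curve, years)
    total = like.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("date has no mass on the curve domain")
    return CalibratedDensity(years=years, probs=like / total)


@dataclass(frozen=True)
class SpanPosterior:
    """Joint posterior over phase start/end and the span marginal."""

    s_grid: np.ndarray          # candidate start years
    e_grid: np.ndarray          # candidate end years
    joint: np.ndarray           # len(s_grid) x len(e_grid), sums to 1
    span_values: np.ndarray     # distinct spans e - s, ascending
    span_probs: np.ndarray      # marginal over span_values, sums to 1

    def span_quantile(self, q) -> np.ndarray | float:
        cum = np.cumsum(self.span_probs)
        idx = np.searchsorted(cum, np.asarray(q, dtype=float))
        idx = np.clip(idx, 0, len(self.span_values) - 1)
        out = self.span_values[idx]
        return out if out.ndim else float(out)

    @property
    def span_median(self) -> float:
        return float(self.span_quantile(0.5))

    def span_interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        return float(self.span_quantile(alpha)), float(self.span_quantile(1 - alpha))

    @property
    def span_mean(self) -> float:
        return float(np.sum(self.span_values * self.span_probs))


def span_posterior(
    dets: list[C14Determination],
    curve: CalibrationCurve,
    prior: str = "flat",
    grid_step: int = 5,
    year_range: tuple[int, int] | None = None,
) -> SpanPosterior:
    """Posterior of the activity span given dates uniform within the phase.

    Model: an episode of activity occupies an unknown interval ``[s, e]``,
    ``s < e``; each dated event's true year is Uniform(s, e) and its
    measurement follows the calibration likelihood.  Marginalizing the true
    years gives

        L(s, e) = prod_i [ (1 / (e - s)) * sum_{t in [s, e]} like_i(t) * step ]

    evaluated with per-date cumulative sums (O(1) per candidate interval).
    ``prior`` is ``'flat'`` on {s < e} or ``'one_over_span'`` (∝ 1/(e-s),
    penalizing long phases the way hierarchical uniform-phase models do).
    """
    if len(dets) < 2:
        raise ValueError("span estimation needs at least 2 determinations")
    if prior not in ("flat", "one_over_span"):
        raise ValueError(f"unknown prior {prior!r}")
    y0, y1 = curve.year_domain() if year_range is None else year_range
    grid = np.arange(y0, y1 + 1, grid_step, dtype=int)
    if len(grid) < 3:
        raise ValueError("grid too coarse: fewer than 3 candidate years")

    # per-date likelihood (x grid step) and cumulative sums; the interval
    # integral uses trapezoid weights so endpoints are not double-counted
    n = len(grid)
    likes = np.empty((len(dets), n))
    cums = np.empty((len(dets), n))
    for i, det in enumerate(dets):
        likes[i] = _cal_likelihood(det, curve, grid) * grid_step
        cums[i] = np.cumsum(likes[i])

    si, ei = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    valid = ei > si
    spans = (grid[ei] - grid[si]).astype(float)
    safe_spans = np.where(valid, spans, 1.0)
    log_l = np.where(valid, 0.0, -np.inf)
    with np.errstate(divide="ignore"):
        log_span = np.log(safe_spans)
        for i in range(len(dets)):
            # trapezoid integral of like over [s, e]:
            # sum of grid points in [s, e] minus half the two endpoints
            inner = (
                cums[i][ei]
                - np.where(si > 0, cums[i][si - 1], 0.0)
                - 0.5 * (likes[i][si] + likes[i][ei])
            )
            term = np.where(valid & (inner > 0), inner, np.nan)
            log_l = log_l + np.where(np.isnan(term), -np.inf, np.log(term)) - log_span
        if prior == "one_over_span":
            log_l = log_l - log_span

    peak = np.max(log_l[valid]) if valid.any() else -np.inf
    if not np.isfinite(peak):
        raise ValueError("span posterior has zero mass; widen the grid")
    joint = np.where(np.isfinite(log_l), np.exp(log_l - peak), 0.0)
    joint /= joint.sum()

    flat_spans = spans[valid]
    flat_probs = joint[valid]
    span_values = np.unique(flat_spans)
    span_probs = np.zeros_like(span_values)
    idx = np.searchsorted(span_values, flat_spans)
    np.add.at(span_probs, idx, flat_probs)
    return SpanPosterior(
        s_grid=grid, e_grid=grid, joint=joint,
        span_values=span_values, span_probs=span_probs,
    )


def dets_to_frame(dets: list[C14Determination], labels=None) -> pd.DataFrame:
    labels = labels if labels is not None else range(len(dets))
    return pd.DataFrame(
        {
            "mine_id": list(labels),
            "c14_age": [d.c14_age for d in dets],
            "sigma": [d.sigma_lab for d in dets],
        }
    )
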