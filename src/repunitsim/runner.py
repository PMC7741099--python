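"""Configuration, seeding and end-to-end experiment drivers.

Every experiment is reproducible from a YAML config plus one master seed.
The master seed fans out to named, statistically independent substreams
(one per experiment stage), so adding an experiment never perturbs
another's draws.  Each run writes flat CSV/JSON outputs plus a manifest
recording the fully-resolved configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import c14, minesim, popsim, surveysim
from .timeline import Periodization, make_bins

__all__ = [
    "ExperimentConfig",
    "PopsimConfig",
    "MinesimConfig",
    "SamplingConfig",
    "RngRegistry",
    "load_config",
    "run_periodization",
    "run_duration",
    "run_sampling",
    "run_all",
]


class ConfigError(ValueError):
    """A config file violated the schema; the message names the key path."""


# ---------------------------------------------------------------------------
# seeding

class RngRegistry:
    """Named independent random substreams derived from one master seed.

    Substream seeds are derived by mixing the master seed with a CRC-32 of
    the stream name into a ``SeedSequence``, so streams are independent and
    stable across runs and code changes elsewhere.
    """

    def __init__(self, master_seed: int):
        self.master_seed = int(master_seed)

    def seed_sequence(self, name: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.master_seed, zlib.crc32(name.encode())])

    def get(self, name: str) -> np.random.Generator:
        return np.random.default_rng(self.seed_sequence(name))


# ---------------------------------------------------------------------------
# config schema

@dataclass
class PopsimConfig:
    t_min: int = -800
    t_max: int = -300
    t_mid: float = -550.0
    rate: float = 0.1
    floor: float = 1.0
    ceiling: float = 10.0
    n_events: int = 1000
    bin_width: int = 50
    n_sim: int = 1000
    periodization: str = "three_mismatched"  # preset name or path to a CSV

    def build_scenario(self) -> popsim.PeriodizationScenario:
        curve = popsim.LogisticCurve(
            t_min=self.t_min, t_max=self.t_max, t_mid=self.t_mid,
            rate=self.rate, floor=self.floor, ceiling=self.ceiling,
        )
        presets = popsim.preset_periodizations(self.t_min, self.t_max, int(self.t_mid))
        if self.periodization in presets:
            per = presets[self.periodization]
        else:
            per = Periodization.from_csv(self.periodization, require_contiguous=True)
        return popsim.PeriodizationScenario(
            curve=curve, periodization=per, n_events=self.n_events,
            bin_width=self.bin_width, n_sim=self.n_sim,
        )


@dataclass
class MinesimConfig:
    t_start: int = -1750
    t_end: int = -750
    mean_start: float = 200.0
    mean_end: float = 10.0
    dispersion: float = 2.0
    n_active: int = 100
    bin_width: int = 100
    n_dates_per_mine: int = 5
    mines_per_target: int = 5
    target_years: tuple = (-1700, -1250, -800)
    sigma_lab: float = 25.0
    sigma_curve: float = 10.0
    curve_kind: str = "identity"            # 'identity' | 'plateau'
    plateau_calbp: tuple = (2400.0, 2750.0)
    span_grid_step: int = 5
    span_prior: str = "flat"

    def build_model(self) -> minesim.DurationModel:
        return minesim.DurationModel(
            t_start=self.t_start, t_end=self.t_end,
            mean_start=self.mean_start, mean_end=self.mean_end,
            dispersion=self.dispersion,
        )

    def build_curve(self) -> c14.CalibrationCurve:
        # pad the curve domain so dates near the window edges calibrate fully
        calbp_min = 1950 - self.t_end - 400
        calbp_max = 1950 - self.t_start + 400
        return c14.synthetic_curve(
            kind=self.curve_kind,
            calbp_min=calbp_min, calbp_max=calbp_max,
            sigma_curve=self.sigma_curve,
            plateau=self.plateau_calbp if self.curve_kind == "plateau" else None,
        )


@dataclass
class SamplingConfig:
    n_units: int = 1000
    n_sites: int = 200
    phase1_sigma: float = 0.8
    r_grid: tuple = (0.1, 0.3, 0.7)
    b_grid: tuple = (0.0, 0.5, 1.0)
    n_sim: int = 100


@dataclass
class ExperimentConfig:
    """Fully-resolved configuration for one or more experiments."""

    seed: int = 0
    out_dir: str = "results"
    periodization: PopsimConfig = field(default_factory=PopsimConfig)
    duration: MinesimConfig = field(default_factory=MinesimConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "periodization": PopsimConfig,
    "duration": MinesimConfig,
    "sampling": SamplingConfig,
}


def _build_section(cls, data: dict, path: str):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown config key {path}.{key}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path_or_dict) -> ExperimentConfig:
    """Load and validate a YAML config, filling defaults.

    Unknown keys are rejected with the full key path; an empty file yields
    all defaults.  The resolved config round-trips losslessly through YAML.
    """
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {"seed", "out_dir", *_SECTION_TYPES}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]}")
    kwargs = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    for name, cls in _SECTION_TYPES.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section {name} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    return ExperimentConfig(**kwargs)


def save_resolved_config(config: ExperimentConfig, out_dir: Path) -> Path:
    path = out_dir / "config.resolved.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(_tuples_to_lists(config.to_dict()), fh, sort_keys=False)
    return path


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# experiment drivers

def run_periodization(config: ExperimentConfig, out_dir=None, plot=False) -> dict:
    """Logistic truth vs aoristic reconstruction under a periodization."""
    cfg = config.periodization
    scenario = cfg.build_scenario()
    rng = RngRegistry(config.seed).get("periodization")
    result = popsim.run_periodization_experiment(scenario, rng)
    outputs = {"metrics": result.metrics()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.truth.to_frame().to_csv(out_dir / "truth.csv", index=False)
        result.envelope.envelope_frame().to_csv(out_dir / "envelope.csv", index=False)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(result.metrics(), fh, indent=2)
        outputs["files"] = ["truth.csv", "envelope.csv", "metrics.json"]
        if plot:
            outputs["files"].append(_plot_periodization(result, out_dir))
    outputs["result"] = result
    return outputs


def _plot_periodization(result, out_dir: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mid = result.truth.midpoints
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(mid, result.envelope.lo, result.envelope.hi,
                    alpha=0.3, label="envelope")
    ax.plot(mid, result.envelope.mean, "o-", label="aoristic mean")
    ax.plot(mid, result.truth.counts, "r--", label="truth")
    ax.set_xlabel("calendar year")
    ax.set_ylabel("events per bin")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "periodization.png", dpi=120)
    plt.close(fig)
    return "periodization.png"


def run_duration(config: ExperimentConfig, out_dir=None, plot=False) -> dict:
    """Mine turnover, naive counts, dating and pooled span posteriors."""
    cfg = config.duration
    model = cfg.build_model()
    registry = RngRegistry(config.seed)
    mines = minesim.simulate_mines(cfg.n_active, model, registry.get("mines"))
    occupancy = minesim.in_use_counts(mines, cfg.t_start, cfg.t_end)
    bins = make_bins(cfg.t_start, cfg.t_end, cfg.bin_width)
    naive = minesim.naive_mine_count(mines, bins)

    curve = cfg.build_curve()
    date_rng = registry.get("dating")
    selected = minesim.select_mines_near(
        mines, cfg.target_years, cfg.mines_per_target
    )
    span_rows = []
    for target, group in selected.items():
        for mine in group:
            years = minesim.sample_mine_years(mine, cfg.n_dates_per_mine, date_rng)
            dets = [
                c14.back_calibrate(int(y), curve, cfg.sigma_lab, date_rng)
                for y in years
            ]
            post = c14.span_posterior(
                dets, curve, prior=cfg.span_prior,
                grid_step=cfg.span_grid_step,
                year_range=(cfg.t_start, cfg.t_end),
            )
            lo, hi = post.span_interval(0.95)
            span_rows.append(
                {
                    "target_year": target,
                    "mine_id": mine.id,
                    "true_duration": mine.duration,
                    "span_median": post.span_median,
                    "span_lo": lo,
                    "span_hi": hi,
                }
            )
    spans = pd.DataFrame(span_rows)
    outputs = {
        "mines": mines,
        "occupancy": occupancy,
        "naive": naive,
        "spans": spans,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        minesim.mines_to_frame(mines).to_csv(out_dir / "mines.csv", index=False)
        naive.to_frame().to_csv(out_dir / "naive_counts.csv", index=False)
        spans.to_csv(out_dir / "span_posteriors.csv", index=False)
        with open(out_dir / "span_summary.json", "w") as fh:
            json.dump(
                {
                    "grid_step": cfg.span_grid_step,
                    "prior": cfg.span_prior,
                    "curve_kind": cfg.curve_kind,
                    "dispersion": cfg.dispersion,
                    "pooled_median_by_target": {
                        str(t): float(spans[spans.target_year == t].span_median.median())
                        for t in selected
                    },
                },
                fh,
                indent=2,
            )
        outputs["files"] = [
            "mines.csv", "naive_counts.csv", "span_posteriors.csv",
            "span_summary.json",
        ]
        if plot:
            outputs["files"].append(
                _plot_duration(occupancy, naive, cfg, out_dir)
            )
    return outputs


def _plot_duration(occupancy, naive, cfg, out_dir: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(naive.midpoints, naive.counts, "o-", label="naive mine count")
    ax.plot(np.arange(cfg.t_start, cfg.t_end), occupancy, "r--",
            label="mines in use (truth)")
    ax.set_xlabel("calendar year")
    ax.set_ylabel("mines per bin")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "duration.png", dpi=120)
    plt.close(fig)
    return "duration.png"


def run_sampling(config: ExperimentConfig, out_dir=None, plot=False) -> dict:
    """Two-phase settlement pattern under size-biased survey sampling."""
    cfg = config.sampling
    registry = RngRegistry(config.seed)
    pattern = surveysim.generate_pattern(
        cfg.n_units, cfg.n_sites, registry.get("pattern"),
        phase1_sigma=cfg.phase1_sigma,
    )
    summaries = surveysim.run_sampling_experiment(
        pattern, registry.get("sampling"),
        r_grid=cfg.r_grid, b_grid=cfg.b_grid, n_sim=cfg.n_sim,
    )
    outputs = {"pattern": pattern, "summaries": summaries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        surveysim.summaries_to_frame(summaries).to_csv(
            out_dir / "sampling_summary.csv", index=False
        )
        reps = pd.DataFrame(
            [
                {"r": s.r, "b": s.bias_exponent, "replicate": i, "percent_change": c}
                for s in summaries
                for i, c in enumerate(s.changes)
            ]
        )
        reps.to_csv(out_dir / "sampling_replicates.csv", index=False)
        outputs["files"] = ["sampling_summary.csv", "sampling_replicates.csv"]
        if plot:
            outputs["files"].append(_plot_sampling(summaries, out_dir))
    return outputs


def _plot_sampling(summaries, out_dir: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for b in sorted({s.bias_exponent for s in summaries}):
        sel = sorted(
            (s for s in summaries if s.bias_exponent == b), key=lambda s: s.r
        )
        rs = [s.r for s in sel]
        ax.errorbar(
            rs, [s.mean for s in sel],
            yerr=[[s.mean - s.lo for s in sel], [s.hi - s.mean for s in sel]],
            fmt="o-", capsize=3, label=f"b = {b:g}",
        )
    ax.axhline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("sampling fraction r")
    ax.set_ylabel("percent change")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "sampling.png", dpi=120)
    plt.close(fig)
    return "sampling.png"


_EXPERIMENTS = {
    "periodization": run_periodization,
    "duration": run_duration,
    "sampling": run_sampling,
}


def run_all(
    config: ExperimentConfig, out_dir=None, experiments=None, plot=False
) -> dict:
    """Run the requested experiments and write a manifest of outputs."""
    names = list(experiments) if experiments else list(_EXPERIMENTS)
    unknown = set(names) - set(_EXPERIMENTS)
    if unknown:
        raise ConfigError(f"unknown experiment {sorted(unknown)[0]}")
    base = Path(out_dir) if out_dir is not None else None
    manifest = {"seed": config.seed, "experiments": {}}
    results = {}
    for name in names:
        sub = base / name if base is not None else None
        res = _EXPERIMENTS[name](config, sub, plot=plot)
        results[name] = res
        manifest["experiments"][name] = res.get("files", [])
    if base is not None:
        base.mkdir(parents=True, exist_ok=True)
        save_resolved_config(config, base)
        manifest["config"] = "config.resolved.yaml"
        with open(base / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
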