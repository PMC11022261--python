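"""Scenario analysis: single-parameter sweeps and the full study layout.

A sweep varies one reach or effectiveness parameter over a grid (5%
absolute increments by default, from the status-quo value up to 100%) while
every other parameter stays at its configured value, and reports the burden
reduction of each grid point against a no-healthcare null.  The null
replicate set is computed once and shared across all grid points and all
sweeps, so every curve uses the same denominator and, with common random
numbers, paired per-run streams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .outcomes_metrics import (BurdenResult, burden_reduction,
                               plausibility_frame, plausibility_report)
from .params_config import ModelConfig, config_to_dict, get_param, null_config, set_param
from .population_mc import ReplicateSet, run_replicates

__all__ = ["ScenarioSpec", "SWEEP_PARAMETERS", "default_grid", "sweep", "run_study"]

#: the six reach/effectiveness parameters varied one at a time
SWEEP_PARAMETERS = (
    "services.prevention_reach",
    "services.prevention_effect",
    "services.treatment_reach",
    "services.treatment_effect",
    "services.aftercare_reach",
    "services.aftercare_effect",
)


def default_grid(start: float, step: float = 0.05, stop: float = 1.0) -> list[float]:
    """Absolute-increment grid from ``start`` to ``stop`` inclusive."""
    values = [round(start, 10)]
    # continue on the step lattice above the start value
    k = int(np.floor(start / step)) + 1
    v = round(k * step, 10)
    while v <= stop + 1e-12:
        if v > values[-1] + 1e-12:
            values.append(round(min(v, stop), 10))
        v = round(v + step, 10)
    if values[-1] < stop - 1e-12:
        values.append(stop)
    return values


@dataclass
class ScenarioSpec:
    """One sweep: a parameter path and the grid of absolute values."""

    parameter_path: str
    grid: list[float] | None = None     # default: status-quo value .. 1.0 in 0.05 steps
    include_zero_start: bool = False    # start grid at 0 instead of the status quo

    def resolve_grid(self, cfg: ModelConfig) -> list[float]:
        if self.grid is not None:
            g = list(self.grid)
            if any(not 0 <= v <= 1 for v in g):
                raise ValueError("grid values must lie in [0, 1]")
            if any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError("grid must be strictly increasing")
            return g
        start = 0.0 if self.include_zero_start else float(get_param(cfg, self.parameter_path))
        return default_grid(start)


def sweep(cfg: ModelConfig, spec: ScenarioSpec,
          null_replicates: ReplicateSet | None = None) -> pd.DataFrame:
    """Burden reduction versus the shared null across one parameter grid.

    Returns one row per grid value: (parameter, value, burden,
    reduction_pct, ci_low, ci_high, n_runs, n_lives, base_seed).
    """
    if spec.parameter_path not in SWEEP_PARAMETERS:
        raise ValueError(f"unknown sweep parameter {spec.parameter_path!r}; "
                         f"expected one of {SWEEP_PARAMETERS}")
    null = null_replicates if null_replicates is not None else run_replicates(null_config(cfg))
    rows = []
    for value in spec.resolve_grid(cfg):
        scen_cfg = set_param(cfg, spec.parameter_path, value)
        reps = run_replicates(scen_cfg)
        res = burden_reduction(reps, null, level=cfg.simulation.ci_level)
        rows.append({
            "parameter": spec.parameter_path,
            "value": value,
            "burden": res.burden,
            "reduction_pct": res.reduction_pct,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n_runs": cfg.simulation.n_runs,
            "n_lives": cfg.simulation.n_lives_per_run,
            "base_seed": cfg.simulation.base_seed,
        })
    return pd.DataFrame(rows)


def _config_hash(cfg: ModelConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_study(cfg: ModelConfig, out_dir, parameters=SWEEP_PARAMETERS,
              write_plots: bool = False) -> dict:
    """The full experimental layout of the study.

    Runs, in order: the status-quo cohort replicates (plausibility check and
    headline burden reduction), the shared no-healthcare null, and one sweep
    per reach/effectiveness parameter.  Everything is written to ``out_dir``
    (``plausibility.csv``, ``status_quo.csv``, ``scenario_<param>.csv``)
    together with a ``manifest.json`` recording config hash, seeds and
    completion state; a partial failure leaves completed tables on disk with
    the manifest marking what is missing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "depsim_version": __version__,
        "config_hash": _config_hash(cfg),
        "config": config_to_dict(cfg),
        "base_seed": cfg.simulation.base_seed,
        "n_runs": cfg.simulation.n_runs,
        "n_lives_per_run": cfg.simulation.n_lives_per_run,
        "completed": [],
        "failed": None,
    }

    def _checkpoint():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    results: dict = {}
    try:
        status_quo = run_replicates(cfg)
        null = run_replicates(null_config(cfg))
        stats = plausibility_report(status_quo.merged())
        plausibility_frame(stats).to_csv(out / "plausibility.csv", index=False)
        results["plausibility"] = stats
        manifest["completed"].append("plausibility")

        headline = burden_reduction(status_quo, null, level=cfg.simulation.ci_level)
        pd.DataFrame([headline.__dict__]).to_csv(out / "status_quo.csv", index=False)
        results["status_quo"] = headline
        manifest["completed"].append("status_quo")
        _checkpoint()

        results["sweeps"] = {}
        for param in parameters:
            table = sweep(cfg, ScenarioSpec(param), null_replicates=null)
            name = param.rsplit(".", 1)[-1]
            table.to_csv(out / f"scenario_{name}.csv", index=False)
            results["sweeps"][param] = table
            manifest["completed"].append(f"scenario_{name}")
            _checkpoint()
        if write_plots:
            _plot_sweeps(results["sweeps"], headline, out)
    except Exception as exc:  # leave completed outputs + a marked manifest
        manifest["failed"] = repr(exc)
        _checkpoint()
        raise
    _checkpoint()
    return results


def _plot_sweeps(sweeps: dict, headline: BurdenResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for param, table in sweeps.items():
        label = param.rsplit(".", 1)[-1].replace("_", " ")
        ax.errorbar(table["value"] * 100, table["reduction_pct"],
                    yerr=[table["reduction_pct"] - table["ci_low"],
                          table["ci_high"] - table["reduction_pct"]],
                    label=label, capsize=2)
    ax.axhline(headline.reduction_pct, ls="--", c="grey", lw=1,
               label="current system")
    ax.set_xlabel("parameter setting (%)")
    ax.set_ylabel("disease-burden reduction vs no healthcare (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "sweeps.png", dpi=150)
    plt.close(fig)
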