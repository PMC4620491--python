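"""End-to-end pipeline: COLVAR tables + bias grids → microstate landscape →
slice summaries (→ optional two-state thermodynamic curves), with a JSON
run manifest.  All randomness flows from the single config seed; rerunning
the same config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import KT_350
from .ensemble import ensemble_average, observable_table, slice_landscape
from .fes import (
    BinningSpec,
    ReplicaRun,
    assign_microstates,
    estimate_errors,
    reconstruct_fes,
    write_microstates_tsv,
)
from .io import load_config, read_bias_grid, read_colvar
from .thermo import TwoStateThermo, population_curves, t_max_structured

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end landscape pipeline."""

    colvar_paths: list[str]
    bias_paths: list[str]
    biased_cvs: list[str]
    cv_names: list[str]
    widths: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    t_eq: float = 0.0
    kT: float = KT_350
    slice_width: float = 6.0
    observables: list[str] = field(default_factory=list)
    thermo_states: list[dict] = field(default_factory=list)
    n_error_blocks: int = 4
    outdir: str = "bexfes_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.slice_width <= 0:
            raise ValueError("slice width must be positive")
        if not (len(self.colvar_paths) == len(self.bias_paths) == len(self.biased_cvs)):
            raise ValueError("colvar_paths, bias_paths and biased_cvs must align; "
                             "a replica missing a bias grid is not allowed")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = load_config(path)
        raw["ranges"] = {k: tuple(v) for k, v in raw.get("ranges", {}).items()}
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("read inputs")
def _read_runs(config: PipelineConfig) -> list[ReplicaRun]:
    runs = []
    for k, (cp, bp, cv) in enumerate(zip(config.colvar_paths, config.bias_paths,
                                         config.biased_cvs)):
        table = read_colvar(cp)
        grid = read_bias_grid(bp)
        runs.append(ReplicaRun(replica_id=k, biased_cv=cv, cv_table=table,
                               bias_grid=grid))
    return runs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write TSV outputs plus a manifest.

    Stages: microstate assignment → WHAM free energies → block errors →
    free-energy slices and ensemble averages of the configured observable
    columns → optional two-state thermodynamic curves.  Returns the run
    manifest (also written to ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    runs = _read_runs(config)
    spec = BinningSpec(config.cv_names, config.widths, config.ranges, config.t_eq)

    occ = _stage("assign microstates")(assign_microstates)(runs, spec)
    fes = _stage("reconstruct FES")(reconstruct_fes)(occ, runs, spec, kT=config.kT)
    fes.errors = _stage("estimate errors")(estimate_errors)(
        occ, runs, spec, n_blocks=config.n_error_blocks, kT=config.kT)
    write_microstates_tsv(fes, outdir / "microstates.tsv")

    slices = _stage("slice landscape")(slice_landscape)(fes, config.slice_width)
    slice_rows = [{"lower": s.lower, "upper": s.upper, "n_microstates": len(s),
                   "n_frames": int(occ.microstates.loc[s.microstate_ids, "n"].sum())}
                  for s in slices]
    pd.DataFrame(slice_rows).to_csv(outdir / "slices.tsv", sep="\t", index=False)

    averages = {}
    for name in config.observables:
        if name not in occ.frames.columns:
            raise PipelineError(f"stage 'ensemble averages' failed: "
                                f"observable column {name!r} not in frames")
        obs = observable_table(fes, occ.frames[name].to_numpy())
        averages[name] = ensemble_average(fes, obs, T=config.kT / 0.008314)
    if averages:
        pd.DataFrame([averages]).to_csv(outdir / "ensemble_averages.tsv",
                                        sep="\t", index=False)

    thermo_summary = []
    if config.thermo_states:
        models = [TwoStateThermo(**st) for st in config.thermo_states]
        grid = np.linspace(250.0, 400.0, 301)
        curves = population_curves(models, grid)
        curve_df = pd.DataFrame({"T": grid})
        for c in curves:
            curve_df[f"dG_{c.name}"] = c.delta_g
            curve_df[f"ln_ratio_{c.name}"] = c.ln_ratio
        curve_df.to_csv(outdir / "thermo_curves.tsv", sep="\t", index=False)
        for m in models:
            t_star, interior = t_max_structured(m)
            thermo_summary.append({"state": m.name, "t_max_K": round(t_star, 2),
                                   "interior": interior})

    min_idx = int(np.argmin(fes.F))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "kT": config.kT,
        "t_eq": config.t_eq,
        "binning_cvs": config.cv_names,
        "n_replicas": len(runs),
        "n_frames_retained": int(len(occ.frames)),
        "n_frames_dropped": int(occ.n_dropped),
        "n_microstates": int(len(occ.microstates)),
        "wham_iterations": fes.n_iter,
        "wham_residual": fes.residual,
        "wham_converged": fes.residual < 1e-4,
        "min_f_microstate": int(occ.microstates.index[min_idx]),
        "f_max": float(fes.F.max()),
        "thermo": thermo_summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
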