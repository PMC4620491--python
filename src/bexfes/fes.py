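"""Microstate free-energy reconstruction from bias-exchange sampling.

Post-equilibration frames from all replicas are binned into hypercube
microstates in a chosen CV subspace.  Each replica k contributes a
one-dimensional bias potential V_k along its biased CV; the unbiased
microstate free energies F_α follow from the self-consistent
weighted-histogram (WHAM) equations

    F_α = −kT · ln[ Σ_k n_kα / Σ_k N_k · exp((f_k − V_kα)/kT) ]
    f_k = −kT · ln Σ_α exp(−(F_α + V_kα)/kT)

iterated until the maximum change of F_α falls below a tolerance, with the
global minimum shifted to zero.  Errors come from block analysis over the
post-equilibration time span, and hypercubes mixing structurally
inconsistent members can be refined by recursive splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KT_350

_RESERVED = ("replica", "time", "microstate")


class ConvergenceError(RuntimeError):
    """WHAM iteration failed to reach the tolerance."""

    def __init__(self, msg, residual=None, n_iter=None):
        super().__init__(msg)
        self.residual = residual
        self.n_iter = n_iter


@dataclass
class ReplicaRun:
    """One replica's CV trajectory and accumulated 1-D bias potential.

    ``cv_table`` holds a ``time`` column (ps) plus one column per CV;
    ``bias_grid`` is an (n, 2) array of (cv_value, bias kJ/mol) pairs with
    strictly increasing cv values along the replica's ``biased_cv``.
    """

    replica_id: int
    biased_cv: str
    cv_table: pd.DataFrame
    bias_grid: np.ndarray
    swaps: list | None = None

    def __post_init__(self):
        self.bias_grid = np.asarray(self.bias_grid, float)
        if self.bias_grid.ndim != 2 or self.bias_grid.shape[1] != 2:
            raise ValueError("bias_grid must be an (n, 2) array")
        if np.any(np.diff(self.bias_grid[:, 0]) <= 0):
            raise ValueError("bias grid cv values must be strictly increasing")
        if "time" not in self.cv_table.columns:
            raise ValueError("cv_table needs a 'time' column")

    def bias_at(self, values) -> np.ndarray:
        """Bias (kJ/mol) at CV values, linear interpolation.

        Values beyond the grid are linearly extrapolated from the terminal
        grid segments, with a warning.
        """
        values = np.atleast_1d(np.asarray(values, float))
        x, y = self.bias_grid[:, 0], self.bias_grid[:, 1]
        out = np.interp(values, x, y)
        below, above = values < x[0], values > x[-1]
        if below.any():
            slope = (y[1] - y[0]) / (x[1] - x[0])
            out[below] = y[0] + slope * (values[below] - x[0])
        if above.any():
            slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
            out[above] = y[-1] + slope * (values[above] - x[-1])
        if below.any() or above.any():
            warnings.warn(f"replica {self.replica_id}: bias extrapolated beyond grid",
                          stacklevel=2)
        return out


@dataclass
class BinningSpec:
    """Hypercube binning of a CV subspace.

    ``widths`` map each binning CV to its bin width (a natural default is
    the metadynamics Gaussian width of that CV); ``ranges`` give the
    per-CV closed-below/open-above interval covered by bins — frames
    outside are dropped and counted.  ``t_eq`` is the equilibration time
    (ps); frames with time ≤ t_eq never enter the analysis.
    """

    cv_names: list[str]
    widths: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    t_eq: float = 0.0

    def __post_init__(self):
        for cv in self.cv_names:
            if cv not in self.widths or self.widths[cv] <= 0:
                raise ValueError(f"positive bin width required for CV {cv!r}")
            lo, hi = self.ranges[cv]
            if hi <= lo:
                raise ValueError(f"empty range for CV {cv!r}")


@dataclass
class Occupancy:
    """Frame-to-microstate assignment.

    ``frames`` carries replica, time, every CV column and the assigned
    ``microstate`` id; ``microstates`` is indexed by id with per-CV bounds
    (``lo_<cv>``/``hi_<cv>``), centers (``center_<cv>``), per-replica counts
    (``n_rep<k>``) and the total count ``n``.
    """

    frames: pd.DataFrame
    microstates: pd.DataFrame
    spec: BinningSpec
    n_dropped: int = 0

    @property
    def replica_ids(self) -> list[int]:
        return sorted(self.frames["replica"].unique())

    def counts_matrix(self) -> np.ndarray:
        """(n_replicas, n_microstates) occupancy matrix n_kα."""
        return np.array([
            self.microstates[f"n_rep{k}"].to_numpy() for k in self.replica_ids
        ])


def _microstate_table(frames: pd.DataFrame, spec: BinningSpec,
                      replica_ids) -> pd.DataFrame:
    cvs = spec.cv_names
    idx_cols = [f"_idx_{cv}" for cv in cvs]
    groups = frames.groupby(idx_cols, sort=True)
    rows = []
    for key, grp in groups:
        key = key if isinstance(key, tuple) else (key,)
        row = {}
        for cv, k in zip(cvs, key):
            lo, _ = spec.ranges[cv]
            w = spec.widths[cv]
            row[f"idx_{cv}"] = int(k)
            row[f"lo_{cv}"] = lo + k * w
            row[f"hi_{cv}"] = lo + (k + 1) * w
            row[f"center_{cv}"] = lo + (k + 0.5) * w
        for rep in replica_ids:
            row[f"n_rep{rep}"] = int((grp["replica"] == rep).sum())
        row["n"] = len(grp)
        rows.append((row, grp.index))
    table = pd.DataFrame([r for r, _ in rows])
    table.index.name = "microstate"
    assignment = pd.Series(-1, index=frames.index, dtype=int)
    for mid, (_, members) in enumerate(rows):
        assignment.loc[members] = mid
    frames = frames.drop(columns=idx_cols).copy()
    frames["microstate"] = assignment
    return frames, table


def assign_microstates(runs: list[ReplicaRun], spec: BinningSpec) -> Occupancy:
    """Bin post-equilibration frames from all replicas into hypercubes.

    Frames with time ≤ ``spec.t_eq`` are discarded; retained frames map to
    exactly one hypercube; frames outside the binning ranges are dropped
    and counted in ``n_dropped``.
    """
    if not runs:
        raise ValueError("need at least one replica run")
    parts = []
    for run in runs:
        missing = [cv for cv in spec.cv_names if cv not in run.cv_table.columns]
        if missing:
            raise ValueError(
                f"replica {run.replica_id} lacks CV column(s) {', '.join(missing)}")
        tbl = run.cv_table[run.cv_table["time"] > spec.t_eq].copy()
        tbl["replica"] = run.replica_id
        parts.append(tbl)
    frames = pd.concat(parts, ignore_index=True)
    if frames.empty:
        raise ValueError("all frames fall before the equilibration time t_eq")

    in_range = np.ones(len(frames), dtype=bool)
    for cv in spec.cv_names:
        lo, hi = spec.ranges[cv]
        v = frames[cv].to_numpy()
        in_range &= (v >= lo) & (v < hi)
        frames[f"_idx_{cv}"] = np.floor((v - lo) / spec.widths[cv]).astype(int)
    n_dropped = int((~in_range).sum())
    frames = frames[in_range].reset_index(drop=True)
    if frames.empty:
        raise ValueError("no frames inside the binning ranges")

    replica_ids = sorted(r.replica_id for r in runs)
    frames, table = _microstate_table(frames, spec, replica_ids)
    return Occupancy(frames, table, spec, n_dropped)


@dataclass
class MicrostateFES:
    """Microstate free energies with the occupancy they came from."""

    occupancy: Occupancy
    F: np.ndarray  # kJ/mol, min = 0
    errors: np.ndarray  # kJ/mol, NaN where unavailable
    kT: float
    n_iter: int
    residual: float

    @property
    def microstates(self) -> pd.DataFrame:
        out = self.occupancy.microstates.copy()
        out["F"] = self.F
        out["error"] = self.errors
        return out

    def center(self, mid: int) -> np.ndarray:
        cvs = self.occupancy.spec.cv_names
        return self.occupancy.microstates.loc[mid, [f"center_{cv}" for cv in cvs]].to_numpy(float)


def _bias_at_microstates(occ: Occupancy, runs: list[ReplicaRun]) -> np.ndarray:
    """V_kα: replica-k bias evaluated at each microstate, (K, M)."""
    table = occ.microstates
    out = np.zeros((len(runs), len(table)))
    for k, run in enumerate(runs):
        cv = run.biased_cv
        if cv in occ.spec.cv_names:
            out[k] = run.bias_at(table[f"center_{cv}"].to_numpy())
        else:
            # biased CV not among the binning CVs: average the bias over the
            # member frames' values of that CV
            if cv not in occ.frames.columns:
                raise ValueError(f"biased CV {cv!r} absent from frame table")
            per_frame = run.bias_at(occ.frames[cv].to_numpy())
            means = pd.Series(per_frame).groupby(occ.frames["microstate"]).mean()
            out[k] = means.reindex(table.index, fill_value=0.0).to_numpy()
    return out


def _wham(n_ka: np.ndarray, V_ka: np.ndarray, kT: float, tol: float,
          max_iter: int) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Solve the multi-histogram equations; returns (F, f_k, iters, residual)."""
    N_k = n_ka.sum(axis=1)
    n_a = n_ka.sum(axis=0)
    if np.any(n_a == 0):
        raise ValueError("every microstate must be occupied")
    log_n_a = np.log(n_a)
    log_N_k = np.log(np.maximum(N_k, 1e-300))
    F = np.zeros(n_ka.shape[1])
    residual = np.inf
    for it in range(1, max_iter + 1):
        f_k = -kT * logsumexp(-(F[None, :] + V_ka) / kT, axis=1)
        log_denom = logsumexp(log_N_k[:, None] + (f_k[:, None] - V_ka) / kT, axis=0)
        F_new = -kT * (log_n_a - log_denom)
        F_new -= F_new.min()
        residual = float(np.max(np.abs(F_new - F)))
        F = F_new
        if residual < tol:
            return F, f_k, it, residual
    raise ConvergenceError(
        f"WHAM did not converge in {max_iter} iterations (residual {residual:.3g})",
        residual=residual, n_iter=max_iter)


def reconstruct_fes(occupancy: Occupancy, runs: list[ReplicaRun],
                    spec: BinningSpec | None = None, kT: float = KT_350,
                    tol: float = 1e-4, max_iter: int = 10000) -> MicrostateFES:
    """Estimate microstate free energies from biased replica populations.

    Solves the weighted-histogram equations over replicas using each
    replica's 1-D bias interpolated at the microstate centers along its
    biased CV.  The output is shifted so that min F_α = 0; the iteration
    count and final residual are reported on the result.
    """
    spec = spec or occupancy.spec
    n_ka = occupancy.counts_matrix()
    if np.any(n_ka.sum(axis=1) == 0):
        empty = [occupancy.replica_ids[k] for k in np.where(n_ka.sum(axis=1) == 0)[0]]
        raise ValueError(f"replica(s) {empty} contribute no retained frames")
    V_ka = _bias_at_microstates(occupancy, runs)
    F, _, n_iter, residual = _wham(n_ka, V_ka, kT, tol, max_iter)
    errors = np.full(len(F), np.nan)
    return MicrostateFES(occupancy, F, errors, kT, n_iter, residual)


def estimate_errors(occupancy: Occupancy, runs: list[ReplicaRun],
                    spec: BinningSpec | None = None, n_blocks: int = 4,
                    kT: float = KT_350, tol: float = 1e-4,
                    max_iter: int = 10000) -> np.ndarray:
    """Block-analysis errors of the microstate free energies, kJ/mol.

    The post-equilibration time span is cut into ``n_blocks`` equal windows;
    F_α is re-estimated per block (same biases) and the error is the
    standard deviation over blocks divided by √n_blocks.  Microstates absent
    from any block get NaN (unavailable), never zero.
    """
    spec = spec or occupancy.spec
    frames = occupancy.frames
    t0, t1 = frames["time"].min(), frames["time"].max()
    edges = np.linspace(t0, t1, n_blocks + 1)
    edges[0] -= 1e-9  # include the earliest frame
    M = len(occupancy.microstates)
    V_full = _bias_at_microstates(occupancy, runs)
    block_F = np.full((n_blocks, M), np.nan)
    for b in range(n_blocks):
        sel = (frames["time"] > edges[b]) & (frames["time"] <= edges[b + 1])
        sub = frames[sel]
        if sub.empty:
            raise ValueError(f"time block {b} contains no frames")
        counts = np.zeros((len(runs), M))
        for k, run in enumerate(runs):
            c = sub[sub["replica"] == run.replica_id].groupby("microstate").size()
            counts[k, c.index.to_numpy()] = c.to_numpy()
        present = counts.sum(axis=0) > 0
        active = counts.sum(axis=1) > 0
        F_b, _, _, _ = _wham(counts[np.ix_(active, present)],
                             V_full[np.ix_(active, present)], kT, tol, max_iter)
        block_F[b, present] = F_b
    common = ~np.isnan(block_F).any(axis=0)
    if common.any():
        # remove the per-block gauge freedom before taking the spread
        shifts = block_F[:, common].mean(axis=1)
        block_F -= shifts[:, None]
    errors = block_F.std(axis=0, ddof=0) / np.sqrt(n_blocks)
    errors[~common] = np.nan
    return errors


def refine_bins(occupancy: Occupancy, runs: list[ReplicaRun],
                spec: BinningSpec | None = None,
                spread_threshold: float = 1.0) -> Occupancy:
    """Split hypercubes whose members are inconsistent in non-binned CVs.

    A hypercube whose member frames' standard deviation in any CV column
    outside the binning subset exceeds ``spread_threshold`` is split in
    half along its widest binned axis (width measured in units of that
    axis's original bin width), recursively, until consistent or at the
    minimum width of one eighth of the original bin width.
    """
    if spread_threshold <= 0:
        raise ValueError("spread_threshold must be positive")
    spec = spec or occupancy.spec
    frames = occupancy.frames
    cvs = spec.cv_names
    other = [c for c in frames.columns if c not in cvs and c not in _RESERVED]

    table = occupancy.microstates
    stack = [(dict(table.loc[mid].items()),
              frames.index[frames["microstate"] == mid])
             for mid in table.index]
    done = []
    while stack:
        row, members = stack.pop()
        grp = frames.loc[members]
        spread_bad = any(grp[c].std(ddof=0) > spread_threshold for c in other) \
            if len(grp) > 1 and other else False
        widths_rel = {cv: (row[f"hi_{cv}"] - row[f"lo_{cv}"]) / spec.widths[cv]
                      for cv in cvs}
        widest = max(widths_rel, key=widths_rel.get)
        if not spread_bad or widths_rel[widest] <= 1.0 / 8.0 + 1e-12:
            done.append((row, members))
            continue
        mid_val = 0.5 * (row[f"lo_{widest}"] + row[f"hi_{widest}"])
        left = grp.index[grp[widest] < mid_val]
        right = grp.index[grp[widest] >= mid_val]
        for side, bounds in ((left, (row[f"lo_{widest}"], mid_val)),
                             (right, (mid_val, row[f"hi_{widest}"]))):
            if len(side) == 0:
                continue
            child = dict(row)
            child[f"lo_{widest}"], child[f"hi_{widest}"] = bounds
            child[f"center_{widest}"] = 0.5 * (bounds[0] + bounds[1])
            stack.append((child, side))

    new_frames = frames.copy()
    rows = []
    for mid, (row, members) in enumerate(done):
        row = dict(row)
        for rep in occupancy.replica_ids:
            row[f"n_rep{rep}"] = int((frames.loc[members, "replica"] == rep).sum())
        row["n"] = len(members)
        rows.append(row)
        new_frames.loc[members, "microstate"] = mid
    new_table = pd.DataFrame(rows)
    new_table.index.name = "microstate"
    return Occupancy(new_frames, new_table, spec, occupancy.n_dropped)


def write_microstates_tsv(fes: MicrostateFES, path) -> None:
    """Write the microstate table (bounds, centers, counts, F, error) as TSV."""
    fes.microstates.to_csv(path, sep="\t", index=True)
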