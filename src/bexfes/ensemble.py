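"""Boltzmann ensemble averages and free-energy-sliced structural summaries.

Once microstate free energies are known, any observable averages as
⟨O⟩ = Σ_α O_α·exp(−F_α/kT) / Σ_α exp(−F_α/kT) with O_α the arithmetic mean
over the frames populating microstate α.  To expose how structure changes
away from the global minimum, microstates are grouped into slices of equal
free-energy width (6 kJ/mol by default, about twice thermal energy) and
per-slice secondary-structure populations and ΔSASA profiles are computed
against the global-minimum microstate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import R_KJ
from .fes import MicrostateFES


def observable_table(fes: MicrostateFES, per_frame_values) -> pd.DataFrame | pd.Series:
    """Per-microstate means O_α of a per-frame observable.

    ``per_frame_values`` is aligned with ``fes.occupancy.frames`` rows;
    scalars give a Series indexed by microstate, 2-D arrays (frames ×
    residues) a DataFrame with one column per residue.
    """
    frames = fes.occupancy.frames
    values = np.asarray(per_frame_values, float)
    if len(values) != len(frames):
        raise ValueError("per-frame values must align with the frame table")
    groups = frames["microstate"]
    if values.ndim == 1:
        return pd.Series(values).groupby(groups.to_numpy()).mean()
    df = pd.DataFrame(values)
    return df.groupby(groups.to_numpy()).mean()


def _weights(F: np.ndarray, kT: float) -> np.ndarray:
    z = -(F - F.min()) / kT
    w = np.exp(z)
    return w / w.sum()


def ensemble_average(fes: MicrostateFES, obs, T: float = 350.0):
    """Boltzmann-weighted ensemble average of a per-microstate observable.

    ``obs`` is a Series (scalar observable) or DataFrame (vector observable,
    e.g. per-residue) indexed by microstate id; every microstate of the FES
    must be covered.  Weights use kT = R·T with a max-shift for stability.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    ids = fes.occupancy.microstates.index
    obs = obs if isinstance(obs, (pd.Series, pd.DataFrame)) else pd.Series(obs)
    missing = ids.difference(obs.index)
    if len(missing):
        raise ValueError(f"observable missing for microstate(s) {list(missing)[:5]}")
    vals = obs.loc[ids]
    w = _weights(fes.F, R_KJ * T)
    if isinstance(vals, pd.Series):
        return float(np.dot(w, vals.to_numpy()))
    return pd.Series(vals.to_numpy().T @ w, index=vals.columns)


@dataclass
class FESlice:
    """Microstates within one free-energy band [lower, upper)."""

    lower: float
    upper: float
    microstate_ids: list[int]

    def __len__(self):
        return len(self.microstate_ids)


def slice_landscape(fes: MicrostateFES, width: float = 6.0) -> list[FESlice]:
    """Partition occupied microstates into half-open free-energy slices.

    Slices are [i·width, (i+1)·width) from 0 up to the maximum F; every
    occupied microstate lands in exactly one slice; empty slices are kept
    out of the result.
    """
    if width <= 0:
        raise ValueError("slice width must be positive")
    ids = fes.occupancy.microstates.index.to_numpy()
    idx = np.floor(fes.F / width).astype(int)
    out = []
    for i in range(idx.max() + 1):
        members = ids[idx == i]
        if len(members):
            out.append(FESlice(i * width, (i + 1) * width, list(members)))
    return out


def _slice_weights(fes: MicrostateFES, sl: FESlice, weighting: str) -> np.ndarray:
    loc = fes.occupancy.microstates.index.get_indexer(sl.microstate_ids)
    if weighting == "uniform":
        return np.full(len(loc), 1.0 / len(loc))
    if weighting == "boltzmann":
        return _weights(fes.F[loc], fes.kT)
    raise ValueError(f"unknown weighting {weighting!r}")


def slice_ss_populations(slices: list[FESlice], fes: MicrostateFES,
                         per_frame_labels, weighting: str = "boltzmann",
                         labels: str = "HEPC") -> dict[tuple, pd.DataFrame]:
    """Per-slice, per-residue secondary-structure fractions.

    ``per_frame_labels`` is an (n_frames, n_res) array of labels aligned
    with the occupancy frame table.  Within a slice, microstate label
    fractions are combined with Boltzmann weights renormalized inside the
    slice (or uniformly).  Fractions per residue sum to 1.  Returns a dict
    keyed by (lower, upper) free-energy bounds.
    """
    lab = np.asarray(per_frame_labels)
    frames = fes.occupancy.frames
    if lab.shape[0] != len(frames):
        raise ValueError("per-frame labels must align with the frame table")
    per_ms = {}
    for label in labels:
        per_ms[label] = observable_table(fes, (lab == label).astype(float))
    out = {}
    for sl in slices:
        if len(sl) == 0:
            continue
        w = _slice_weights(fes, sl, weighting)
        frac = {label: per_ms[label].loc[sl.microstate_ids].to_numpy().T @ w
                for label in labels}
        df = pd.DataFrame(frac)
        df.index = np.arange(1, lab.shape[1] + 1)
        df.index.name = "residue"
        out[(sl.lower, sl.upper)] = df
    return out


def slice_delta_sasa(slices: list[FESlice], fes: MicrostateFES,
                     per_frame_sasa, weighting: str = "boltzmann"):
    """Per-slice, per-residue SASA difference with the global minimum.

    The reference is the microstate at F = 0 (the zero-width slice holding
    the global minimum): Δ_r = ⟨SASA_r⟩_slice − ⟨SASA_r⟩_min.  Returns
    ``(per_residue, per_slice_mean)`` where ``per_residue`` maps slice
    bounds to a per-residue Δ Series and ``per_slice_mean`` maps them to
    the residue-mean Δ.
    """
    sasa = np.asarray(per_frame_sasa, float)
    per_ms = observable_table(fes, sasa)
    min_id = fes.occupancy.microstates.index[int(np.argmin(fes.F))]
    ref = per_ms.loc[min_id].to_numpy()
    per_residue, per_mean = {}, {}
    for sl in slices:
        if len(sl) == 0:
            continue
        w = _slice_weights(fes, sl, weighting)
        mean_slice = per_ms.loc[sl.microstate_ids].to_numpy().T @ w
        delta = mean_slice - ref
        s = pd.Series(delta, index=np.arange(1, sasa.shape[1] + 1))
        s.index.name = "residue"
        per_residue[(sl.lower, sl.upper)] = s
        per_mean[(sl.lower, sl.upper)] = float(delta.mean())
    return per_residue, per_mean


def ss_populations_tsv(pops: dict, path) -> None:
    """Write per-slice secondary-structure fractions as a long-format TSV."""
    rows = []
    for (lo, hi), df in pops.items():
        for residue, row in df.iterrows():
            rec = {"slice_lower": lo, "slice_upper": hi, "residue": residue}
            rec.update(row.to_dict())
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def delta_sasa_tsv(per_residue: dict, path) -> None:
    """Write per-slice ΔSASA profiles as a long-format TSV."""
    rows = []
    for (lo, hi), s in per_residue.items():
        for residue, val in s.items():
            rows.append({"slice_lower": lo, "slice_upper": hi,
                         "residue": residue, "delta_sasa": val})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
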