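"""Synthetic inputs with known ground truth for the whole pipeline.

Every data source the analysis consumes can be generated here with the
true answer in hand: multi-basin free-energy landscapes over a few CVs,
bias-exchange sampling of those landscapes under the metadynamics schedule
of the study (Gaussian height 0.30 kJ/mol every 5 steps, bias exchanges
every 20 steps, optional upper walls, equilibration discard), toy peptide
conformations with prescribed helix/sheet/coil content, exponential
PFG-NMR diffusion decays with known D, and force-field energy traces with
a restraint channel.

The sampler is a Metropolis random walk in CV space on F(s) + V_k(s_k):
any ergodic sampler of the biased Boltzmann density validates the
reconstruction method; atomistic dynamics is out of scope.  One sampler
step plays the role of 1 ps so the deposition/exchange strides keep their
familiar values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophys import DiffusionDecay
from .constants import GAMMA_1H, R_KJ
from .fes import ReplicaRun
from .structure import (
    HELIX_PHI_PSI,
    STRAND_PHI_PSI,
    ConfigurationError,
    Conformation,
    build_backbone,
)
from .thermo import EnergyTrace

WALL_SPRING = 500.0  # kJ/mol per CV-unit², half-harmonic upper walls


@dataclass
class ToyLandscape:
    """Specification of a multi-well free-energy landscape over CVs.

    Each well is a Gaussian basin ``(center, depth kJ/mol, width)``; the
    landscape is F(s) = −kT·ln Σ_w exp(depth_w/kT − ½|s−c_w|²_scaled),
    normalized so the global minimum is 0.
    """

    cv_names: list[str]
    wells: list[tuple]  # (center vector, depth, width vector)
    domain: list[tuple[float, float]]
    temperature: float = 350.0

    def __post_init__(self):
        if not self.wells:
            raise ConfigurationError("landscape needs at least one well")
        if len(self.domain) != len(self.cv_names):
            raise ConfigurationError("domain must match cv_names")
        for lo, hi in self.domain:
            if hi <= lo:
                raise ConfigurationError("empty domain interval")
        for center, depth, width in self.wells:
            if depth <= 0:
                raise ConfigurationError("well depths must be positive")
            if len(center) != len(self.cv_names):
                raise ConfigurationError("well center dimension mismatch")
            for x, (lo, hi) in zip(center, self.domain):
                if not lo <= x <= hi:
                    raise ConfigurationError(f"well center {x} outside domain")

    @property
    def kT(self) -> float:
        return R_KJ * self.temperature

    @property
    def n_cv(self) -> int:
        return len(self.cv_names)


class Landscape:
    """Ground-truth free energy built from a :class:`ToyLandscape` spec."""

    def __init__(self, spec: ToyLandscape, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self._centers = np.array([w[0] for w in spec.wells], float)
        self._depths = np.array([w[1] for w in spec.wells], float)
        self._widths = np.array([w[2] for w in spec.wells], float)
        self._offset = 0.0
        self._offset = float(min(self._f_raw(c) for c in self._centers))

    def _f_raw(self, s) -> np.ndarray | float:
        s = np.asarray(s, float)
        scalar = s.ndim == 1
        pts = s[None, :] if scalar else s.reshape(-1, s.shape[-1])
        # log-sum-exp over wells of depth/kT − ½ Σ ((s−c)/σ)²
        z = (self._depths[None, :] / self.spec.kT
             - 0.5 * np.sum(((pts[:, None, :] - self._centers[None, :, :])
                             / self._widths[None, :, :]) ** 2, axis=2))
        zmax = z.max(axis=1)
        f = -self.spec.kT * (zmax + np.log(np.sum(np.exp(z - zmax[:, None]), axis=1)))
        return float(f[0]) if scalar else f.reshape(s.shape[:-1])

    def F(self, s) -> np.ndarray | float:
        """Free energy (kJ/mol) at CV point(s) ``s``, global minimum at 0."""
        return self._f_raw(s) - self._offset

    def marginal(self, cv: int | str, n_grid: int = 201,
                 n_quad: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Exact marginal free energy along one CV by dense quadrature.

        Integrates exp(−F/kT) over all other CVs on a dense grid and
        returns ``(grid, F_marginal)`` with the marginal minimum at 0.
        """
        if isinstance(cv, str):
            cv = self.spec.cv_names.index(cv)
        d = self.spec.n_cv
        if n_quad is None:
            n_quad = {1: 1, 2: 201, 3: 101, 4: 41}.get(d, 41)
        lo, hi = self.spec.domain[cv]
        grid = np.linspace(lo, hi, n_grid)
        if d == 1:
            f = self.F(grid[:, None])
            return grid, f - f.min()
        axes = [np.linspace(l, h, n_quad) for i, (l, h) in enumerate(self.spec.domain)
                if i != cv]
        mesh = np.meshgrid(grid, *axes, indexing="ij")
        pts = np.empty(mesh[0].shape + (d,))
        pts[..., cv] = mesh[0]
        j = 1
        for i in range(d):
            if i == cv:
                continue
            pts[..., i] = mesh[j]
            j += 1
        dens = np.exp(-self.F(pts) / self.spec.kT)
        for j_ax in range(d - 1, 0, -1):
            dens = np.trapezoid(dens, axes[j_ax - 1], axis=j_ax)
        f = -self.spec.kT * np.log(dens)
        return grid, f - f.min()


def make_landscape(spec: ToyLandscape, seed: int = 0) -> Landscape:
    """Build the ground-truth landscape object for a :class:`ToyLandscape`."""
    return Landscape(spec, seed)


@dataclass
class MetadSchedule:
    """Metadynamics schedule of the bias-exchange sampler.

    Defaults follow the study: Gaussians of height 0.30 kJ/mol deposited
    every 5 steps (1 step ≡ 1 ps), bias exchanges attempted every 20 steps,
    optional loose upper walls, and an equilibration span ``t_eq`` whose
    frames are discarded by the analysis.
    """

    gaussian_height: float = 0.30
    gaussian_width_per_cv: list[float] = field(default_factory=lambda: [0.2])
    deposition_stride: int = 5
    exchange_stride: int = 20
    wall_positions: list[float | None] | None = None
    t_eq: int = 0

    def __post_init__(self):
        if self.gaussian_height < 0:
            raise ConfigurationError("gaussian height must be non-negative")
        if self.deposition_stride <= 0 or self.exchange_stride <= 0:
            raise ConfigurationError("strides must be positive")
        if self.exchange_stride % self.deposition_stride != 0:
            raise ConfigurationError("exchange stride must be a multiple of the deposition stride")


def _wall_energy(s: np.ndarray, walls) -> float:
    if walls is None:
        return 0.0
    e = 0.0
    for x, w in zip(s, walls):
        if w is not None and x > w:
            e += 0.5 * WALL_SPRING * (x - w) ** 2
    return e


def sample_biased_replicas(landscape: Landscape, schedule: MetadSchedule,
                           n_replicas: int, n_steps: int,
                           seed: int = 0) -> list[ReplicaRun]:
    """Bias-exchange Metropolis sampling of a toy landscape.

    Replica k walks in the full CV space under F(s) + V_k(s_k) where V_k is
    its own growing 1-D bias along CV k; Gaussians are deposited on a grid
    every ``deposition_stride`` steps and configuration swaps between a
    random adjacent replica pair are attempted every ``exchange_stride``
    steps with the standard Metropolis criterion on the two biases.  Step
    sizes are tuned to 30–50% acceptance during the equilibration span.

    Deposition runs during the equilibration span and stops at ``t_eq``
    (when ``t_eq > 0``), realizing the premise of the reconstruction that
    the bias potentials are stationary for the frames entering the
    analysis; with ``t_eq = 0`` Gaussians are deposited throughout.

    Each returned :class:`ReplicaRun` carries the full CV trajectory
    (1 frame per step, times in ps), the accumulated bias grid (stationary
    after ``t_eq``), and the swap records.
    """
    spec = landscape.spec
    d = spec.n_cv
    if n_replicas > d:
        raise ConfigurationError("n_replicas must not exceed the number of CVs")
    if n_steps <= schedule.t_eq:
        raise ConfigurationError("no post-equilibration frames: n_steps <= t_eq")
    widths = list(schedule.gaussian_width_per_cv)
    if len(widths) == 1 and d > 1:
        widths = widths * d
    if len(widths) < n_replicas:
        raise ConfigurationError("need a Gaussian width per biased CV")
    walls = schedule.wall_positions
    kT = spec.kT
    rng = np.random.default_rng(seed)

    # bias grids extend 5σ beyond the domain so no deposited mass is clipped
    grids, biases = [], []
    for k in range(n_replicas):
        lo, hi = spec.domain[k]
        pad = 5.0 * widths[k]
        n_pts = max(201, int((hi - lo + 2 * pad) / (widths[k] / 4.0)) + 1)
        grids.append(np.linspace(lo - pad, hi + pad, n_pts))
        biases.append(np.zeros(n_pts))

    lows = np.array([lo for lo, _ in spec.domain])
    highs = np.array([hi for _, hi in spec.domain])
    pos = lows + (highs - lows) * rng.random((n_replicas, d))
    step = np.tile(0.1 * (highs - lows), (n_replicas, 1))

    def energy(k, s):
        if np.any(s < lows) or np.any(s > highs):
            return math.inf
        e = landscape.F(s) + _wall_energy(s, walls)
        e += float(np.interp(s[k], grids[k], biases[k]))
        return e

    traj = np.empty((n_replicas, n_steps, d))
    swaps: list[list] = [[] for _ in range(n_replicas)]
    current = np.array([energy(k, pos[k]) for k in range(n_replicas)])
    accepted = np.zeros(n_replicas)
    proposed = np.zeros(n_replicas)
    tune_until = max(schedule.t_eq, min(n_steps, 1000))

    for t in range(1, n_steps + 1):
        for k in range(n_replicas):
            trial = pos[k] + step[k] * rng.standard_normal(d)
            e_new = energy(k, trial)
            proposed[k] += 1
            if e_new <= current[k] or rng.random() < math.exp(-(e_new - current[k]) / kT):
                pos[k] = trial
                current[k] = e_new
                accepted[k] += 1
        if t <= tune_until and t % 200 == 0:
            for k in range(n_replicas):
                rate = accepted[k] / max(proposed[k], 1)
                if rate > 0.5:
                    step[k] *= 1.3
                elif rate < 0.3:
                    step[k] /= 1.3
            accepted[:] = 0
            proposed[:] = 0
        depositing = t <= schedule.t_eq or schedule.t_eq == 0
        if depositing and schedule.gaussian_height > 0 and t % schedule.deposition_stride == 0:
            for k in range(n_replicas):
                biases[k] += schedule.gaussian_height * np.exp(
                    -0.5 * ((grids[k] - pos[k][k]) / widths[k]) ** 2)
                current[k] = energy(k, pos[k])
        if n_replicas >= 2 and t % schedule.exchange_stride == 0:
            i = int(rng.integers(0, n_replicas - 1))
            j = i + 1
            vi_i = float(np.interp(pos[i][i], grids[i], biases[i]))
            vi_j = float(np.interp(pos[j][i], grids[i], biases[i]))
            vj_j = float(np.interp(pos[j][j], grids[j], biases[j]))
            vj_i = float(np.interp(pos[i][j], grids[j], biases[j]))
            delta = (vi_j + vj_i - vi_i - vj_j) / kT
            ok = delta <= 0 or rng.random() < math.exp(-delta)
            if ok:
                pos[[i, j]] = pos[[j, i]]
                current[i] = energy(i, pos[i])
                current[j] = energy(j, pos[j])
            swaps[i].append((t, i, j, ok))
            swaps[j].append((t, i, j, ok))
        traj[:, t - 1, :] = pos

    runs = []
    times = np.arange(1, n_steps + 1, dtype=float)
    for k in range(n_replicas):
        # deposition stops at t_eq, so the final grid equals the bias the
        # post-equilibration frames were sampled under
        table = pd.DataFrame({"time": times})
        for idx, name in enumerate(spec.cv_names):
            table[name] = traj[k, :, idx]
        runs.append(ReplicaRun(
            replica_id=k, biased_cv=spec.cv_names[k], cv_table=table,
            bias_grid=np.column_stack([grids[k], biases[k]]), swaps=swaps[k]))
    return runs


# ---------------------------------------------------------------------------
# Toy peptides
# ---------------------------------------------------------------------------

_COIL_ALPHA_WEIGHT = 0.2


def _coil_draw(rng: np.random.Generator) -> tuple[float, float]:
    """Random-coil dihedral draw: broad β/PPII basin with a 20% α admixture."""
    if rng.random() < _COIL_ALPHA_WEIGHT:
        return rng.uniform(-100, -30), rng.uniform(-67, -7)
    return rng.uniform(-150, -60), rng.uniform(90, 180)


def _has_clash(conf: Conformation, cutoff: float = 1.5) -> bool:
    coords, resnums = [], []
    for i, _, xyz in conf.atoms():
        coords.append(xyz)
        resnums.append(i)
    coords = np.array(coords)
    resnums = np.array(resnums)
    for a in range(len(coords)):
        d = np.linalg.norm(coords[a + 1:] - coords[a], axis=1)
        far = np.abs(resnums[a + 1:] - resnums[a]) >= 2
        if np.any((d < cutoff) & far):
            return True
    return False


def make_toy_peptide(n_res: int, ss_string: str, seed: int = 0,
                     sequence: str | None = None) -> Conformation:
    """Build a toy peptide with prescribed secondary structure.

    ``ss_string`` assigns each residue H (ideal helix dihedrals), E (ideal
    strand) or C (random-coil draw).  The backbone (N, CA, C, O and CB for
    non-Gly) uses ideal bond geometry; coil draws are resampled up to 50
    times if atoms from residues ≥ 2 apart come within 1.5 Å.
    """
    if n_res < 3:
        raise ConfigurationError("need at least 3 residues")
    if len(ss_string) != n_res:
        raise ConfigurationError("ss_string length must equal n_res")
    bad = set(ss_string) - set("HEC")
    if bad:
        raise ConfigurationError(f"invalid secondary-structure code(s): {sorted(bad)}")
    sequence = sequence or "A" * n_res
    if len(sequence) != n_res:
        raise ConfigurationError("sequence length must equal n_res")
    rng = np.random.default_rng(seed)

    for _ in range(50):
        phi, psi = np.empty(n_res), np.empty(n_res)
        for i, code in enumerate(ss_string):
            if code == "H":
                phi[i], psi[i] = HELIX_PHI_PSI
            elif code == "E":
                phi[i], psi[i] = STRAND_PHI_PSI
            else:
                phi[i], psi[i] = _coil_draw(rng)
        conf = build_backbone(sequence, phi, psi)
        if "C" not in ss_string or not _has_clash(conf):
            return conf
    import warnings

    warnings.warn("clash rejection exhausted 50 attempts; returning last build",
                  stacklevel=2)
    return conf


# ---------------------------------------------------------------------------
# Diffusion decays and energy traces
# ---------------------------------------------------------------------------

def make_diffusion_decay(D: float, I0: float, delta: float, Delta: float,
                         gradients, noise_sd: float = 0.0,
                         seed: int = 0) -> DiffusionDecay:
    """Synthesize a Stejskal–Tanner decay with known diffusion coefficient.

    Intensities are I0·exp(−D·γ²g²δ²(Δ−δ/3))·(1+ε) with multiplicative
    Gaussian noise of fractional standard deviation ``noise_sd``.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if D <= 0:
        raise ConfigurationError("D must be positive")
    gradients = np.asarray(gradients, float)
    if gradients.size == 0:
        raise ConfigurationError("need at least one gradient strength")
    rng = np.random.default_rng(seed)
    b = (GAMMA_1H * gradients * delta) ** 2 * (Delta - delta / 3.0)
    intens = I0 * np.exp(-D * b)
    if noise_sd > 0:
        intens = intens * (1.0 + noise_sd * rng.standard_normal(len(gradients)))
        intens = np.maximum(intens, 1e-12 * I0)
    return DiffusionDecay(gradients=gradients, intensities=intens,
                          delta=delta, Delta=Delta, true_D=D)


def make_energy_trace(true_mean: float, sd: float, n_frames: int,
                      restraint_violation_fraction: float = 0.0,
                      seed: int = 0) -> EnergyTrace:
    """Synthesize a restrained-run energy trace with known mean.

    A ``restraint_violation_fraction`` of frames get a restraint energy
    above the 2.9 kJ/mol thermal threshold and a +20 kJ/mol energy offset,
    so that restraint filtering is detectable; the remaining frames carry
    Gaussian energies around ``true_mean`` and sub-threshold restraints.
    Frames are spaced 5 ps apart.
    """
    if not 0.0 <= restraint_violation_fraction < 1.0:
        raise ConfigurationError("violation fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    energy = true_mean + sd * rng.standard_normal(n_frames)
    restraint = rng.uniform(0.0, 2.9, n_frames)
    n_bad = int(round(restraint_violation_fraction * n_frames))
    if n_bad:
        bad = rng.choice(n_frames, size=n_bad, replace=False)
        restraint[bad] = 2.9 + rng.uniform(0.5, 5.0, n_bad)
        energy[bad] += 20.0
    times = 5.0 * np.arange(n_frames)
    return EnergyTrace(times, energy, restraint, true_mean=true_mean)
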