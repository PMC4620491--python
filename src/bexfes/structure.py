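"""Structural collective variables and observables.

This module computes, from a peptide conformation, the collective variables
used to bias and analyse disordered-peptide sampling — side-chain
coordination number, α-helical and β-sheet segment counts based on a
rational switching function of segment RMSD, and side-chain dihedral
similarity — together with standard structural observables: a dihedral-box
secondary-structure assignment, Shrake–Rupley solvent accessible surface
area and the radius of gyration.

Conventions: coordinates in Å; switching-function radii in nm (distances
are converted explicitly where a switching function is applied); residues
numbered 1..n.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (
    ATOMIC_MASS,
    CHI1_ATOM,
    HYDROPHOBIC,
    VDW_DEFAULT,
    VDW_RADII,
)

logger = logging.getLogger(__name__)

# Ideal backbone dihedrals (degrees) for secondary-structure classes.
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

# Ideal backbone geometry (Å / degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5


class ConfigurationError(ValueError):
    """Invalid construction parameters for a domain object."""


@dataclass
class Conformation:
    """A single peptide conformation.

    Attributes
    ----------
    sequence:
        One-letter residue codes, residue i (1-based) at ``sequence[i-1]``.
    residues:
        One dict per residue mapping atom name (``N``, ``CA``, ``C``, ``O``,
        ``CB``, ...) to a length-3 coordinate array in Å.
    chain_id:
        Single-character chain identifier used on output.
    """

    sequence: str
    residues: list[dict[str, np.ndarray]]
    chain_id: str = "A"

    def __post_init__(self):
        if len(self.sequence) != len(self.residues):
            raise ConfigurationError("sequence length != number of residues")
        for i, res in enumerate(self.residues, start=1):
            for name in ("N", "CA", "C"):
                if name not in res:
                    raise ConfigurationError(f"residue {i} missing backbone atom {name}")
            for name, xyz in res.items():
                res[name] = np.asarray(xyz, dtype=float)
                if not np.all(np.isfinite(res[name])):
                    raise ConfigurationError(f"non-finite coordinates at residue {i} atom {name}")

    @property
    def n_res(self) -> int:
        return len(self.residues)

    def atom(self, resnum: int, name: str) -> np.ndarray:
        """Coordinates of atom ``name`` in residue ``resnum`` (1-based)."""
        return self.residues[resnum - 1][name]

    def atoms(self):
        """Yield (resnum, atom_name, xyz) over all atoms in residue order."""
        for i, res in enumerate(self.residues, start=1):
            for name, xyz in res.items():
                yield i, name, xyz

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array."""
        return np.array([xyz for _, _, xyz in self.atoms()])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Conformation":
        """Return a rigidly transformed copy (x → R·x + t)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        new = [{name: rot @ xyz + t for name, xyz in res.items()} for res in self.residues]
        return Conformation(self.sequence, new, self.chain_id)


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a PDB-style atom name."""
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    return stripped[:1].upper()


# ---------------------------------------------------------------------------
# Internal-coordinate backbone construction
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D from internal coordinates relative to A–B–C.

    ``bond`` is |C–D|, ``angle_deg`` the B–C–D angle and ``torsion_deg`` the
    A–B–C–D dihedral (NeRF construction).
    """
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB position from the backbone N, CA, C triad."""
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    # -0.605·bisector + 0.796·normal gives ~110° to both backbone bonds
    direction = -0.605 * bis + 0.796 * perp
    return ca + _B_CA_CB * direction / np.linalg.norm(direction)


def build_backbone(sequence: str, phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | None = None, chain_id: str = "A") -> Conformation:
    """Build an ideal-geometry peptide backbone from dihedral angles.

    ``phi[i]``/``psi[i]`` are the backbone dihedrals of residue i+1 in
    degrees (``phi[0]`` and ``psi[-1]`` affect only terminal-atom placement).
    Atoms N, CA, C, O are built for every residue and CB for non-glycine.
    """
    n_res = len(sequence)
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    if omega is None:
        omega = np.full(n_res, 180.0)
    if not (len(phi) == len(psi) == n_res):
        raise ConfigurationError("phi/psi length must equal sequence length")

    residues: list[dict[str, np.ndarray]] = []
    # First residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = residues[i - 1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi[i - 1])
        ca_i = place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, omega[i])
        c_i = place_atom(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi[i])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})

    for i, res in enumerate(residues):
        # Carbonyl O anti to the following amide N
        res["O"] = place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        if sequence[i] != "G":
            res["CB"] = _place_cb(res["N"], res["CA"], res["C"])
    return Conformation(sequence, residues, chain_id)


# ---------------------------------------------------------------------------
# Dihedral geometry
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def phi_psi(conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
    """Backbone φ/ψ per residue in degrees; NaN where undefined (termini)."""
    n = conf.n_res
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(1, n + 1):
        res = conf.residues[i - 1]
        if i > 1:
            phi[i - 1] = dihedral(conf.atom(i - 1, "C"), res["N"], res["CA"], res["C"])
        if i < n:
            psi[i - 1] = dihedral(res["N"], res["CA"], res["C"], conf.atom(i + 1, "N"))
    return phi, psi


def chi1(conf: Conformation, resnum: int) -> float | None:
    """Side-chain χ1 (N–CA–CB–Xγ) in degrees, or None if atoms are missing."""
    aa = conf.sequence[resnum - 1]
    gamma = CHI1_ATOM.get(aa)
    res = conf.residues[resnum - 1]
    if gamma is None or gamma not in res or "CB" not in res:
        return None
    return dihedral(res["N"], res["CA"], res["CB"], res[gamma])


# ---------------------------------------------------------------------------
# Switching function and coordination number
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters.

    ``s(r) = (1 - x^n) / (1 - x^m)`` with ``x = (r - d0)/r0``; ``n`` is the
    numerator exponent and ``m > n`` the denominator exponent; ``r0`` and
    ``d0`` are in nm.
    """

    n: int = 4
    m: int = 8
    r0: float = 0.4
    d0: float = 0.0

    def __post_init__(self):
        if not (self.m > self.n > 0):
            raise ConfigurationError("switching exponents require m > n > 0")
        if self.r0 <= 0:
            raise ConfigurationError("r0 must be positive")


#: Parameter sets used for the biasing CVs of the study.
ALPHA_SWITCHING = SwitchingParams(n=4, m=8, r0=0.1)
BETA_SWITCHING = SwitchingParams(n=6, m=12, r0=0.1)
COORDINATION_SWITCHING = SwitchingParams(n=4, m=8, r0=0.4)


def switching(r: float, p: SwitchingParams = COORDINATION_SWITCHING) -> float:
    """Evaluate the rational switching function at distance ``r`` (nm).

    Returns a value in (0, 1]; 1 at r ≤ d0, n/m at r = r0 + d0 (continuous
    limit), decreasing towards 0 at large r.
    """
    if r < 0:
        raise ValueError("distance must be non-negative")
    x = (r - p.d0) / p.r0
    if x <= 0.0:
        return 1.0
    if abs(x - 1.0) < 1e-9:
        return p.n / p.m
    xn = x ** p.n
    xm = x ** p.m
    return (1.0 - xn) / (1.0 - xm)


def coordination_number(conf: Conformation, residue_set=None,
                        p: SwitchingParams = COORDINATION_SWITCHING) -> float:
    """Side-chain coordination number over a residue selection.

    Sums ``switching(r_ij)`` over distinct residue pairs in the selection,
    using CB as side-chain reference atom (CA for glycine).  ``residue_set``
    is an iterable of 1-based residue numbers; by default the hydrophobic
    residues of the sequence.
    """
    if residue_set is None:
        residue_set = [i for i in range(1, conf.n_res + 1)
                       if conf.sequence[i - 1] in HYDROPHOBIC]
    residue_set = sorted(set(residue_set))
    if not residue_set:
        raise ValueError("empty residue selection")
    refs = []
    for i in residue_set:
        res = conf.residues[i - 1]
        if "CB" in res:
            refs.append(res["CB"])
        else:
            if conf.sequence[i - 1] != "G":
                warnings.warn(f"residue {i} lacks CB; using CA", stacklevel=2)
            refs.append(res["CA"])
    refs = np.array(refs)
    total = 0.0
    for a in range(len(refs)):
        for b in range(a + 1, len(refs)):
            r_nm = np.linalg.norm(refs[a] - refs[b]) / 10.0
            total += switching(r_nm, p)
    return total


# ---------------------------------------------------------------------------
# Segment-RMSD secondary-structure counts
# ---------------------------------------------------------------------------

_SEGMENT_ATOMS = ("N", "CA", "C", "O", "CB")


@lru_cache(maxsize=None)
def _helix_template() -> tuple:
    conf = build_backbone("A" * 6, [HELIX_PHI_PSI[0]] * 6, [HELIX_PHI_PSI[1]] * 6)
    return tuple((i, name, tuple(conf.atom(i, name)))
                 for i in range(1, 7) for name in _SEGMENT_ATOMS)


@lru_cache(maxsize=None)
def _strand_pair_template(antiparallel: bool) -> tuple:
    # Two ideal 3-residue strands separated by the canonical ~4.8 Å sheet
    # spacing; the antiparallel partner runs in the reverse direction.
    s1 = build_backbone("AAA", [STRAND_PHI_PSI[0]] * 3, [STRAND_PHI_PSI[1]] * 3)
    coords1 = [(i, name, s1.atom(i, name)) for i in range(1, 4) for name in _SEGMENT_ATOMS]
    center = np.mean([c for _, _, c in coords1], axis=0)
    flip = np.diag([-1.0, 1.0, -1.0])  # 180° about the y axis
    shift = np.array([0.0, 4.8, 0.0])
    out = []
    for i, name, c in coords1:
        out.append((i, name, tuple(c)))
    for i, name, c in coords1:
        c2 = (flip @ (c - center)) + center + shift if antiparallel else c + shift
        out.append((i + 3, name, tuple(c2)))
    return tuple(out)


def _superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD (Å) between coordinate sets after optimal superposition."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        _, rssd = Rotation.align_vectors(a, b)
    return float(rssd) / math.sqrt(len(a))


def _window_coords(conf: Conformation, start: int, length: int) -> list:
    """(local_index, name, xyz) for a window; CB skipped where absent."""
    out = []
    for k in range(length):
        res = conf.residues[start - 1 + k]
        for name in _SEGMENT_ATOMS:
            if name in res:
                out.append((k + 1, name, res[name]))
    return out


def _match_template(window, template):
    keys = {(i, n) for i, n, _ in window}
    t_keys = {(i, n) for i, n, _ in template}
    common = keys & t_keys
    w = np.array([c for i, n, c in window if (i, n) in common])
    t = np.array([c for i, n, c in template if (i, n) in common])
    return w, t


def ss_segment_count(conf: Conformation, mode: str,
                     p: SwitchingParams | None = None,
                     max_separation: int = 30) -> float:
    """Secondary-structure segment count collective variable.

    ``mode='alpha'`` sums ``switching(RMSD to an ideal 6-residue helix)``
    over all contiguous 6-residue windows.  ``mode='antibeta'`` /
    ``'parabeta'`` sum ``switching(RMSD to an ideal two-strand pair)`` over
    pairs of 3-residue segments separated by at least 2 residues in
    sequence (and at most ``max_separation``).  RMSDs are over backbone
    N, CA, C, O, CB after optimal superposition, converted to nm before the
    switching function.
    """
    if mode not in ("alpha", "antibeta", "parabeta"):
        raise ValueError(f"unknown mode {mode!r}")
    if conf.n_res < 6:
        warnings.warn("fewer than 6 residues; segment count is 0", stacklevel=2)
        return 0.0
    if p is None:
        p = ALPHA_SWITCHING if mode == "alpha" else BETA_SWITCHING

    total = 0.0
    if mode == "alpha":
        template = _helix_template()
        for start in range(1, conf.n_res - 5 + 1):
            w, t = _match_template(_window_coords(conf, start, 6), template)
            total += switching(_superposed_rmsd(w, t) / 10.0, p)
        return total

    template = _strand_pair_template(antiparallel=(mode == "antibeta"))
    for i in range(1, conf.n_res - 2 + 1):
        for j in range(i + 5, conf.n_res - 2 + 1):
            if j - i > max_separation:
                break
            seg = _window_coords(conf, i, 3)
            seg += [(k + 3, n, c) for k, n, c in _window_coords(conf, j, 3)]
            w, t = _match_template(seg, template)
            total += switching(_superposed_rmsd(w, t) / 10.0, p)
    return total


def alphabeta_similarity(conf: Conformation, reference_angles,
                         residue_class: str = "hydrophobic") -> float:
    """Side-chain dihedral similarity ``0.5·Σ_i [1 + cos(χ1_i − ref_i)]``.

    The sum runs over residues of the requested class (``hydrophobic`` or
    ``polar``) that have a defined χ1.  ``reference_angles`` is either a
    scalar (degrees, applied to all residues) or a mapping from 1-based
    residue number to degrees; it must cover every counted residue.
    """
    if residue_class not in ("hydrophobic", "polar"):
        raise ValueError("residue_class must be 'hydrophobic' or 'polar'")
    total = 0.0
    for i in range(1, conf.n_res + 1):
        aa = conf.sequence[i - 1]
        is_hydro = aa in HYDROPHOBIC
        if (residue_class == "hydrophobic") != is_hydro:
            continue
        angle = chi1(conf, i)
        if angle is None:
            logger.debug("residue %d (%s) lacks chi1 atoms; skipped", i, aa)
            continue
        if np.isscalar(reference_angles):
            ref = float(reference_angles)
        else:
            if i not in reference_angles:
                raise ValueError(f"no reference angle for residue {i}")
            ref = float(reference_angles[i])
        total += 0.5 * (1.0 + math.cos(math.radians(angle - ref)))
    return total


# ---------------------------------------------------------------------------
# Secondary-structure assignment
# ---------------------------------------------------------------------------

def assign_secondary_structure(conf: Conformation) -> list[str]:
    """Per-residue label in {H, E, P, C} from backbone dihedral regions.

    H: φ∈[−100,−30], ψ∈[−67,−7] in runs of ≥ 4 residues; E: φ∈[−180,−90],
    ψ∈[90,180] in runs of ≥ 2; P (polyproline II): φ∈[−90,−55], ψ∈[120,180]
    when not already strand; C otherwise.  Terminal residues (undefined φ or
    ψ) are C; chain breaks (consecutive CA–CA > 4.5 Å) split runs.
    """
    n = conf.n_res
    phi, psi = phi_psi(conf)

    breaks = set()  # break after residue i (1-based)
    for i in range(1, n):
        d = np.linalg.norm(conf.atom(i, "CA") - conf.atom(i + 1, "CA"))
        if d > 4.5:
            breaks.add(i)

    def in_box(i, phi_lo, phi_hi, psi_lo, psi_hi):
        f, s = phi[i], psi[i]
        if np.isnan(f) or np.isnan(s):
            return False
        return phi_lo <= f <= phi_hi and psi_lo <= s <= psi_hi

    in_h = [in_box(i, -100, -30, -67, -7) for i in range(n)]
    in_e = [in_box(i, -180, -90, 90, 180) for i in range(n)]
    in_p = [in_box(i, -90, -55, 120, 180) for i in range(n)]

    labels = ["C"] * n

    # contiguous stretches not interrupted by a chain break
    segments = []
    start = 0
    for i in range(1, n + 1):
        if i == n or i in breaks:
            segments.append(range(start, i))
            start = i

    def mark_runs(flags, min_run, label):
        for seg in segments:
            run = []
            for i in list(seg) + [None]:
                if i is not None and flags[i]:
                    run.append(i)
                    continue
                if len(run) >= min_run:
                    for k in run:
                        if labels[k] == "C":
                            labels[k] = label
                run = []

    mark_runs(in_h, 4, "H")
    mark_runs(in_e, 2, "E")
    for i in range(n):
        if labels[i] == "C" and in_p[i]:
            labels[i] = "P"
    return labels


def ss_fractions(labels: list[str]) -> dict[str, float]:
    """Fraction of residues per label."""
    n = len(labels)
    return {lab: labels.count(lab) / n for lab in "HEPC"}


# ---------------------------------------------------------------------------
# SASA and radius of gyration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n_points)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = 2.0 * math.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _vdw_radius(atom_name: str) -> float:
    el = element_of(atom_name)
    if el not in VDW_RADII:
        warnings.warn(f"unknown element {el!r}; using {VDW_DEFAULT} Å", stacklevel=3)
        return VDW_DEFAULT
    return VDW_RADII[el]


def sasa_per_residue(conf: Conformation, probe: float = 1.4,
                     n_points: int = 960) -> np.ndarray:
    """Per-residue solvent accessible surface area, Å².

    Shrake–Rupley quadrature: for every atom, ``n_points`` quasi-uniform
    points on the expanded sphere of radius r_vdW + probe; a point is
    accessible when outside every neighbouring atom's expanded sphere.
    Atom areas are summed per residue; the total SASA is the array sum.
    """
    res_ids, radii, centers = [], [], []
    for i, name, xyz in conf.atoms():
        res_ids.append(i)
        radii.append(_vdw_radius(name) + probe)
        centers.append(xyz)
    res_ids = np.array(res_ids)
    radii = np.array(radii)
    centers = np.array(centers)
    unit = _fibonacci_sphere(n_points)

    out = np.zeros(conf.n_res)
    n_atoms = len(radii)
    for a in range(n_atoms):
        d = np.linalg.norm(centers - centers[a], axis=1)
        neigh = np.where((d < radii + radii[a]) & (np.arange(n_atoms) != a))[0]
        pts = centers[a] + radii[a] * unit
        accessible = np.ones(n_points, dtype=bool)
        for b in neigh:
            accessible &= np.sum((pts - centers[b]) ** 2, axis=1) > radii[b] ** 2
            if not accessible.any():
                break
        area = 4.0 * math.pi * radii[a] ** 2 * accessible.mean()
        out[res_ids[a] - 1] += area
    return out


def radius_of_gyration(conf: Conformation, mass_weighted: bool = False) -> float:
    """Radius of gyration in Å over all atoms, optionally mass-weighted."""
    coords, weights = [], []
    for _, name, xyz in conf.atoms():
        coords.append(xyz)
        weights.append(ATOMIC_MASS.get(element_of(name), 12.0) if mass_weighted else 1.0)
    coords = np.array(coords)
    if len(coords) < 2:
        raise ValueError("radius of gyration needs at least 2 atoms")
    w = np.array(weights)
    com = np.average(coords, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1), weights=w)))


def cv_vector(conf: Conformation) -> dict[str, float]:
    """All biasing CVs of the study for one conformation."""
    return {
        "coordination": coordination_number(conf),
        "alpha_count": ss_segment_count(conf, "alpha"),
        "antibeta_count": ss_segment_count(conf, "antibeta"),
        "parabeta_count": ss_segment_count(conf, "parabeta"),
        "rg": radius_of_gyration(conf),
    }
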