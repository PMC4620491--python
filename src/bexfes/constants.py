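"""Physical constants and small lookup tables shared across the package.

Units follow the package-wide convention: coordinates in Å, switching radii
in nm, energies in kJ/mol, temperatures in K unless a function says otherwise.
"""

# Gas constant, kJ/(mol·K)
R_KJ = 0.008314

# Boltzmann constant, J/K
KB_J = 1.380649e-23

# 1H gyromagnetic ratio, rad/(s·T)
GAMMA_1H = 2.67522128e8

# Thermal energy at the simulation temperature of 350 K, kJ/mol
KT_350 = 2.9

#: Average (isotope-abundance weighted) residue masses, Da.  A residue mass is
#: the amino-acid mass minus one water; a peptide's mass is the residue sum
#: plus one water.
RESIDUE_MASS_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS_AVG = 18.01528

#: Bondi van der Waals radii by element, Å.  Unlisted elements fall back to
#: 1.8 Å (with a warning at the call site).
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75,
}
VDW_DEFAULT = 1.8

#: Atomic masses by element, Da (for mass-weighted Rg).
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: Dynamic viscosity of water, mPa·s, tabulated against °C (standard
#: reference values; linearly interpolated between entries).
WATER_VISCOSITY_TABLE = [
    (0, 1.7914), (5, 1.5188), (10, 1.3059), (15, 1.1374), (20, 1.0016),
    (25, 0.8902), (30, 0.7972), (35, 0.7190), (40, 0.6527), (45, 0.5958),
    (50, 0.5465), (60, 0.4660), (70, 0.4035), (80, 0.3540), (90, 0.3149),
    (100, 0.2822),
]

#: One-letter → three-letter residue codes (PDB naming).
THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

#: Residues counted as hydrophobic for the coordination-number selection and
#: the hydrophobic side-chain similarity CV.
HYDROPHOBIC = set("ACFILMVWY")

#: Atom defining the chi1 dihedral (N-CA-CB-X) per residue; absent for G/A.
CHI1_ATOM = {
    "R": "CG", "N": "CG", "D": "CG", "C": "SG", "Q": "CG", "E": "CG",
    "H": "CG", "I": "CG1", "L": "CG", "K": "CG", "M": "CG", "F": "CG",
    "P": "CG", "S": "OG", "T": "OG1", "W": "CG", "Y": "CG", "V": "CG1",
}


def kT(temperature_K: float) -> float:
    """Thermal energy R·T in kJ/mol."""
    return R_KJ * temperature_K


def water_viscosity(temp_C: float) -> float:
    """Dynamic viscosity of water in Pa·s at ``temp_C`` (0–100 °C, linear
    interpolation of a standard table)."""
    import numpy as np

    t, eta = zip(*WATER_VISCOSITY_TABLE)
    return float(np.interp(temp_C, t, eta)) * 1e-3
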