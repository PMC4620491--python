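"""File formats: COLVAR-style tables, bias grids, PDB structures, configs.

COLVAR tables are whitespace-delimited with a ``#! FIELDS time cv1 ...``
header (the dialect written by common metadynamics engines); bias grids are
two-column text files (cv_value, bias kJ/mol).  PDB structures go through
Biopython.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import ONE_LETTER, THREE_LETTER
from .structure import Conformation


def read_colvar(path) -> pd.DataFrame:
    """Read a COLVAR-style table into a DataFrame.

    The first line must be ``#! FIELDS <names...>``; later comment lines
    (starting with ``#``) are skipped; a row whose width disagrees with the
    header raises an error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#!") or "FIELDS" not in header:
            raise ValueError(f"{path}: missing '#! FIELDS' header line")
        names = header.split()[2:]
        if not names:
            raise ValueError(f"{path}: header names no columns")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(names):
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {len(names)}")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=names)
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError(f"{path}: non-finite values in table")
    return df


def write_colvar(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as a COLVAR-style table."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        np.savetxt(fh, df.to_numpy(), fmt="%.10g")


def read_bias_grid(path) -> np.ndarray:
    """Read a two-column (cv_value, bias) grid file."""
    grid = np.loadtxt(path, comments="#")
    if grid.ndim != 2 or grid.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns")
    return grid


def write_bias_grid(grid: np.ndarray, path) -> None:
    """Write a two-column (cv_value, bias) grid file."""
    np.savetxt(path, np.asarray(grid, float), fmt="%.10g",
               header="cv_value bias_kJ_per_mol")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C")


def read_structure(path) -> Conformation:
    """Read a PDB file into a :class:`Conformation`.

    Uses the first model (with a warning if more exist); rejects insertion
    codes; raises when a residue lacks a backbone atom.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models")
    if len(models) > 1:
        warnings.warn(f"{path}: {len(models)} models; using the first", stacklevel=2)
    chains = list(models[0])
    chain = chains[0]
    sequence = []
    residues = []
    for res in chain:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue
        if icode.strip():
            raise ValueError(f"{path}: insertion code at residue {resseq}")
        resname = res.get_resname()
        one = ONE_LETTER.get(resname)
        if one is None:
            raise ValueError(f"{path}: unknown residue {resname} {resseq}")
        atoms = {a.get_name(): np.array(a.get_coord(), float) for a in res}
        for name in _BACKBONE:
            if name not in atoms:
                raise ValueError(f"{path}: residue {resname} {resseq} missing atom {name}")
        sequence.append(one)
        residues.append(atoms)
    if not residues:
        raise ValueError(f"{path}: no amino-acid residues")
    return Conformation("".join(sequence), residues, chain.id or "A")


def write_structure(conf: Conformation, path) -> None:
    """Write a :class:`Conformation` as a single-chain PDB file."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_chain(conf.chain_id)
    builder.init_seg("    ")
    for i, res in enumerate(conf.residues, start=1):
        resname = THREE_LETTER[conf.sequence[i - 1]]
        builder.init_residue(resname, " ", i, " ")
        for name, xyz in res.items():
            builder.init_atom(name, np.asarray(xyz, float), 0.0, 1.0, " ",
                              name.center(4), element=name[0])
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
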