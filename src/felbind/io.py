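"""Readers and writers for the external text formats.

No numerics live here beyond unit conversion at the boundary: energies
arrive in kJ/mol (GROMACS convention) or kcal/mol and are stored in
kcal/mol; PDB coordinates arrive in Å and are stored in nm.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bar import WindowSamples
from .colvars import CVSample, Structure
from .errors import EmptyInputError, ParseError, ValidationError
from .landscape import FELGrid
from .metrics import MOLAR_FACTORS
from .units import NM_PER_ANGSTROM, kcal_from_kj

__all__ = [
    "ComplexRecord",
    "read_dhdl",
    "read_window",
    "read_dataset",
    "write_dataset",
    "read_coordinates",
    "read_cv_series",
    "write_cv_series",
    "read_fel",
    "write_fel",
]

_COMMENT_PREFIXES = ("#", "@", ";")


def _read_two_column(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_COMMENT_PREFIXES):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError("expected two whitespace-separated numbers",
                                 line=lineno)
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(f"malformed numeric field: {exc}",
                                 line=lineno) from exc
    if not rows:
        raise EmptyInputError(f"{path}: no data lines")
    return np.asarray(rows, dtype=float)


def read_dhdl(path, unit: str = "kJ/mol") -> np.ndarray:
    """Read one direction of Hamiltonian-difference samples, in kcal/mol.

    Lines beginning with ``#``, ``@`` or ``;`` are comments; data lines are
    ``time  dU``.  ``unit`` declares the energy unit of the file
    (``kJ/mol`` by default, or ``kcal/mol``).
    """
    data = _read_two_column(path)
    du = data[:, 1]
    if unit == "kJ/mol":
        du = kcal_from_kj(du)
    elif unit != "kcal/mol":
        raise ValidationError(f"unknown energy unit {unit!r}")
    return du


def read_window(
    forward_path,
    reverse_path,
    lambda_j: float,
    lambda_k: float,
    temperature: float = 298.0,
    unit: str = "kJ/mol",
    stride: int = 1,
) -> WindowSamples:
    """Assemble a :class:`WindowSamples` from two dhdl-style files.

    ``stride`` subsamples the time series (default 1: every frame is kept,
    no decorrelation).
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    return WindowSamples(
        lambda_j=lambda_j,
        lambda_k=lambda_k,
        du_forward=read_dhdl(forward_path, unit=unit)[::stride],
        du_reverse=read_dhdl(reverse_path, unit=unit)[::stride],
        temperature=temperature,
    )


@dataclass
class ComplexRecord:
    """One benchmark row: experimental affinity plus computed free energies."""

    complex_id: str
    affinity_value: float | None = None
    affinity_unit: str | None = None
    affinity_type: str | None = None   # IC50 | Ki | direct_dG
    dg_calculated: float | None = None  # kcal/mol
    dg_correction: float | None = None  # kcal/mol
    dg_experimental: float | None = None  # kcal/mol

    def __post_init__(self) -> None:
        if self.affinity_type in ("IC50", "Ki"):
            if self.affinity_value is None or self.affinity_value <= 0:
                raise ValidationError(
                    f"{self.complex_id}: affinity must be positive, "
                    f"got {self.affinity_value}"
                )
            if self.affinity_unit not in MOLAR_FACTORS:
                raise ValidationError(
                    f"{self.complex_id}: unknown affinity unit "
                    f"{self.affinity_unit!r}"
                )
        elif self.affinity_type not in (None, "direct_dG"):
            raise ValidationError(
                f"{self.complex_id}: unknown affinity type {self.affinity_type!r}"
            )


_DATASET_COLUMNS = ["complex_id", "affinity_value", "affinity_unit",
                    "affinity_type", "dg_calculated", "dg_correction",
                    "dg_experimental"]


def read_dataset(path) -> list[ComplexRecord]:
    """Read a benchmark CSV (header required) into ComplexRecords.

    Required columns: ``complex_id``; all others optional and may be blank.
    """
    df = pd.read_csv(path, dtype={"complex_id": str})
    if "complex_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'complex_id'")
    records = []
    for i, row in df.iterrows():
        kwargs = {"complex_id": row["complex_id"]}
        for col in _DATASET_COLUMNS[1:]:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = row[col]
        try:
            records.append(ComplexRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i + 2}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"{path}: no data rows")
    return records


def write_dataset(records: list[ComplexRecord], path) -> None:
    """Write ComplexRecords back to CSV with full numeric precision."""
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in _DATASET_COLUMNS} for r in records]
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_coordinates(path) -> Structure:
    """Read a structure from a PDB subset or a ``mass x y z`` table (nm).

    PDB files (detected by ATOM/HETATM records) are read with coordinates
    converted Å -> nm and masses inferred from the element column; the
    plain-text dialect gives mass and coordinates directly in amu and nm.
    """
    text = Path(path).read_text()
    if any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        return _read_pdb(text, path)
    return _read_xyz_mass(text, path)


# Enough of the periodic table for protein/ligand heavy atoms + hydrogens.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "FE": 55.845, "ZN": 65.38, "MG": 24.305, "NA": 22.990, "K": 39.098,
    "CA": 40.078,
}


def _read_pdb(text: str, path) -> Structure:
    coords, masses = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"bad PDB coordinate field: {exc}", line=lineno) from exc
        element = line[76:78].strip().upper()
        if not element:  # fall back on the first letter of the atom name
            element = line[12:16].strip().lstrip("0123456789")[:1].upper()
        mass = _ELEMENT_MASSES.get(element)
        if mass is None:
            raise ParseError(f"unknown element {element!r}", line=lineno)
        coords.append((x * NM_PER_ANGSTROM, y * NM_PER_ANGSTROM,
                       z * NM_PER_ANGSTROM))
        masses.append(mass)
    if not coords:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    return Structure(coords=np.array(coords), masses=np.array(masses))


def _read_xyz_mass(text: str, path) -> Structure:
    coords, masses = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith(_COMMENT_PREFIXES):
            continue
        parts = s.split()
        if len(parts) < 4:
            raise ParseError("expected 'mass x y z'", line=lineno)
        try:
            m, x, y, z = (float(v) for v in parts[:4])
        except ValueError as exc:
            raise ParseError(f"malformed numeric field: {exc}", line=lineno) from exc
        if m <= 0:
            raise ValidationError(f"line {lineno}: non-positive mass {m}")
        masses.append(m)
        coords.append((x, y, z))
    if not coords:
        raise EmptyInputError(f"{path}: no atom lines")
    return Structure(coords=np.array(coords), masses=np.array(masses))


def read_cv_series(path) -> list[CVSample]:
    """Read a CSV with columns time, rg_nm, rmsd_nm (extra columns ignored)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        t, rg, rmsd = cols["time"], cols["rg_nm"], cols["rmsd_nm"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing column {exc}") from exc
    samples = [CVSample(time=row[t], rg=row[rg], rmsd=row[rmsd])
               for _, row in df.iterrows()]
    if not samples:
        raise EmptyInputError(f"{path}: no rows")
    times = [s.time for s in samples]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError(f"{path}: time not non-decreasing")
    return samples


def write_cv_series(samples: list[CVSample], path) -> None:
    df = pd.DataFrame({"time": [s.time for s in samples],
                       "rg_nm": [s.rg for s in samples],
                       "rmsd_nm": [s.rmsd for s in samples]})
    df.to_csv(path, index=False, float_format="%.10g")


def write_fel(fel: FELGrid, path) -> None:
    """Serialise a landscape as portable CSV.

    Header comment lines (``#``) carry kT, sample count and both edge
    arrays; data rows list occupied bins as ``i,j,count,g``.
    """
    occ = np.argwhere(fel.occupied)
    with open(path, "w") as fh:
        fh.write(f"# kT_kcal_mol {fel.kT:.10g}\n")
        fh.write(f"# n_samples {fel.n_samples}\n")
        fh.write("# rg_edges " + " ".join(f"{e:.10g}" for e in fel.rg_edges) + "\n")
        fh.write("# rmsd_edges " + " ".join(f"{e:.10g}" for e in fel.rmsd_edges) + "\n")
        fh.write("i,j,count,g_kcal_mol\n")
        for i, j in occ:
            cnt = 0 if fel.counts is None else int(fel.counts[i, j])
            fh.write(f"{i},{j},{cnt},{fel.g[i, j]:.10g}\n")


def read_fel(path) -> FELGrid:
    """Read a landscape written by :func:`write_fel`."""
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, rest = line[1:].strip().partition(" ")
                meta[key] = rest
            elif line.strip() and not line.startswith("i,"):
                rows.append(line.strip().split(","))
    try:
        kT = float(meta["kT_kcal_mol"])
        n_samples = int(meta["n_samples"])
        rg_edges = np.array([float(v) for v in meta["rg_edges"].split()])
        rmsd_edges = np.array([float(v) for v in meta["rmsd_edges"].split()])
    except KeyError as exc:
        raise ParseError(f"{path}: missing landscape metadata {exc}") from exc
    g = np.full((len(rg_edges) - 1, len(rmsd_edges) - 1), np.nan)
    counts = np.zeros_like(g)
    for i, j, cnt, val in rows:
        g[int(i), int(j)] = float(val)
        counts[int(i), int(j)] = float(cnt)
    return FELGrid(rg_edges=rg_edges, rmsd_edges=rmsd_edges, g=g, kT=kT,
                   n_samples=n_samples, counts=counts)
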