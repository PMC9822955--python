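"""Molecular geometries, XYZ file I/O, and the desk-scale test systems.

All coordinates are stored internally in Bohr (Hartree atomic units,
e = hbar = m_e = 1); XYZ files use Angstrom per the de-facto standard.
Nuclei are fixed throughout the package — there is no dynamics on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: element symbol -> atomic number, far enough for the systems in scope
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Zn": 30, "Ag": 47,
}


class GeometryError(ValueError):
    """Invalid geometry construction or parse failure."""


@dataclass(frozen=True)
class MolecularGeometry:
    """A fixed-nuclei molecule: element symbols, Cartesian positions (Bohr),
    total charge and spin multiplicity.

    Only neutral (or at least even-electron) closed-shell systems are in
    scope for the electronic-structure layers built on top of this type.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Bohr
    charge: int = 0
    multiplicity: int = 1
    comment: str = field(default="", compare=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (n, 3), got {coords.shape}")
        if coords.shape[0] != len(self.symbols):
            raise GeometryError("symbols/coords length mismatch")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        for s in self.symbols:
            if s not in ATOMIC_NUMBERS:
                raise GeometryError(f"unknown element symbol {s!r}")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.symbols])

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    def require_closed_shell(self) -> None:
        if self.n_electrons % 2 or self.multiplicity != 1:
            raise GeometryError(
                f"restricted closed-shell scope: {self.n_electrons} electrons, "
                f"multiplicity {self.multiplicity}"
            )

    def translated(self, shift) -> "MolecularGeometry":
        """Rigidly translate by ``shift`` (Bohr)."""
        return MolecularGeometry(
            self.symbols, self.coords + np.asarray(shift, dtype=float),
            self.charge, self.multiplicity, self.comment,
        )

    def nuclear_repulsion(self) -> float:
        z = self.atomic_numbers.astype(float)
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def nuclear_dipole(self) -> np.ndarray:
        """Sum_a Z_a R_a (a.u.), the nuclear part of the dipole moment."""
        return self.atomic_numbers.astype(float) @ self.coords

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.symbols:
            counts[s] = counts.get(s, 0) + 1
        return counts


def _unit(v, name):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"{name} must be a nonzero vector")
    return v / n


def make_h2_dimer(
    bond_length: float = 1.4,
    separation: float = 6.0,
    bond_axis=(0.0, 0.0, 1.0),
    separation_axis=(1.0, 0.0, 0.0),
) -> MolecularGeometry:
    """Two parallel H2 molecules, centroid at the origin.

    Bonds (length ``bond_length`` Bohr) lie along ``bond_axis``; the two
    molecular midpoints are displaced by ``separation`` Bohr along
    ``separation_axis``. The two axes must be orthonormal. The defaults
    (r_HH = 1.4 Bohr, 6 Bohr apart, bonds along z, separation along x)
    put the four atoms in the xz plane, so a z-polarized pulse leaves the
    in-plane mirror symmetry intact.
    """
    if bond_length <= 0:
        raise GeometryError("bond_length must be positive")
    if separation <= 0:
        raise GeometryError("separation must be positive (molecules overlap)")
    b = _unit(bond_axis, "bond_axis")
    s = _unit(separation_axis, "separation_axis")
    if abs(b @ s) > 1e-10:
        raise GeometryError("bond_axis and separation_axis must be orthogonal")
    half_bond = 0.5 * bond_length * b
    half_sep = 0.5 * separation * s
    coords = np.array([
        -half_sep - half_bond,
        -half_sep + half_bond,
        +half_sep - half_bond,
        +half_sep + half_bond,
    ])
    return MolecularGeometry(("H", "H", "H", "H"), coords,
                             comment="H2 dimer fixture")


# gas-phase water monomer geometry
_R_OH_ANG = 0.9572
_HOH_DEG = 104.52


def make_h2o_dimer(oo_distance: float) -> MolecularGeometry:
    """Hydrogen-bonded water dimer with O...O distance ``oo_distance`` (Bohr).

    The donor molecule points one O-H bond straight at the acceptor oxygen
    along the O-O (x) axis; monomers use r_OH = 0.9572 A, HOH = 104.52 deg.
    The acceptor's bonds lie in the xy plane, the donor's free H in the xz
    plane, giving the usual near-Cs arrangement. Any positive separation is
    accepted (studies of the indicator scheme go out to 10 A).
    """
    if oo_distance <= 0:
        raise GeometryError("oo_distance must be positive")
    r_oh = _R_OH_ANG * BOHR_PER_ANGSTROM
    half = math.radians(_HOH_DEG) / 2.0
    full = math.radians(_HOH_DEG)

    # acceptor at origin, bonds opening away from the donor (+x side)
    acc_o = np.zeros(3)
    acc_h1 = r_oh * np.array([-math.cos(half), math.sin(half), 0.0])
    acc_h2 = r_oh * np.array([-math.cos(half), -math.sin(half), 0.0])

    don_o = np.array([oo_distance, 0.0, 0.0])
    don_h_bridge = don_o + r_oh * np.array([-1.0, 0.0, 0.0])
    don_h_free = don_o + r_oh * np.array(
        [-math.cos(full), 0.0, math.sin(full)]
    )
    coords = np.array([acc_o, acc_h1, acc_h2, don_o, don_h_bridge, don_h_free])
    return MolecularGeometry(("O", "H", "H", "O", "H", "H"), coords,
                             comment="H2O dimer fixture")


def read_xyz(path) -> MolecularGeometry:
    """Read a standard XYZ file (count line, comment line, element + Angstrom
    columns); coordinates are converted to Bohr on input."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GeometryError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise GeometryError(f"{path}: malformed atom-count line") from exc
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise GeometryError(
            f"{path}: count line says {n} atoms but only {len(body)} atom lines"
        )
    symbols, coords = [], []
    for ln in body[:n]:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{path}: malformed atom line {ln!r}")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise GeometryError(f"{path}: unknown element symbol {parts[0]!r}")
        symbols.append(sym)
        coords.append([float(x) for x in parts[1:4]])
    coords = np.array(coords) * BOHR_PER_ANGSTROM
    return MolecularGeometry(tuple(symbols), coords, comment=comment)


def write_xyz(geom: MolecularGeometry, path) -> None:
    """Write ``geom`` as a standard XYZ file (Angstrom)."""
    lines = [str(geom.n_atoms), geom.comment or "generated by aotrunc"]
    for sym, xyz in zip(geom.symbols, geom.coords * ANGSTROM_PER_BOHR):
        lines.append(f"{sym:<3s} {xyz[0]:>18.10f} {xyz[1]:>18.10f} {xyz[2]:>18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")
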