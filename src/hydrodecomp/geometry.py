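"""Molecular geometry and solvent-accessible surface area (ASA).

The solvent-accessible surface is the locus traced by the centre of a
spherical probe (default 1.4 Å, a water molecule) rolled over the van der
Waals surface of the solute.  ASA is computed by the Shrake–Rupley method:
a quasi-uniform lattice of test points is placed on each atom's
probe-expanded sphere and a point contributes area iff it lies outside
every other atom's expanded sphere.

Point placement uses a deterministic golden-spiral lattice, so results are
bit-reproducible for a fixed point count — no random state is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "ASAResult",
    "BONDI_RADII",
    "read_coordinates",
    "read_radii_table",
    "assign_radii",
    "sphere_points",
    "shrake_rupley_asa",
]

#: Bondi van der Waals radii (Å) for the elements that occur in small
#: organic solutes.  User-overridable wherever a radius set is accepted.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

# Element symbols recognised by the readers (organic subset plus common
# heteroatoms); parsing fails loudly on anything else.
_KNOWN_ELEMENTS = frozenset(
    BONDI_RADII
) | frozenset({"B", "Si", "Se", "Na", "K", "Mg", "Ca", "Zn", "Fe"})


class CoordinateParseError(ValueError):
    """Raised when an XYZ/PDB file does not parse under its dialect."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, Cartesian position (Å), vdW radius (Å).

    ``vdw_radius`` is ``None`` until :func:`assign_radii` runs; coordinate
    files never carry radii.
    """

    element: str
    position: np.ndarray
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.vdw_radius is not None and not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")


@dataclass(frozen=True)
class Molecule:
    """A named, ordered collection of atoms."""

    name: str
    atoms: tuple[Atom, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise ValueError("a Molecule needs at least one atom")
        coords = self.coordinates
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 == 0.0):
            i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
            raise ValueError(f"atoms {i} and {j} sit at identical positions")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def radii(self) -> np.ndarray:
        """Assigned vdW radii; raises if any atom is missing one."""
        vals = []
        for i, a in enumerate(self.atoms):
            if a.vdw_radius is None:
                raise RuntimeError(
                    f"atom {i} ({a.element}) has no vdW radius; call assign_radii first"
                )
            vals.append(a.vdw_radius)
        return np.array(vals)


@dataclass(frozen=True)
class ASAResult:
    """Total and per-atom solvent-accessible surface area (Å²).

    ``total_asa`` is exactly ``sum(per_atom_asa)`` by construction.
    """

    total_asa: float
    per_atom_asa: tuple[float, ...]
    probe_radius: float
    n_sphere_points: int


def _normalize_element(raw: str) -> str:
    sym = raw.strip()
    if not sym:
        return sym
    return sym[0].upper() + sym[1:].lower()


def _parse_xyz(lines: list[str], name: str) -> Molecule:
    if not lines:
        raise CoordinateParseError("empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise CoordinateParseError(f"XYZ header is not an atom count: {lines[0]!r}") from None
    body = [ln for ln in lines[2 : 2 + count]]
    records = [ln for ln in body if ln.strip()]
    if len(records) != count:
        raise CoordinateParseError(
            f"XYZ header declares {count} atoms but {len(records)} records follow"
        )
    atoms = []
    for offset, ln in enumerate(records):
        parts = ln.split()
        if len(parts) < 4:
            raise CoordinateParseError(f"line {offset + 3}: expected 'El x y z', got {ln!r}")
        el = _normalize_element(parts[0])
        if el not in _KNOWN_ELEMENTS:
            raise CoordinateParseError(f"line {offset + 3}: unknown element symbol {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise CoordinateParseError(f"line {offset + 3}: non-numeric coordinate in {ln!r}") from None
        atoms.append(Atom(el, np.array(xyz)))
    return Molecule(name, tuple(atoms))


def _parse_pdb(lines: list[str], name: str) -> Molecule:
    atoms = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(ln[30:38])
            y = float(ln[38:46])
            z = float(ln[46:54])
        except ValueError:
            raise CoordinateParseError(f"line {lineno}: bad coordinate fields in {ln!r}") from None
        el_field = ln[76:78].strip() if len(ln) >= 77 else ""
        if not el_field:
            # fall back to the atom-name column, stripping digits
            el_field = "".join(c for c in ln[12:16] if c.isalpha())[:2]
            if len(el_field) == 2 and _normalize_element(el_field) not in _KNOWN_ELEMENTS:
                el_field = el_field[0]
        el = _normalize_element(el_field)
        if el not in _KNOWN_ELEMENTS:
            raise CoordinateParseError(f"line {lineno}: unknown element symbol {el_field!r}")
        atoms.append(Atom(el, np.array([x, y, z])))
    if not atoms:
        raise CoordinateParseError("no ATOM/HETATM records found")
    return Molecule(name, tuple(atoms))


def read_coordinates(path, fmt: str | None = None) -> Molecule:
    """Read a molecule from an XYZ or PDB file.

    Parameters
    ----------
    path:
        File path.  The molecule name is the file stem.
    fmt:
        ``"xyz"`` or ``"pdb"``; inferred from the suffix when omitted.
    """
    from pathlib import Path

    p = Path(path)
    if fmt is None:
        fmt = p.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in {"xyz", "pdb"}:
        raise ValueError(f"unsupported coordinate format {fmt!r} (use 'xyz' or 'pdb')")
    lines = p.read_text(encoding="utf-8").splitlines()
    if fmt == "xyz":
        return _parse_xyz(lines, p.stem)
    return _parse_pdb(lines, p.stem)


def read_radii_table(path) -> dict[str, float]:
    """Read a two-column (element, radius Å) whitespace/comma text table."""
    from pathlib import Path

    table: dict[str, float] = {}
    for lineno, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        ln = ln.split("#")[0].strip()
        if not ln:
            continue
        parts = ln.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"radii table line {lineno}: expected 'element radius', got {ln!r}")
        table[_normalize_element(parts[0])] = float(parts[1])
    return table


def assign_radii(mol: Molecule, radius_set: dict[str, float] | None = None) -> Molecule:
    """Return a copy of *mol* with vdW radii assigned from a lookup table.

    Defaults to :data:`BONDI_RADII`.  Raises ``KeyError`` listing every
    element the table is missing.
    """
    table = BONDI_RADII if radius_set is None else radius_set
    missing = sorted({el for el in mol.elements if el not in table})
    if missing:
        raise KeyError(f"radius set has no entry for element(s): {', '.join(missing)}")
    atoms = tuple(replace(a, vdw_radius=float(table[a.element])) for a in mol.atoms)
    return Molecule(mol.name, atoms)


def sphere_points(n: int) -> np.ndarray:
    """*n* quasi-uniform unit-sphere points on a golden-spiral lattice.

    Deterministic: no RNG, so repeated calls are bit-identical.
    """
    if n < 12:
        raise ValueError(f"need at least 12 sphere points, got {n}")
    k = np.arange(n, dtype=float)
    # z descends uniformly through (-1, 1); azimuth advances by the golden angle
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_asa(
    mol: Molecule,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    include_hydrogens: bool = True,
) -> ASAResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom contributes ``(exposed points / total points) × 4π(r_i + p)²``
    where *p* is the probe radius.  A test point is exposed iff it lies
    strictly outside every *other* atom's expanded sphere; a point exactly
    on a neighbour's surface counts as exposed.

    When ``include_hydrogens`` is false, H atoms neither contribute area
    nor occlude other atoms; per-atom entries for H are zero (order kept).
    """
    if probe_radius < 0:
        raise ValueError(f"probe_radius must be non-negative, got {probe_radius}")
    radii = mol.radii  # raises if unassigned
    coords = mol.coordinates
    keep = np.ones(len(mol), dtype=bool)
    if not include_hydrogens:
        keep = np.array([el != "H" for el in mol.elements])
        if not keep.any():
            raise ValueError("no heavy atoms left after excluding hydrogens")

    unit = sphere_points(n_sphere_points)
    expanded = radii + probe_radius
    per_atom = np.zeros(len(mol))
    active = np.flatnonzero(keep)
    for i in active:
        r_i = expanded[i]
        pts = coords[i] + r_i * unit  # (n, 3)
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in active:
            if j == i:
                continue
            # cheap reject: spheres can't overlap
            d_ij = np.linalg.norm(coords[j] - coords[i])
            if d_ij >= r_i + expanded[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= expanded[j] ** 2  # boundary ties count as exposed
            if not exposed.any():
                break
        frac = np.count_nonzero(exposed) / n_sphere_points
        per_atom[i] = frac * 4.0 * math.pi * r_i**2
    per_atom_vals = tuple(float(v) for v in per_atom)
    return ASAResult(
        total_asa=float(sum(per_atom_vals)),
        per_atom_asa=per_atom_vals,
        probe_radius=float(probe_radius),
        n_sphere_points=int(n_sphere_points),
    )
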