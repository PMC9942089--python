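"""Molecular geometry: XYZ I/O, selection filters, cell placement, height maps.

A :class:`Molecule` is an ordered list of (element, x, y, z) atoms in
angstrom with a non-negative integer identifier (CID-like). Selection
filters implement the quasi-planar organic-molecule criteria used to build
constant-height AFM image collections: an element whitelist, a minimum atom
count, an xy footprint that fits a square simulation cell, and a bounded
z-extent (quasi-planarity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .elements import (
    PERIODIC_SYMBOLS,
    SUPPORTED_ELEMENTS,
    ElementTable,
    default_element_table,
)

__all__ = [
    "Atom",
    "Molecule",
    "FilterCriteria",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "z_extent",
    "passes_filter",
    "center_in_cell",
    "chemical_formula",
    "height_map",
]

_CID_RE = re.compile(r"CID=(\d+)")


@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Molecule:
    """An identified molecular geometry (coordinates in angstrom)."""

    id: int
    atoms: Tuple[Atom, ...]
    name: Optional[str] = None
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError("molecule id must be non-negative")
        if len(self.atoms) < 1:
            raise ValueError("molecule must have at least one atom")
        object.__setattr__(self, "atoms", tuple(self.atoms))
        coords = self.coordinates
        if not np.all(np.isfinite(coords)):
            raise ValueError("all coordinates must be finite")

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    @property
    def elements(self) -> Tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def with_coordinates(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        new_atoms = tuple(
            Atom(a.element, *xyz) for a, xyz in zip(self.atoms, coords)
        )
        return replace(self, atoms=new_atoms)


@dataclass(frozen=True)
class FilterCriteria:
    """Selection rules for the quasi-planar organic subset."""

    allowed_elements: frozenset = field(default_factory=lambda: SUPPORTED_ELEMENTS)
    min_atoms: int = 8
    cell_side: float = 24.0
    max_z_extent: float = 1.83

    def __post_init__(self) -> None:
        if self.min_atoms < 1:
            raise ValueError("min_atoms must be >= 1")
        if self.cell_side <= 0:
            raise ValueError("cell_side must be > 0")
        if self.max_z_extent <= 0:
            raise ValueError("max_z_extent must be > 0")
        object.__setattr__(self, "allowed_elements", frozenset(self.allowed_elements))


class XYZParseError(ValueError):
    """Raised for malformed XYZ files; message names the offending line."""


def read_xyz(path) -> Molecule:
    """Read a standard XYZ file (count line, comment line, atom records).

    The comment line is scanned for a ``CID=<n>`` token; absent that the
    molecule id is 0. Unknown element symbols and non-numeric coordinates
    raise :class:`XYZParseError` naming the line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path} line 1: malformed atom count {lines[0]!r}") from None
    if natoms < 1:
        raise XYZParseError(f"{path} line 1: atom count must be >= 1")
    comment = lines[1] if len(lines) > 1 else ""
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) != natoms:
        raise XYZParseError(
            f"{path}: count line says {natoms} atoms but {len(records)} records follow"
        )
    atoms: List[Atom] = []
    for i, ln in enumerate(records, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path} line {i}: expected 'element x y z', got {ln!r}")
        sym = parts[0]
        if sym not in PERIODIC_SYMBOLS:
            raise XYZParseError(f"{path} line {i}: unknown element symbol {sym!r}")
        try:
            x, y, z = (float(v) for v in parts[1:4])
        except ValueError:
            raise XYZParseError(f"{path} line {i}: non-numeric coordinate in {ln!r}") from None
        atoms.append(Atom(sym, x, y, z))
    m = _CID_RE.search(comment)
    cid = int(m.group(1)) if m else 0
    name = None
    stripped = _CID_RE.sub("", comment).strip()
    if stripped:
        name = stripped
    return Molecule(id=cid, atoms=tuple(atoms), name=name)


def write_xyz(molecule: Molecule, path) -> None:
    """Write a standard XYZ file carrying ``CID=<id>`` in the comment line."""
    path = Path(path)
    lines = [str(len(molecule.atoms))]
    comment = f"CID={molecule.id}"
    if molecule.name:
        comment = f"{molecule.name} {comment}"
    lines.append(comment)
    for a in molecule.atoms:
        lines.append(f"{a.element:<2s} {a.x:15.6f} {a.y:15.6f} {a.z:15.6f}")
    path.write_text("\n".join(lines) + "\n")


def z_extent(molecule: Molecule) -> float:
    """Height spread max(z) - min(z); 0 for a single atom."""
    zs = molecule.coordinates[:, 2]
    return float(zs.max() - zs.min())


def passes_filter(molecule: Molecule, criteria: Optional[FilterCriteria] = None) -> Tuple[bool, str]:
    """Apply the four selection rules; returns (accepted, reason).

    ``reason`` names the first failing rule ("element", "min_atoms", "cell",
    "z_extent") or is "ok". The z-extent threshold is inclusive. The cell
    fit uses raw atomic centers (no radii padding).
    """
    if criteria is None:
        criteria = FilterCriteria()
    bad = set(molecule.elements) - set(criteria.allowed_elements)
    if bad:
        return False, "element"
    if len(molecule) < criteria.min_atoms:
        return False, "min_atoms"
    coords = molecule.coordinates
    spans = coords[:, :2].max(axis=0) - coords[:, :2].min(axis=0)
    if spans[0] > criteria.cell_side or spans[1] > criteria.cell_side:
        return False, "cell"
    if z_extent(molecule) > criteria.max_z_extent:
        return False, "z_extent"
    return True, "ok"


def center_in_cell(molecule: Molecule, cell_side: float = 24.0, z_ref: float = 0.0) -> Molecule:
    """Translate so the xy centroid sits at the cell center and the mean
    atomic z at ``z_ref``. Relative geometry is untouched; idempotent.
    """
    coords = molecule.coordinates
    spans = coords[:, :2].max(axis=0) - coords[:, :2].min(axis=0)
    if spans.max() > cell_side:
        raise ValueError(
            f"molecule xy footprint {spans.max():.2f} A exceeds cell side {cell_side} A"
        )
    shift = np.empty(3)
    centroid = coords.mean(axis=0)
    shift[:2] = cell_side / 2.0 - centroid[:2]
    shift[2] = z_ref - centroid[2]
    return molecule.with_coordinates(coords + shift)


def chemical_formula(molecule: Molecule) -> str:
    """Hill-notation formula: C first, H second, remaining alphabetical."""
    counts: dict = {}
    for sym in molecule.elements:
        counts[sym] = counts.get(sym, 0) + 1

    def fmt(sym: str) -> str:
        n = counts[sym]
        return sym if n == 1 else f"{sym}{n}"

    parts: List[str] = []
    if "C" in counts:
        parts.append(fmt("C"))
        if "H" in counts:
            parts.append(fmt("H"))
        rest = sorted(s for s in counts if s not in ("C", "H"))
    else:
        rest = sorted(counts)
    parts.extend(fmt(s) for s in rest)
    return "".join(parts)


def height_map(
    molecule: Molecule,
    pixels: int = 256,
    cell_side: float = 24.0,
    table: Optional[ElementTable] = None,
) -> np.ndarray:
    """Grayscale atom-height descriptor image.

    Each atom is painted as a filled disk of its render radius; intensity is
    linear in atomic z between the molecule's min and max z (single-plane
    molecules render at mid-gray 0.5). Higher atoms are painted later and
    overwrite lower ones on overlap. Returns a float array in [0, 1] of
    shape (pixels, pixels); row 0 is y = 0.
    """
    if pixels <= 0:
        raise ValueError("pixels must be > 0")
    if table is None:
        table = default_element_table()
    coords = molecule.coordinates
    zmin, zmax = coords[:, 2].min(), coords[:, 2].max()
    zspan = zmax - zmin
    img = np.zeros((pixels, pixels), dtype=float)
    scale = pixels / cell_side  # px per A
    xs = (np.arange(pixels) + 0.5) / scale
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    order = np.argsort(coords[:, 2], kind="stable")
    for idx in order:
        a = molecule.atoms[idx]
        r = table[a.element].render_radius
        intensity = 0.5 if zspan == 0 else (a.z - zmin) / zspan
        mask = (X - a.x) ** 2 + (Y - a.y) ** 2 <= r * r
        img[mask] = intensity
    return img
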