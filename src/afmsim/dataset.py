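"""Parameter-grid enumeration, dataset layout, builder, lookup and fixtures.

An image collection is organized as one subset directory per (amplitude,
stiffness) pair, each holding one subfolder per molecule (named by its
CID-like integer id) with one grayscale PNG per tip-sample distance:

    root/
      layout.json                  <- machine-readable layout convention
      manifest.json                <- per-molecule status + image checksums
      index_formula.json           <- formula -> [CID, ...]
      index_name.json / index_formula_by_cid.json
      A00.40_K00.40/<CID>/df_0.png ... df_9.png + stack.json

``df_0.png`` is the farthest height. The default parameter grid spans
6 amplitudes x 4 stiffnesses x 10 heights = 240 combinations and hence
24 subsets of 10 images per molecule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .elements import default_element_table
from .geometry import (
    Atom,
    FilterCriteria,
    Molecule,
    center_in_cell,
    chemical_formula,
    passes_filter,
)
from .grids import GridSpec
from .pipeline import build_force_field
from .relaxation import ScanConfig
from .spectroscopy import CantileverConfig, generate_stacks

__all__ = [
    "ParameterGrid",
    "DatasetLayout",
    "BuildConfig",
    "BuildSummary",
    "enumerate_combinations",
    "subset_directories",
    "subset_label",
    "build_dataset",
    "lookup",
    "audit",
    "fixture_molecules",
]

LAYOUT_VERSION = 1


@dataclass(frozen=True)
class ParameterGrid:
    """The (amplitude, stiffness, height) grid of operational parameters."""

    amplitudes: Tuple[float, ...] = (0.40, 0.60, 0.80, 1.00, 1.20, 1.40)  # A
    kappas: Tuple[float, ...] = (0.40, 0.60, 0.80, 1.00)  # N/m
    heights: Tuple[float, ...] = (
        2.80, 2.90, 3.00, 3.10, 3.20, 3.30, 3.40, 3.50, 3.60, 3.70,
    )  # A

    def __post_init__(self) -> None:
        for name in ("amplitudes", "kappas", "heights"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, vals)


def enumerate_combinations(grid: ParameterGrid) -> List[Tuple[float, float, float]]:
    """Cartesian product of the grid in (A-major, kappa, height) order."""
    return [
        (a, k, h)
        for a in grid.amplitudes
        for k in grid.kappas
        for h in grid.heights
    ]


def subset_label(amplitude: float, kappa: float) -> str:
    """Zero-padded fixed-width subset directory name for one (A, kappa)."""
    return f"A{amplitude:05.2f}_K{kappa:05.2f}"


def subset_directories(grid: ParameterGrid) -> List[str]:
    """One subset label per (A, kappa) pair, in enumeration order."""
    return [subset_label(a, k) for a in grid.amplitudes for k in grid.kappas]


@dataclass(frozen=True)
class DatasetLayout:
    """Filesystem conventions of a built collection."""

    root: Path
    image_pattern: str = "df_{index}.png"
    manifest_name: str = "manifest.json"
    layout_name: str = "layout.json"
    index_formula: str = "index_formula.json"
    index_name: str = "index_name.json"
    index_formula_by_cid: str = "index_formula_by_cid.json"

    def subset_dir(self, amplitude: float, kappa: float) -> Path:
        return Path(self.root) / subset_label(amplitude, kappa)

    def molecule_dir(self, amplitude: float, kappa: float, cid: int) -> Path:
        return self.subset_dir(amplitude, kappa) / str(cid)

    def image_path(self, amplitude: float, kappa: float, cid: int, height_index: int) -> Path:
        return self.molecule_dir(amplitude, kappa, cid) / self.image_pattern.format(
            index=height_index
        )

    def write_layout_spec(self, grid: ParameterGrid) -> None:
        spec = {
            "version": LAYOUT_VERSION,
            "subset_pattern": "A{amplitude:05.2f}_K{kappa:05.2f}",
            "molecule_subfolder": "<CID>",
            "image_pattern": self.image_pattern,
            "height_order": "index 0 is the farthest height, 9 the closest",
            "amplitudes_A": list(grid.amplitudes),
            "kappas_N_per_m": list(grid.kappas),
            "heights_A": list(grid.heights),
        }
        Path(self.root).mkdir(parents=True, exist_ok=True)
        (Path(self.root) / self.layout_name).write_text(json.dumps(spec, indent=2) + "\n")


@dataclass
class BuildConfig:
    """Everything the builder needs besides the molecules and the grid."""

    grid_spec: GridSpec = field(default_factory=GridSpec)
    pixels: int = 256
    cantilever: CantileverConfig = field(default_factory=CantileverConfig)
    apply_filter: bool = True
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    normalize: str = "image"
    dz: float = 0.1
    force_tol: float = 1e-6
    max_iter: int = 400


@dataclass
class BuildSummary:
    """Outcome of a build run."""

    built: int = 0
    skipped: int = 0  # already complete (resume)
    filtered: int = 0
    failed: int = 0
    images_written: int = 0
    errors: Dict[int, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.failed == 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _molecule_complete(layout: DatasetLayout, manifest: dict, cid: int,
                       grid: ParameterGrid) -> bool:
    """A molecule is complete when every recorded image checksum matches disk."""
    entry = manifest.get("molecules", {}).get(str(cid))
    if not entry or entry.get("status") != "ok":
        return False
    n_heights = len(grid.heights)
    for a in grid.amplitudes:
        for k in grid.kappas:
            label = subset_label(a, k)
            recorded = entry.get("images", {}).get(label)
            if not recorded or len(recorded) != n_heights:
                return False
            for fname, digest in recorded.items():
                p = layout.molecule_dir(a, k, cid) / fname
                if not p.exists() or _sha256(p) != digest:
                    return False
    return True


def build_dataset(
    molecules: Sequence[Molecule],
    grid: Optional[ParameterGrid] = None,
    config: Optional[BuildConfig] = None,
    root="dataset",
) -> Tuple[DatasetLayout, BuildSummary]:
    """Simulate and write the full image tree for a set of molecules.

    Per molecule: optional filtering, cell centering, one force-field
    build, one relaxed scan per stiffness (shared across amplitudes and
    heights), then one PNG per (A, kappa, height). Resume is idempotent:
    molecules whose recorded image checksums all match on disk are skipped
    and nothing is rewritten. Per-molecule failures are logged in the
    summary and do not abort the run.
    """
    if grid is None:
        grid = ParameterGrid()
    if config is None:
        config = BuildConfig()
    layout = DatasetLayout(root=Path(root))
    layout.write_layout_spec(grid)
    manifest_path = Path(root) / layout.manifest_name
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    else:
        manifest = {"version": LAYOUT_VERSION, "molecules": {}}
    summary = BuildSummary()
    table = default_element_table()
    cfg = ScanConfig(
        dz=config.dz,
        force_tol=config.force_tol,
        max_iter=config.max_iter,
        heights=grid.heights,
        pixels=config.pixels,
    )
    for mol in molecules:
        cid = mol.id
        if config.apply_filter:
            ok, reason = passes_filter(mol, config.criteria)
            if not ok:
                summary.filtered += 1
                manifest["molecules"][str(cid)] = {
                    "status": "filtered", "reason": reason,
                    "formula": chemical_formula(mol), "name": mol.name,
                }
                continue
        if _molecule_complete(layout, manifest, cid, grid):
            summary.skipped += 1
            continue
        try:
            centered = center_in_cell(mol, cell_side=config.grid_spec.cell_side)
            ff = build_force_field(centered, table, config.grid_spec, center=False)
            images: Dict[str, Dict[str, str]] = {}
            for kappa in grid.kappas:
                stacks = generate_stacks(
                    centered, ff, kappa, grid.amplitudes,
                    cfg=cfg, cant=config.cantilever, normalize=config.normalize,
                )
                for amp, stack in zip(grid.amplitudes, stacks):
                    mdir = layout.molecule_dir(amp, kappa, cid)
                    paths = stack.save(mdir)
                    images[subset_label(amp, kappa)] = {
                        p.name: _sha256(p) for p in paths
                    }
                    summary.images_written += len(paths)
            manifest["molecules"][str(cid)] = {
                "status": "ok",
                "formula": chemical_formula(mol),
                "name": mol.name,
                "images": images,
            }
            summary.built += 1
        except Exception as exc:  # noqa: BLE001 - per-molecule isolation
            summary.failed += 1
            summary.errors[cid] = str(exc)
            manifest["molecules"][str(cid)] = {
                "status": "error", "reason": str(exc),
                "formula": chemical_formula(mol), "name": mol.name,
            }
    manifest["parameters"] = {
        "amplitudes_A": list(grid.amplitudes),
        "kappas_N_per_m": list(grid.kappas),
        "heights_A": list(grid.heights),
        "pixels": config.pixels,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    _write_indexes(layout, manifest)
    return layout, summary


def _write_indexes(layout: DatasetLayout, manifest: dict) -> None:
    by_formula: Dict[str, List[int]] = {}
    by_cid_name: Dict[str, Optional[str]] = {}
    by_cid_formula: Dict[str, str] = {}
    for cid_s, entry in manifest.get("molecules", {}).items():
        if entry.get("status") != "ok":
            continue
        f = entry.get("formula", "")
        by_formula.setdefault(f, []).append(int(cid_s))
        by_cid_name[cid_s] = entry.get("name")
        by_cid_formula[cid_s] = f
    root = Path(layout.root)
    (root / layout.index_formula).write_text(json.dumps(by_formula, indent=2) + "\n")
    (root / layout.index_name).write_text(json.dumps(by_cid_name, indent=2) + "\n")
    (root / layout.index_formula_by_cid).write_text(
        json.dumps(by_cid_formula, indent=2) + "\n"
    )


class IndexMissingError(FileNotFoundError):
    """The dataset root lacks its index files (distinct from 'no match')."""


def lookup(query: str, root) -> Dict[int, List[str]]:
    """Find molecules by CID, chemical formula, or exact name.

    All-digit queries are CID lookups; otherwise the query is matched first
    as a formula (all CIDs sharing it), then as a case-insensitive exact
    name. Returns {CID: [subset paths holding its images]}; an empty dict
    means no match. A missing index raises :class:`IndexMissingError`.
    """
    root = Path(root)
    layout = DatasetLayout(root=root)
    fpath = root / layout.index_formula
    npath = root / layout.index_name
    if not fpath.exists() or not npath.exists():
        raise IndexMissingError(f"{root}: dataset indexes not found")
    by_formula = json.loads(fpath.read_text())
    by_cid_name = json.loads(npath.read_text())
    cids: List[int] = []
    q = query.strip()
    if q.isdigit():
        if q in by_cid_name:
            cids = [int(q)]
    elif q in by_formula:
        cids = list(by_formula[q])
    else:
        cids = [
            int(c) for c, name in by_cid_name.items()
            if name and name.lower() == q.lower()
        ]
    out: Dict[int, List[str]] = {}
    for cid in sorted(cids):
        paths = sorted(
            str(p.parent.relative_to(root))
            for p in root.glob(f"A*_K*/{cid}/df_0.png")
        )
        out[cid] = paths
    return out


def audit(root) -> Dict[str, int]:
    """fsck-style check: manifest totals vs files actually on disk.

    Returns counts {"manifest_images": n, "disk_images": m, "mismatched": k};
    ``mismatched`` counts recorded images that are missing or whose checksum
    differs.
    """
    root = Path(root)
    layout = DatasetLayout(root=root)
    manifest = json.loads((root / layout.manifest_name).read_text())
    n_manifest = 0
    n_bad = 0
    for cid_s, entry in manifest.get("molecules", {}).items():
        for label, files in entry.get("images", {}).items():
            for fname, digest in files.items():
                n_manifest += 1
                p = root / label / cid_s / fname
                if not p.exists() or _sha256(p) != digest:
                    n_bad += 1
    n_disk = sum(1 for _ in root.glob("A*_K*/*/df_*.png"))
    return {"manifest_images": n_manifest, "disk_images": n_disk, "mismatched": n_bad}


# ---------------------------------------------------------------------------
# Fixture molecules


def _ring(n: int, bond: float, elements: Sequence[str], z: float = 0.0):
    """Regular n-ring of the given elements with the given bond length."""
    radius = bond / (2.0 * np.sin(np.pi / n))
    out = []
    for i, el in enumerate(elements):
        ang = 2.0 * np.pi * i / n
        out.append(Atom(el, radius * np.cos(ang), radius * np.sin(ang), z))
    return out


def _ring_substituents(n: int, bond: float, reach: float, entries, z: float = 0.0):
    """Substituent atoms placed radially outward from ring positions.

    ``entries`` maps ring index -> element symbol (or None to skip).
    """
    radius = bond / (2.0 * np.sin(np.pi / n))
    out = []
    for i, el in entries.items():
        if el is None:
            continue
        ang = 2.0 * np.pi * i / n
        r = radius + reach
        out.append(Atom(el, r * np.cos(ang), r * np.sin(ang), z))
    return out


def fixture_molecules(seed: int = 0) -> List[Molecule]:
    """Deterministic synthetic molecule set for tests and examples.

    Positive fixtures are quasi-planar, 8-30 atoms, fit a 24 A cell and
    jointly cover all ten supported elements, including a halogen- and
    hydroxy-substituted aza-ring analogous to a halogenated pyridinol.
    Four deliberately rejected molecules (named ``reject-<rule>``) each
    violate exactly one selection rule. The seed jitters xy coordinates by
    up to 0.03 A; the same seed always reproduces identical coordinates.
    """
    rng = np.random.default_rng(seed)
    mols: List[Molecule] = []

    # 1. benzene-like C6H6
    atoms = _ring(6, 1.39, ["C"] * 6)
    atoms += _ring_substituents(6, 1.39, 1.09, {i: "H" for i in range(6)})
    mols.append(Molecule(id=9000001, atoms=tuple(atoms), name="hexaring"))

    # 2. halogenated hydroxy aza-ring, composition C5H2BrClINO (12 atoms)
    ring = _ring(6, 1.35, ["N", "C", "C", "C", "C", "C"])
    subs = _ring_substituents(6, 1.35, 1.9, {1: "I", 2: "O", 3: "Br", 5: "Cl"})
    h_on_c = _ring_substituents(6, 1.35, 1.09, {4: "H"})
    # hydroxyl H just beyond the O
    o = subs[1]
    oh = Atom("H", o.x * 1.25, o.y * 1.25, 0.0)
    atoms = ring + subs + h_on_c + [oh]
    mols.append(Molecule(id=9000002, atoms=tuple(atoms), name="halo-aza-ring"))

    # 3. thiophene-like C4H4S (9 atoms)
    ring = _ring(5, 1.42, ["S", "C", "C", "C", "C"])
    subs = _ring_substituents(5, 1.42, 1.09, {1: "H", 2: "H", 3: "H", 4: "H"})
    mols.append(Molecule(id=9000003, atoms=tuple(ring + subs), name="thio-ring"))

    # 4. phosphinine-like C5H5P (11 atoms)
    ring = _ring(6, 1.42, ["P", "C", "C", "C", "C", "C"])
    subs = _ring_substituents(6, 1.42, 1.09, {i: "H" for i in range(1, 6)})
    mols.append(Molecule(id=9000004, atoms=tuple(ring + subs), name="phospha-ring"))

    # 5. fluorinated ring C6H5F (12 atoms)
    ring = _ring(6, 1.39, ["C"] * 6)
    subs = _ring_substituents(6, 1.39, 1.09, {i: "H" for i in range(1, 6)})
    subs += _ring_substituents(6, 1.39, 1.35, {0: "F"})
    mols.append(Molecule(id=9000005, atoms=tuple(ring + subs), name="fluoro-ring"))

    # 6. methylated ring C7H8 with sp3 out-of-plane hydrogens (z span 1.78 A)
    ring = _ring(6, 1.39, ["C"] * 6)
    subs = _ring_substituents(6, 1.39, 1.09, {i: "H" for i in range(1, 6)})
    cm = _ring_substituents(6, 1.39, 1.50, {0: "C"})[0]
    hx = cm.x + 1.03
    methyl_h = [
        Atom("H", hx, cm.y, 0.0),
        Atom("H", cm.x + 0.4, cm.y + 0.6, 0.89),
        Atom("H", cm.x + 0.4, cm.y - 0.6, -0.89),
    ]
    atoms = ring + subs + [cm] + methyl_h
    mols.append(Molecule(id=9000006, atoms=tuple(atoms), name="methyl-ring"))

    # jitter positives in xy only (keeps planarity and cell fit)
    jittered: List[Molecule] = []
    for m in mols:
        coords = m.coordinates
        coords[:, :2] += rng.uniform(-0.03, 0.03, size=(len(m), 2))
        jittered.append(m.with_coordinates(coords))
    mols = jittered

    # negative fixtures, one per selection rule
    mols.append(Molecule(
        id=9100001,
        atoms=(Atom("O", -1.16, 0, 0), Atom("C", 0, 0, 0), Atom("O", 1.16, 0, 0)),
        name="reject-min_atoms",
    ))
    mols.append(Molecule(
        id=9100002,
        atoms=tuple(
            _ring(6, 1.39, ["C"] * 6)
            + _ring_substituents(6, 1.39, 1.09, {i: "H" for i in range(1, 6)})
            + [Atom("Fe", 0.0, 0.0, 1.6)]
        ),
        name="reject-element",
    ))
    chain = [Atom("C", 1.3 * i, 0.0, 0.0) for i in range(20)]
    chain += [Atom("H", -1.0, 0.0, 0.0), Atom("H", 1.3 * 19 + 1.0, 0.0, 0.0)]
    mols.append(Molecule(id=9100003, atoms=tuple(chain), name="reject-cell"))
    ring = _ring(6, 1.39, ["C"] * 6)
    bent = [Atom("H", a.x * 1.78, a.y * 1.78, 2.5 if i % 2 else 0.0)
            for i, a in enumerate(ring)]
    mols.append(Molecule(id=9100004, atoms=tuple(ring + bent), name="reject-z_extent"))
    return mols
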