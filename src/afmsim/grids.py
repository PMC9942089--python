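"""Periodic orthorhombic scalar fields and their I/O.

:class:`Grid3D` carries every volumetric quantity in the pipeline: sample
electron density (e/A^3), sample electrostatic potential (V = eV/e), tip
differential density, and interaction-energy grids (eV). Cells are
orthorhombic and periodic; the default simulation cell is a 24 A square
base with 20 A of height. File formats are XCrySDen XSF 3D datagrids and
Gaussian cube.

The synthetic-field generators stand in for DFT outputs: atom-centered
exponential electron densities normalized to valence-electron counts, a
Gaussian-smeared ionic charge, the periodic Poisson solution for the sample
potential, and a neutral multipolar CO-tip differential density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .elements import ElementTable, default_element_table
from .geometry import Molecule

__all__ = [
    "COULOMB_EV_A",
    "BOHR_A",
    "Grid3D",
    "GridSpec",
    "TipDensity",
    "TipDensityParams",
    "read_xsf",
    "write_xsf",
    "read_cube",
    "synthetic_electron_density",
    "nuclear_charge_density",
    "poisson_potential",
    "synthetic_tip_density",
    "synthetic_probe_density",
    "save_grid_hdf5",
    "load_grid_hdf5",
]

#: Coulomb constant e^2/(4 pi eps0) in eV*A (charges in e, lengths in A).
COULOMB_EV_A = 14.399645
BOHR_A = 0.529177210903


@dataclass
class Grid3D:
    """Scalar field on a periodic orthorhombic lattice.

    ``values[i, j, k]`` lives at ``origin + (i*dx, j*dy, k*dz)``; the cell is
    spanned by the diagonal of ``cell`` and the grid is periodic, so the
    point at index ``nx`` is identified with index 0.
    """

    origin: np.ndarray
    cell: np.ndarray  # (3, 3), rows are lattice vectors; diagonal required
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array with positive shape")
        off = self.cell - np.diag(np.diag(self.cell))
        if np.abs(off).max() > 1e-9:
            raise ValueError("only orthorhombic (diagonal) cells are supported")
        if np.linalg.det(self.cell) <= 0:
            raise ValueError("cell volume must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def lengths(self) -> np.ndarray:
        return np.diag(self.cell).copy()

    @property
    def spacing(self) -> np.ndarray:
        return self.lengths / np.array(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coordinate arrays along each axis (grid-point positions)."""
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        )

    def integral(self) -> float:
        """Midpoint quadrature of the field over the cell."""
        return float(self.values.sum() * self.voxel_volume)

    def like(self, values: np.ndarray) -> "Grid3D":
        """New grid on the same lattice with different values."""
        return Grid3D(self.origin.copy(), self.cell.copy(), values)

    def same_lattice(self, other: "Grid3D", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.cell, other.cell, atol=tol)
        )


@dataclass(frozen=True)
class GridSpec:
    """Lattice specification for synthetic fields and energy grids.

    ``cell_side`` is the square xy side; ``z_height`` the cell height with
    origin at ``z_origin`` (molecule plane at z = 0 by convention, vacuum
    above for the tip scan). ``spacing`` is a target; actual per-axis
    spacings divide the cell lengths exactly.
    """

    cell_side: float = 24.0
    z_height: float = 20.0
    z_origin: float = -6.0
    spacing: float = 0.15

    def __post_init__(self) -> None:
        if self.cell_side <= 0 or self.z_height <= 0 or self.spacing <= 0:
            raise ValueError("cell_side, z_height and spacing must be > 0")

    @property
    def shape(self) -> Tuple[int, int, int]:
        nxy = max(1, round(self.cell_side / self.spacing))
        nz = max(1, round(self.z_height / self.spacing))
        return (nxy, nxy, nz)

    @property
    def origin(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.z_origin])

    @property
    def cell(self) -> np.ndarray:
        return np.diag([self.cell_side, self.cell_side, self.z_height])

    def empty_grid(self) -> Grid3D:
        return Grid3D(self.origin, self.cell, np.zeros(self.shape))

    def meshgrid(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        g = self.empty_grid()
        x, y, z = g.axes()
        return np.meshgrid(x, y, z, indexing="ij")


# ---------------------------------------------------------------------------
# XSF / cube I/O


def write_xsf(grid: Grid3D, path) -> None:
    """Write an XCrySDen 3D datagrid.

    Follows the XSF convention that periodic axes include a duplicated end
    point: an (nx, ny, nz) internal grid is stored as (nx+1, ny+1, nz+1)
    values with the first plane repeated at the far face.
    """
    path = Path(path)
    nx, ny, nz = grid.shape
    ext = np.empty((nx + 1, ny + 1, nz + 1))
    ext[:nx, :ny, :nz] = grid.values
    ext[nx, :, :] = ext[0, :, :]
    ext[:, ny, :] = ext[:, 0, :]
    ext[:, :, nz] = ext[:, :, 0]
    lines = [
        "BEGIN_BLOCK_DATAGRID_3D",
        "  afmsim_grid",
        "  BEGIN_DATAGRID_3D_field",
        f"    {nx + 1} {ny + 1} {nz + 1}",
        "    {:.10f} {:.10f} {:.10f}".format(*grid.origin),
    ]
    for v in grid.cell:
        lines.append("    {:.10f} {:.10f} {:.10f}".format(*v))
    # XSF datagrids are written x-fastest
    flat = ext.transpose(2, 1, 0).reshape(-1)
    for i in range(0, flat.size, 5):
        lines.append("    " + " ".join(f"{v:.17e}" for v in flat[i:i + 5]))
    lines += ["  END_DATAGRID_3D", "END_BLOCK_DATAGRID_3D"]
    path.write_text("\n".join(lines) + "\n")


def read_xsf(path) -> Grid3D:
    """Read the first 3D datagrid of an XSF file.

    The duplicated periodic end points are stripped so the returned grid has
    one value per distinct lattice point.
    """
    path = Path(path)
    tokens_lines = path.read_text().splitlines()
    start = None
    for i, ln in enumerate(tokens_lines):
        if ln.strip().startswith("BEGIN_DATAGRID_3D"):
            start = i
            break
    if start is None:
        raise ValueError(f"{path}: no BEGIN_DATAGRID_3D block found")
    body: list = []
    for ln in tokens_lines[start + 1:]:
        if ln.strip().startswith("END_DATAGRID_3D"):
            break
        body.extend(ln.split())
    else:
        raise ValueError(f"{path}: unterminated datagrid block")
    if len(body) < 13:
        raise ValueError(f"{path}: truncated datagrid header")
    nxe, nye, nze = (int(v) for v in body[0:3])
    origin = np.array([float(v) for v in body[3:6]])
    cell = np.array([float(v) for v in body[6:15]]).reshape(3, 3)
    data = np.array([float(v) for v in body[15:]])
    if data.size != nxe * nye * nze:
        raise ValueError(
            f"{path}: datagrid advertises {nxe * nye * nze} values, found {data.size}"
        )
    ext = data.reshape(nze, nye, nxe).transpose(2, 1, 0)
    vals = ext[: nxe - 1, : nye - 1, : nze - 1]
    return Grid3D(origin, cell, vals.copy())


def read_cube(path) -> Grid3D:
    """Read a Gaussian cube file; Bohr units are converted to angstrom.

    Cube grids are taken as non-periodic samplings and wrapped into a
    periodic cell spanning ``n * spacing`` per axis.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ValueError(f"{path}: truncated cube file")
    natoms_f = lines[2].split()
    natoms = int(natoms_f[0])
    origin = np.array([float(v) for v in natoms_f[1:4]])
    ns = []
    vecs = []
    for ln in lines[3:6]:
        parts = ln.split()
        ns.append(int(parts[0]))
        vecs.append([float(v) for v in parts[1:4]])
    ns = np.array(ns)
    vecs = np.array(vecs)
    # positive voxel counts signal Bohr units (cube convention)
    to_a = BOHR_A if np.all(ns > 0) else 1.0
    ns = np.abs(ns)
    origin = origin * to_a
    vecs = vecs * to_a
    data_tokens: list = []
    for ln in lines[6 + abs(natoms):]:
        data_tokens.extend(ln.split())
    data = np.array([float(v) for v in data_tokens])
    if data.size != int(np.prod(ns)):
        raise ValueError(
            f"{path}: expected {int(np.prod(ns))} values, found {data.size}"
        )
    vals = data.reshape(ns[0], ns[1], ns[2])  # cube order: z fastest
    cell = vecs * ns[:, None]
    # density units in cube are e/Bohr^3; convert to e/A^3
    if to_a != 1.0:
        vals = vals / (BOHR_A ** 3)
    return Grid3D(origin, cell, vals)


def save_grid_hdf5(grid: Grid3D, path, name: str = "grid") -> None:
    """Store a grid (origin, cell, values) in an HDF5 file."""
    import h5py

    with h5py.File(Path(path), "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("origin", data=grid.origin)
        g.create_dataset("cell", data=grid.cell)
        g.create_dataset("values", data=grid.values, compression="gzip")


def load_grid_hdf5(path, name: str = "grid") -> Grid3D:
    """Load a grid stored by :func:`save_grid_hdf5`."""
    import h5py

    with h5py.File(Path(path), "r") as f:
        g = f[name]
        return Grid3D(g["origin"][...], g["cell"][...], g["values"][...])


# ---------------------------------------------------------------------------
# Synthetic sample fields


def _atom_distance_grids(spec: GridSpec, positions: np.ndarray):
    """Yield per-atom distance grids with minimum-image wrap in x and y."""
    X, Y, Z = spec.meshgrid()
    Lx, Ly = spec.cell_side, spec.cell_side
    for pos in positions:
        dx = X - pos[0]
        dy = Y - pos[1]
        dx -= Lx * np.round(dx / Lx)
        dy -= Ly * np.round(dy / Ly)
        dz = Z - pos[2]
        yield np.sqrt(dx * dx + dy * dy + dz * dz)


def synthetic_electron_density(
    molecule: Optional[Molecule],
    table: Optional[ElementTable] = None,
    spec: Optional[GridSpec] = None,
) -> Grid3D:
    """Smooth atom-centered stand-in for the DFT sample electron density.

    rho(r) = sum_a N_val,a * exp(-|r - R_a| / lambda_a) / (8 pi lambda_a^3),
    so each atom integrates to its valence-electron count. ``molecule=None``
    (or an empty atom list wrapped upstream) gives an all-zero grid.
    """
    if table is None:
        table = default_element_table()
    if spec is None:
        spec = GridSpec()
    grid = spec.empty_grid()
    if grid.spacing.max() > 0.5:
        raise ValueError("grid spacing above 0.5 A is too coarse for densities")
    if molecule is None:
        return grid
    vals = grid.values
    positions = molecule.coordinates
    for atom, r in zip(molecule.atoms, _atom_distance_grids(spec, positions)):
        p = table[atom.element]
        lam = p.decay_length
        norm = p.valence_electrons / (8.0 * np.pi * lam ** 3)
        vals += norm * np.exp(-r / lam)
    return grid


def nuclear_charge_density(
    molecule: Optional[Molecule],
    table: Optional[ElementTable] = None,
    spec: Optional[GridSpec] = None,
    smear_sigma: float = 0.4,
) -> Grid3D:
    """Gaussian-smeared ionic point charges (+N_val per atom).

    With the valence charge +N_val per atom the total ionic charge balances
    the synthetic electron density, so their difference is neutral.
    ``smear_sigma`` must resolve on the grid (>= 2 voxels).
    """
    if table is None:
        table = default_element_table()
    if spec is None:
        spec = GridSpec()
    grid = spec.empty_grid()
    if smear_sigma < 2.0 * grid.spacing.max():
        raise ValueError(
            f"smear_sigma {smear_sigma} A under-resolved: needs >= 2 voxels "
            f"({2 * grid.spacing.max():.3f} A)"
        )
    if molecule is None:
        return grid
    vals = grid.values
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * smear_sigma ** 3)
    for atom, r in zip(molecule.atoms, _atom_distance_grids(spec, molecule.coordinates)):
        q = table[atom.element].valence_electrons
        vals += q * norm * np.exp(-0.5 * (r / smear_sigma) ** 2)
    return grid


def poisson_potential(total_charge: Grid3D, neutralize: bool = False) -> Grid3D:
    """Periodic electrostatic potential of a charge density (spectral solve).

    Solves nabla^2 V = -rho / eps0 in the periodic cell by FFT inversion;
    the zero-frequency component is set to 0, so V has zero mean. Units:
    rho in e/A^3 gives V in volts (eV per e).

    A net-charged input is rejected unless ``neutralize=True``, in which
    case the k=0 zeroing amounts to adding a uniform compensating
    background (the standard Ewald convention).
    """
    net = total_charge.integral()
    if not neutralize and abs(net) > 1e-3:
        raise ValueError(
            f"charge density is not neutral (net {net:+.3e} e); "
            "pass neutralize=True to add a uniform compensating background"
        )
    nx, ny, nz = total_charge.shape
    L = total_charge.lengths
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=L[0] / nx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=L[1] / ny)
    kz = 2.0 * np.pi * np.fft.rfftfreq(nz, d=L[2] / nz)
    k2 = (
        kx[:, None, None] ** 2
        + ky[None, :, None] ** 2
        + kz[None, None, :] ** 2
    )
    rho_k = np.fft.rfftn(total_charge.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_k = 4.0 * np.pi * COULOMB_EV_A * rho_k / k2
    v_k[0, 0, 0] = 0.0
    v = np.fft.irfftn(v_k, s=(nx, ny, nz), axes=(0, 1, 2))
    return total_charge.like(v)


# ---------------------------------------------------------------------------
# Tip differential density


@dataclass(frozen=True)
class TipDensityParams:
    """Two opposite-signed Gaussian lobes on the tip axis plus an optional
    axial quadrupole term.

    The apex (negative) lobe sits toward the sample (below the probe
    center); the balancing positive lobe behind it. ``quadrupole`` adds a
    +/-/+ triplet of net-zero charge contributing only even axial moments.
    Defaults give a CO-like weak negative apex dipole; they are free model
    parameters, not fitted values.
    """

    lobe_charge: float = 0.2  # e, magnitude of each dipole lobe
    lobe_offset: float = 0.25  # A, half-separation of the lobes on the axis
    lobe_sigma: float = 0.35  # A, Gaussian width of both lobes
    quadrupole: float = 0.0  # e*A^2, axial quadrupole strength
    quad_offset: float = 0.35  # A, offset of the quadrupole satellites
    quad_sigma: float = 0.30  # A

    def __post_init__(self) -> None:
        if self.lobe_sigma <= 0 or self.quad_sigma <= 0:
            raise ValueError("Gaussian widths must be > 0")
        if self.lobe_offset < 0 or self.quad_offset <= 0:
            raise ValueError("offsets must be non-negative")


@dataclass
class TipDensity:
    """CO-tip differential charge density wrapped on a periodic cell.

    The probe center sits at the grid origin corner (index 0,0,0) with the
    density wrapped periodically, so FFT cross-correlation against sample
    fields directly yields energies indexed by probe position on the same
    lattice. ``axis`` points from probe toward tip body (+z); the apex lobe
    extends along -z toward the sample.
    """

    grid: Grid3D
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        net = abs(self.grid.integral())
        if net > 1e-6:
            raise ValueError(f"tip differential density must be neutral (net {net:.2e} e)")


def _wrapped_axial_gaussian(spec: GridSpec, z0: float, sigma: float) -> np.ndarray:
    """Normalized Gaussian at (0, 0, z0) relative to the cell origin corner,
    minimum-image wrapped on all three axes."""
    g = spec.empty_grid()
    x, y, z = g.axes()
    L = g.lengths
    dx = x - g.origin[0]
    dy = y - g.origin[1]
    dz = z - g.origin[2] - z0
    dx -= L[0] * np.round(dx / L[0])
    dy -= L[1] * np.round(dy / L[1])
    dz -= L[2] * np.round(dz / L[2])
    r2 = (
        dx[:, None, None] ** 2
        + dy[None, :, None] ** 2
        + dz[None, None, :] ** 2
    )
    return np.exp(-0.5 * r2 / sigma ** 2) / ((2.0 * np.pi) ** 1.5 * sigma ** 3)


def synthetic_tip_density(
    params: Optional[TipDensityParams] = None,
    spec: Optional[GridSpec] = None,
) -> TipDensity:
    """Model CO-tip differential density: neutral, axially symmetric.

    The dipole part is -q at z = -lobe_offset (apex side, toward the sample)
    and +q at z = +lobe_offset, giving an axial dipole moment
    p_z = +2 q * lobe_offset (e*A) pointing from the negative apex into the
    tip body. The optional quadrupole triplet is charge-free and dipole-free.
    Discrete quadrature imbalance is corrected by rescaling the positive
    part so the net integral vanishes to < 1e-6 e.
    """
    if params is None:
        params = TipDensityParams()
    if spec is None:
        spec = GridSpec()
    g = spec.empty_grid()
    vals = np.zeros(spec.shape)
    q = params.lobe_charge
    if q != 0.0:
        vals -= q * _wrapped_axial_gaussian(spec, -params.lobe_offset, params.lobe_sigma)
        vals += q * _wrapped_axial_gaussian(spec, +params.lobe_offset, params.lobe_sigma)
    if params.quadrupole != 0.0:
        d = params.quad_offset
        qq = params.quadrupole / (2.0 * d * d)  # satellite charge for Q_zz = quadrupole
        vals += qq * _wrapped_axial_gaussian(spec, -d, params.quad_sigma)
        vals += qq * _wrapped_axial_gaussian(spec, +d, params.quad_sigma)
        vals -= 2.0 * qq * _wrapped_axial_gaussian(spec, 0.0, params.quad_sigma)
    dv = g.voxel_volume
    pos = vals.clip(min=0.0)
    neg = vals.clip(max=0.0)
    s_pos, s_neg = pos.sum() * dv, -neg.sum() * dv
    if s_pos > 0 and s_neg > 0:
        imbalance = abs(s_pos - s_neg) / max(s_pos, s_neg)
        if imbalance > 0.05:
            raise ValueError(
                f"lobe amplitudes unbalanced beyond tolerance ({imbalance:.1%})"
            )
        vals = pos * (s_neg / s_pos) + neg
    return TipDensity(grid=Grid3D(g.origin, g.cell, vals))


def synthetic_probe_density(
    spec: Optional[GridSpec] = None,
    n_electrons: float = 10.0,
    decay_length: float = 0.28,
) -> Grid3D:
    """Non-negative stand-in for the total CO electron density at the probe.

    A single exponential profile wrapped at the cell origin corner (the
    probe center), normalized to the CO valence-electron count (10 e by
    default). This is the density entering the Pauli-overlap term; the
    signed differential density of :func:`synthetic_tip_density` enters
    only the electrostatic convolution.
    """
    if spec is None:
        spec = GridSpec()
    g = spec.empty_grid()
    x, y, z = g.axes()
    L = g.lengths
    dx = x - g.origin[0]
    dy = y - g.origin[1]
    dzc = z - g.origin[2]
    dx -= L[0] * np.round(dx / L[0])
    dy -= L[1] * np.round(dy / L[1])
    dzc -= L[2] * np.round(dzc / L[2])
    r = np.sqrt(
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dzc[None, None, :] ** 2
    )
    lam = decay_length
    g.values[...] = n_electrons / (8.0 * np.pi * lam ** 3) * np.exp(-r / lam)
    return g
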