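"""Tip-sample interaction-energy grids and their continuous evaluation.

The rigid-probe potential-energy surface is split into three grid
contributions indexed by probe (O-apex) position on the cell lattice:

* van der Waals: attractive pairwise -C6/r^6 over the atoms, clamped at a
  per-element minimum-approach radius (the repulsive wall is carried by the
  short-range term, not by a r^-12 term);
* electrostatics: FFT cross-correlation of the sample potential with the
  tip differential charge density, E(R) = integral V(r) drho(r - R) dV;
* short range (Pauli): density-overlap repulsion
  E(R) = V0 * integral rho_sample^alpha (r) rho_tip^alpha (r - R) dV.

A fourth, configuration-dependent term — the harmonic tilt energy of the CO
probe — lives in :mod:`afmsim.relaxation`.

Grids are periodic in all axes; with the standard 24 A cell and ample z
vacuum the wrap-around of the correlations is negligible (validity
condition, not enforced).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .elements import ElementTable, default_element_table
from .geometry import Molecule
from .grids import Grid3D, GridSpec, TipDensity

__all__ = [
    "PROBE_C6",
    "SRParams",
    "ForceFieldGrids",
    "vdw_energy_grid",
    "es_energy_grid",
    "sr_energy_grid",
    "assemble",
    "energy_at",
    "force_at",
]

#: Effective homonuclear C6 of the CO probe apex (eV*A^6), O-dominated.
PROBE_C6 = 20.0


@dataclass(frozen=True)
class SRParams:
    """Density-overlap repulsion parameters: E_SR = V0 * <rho_s^a, rho_t^a>."""

    V0: float = 18.0  # eV*A^3
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class ForceFieldGrids:
    """The three energy grids plus their voxelwise total, on one lattice."""

    E_vdw: Grid3D
    E_es: Grid3D
    E_sr: Grid3D
    E_total: Grid3D
    sr_params: SRParams

    def __post_init__(self) -> None:
        for g in (self.E_es, self.E_sr, self.E_total):
            if not self.E_vdw.same_lattice(g):
                raise ValueError("force-field grids must share one lattice")
        resid = np.abs(
            self.E_total.values - (self.E_vdw.values + self.E_es.values + self.E_sr.values)
        ).max()
        if resid > 1e-12:
            raise ValueError(f"E_total is not the sum of its parts (max dev {resid:.2e} eV)")
        self._force_grids = None

    def force_grids(self):
        """Lattice samples of F = -grad E_total, cached.

        Central differences with periodic wrap in x and y, one-sided at the
        z boundaries. Trilinear interpolation of these samples gives a
        *continuous* force field, which the probe relaxation needs to drive
        its residual below a tight force tolerance (the gradient of the
        interpolated energy itself is discontinuous across voxel facets).
        """
        if self._force_grids is None:
            v = self.E_total.values
            dx, dy, dz = self.E_total.spacing
            fx = -(np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)) / (2.0 * dx)
            fy = -(np.roll(v, -1, axis=1) - np.roll(v, 1, axis=1)) / (2.0 * dy)
            fz = np.empty_like(v)
            fz[:, :, 1:-1] = -(v[:, :, 2:] - v[:, :, :-2]) / (2.0 * dz)
            fz[:, :, 0] = -(v[:, :, 1] - v[:, :, 0]) / dz
            fz[:, :, -1] = -(v[:, :, -1] - v[:, :, -2]) / dz
            self._force_grids = (
                self.E_total.like(fx), self.E_total.like(fy), self.E_total.like(fz),
            )
        return self._force_grids


def _correlate(a: np.ndarray, b: np.ndarray, dv: float) -> np.ndarray:
    """Periodic cross-correlation C[m] = sum_n a[n] b[n - m] * dv via FFT."""
    fa = np.fft.rfftn(a)
    fb = np.fft.rfftn(b)
    return np.fft.irfftn(fa * np.conj(fb), s=a.shape, axes=(0, 1, 2)) * dv


def vdw_energy_grid(
    molecule: Optional[Molecule],
    table: Optional[ElementTable] = None,
    spec: Optional[GridSpec] = None,
    probe_c6: float = PROBE_C6,
) -> Grid3D:
    """Attractive dispersion grid E(R) = -sum_a C6_pair(a) / r_a^6.

    Pair coefficients are geometric means of the element and probe C6.
    Distances are clamped below the element's minimum-approach radius to
    its boundary value, so the grid is finite and everywhere <= 0.
    Minimum-image convention in x and y (periodic cell).
    """
    if table is None:
        table = default_element_table()
    if spec is None:
        spec = GridSpec()
    grid = spec.empty_grid()
    if molecule is None:
        return grid
    X, Y, Z = spec.meshgrid()
    L = spec.cell_side
    vals = grid.values
    for atom in molecule.atoms:
        p = table[atom.element]
        c6_pair = np.sqrt(p.c6 * probe_c6)
        dx = X - atom.x
        dy = Y - atom.y
        dx -= L * np.round(dx / L)
        dy -= L * np.round(dy / L)
        r2 = dx * dx + dy * dy + (Z - atom.z) ** 2
        r2 = np.maximum(r2, p.min_approach ** 2)
        vals -= c6_pair / r2 ** 3
    return grid


def es_energy_grid(v_sample: Grid3D, tip: TipDensity) -> Grid3D:
    """Electrostatic energy grid E(R) = integral V(r) * drho(r - R) dV.

    ``tip.grid`` must live on the same lattice as ``v_sample`` with the
    probe center wrapped at the origin corner; the FFT cross-correlation
    then yields the energy at every probe lattice position. Units: V in
    volts, drho in e/A^3 -> E in eV.
    """
    if not v_sample.same_lattice(tip.grid):
        raise ValueError("sample potential and tip density grids are incommensurate")
    e = _correlate(v_sample.values, tip.grid.values, v_sample.voxel_volume)
    return v_sample.like(e)


def sr_energy_grid(
    rho_sample: Grid3D,
    rho_tip: Grid3D,
    params: Optional[SRParams] = None,
) -> Grid3D:
    """Pauli-repulsion grid from the overlap of probe and sample densities.

    E(R) = V0 * integral rho_sample^alpha (r) * rho_tip^alpha (r - R) dV;
    for alpha = 1 a plain density cross-correlation scaled by V0. Both
    densities must be non-negative; the output is clamped at 0 to remove
    FFT rounding noise (the exact correlation of non-negative fields is
    non-negative).
    """
    if params is None:
        params = SRParams()
    if not rho_sample.same_lattice(rho_tip):
        raise ValueError("sample and tip density grids are incommensurate")
    for name, g in (("sample", rho_sample), ("tip", rho_tip)):
        if g.values.min() < -1e-12:
            raise ValueError(f"{name} density has negative values ({g.values.min():.2e})")
    a = np.clip(rho_sample.values, 0.0, None)
    b = np.clip(rho_tip.values, 0.0, None)
    if params.alpha != 1.0:
        a = a ** params.alpha
        b = b ** params.alpha
    e = params.V0 * _correlate(a, b, rho_sample.voxel_volume)
    return rho_sample.like(np.clip(e, 0.0, None))


def assemble(
    E_vdw: Grid3D,
    E_es: Optional[Grid3D] = None,
    E_sr: Optional[Grid3D] = None,
    sr_params: Optional[SRParams] = None,
) -> ForceFieldGrids:
    """Sum the contributions voxelwise into a :class:`ForceFieldGrids`.

    Omitted parts enter as zero grids on the common lattice; the individual
    grids are retained for diagnostics.
    """
    if E_es is None:
        E_es = E_vdw.like(np.zeros(E_vdw.shape))
    if E_sr is None:
        E_sr = E_vdw.like(np.zeros(E_vdw.shape))
    for g in (E_es, E_sr):
        if not E_vdw.same_lattice(g):
            raise ValueError("force-field parts do not share one lattice")
    total = E_vdw.like(E_vdw.values + E_es.values + E_sr.values)
    return ForceFieldGrids(
        E_vdw=E_vdw,
        E_es=E_es,
        E_sr=E_sr,
        E_total=total,
        sr_params=sr_params or SRParams(),
    )


# ---------------------------------------------------------------------------
# Continuous evaluation (trilinear interpolation, periodic in xy)


def interpolate(grid: Grid3D, positions: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a grid at arbitrary positions.

    ``positions`` is (..., 3) in angstrom. x and y wrap periodically; z must
    lie within the grid's z support (last lattice point inclusive) or a
    ``ValueError`` is raised.
    """
    pos = np.asarray(positions, dtype=float)
    scalar = pos.ndim == 1
    pos = np.atleast_2d(pos)
    sp = grid.spacing
    nx, ny, nz = grid.shape
    fx = (pos[..., 0] - grid.origin[0]) / sp[0]
    fy = (pos[..., 1] - grid.origin[1]) / sp[1]
    fz = (pos[..., 2] - grid.origin[2]) / sp[2]
    if np.any(fz < -1e-9) or np.any(fz > nz - 1 + 1e-9):
        raise ValueError("z position outside grid support")
    fz = np.clip(fz, 0.0, nz - 1)
    ix = np.floor(fx).astype(np.int64)
    iy = np.floor(fy).astype(np.int64)
    iz = np.floor(fz).astype(np.int64)
    iz = np.minimum(iz, nz - 2) if nz > 1 else np.zeros_like(iz)
    tx = fx - ix
    ty = fy - iy
    tz = fz - iz
    ix %= nx
    iy %= ny
    ix1 = (ix + 1) % nx
    iy1 = (iy + 1) % ny
    iz1 = np.minimum(iz + 1, nz - 1)
    v = grid.values
    c000 = v[ix, iy, iz]
    c100 = v[ix1, iy, iz]
    c010 = v[ix, iy1, iz]
    c110 = v[ix1, iy1, iz]
    c001 = v[ix, iy, iz1]
    c101 = v[ix1, iy, iz1]
    c011 = v[ix, iy1, iz1]
    c111 = v[ix1, iy1, iz1]
    c00 = c000 * (1 - tx) + c100 * tx
    c10 = c010 * (1 - tx) + c110 * tx
    c01 = c001 * (1 - tx) + c101 * tx
    c11 = c011 * (1 - tx) + c111 * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    out = c0 * (1 - tz) + c1 * tz
    return out[0] if scalar else out


def energy_at(ff: ForceFieldGrids, position) -> float | np.ndarray:
    """Total rigid-probe energy (eV) at a probe position (trilinear)."""
    return interpolate(ff.E_total, position)


def force_at(ff: ForceFieldGrids, position, h: float = 0.02) -> np.ndarray:
    """Force -grad E_total (eV/A) by central differences of the
    interpolated field with step ``h`` (A)."""
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    scalar = np.asarray(position).ndim == 1
    out = np.empty_like(pos)
    for d in range(3):
        dp = np.zeros(3)
        dp[d] = h
        out[..., d] = -(
            interpolate(ff.E_total, pos + dp) - interpolate(ff.E_total, pos - dp)
        ) / (2.0 * h)
    return out[0] if scalar else out
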