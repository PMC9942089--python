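"""End-to-end field construction: molecule in, force-field grids out.

Chains the synthetic-field generators — electron density, smeared ionic
charge, periodic Poisson potential, tip densities — into the three-part
interaction-energy grid used by the relaxation and imaging layers. Real
(DFT-derived) fields read from XSF/cube files can be substituted for any
synthetic piece; the downstream code only sees :class:`Grid3D` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .elements import ElementTable, default_element_table
from .forcefield import (
    ForceFieldGrids,
    SRParams,
    assemble,
    es_energy_grid,
    sr_energy_grid,
    vdw_energy_grid,
)
from .geometry import Molecule, center_in_cell
from .grids import (
    Grid3D,
    GridSpec,
    TipDensity,
    TipDensityParams,
    nuclear_charge_density,
    poisson_potential,
    synthetic_electron_density,
    synthetic_probe_density,
    synthetic_tip_density,
)

__all__ = ["SampleFields", "build_sample_fields", "build_force_field"]


@dataclass
class SampleFields:
    """The volumetric inputs of one sample: density and potential."""

    rho_electron: Grid3D  # e/A^3, non-negative
    v_sample: Grid3D  # V, zero-mean periodic potential


def build_sample_fields(
    molecule: Molecule,
    table: Optional[ElementTable] = None,
    spec: Optional[GridSpec] = None,
    smear_sigma: Optional[float] = None,
) -> SampleFields:
    """Synthetic sample electron density and electrostatic potential.

    The total charge density entering the Poisson solve is the smeared
    ionic charge minus the electron density; both integrate to the valence
    count, so the input is neutral to quadrature accuracy.
    """
    if table is None:
        table = default_element_table()
    if spec is None:
        spec = GridSpec()
    if smear_sigma is None:
        g = spec.empty_grid()
        smear_sigma = max(0.4, 2.0 * float(g.spacing.max()))
    rho_e = synthetic_electron_density(molecule, table, spec)
    rho_n = nuclear_charge_density(molecule, table, spec, smear_sigma=smear_sigma)
    total = rho_e.like(rho_n.values - rho_e.values)
    v = poisson_potential(total, neutralize=True)
    return SampleFields(rho_electron=rho_e, v_sample=v)


def build_force_field(
    molecule: Molecule,
    table: Optional[ElementTable] = None,
    spec: Optional[GridSpec] = None,
    sr_params: Optional[SRParams] = None,
    tip_params: Optional[TipDensityParams] = None,
    center: bool = True,
    sample_fields: Optional[SampleFields] = None,
    tip_density: Optional[TipDensity] = None,
    probe_density: Optional[Grid3D] = None,
) -> ForceFieldGrids:
    """Assemble the rigid-probe energy grids for one molecule.

    Any of the volumetric ingredients (sample fields, tip differential
    density for electrostatics, probe total density for the Pauli overlap)
    may be supplied explicitly — e.g. read from DFT files — otherwise the
    synthetic models are used. ``center=True`` first places the molecule at
    the cell center with its mean z-plane at 0.
    """
    if table is None:
        table = default_element_table()
    if spec is None:
        spec = GridSpec()
    if center:
        molecule = center_in_cell(molecule, cell_side=spec.cell_side)
    if sample_fields is None:
        sample_fields = build_sample_fields(molecule, table, spec)
    if tip_density is None:
        tip_density = synthetic_tip_density(tip_params, spec)
    if probe_density is None:
        probe_density = synthetic_probe_density(spec)
    e_vdw = vdw_energy_grid(molecule, table, spec)
    e_es = es_energy_grid(sample_fields.v_sample, tip_density)
    e_sr = sr_energy_grid(sample_fields.rho_electron, probe_density, sr_params)
    return assemble(e_vdw, e_es, e_sr, sr_params=sr_params)
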