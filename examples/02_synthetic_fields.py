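"""Build the synthetic volumetric fields for one molecule and export XSF.

The electron density is a sum of atom-centered exponentials normalized to
valence-electron counts; the ionic charge is Gaussian-smeared; their
difference (neutral) is fed to the periodic spectral Poisson solver to get
the sample electrostatic potential. Integrals verify the normalizations.
"""

from afmsim import GridSpec, center_in_cell, fixture_molecules
from afmsim.grids import (
    nuclear_charge_density,
    poisson_potential,
    synthetic_electron_density,
    write_xsf,
)

mol = next(m for m in fixture_molecules(seed=1) if m.name == "halo-aza-ring")
mol = center_in_cell(mol, 24.0)
spec = GridSpec(spacing=0.25)  # 96 x 96 x 80 voxels over 24 x 24 x 20 A

rho_e = synthetic_electron_density(mol, spec=spec)
rho_n = nuclear_charge_density(mol, spec=spec, smear_sigma=0.5)
total = rho_e.like(rho_n.values - rho_e.values)
v = poisson_potential(total, neutralize=True)

print(f"molecule: {mol.name}, {len(mol)} atoms")
print(f"electron density integral: {rho_e.integral():8.3f} e "
      "(= total valence electrons)")
print(f"ionic charge integral:     {rho_n.integral():8.3f} e")
print(f"net cell charge:           {total.integral():+8.4f} e (should be ~0)")
print(f"potential range:           {v.values.min():+.2f} .. {v.values.max():+.2f} V "
      "(zero-mean by construction)")

write_xsf(v, "sample_potential.xsf")
print("wrote sample_potential.xsf (open with any XSF viewer)")
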