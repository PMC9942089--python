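"""Relaxed force-distance curve over one atom and its frequency shift.

Builds the three-part force field (dispersion + electrostatics + Pauli
overlap), scans the CO probe down over the bromine atom with tilt
relaxation at every 0.1 A step, differentiates the relaxed energy into
F_z(z), and converts to Δf with the large-amplitude weighted average.
"""

import numpy as np

from afmsim import (
    CantileverConfig,
    GridSpec,
    ScanConfig,
    TipModel,
    center_in_cell,
    fixture_molecules,
    frequency_shift_curve,
    z_scan,
)
from afmsim.pipeline import build_force_field

mol = next(m for m in fixture_molecules(seed=1) if m.name == "halo-aza-ring")
spec = GridSpec(spacing=0.375)
ff = build_force_field(mol, spec=spec)
mol = center_in_cell(mol, 24.0)
br = next(a for a in mol.atoms if a.element == "Br")

tip = TipModel(kappa=0.4)  # soft CO attachment
cfg = ScanConfig(heights=tuple(np.arange(2.8, 6.81, 0.1).round(2)))
curve = z_scan([br.x, br.y], ff, tip, cfg)
curve.save_text("force_curve_Br.txt")

cant = CantileverConfig(A=1.0)
z_eval, df = frequency_shift_curve(curve, cant)

print(f"probe over Br at ({br.x:.2f}, {br.y:.2f}); kappa = {tip.kappa} N/m, "
      f"A = {cant.A} A")
print(f"{'z (A)':>7s} {'F_z (eV/A)':>12s} {'df (Hz)':>10s}")
for z0 in (2.8, 3.0, 3.2, 3.5, 4.0, 4.5, 5.5, 6.5):
    i = int(round((z0 - curve.z[0]) / cfg.dz))
    j = int(round((z0 - z_eval[0]) / cfg.dz))
    fzv = curve.fz[i]
    dfv = f"{df[j]:10.2f}" if j < len(df) else "        --"
    print(f"{z0:7.1f} {fzv:12.4f} {dfv}")
print("far out the probe feels weak attraction (F_z < 0); on approach the "
      "density-overlap repulsion takes over and F_z and df turn positive.")
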