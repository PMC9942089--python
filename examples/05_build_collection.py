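"""Build a miniature image collection and query it.

Runs the dataset pipeline end to end on two fixture molecules with a
reduced parameter grid (2 amplitudes x 1 stiffness x 2 heights, small
images for speed), then exercises the CID / formula / name lookup and the
manifest audit. The full-scale layout is identical, just larger: 24
subset directories and 10 images per molecule folder.
"""

from afmsim import (
    BuildConfig,
    GridSpec,
    ParameterGrid,
    audit,
    build_dataset,
    chemical_formula,
    fixture_molecules,
    lookup,
)

mols = [m for m in fixture_molecules(seed=1)
        if not (m.name or "").startswith("reject-")][:2]
grid = ParameterGrid(amplitudes=(0.6, 1.0), kappas=(0.4,), heights=(3.0, 3.4))
config = BuildConfig(grid_spec=GridSpec(spacing=0.5), pixels=32)

layout, summary = build_dataset(mols, grid, config, root="mini_collection")
print(f"built {summary.built} molecules, {summary.images_written} images "
      f"({len(grid.amplitudes)}A x {len(grid.kappas)}k x {len(grid.heights)}h each)")

for m in mols:
    hits = lookup(chemical_formula(m), "mini_collection")
    print(f"lookup {chemical_formula(m):<12s} -> CIDs {sorted(hits)}")

counts = audit("mini_collection")
print(f"audit: {counts['disk_images']} images on disk, "
      f"{counts['manifest_images']} in manifest, {counts['mismatched']} mismatched")
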