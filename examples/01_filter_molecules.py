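"""Apply the quasi-planar organic selection filter to the fixture set.

Each molecule is tested against the four rules — element whitelist, at
least 8 atoms, xy footprint inside a 24 A square cell, z-extent at most
1.83 A — and the accept/reject decision with the first failing rule is
printed. The four 'reject-*' fixtures each violate exactly one rule.
"""

from afmsim import FilterCriteria, chemical_formula, fixture_molecules, passes_filter, z_extent

criteria = FilterCriteria()
print(f"criteria: >= {criteria.min_atoms} atoms, {criteria.cell_side:.0f} A cell, "
      f"z-extent <= {criteria.max_z_extent} A, elements {sorted(criteria.allowed_elements)}")
print()
for mol in fixture_molecules(seed=1):
    ok, reason = passes_filter(mol, criteria)
    verdict = "accept" if ok else f"reject ({reason})"
    print(f"{mol.name:<18s} {chemical_formula(mol):<16s} "
          f"{len(mol):3d} atoms  z-extent {z_extent(mol):5.2f} A  -> {verdict}")
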