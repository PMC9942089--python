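"""Volumetric fields: XSF/cube I/O, synthetic densities, Poisson, tip model."""

import numpy as np
import pytest
from scipy.special import erf

from afmsim.geometry import Atom, Molecule
from afmsim.grids import (
    COULOMB_EV_A,
    Grid3D,
    GridSpec,
    TipDensityParams,
    load_grid_hdf5,
    nuclear_charge_density,
    poisson_potential,
    read_cube,
    read_xsf,
    save_grid_hdf5,
    synthetic_electron_density,
    synthetic_probe_density,
    synthetic_tip_density,
    write_xsf,
)

BOHR = 0.529177210903


def single_atom(el, x=12.0, y=12.0, z=0.0):
    return Molecule(id=1, atoms=(Atom(el, x, y, z),))


class TestXSF:
    def test_minimal_hand_written_grid(self, tmp_path):
        # 2x2x2 internal grid stored as 3x3x3 with duplicated end planes,
        # x-fastest ordering
        vals = np.arange(8, dtype=float).reshape(2, 2, 2)
        ext = np.empty((3, 3, 3))
        ext[:2, :2, :2] = vals
        ext[2] = ext[0]
        ext[:, 2] = ext[:, 0]
        ext[:, :, 2] = ext[:, :, 0]
        flat = ext.transpose(2, 1, 0).reshape(-1)
        body = "\n".join(" ".join(f"{v:.1f}" for v in flat[i:i + 5])
                         for i in range(0, flat.size, 5))
        text = (
            "BEGIN_BLOCK_DATAGRID_3D\n grid\n BEGIN_DATAGRID_3D_x\n"
            " 3 3 3\n 0 0 0\n 2 0 0\n 0 2 0\n 0 0 2\n"
            f"{body}\n END_DATAGRID_3D\nEND_BLOCK_DATAGRID_3D\n"
        )
        p = tmp_path / "g.xsf"
        p.write_text(text)
        g = read_xsf(p)
        assert g.shape == (2, 2, 2)
        np.testing.assert_array_equal(g.values, vals)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        spec = GridSpec(cell_side=3.0, z_height=4.5, z_origin=-1.0, spacing=0.5)
        g = spec.empty_grid()
        g.values[...] = rng.normal(size=g.shape)
        p = tmp_path / "rt.xsf"
        write_xsf(g, p)
        back = read_xsf(p)
        np.testing.assert_array_equal(back.values, g.values)
        np.testing.assert_allclose(back.cell, g.cell)
        np.testing.assert_allclose(back.origin, g.origin)

    def test_missing_datagrid_block(self, tmp_path):
        p = tmp_path / "no.xsf"
        p.write_text("CRYSTAL\nPRIMVEC\n1 0 0\n0 1 0\n0 0 1\n")
        with pytest.raises(ValueError, match="DATAGRID"):
            read_xsf(p)

    def test_inconsistent_dimensions(self, tmp_path):
        p = tmp_path / "short.xsf"
        p.write_text(
            "BEGIN_DATAGRID_3D_x\n 2 2 2\n 0 0 0\n 1 0 0\n 0 1 0\n 0 0 1\n"
            "1.0 2.0 3.0\n END_DATAGRID_3D\n"
        )
        with pytest.raises(ValueError, match="values"):
            read_xsf(p)


class TestCube:
    def _write_cube(self, path, n, spacing_bohr, values):
        lines = ["cube", "synthetic test density",
                 f"1 0.0 0.0 0.0",
                 f"{n} {spacing_bohr:.6f} 0.0 0.0",
                 f"{n} 0.0 {spacing_bohr:.6f} 0.0",
                 f"{n} 0.0 0.0 {spacing_bohr:.6f}",
                 "6 6.0 0.0 0.0 0.0"]
        flat = values.reshape(-1)
        for i in range(0, flat.size, 6):
            lines.append(" ".join(f"{v:.17e}" for v in flat[i:i + 6]))
        path.write_text("\n".join(lines) + "\n")

    def test_bohr_units_preserve_integral(self, tmp_path):
        n, spacing_bohr = 8, 1.0
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, size=(n, n, n))  # e/Bohr^3
        p = tmp_path / "d.cube"
        self._write_cube(p, n, spacing_bohr, vals)
        g = read_cube(p)
        integral_bohr = vals.sum() * spacing_bohr ** 3  # e
        assert g.integral() == pytest.approx(integral_bohr, rel=1e-12)
        assert g.spacing[0] == pytest.approx(spacing_bohr * BOHR)


class TestSyntheticDensity:
    @pytest.mark.parametrize("el, nval", [("C", 4.0), ("H", 1.0), ("Br", 7.0)])
    def test_norm_matches_valence_count(self, el, nval):
        spec = GridSpec(spacing=0.15, z_height=16.0, z_origin=-8.0)
        rho = synthetic_electron_density(single_atom(el, z=0.07), spec=spec)
        assert rho.integral() == pytest.approx(nval, rel=0.01)

    def test_empty_molecule_zero_grid(self):
        rho = synthetic_electron_density(None, spec=GridSpec(spacing=0.4))
        assert np.all(rho.values == 0.0)

    def test_exchange_symmetry_of_identical_atoms(self):
        spec = GridSpec(cell_side=8.0, z_height=8.0, z_origin=-4.0, spacing=0.25)
        m = Molecule(id=1, atoms=(Atom("C", 3.0, 4.0, 0.0), Atom("C", 5.0, 4.0, 0.0)))
        rho = synthetic_electron_density(m, spec=spec)
        # mirror across the x = 4 plane maps the atoms onto each other
        flipped = rho.values[::-1, :, :]
        flipped = np.roll(flipped, 33, axis=0)  # x -> 8 - x on the lattice
        np.testing.assert_allclose(rho.values, flipped, atol=1e-10)

    def test_coarse_spacing_refused(self):
        with pytest.raises(ValueError, match="coarse"):
            synthetic_electron_density(single_atom("C"), spec=GridSpec(spacing=0.6))

    def test_density_non_negative(self, halo_ring, coarse_spec):
        from afmsim.geometry import center_in_cell

        rho = synthetic_electron_density(center_in_cell(halo_ring, 24.0), spec=coarse_spec)
        assert rho.values.min() >= 0.0


class TestNuclearCharge:
    def test_hydrogen_total_charge(self):
        spec = GridSpec(spacing=0.2, z_height=12.0, z_origin=-6.0)
        rho = nuclear_charge_density(single_atom("H"), spec=spec, smear_sigma=0.45)
        assert rho.integral() == pytest.approx(1.0, rel=0.01)

    def test_zero_atoms_zero_grid(self):
        rho = nuclear_charge_density(None, spec=GridSpec(spacing=0.2), smear_sigma=0.45)
        assert np.all(rho.values == 0.0)

    def test_neutrality_against_electron_density(self, benzene_like):
        from afmsim.geometry import center_in_cell

        spec = GridSpec(spacing=0.2)
        m = center_in_cell(benzene_like, 24.0)
        rho_e = synthetic_electron_density(m, spec=spec)
        rho_n = nuclear_charge_density(m, spec=spec, smear_sigma=0.45)
        total = rho_n.integral() - rho_e.integral()
        assert abs(total) / rho_e.integral() < 0.02

    def test_under_resolved_sigma_refused(self):
        with pytest.raises(ValueError, match="under-resolved"):
            nuclear_charge_density(single_atom("H"), spec=GridSpec(spacing=0.3),
                                   smear_sigma=0.3)


class TestPoisson:
    def test_zero_charge_zero_potential(self):
        g = GridSpec(cell_side=4.0, z_height=4.0, z_origin=0.0, spacing=0.5).empty_grid()
        v = poisson_potential(g)
        assert np.all(v.values == 0.0)

    def test_non_neutral_input_refused(self):
        spec = GridSpec(cell_side=4.0, z_height=4.0, z_origin=0.0, spacing=0.5)
        g = spec.empty_grid()
        g.values += 1.0
        with pytest.raises(ValueError, match="net"):
            poisson_potential(g)

    def test_gaussian_matches_erf_oracle(self):
        """Isolated Gaussian charge: V(r) = k q erf(r/sigma sqrt2)/r, with
        nearest periodic images and the uniform compensating background
        added to the oracle."""
        spec = GridSpec(cell_side=32.0, z_height=32.0, z_origin=0.0, spacing=0.25)
        g = spec.empty_grid()
        x, y, z = g.axes()
        c, sigma, q = 16.0, 0.6, 1.0
        r2 = ((x[:, None, None] - c) ** 2 + (y[None, :, None] - c) ** 2
              + (z[None, None, :] - c) ** 2)
        g.values[...] = q * np.exp(-0.5 * r2 / sigma ** 2) / (
            (2 * np.pi) ** 1.5 * sigma ** 3)
        V = poisson_potential(g, neutralize=True)
        line = V.values[:, 64, 64]
        r = np.abs(x - c)
        mask = (r > 0.8) & (r < spec.cell_side / 4)
        rm = r[mask]
        oracle = COULOMB_EV_A * q * erf(rm / (sigma * np.sqrt(2))) / rm
        L = spec.cell_side
        for n in range(-2, 3):
            for m in range(-2, 3):
                for k in range(-2, 3):
                    if n == m == k == 0:
                        continue
                    d = np.sqrt((x[mask] - c - L * n) ** 2 + (L * m) ** 2 + (L * k) ** 2)
                    oracle += COULOMB_EV_A * q / d
        oracle += (2 * np.pi / 3) * COULOMB_EV_A * q / L ** 3 * rm ** 2
        offset = np.mean(line[mask] - oracle)
        rel = np.abs(line[mask] - offset - oracle) / np.abs(
            COULOMB_EV_A * q * erf(rm / (sigma * np.sqrt(2))) / rm)
        assert rel.max() < 0.02

    def test_dipole_antisymmetry(self):
        spec = GridSpec(cell_side=12.0, z_height=12.0, z_origin=0.0, spacing=0.25)
        g = spec.empty_grid()
        x, y, z = g.axes()
        sigma = 0.5
        for q, zc in ((1.0, 5.0), (-1.0, 7.0)):
            r2 = ((x[:, None, None] - 6.0) ** 2 + (y[None, :, None] - 6.0) ** 2
                  + (z[None, None, :] - zc) ** 2)
            g.values += q * np.exp(-0.5 * r2 / sigma ** 2) / (
                (2 * np.pi) ** 1.5 * sigma ** 3)
        V = poisson_potential(g)
        # antisymmetric about the z = 6 midplane: V(z) = -V(12 - z)
        vals = V.values
        mirrored = -np.roll(vals[:, :, ::-1], 1, axis=2)
        scale = np.abs(vals).max()
        np.testing.assert_allclose(vals / scale, mirrored / scale, atol=1e-10)

    def test_zero_mean_and_spectral_consistency(self):
        rng = np.random.default_rng(5)
        spec = GridSpec(cell_side=6.0, z_height=6.0, z_origin=0.0, spacing=0.375)
        g = spec.empty_grid()
        g.values[...] = rng.normal(size=g.shape)
        g.values -= g.values.mean()
        V = poisson_potential(g)
        assert abs(V.values.mean()) < 1e-12
        # discrete spectral Laplacian recovers -rho/eps0
        nx, ny, nz = g.shape
        L = g.lengths
        kx = 2 * np.pi * np.fft.fftfreq(nx, L[0] / nx)
        ky = 2 * np.pi * np.fft.fftfreq(ny, L[1] / ny)
        kz = 2 * np.pi * np.fft.rfftfreq(nz, L[2] / nz)
        k2 = kx[:, None, None] ** 2 + ky[None, :, None] ** 2 + kz[None, None, :] ** 2
        lap = np.fft.irfftn(-k2 * np.fft.rfftn(V.values), s=g.shape, axes=(0, 1, 2))
        target = -4 * np.pi * COULOMB_EV_A * g.values
        np.testing.assert_allclose(lap, target, atol=1e-6 * np.abs(target).max())


class TestTipDensity:
    def test_default_is_neutral(self):
        tip = synthetic_tip_density(spec=GridSpec(spacing=0.25))
        assert abs(tip.grid.integral()) < 1e-6

    def test_axial_dipole_matches_configuration(self):
        params = TipDensityParams(lobe_charge=0.3, lobe_offset=0.3)
        tip = synthetic_tip_density(params, spec=GridSpec(spacing=0.15))
        g = tip.grid
        _, _, z = g.axes()
        L = g.lengths
        dz = z - g.origin[2]
        dz -= L[2] * np.round(dz / L[2])
        pz = (g.values * dz[None, None, :]).sum() * g.voxel_volume
        assert pz == pytest.approx(2 * 0.3 * 0.3, rel=0.02)

    def test_quadrupole_term_charge_and_dipole_free(self):
        params = TipDensityParams(lobe_charge=0.0, quadrupole=0.25)
        tip = synthetic_tip_density(params, spec=GridSpec(spacing=0.15))
        g = tip.grid
        _, _, z = g.axes()
        L = g.lengths
        dz = z - g.origin[2]
        dz -= L[2] * np.round(dz / L[2])
        pz = (g.values * dz[None, None, :]).sum() * g.voxel_volume
        qzz = (g.values * dz[None, None, :] ** 2).sum() * g.voxel_volume
        assert abs(tip.grid.integral()) < 1e-6
        assert abs(pz) < 1e-9
        assert qzz == pytest.approx(0.25, rel=0.05)

    def test_axial_rotation_symmetry(self):
        """Cylindrical symmetry about the tip axis: invariant under the
        90-degree lattice rotation (i, j) -> (j, -i) about the origin."""
        tip = synthetic_tip_density(spec=GridSpec(spacing=0.25))
        v = tip.grid.values
        n = v.shape[0]
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        rotated = v[j, (-i) % n, :]
        np.testing.assert_allclose(v, rotated, atol=1e-9)
        np.testing.assert_allclose(v, v.transpose(1, 0, 2), atol=1e-9)


class TestHDF5:
    def test_grid_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        spec = GridSpec(cell_side=3.0, z_height=3.0, z_origin=0.0, spacing=0.5)
        g = spec.empty_grid()
        g.values[...] = rng.normal(size=g.shape)
        p = tmp_path / "g.h5"
        save_grid_hdf5(g, p)
        back = load_grid_hdf5(p)
        np.testing.assert_array_equal(back.values, g.values)


class TestProbeDensity:
    def test_norm_and_positivity(self):
        rho = synthetic_probe_density(GridSpec(spacing=0.15))
        assert rho.values.min() >= 0.0
        assert rho.integral() == pytest.approx(10.0, rel=0.01)
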