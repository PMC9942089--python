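"""Energy grids: dispersion sum, FFT correlations vs direct sums, interpolation."""

import numpy as np
import pytest

from afmsim.elements import default_element_table
from afmsim.forcefield import (
    PROBE_C6,
    SRParams,
    assemble,
    energy_at,
    es_energy_grid,
    force_at,
    interpolate,
    sr_energy_grid,
    vdw_energy_grid,
)
from afmsim.geometry import Atom, Molecule
from afmsim.grids import Grid3D, GridSpec, TipDensity


@pytest.fixture
def small_spec():
    return GridSpec(cell_side=4.0, z_height=4.0, z_origin=0.0, spacing=0.25)


def rand_grid(spec, rng, positive=False):
    g = spec.empty_grid()
    vals = rng.normal(size=g.shape)
    if positive:
        vals = np.abs(vals)
    g.values[...] = vals
    return g


def direct_correlation(a, b, dv):
    """O(N^2) periodic cross-correlation C[m] = sum_n a[n] b[n-m] dv."""
    out = np.empty_like(a)
    for m0 in range(a.shape[0]):
        for m1 in range(a.shape[1]):
            for m2 in range(a.shape[2]):
                out[m0, m1, m2] = (
                    a * np.roll(b, (m0, m1, m2), axis=(0, 1, 2))
                ).sum() * dv
    return out


class TestVdw:
    def test_empty_molecule_zero(self, small_spec):
        g = vdw_energy_grid(None, spec=small_spec)
        assert np.all(g.values == 0.0)

    def test_single_atom_formula(self):
        """E = -sqrt(C6_C * C6_probe)/r^6 at r = 2 A above the atom."""
        table = default_element_table()
        spec = GridSpec(cell_side=8.0, z_height=8.0, z_origin=-4.0, spacing=0.25)
        m = Molecule(id=1, atoms=(Atom("C", 4.0, 4.0, 0.0),))
        g = vdw_energy_grid(m, table, spec)
        c6 = np.sqrt(table["C"].c6 * PROBE_C6)
        # lattice point exactly 2 A above the atom
        val = interpolate(g, np.array([4.0, 4.0, 2.0]))
        assert val == pytest.approx(-c6 / 2.0 ** 6, rel=1e-12)

    def test_matches_bruteforce_pair_sum(self, table):
        rng = np.random.default_rng(4)
        spec = GridSpec(cell_side=8.0, z_height=8.0, z_origin=-4.0, spacing=0.5)
        atoms = tuple(
            Atom(el, *pos)
            for el, pos in zip(
                ["C", "H", "O", "N", "Br"], rng.uniform(2, 6, size=(5, 3)) - [0, 0, 4]
            )
        )
        m = Molecule(id=1, atoms=atoms)
        g = vdw_energy_grid(m, table, spec)
        x, y, z = g.axes()
        idx = rng.integers(0, np.array(g.shape), size=(50, 3))
        L = spec.cell_side
        for i, j, k in idx:
            pos = np.array([x[i], y[j], z[k]])
            expected = 0.0
            for a in atoms:
                p = table[a.element]
                d = pos - a.position
                d[0] -= L * np.round(d[0] / L)
                d[1] -= L * np.round(d[1] / L)
                r2 = max(float(d @ d), p.min_approach ** 2)
                expected -= np.sqrt(p.c6 * PROBE_C6) / r2 ** 3
            assert g.values[i, j, k] == pytest.approx(expected, abs=1e-10)

    def test_everywhere_non_positive(self, halo_ff):
        assert halo_ff.E_vdw.values.max() <= 0.0


class TestES:
    def test_delta_tip_sifts_potential(self, small_spec):
        """A single -q voxel acts as -q*delta(r): E(R) = -q V(R)."""
        from afmsim.forcefield import _correlate

        rng = np.random.default_rng(7)
        V = rand_grid(small_spec, rng)
        tip = small_spec.empty_grid()
        q = 0.37
        tip.values[0, 0, 0] = -q / tip.voxel_volume
        E = V.like(_correlate(V.values, tip.values, V.voxel_volume))
        np.testing.assert_allclose(E.values, -q * V.values, atol=1e-9)

    def test_zero_potential_zero_grid(self, small_spec):
        V = small_spec.empty_grid()
        tip = rand_grid(small_spec, np.random.default_rng(8))
        tip.values -= tip.values.mean()  # neutral
        E = es_energy_grid(V, TipDensity(grid=tip))
        assert np.all(E.values == 0.0)

    def test_fft_equals_direct_sum(self, small_spec):
        rng = np.random.default_rng(9)
        V = rand_grid(small_spec, rng)
        tipg = rand_grid(small_spec, rng)
        tipg.values -= tipg.values.mean()
        E = es_energy_grid(V, TipDensity(grid=tipg))
        direct = direct_correlation(V.values, tipg.values, V.voxel_volume)
        np.testing.assert_allclose(E.values, direct, atol=1e-8)

    def test_linearity_in_tip_density(self, small_spec):
        rng = np.random.default_rng(10)
        V = rand_grid(small_spec, rng)
        tipg = rand_grid(small_spec, rng)
        tipg.values -= tipg.values.mean()
        E1 = es_energy_grid(V, TipDensity(grid=tipg))
        tipg2 = tipg.like(2.0 * tipg.values)
        E2 = es_energy_grid(V, TipDensity(grid=tipg2))
        np.testing.assert_allclose(E2.values, 2.0 * E1.values, rtol=1e-12)

    def test_incommensurate_grids_rejected(self, small_spec):
        V = small_spec.empty_grid()
        other = GridSpec(cell_side=4.0, z_height=4.0, z_origin=0.0, spacing=0.5)
        tip = other.empty_grid()
        with pytest.raises(ValueError, match="incommensurate"):
            es_energy_grid(V, TipDensity(grid=tip))


class TestSR:
    def test_zero_density_zero_grid(self, small_spec):
        z = small_spec.empty_grid()
        r = rand_grid(small_spec, np.random.default_rng(12), positive=True)
        assert np.all(sr_energy_grid(z, r).values == 0.0)
        assert np.all(sr_energy_grid(r, z).values == 0.0)

    def test_gaussian_overlap_closed_form(self):
        """Two unit-norm Gaussians of width sigma at separation d:
        E = V0 (4 pi sigma^2)^(-3/2) exp(-d^2 / 4 sigma^2)."""
        spec = GridSpec(cell_side=10.0, z_height=10.0, z_origin=0.0, spacing=0.125)
        sigma, d, V0 = 0.5, 1.5, 18.0
        g1 = spec.empty_grid()
        x, y, z = g1.axes()
        c = 5.0
        r2a = ((x[:, None, None] - c) ** 2 + (y[None, :, None] - c) ** 2
               + (z[None, None, :] - c) ** 2)
        g1.values[...] = np.exp(-0.5 * r2a / sigma ** 2) / ((2 * np.pi) ** 1.5 * sigma ** 3)
        # tip Gaussian wrapped at the origin corner
        g2 = spec.empty_grid()
        dx = x - 0.0
        dx -= 10.0 * np.round(dx / 10.0)
        r2b = (dx[:, None, None] ** 2 + dx[None, :, None] ** 2 + dx[None, None, :] ** 2)
        g2.values[...] = np.exp(-0.5 * r2b / sigma ** 2) / ((2 * np.pi) ** 1.5 * sigma ** 3)
        E = sr_energy_grid(g1, g2, SRParams(V0=V0, alpha=1.0))
        # probe at (c, c, c + d) -> offset (c, c, c + d) on the lattice
        i = int(round(c / g1.spacing[0]))
        k = int(round((c + d) / g1.spacing[2]))
        closed = V0 * (4 * np.pi * sigma ** 2) ** -1.5 * np.exp(-d ** 2 / (4 * sigma ** 2))
        assert E.values[i, i, k] == pytest.approx(closed, rel=0.01)

    def test_fft_equals_direct_sum(self, small_spec):
        rng = np.random.default_rng(13)
        a = rand_grid(small_spec, rng, positive=True)
        b = rand_grid(small_spec, rng, positive=True)
        E = sr_energy_grid(a, b, SRParams(V0=18.0, alpha=1.0))
        direct = 18.0 * direct_correlation(a.values, b.values, a.voxel_volume)
        np.testing.assert_allclose(E.values, direct, atol=1e-8)

    def test_alpha_powers_applied(self, small_spec):
        rng = np.random.default_rng(14)
        a = rand_grid(small_spec, rng, positive=True)
        b = rand_grid(small_spec, rng, positive=True)
        E2 = sr_energy_grid(a, b, SRParams(V0=1.0, alpha=2.0))
        a2 = a.like(a.values ** 2)
        b2 = b.like(b.values ** 2)
        E_ref = sr_energy_grid(a2, b2, SRParams(V0=1.0, alpha=1.0))
        np.testing.assert_allclose(E2.values, E_ref.values, atol=1e-10)

    def test_negative_density_rejected(self, small_spec):
        bad = small_spec.empty_grid()
        bad.values -= 0.5
        good = small_spec.empty_grid()
        with pytest.raises(ValueError, match="negative"):
            sr_energy_grid(bad, good)

    def test_everywhere_non_negative(self, halo_ff):
        assert halo_ff.E_sr.values.min() >= 0.0

    def test_bilinear_in_densities(self, small_spec):
        rng = np.random.default_rng(15)
        a = rand_grid(small_spec, rng, positive=True)
        b = rand_grid(small_spec, rng, positive=True)
        E = sr_energy_grid(a, b)
        E3 = sr_energy_grid(a.like(3 * a.values), b)
        np.testing.assert_allclose(E3.values, 3 * E.values, rtol=1e-12)


class TestAssemble:
    def test_total_is_sum_of_parts(self, small_spec):
        rng = np.random.default_rng(16)
        vdw = small_spec.empty_grid()
        vdw.values[...] = -np.abs(rng.normal(size=vdw.shape))
        es = rand_grid(small_spec, rng)
        sr = rand_grid(small_spec, rng, positive=True)
        ff = assemble(vdw, es, sr)
        idx = rng.integers(0, np.array(vdw.shape), size=(100, 3))
        for i, j, k in idx:
            assert ff.E_total.values[i, j, k] == pytest.approx(
                vdw.values[i, j, k] + es.values[i, j, k] + sr.values[i, j, k],
                abs=1e-12,
            )

    def test_omitted_part_enters_as_zero(self, small_spec):
        rng = np.random.default_rng(17)
        vdw = small_spec.empty_grid()
        vdw.values[...] = -np.abs(rng.normal(size=vdw.shape))
        es = rand_grid(small_spec, rng)
        ff = assemble(vdw, es)
        np.testing.assert_array_equal(ff.E_total.values, vdw.values + es.values)
        assert np.all(ff.E_sr.values == 0.0)

    def test_all_zero_parts(self, small_spec):
        ff = assemble(small_spec.empty_grid())
        assert np.all(ff.E_total.values == 0.0)

    def test_lattice_mismatch_rejected(self, small_spec):
        other = GridSpec(cell_side=4.0, z_height=4.0, z_origin=0.0, spacing=0.5)
        with pytest.raises(ValueError, match="lattice"):
            assemble(small_spec.empty_grid(), other.empty_grid())


class TestInterpolation:
    def test_lattice_point_identity(self, small_spec):
        rng = np.random.default_rng(18)
        ff = assemble(small_spec.empty_grid(), rand_grid(small_spec, rng))
        g = ff.E_total
        x, y, z = g.axes()
        for i, j, k in rng.integers(0, np.array(g.shape) - 1, size=(20, 3)):
            assert energy_at(ff, np.array([x[i], y[j], z[k]])) == pytest.approx(
                g.values[i, j, k], abs=1e-12
            )

    def test_linear_field_exact_force(self):
        spec = GridSpec(cell_side=4.0, z_height=8.0, z_origin=0.0, spacing=0.5)
        g = spec.empty_grid()
        _, _, Z = spec.meshgrid()
        c = 0.7
        g.values[...] = c * Z
        ff = assemble(g.like(np.zeros(g.shape)), g)
        f = force_at(ff, np.array([2.0, 2.0, 4.0]))
        np.testing.assert_allclose(f, [0.0, 0.0, -c], atol=1e-6)

    def test_force_matches_five_point_stencil(self, small_spec):
        rng = np.random.default_rng(19)
        ff = assemble(small_spec.empty_grid(), rand_grid(small_spec, rng))
        pos = np.array([1.7, 2.3, 2.1])
        f = force_at(ff, pos)
        h = 0.02
        for d in range(3):
            dp = np.zeros(3)
            dp[d] = h
            five = -(
                -energy_at(ff, pos + 2 * dp)
                + 8 * energy_at(ff, pos + dp)
                - 8 * energy_at(ff, pos - dp)
                + energy_at(ff, pos - 2 * dp)
            ) / (12 * h)
            assert f[d] == pytest.approx(five, abs=1e-4)

    def test_z_outside_support_raises(self, small_spec):
        ff = assemble(small_spec.empty_grid())
        with pytest.raises(ValueError, match="support"):
            energy_at(ff, np.array([1.0, 1.0, 9.0]))

    def test_lateral_force_vanishes_on_symmetry_axis(self, table):
        """A z-mirror-symmetric single atom: no lateral force on its axis."""
        spec = GridSpec(cell_side=8.0, z_height=8.0, z_origin=-4.0, spacing=0.25)
        m = Molecule(id=1, atoms=(Atom("C", 4.0, 4.0, 0.0),))
        ff = assemble(vdw_energy_grid(m, table, spec))
        f = force_at(ff, np.array([4.0, 4.0, 3.0]))
        assert abs(f[0]) < 1e-6 and abs(f[1]) < 1e-6
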