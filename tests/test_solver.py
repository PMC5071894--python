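import warnings

import numpy as np
import pytest

import aeroscatter.solver as solver_mod
from aeroscatter import (CoupledDipoleSolver, DipoleLattice, EllipsoidSpec,
                         Material, PlaneWave, azimuth_sweep, backscatter_matrix,
                         frequency_sweep, look_direction, make_ellipsoid_lattice,
                         mie_solve, polarizability, solve_internal,
                         symmetric_solve, tissue_default)
from aeroscatter.errors import GeometryError, ValidationError
from aeroscatter.materials import _alpha_internal

LAM = 0.03
K = 2 * np.pi / LAM


def small_sphere_lattice(x=0.5, mkd=0.5, material=None, fill=True):
    material = material or tissue_default("bat_effective")
    m = abs(np.sqrt(complex(material.epsilon_r)))
    a = x / K
    d = mkd / (m * K)
    return make_ellipsoid_lattice(EllipsoidSpec(a, a, a), d, material,
                                  fill_fractions=fill), a


class TestSingleAndTwoDipoles:
    def test_single_dipole_moment_exact(self):
        lat = DipoleLattice(positions=[[0, 0, 0]], spacing=1e-4,
                            material_ids=[0], materials=(Material(4.0),))
        pw = PlaneWave(LAM, [-1, 0, 0])
        P, res = solve_internal(lat, pw, "h", polarizability_model="cm")
        alpha = polarizability(Material(4.0), 1e-4, LAM, "cm").alpha
        assert res == 0.0
        assert np.allclose(P, alpha * pw.h_hat)

    def test_single_dipole_backscatter_closed_form(self):
        d = LAM / 100
        lat = DipoleLattice(positions=[[0, 0, 0]], spacing=d,
                            material_ids=[0], materials=(Material(4.0),))
        S = backscatter_matrix(lat, PlaneWave(LAM, [-1, 0, 0]),
                               polarizability_model="cm")
        alpha = polarizability(Material(4.0), d, LAM, "cm").alpha
        expect = 4 * np.pi * K**4 * abs(alpha) ** 2
        assert S.sigma_hh == pytest.approx(expect, rel=1e-12)
        assert S.sigma_vv == pytest.approx(expect, rel=1e-12)
        assert S.sigma_hv == 0.0

    def test_two_dipoles_match_hand_solution(self):
        """Two dipoles along the polarization axis vs the closed-form 2×2 solve."""
        d = 2e-4
        s = 5 * d                       # beyond the near-integration radius
        lat = DipoleLattice(positions=[[0, 0, 0], [0, s, 0]], spacing=d,
                            material_ids=[0, 0], materials=(Material(4.0),))
        pw = PlaneWave(LAM, [-1, 0, 0])     # ĥ = +ŷ: polarization along the pair
        assert np.allclose(pw.h_hat, [0, 1, 0])
        P, _ = solve_internal(lat, pw, "h", polarizability_model="cm")
        alpha = complex(_alpha_internal(4.0, d, K, "cm"))
        # longitudinal point-dipole coupling at separation s (internal convention)
        g = 2 * np.exp(1j * K * s) * (1 / s**3 - 1j * K / s**2)
        p_expect = alpha / (1 - alpha * g)          # symmetric pair, equal fields
        assert np.allclose(P[:, 1], p_expect, rtol=1e-10)
        assert np.allclose(P[:, [0, 2]], 0.0, atol=1e-18)


class TestSphereAgainstMie:
    def test_small_sphere_matches_mie(self, bat_material):
        """x = 0.5 tissue sphere at the gate spacing vs the Mie oracle."""
        lat, a = small_sphere_lattice(x=0.5, mkd=0.35)
        S = backscatter_matrix(lat, PlaneWave(LAM, [-1, 0, 0]), tolerance=1e-4)
        mie = mie_solve(a, LAM, bat_material).sigma_b
        assert S.sigma_hh == pytest.approx(mie, rel=0.10)
        assert S.sigma_vv == pytest.approx(mie, rel=0.10)
        assert S.sigma_hv / S.sigma_hh < 1e-4

    def test_fft_and_dense_paths_agree(self, bat_material, monkeypatch):
        lat, _ = small_sphere_lattice(x=0.5, mkd=0.5)
        pw = PlaneWave(LAM, [-1, 0, 0])
        S_dense = backscatter_matrix(lat, pw, tolerance=1e-6)
        monkeypatch.setattr(solver_mod, "DENSE_LIMIT", 0)
        S_fft = backscatter_matrix(lat, pw, tolerance=1e-6)
        assert S_fft.s_hh == pytest.approx(S_dense.s_hh, rel=1e-4)
        assert S_fft.s_vv == pytest.approx(S_dense.s_vv, rel=1e-4)

    def test_reciprocity(self, bat_material):
        """S_HV = S_VH for any look angle at a lossy anisotropic body."""
        lat = make_ellipsoid_lattice(EllipsoidSpec(0.004, 0.002, 0.0015),
                                     0.0004, bat_material, fill_fractions=True)
        for az in (17.0, 63.0):
            khat, nplane = look_direction(az, 35.0)
            S = backscatter_matrix(lat, PlaneWave(LAM, khat, nplane),
                                   tolerance=1e-6)
            denom = max(abs(S.s.ravel()))
            assert abs(S.s_hv - S.s_vh) / denom < 0.01

    def test_energy_budget_lossy(self, bat_material):
        lat, _ = small_sphere_lattice(x=0.5, mkd=0.5)
        solver = CoupledDipoleSolver(lat, LAM, tolerance=1e-6)
        pw = PlaneWave(LAM, [-1, 0, 0])
        P, _ = solver.solve(pw, "h")
        c_ext, c_abs, c_sca = solver.cross_sections(P, pw, "h")
        assert c_ext > c_sca > 0
        assert c_abs > 0

    def test_energy_conservation_lossless(self):
        mat = Material(2.25, "lossless")
        lat, _ = small_sphere_lattice(x=0.5, mkd=0.4, material=mat)
        solver = CoupledDipoleSolver(lat, LAM, tolerance=1e-8)
        pw = PlaneWave(LAM, [-1, 0, 0])
        P, _ = solver.solve(pw, "h")
        c_ext, c_abs, c_sca = solver.cross_sections(P, pw, "h")
        assert c_ext == pytest.approx(c_sca, rel=0.01)


class TestGeometryOfLooks:
    def test_polarization_basis_righthanded(self):
        pw = PlaneWave(LAM, [-1, 0, 0])
        assert np.allclose(np.cross(pw.h_hat, pw.v_hat), pw.k_hat)
        assert abs(np.dot(pw.h_hat, pw.k_hat)) < 1e-12

    def test_headon_look_is_minus_x(self):
        khat, nplane = look_direction(0.0, 35.0)
        assert np.allclose(khat, [-1, 0, 0])

    def test_tilt_rotates_plane_normal(self):
        _, nplane = look_direction(90.0, 35.0)
        assert np.dot(nplane, [0, 0, 1]) == pytest.approx(np.cos(np.radians(35)))

    def test_rotation_covariance(self, bat_material):
        """Rotating body and look geometry together leaves σ unchanged."""
        lat = make_ellipsoid_lattice(EllipsoidSpec(0.004, 0.002, 0.0015),
                                     0.0004, bat_material, fill_fractions=True)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        lat_rot = DipoleLattice(positions=lat.positions @ rot.T,
                                spacing=lat.spacing,
                                material_ids=lat.material_ids,
                                materials=lat.materials, fill=lat.fill)
        khat = np.array([-1.0, 0.0, 0.0])
        S = backscatter_matrix(lat, PlaneWave(LAM, khat), tolerance=1e-6)
        S_rot = backscatter_matrix(lat_rot, PlaneWave(LAM, rot @ khat),
                                   tolerance=1e-6)
        assert S_rot.sigma_hh == pytest.approx(S.sigma_hh, rel=1e-3)
        assert S_rot.sigma_vv == pytest.approx(S.sigma_vv, rel=1e-3)


class TestAzimuthSweep:
    def test_sphere_pattern_flat(self, bat_material):
        lat, _ = small_sphere_lattice(x=0.5, mkd=0.35)
        pat = azimuth_sweep(lat, LAM, 0.0, 45.0, tolerance=1e-5)
        assert pat.sigma_vv.max() / pat.sigma_vv.min() <= 1.02
        assert pat.sigma_hh.max() / pat.sigma_hh.min() <= 1.02

    def test_ellipsoid_mirror_symmetries(self, bat_material):
        """σ(φ) = σ(−φ) = σ(180°−φ) for a centered ellipsoid, solved honestly."""
        lat = make_ellipsoid_lattice(EllipsoidSpec(0.005, 0.0025, 0.0018),
                                     0.0004, bat_material, fill_fractions=True)
        pat = azimuth_sweep(lat, LAM, 35.0, 30.0, tolerance=1e-6,
                            exploit_mirror_symmetry=False)
        az = pat.azimuth_deg
        for phi in (30.0, 60.0):
            i = int(np.flatnonzero(az == phi)[0])
            for mirror_phi in ((-phi) % 360, (180 - phi) % 360):
                j = int(np.flatnonzero(az == mirror_phi)[0])
                assert pat.sigma_vv[j] == pytest.approx(pat.sigma_vv[i], rel=0.02)
                assert pat.sigma_hh[j] == pytest.approx(pat.sigma_hh[i], rel=0.02)

    def test_mirror_shortcut_matches_full(self, bat_material):
        lat = make_ellipsoid_lattice(EllipsoidSpec(0.004, 0.002, 0.0015),
                                     0.0005, bat_material, fill_fractions=True)
        full = azimuth_sweep(lat, LAM, 35.0, 45.0, tolerance=1e-6)
        fast = azimuth_sweep(lat, LAM, 35.0, 45.0, tolerance=1e-6,
                             exploit_mirror_symmetry=True)
        assert np.allclose(fast.sigma_vv, full.sigma_vv, rtol=0.02)

    def test_bad_step_rejected(self, bat_material):
        lat, _ = small_sphere_lattice()
        with pytest.raises(ValidationError):
            azimuth_sweep(lat, LAM, 0.0, 7.0)


class TestFrequencySweep:
    def test_rayleigh_f4_scaling(self):
        """Backscatter of an electrically small sphere scales as f⁴."""
        mat = Material(4.0 - 0.5j, "weak")
        a = 0.002
        spec = EllipsoidSpec(a, a, a)

        def factory(_d):
            return make_ellipsoid_lattice(spec, a / 5, mat, fill_fractions=True)

        freqs = [1.0e9, 0.5e9, 0.25e9]
        pats = frequency_sweep(factory, freqs, 0.0, 90.0, tolerance=1e-8)
        sig = np.array([p.sigma_vv[0] for p in pats])
        slope = np.polyfit(np.log(freqs), np.log(sig), 1)[0]
        assert slope == pytest.approx(4.0, abs=0.1)

    def test_single_frequency_consistency(self, bat_material):
        lat, _ = small_sphere_lattice()
        pat_direct = azimuth_sweep(lat, LAM, 0.0, 90.0, tolerance=1e-6)
        pats = frequency_sweep(lambda d: lat, [solver_mod.SPEED_OF_LIGHT / LAM],
                               0.0, 90.0, tolerance=1e-6)
        assert np.allclose(pats[0].sigma_vv, pat_direct.sigma_vv, rtol=1e-6)

    def test_empty_list_rejected(self, bat_material):
        lat, _ = small_sphere_lattice()
        with pytest.raises(ValidationError):
            frequency_sweep(lambda d: lat, [], 0.0, 90.0)


class TestSymmetricSolve:
    @pytest.fixture(scope="class")
    def half_and_spec(self, bat_material):
        spec = EllipsoidSpec(0.005, 0.0025, 0.0018)
        lat = make_ellipsoid_lattice(spec, 0.0005, bat_material,
                                     fill_fractions=True)
        keep = lat.positions[:, 1] > 0
        half = DipoleLattice(positions=lat.positions[keep], spacing=lat.spacing,
                             material_ids=lat.material_ids[keep],
                             materials=lat.materials,
                             fill=None if lat.fill is None else lat.fill[keep])
        return half, lat

    def test_matches_full_solve(self, half_and_spec):
        half, full = half_and_spec
        pw = PlaneWave(LAM, [-1, 0, 0])
        S_half = symmetric_solve(half, "y", 0.0, pw, tolerance=1e-6)
        S_full = backscatter_matrix(full, pw, tolerance=1e-6)
        for p, q in ((0, 0), (1, 1)):
            assert abs(S_half.s[p, q]) == pytest.approx(abs(S_full.s[p, q]),
                                                        rel=0.01)

    def test_symmetric_incidence_kills_cross_pol(self, half_and_spec):
        """k̂ in the sagittal mirror plane: the mirror-odd mode carries no
        co-to-cross coupling, so S_HV vanishes."""
        half, _ = half_and_spec
        S = symmetric_solve(half, "y", 0.0, PlaneWave(LAM, [-1, 0, 0]),
                            tolerance=1e-8)
        assert S.sigma_hv / max(S.sigma_hh, S.sigma_vv) < 1e-6

    def test_full_lattice_rejected(self, half_and_spec):
        _, full = half_and_spec
        with pytest.raises(GeometryError):
            symmetric_solve(full, "y", 0.0, PlaneWave(LAM, [-1, 0, 0]))


class TestCoarseLatticeGuards:
    def test_mkd_above_one_rejected(self, bat_material):
        lat = make_ellipsoid_lattice(EllipsoidSpec(0.01, 0.01, 0.01), 0.002,
                                     bat_material)
        with pytest.raises(ValidationError):
            CoupledDipoleSolver(lat, LAM)

    def test_mkd_above_half_warns(self, bat_material):
        lat, _ = small_sphere_lattice(x=0.5, mkd=0.8)
        with pytest.warns(UserWarning, match="kd"):
            CoupledDipoleSolver(lat, LAM, tolerance=1e-3)
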