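"""Grids, planform synthesis, symmetry operations, fixtures, snapshot IO."""

import numpy as np
import pytest

import corticalmaps as cm
from corticalmaps import fields_core as fc
from corticalmaps.energetics import ModelParams
from conftest import ETA_MID


class TestGrid:
    def test_domain_lengths(self):
        g = cm.make_grid(128, 128, 4, 4, lam=1.0)
        assert g.Lx == pytest.approx(4.0)
        assert g.Ly == pytest.approx(8.0 / np.sqrt(3.0))
        assert g.kc == pytest.approx(2.0 * np.pi)

    def test_triad_modes_land_on_integer_indices(self):
        """FFT of a pure triad mode has a single nonzero coefficient."""
        g = cm.make_grid(64, 64, 2, 2)
        X, Y = g.meshes()
        for j in range(3):
            k = g.triad_k(j)
            F = np.fft.fft2(np.exp(1j * (k[0] * X + k[1] * Y)))
            F[np.abs(F) < 1e-6 * g.nx * g.ny] = 0.0
            assert np.count_nonzero(F) == 1
            ix, iy = g.mode_indices(k)
            assert abs(F[ix, iy]) == pytest.approx(g.nx * g.ny)

    def test_rejects_non_commensurate_triad(self):
        with pytest.raises(fc.CommensurabilityError):
            cm.make_grid(64, 64, 1, 1)

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError):
            cm.make_grid(16, 64, 2, 1)

    def test_two_by_one_grid_covers_two_unit_cells(self):
        g = cm.make_grid(64, 32, 2, 1)
        assert g.n_unit_cells == pytest.approx(2.0)


ALL_FIXTURES = ["op_stripes", "op_rhombic", "op_scotoma", "hpwc_ipsi",
                "hpwc_braitenberg", "od_stripes", "od_hexagons", "od_constant"]


def _params_for(label, kc):
    if label in ("op_scotoma", "od_stripes"):
        return ModelParams(r_op=0.1, r_od=0.2, coupling_kind="product_low",
                           c=0.8, eta=0.2, kc=kc)
    if label == "hpwc_braitenberg":
        return ModelParams(r_op=0.1, r_od=0.2, coupling_kind="gradient_low",
                           c=3.0 / kc ** 4, eta=ETA_MID, kc=kc)
    if label == "od_constant":
        return ModelParams(r_op=0.1, r_od=0.2, gamma=None, eta=1.2, kc=kc)
    if label in ("op_stripes", "op_rhombic"):
        return ModelParams(r_op=0.1, r_od=0.2, c=0.0, gamma=0.0, kc=kc)
    return ModelParams(r_op=0.1, r_od=0.2, coupling_kind="product_low",
                       c=1.0, eta=ETA_MID, kc=kc)


class TestSynthesisRoundTrip:
    @pytest.mark.parametrize("label", ALL_FIXTURES)
    def test_projection_recovers_amplitudes(self, grid_small, label):
        """project(synthesize(amps)) == amps to 1e-12 for every fixture."""
        params = _params_for(label, grid_small.kc)
        opmap, odmap = cm.fixture(label, grid_small, params)
        back = fc.project_planform(opmap, odmap)
        sol_amps = fc.project_planform(opmap, odmap)
        # synthesize again from the recovered amplitudes and compare fields
        op2, od2 = fc.synthesize_planform(grid_small, back)
        assert np.allclose(op2.z, opmap.z, atol=1e-12)
        assert np.allclose(od2.o, odmap.o, atol=1e-12)
        assert np.allclose(sol_amps.A, back.A, atol=1e-12)

    def test_single_mode_gives_unit_selectivity_ramp(self, grid_small):
        amps = fc.PlanformAmplitudes()
        amps.A[0] = 1.0
        opmap, _ = fc.synthesize_planform(grid_small, amps)
        assert np.allclose(np.abs(opmap.z), 1.0)
        th = opmap.theta
        assert np.allclose(th[:, 1:] - th[:, :1], th[:, :1] * 0, atol=1e-9)

    def test_hexagonal_od_has_sixfold_spectrum(self, grid_small):
        params = _params_for("od_hexagons", grid_small.kc)
        _, odmap = cm.fixture("od_hexagons", grid_small, params)
        F = np.abs(np.fft.fft2(odmap.o - odmap.o.mean()))
        peaks = np.argwhere(F > 0.5 * F.max())
        assert len(peaks) == 6

    def test_non_commensurate_wavevector_raises(self, grid_small):
        amps = fc.PlanformAmplitudes(angle=0.1)   # rotated off the lattice
        amps.A[0] = 1.0
        with pytest.raises(fc.CommensurabilityError):
            fc.synthesize_planform(grid_small, amps)


class TestSymmetryOperations:
    def test_orientation_shift_identity_and_period(self, grid_small):
        params = _params_for("hpwc_ipsi", grid_small.kc)
        opmap, _ = cm.fixture("hpwc_ipsi", grid_small, params)
        for phi in (0.0, 2.0 * np.pi):
            shifted = fc.apply_orientation_shift(opmap, phi)
            assert np.allclose(shifted.z, opmap.z, atol=1e-12)

    def test_orientation_shift_by_pi_rotates_theta_90deg(self, grid_small):
        params = _params_for("op_stripes", grid_small.kc)
        opmap, _ = cm.fixture("op_stripes", grid_small, params)
        shifted = fc.apply_orientation_shift(opmap, np.pi)
        dth = np.mod(shifted.theta - opmap.theta, np.pi)
        assert np.allclose(dth, np.pi / 2, atol=1e-9)

    def test_shift_commutes_with_synthesis(self, grid_small):
        """Shifting all OP amplitudes equals shifting the synthesized map."""
        params = _params_for("hpwc_ipsi", grid_small.kc)
        opmap, odmap = cm.fixture("hpwc_ipsi", grid_small, params)
        amps = fc.project_planform(opmap, odmap)
        phi = 0.77
        amps.A *= np.exp(1j * phi)
        amps.A_opp *= np.exp(1j * phi)
        op2, _ = fc.synthesize_planform(grid_small, amps)
        assert np.allclose(op2.z, fc.apply_orientation_shift(opmap, phi).z,
                           atol=1e-12)

    def test_eye_inversion_negates_od_exactly(self, grid_small):
        params = _params_for("od_hexagons", grid_small.kc)
        _, odmap = cm.fixture("od_hexagons", grid_small, params)
        amps = fc.project_planform(fc.OPMap(np.zeros_like(odmap.o, complex),
                                            grid_small), odmap)
        amps.B = -amps.B
        amps.delta = -amps.delta
        _, flipped = fc.synthesize_planform(grid_small, amps)
        assert np.allclose(flipped.o, -odmap.o, atol=1e-12)

    def test_crystal_sixfold_rotation_with_orientation_shift(self, grid_small):
        """The uniform crystal is invariant under a 60-degree rotation
        combined with the matching orientation shift (checked in mode space,
        where the rotation is exact)."""
        params = _params_for("hpwc_ipsi", grid_small.kc)
        opmap, odmap = cm.fixture("hpwc_ipsi", grid_small, params)
        amps = fc.project_planform(opmap, odmap)
        # rotation by 60 deg maps mode k_j -> -k_{j+2(cyclic)}; assemble the
        # rotated amplitude vector
        C = np.concatenate([amps.A, amps.A_opp])
        rot = np.empty(6, complex)
        for j in range(3):
            rot[(j + 2) % 3 + 3] = C[j]        # k_j -> -k_{j+2}
            rot[(j + 2) % 3] = C[j + 3]        # -k_j -> k_{j+2}
        # an orientation shift must make the rotated state coincide
        ratios = rot / C
        assert np.allclose(np.abs(ratios), 1.0, atol=1e-10)
        assert np.ptp(np.angle(ratios * np.conj(ratios[0]))) < 1e-10


class TestThetaSelectivityRoundTrip:
    def test_reconstruction_is_exact(self, grid_small):
        params = _params_for("hpwc_ipsi", grid_small.kc)
        opmap, _ = cm.fixture("hpwc_ipsi", grid_small, params)
        rebuilt = fc.OPMap.from_theta_selectivity(opmap.theta,
                                                  opmap.selectivity,
                                                  grid_small)
        assert np.allclose(rebuilt.z, opmap.z, atol=1e-10)


class TestFixtureContracts:
    def test_scotoma_requires_product_coupling(self, grid_small):
        params = ModelParams(r_op=0.1, r_od=0.2, coupling_kind="gradient_low",
                             c=1.0, eta=0.2, kc=grid_small.kc)
        with pytest.raises(ValueError):
            cm.fixture("op_scotoma", grid_small, params)

    def test_crystal_outside_existence_names_border(self, grid_small):
        params = ModelParams(r_op=0.1, r_od=0.2, coupling_kind="product_low",
                             c=5.0, eta=ETA_MID, kc=grid_small.kc)
        with pytest.raises(ValueError, match="border"):
            cm.fixture("hpwc_ipsi", grid_small, params)

    def test_od_constant_is_uniform(self, grid_small):
        params = _params_for("od_constant", grid_small.kc)
        _, odmap = cm.fixture("od_constant", grid_small, params)
        assert np.ptp(odmap.o) < 1e-12
        assert odmap.o[0, 0] == pytest.approx(params.delta)

    def test_stripe_fixture_is_pinwheel_free_single_mode(self, grid_small):
        params = _params_for("op_stripes", grid_small.kc)
        opmap, _ = cm.fixture("op_stripes", grid_small, params)
        F = np.abs(np.fft.fft2(opmap.z))
        F[np.abs(F) < 1e-6 * F.max()] = 0
        assert np.count_nonzero(F) == 1


class TestSnapshotIO:
    def test_h5_roundtrip(self, grid_small, tmp_path):
        params = _params_for("hpwc_ipsi", grid_small.kc)
        opmap, odmap = cm.fixture("hpwc_ipsi", grid_small, params)
        path = tmp_path / "snap.h5"
        fc.save_fields(path, opmap, odmap, params)
        op2, od2, p2 = fc.load_fields(path)
        assert np.allclose(op2.z, opmap.z)
        assert np.allclose(od2.o, odmap.o)
        assert p2.c == params.c
        assert op2.grid.Lx == pytest.approx(grid_small.Lx)
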