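"""Coupled OP amplitude equations: closed-form branches, stability,
continuation, potential."""

import numpy as np
import pytest

from corticalmaps import op_amplitudes as opa
from corticalmaps.energetics import ModelParams
from conftest import ETA_MID, params_gradient, params_product


def residual(sol):
    st = sol.state
    return np.linalg.norm(opa.op_amplitude_rhs(st.C, st.params, st.od))


class TestClosedFormResiduals:
    """Every closed-form branch is stationary to < 1e-10 across its range."""

    @pytest.mark.parametrize("label", ["op_stripes", "op_rhombic",
                                       "hpwc_psi_a", "hpwc_psi_b"])
    def test_uncoupled_branches(self, label):
        for r in np.linspace(0.01, 0.5, 25):
            p = ModelParams(r_op=r, r_od=0.2, c=0.0, gamma=0.0, kc=1.0)
            sol = opa.stationary_branch(label, p, "stripes")
            assert residual(sol) < 1e-10

    def test_product_od_stripes_family(self):
        count = 0
        for eta in np.linspace(0.05, 0.42, 6):
            for c in np.linspace(0.05, 1.4, 10):
                p = params_product(c=c, eta=eta)
                for label in ("op_stripes", "op_scotoma"):
                    sol = opa.stationary_branch(label, p, "stripes")
                    if sol.exists:
                        assert residual(sol) < 1e-10, (label, eta, c)
                        count += 1
        assert count >= 60

    def test_uniform_crystal_families(self):
        count = 0
        for kind, pf in (("product_low", params_product),
                         ("gradient_low", params_gradient)):
            for eta in np.linspace(0.26, 1.05, 6):
                for c in np.linspace(0.05, 1.2, 10):
                    p = pf(c=c, eta=eta)
                    for label in ("hpwc_psi_a", "hpwc_psi_b"):
                        sol = opa.stationary_branch(label, p, "hexagons")
                        if sol.exists:
                            assert residual(sol) < 1e-10, (kind, label, eta, c)
                            count += 1
        assert count >= 60


class TestStripeDeformation:
    def test_amplitudes_collapse_at_printed_border(self):
        p0 = params_product(c=0.0, eta=0.2)
        borders = opa.existence_borders("product_low", "stripes", p0)
        c_star = borders["stripe_collapse"]
        sol = opa.stationary_branch("op_stripes", params_product(
            c=c_star * (1 - 1e-9), eta=0.2), "stripes")
        assert abs(sol.info["A_plus"] - sol.info["A_minus"]) < 1e-4

    def test_uncoupled_limit_recovers_single_mode(self):
        sol = opa.stationary_branch("op_stripes", params_product(c=0.0),
                                    "stripes")
        assert abs(sol.state.C[0]) == pytest.approx(np.sqrt(0.1))
        assert np.allclose(sol.state.C[1:], 0.0)

    def test_scotoma_continues_the_collapsed_branch(self):
        p = params_product(c=1.2, eta=0.2)
        sol = opa.stationary_branch("op_scotoma", p, "stripes")
        assert sol.exists and sol.info["at_or_beyond_collapse"]
        a = np.abs(sol.state.C)
        assert a[0] == pytest.approx(a[3])


class TestExistenceBorders:
    def test_product_suppression_border_is_bias_independent(self):
        """The final existence border equals 3 r_op / r_od at any bias,
        for OD stripes (scotoma) and OD hexagons (stable crystal) alike."""
        for eta, od_label in [(0.1, "stripes"), (0.35, "stripes"),
                              (0.3, "hexagons"), (0.9, "hexagons")]:
            p = params_product(eta=eta)
            b = opa.existence_borders("product_low", od_label, p)
            key = "suppression" if od_label == "stripes" else "suppression_psi_b"
            assert b[key] == pytest.approx(3 * 0.1 / 0.2, rel=1e-9)

    def test_amplitude_vanishes_continuously_at_border(self):
        p0 = params_product(eta=ETA_MID)
        b = opa.existence_borders("product_low", "hexagons", p0)["suppression_psi_b"]
        amps = []
        for f in (0.9, 0.99, 0.999):
            sol = opa.stationary_branch("hpwc_psi_b",
                                        params_product(c=f * b), "hexagons")
            amps.append(np.abs(sol.state.C[0]))
        assert amps[0] > amps[1] > amps[2]
        assert amps[2] < 0.2 * amps[0]
        beyond = opa.stationary_branch("hpwc_psi_b",
                                       params_product(c=1.001 * b), "hexagons")
        assert not beyond.exists

    def test_gradient_borders_scale_with_hexagon_amplitude(self):
        p = params_gradient(eta=ETA_MID)
        od = p.od_branch("hexagons")
        b = opa.existence_borders("gradient_low", "hexagons", p)
        assert b["suppression_psi_a"] == pytest.approx(
            2 * p.r_op / (3 * p.kc ** 4 * od.amplitude ** 2), rel=1e-9)
        assert b["suppression_psi_b"] == pytest.approx(
            p.r_op / (2 * p.kc ** 4 * od.amplitude ** 2), rel=1e-9)


class TestStability:
    def test_uncoupled_stripes_and_rhombs_stable_stripes_preferred(self):
        p = ModelParams(r_op=0.1, r_od=0.2, c=0.0, gamma=0.0, kc=1.0)
        st = opa.stationary_branch("op_stripes", p, "stripes")
        rh = opa.stationary_branch("op_rhombic", p, "stripes")
        assert opa.linear_stability(st, p).stable
        assert opa.linear_stability(rh, p).stable
        assert st.V == pytest.approx(-0.1 ** 2 / 2)
        assert rh.V == pytest.approx(-2 * 0.1 ** 2 / 5)
        assert st.V < rh.V

    def test_product_crystal_stable_above_bias_dependent_coupling(self):
        lo = opa.stationary_branch("hpwc_psi_b", params_product(c=0.1),
                                   "hexagons")
        hi = opa.stationary_branch("hpwc_psi_b", params_product(c=0.8),
                                   "hexagons")
        assert not opa.linear_stability(lo, lo.state.params).stable
        assert opa.linear_stability(hi, hi.state.params).stable

    def test_gradient_unstable_psi_family_never_stabilizes(self):
        for c in (0.2, 0.5, 1.0):
            sol = opa.stationary_branch("hpwc_psi_b", params_gradient(c=c),
                                        "hexagons")
            if sol.exists:
                rep = opa.linear_stability(sol, sol.state.params)
                assert not rep.stable

    def test_orientation_shift_gauge_invariance(self):
        """A global phase shift changes neither residual, potential, nor
        spectrum; the corresponding zero mode is present in every report."""
        sol = opa.stationary_branch("hpwc_psi_b", params_product(c=0.8),
                                    "hexagons")
        p = sol.state.params
        rep0 = opa.linear_stability(sol, p)
        assert rep0.n_symmetry >= 1
        shifted = opa.StationarySolution(
            sol.label, opa.AmplitudeState(sol.state.C * np.exp(0.37j),
                                          sol.state.od, p))
        assert residual(shifted) < 1e-10
        assert opa.potential_value(shifted, p) == pytest.approx(sol.V)
        rep1 = opa.linear_stability(shifted, p)
        assert np.allclose(np.sort(rep1.eigenvalues),
                           np.sort(rep0.eigenvalues), atol=1e-6)


class TestPotential:
    def test_trivial_state_has_zero_potential(self):
        sol = opa.stationary_branch("trivial", params_product(), "hexagons")
        assert sol.V == 0.0

    def test_gradient_of_potential_reproduces_rhs(self):
        rng = np.random.default_rng(7)
        p = params_product(c=0.6)
        od = p.od_branch("hexagons")
        C = 0.2 * (rng.standard_normal(6) + 1j * rng.standard_normal(6))
        rhs = opa.op_amplitude_rhs(C, p, od)
        h = 1e-6
        for i in range(6):
            for dv in (1.0, 1.0j):
                dC = np.zeros(6, complex)
                dC[i] = dv * h
                st = lambda CC: opa.potential_value(
                    opa.AmplitudeState(CC, od, p))
                dV = (st(C + dC) - st(C - dC)) / (2 * h)
                # dV/dt = -2 |rhs|^2 => directional: dV = -2 Re(conj(rhs) dC)
                assert dV == pytest.approx(
                    -2 * (np.conj(rhs[i]) * dv).real, abs=1e-5)

    def test_crystal_beats_stripes_at_strong_coupling(self):
        p = params_product(c=0.8)
        cr = opa.stationary_branch("hpwc_psi_b", p, "hexagons")
        st = opa.stationary_branch("op_stripes", p, "hexagons")
        assert cr.exists
        assert (not st.exists) or cr.V < st.V


class TestNewtonContinuation:
    def test_zero_length_path_returns_seed(self):
        p0 = params_product(c=0.0)
        seed = opa.stationary_branch("op_stripes", p0, "hexagons")
        out = opa.newton_continue(seed.state, p0, [0.0])
        assert np.allclose(out[-1][1], seed.state.C)

    def test_continuation_is_tolerance_consistent(self):
        p = params_product(c=0.15)
        p0 = params_product(c=0.0)
        seed = opa.stationary_branch("op_stripes", p0, "hexagons")
        path = np.linspace(0.0, 0.15, 6)[1:]
        a = opa.newton_continue(seed.state, p, path, tol=1e-10)
        b = opa.newton_continue(seed.state, p, path, tol=1e-13)
        assert np.allclose(a[-1][1], b[-1][1], atol=1e-8)

    def test_rhombic_branch_terminates_before_crystal_border(self):
        """Following the rhombic family toward strong product coupling, the
        branch ends (Newton stops converging) below the crystal's existence
        border -- the bistability window closes from the rhombic side."""
        p0 = params_product(c=0.0)
        border = opa.existence_borders("product_low", "hexagons",
                                       p0)["suppression_psi_b"]
        seed = opa.stationary_branch("op_rhombic", p0, "hexagons")
        path = np.linspace(0.0, border, 40)[1:]
        samples = opa.newton_continue(seed.state, params_product(c=border),
                                      path, max_halvings=6)
        assert samples
        assert samples[-1][0] < border

    def test_non_stationary_seed_is_rejected(self):
        p0 = params_product(c=0.0)
        seed = opa.stationary_branch("op_stripes", p0, "hexagons")
        bad = opa.AmplitudeState(seed.state.C + 0.05, seed.state.od, p0)
        with pytest.raises(ValueError, match="not stationary"):
            opa.newton_continue(bad, params_product(c=0.1), [0.1])


class TestCouplingStructure:
    def test_gradient_coupling_with_constant_od_is_inert(self):
        """With a spatially constant OD map the gradient-type interaction
        leaves the OP dynamics unaffected."""
        rng = np.random.default_rng(3)
        C = 0.3 * (rng.standard_normal(6) + 1j * rng.standard_normal(6))
        p_off = ModelParams(r_op=0.1, r_od=0.2, coupling_kind="gradient_low",
                            c=0.0, eta=1.2, kc=1.0)
        p_on = ModelParams(r_op=0.1, r_od=0.2, coupling_kind="gradient_low",
                           c=2.0, eta=1.2, kc=1.0)
        od = p_on.od_branch("constant")
        assert np.allclose(opa.op_amplitude_rhs(C, p_on, od),
                           opa.op_amplitude_rhs(C, p_off, od))

    def test_ice_cube_solution_for_gradient_od_stripes(self):
        sol = opa.stationary_branch("op_stripes", params_gradient(c=2.0),
                                    "stripes")
        assert sol.angle == pytest.approx(np.pi / 2)
        assert abs(sol.state.C[0]) == pytest.approx(np.sqrt(0.1))
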