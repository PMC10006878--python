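import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from isfetsim import (
    CONST,
    SiteBindingParams,
    composition_from_ph_and_chloride,
    ph_sensitivity,
    sigma0_site_binding,
    solve_surface_state,
    surface_concentrations,
    thermal_voltage,
)
from isfetsim.physchem import InvalidParameterError
from isfetsim.surface_chemistry import DegenerateChemistryError, _sigma0_of_psi0


@pytest.fixture(scope="module")
def comp80():
    return composition_from_ph_and_chloride(80.0)


@pytest.fixture(scope="module")
def params():
    return SiteBindingParams()


class TestSurfaceConcentrations:
    def test_zero_potential_identity(self, comp80):
        c_h, c_cl = surface_concentrations(0.0, comp80)
        assert c_h == pytest.approx(comp80.conc("H"), rel=1e-14)
        assert c_cl == pytest.approx(comp80.conc("Cl"), rel=1e-14)

    def test_unit_exponent(self, comp80):
        vt = thermal_voltage(comp80.T)
        _, c_cl = surface_concentrations(vt, comp80)
        assert c_cl == pytest.approx(np.e * comp80.conc("Cl"), rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(psi0=st.floats(-0.3, 0.3))
    def test_product_invariant(self, comp80, psi0):
        """Opposite Boltzmann exponents cancel: H_S * Cl_S = H_B * Cl_B."""
        c_h, c_cl = surface_concentrations(psi0, comp80)
        assert c_h * c_cl == pytest.approx(
            comp80.conc("H") * comp80.conc("Cl"), rel=1e-9
        )


class TestSigma0SiteBinding:
    def test_point_of_zero_charge(self, params):
        p = replace(params, K_c=0.0)
        h_pzc = np.sqrt(p.K_a * p.K_b)
        assert sigma0_site_binding(h_pzc, 1e-3, 0.0, p) == pytest.approx(0.0, abs=1e-20)

    def test_chloride_saturation(self, params):
        """K_c -> infinity drives every site negative: sigma0 -> -q N_S."""
        p = replace(params, K_c=1e12)
        s = sigma0_site_binding(1e-4, 1e-3, 80.0, p)
        assert s == pytest.approx(-CONST.q * p.N_S, rel=1e-6)

    def test_generic_point_against_hand_evaluation(self, params):
        hs, hb, cls_ = 3.7e-4, 1.0e-3, 55.0
        p = params
        num = hs**2 * hb - p.K_a * p.K_b * hb - p.K_c * cls_ * hs**2
        den = hs**2 * hb + p.K_a * p.K_b * hb + p.K_c * cls_ * hs**2 + p.K_b * hs * hb
        expected = CONST.q * p.N_S * num / den
        assert sigma0_site_binding(hs, hb, cls_, p) == pytest.approx(expected, rel=1e-14)

    @settings(deadline=None, derandomize=True)
    @given(
        hs=st.floats(1e-8, 1e2),
        cls_=st.floats(0.0, 200.0),
    )
    def test_bounded_by_total_site_charge(self, params, hs, cls_):
        assert abs(sigma0_site_binding(hs, 1e-3, cls_, params)) < CONST.q * params.N_S

    def test_degenerate_chemistry_raises(self):
        p = SiteBindingParams(K_a=0.0, K_b=0.0, K_c=0.0)
        with pytest.raises(DegenerateChemistryError):
            sigma0_site_binding(0.0, 0.0, 0.0, p)


class TestSolveSurfaceState:
    def test_pzc_gives_zero_everything(self):
        """K_c = 0 at the point-of-zero-charge pH: psi0 = sigma0 = drop = 0."""
        p = SiteBindingParams(K_c=0.0)  # PZC at pH 7
        comp = composition_from_ph_and_chloride(80.0, pH=7.0)
        s = solve_surface_state(comp, p)
        assert s.psi0 == pytest.approx(0.0, abs=1e-9)
        assert s.sigma0 == pytest.approx(0.0, abs=1e-10)
        assert s.delta_phi_st == pytest.approx(0.0, abs=1e-10)

    def test_chloride_drives_surface_negative(self, params):
        psis = [
            solve_surface_state(composition_from_ph_and_chloride(c), params).psi0
            for c in (30.0, 60.0, 90.0, 120.0)
        ]
        assert all(b < a for a, b in zip(psis, psis[1:]))

    def test_monotonicity_against_residual_scan(self, params):
        """Brute-force check: the charge-balance residual crosses zero at a
        more negative psi0 when the chloride level is raised."""
        from isfetsim.electrolyte import gouy_chapman_sigma

        def residual_root(c0):
            comp = composition_from_ph_and_chloride(c0)
            c_an = sum(c for s, c in zip(comp.species, comp.bulk_conc) if s.z < 0)
            psi0_grid = np.linspace(-0.5, 0.2, 20001)
            res = []
            for psi0 in psi0_grid:
                s0 = _sigma0_of_psi0(psi0, comp, params)
                psi_d = psi0 - s0 / params.C_st
                res.append(s0 - gouy_chapman_sigma(psi_d, c_an, comp))
            res = np.asarray(res)
            k = np.where(np.diff(np.sign(res)) != 0)[0]
            assert k.size == 1  # single root in the scan window
            return psi0_grid[k[0]]

        lo, hi = residual_root(50.0), residual_root(110.0)
        assert hi < lo
        s50 = solve_surface_state(composition_from_ph_and_chloride(50.0), params).psi0
        assert s50 == pytest.approx(lo, abs=1e-4)

    def test_couplings_agree(self, comp80, params):
        a = solve_surface_state(comp80, params, coupling="analytic_GCS")
        b = solve_surface_state(comp80, params, coupling="full_PNP")
        assert b.psi0 == pytest.approx(a.psi0, rel=0.01)

    def test_stern_contract(self, comp80, params):
        s = solve_surface_state(comp80, params)
        assert s.psi0 - s.psi_d == pytest.approx(s.sigma0 / params.C_st, rel=1e-12)

    def test_charge_closure(self, comp80, params):
        s = solve_surface_state(comp80, params)
        assert s.residual < 1e-12

    def test_sigma0_bound(self, comp80, params):
        s = solve_surface_state(comp80, params)
        assert abs(s.sigma0) < CONST.q * params.N_S

    def test_chloride_signal_dominates_ionic_strength(self, params):
        """With K_c > 0 the chloride response is >100x the K_c = 0 residual."""

        def slope(p):
            a = solve_surface_state(composition_from_ph_and_chloride(79.0), p).psi0
            b = solve_surface_state(composition_from_ph_and_chloride(81.0), p).psi0
            return (b - a) / 2.0

        with_cl = slope(params)
        without = slope(replace(params, K_c=0.0))
        assert abs(with_cl / without) > 100


class TestPhSensitivity:
    def test_nernstian_bound_and_limit(self):
        vt_ln10 = thermal_voltage(298.15) * np.log(10)
        for n_s in (1e16, 1e17, 1e18, 1e19):
            p = SiteBindingParams(N_S=n_s, K_c=0.0)
            slope = ph_sensitivity(p)
            assert abs(slope) <= vt_ln10 * (1 + 1e-9)
        # large site density approaches the Nernst slope within 2%
        slope = ph_sensitivity(SiteBindingParams(N_S=1e19, K_c=0.0))
        assert abs(slope) == pytest.approx(vt_ln10, rel=0.02)

    def test_no_sites_no_response(self):
        slope = ph_sensitivity(SiteBindingParams(N_S=1e10, K_c=0.0))
        assert abs(slope) < 1e-6

    def test_titration_is_monotone_decreasing(self):
        """Surface potential falls as pH rises (brute-force titration scan)."""
        p = SiteBindingParams(K_c=0.0)
        psis = [
            solve_surface_state(composition_from_ph_and_chloride(80.0, pH=ph), p).psi0
            for ph in np.linspace(4.0, 9.0, 11)
        ]
        assert all(b < a for a, b in zip(psis, psis[1:]))

    def test_requires_chloride_blind_chemistry(self):
        with pytest.raises(InvalidParameterError):
            ph_sensitivity(SiteBindingParams(K_c=0.1))
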