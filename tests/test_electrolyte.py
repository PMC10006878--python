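import numpy as np
import pytest

from isfetsim import (
    SurfaceBC,
    UnsupportedCompositionError,
    composition_from_ph_and_chloride,
    debye_length,
    double_layer_capacitance,
    gouy_chapman_sigma,
    make_grid,
    refine,
    solve_pnp,
)
from isfetsim.physchem import ElectrolyteComposition, InvalidParameterError, IonSpecies


def anion_total(comp):
    return sum(c for s, c in zip(comp.species, comp.bulk_conc) if s.z < 0)


@pytest.fixture(scope="module")
def grid100(comp100):
    return make_grid(comp100)


class TestGouyChapmanSigma:
    def test_neutral_surface(self, comp100):
        assert gouy_chapman_sigma(0.0, 100.0, comp100) == 0.0

    def test_antisymmetry(self, comp100):
        s = gouy_chapman_sigma(0.05, 100.0, comp100)
        assert gouy_chapman_sigma(-0.05, 100.0, comp100) == pytest.approx(-s, rel=1e-14)

    def test_small_potential_matches_debye_capacitance(self, comp100):
        # series expansion: sigma -> (eps/lambda_D) * psi as psi -> 0
        psi = 1e-3
        lam = debye_length(comp100)
        c_debye = 8.8541878188e-12 * comp100.eps_r / lam
        sigma = gouy_chapman_sigma(psi, anion_total(comp100), comp100)
        assert sigma == pytest.approx(c_debye * psi, rel=5e-3)

    def test_rejects_divalent_composition(self):
        comp = ElectrolyteComposition(
            species=(IonSpecies("Ca", 2, 0.79e-9), IonSpecies("Cl", -1, 2.03e-9)),
            bulk_conc=(50.0, 100.0),
            pH=7.0,
        )
        with pytest.raises(UnsupportedCompositionError):
            gouy_chapman_sigma(0.025, 50.0, comp)


class TestSolvePNP:
    def test_uncharged_surface_is_flat(self, comp100, grid100):
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_charge", sigma0=0.0), grid100)
        assert np.allclose(st.phi_l, 0.0, atol=1e-12)
        for i, (sp, cb) in enumerate(zip(comp100.species, comp100.bulk_conc)):
            assert np.allclose(st.conc[i], cb, rtol=1e-10)

    @pytest.mark.parametrize("psi", [0.025, -0.025, 0.075, -0.075])
    @pytest.mark.parametrize("c0", [10.0, 100.0])
    def test_grahame_oracle(self, psi, c0):
        """Integrated diffuse charge matches the Grahame closed form to <1%."""
        comp = composition_from_ph_and_chloride(c0)
        st = solve_pnp(comp, SurfaceBC(mode="fixed_potential", phi_OHP=psi), make_grid(comp))
        sigma_ref = -gouy_chapman_sigma(psi, anion_total(comp), comp)
        assert st.sigma_diffuse == pytest.approx(sigma_ref, rel=0.01)

    def test_refinement_error_decreases_monotonically(self, comp100):
        psi = 0.075
        sigma_ref = -gouy_chapman_sigma(psi, anion_total(comp100), comp100)
        errs = []
        grid = make_grid(comp100, n_nodes=101)
        for _ in range(3):
            st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=psi), grid)
            errs.append(abs(st.sigma_diffuse - sigma_ref) / abs(sigma_ref))
            grid = refine(grid)
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] < 0.01

    def test_charge_conjugation_swaps_counterions(self, comp100, grid100):
        """Mirror the OHP potential: Na+ and Cl- profiles exchange roles."""
        stp = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.04), grid100)
        stm = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=-0.04), grid100)
        i_na = [s.name for s in comp100.species].index("Na")
        i_cl = [s.name for s in comp100.species].index("Cl")
        ratio_na = stp.conc[i_na] / comp100.bulk_conc[i_na]
        ratio_cl = stm.conc[i_cl] / comp100.bulk_conc[i_cl]
        assert np.allclose(ratio_na, ratio_cl, rtol=1e-8)

    def test_boltzmann_relation_at_blocking_surface(self, comp100, grid100):
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.05), grid100)
        from isfetsim.physchem import thermal_voltage

        Vt = thermal_voltage(comp100.T)
        for i, (sp, cb) in enumerate(zip(comp100.species, comp100.bulk_conc)):
            expected = cb * np.exp(-sp.z * st.phi_l / Vt)
            assert np.allclose(st.conc[i], expected, rtol=1e-6)

    def test_flux_divergence_vanishes(self, comp100, grid100):
        """Mass preservation: scaled divergence of every species flux < 1e-8."""
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.075), grid100)
        L = grid100.L_bulk
        for i, sp in enumerate(comp100.species):
            div = np.abs(np.diff(st.J[i]))
            scale = sp.D * max(comp100.bulk_conc) / L
            assert div.max() / scale < 1e-8

    def test_bulk_node_electroneutral(self, comp100, grid100):
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.05), grid100)
        z = np.array([s.z for s in comp100.species], dtype=float)
        assert abs((z * st.conc[:, -1]).sum()) < 1e-9 * max(comp100.bulk_conc)

    def test_screening_beyond_ten_debye_lengths(self, comp100, grid100):
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.075), grid100)
        lam = debye_length(comp100)
        far = grid100.y > 10 * lam
        assert np.max(np.abs(st.phi_l[far])) < 1e-3 * abs(st.phi_l[0])

    def test_grid_shorter_than_30_debye_rejected(self, comp100):
        from isfetsim.electrolyte import Grid1D

        lam = debye_length(comp100)
        grid = Grid1D(y=np.linspace(0.0, 10 * lam, 64))
        with pytest.raises(InvalidParameterError):
            solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.01), grid)

    def test_bc_requires_exactly_one_mode(self):
        with pytest.raises(InvalidParameterError):
            SurfaceBC(mode="fixed_charge", sigma0=0.01, phi_OHP=0.01)
        with pytest.raises(InvalidParameterError):
            SurfaceBC(mode="fixed_potential")


class TestDoubleLayerCapacitance:
    def test_high_salt_approaches_stern(self):
        """C_diff diverges at high ionic strength, leaving C_st = 0.20 F/m^2."""
        comp = composition_from_ph_and_chloride(3000.0)
        st = solve_pnp(comp, SurfaceBC(mode="fixed_potential", phi_OHP=0.01), make_grid(comp))
        c = double_layer_capacitance(st, C_st=0.20)
        assert c == pytest.approx(0.20, rel=0.15)
        assert c < 0.20

    def test_infinite_stern_gives_diffuse_capacitance(self, comp100, grid100):
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.01), grid100)
        c_diff = double_layer_capacitance(st, C_st=np.inf)
        lam = debye_length(comp100)
        assert c_diff == pytest.approx(8.8541878188e-12 * comp100.eps_r / lam, rel=0.02)

    def test_equal_capacitances_halve(self, comp100, grid100):
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.01), grid100)
        c_diff = double_layer_capacitance(st, C_st=np.inf)
        c = double_layer_capacitance(st, C_st=c_diff)
        assert c == pytest.approx(0.5 * c_diff, rel=1e-6)

    def test_below_both_components(self, comp100, grid100):
        st = solve_pnp(comp100, SurfaceBC(mode="fixed_potential", phi_OHP=0.01), grid100)
        c_diff = double_layer_capacitance(st, C_st=np.inf)
        c = double_layer_capacitance(st, C_st=0.2)
        assert c < min(0.2, c_diff)
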