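import numpy as np
import pytest

from isfetsim import (
    BiasPoint,
    DeviceGeometry,
    OxideSpec,
    SemiconductorParams,
    fermi_potential,
    ids_compact,
    make_threshold_params,
    threshold_voltage,
    thermal_voltage,
)
from isfetsim.physchem import CONST, InvalidParameterError
from isfetsim.semiconductor import (
    ExtractionError,
    bulk_depletion_charge,
    extract_vth_curve,
)


@pytest.fixture(scope="module")
def sp_():
    return SemiconductorParams()


@pytest.fixture(scope="module")
def geom():
    return DeviceGeometry()


@pytest.fixture(scope="module")
def tp(sp_, geom):
    return make_threshold_params(sp_, geom.oxide)


class TestFermiPotential:
    def test_intrinsic_gives_zero(self):
        p = SemiconductorParams(N_A=1e16 * (1 + 1e-12), n_i=1e16)
        assert fermi_potential(p) == pytest.approx(0.0, abs=1e-12)

    def test_unit_log(self):
        p = SemiconductorParams(N_A=np.e * 1e16, n_i=1e16)
        assert fermi_potential(p) == pytest.approx(thermal_voltage(298.15), rel=1e-9)

    def test_reference_doping(self, sp_):
        # (kT/q) ln(1e23/1e16), hand-evaluated
        expected = CONST.k * 298.15 / CONST.q * np.log(1e7)
        assert fermi_potential(sp_) == pytest.approx(expected, rel=1e-12)


class TestThresholdVoltage:
    def test_psi0_coupling_is_minus_one(self, tp):
        v0 = threshold_voltage(tp, 0.0)
        assert threshold_voltage(tp, 0.010) == pytest.approx(v0 - 0.010, abs=1e-15)

    def test_only_fermi_term(self, sp_, geom):
        from isfetsim.semiconductor import ThresholdParams

        tp = ThresholdParams(
            E_ref=0.0, chi_sol=0.0, phi_si=0.0, Q_ox=0.0, Q_ss=0.0, Q_B=0.0,
            C_ox=geom.oxide.C_ox, phi_f=fermi_potential(sp_),
        )
        assert threshold_voltage(tp, 0.0) == pytest.approx(2 * fermi_potential(sp_))

    def test_full_formula_hand_evaluation(self, sp_, geom, tp):
        expected = (
            tp.E_ref - 0.05 + tp.chi_sol - tp.phi_si
            - (tp.Q_ox + tp.Q_ss + tp.Q_B) / tp.C_ox
            + 2 * tp.phi_f + tp.v_cal
        )
        assert threshold_voltage(tp, 0.05) == pytest.approx(expected, rel=1e-14)

    def test_depletion_charge_consistent_with_formula(self, sp_):
        expected = np.sqrt(
            4 * CONST.eps0 * sp_.eps_r_si * CONST.q * sp_.N_A * fermi_potential(sp_)
        )
        assert bulk_depletion_charge(sp_) == pytest.approx(expected, rel=1e-14)


class TestIdsCompact:
    def test_zero_overdrive_cuts_off(self, tp, sp_, geom):
        vth = threshold_voltage(tp, 0.0)
        assert ids_compact(tp, sp_, geom, BiasPoint(vth, 1.0), 0.0) == 0.0

    def test_square_law(self, tp, sp_, geom):
        vth = threshold_voltage(tp, 0.0)
        i1 = ids_compact(tp, sp_, geom, BiasPoint(vth + 0.2, 2.0), 0.0)
        i2 = ids_compact(tp, sp_, geom, BiasPoint(vth + 0.4, 2.0), 0.0)
        assert i2 == pytest.approx(4 * i1, rel=1e-12)

    def test_continuity_at_saturation_boundary(self, tp, sp_, geom):
        vth = threshold_voltage(tp, 0.0)
        v_ov = 0.3
        sat = ids_compact(tp, sp_, geom, BiasPoint(vth + v_ov, v_ov), 0.0)
        tri = ids_compact(tp, sp_, geom, BiasPoint(vth + v_ov, v_ov - 1e-9), 0.0)
        assert sat == pytest.approx(tri, rel=1e-6)

    def test_p_polarity_reverses_threshold_response(self, tp, sp_, geom):
        """p-style overdrive grows when V_TH rises (chloride adsorption)."""
        bias = BiasPoint(1.6, 1.44)
        i_lo = ids_compact(tp, sp_, geom, bias, -0.30, polarity="p")
        i_hi = ids_compact(tp, sp_, geom, bias, -0.32, polarity="p")
        assert i_hi > i_lo > 0

    def test_geometry_invariant_enforced(self):
        with pytest.raises(InvalidParameterError):
            DeviceGeometry(gate_length=2.5e-6)


class TestVthExtraction:
    def test_recovers_synthetic_square_law(self):
        K, vth, vds = 4e-4, 0.63, 0.05
        vgs = np.linspace(0.0, 1.5, 151)
        ids = np.where(
            vgs > vth,
            np.where(vds >= vgs - vth, K * (vgs - vth) ** 2,
                     K * (2 * (vgs - vth) * vds - vds**2)),
            0.0,
        )
        assert extract_vth_curve(vgs, ids, vds) == pytest.approx(vth, abs=2e-3)

    def test_flat_curve_raises(self):
        vgs = np.linspace(0.0, 1.0, 11)
        with pytest.raises(ExtractionError):
            extract_vth_curve(vgs, np.zeros_like(vgs), 0.05)

    def test_non_monotone_curve_raises(self):
        vgs = np.linspace(0.0, 1.0, 11)
        ids = np.abs(np.sin(8 * vgs)) * 1e-5
        with pytest.raises(ExtractionError):
            extract_vth_curve(vgs, ids, 0.05)


class TestDriftDiffusion:
    def test_equilibrium_mass_action(self, dd_equilibrium, sp_):
        """n p = n_i^2 within 0.1% at every node at zero bias."""
        ratio = dd_equilibrium.n * dd_equilibrium.p / sp_.n_i**2
        assert np.all(np.abs(ratio - 1.0) < 1e-3)

    def test_zero_drain_bias_zero_current(self, dd_vds_zero, dd_linear):
        """V_DS = 0 leaves no terminal current (vs the 50 mV current scale)."""
        assert abs(dd_vds_zero.I_drain) < 1e-6 * abs(dd_linear.I_drain)

    def test_source_drain_current_balance(self, dd_linear, dd_saturation_sweep):
        for st in (dd_linear, dd_saturation_sweep[2]):
            assert abs(abs(st.I_source) - abs(st.I_drain)) < 1e-3 * abs(st.I_drain)

    def test_compact_dd_square_law_agreement(self, dd_vth, dd_saturation_sweep):
        """In saturation, DD current is linear in (V_GS - V_TH)^2, R^2 > 0.98."""
        v_gs, ids, _ = dd_saturation_sweep
        X = (v_gs - dd_vth) ** 2
        A = np.vstack([X, np.ones_like(X)]).T
        coef, res, _, _ = np.linalg.lstsq(A, ids, rcond=None)
        r2 = 1.0 - res[0] / ((ids - ids.mean()) ** 2).sum()
        assert r2 > 0.98
        assert coef[0] > 0

    def test_gate_translation_property(self, dd_setup, dd_vth):
        """+50 mV on the gate potential moves the extracted V_TH by -50 mV."""
        from isfetsim.semiconductor import extract_vth_dd

        sp_, geom, mesh = dd_setup
        vgs = np.arange(0.3, 1.21, 0.1)
        shifted = extract_vth_dd(sp_, geom, vgs, v_ds=0.05, mesh=mesh, gate_offset=0.05)
        assert shifted - dd_vth == pytest.approx(-0.05, abs=5e-3)

    def test_oxide_thickness_weakens_compact_response(self, sp_):
        """Thicker oxide, smaller current change for the same psi0 shift."""
        deltas = []
        for d in (30e-9, 45e-9, 60e-9, 90e-9):
            geom = DeviceGeometry(oxide=OxideSpec(d_ins=d))
            tp = make_threshold_params(sp_, geom.oxide)
            bias = BiasPoint(1.6, 1.44)
            i0 = ids_compact(tp, sp_, geom, bias, -0.30, polarity="p")
            i1 = ids_compact(tp, sp_, geom, bias, -0.31, polarity="p")
            deltas.append(i1 - i0)
        assert all(b < a for a, b in zip(deltas, deltas[1:]))
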