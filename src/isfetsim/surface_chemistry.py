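"""Self-consistent oxide-surface chemistry for the chloride-sensing ISFET.

The gate oxide carries amphoteric hydroxyl sites that protonate, deprotonate,
and — the chloride-sensing mechanism — bind Cl- onto protonated sites,
displacing adsorbed protons and charging the surface negative. The surface
charge density sigma0, the surface potential psi0 = phi_M - phi_l,bulk, and
the diffuse-layer charge are closed self-consistently through the Stern
capacitor: the potential ladder along the vertical axis is

    phi_M  --(Stern drop sigma0/C_st)-->  phi_OHP  --(diffuse layer)-->  phi_l,bulk

so psi0 = psi_d + sigma0/C_st with psi_d the OHP potential relative to bulk.
This orientation makes the chemistry/double-layer coupling a negative
feedback (an adsorbing surface depresses its own adsorption), which is the
stable branch; see docs/methods.md for the sign discussion.

Equilibrium-constant convention: concentrations in mol/m^3; K_a*K_b carries
(mol/m^3)^2, K_b carries mol/m^3, K_c is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .physchem import (
    CONST,
    ElectrolyteComposition,
    InvalidParameterError,
    composition_from_ph_and_chloride,
    thermal_voltage,
)
from . import electrolyte as el


class DegenerateChemistryError(ZeroDivisionError):
    """Site-binding denominator vanished (all-zero chemistry)."""


class RootFindError(RuntimeError):
    """Surface-state bracketing failed; carries a diagnostic residual sweep."""

    def __init__(self, message: str, sweep: list[tuple[float, float]] | None = None):
        super().__init__(message)
        self.sweep = sweep or []


@dataclass(frozen=True)
class SiteBindingParams:
    """Site-binding constants for the oxide surface.

    Defaults are a generic HfO2-like chemistry: point of zero charge at pH 7
    (sqrt(K_a K_b) = 1e-4 mol/m^3), moderate amphoteric spread, K_c = 0.1,
    Stern capacitance 0.20 F/m^2 (20 uF/cm^2). N_S = 1e19 m^-2 (10 sites/nm^2,
    upper end of the oxide literature) keeps the surface strongly buffered, so
    the chloride signal dominates the ionic-strength feedthrough by >100x.
    All config-overridable; the device-level calibration tunes K_c and N_S
    against a sensitivity anchor.
    """

    N_S: float = 1.0e19  # sites/m^2
    K_a: float = 1.0e-5  # (mol/m^3)
    K_b: float = 1.0e-3  # (mol/m^3)
    K_c: float = 0.1  # dimensionless
    C_st: float = 0.20  # F/m^2

    def __post_init__(self) -> None:
        if not self.N_S > 0:
            raise InvalidParameterError("N_S must be > 0")
        if self.K_a < 0 or self.K_b < 0 or self.K_c < 0:
            raise InvalidParameterError("equilibrium constants must be >= 0")
        if not self.C_st > 0:
            raise InvalidParameterError("C_st must be > 0")


@dataclass(frozen=True)
class ElectrodeModel:
    """Reference-electrode ladder fixing the bulk electrolyte potential.

    The gate drives the liquid through an Ag/AgCl reference electrode:
    phi_l,bulk = V_ga - W_Ag - E_eq. E_ref and chi_sol enter the compact
    threshold expression, not the electrolyte-side chemistry.
    """

    V_ga: float = 1.6  # applied gate voltage (V)
    W_Ag: float = 4.6  # silver work function (V)
    E_eq: float = 0.197  # Ag/AgCl equilibrium potential vs SHE (V)
    E_ref: float = 4.797  # reference electrode potential rel. vacuum (V)
    chi_sol: float = 0.05  # solution surface dipole potential (V)

    @property
    def phi_l_bulk(self) -> float:
        return self.V_ga - self.W_Ag - self.E_eq


@dataclass(frozen=True)
class SurfaceSolution:
    """Converged surface state.

    psi0 : phi_M - phi_l,bulk (V)
    sigma0 : oxide surface charge density (C/m^2)
    delta_phi_st : Stern drop phi_M - phi_OHP = sigma0/C_st (V)
    """

    psi0: float
    sigma0: float
    delta_phi_st: float
    c_H_surface: float
    c_Cl_surface: float
    residual: float

    @property
    def psi_d(self) -> float:
        """Diffuse-layer (OHP) potential relative to bulk (V)."""
        return self.psi0 - self.delta_phi_st


def surface_concentrations(
    psi0: float, comp: ElectrolyteComposition
) -> tuple[float, float]:
    """Boltzmann surface concentrations at surface potential psi0.

    Cl_S = Cl_B exp(+q psi0/kT) (anion), H_S = H_B exp(-q psi0/kT) (cation);
    their product is invariant in psi0.
    """
    if not np.isfinite(psi0):
        raise InvalidParameterError("psi0 must be finite")
    Vt = thermal_voltage(comp.T)
    c_h = comp.conc("H") * np.exp(-psi0 / Vt)
    c_cl = comp.conc("Cl") * np.exp(psi0 / Vt)
    return float(c_h), float(c_cl)


def sigma0_site_binding(
    c_H_surface: float,
    c_H_bulk: float,
    c_Cl_surface: float,
    p: SiteBindingParams,
) -> float:
    """Surface charge density from the chloride-modified site-binding model.

    sigma0 = q N_S (H_S^2 H_B - K_a K_b H_B - K_c Cl_S H_S^2)
                 / (H_S^2 H_B + K_a K_b H_B + K_c Cl_S H_S^2 + K_b H_S H_B)

    |sigma0| < q N_S always (each term appears in the denominator).
    """
    if min(c_H_surface, c_H_bulk, c_Cl_surface) < 0:
        raise InvalidParameterError("concentrations must be >= 0")
    hs2hb = c_H_surface**2 * c_H_bulk
    kakb = p.K_a * p.K_b * c_H_bulk
    kccl = p.K_c * c_Cl_surface * c_H_surface**2
    den = hs2hb + kakb + kccl + p.K_b * c_H_surface * c_H_bulk
    if den == 0.0:
        raise DegenerateChemistryError("site-binding denominator is zero")
    return CONST.q * p.N_S * (hs2hb - kakb - kccl) / den


def _sigma0_of_psi0(psi0: float, comp: ElectrolyteComposition, p: SiteBindingParams) -> float:
    # beyond ~2 V the site-binding charge is saturated at +-q N_S; clamping
    # keeps the Boltzmann exponentials finite at bracketing extremes
    c_h, c_cl = surface_concentrations(float(np.clip(psi0, -2.0, 2.0)), comp)
    return sigma0_site_binding(c_h, comp.conc("H"), c_cl, p)


def solve_surface_state(
    comp: ElectrolyteComposition,
    p: SiteBindingParams,
    electrode: ElectrodeModel | None = None,
    coupling: str = "analytic_GCS",
    grid: el.Grid1D | None = None,
    bracket: float = 1.5,
    tol_sigma: float = 1e-12,
) -> SurfaceSolution:
    """Find psi0 such that the site-binding surface charge balances the
    diffuse-layer charge, with the Stern drop sigma0/C_st between phi_M and
    the OHP.

    coupling = "analytic_GCS" uses the Grahame closed form for the diffuse
    charge (monovalent bath); "full_PNP" uses the finite-volume PNP solver.
    The converged residual |sigma0 + sigma_diffuse| is below tol_sigma.
    """
    if electrode is None:
        electrode = ElectrodeModel()
    if coupling not in ("analytic_GCS", "full_PNP"):
        raise InvalidParameterError(f"unknown coupling {coupling!r}")
    c_anion = float(
        sum(c for s, c in zip(comp.species, comp.bulk_conc) if s.z < 0)
    )
    if coupling == "full_PNP" and grid is None:
        grid = el.make_grid(comp)

    def sigma_diffuse(psi_d: float) -> float:
        if coupling == "analytic_GCS":
            return -el.gouy_chapman_sigma(psi_d, c_anion, comp)
        st = el.solve_pnp(comp, el.SurfaceBC(mode="fixed_potential", phi_OHP=psi_d), grid)
        return st.sigma_diffuse

    # Root-find on the OHP potential psi_d, which stays within the double
    # layer's own scale (tens of mV) no matter how stiff the site-binding
    # chemistry is; psi0 = psi_d + sigma0/C_st can swing much wider.
    # g(psi_d) = sigma0(psi0(psi_d)) + sigma_diffuse(psi_d), with psi0 found
    # from the Stern relation at the charge demanded by the diffuse layer.
    def g(psi_d: float) -> float:
        s_dif = sigma_diffuse(psi_d)
        psi0 = psi_d - s_dif / p.C_st  # sigma0 = -sigma_diffuse at closure
        return _sigma0_of_psi0(psi0, comp, p) + s_dif

    if coupling == "full_PNP":
        # seed from the analytic solution; the PNP solver then only ever
        # sees OHP potentials near the physical answer
        seed = solve_surface_state(comp, p, electrode, coupling="analytic_GCS").psi_d
        a, b = seed - 0.02, seed + 0.02
    else:
        a, b = -min(bracket, 0.5), min(bracket, 0.5)
    for _ in range(6):
        ga, gb = g(a), g(b)
        if ga * gb <= 0:
            break
        width = b - a
        a, b = a - width / 2, b + width / 2
    else:
        sweep = [(x, g(x)) for x in np.linspace(a, b, 21)]
        raise RootFindError("could not bracket the surface-state residual", sweep)

    psi_d = brentq(g, a, b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    s_dif = sigma_diffuse(psi_d)
    psi0 = psi_d - s_dif / p.C_st
    s0 = _sigma0_of_psi0(psi0, comp, p)
    c_h, c_cl = surface_concentrations(psi0, comp)
    res = abs(s0 + s_dif)
    return SurfaceSolution(
        psi0=float(psi0),
        sigma0=float(s0),
        delta_phi_st=float(s0 / p.C_st),
        c_H_surface=c_h,
        c_Cl_surface=c_cl,
        residual=float(res),
    )


def ph_sensitivity(
    p: SiteBindingParams,
    comp: ElectrolyteComposition | None = None,
    electrode: ElectrodeModel | None = None,
    dpH: float = 0.1,
    coupling: str = "analytic_GCS",
) -> float:
    """d psi0 / d pH (V per pH unit) by central difference, K_c = 0 only.

    Classical ISFET diagnostic: magnitude is bounded by the Nernst slope
    (kT/q) ln 10 and approaches it for large site density.
    """
    if p.K_c != 0:
        raise InvalidParameterError("ph_sensitivity requires a K_c = 0 configuration")
    if comp is None:
        comp = composition_from_ph_and_chloride(100.0)
    c_cl = comp.conc("Cl")
    out = []
    for ph in (comp.pH + dpH, comp.pH - dpH):
        c = composition_from_ph_and_chloride(c_cl, pH=ph, eps_r=comp.eps_r, T=comp.T)
        out.append(solve_surface_state(c, p, electrode, coupling=coupling).psi0)
    return (out[0] - out[1]) / (2.0 * dpH)
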