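"""Transistor models: compact ISFET square law and a 2D drift-diffusion solver.

Two levels, per the device's role as readout of the surface chemistry:

* compact — the ISFET threshold voltage (reference-electrode ladder plus the
  chemistry's surface potential psi0) feeding a long-channel square law.
* dd — finite-volume drift-diffusion over the 3 um x 0.7 um device
  cross-section: Poisson + electron/hole continuity with Scharfetter-Gummel
  exponential-fitting fluxes, solved by Gummel iteration (nonlinear Poisson
  with frozen quasi-Fermi levels, then linear continuity solves). Operation
  is isothermal, so the thermal-diffusion terms of the transport equations
  vanish; recombination is neglected (no generation path matters at these
  biases), which makes terminal-current conservation exact to solver
  tolerance.

Boundary conditions: ohmic source/drain contacts on the top surface, an
ohmic body contact along the bottom, a thin-insulator gate (Robin condition
through the oxide capacitance, forcing the oxide top potential to the
electrolyte-side phi_M) over the gate window, homogeneous Neumann elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .physchem import CONST, InvalidParameterError, thermal_voltage


class GummelConvergenceError(RuntimeError):
    def __init__(self, message: str, residual_history: list[float] | None = None):
        super().__init__(message)
        self.residual_history = residual_history or []


class ExtractionError(RuntimeError):
    """Threshold extraction failed (degenerate or non-monotone transfer curve)."""


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OxideSpec:
    """Gate insulator stack."""

    material: str = "HfO2"
    eps_ins: float = 25.0
    d_ins: float = 30e-9
    l_ins: float = 1.6e-6

    def __post_init__(self) -> None:
        if self.eps_ins < 1.0:
            raise InvalidParameterError("eps_ins must be >= 1")
        if not self.d_ins > 0:
            raise InvalidParameterError("d_ins must be > 0")

    @property
    def C_ox(self) -> float:
        """Oxide capacitance per unit area (F/m^2)."""
        return CONST.eps0 * self.eps_ins / self.d_ins


@dataclass(frozen=True)
class SemiconductorParams:
    """Silicon parameters (room temperature defaults)."""

    N_A: float = 1.0e23  # acceptor concentration (1/m^3)
    n_i: float = 1.0e16  # intrinsic carrier concentration (1/m^3)
    mu_n: float = 0.14  # electron mobility (m^2/(V s))
    mu_p: float = 0.045  # hole mobility (m^2/(V s))
    eps_r_si: float = 11.7
    T: float = 298.15
    N_c: float = 2.86e25  # effective DOS, conduction band (1/m^3)
    N_v: float = 3.10e25  # effective DOS, valence band (1/m^3)
    E_c: float = 1.12  # band edges (eV, valence edge at 0)
    E_v: float = 0.0
    N_D_contact: float = 1.0e26  # source/drain donor doping (1/m^3)
    junction_depth: float = 0.15e-6  # source/drain junction depth (m)

    def __post_init__(self) -> None:
        if not (self.N_A > self.n_i > 0):
            raise InvalidParameterError("require N_A > n_i > 0")
        if not (self.mu_n > 0 and self.mu_p > 0):
            raise InvalidParameterError("mobilities must be > 0")


@dataclass(frozen=True)
class DeviceGeometry:
    """Device cross-section (values from the modeled sensor layout)."""

    body_height: float = 0.7e-6
    body_width: float = 3.0e-6
    sd_length: float = 0.5e-6
    gate_length: float = 1.3e-6
    W: float = 1.0e-6  # out-of-plane channel width (m)
    L: float = 1.3e-6  # channel length (m)
    oxide: OxideSpec = field(default_factory=OxideSpec)

    def __post_init__(self) -> None:
        vals = (self.body_height, self.body_width, self.sd_length, self.gate_length, self.W, self.L)
        if any(v <= 0 for v in vals):
            raise InvalidParameterError("all geometry dimensions must be > 0")
        if self.gate_length + 2 * self.sd_length > self.body_width + 1e-15:
            raise InvalidParameterError("gate_length + 2*sd_length must fit in body_width")


@dataclass(frozen=True)
class BiasPoint:
    V_GS: float
    V_DS: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.V_GS) and np.isfinite(self.V_DS)):
            raise InvalidParameterError("bias must be finite")


@dataclass(frozen=True)
class ThresholdParams:
    """Terms of the ISFET threshold-voltage expression.

    V_TH = E_ref - psi0 + chi_sol - phi_si - (Q_ox + Q_ss + Q_B)/C_ox
           + 2 phi_f + v_cal

    v_cal is a constant operating-point offset closed by calibration (the
    residual of work functions, interface charges and packaging that the
    compact level does not resolve); the literal ladder is the v_cal = 0 case.
    """

    E_ref: float
    chi_sol: float
    phi_si: float
    Q_ox: float
    Q_ss: float
    Q_B: float
    C_ox: float
    phi_f: float
    v_cal: float = 0.0

    def __post_init__(self) -> None:
        if not self.C_ox > 0:
            raise InvalidParameterError("C_ox must be > 0")


def fermi_potential(p: SemiconductorParams) -> float:
    """phi_f = (kT/q) ln(N_A/n_i), the doped-vs-intrinsic Fermi splitting."""
    return thermal_voltage(p.T) * float(np.log(p.N_A / p.n_i))


def bulk_depletion_charge(p: SemiconductorParams) -> float:
    """Q_B at strong inversion: sqrt(4 eps_si q N_A phi_f) (C/m^2)."""
    return float(
        np.sqrt(4.0 * CONST.eps0 * p.eps_r_si * CONST.q * p.N_A * fermi_potential(p))
    )


def make_threshold_params(
    sp_: SemiconductorParams,
    oxide: OxideSpec,
    E_ref: float = 4.797,
    chi_sol: float = 0.05,
    phi_si: float = 4.05,
    Q_ox: float = 0.0,
    Q_ss: float = 0.0,
    v_cal: float = -2.73,
) -> ThresholdParams:
    """Assemble ThresholdParams with Q_B and phi_f auto-computed.

    The default v_cal places the device at a p-style operating point with
    about 0.5 V of overdrive at the default chemistry and V_GS = 1.6 V.
    """
    return ThresholdParams(
        E_ref=E_ref,
        chi_sol=chi_sol,
        phi_si=phi_si,
        Q_ox=Q_ox,
        Q_ss=Q_ss,
        Q_B=bulk_depletion_charge(sp_),
        C_ox=oxide.C_ox,
        phi_f=fermi_potential(sp_),
        v_cal=v_cal,
    )


def threshold_voltage(tp: ThresholdParams, psi0: float) -> float:
    """ISFET threshold voltage; dV_TH/dpsi0 = -1 exactly."""
    return (
        tp.E_ref
        - psi0
        + tp.chi_sol
        - tp.phi_si
        - (tp.Q_ox + tp.Q_ss + tp.Q_B) / tp.C_ox
        + 2.0 * tp.phi_f
        + tp.v_cal
    )


def ids_compact(
    tp: ThresholdParams,
    sp_: SemiconductorParams,
    geom: DeviceGeometry,
    bias: BiasPoint,
    psi0: float,
    polarity: str = "n",
) -> float:
    """Long-channel square-law drain current (A).

    polarity="n": overdrive V_GS - V_TH (current falls as V_TH rises);
    polarity="p": overdrive V_GS - |V_TH| = V_GS + V_TH for a negative
    threshold, so current rises as V_TH rises -- the sign convention under
    which increasing chloride concentration increases the saturation current.
    Returns 0 below threshold (no subthreshold term in the square law);
    triode and saturation branches join continuously.
    """
    if polarity not in ("n", "p"):
        raise InvalidParameterError(f"unknown polarity {polarity!r}")
    vth = threshold_voltage(tp, psi0)
    K = 0.5 * sp_.mu_n * tp.C_ox * geom.W / geom.L
    v_ov = bias.V_GS - vth if polarity == "n" else bias.V_GS + vth
    if v_ov <= 0.0:
        return 0.0
    v_ds = abs(bias.V_DS)
    if v_ds >= v_ov:
        return K * v_ov**2
    return K * (2.0 * v_ov * v_ds - v_ds**2)


# --------------------------------------------------------------------------
# Drift-diffusion level
# --------------------------------------------------------------------------


@dataclass
class Mesh2D:
    """Structured rectilinear mesh over the device cross-section.

    x runs laterally (source -> drain), y runs from the top surface (y=0,
    oxide interface) down to the body contact. Node spacing is geometrically
    refined toward the top surface to resolve the inversion layer.
    """

    x: np.ndarray
    y: np.ndarray

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def index(self, i: int, j: int) -> int:
        """Flat index of node (i-th x, j-th y)."""
        return j * self.nx + i


def make_mesh(
    geom: DeviceGeometry,
    nx: int = 61,
    ny: int = 41,
    surface_cell: float = 0.5e-9,
) -> Mesh2D:
    """Default 61 x 41 mesh, geometric refinement under the gate oxide."""
    x = np.linspace(0.0, geom.body_width, nx)
    n_int = ny - 1
    H = geom.body_height
    if surface_cell * n_int >= H:
        y = np.linspace(0.0, H, ny)
    else:
        r = brentq(
            lambda r_: surface_cell * (r_**n_int - 1.0) / (r_ - 1.0) - H,
            1.0 + 1e-12,
            3.0,
            xtol=1e-14,
        )
        h = surface_cell * r ** np.arange(n_int)
        y = np.concatenate([[0.0], np.cumsum(h)])
        y[-1] = H
    return Mesh2D(x=x, y=y)


@dataclass
class DDState:
    """Converged drift-diffusion solution."""

    mesh: Mesh2D
    V: np.ndarray  # (ny, nx), intrinsic-referenced electrostatic potential
    n: np.ndarray  # (ny, nx), electrons 1/m^3
    p: np.ndarray  # (ny, nx), holes 1/m^3
    I_source: float  # terminal currents (A), positive into the device
    I_drain: float
    I_body: float
    iterations: int
    residual: float
    bias: BiasPoint
    gate_potential: float


def _contact_masks(mesh: Mesh2D, geom: DeviceGeometry):
    """Boolean masks over the top row for source/drain/gate, per x-node."""
    x = mesh.x
    src = x <= geom.sd_length + 1e-15
    drn = x >= geom.body_width - geom.sd_length - 1e-15
    g0 = 0.5 * (geom.body_width - geom.gate_length)
    gate = (x >= g0 - 1e-15) & (x <= g0 + geom.gate_length + 1e-15)
    return src, drn, gate


def _doping(mesh: Mesh2D, sp_: SemiconductorParams, geom: DeviceGeometry) -> np.ndarray:
    """Net doping C = N_D - N_A on the (ny, nx) grid.

    The n+ wells extend laterally from the contacts to the gate edges
    (metallurgical junction self-aligned with the gate), so the gated channel
    connects directly to source and drain."""
    C = np.full((mesh.ny, mesh.nx), -sp_.N_A)
    g0 = 0.5 * (geom.body_width - geom.gate_length)
    well_src = mesh.x <= g0 + 1e-15
    well_drn = mesh.x >= geom.body_width - g0 - 1e-15
    shallow = mesh.y <= sp_.junction_depth + 1e-15
    C[np.ix_(shallow, well_src)] = sp_.N_D_contact - sp_.N_A
    C[np.ix_(shallow, well_drn)] = sp_.N_D_contact - sp_.N_A
    return C


def _bernoulli(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-5
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs**2 / 12.0
    xl = np.clip(x[~small], -500.0, 500.0)
    out[~small] = xl / np.expm1(xl)
    return out


def solve_dd(
    sp_: SemiconductorParams,
    geom: DeviceGeometry,
    bias: BiasPoint,
    gate_potential: float,
    mesh: Mesh2D | None = None,
    tol: float = 1e-9,
    max_gummel: int = 300,
    _warm: DDState | None = None,
) -> DDState:
    """Self-consistent Poisson + drift-diffusion at one bias point.

    ``gate_potential`` is the potential phi_M imposed at the top of the gate
    oxide (by the electrolyte stack, or directly when exercising the bare
    MOSFET). Source and body are grounded; V_DS is applied at the drain.
    Bias ramping is handled internally for large steps.
    """
    if mesh is None:
        mesh = make_mesh(geom)
    if mesh.ny < 8:
        raise InvalidParameterError("mesh too coarse: need >= 8 nodes across the channel depth")

    Vt = thermal_voltage(sp_.T)
    ni = sp_.n_i
    eps = CONST.eps0 * sp_.eps_r_si
    q = CONST.q
    C_ox = geom.oxide.C_ox
    nx, ny = mesh.nx, mesh.ny
    N = nx * ny
    x, y = mesh.x, mesh.y
    dx = np.diff(x)
    dy = np.diff(y)
    wx = np.empty(nx)
    wx[0], wx[-1] = dx[0] / 2, dx[-1] / 2
    wx[1:-1] = 0.5 * (dx[:-1] + dx[1:])
    wy = np.empty(ny)
    wy[0], wy[-1] = dy[0] / 2, dy[-1] / 2
    wy[1:-1] = 0.5 * (dy[:-1] + dy[1:])

    C = _doping(mesh, sp_, geom)
    src, drn, gate = _contact_masks(mesh, geom)

    # ---- Dirichlet data -------------------------------------------------
    def contact_equilibrium(Cdop: float):
        """(n, p) at an ohmic contact from neutrality + mass action."""
        nc = 0.5 * (Cdop + np.sqrt(Cdop**2 + 4 * ni**2))
        return nc, ni**2 / nc

    dirichlet = np.zeros((ny, nx), dtype=bool)
    dirichlet[0, src] = True
    dirichlet[0, drn] = True
    dirichlet[-1, :] = True  # body contact

    def dirichlet_values(v_source: float, v_drain: float, v_body: float):
        Vd = np.zeros((ny, nx))
        nd = np.zeros((ny, nx))
        pd = np.zeros((ny, nx))
        n_sd, p_sd = contact_equilibrium(sp_.N_D_contact - sp_.N_A)
        n_b, p_b = contact_equilibrium(-sp_.N_A)
        Vd[0, src] = v_source + Vt * np.log(n_sd / ni)
        nd[0, src], pd[0, src] = n_sd, p_sd
        Vd[0, drn] = v_drain + Vt * np.log(n_sd / ni)
        nd[0, drn], pd[0, drn] = n_sd, p_sd
        Vd[-1, :] = v_body - Vt * np.log(p_b / ni)
        nd[-1, :], pd[-1, :] = n_b, p_b
        return Vd, nd, pd

    # ---- assembly helpers ----------------------------------------------
    def laplacian_entries():
        """Geometric coefficients eps*A/d for the 4 face directions, plus the
        gate Robin contribution. Returns (rows, cols, base vals, diag extra)."""
        rows, cols, vals = [], [], []
        diag = np.zeros(N)

        def couple(k1, k2, gcoef):
            rows.extend([k1, k2, k1, k2])
            cols.extend([k2, k1, k1, k2])
            vals.extend([gcoef, gcoef, -gcoef, -gcoef])

        for j in range(ny):
            for i in range(nx - 1):
                gcoef = eps * wy[j] / dx[i]
                couple(mesh.index(i, j), mesh.index(i + 1, j), gcoef)
        for j in range(ny - 1):
            for i in range(nx):
                gcoef = eps * wx[i] / dy[j]
                couple(mesh.index(i, j), mesh.index(i, j + 1), gcoef)
        # thin-insulator gate: flux C_ox*(phi_M - V) over the gate window
        for i in np.where(gate)[0]:
            diag[mesh.index(i, 0)] -= C_ox * wx[i]
        return rows, cols, vals, diag

    lap_rows, lap_cols, lap_vals, gate_diag = laplacian_entries()
    vol = np.outer(wy, wx)  # cell areas (per unit out-of-plane width)
    gate_rhs = np.zeros(N)
    for i in np.where(gate)[0]:
        gate_rhs[mesh.index(i, 0)] = C_ox * wx[i]  # times phi_M

    dir_flat = dirichlet.ravel()

    def solve_nonlinear_poisson(V, Fn, Fp, Vdir, phi_M):
        """Newton on Poisson with frozen quasi-Fermi potentials."""
        Vf = V.ravel().copy()
        Vdirf = Vdir.ravel()
        Vf[dir_flat] = Vdirf[dir_flat]
        base = sp.coo_matrix((lap_vals, (lap_rows, lap_cols)), shape=(N, N)).tocsr()
        volf = vol.ravel()
        Cf = C.ravel()
        Fnf, Fpf = Fn.ravel(), Fp.ravel()
        for _ in range(100):
            nf = ni * np.exp(np.clip((Vf - Fnf) / Vt, -80, 80))
            pf = ni * np.exp(np.clip((Fpf - Vf) / Vt, -80, 80))
            R = base @ Vf + gate_diag * Vf + gate_rhs * phi_M + q * (pf - nf + Cf) * volf
            dRdV = gate_diag - q * (nf + pf) / Vt * volf
            A = base + sp.diags(dRdV)
            # impose Dirichlet rows
            R[dir_flat] = Vf[dir_flat] - Vdirf[dir_flat]
            A = A.tolil()
            for k in np.where(dir_flat)[0]:
                A.rows[k] = [k]
                A.data[k] = [1.0]
            dV = spla.spsolve(A.tocsr(), -R)
            clamp = 10.0 * Vt
            dV = clamp * np.tanh(dV / clamp)
            Vf += dV
            if np.max(np.abs(dV)) < 1e-12:
                break
        return Vf.reshape(ny, nx)

    def face_coefficients(V, carrier):
        """SG conductances for the linear continuity solve.

        carrier='n': equilibrium n ratio e^{+dV/Vt}; 'p': e^{-dV/Vt}.
        Returns per-face (coef_left_node, coef_right_node) for x and y faces.
        """
        sgn = -1.0 if carrier == "n" else 1.0
        D = (sp_.mu_n if carrier == "n" else sp_.mu_p) * Vt
        dux = sgn * np.diff(V, axis=1) / Vt  # (ny, nx-1)
        duy = sgn * np.diff(V, axis=0) / Vt  # (ny-1, nx)
        # particle flux L->R = (D/d)*(B(du)*c_L - B(-du)*c_R)
        cxL = D / dx[None, :] * _bernoulli(dux) * wy[:, None]
        cxR = D / dx[None, :] * _bernoulli(-dux) * wy[:, None]
        cyL = D / dy[:, None] * _bernoulli(duy) * wx[None, :]
        cyR = D / dy[:, None] * _bernoulli(-duy) * wx[None, :]
        return cxL, cxR, cyL, cyR

    def solve_continuity(V, carrier, cdir):
        """Zero-divergence SG continuity solve with Dirichlet contacts."""
        cxL, cxR, cyL, cyR = face_coefficients(V, carrier)
        rows, cols, vals = [], [], []
        b = np.zeros(N)

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        for j in range(ny):
            for i in range(nx - 1):
                kL, kR = mesh.index(i, j), mesh.index(i + 1, j)
                # net outflux appears in each node's balance
                add(kL, kL, cxL[j, i])
                add(kL, kR, -cxR[j, i])
                add(kR, kL, -cxL[j, i])
                add(kR, kR, cxR[j, i])
        for j in range(ny - 1):
            for i in range(nx):
                kL, kR = mesh.index(i, j), mesh.index(i, j + 1)
                add(kL, kL, cyL[j, i])
                add(kL, kR, -cyR[j, i])
                add(kR, kL, -cyL[j, i])
                add(kR, kR, cyR[j, i])
        A = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tolil()
        cdirf = cdir.ravel()
        for k in np.where(dir_flat)[0]:
            A.rows[k] = [k]
            A.data[k] = [1.0]
            b[k] = cdirf[k]
        c = spla.spsolve(A.tocsr(), b)
        return np.maximum(c, 1e-30).reshape(ny, nx), (cxL, cxR, cyL, cyR)

    def contact_currents(n, p, coef_n, coef_p):
        """Terminal currents by summing SG fluxes into each contact node."""
        def particle_influx(c, cxL, cxR, cyL, cyR, mask2d):
            influx = np.zeros((ny, nx))
            fx = cxL * c[:, :-1] - cxR * c[:, 1:]  # particle flux L->R
            fy = cyL * c[:-1, :] - cyR * c[1:, :]
            influx[:, 1:] += fx
            influx[:, :-1] -= fx
            influx[1:, :] += fy
            influx[:-1, :] -= fy
            return float(influx[mask2d].sum())

        masks = {}
        m_src = np.zeros((ny, nx), dtype=bool)
        m_src[0, src] = True
        m_drn = np.zeros((ny, nx), dtype=bool)
        m_drn[0, drn] = True
        m_body = np.zeros((ny, nx), dtype=bool)
        m_body[-1, :] = True
        out = {}
        for name, m in (("source", m_src), ("drain", m_drn), ("body", m_body)):
            fn = particle_influx(n, *coef_n, m)
            fp = particle_influx(p, *coef_p, m)
            # electron influx carries charge -q into the contact; terminal
            # current defined positive flowing from contact into the device
            out[name] = geom.W * q * (fn - fp)
        return out

    # ---- Gummel loop with internal bias ramping -------------------------
    def gummel(v_drain, phi_M, V, Fn, Fp, max_iter, tol_):
        """Converges on the potential update. Quasi-Fermi levels recovered
        from the continuity solves are clamped to the contact range (their
        physical bounds in steady state without generation), which keeps
        linear-solver noise in carrier-starved regions out of the loop."""
        Vdir, ndir, pdir = dirichlet_values(0.0, v_drain, 0.0)
        f_lo, f_hi = min(0.0, v_drain), max(0.0, v_drain)
        history = []
        n = p = coef_n = coef_p = None
        for it in range(max_iter):
            V_new = solve_nonlinear_poisson(V, Fn, Fp, Vdir, phi_M)
            dV = float(np.max(np.abs(V_new - V)))
            V = V_new
            n, coef_n = solve_continuity(V, "n", ndir)
            p, coef_p = solve_continuity(V, "p", pdir)
            Fn = np.clip(V - Vt * np.log(n / ni), f_lo, f_hi)
            Fp = np.clip(V + Vt * np.log(p / ni), f_lo, f_hi)
            history.append(dV)
            if dV < tol_:
                # report carrier fields consistent with the converged
                # potential and clamped quasi-Fermi levels (exact Boltzmann
                # at equilibrium); raw solves stay behind the currents
                n_rep = ni * np.exp(np.clip((V - Fn) / Vt, -200, 200))
                p_rep = ni * np.exp(np.clip((Fp - V) / Vt, -200, 200))
                return V, n_rep, p_rep, n, p, Fn, Fp, coef_n, coef_p, history
        raise GummelConvergenceError(
            f"Gummel iteration did not converge (last update {history[-1]:.3e} V)", history
        )

    # start from charge-neutral potential at zero bias, ramp V_DS and phi_M
    if _warm is not None:
        V = _warm.V.copy()
        Fn = V - Vt * np.log(_warm.n / ni)
        Fp = V + Vt * np.log(_warm.p / ni)
        start_vd, start_pg = _warm.bias.V_DS, _warm.gate_potential
    else:
        V = Vt * np.arcsinh(C / (2.0 * ni))
        Fn = np.zeros_like(V)
        Fp = np.zeros_like(V)
        start_vd, start_pg = 0.0, 0.0

    target_vd, target_pg = bias.V_DS, gate_potential
    n_ramp = max(
        1,
        int(np.ceil(abs(target_vd - start_vd) / 0.25)),
        int(np.ceil(abs(target_pg - start_pg) / 0.5)),
    )
    total_iters = 0
    for s in range(1, n_ramp + 1):
        f = s / n_ramp
        vd = start_vd + f * (target_vd - start_vd)
        pg = start_pg + f * (target_pg - start_pg)
        last = s == n_ramp
        V, n, p, n_raw, p_raw, Fn, Fp, coef_n, coef_p, hist = gummel(
            vd, pg, V, Fn, Fp, max_gummel, tol if last else max(tol, 1e-7)
        )
        total_iters += len(hist)

    cur = contact_currents(n_raw, p_raw, coef_n, coef_p)
    return DDState(
        mesh=mesh,
        V=V,
        n=n,
        p=p,
        I_source=cur["source"],
        I_drain=cur["drain"],
        I_body=cur["body"],
        iterations=total_iters,
        residual=hist[-1],
        bias=bias,
        gate_potential=gate_potential,
    )


# --------------------------------------------------------------------------
# Threshold extraction
# --------------------------------------------------------------------------


def extract_vth_curve(v_gs: np.ndarray, i_ds: np.ndarray, v_ds: float) -> float:
    """Threshold by maximum-transconductance extrapolation.

    At the maximum-gm point, extrapolate the transfer curve linearly to zero
    current and subtract V_DS/2 (the triode intercept sits at V_TH + V_DS/2).
    """
    v_gs = np.asarray(v_gs, dtype=float)
    i_ds = np.asarray(i_ds, dtype=float)
    if v_gs.size < 3:
        raise ExtractionError("need at least 3 sweep points")
    if np.all(i_ds <= 0) or np.max(i_ds) < 1e-300:
        raise ExtractionError("flat transfer curve: nothing to extract")
    conducting = i_ds > 1e-3 * i_ds.max()
    if np.any(np.diff(i_ds[conducting]) < 0):
        raise ExtractionError("non-monotone transfer curve")
    gm = np.gradient(i_ds, v_gs)
    k = int(np.argmax(gm))
    if gm[k] <= 0:
        raise ExtractionError("non-positive transconductance")
    v_int = v_gs[k] - i_ds[k] / gm[k]
    return float(v_int - v_ds / 2.0)


def extract_vth_dd(
    sp_: SemiconductorParams,
    geom: DeviceGeometry,
    v_gs_sweep: np.ndarray,
    v_ds: float = 0.05,
    mesh: Mesh2D | None = None,
    gate_offset: float = 0.0,
) -> float:
    """Run the DD model over a V_GS sweep at small V_DS and extract V_TH.

    ``gate_offset`` shifts the gate potential relative to V_GS (the flat-band
    ladder of the full ISFET stack); a +x offset shifts the extracted V_TH
    by -x.
    """
    if mesh is None:
        mesh = make_mesh(geom)
    ids = []
    warm = None
    for vg in v_gs_sweep:
        st = solve_dd(
            sp_, geom, BiasPoint(V_GS=float(vg), V_DS=v_ds), float(vg) + gate_offset,
            mesh=mesh, _warm=warm,
        )
        warm = st
        ids.append(abs(st.I_drain))
    return extract_vth_curve(np.asarray(v_gs_sweep), np.asarray(ids), v_ds)
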