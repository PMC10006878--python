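"""Steady-state 1D Poisson-Nernst-Planck solver for the electric double layer.

The electrolyte is resolved along the device's vertical axis above the gate:
y = 0 at the outer Helmholtz plane (OHP), y = L_bulk at the bulk boundary.
The Stern gap below the OHP is not meshed; it is the lumped capacitor handled
by the surface-chemistry layer. Lateral uniformity over the gate is assumed
(gate width is orders of magnitude larger than the Debye length).

Discretization: finite volume with exponential-fitting (Scharfetter-Gummel)
fluxes for the Nernst-Planck equation, damped Newton on the fully coupled
system. With a blocking surface the steady state is the Poisson-Boltzmann
double layer, so the Grahame equation serves as the analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .physchem import (
    CONST,
    Constants,
    ElectrolyteComposition,
    InvalidParameterError,
    debye_length,
    thermal_voltage,
)


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float] | None = None):
        super().__init__(message)
        self.residual_history = residual_history or []


class UnsupportedCompositionError(ValueError):
    """Closed form requested for a composition it does not cover."""


# --------------------------------------------------------------------------
# Grid
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid1D:
    """Strictly increasing node coordinates, geometrically refined near y=0."""

    y: np.ndarray  # m

    def __post_init__(self) -> None:
        if np.any(np.diff(self.y) <= 0):
            raise InvalidParameterError("grid coordinates must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return self.y.size

    @property
    def L_bulk(self) -> float:
        return float(self.y[-1])


def make_grid(
    comp: ElectrolyteComposition,
    n_nodes: int = 201,
    L_over_debye: float = 30.0,
    first_cell_over_debye: float = 0.02,
) -> Grid1D:
    """Auto-sized grid: length >= 30 Debye lengths, geometric stretching from
    a first cell of ~lambda_D/50 at the OHP."""
    if L_over_debye < 30.0:
        L_over_debye = 30.0
    lam = debye_length(comp)
    L = L_over_debye * lam
    h0 = first_cell_over_debye * lam
    n_int = n_nodes - 1
    # geometric ratio r with h0*(r^n - 1)/(r - 1) = L
    from scipy.optimize import brentq

    def total(r: float) -> float:
        return h0 * (r**n_int - 1.0) / (r - 1.0) - L

    if h0 * n_int >= L:  # uniform already long enough
        r = 1.0
        y = np.linspace(0.0, h0 * n_int, n_nodes)
    else:
        r = brentq(total, 1.0 + 1e-12, 2.0, xtol=1e-14)
        h = h0 * r ** np.arange(n_int)
        y = np.concatenate([[0.0], np.cumsum(h)])
    return Grid1D(y=y)


def refine(grid: Grid1D) -> Grid1D:
    """Halve every interval (nested refinement, for convergence studies)."""
    y = grid.y
    mid = 0.5 * (y[:-1] + y[1:])
    return Grid1D(y=np.sort(np.concatenate([y, mid])))


# --------------------------------------------------------------------------
# Boundary condition and state containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceBC:
    """Surface boundary at the OHP: either a fixed charge density sigma0
    (C/m^2, the charge on the electrode side) or a fixed potential phi_OHP
    (V, relative to the bulk electrolyte potential)."""

    mode: str  # "fixed_charge" | "fixed_potential"
    sigma0: float | None = None
    phi_OHP: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed_charge":
            if self.sigma0 is None or self.phi_OHP is not None:
                raise InvalidParameterError("fixed_charge mode requires sigma0 only")
        elif self.mode == "fixed_potential":
            if self.phi_OHP is None or self.sigma0 is not None:
                raise InvalidParameterError("fixed_potential mode requires phi_OHP only")
        else:
            raise InvalidParameterError(f"unknown SurfaceBC mode {self.mode!r}")


@dataclass
class ElectrolyteState:
    """Converged double-layer solution on a grid."""

    grid: Grid1D
    comp: ElectrolyteComposition
    bc: SurfaceBC
    phi_l: np.ndarray  # V, per node (includes phi_bulk offset)
    conc: np.ndarray  # mol/m^3, shape (n_species, n_nodes)
    J: np.ndarray  # mol/(m^2 s), shape (n_species, n_nodes-1), face fluxes
    phi_bulk: float
    iterations: int
    residual: float

    @property
    def sigma_diffuse(self) -> float:
        """Integrated space charge of the diffuse layer (C/m^2)."""
        dV = _cell_volumes(self.grid.y)
        z = np.array([s.z for s in self.comp.species], dtype=float)
        rho = CONST.F * (z[:, None] * self.conc).sum(axis=0)  # C/m^3
        return float((rho * dV).sum())

    @property
    def psi_OHP(self) -> float:
        """Potential at y=0 relative to bulk (V)."""
        return float(self.phi_l[0] - self.phi_bulk)

    def to_frame(self):
        """Profile as a DataFrame (y_m, phi_l_V, c_<name>_molm3 ...)."""
        import pandas as pd

        data = {"y_m": self.grid.y, "phi_l_V": self.phi_l}
        for i, spc in enumerate(self.comp.species):
            data[f"c_{spc.name}_molm3"] = self.conc[i]
        return pd.DataFrame(data)


def _cell_volumes(y: np.ndarray) -> np.ndarray:
    h = np.diff(y)
    dV = np.empty_like(y)
    dV[0] = 0.5 * h[0]
    dV[-1] = 0.5 * h[-1]
    dV[1:-1] = 0.5 * (h[:-1] + h[1:])
    return dV


# --------------------------------------------------------------------------
# Bernoulli function (exponential fitting)
# --------------------------------------------------------------------------


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x/(e^x - 1), series-stabilized near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-5
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs**2 / 12.0
    xl = x[~small]
    out[~small] = xl / np.expm1(xl)
    return out


def _bernoulli_prime(x: np.ndarray) -> np.ndarray:
    """dB/dx, stabilized near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-5
    xs = x[small]
    out[small] = -0.5 + xs / 6.0 - xs**3 / 180.0
    xl = x[~small]
    em = np.expm1(xl)
    out[~small] = (em - xl * np.exp(xl)) / em**2
    return out


# --------------------------------------------------------------------------
# Analytic references (Gouy-Chapman-Stern)
# --------------------------------------------------------------------------


def gouy_chapman_sigma(
    psi: float, c: float, comp: ElectrolyteComposition, const: Constants = CONST
) -> float:
    """Grahame equation: electrode charge supporting diffuse-layer potential psi.

    sigma = sqrt(8 eps0 eps_r k T N_Av c) * sinh(q psi / (2 k T)), valid for a
    symmetric 1:1 electrolyte with total cation (= anion) concentration c.
    """
    if any(abs(s.z) != 1 for s in comp.species):
        raise UnsupportedCompositionError("Grahame closed form requires a 1:1 electrolyte")
    if c < 0:
        raise InvalidParameterError("concentration must be >= 0")
    pref = np.sqrt(8.0 * const.eps0 * comp.eps_r * const.k * comp.T * const.N_Av * c)
    return float(pref * np.sinh(psi / (2.0 * thermal_voltage(comp.T, const))))


def _gouy_chapman_psi_guess(sigma: float, c: float, comp: ElectrolyteComposition) -> float:
    """Inverse Grahame (initial guess for fixed-charge solves)."""
    pref = np.sqrt(8.0 * CONST.eps0 * comp.eps_r * CONST.k * comp.T * CONST.N_Av * max(c, 1e-12))
    return float(2.0 * thermal_voltage(comp.T) * np.arcsinh(sigma / pref))


# --------------------------------------------------------------------------
# The coupled PNP solve
# --------------------------------------------------------------------------


def solve_pnp(
    comp: ElectrolyteComposition,
    bc: SurfaceBC,
    grid: Grid1D | None = None,
    phi_bulk: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ElectrolyteState:
    """Solve steady-state Poisson + Nernst-Planck with a blocking surface.

    Unknowns are the electrolyte potential and the four ionic concentrations
    per node. Fluxes use Scharfetter-Gummel exponential fitting; the coupled
    nonlinear system is solved by damped Newton (steps shortened to keep
    concentrations positive). With zero normal flux at the OHP the converged
    state satisfies the Boltzmann relation to discretization error.
    """
    if grid is None:
        grid = make_grid(comp)
    lam = debye_length(comp)
    if grid.L_bulk < 30.0 * lam - 1e-15:
        raise InvalidParameterError("grid must extend to at least 30 Debye lengths")

    y = grid.y
    N = y.size
    h = np.diff(y)
    dV = _cell_volumes(y)
    ns = len(comp.species)
    z = np.array([s.z for s in comp.species], dtype=float)
    D = np.array([s.D for s in comp.species], dtype=float)
    cb = np.array(comp.bulk_conc, dtype=float)
    Vt = thermal_voltage(comp.T)
    eps = CONST.eps0 * comp.eps_r
    F = CONST.F

    # ---- initial guess: Gouy-Chapman profile + Boltzmann concentrations
    c_tot_pos = float(cb[z > 0].sum())
    if bc.mode == "fixed_potential":
        psi0 = float(bc.phi_OHP)
    else:
        psi0 = _gouy_chapman_psi_guess(float(bc.sigma0), c_tot_pos, comp)
    g = np.tanh(psi0 / (4.0 * Vt)) * np.exp(-y / lam)
    phi = 4.0 * Vt * np.arctanh(np.clip(g, -0.999999, 0.999999))
    conc = cb[:, None] * np.exp(-z[:, None] * phi[None, :] / Vt)
    conc = np.maximum(conc, 1e-300)

    # unknown ordering: [phi(0..N-1), c_0(0..N-1), ..., c_{ns-1}(0..N-1)]
    def pack(phi, conc):
        return np.concatenate([phi] + [conc[i] for i in range(ns)])

    def unpack(x):
        return x[:N], np.stack([x[(i + 1) * N : (i + 2) * N] for i in range(ns)])

    # residual scales (for the convergence test)
    scale_phi = max(eps * Vt / max(lam, 1e-12), 1e-30)  # ~ C/m^2 scale
    scale_c = np.maximum(D * cb.max() / max(lam, 1e-12), 1e-30)  # flux scale

    def residual(phi, conc):
        R = np.zeros((ns + 1) * N)
        flux_e = -eps * np.diff(phi) / h  # -eps dphi/dy at faces
        rho = F * (z[:, None] * conc).sum(axis=0)
        # Poisson interior
        R[1 : N - 1] = (flux_e[1:] - flux_e[:-1]) - rho[1:-1] * dV[1:-1]
        if bc.mode == "fixed_potential":
            R[0] = phi[0] - (bc.phi_OHP)
        else:
            R[0] = flux_e[0] - bc.sigma0 - rho[0] * dV[0]
        R[N - 1] = phi[N - 1] - 0.0
        du = np.diff(phi) / Vt  # per-face, multiply by z per species
        for i in range(ns):
            xi = z[i] * du
            Bp = _bernoulli(xi)
            Bm = _bernoulli(-xi)
            J = (D[i] / h) * (Bp * conc[i, :-1] - Bm * conc[i, 1:])
            base = (i + 1) * N
            R[base] = J[0]  # blocking surface: zero flux into the OHP
            R[base + 1 : base + N - 1] = J[1:] - J[:-1]
            R[base + N - 1] = conc[i, -1] - cb[i]
        return R

    def jacobian(phi, conc):
        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        # Poisson rows
        for j in range(1, N - 1):
            add(j, j - 1, -eps / h[j - 1])
            add(j, j, eps / h[j - 1] + eps / h[j])
            add(j, j + 1, -eps / h[j])
            for i in range(ns):
                add(j, (i + 1) * N + j, -F * z[i] * dV[j])
        if bc.mode == "fixed_potential":
            add(0, 0, 1.0)
        else:
            add(0, 0, eps / h[0])
            add(0, 1, -eps / h[0])
            for i in range(ns):
                add(0, (i + 1) * N, -F * z[i] * dV[0])
        add(N - 1, N - 1, 1.0)

        du = np.diff(phi) / Vt
        for i in range(ns):
            xi = z[i] * du
            Bp = _bernoulli(xi)
            Bm = _bernoulli(-xi)
            Bpp = _bernoulli_prime(xi)
            Bmp = _bernoulli_prime(-xi)
            base = (i + 1) * N
            cf = D[i] / h
            # J[f] = cf[f]*(Bp[f]*c[f] - Bm[f]*c[f+1]); dxi/dphi[f+1] = z/Vt
            dJ_dcL = cf * Bp
            dJ_dcR = -cf * Bm
            dJ_dxi = cf * (Bpp * conc[i, :-1] + Bmp * conc[i, 1:])
            dJ_dphiR = dJ_dxi * (z[i] / Vt)
            dJ_dphiL = -dJ_dphiR
            # node 0: R = J[0]
            add(base, base, dJ_dcL[0])
            add(base, base + 1, dJ_dcR[0])
            add(base, 0, dJ_dphiL[0])
            add(base, 1, dJ_dphiR[0])
            # interior: R[j] = J[j] - J[j-1]
            for j in range(1, N - 1):
                add(base + j, base + j - 1, -dJ_dcL[j - 1])
                add(base + j, base + j, dJ_dcL[j] - dJ_dcR[j - 1])
                add(base + j, base + j + 1, dJ_dcR[j])
                add(base + j, j - 1, -dJ_dphiL[j - 1])
                add(base + j, j, dJ_dphiL[j] - dJ_dphiR[j - 1])
                add(base + j, j + 1, dJ_dphiR[j])
            add(base + N - 1, base + N - 1, 1.0)
        A = sp.coo_matrix((vals, (rows, cols)), shape=((ns + 1) * N, (ns + 1) * N))
        return A.tocsr()

    def scaled_norm(R):
        parts = [np.max(np.abs(R[:N])) / scale_phi]
        for i in range(ns):
            parts.append(np.max(np.abs(R[(i + 1) * N : (i + 2) * N])) / scale_c[i])
        return max(parts)

    history: list[float] = []
    for it in range(max_iter):
        R = residual(phi, conc)
        rn = scaled_norm(R)
        history.append(rn)
        if rn < tol:
            break
        A = jacobian(phi, conc)
        dx = spla.spsolve(A, -R)
        dphi, dconc = unpack(dx)
        # damping: keep concentrations strictly positive
        alpha = 1.0
        neg = dconc < 0
        if np.any(neg):
            lim = np.min(np.where(neg, -conc / np.where(neg, dconc, -1.0), np.inf))
            alpha = min(1.0, 0.9 * lim)
        if alpha < 1e-8:
            raise ConvergenceError("damping floor reached (negative concentrations)", history)
        phi = phi + alpha * dphi
        conc = conc + alpha * dconc
    else:
        raise ConvergenceError(
            f"PNP Newton did not converge in {max_iter} iterations (residual {history[-1]:.3e})",
            history,
        )

    # face fluxes at solution (should vanish for a blocking surface)
    du = np.diff(phi) / Vt
    J = np.empty((ns, N - 1))
    for i in range(ns):
        xi = z[i] * du
        J[i] = (D[i] / h) * (_bernoulli(xi) * conc[i, :-1] - _bernoulli(-xi) * conc[i, 1:])

    return ElectrolyteState(
        grid=grid,
        comp=comp,
        bc=bc,
        phi_l=phi + phi_bulk,
        conc=conc,
        J=J,
        phi_bulk=phi_bulk,
        iterations=len(history),
        residual=history[-1],
    )


def double_layer_capacitance(
    state: ElectrolyteState, C_st: float, dpsi: float = 1e-3
) -> float:
    """Series combination of the Stern capacitance and the numerically
    differentiated diffuse-layer capacitance around the state's OHP potential.

    C_diff = d sigma_electrode / d psi_OHP by central difference; the result
    is 1/(1/C_st + 1/C_diff) and is below both."""
    psi = state.psi_OHP
    sig = []
    for p in (psi + dpsi, psi - dpsi):
        st = solve_pnp(state.comp, SurfaceBC(mode="fixed_potential", phi_OHP=p), state.grid)
        sig.append(-st.sigma_diffuse)  # electrode charge = -diffuse charge
    C_diff = abs((sig[0] - sig[1]) / (2.0 * dpsi))
    if np.isinf(C_st):
        return C_diff
    if np.isinf(C_diff):
        return C_st
    return 1.0 / (1.0 / C_st + 1.0 / C_diff)
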