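"""End-to-end sensor assembly: membrane -> surface chemistry -> transistor.

The chain converts a sweat chloride concentration c0 into a drain current:
the ion-selective membrane partitions the sample onto the gate, the
site-binding/double-layer solve yields the surface potential psi0, psi0 sets
the ISFET threshold voltage, and the transistor (compact square law by
default, drift-diffusion on request) turns the threshold shift into current.

Sign convention: chloride adsorption drives psi0 more negative and the
threshold voltage up. The readout uses a p-channel-style overdrive
V_GS + V_TH (with V_TH < 0 at the operating point), so the saturation
current rises with chloride concentration — the response direction of the
modeled sensor. Everything is deterministic; repeated runs are bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .physchem import (
    ElectrolyteComposition,
    InvalidParameterError,
    composition_from_ph_and_chloride,
)
from .ism import MembraneSpec, default_membrane, net_charge_diagnostic, partition
from .surface_chemistry import (
    ElectrodeModel,
    SiteBindingParams,
    solve_surface_state,
)
from . import semiconductor as semi
from .semiconductor import (
    BiasPoint,
    DeviceGeometry,
    OxideSpec,
    SemiconductorParams,
    ids_compact,
    make_threshold_params,
    threshold_voltage,
)

#: NaCl level above which sweat chloride is considered diagnostic for
#: cystic fibrosis (mol/m^3).
CLINICAL_THRESHOLD = 70.0

#: Default bias of all device-level experiments.
DEFAULT_BIAS = BiasPoint(V_GS=1.6, V_DS=1.44)

#: Literature relative permittivities of the studied high-k gate insulators.
OXIDE_MATERIALS: dict[str, float] = {
    "SiO2": 3.9,
    "Al2O3": 9.0,
    "HfSiO4": 11.0,
    "ZrSiO4": 12.6,
    "Y2O3": 15.0,
    "Ta2O5": 22.0,
    "HfO2": 25.0,
    "La2O3": 30.0,
    "TiO2": 80.0,
}


class NonResponsiveDeviceError(RuntimeError):
    """Measured sensitivity is not positive."""


class CalibrationError(RuntimeError):
    """No parameter set within bounds reached the anchors; carries the best fit."""

    def __init__(self, message: str, best_params: dict, best_residual: float):
        super().__init__(message)
        self.best_params = best_params
        self.best_residual = best_residual


class ChainError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class SensorAssembly:
    """The composed sensor. ``composition`` is the sample-side template whose
    pH/temperature are kept while c0 is swept."""

    composition: ElectrolyteComposition = field(
        default_factory=lambda: composition_from_ph_and_chloride(80.0)
    )
    membrane: MembraneSpec = field(default_factory=default_membrane)
    chemistry: SiteBindingParams = field(default_factory=SiteBindingParams)
    electrode: ElectrodeModel = field(default_factory=ElectrodeModel)
    semiconductor: SemiconductorParams = field(default_factory=SemiconductorParams)
    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    model_level: str = "compact"  # "compact" | "dd"
    polarity: str = "p"
    coupling: str = "analytic_GCS"
    v_cal: float = -2.73
    phi_si: float = 4.05

    def __post_init__(self) -> None:
        if self.model_level not in ("compact", "dd"):
            raise InvalidParameterError(f"unknown model_level {self.model_level!r}")

    def threshold_params(self) -> semi.ThresholdParams:
        return make_threshold_params(
            self.semiconductor,
            self.geometry.oxide,
            E_ref=self.electrode.E_ref,
            chi_sol=self.electrode.chi_sol,
            phi_si=self.phi_si,
            v_cal=self.v_cal,
        )


@dataclass(frozen=True)
class ChainResult:
    psi0: float
    V_TH: float
    I_DS: float
    downside_net_charge: float  # membrane electroneutrality diagnostic (mol/m^3)


@dataclass
class SweepResult:
    """Tabulated sweep with the derived per-point quantities."""

    axis_name: str
    axis_values: np.ndarray
    I_DS: np.ndarray
    psi0: np.ndarray
    V_TH: np.ndarray
    metadata: dict

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                self.axis_name: self.axis_values,
                "I_DS_A": self.I_DS,
                "psi0_V": self.psi0,
                "V_TH_V": self.V_TH,
            }
        )
        if self.axis_name == "c0_molm3":
            df["above_clinical_threshold"] = self.axis_values > CLINICAL_THRESHOLD
        return df

    @property
    def determinism_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.axis_values, self.I_DS, self.psi0, self.V_TH):
            h.update(np.asarray(arr, dtype=float).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class SensitivityReport:
    """Sensitivity, current swing and resolution at one operating point.

    resolution * S == min_delta_I holds exactly by construction.
    """

    S: float  # dI_DS/dc0 (A m^3/mol), central difference
    delta_I: float  # current change over `interval` (A)
    resolution: float  # min detectable concentration change (mol/m^3)
    min_delta_I: float  # minimum detectable current change (A)
    c0: float
    fd_step: float
    interval: tuple[float, float]


def _reclose_neutrality(comp: ElectrolyteComposition) -> ElectrolyteComposition:
    """Re-impose bulk electroneutrality after the membrane by adjusting the
    Na+ counter-ion (the diffuse-layer models require a neutral bath)."""
    z_na = comp.species_by_name("Na").z
    residual = sum(
        s.z * c for s, c in zip(comp.species, comp.bulk_conc) if s.name != "Na"
    )
    c_na = -residual / z_na
    if c_na < 0:
        c_na = 0.0
    out = comp.with_conc("Na", c_na)
    c_h = out.conc("H")
    return replace(out, pH=float(3.0 - np.log10(c_h)) if c_h > 0 else out.pH)


@lru_cache(maxsize=8)
def _vth_dd_reference(sp_: SemiconductorParams, geom: DeviceGeometry) -> float:
    """Intrinsic DD threshold of the bare MOSFET (cached; used to translate
    the chemistry's threshold shift onto the DD gate)."""
    vgs = np.arange(0.3, 1.21, 0.1)
    return semi.extract_vth_dd(sp_, geom, vgs, v_ds=0.05)


def run_chain(
    assembly: SensorAssembly, c0: float, bias: BiasPoint = DEFAULT_BIAS
) -> ChainResult:
    """Full pipeline at one chloride concentration: partition -> surface
    state -> threshold -> drain current."""
    base = assembly.composition
    try:
        sample = composition_from_ph_and_chloride(
            c0, pH=base.pH, eps_r=base.eps_r, T=base.T
        )
    except Exception as e:
        raise ChainError("composition", e) from e
    try:
        down_raw = partition(sample, assembly.membrane)
        diag = net_charge_diagnostic(down_raw)
        down = _reclose_neutrality(down_raw)
    except Exception as e:
        raise ChainError("ism", e) from e
    try:
        surf = solve_surface_state(
            down, assembly.chemistry, assembly.electrode, coupling=assembly.coupling
        )
    except Exception as e:
        raise ChainError("surface_chemistry", e) from e
    try:
        tp = assembly.threshold_params()
        vth = threshold_voltage(tp, surf.psi0)
        if assembly.model_level == "compact":
            ids = ids_compact(
                tp, assembly.semiconductor, assembly.geometry, bias, surf.psi0,
                polarity=assembly.polarity,
            )
        else:
            vth_dd = _vth_dd_reference(assembly.semiconductor, assembly.geometry)
            v_ov = bias.V_GS + vth if assembly.polarity == "p" else bias.V_GS - vth
            st = semi.solve_dd(
                assembly.semiconductor, assembly.geometry, bias, vth_dd + v_ov
            )
            ids = abs(st.I_drain)
    except Exception as e:
        raise ChainError("semiconductor", e) from e
    return ChainResult(psi0=surf.psi0, V_TH=vth, I_DS=ids, downside_net_charge=diag)


def concentration_sweep(
    assembly: SensorAssembly,
    c0_values,
    bias: BiasPoint = DEFAULT_BIAS,
) -> SweepResult:
    """I_DS, psi0, V_TH over a chloride sweep (stateless per point)."""
    c0_values = np.asarray(c0_values, dtype=float)
    if np.any(c0_values <= 0):
        raise InvalidParameterError("c0 values must be > 0")
    results = [run_chain(assembly, float(c), bias) for c in c0_values]
    sw = SweepResult(
        axis_name="c0_molm3",
        axis_values=c0_values,
        I_DS=np.array([r.I_DS for r in results]),
        psi0=np.array([r.psi0 for r in results]),
        V_TH=np.array([r.V_TH for r in results]),
        metadata={
            "bias": (bias.V_GS, bias.V_DS),
            "oxide": assembly.geometry.oxide.material,
            "model_level": assembly.model_level,
        },
    )
    sw.metadata["hash"] = sw.determinism_hash
    return sw


def resolution_from_sensitivity(S: float, min_delta_I: float) -> float:
    """Limit of detection in concentration: Delta c0 = min Delta I_DS / S."""
    if S <= 0:
        raise NonResponsiveDeviceError("sensitivity must be positive")
    if min_delta_I <= 0:
        raise InvalidParameterError("min_delta_I must be > 0")
    return min_delta_I / S


def sensitivity_report(
    assembly: SensorAssembly,
    c0: float = 80.0,
    bias: BiasPoint = DEFAULT_BIAS,
    min_delta_I: float = 0.5e-9,
    interval: tuple[float, float] = (50.0, 110.0),
    S_override: float | None = None,
) -> SensitivityReport:
    """Sensitivity S = dI_DS/dc0 by central difference and the derived
    concentration resolution min_delta_I / S.

    The finite-difference step is max(0.01 c0, 0.1 mol/m^3). ``S_override``
    evaluates the resolution arithmetic at an externally stated sensitivity
    (e.g. a published value) without re-simulating.
    """
    if min_delta_I <= 0:
        raise InvalidParameterError("min_delta_I must be > 0")
    step = max(0.01 * c0, 0.1)
    if S_override is not None:
        S = S_override
    else:
        hi = run_chain(assembly, c0 + step, bias).I_DS
        lo = run_chain(assembly, c0 - step, bias).I_DS
        S = (hi - lo) / (2.0 * step)
    if S <= 0:
        raise NonResponsiveDeviceError(f"sensitivity {S:.3e} A m^3/mol is not positive")
    delta_I = (
        run_chain(assembly, interval[1], bias).I_DS
        - run_chain(assembly, interval[0], bias).I_DS
    )
    return SensitivityReport(
        S=S,
        delta_I=delta_I,
        resolution=resolution_from_sensitivity(S, min_delta_I),
        min_delta_I=min_delta_I,
        c0=c0,
        fd_step=step,
        interval=interval,
    )


def oxide_study(
    assembly: SensorAssembly,
    materials,
    bias: BiasPoint = DEFAULT_BIAS,
    c0: float = 80.0,
) -> pd.DataFrame:
    """Per-material sensitivity table.

    ``materials`` is a list of OxideSpec or material names (resolved against
    the built-in permittivity table at the default 30 nm thickness).
    """
    if not materials:
        raise InvalidParameterError("material list must be non-empty")
    rows = []
    for m in materials:
        if isinstance(m, str):
            if m not in OXIDE_MATERIALS:
                raise InvalidParameterError(
                    f"unknown oxide {m!r} and no eps_ins override given"
                )
            ox = OxideSpec(material=m, eps_ins=OXIDE_MATERIALS[m])
        else:
            ox = m
        asm = replace(assembly, geometry=replace(assembly.geometry, oxide=ox))
        try:
            S = sensitivity_report(asm, c0=c0, bias=bias).S
        except NonResponsiveDeviceError:
            S = 0.0  # stack does not conduct at this bias/threshold
        rows.append(
            {
                "material": ox.material,
                "eps_ins": ox.eps_ins,
                "d_ins_m": ox.d_ins,
                "S_A_m3_per_mol": S,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration of the unprinted parameters
# ---------------------------------------------------------------------------

_CAL_BOUNDS = {
    "log10_K_c": (-4.0, 2.0),
    "log10_N_S": (16.0, 20.0),
    "v_cal": (-4.0, 0.0),
}


def calibrate(
    assembly: SensorAssembly,
    S_target: float | None = None,
    I_DS_anchor: tuple[float, float] | None = None,
    bias: BiasPoint = DEFAULT_BIAS,
    c0: float = 80.0,
    rtol: float = 0.05,
) -> SensorAssembly:
    """Fit {K_c, N_S, v_cal} so the simulated anchors match their targets.

    ``S_target`` anchors the chloride sensitivity at (c0, bias);
    ``I_DS_anchor = (I, c0_a)`` anchors the absolute current. Bounded
    least-squares from the assembly's current parameters (fixed start, no
    stochastic search -> deterministic). Raises CalibrationError with the
    best residual if no parameter set within bounds comes within ``rtol``.
    """
    if S_target is None and I_DS_anchor is None:
        raise InvalidParameterError("at least one anchor is required")
    for name, val in (("S_target", S_target), ("I_DS_anchor", I_DS_anchor)):
        if val is None:
            continue
        vals = val if isinstance(val, tuple) else (val,)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise InvalidParameterError(f"{name} must be finite and positive")

    x0 = np.array(
        [np.log10(assembly.chemistry.K_c) if assembly.chemistry.K_c > 0 else -4.0,
         np.log10(assembly.chemistry.N_S),
         assembly.v_cal]
    )
    lb = np.array([b[0] for b in _CAL_BOUNDS.values()])
    ub = np.array([b[1] for b in _CAL_BOUNDS.values()])
    x0 = np.clip(x0, lb, ub)

    def build(x) -> SensorAssembly:
        chem = replace(assembly.chemistry, K_c=10.0 ** x[0], N_S=10.0 ** x[1])
        return replace(assembly, chemistry=chem, v_cal=float(x[2]))

    def residuals(x):
        asm = build(x)
        out = []
        if S_target is not None:
            try:
                rep = sensitivity_report(asm, c0=c0, bias=bias)
                out.append(rep.S / S_target - 1.0)
            except NonResponsiveDeviceError:
                out.append(-1.0)
        if I_DS_anchor is not None:
            target, c0_a = I_DS_anchor
            out.append(run_chain(asm, c0_a, bias).I_DS / target - 1.0)
        return np.asarray(out)

    res = least_squares(
        residuals, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12,
        diff_step=1e-4,
    )
    best = residuals(res.x)
    if np.max(np.abs(best)) > rtol:
        raise CalibrationError(
            f"calibration missed anchors (worst relative residual {np.max(np.abs(best)):.3f})",
            best_params={"K_c": 10.0 ** res.x[0], "N_S": 10.0 ** res.x[1], "v_cal": res.x[2]},
            best_residual=float(np.max(np.abs(best))),
        )
    return build(res.x)
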