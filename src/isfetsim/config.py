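"""Configuration schema, YAML loading/dumping, and named fixtures.

The canonical config dialect is YAML. Every physical parameter of the
simulator is reachable through a nested block; unknown keys are rejected and
all values are validated against the same invariants the domain types
enforce. An empty file is a valid config (all defaults).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .physchem import (
    DEFAULT_DIFFUSIVITIES,
    ElectrolyteComposition,
    composition_from_ph_and_chloride,
)
from .ism import MembraneSpec
from .surface_chemistry import ElectrodeModel, SiteBindingParams
from .semiconductor import (
    BiasPoint,
    DeviceGeometry,
    OxideSpec,
    SemiconductorParams,
)
from .device import SensorAssembly

SCHEMA_VERSION = "1"


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesBlock(_Block):
    """Per-species overrides: diffusion coefficients (m^2/s) and the sodium
    charge number (z = +2 reproduces a divalent-sodium variant)."""

    D_H: float = Field(DEFAULT_DIFFUSIVITIES["H"], gt=0)
    D_OH: float = Field(DEFAULT_DIFFUSIVITIES["OH"], gt=0)
    D_Na: float = Field(DEFAULT_DIFFUSIVITIES["Na"], gt=0)
    D_Cl: float = Field(DEFAULT_DIFFUSIVITIES["Cl"], gt=0)
    z_Na: Literal[1, 2] = 1


class CompositionBlock(_Block):
    c_cl: float = Field(80.0, gt=0, description="bulk chloride (mol/m^3)")
    pH: float = Field(6.0, ge=0, le=14)
    eps_r: float = Field(78.5, ge=1)
    T: float = Field(298.15, gt=0)


class MembraneBlock(_Block):
    l_ism: float = Field(1.67e-6, gt=0)
    d_ism: float = Field(0.5e-6, gt=0)
    K_Cl: float = Field(1.0, ge=0, le=1)
    K_H: float = Field(0.05, ge=0, le=1)
    K_OH: float = Field(0.05, ge=0, le=1)
    K_Na: float = Field(0.05, ge=0, le=1)


class ChemistryBlock(_Block):
    N_S: float = Field(1.0e19, gt=0)
    K_a: float = Field(1.0e-5, ge=0)
    K_b: float = Field(1.0e-3, ge=0)
    K_c: float = Field(0.1, ge=0)
    C_st: float = Field(0.20, gt=0)


class ElectrodeBlock(_Block):
    V_ga: float = 1.6
    W_Ag: float = 4.6
    E_eq: float = 0.197
    E_ref: float = 4.797
    chi_sol: float = 0.05


class SemiconductorBlock(_Block):
    N_A: float = Field(1.0e23, gt=0)
    n_i: float = Field(1.0e16, gt=0)
    mu_n: float = Field(0.14, gt=0)
    mu_p: float = Field(0.045, gt=0)
    eps_r_si: float = Field(11.7, ge=1)
    T: float = Field(298.15, gt=0)
    N_c: float = Field(2.86e25, gt=0)
    N_v: float = Field(3.10e25, gt=0)
    E_c: float = 1.12
    E_v: float = 0.0
    N_D_contact: float = Field(1.0e26, gt=0)
    junction_depth: float = Field(0.15e-6, gt=0)


class OxideBlock(_Block):
    material: str = "HfO2"
    eps_ins: float = Field(25.0, ge=1)
    d_ins: float = Field(30e-9, gt=0)
    l_ins: float = Field(1.6e-6, gt=0)


class GeometryBlock(_Block):
    body_height: float = Field(0.7e-6, gt=0)
    body_width: float = Field(3.0e-6, gt=0)
    sd_length: float = Field(0.5e-6, gt=0)
    gate_length: float = Field(1.3e-6, gt=0)
    W: float = Field(1.0e-6, gt=0)
    L: float = Field(1.3e-6, gt=0)


class BiasBlock(_Block):
    V_GS: float = 1.6
    V_DS: float = 1.44


class ModelBlock(_Block):
    model_level: Literal["compact", "dd"] = "compact"
    polarity: Literal["n", "p"] = "p"
    coupling: Literal["analytic_GCS", "full_PNP"] = "analytic_GCS"
    v_cal: float = -2.73
    phi_si: float = 4.05


class SweepBlock(_Block):
    c0_values: list[float] = Field(default_factory=lambda: [50.0, 70.0, 90.0, 110.0])
    ph_values: list[float] = Field(default_factory=lambda: [4.0, 5.0, 6.0, 7.0, 8.0])
    v_ds_values: list[float] = Field(default_factory=lambda: [round(0.1 * i, 1) for i in range(0, 19)])
    min_delta_I: float = Field(0.5e-9, gt=0)

    @field_validator("c0_values")
    @classmethod
    def _positive_sorted(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("c0_values must be > 0")
        return sorted(v)


class SolverBlock(_Block):
    pnp_n_nodes: int = Field(201, ge=16)
    pnp_L_over_debye: float = Field(30.0, ge=30.0)
    dd_nx: int = Field(61, ge=16)
    dd_ny: int = Field(41, ge=8)


class RunConfig(_Block):
    """Top-level configuration; every block defaults to the standard device."""

    schema_version: str = SCHEMA_VERSION
    species: SpeciesBlock = Field(default_factory=SpeciesBlock)
    composition: CompositionBlock = Field(default_factory=CompositionBlock)
    membrane: MembraneBlock = Field(default_factory=MembraneBlock)
    chemistry: ChemistryBlock = Field(default_factory=ChemistryBlock)
    electrode: ElectrodeBlock = Field(default_factory=ElectrodeBlock)
    semiconductor: SemiconductorBlock = Field(default_factory=SemiconductorBlock)
    oxide: OxideBlock = Field(default_factory=OxideBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    bias: BiasBlock = Field(default_factory=BiasBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)


class ConfigError(ValueError):
    """Parse or validation failure; message names the offending key."""


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None or an empty file gives defaults."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"could not parse {p}: {e}") from e
    if raw is None:
        raw = {}
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        first = e.errors()[0]
        key = ".".join(str(x) for x in first["loc"])
        raise ConfigError(f"invalid config: {key}: {first['msg']}") from e


def dump_config(cfg: RunConfig) -> str:
    """Canonical YAML serialization; load(dump(x)) == x."""
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)


# ---------------------------------------------------------------------------
# Config -> domain objects
# ---------------------------------------------------------------------------


def build_composition(cfg: RunConfig) -> ElectrolyteComposition:
    comp = composition_from_ph_and_chloride(
        cfg.composition.c_cl,
        pH=cfg.composition.pH,
        eps_r=cfg.composition.eps_r,
        T=cfg.composition.T,
        na_charge=cfg.species.z_Na,
    )
    # apply diffusivity overrides
    from dataclasses import replace as _r

    d_over = {
        "H": cfg.species.D_H,
        "OH": cfg.species.D_OH,
        "Na": cfg.species.D_Na,
        "Cl": cfg.species.D_Cl,
    }
    species = tuple(_r(s, D=d_over[s.name]) for s in comp.species)
    return _r(comp, species=species)


def build_assembly(cfg: RunConfig) -> SensorAssembly:
    ox = OxideSpec(
        material=cfg.oxide.material,
        eps_ins=cfg.oxide.eps_ins,
        d_ins=cfg.oxide.d_ins,
        l_ins=cfg.oxide.l_ins,
    )
    geom = DeviceGeometry(
        body_height=cfg.geometry.body_height,
        body_width=cfg.geometry.body_width,
        sd_length=cfg.geometry.sd_length,
        gate_length=cfg.geometry.gate_length,
        W=cfg.geometry.W,
        L=cfg.geometry.L,
        oxide=ox,
    )
    return SensorAssembly(
        composition=build_composition(cfg),
        membrane=MembraneSpec(
            l_ism=cfg.membrane.l_ism,
            d_ism=cfg.membrane.d_ism,
            K_i={
                "Cl": cfg.membrane.K_Cl,
                "H": cfg.membrane.K_H,
                "OH": cfg.membrane.K_OH,
                "Na": cfg.membrane.K_Na,
            },
        ),
        chemistry=SiteBindingParams(
            N_S=cfg.chemistry.N_S,
            K_a=cfg.chemistry.K_a,
            K_b=cfg.chemistry.K_b,
            K_c=cfg.chemistry.K_c,
            C_st=cfg.chemistry.C_st,
        ),
        electrode=ElectrodeModel(
            V_ga=cfg.electrode.V_ga,
            W_Ag=cfg.electrode.W_Ag,
            E_eq=cfg.electrode.E_eq,
            E_ref=cfg.electrode.E_ref,
            chi_sol=cfg.electrode.chi_sol,
        ),
        semiconductor=SemiconductorParams(
            N_A=cfg.semiconductor.N_A,
            n_i=cfg.semiconductor.n_i,
            mu_n=cfg.semiconductor.mu_n,
            mu_p=cfg.semiconductor.mu_p,
            eps_r_si=cfg.semiconductor.eps_r_si,
            T=cfg.semiconductor.T,
            N_c=cfg.semiconductor.N_c,
            N_v=cfg.semiconductor.N_v,
            E_c=cfg.semiconductor.E_c,
            E_v=cfg.semiconductor.E_v,
            N_D_contact=cfg.semiconductor.N_D_contact,
            junction_depth=cfg.semiconductor.junction_depth,
        ),
        geometry=geom,
        model_level=cfg.model.model_level,
        polarity=cfg.model.polarity,
        coupling=cfg.model.coupling,
        v_cal=cfg.model.v_cal,
        phi_si=cfg.model.phi_si,
    )


def build_bias(cfg: RunConfig) -> BiasPoint:
    return BiasPoint(V_GS=cfg.bias.V_GS, V_DS=cfg.bias.V_DS)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("default_device", "paper_hfo2", "titration_suite")


def make_fixture(name: str) -> RunConfig:
    """Named configurations.

    paper_hfo2 — every number of the modeled sensor as published: geometry
    0.7/3/0.5/1.3 um, HfO2 stack (eps 25, 30 nm, 1.6 um), ISM 1.67/0.5 um,
    Stern capacitance 0.20 F/m^2, Ag work function 4.6 V, pH 6, bias
    (1.6 V, 1.44 V), chloride sweep {50, 70, 90, 110} mol/m^3.

    default_device — paper_hfo2 with the chemistry calibrated to the
    published sensitivity anchor (1.2e-7 A m^3/mol).

    titration_suite — chloride-blind chemistry (K_c = 0) for pH titrations.
    """
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    cfg = RunConfig()  # defaults are the published device values
    if name == "paper_hfo2":
        return cfg
    if name == "titration_suite":
        return validate_config({**cfg.model_dump(), "chemistry": {**cfg.chemistry.model_dump(), "K_c": 0.0}})
    # default_device: calibrate chemistry to the published sensitivity
    from .device import calibrate

    asm = calibrate(build_assembly(cfg), S_target=1.2e-7, bias=build_bias(cfg))
    raw = cfg.model_dump()
    raw["chemistry"]["K_c"] = float(asm.chemistry.K_c)
    raw["chemistry"]["N_S"] = float(asm.chemistry.N_S)
    raw["model"]["v_cal"] = float(asm.v_cal)
    return validate_config(raw)
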