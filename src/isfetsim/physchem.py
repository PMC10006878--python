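"""Physical constants, ion species registry, and closed-form electrolyte quantities.

Unit discipline throughout the package: concentrations in mol/m^3 (numerically
equal to mM), potentials in V, lengths in m, charge densities in C/m^2,
capacitances in F/m^2, temperatures in K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.constants as _sc


class InvalidParameterError(ValueError):
    """A physical parameter violates its precondition."""


@dataclass(frozen=True)
class Constants:
    """Fundamental constants (CODATA via scipy).

    q : elementary charge (C)
    k : Boltzmann constant (J/K)
    F : Faraday constant (C/mol)
    R : molar gas constant (J/(mol K))
    eps0 : vacuum permittivity (F/m)
    N_Av : Avogadro number (1/mol)
    """

    q: float = _sc.e
    k: float = _sc.k
    F: float = _sc.physical_constants["Faraday constant"][0]
    R: float = _sc.R
    eps0: float = _sc.epsilon_0
    N_Av: float = _sc.N_A


CONST = Constants()


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species: charge number and infinite-dilution diffusivity."""

    name: str
    z: int
    D: float  # m^2/s

    def __post_init__(self) -> None:
        if self.z not in (-2, -1, 1, 2):
            raise InvalidParameterError(f"{self.name}: charge number {self.z} not in {{-2,-1,+1,+2}}")
        if not self.D > 0:
            raise InvalidParameterError(f"{self.name}: diffusion coefficient must be > 0")


# Infinite-dilution diffusion coefficients at 25 degC (m^2/s), standard
# literature values; overridable through the config layer.
DEFAULT_DIFFUSIVITIES = {"H": 9.31e-9, "OH": 5.27e-9, "Na": 1.33e-9, "Cl": 2.03e-9}
DEFAULT_CHARGES = {"H": 1, "OH": -1, "Na": 1, "Cl": -1}


def default_species(na_charge: int = 1) -> list[IonSpecies]:
    """The four transported species: H+, OH-, Na+, Cl-.

    ``na_charge`` exists only to reproduce a divalent-sodium variant; the
    default is the physical z = +1.
    """
    charges = dict(DEFAULT_CHARGES, Na=na_charge)
    return [IonSpecies(n, charges[n], DEFAULT_DIFFUSIVITIES[n]) for n in ("H", "OH", "Na", "Cl")]


@dataclass(frozen=True)
class ElectrolyteComposition:
    """Bulk electrolyte: species list, concentrations (mol/m^3), pH, eps_r, T."""

    species: tuple[IonSpecies, ...]
    bulk_conc: tuple[float, ...]  # mol/m^3, aligned with species
    pH: float
    eps_r: float = 78.5
    T: float = 298.15

    def __post_init__(self) -> None:
        if len(self.species) != len(self.bulk_conc):
            raise InvalidParameterError("species and bulk_conc length mismatch")
        if any(c < 0 for c in self.bulk_conc):
            raise InvalidParameterError("negative bulk concentration")
        if not (self.T > 0 and self.eps_r >= 1):
            raise InvalidParameterError("require T > 0 and eps_r >= 1")

    def conc(self, name: str) -> float:
        for sp, c in zip(self.species, self.bulk_conc):
            if sp.name == name:
                return c
        raise KeyError(name)

    def species_by_name(self, name: str) -> IonSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    @property
    def net_charge(self) -> float:
        """Sum z_i c_i (mol/m^3 of elementary charge); 0 for a neutral bath."""
        return float(sum(sp.z * c for sp, c in zip(self.species, self.bulk_conc)))

    @property
    def ionic_strength(self) -> float:
        """(1/2) sum z_i^2 c_i in mol/m^3."""
        return 0.5 * float(sum(sp.z**2 * c for sp, c in zip(self.species, self.bulk_conc)))

    def with_conc(self, name: str, value: float) -> "ElectrolyteComposition":
        conc = tuple(value if sp.name == name else c for sp, c in zip(self.species, self.bulk_conc))
        return replace(self, bulk_conc=conc)


def composition_from_ph_and_chloride(
    c_cl: float,
    pH: float = 6.0,
    eps_r: float = 78.5,
    T: float = 298.15,
    na_charge: int = 1,
) -> ElectrolyteComposition:
    """Build the sweat-like four-species bath from pH and target Cl- level.

    c(H+) = 10^(3 - pH) mol/m^3, c(OH-) = 10^(3 - (14 - pH)), c(Cl-) = c_cl;
    Na+ closes bulk electroneutrality (sum z_i c_i = 0). Sodium is the natural
    counter-ion in sweat, which the pH-fixed chloride sweep leaves free.
    """
    if c_cl < 0:
        raise InvalidParameterError("chloride concentration must be >= 0")
    species = default_species(na_charge)
    c_h = 10.0 ** (3.0 - pH)
    c_oh = 10.0 ** (3.0 - (14.0 - pH))
    z_na = species[2].z
    c_na = (c_cl + c_oh - c_h) / z_na
    if c_na < 0:
        raise InvalidParameterError("electroneutrality closure gives negative Na+ concentration")
    return ElectrolyteComposition(
        species=tuple(species), bulk_conc=(c_h, c_oh, c_na, c_cl), pH=pH, eps_r=eps_r, T=T
    )


def nernst_einstein_mobility(D: float, T: float, const: Constants = CONST) -> float:
    """Molar mechanical mobility u_m = D/(R T) in mol s/kg (Nernst-Einstein)."""
    if not D > 0:
        raise InvalidParameterError("D must be > 0")
    if not T > 0:
        raise InvalidParameterError("T must be > 0")
    return D / (const.R * T)


def thermal_voltage(T: float, const: Constants = CONST) -> float:
    """kT/q in volts."""
    if not T > 0:
        raise InvalidParameterError("T must be > 0")
    return const.k * T / const.q


def debye_length(comp: ElectrolyteComposition, const: Constants = CONST) -> float:
    """Electrostatic screening length lambda_D (m).

    lambda_D = sqrt(eps0 eps_r k T / (q^2 N_Av sum z_i^2 c_i)); used to
    auto-size the electrolyte grid.
    """
    s = float(sum(sp.z**2 * c for sp, c in zip(comp.species, comp.bulk_conc)))
    if s <= 0:
        raise InvalidParameterError("zero ionic strength: Debye length undefined")
    return float(
        np.sqrt(const.eps0 * comp.eps_r * const.k * comp.T / (const.q**2 * const.N_Av * s))
    )
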