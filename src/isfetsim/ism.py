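"""Ion-selective membrane as a lumped per-species partition boundary.

The PVC-type membrane above the gate oxide is not meshed: each species'
concentration is attenuated on crossing from the sample (upside) into the
inner sensing volume (downside) by a selectivity coefficient K_i in [0, 1]
(c_down = K_i * c_up). An alternative literal-ratio reading (K_i = c_up/c_down,
so c_down = c_up/K_i) is available via ``mode="literal_ratio"``; the default
multiplicative-decrease reading is the one consistent with K_i in [0, 1]
acting as a filter. The downside composition is generally not electroneutral;
its net charge is a reported diagnostic, and re-closure (if any) is the
caller's decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .physchem import ElectrolyteComposition, InvalidParameterError


@dataclass(frozen=True)
class MembraneSpec:
    """PVC-type ion-selective membrane.

    K_i maps species name -> selectivity coefficient in [0, 1]; species not
    listed default to 1 (unhindered). D_mem_i (in-membrane diffusivities) is
    accepted for forward compatibility but unused by the lumped model.
    """

    l_ism: float = 1.67e-6  # lateral extent (m)
    d_ism: float = 0.5e-6  # thickness (m)
    K_i: dict[str, float] = field(default_factory=dict)
    D_mem_i: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.l_ism > 0 and self.d_ism > 0):
            raise InvalidParameterError("membrane dimensions must be > 0")
        for name, k in self.K_i.items():
            if not (0.0 <= k <= 1.0):
                raise InvalidParameterError(
                    f"selectivity coefficient K[{name}] = {k} outside [0, 1]"
                )

    def coefficient(self, name: str) -> float:
        return self.K_i.get(name, 1.0)


def default_membrane() -> MembraneSpec:
    """Chloride-selective PVC membrane: Cl- passes, other species strongly
    (but imperfectly) rejected."""
    return MembraneSpec(K_i={"Cl": 1.0, "H": 0.05, "OH": 0.05, "Na": 0.05})


def partition(
    comp_upside: ElectrolyteComposition,
    mem: MembraneSpec,
    mode: str = "attenuate",
) -> ElectrolyteComposition:
    """Apply the membrane partition to the sample composition.

    mode="attenuate" (default): c_down = K_i * c_up.
    mode="literal_ratio": c_down = c_up / K_i (K_i = 0 blocks the species).
    """
    if mode not in ("attenuate", "literal_ratio"):
        raise InvalidParameterError(f"unknown partition mode {mode!r}")
    down = []
    for sp, c in zip(comp_upside.species, comp_upside.bulk_conc):
        k = mem.coefficient(sp.name)
        if mode == "attenuate":
            down.append(k * c)
        else:
            down.append(0.0 if k == 0.0 else c / k)
    return replace(comp_upside, bulk_conc=tuple(down))


def net_charge_diagnostic(comp: ElectrolyteComposition) -> float:
    """Downside electroneutrality diagnostic: sum z_i c_i (mol/m^3)."""
    return comp.net_charge
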