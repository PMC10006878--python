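# Methods

This note records the physical model behind `isfetsim`, the numerical
choices, the defaults for parameters the source device description leaves
open, and what the package's tests do and do not establish.

## Scope and model structure

The simulator couples three weakly-interacting subproblems along the
device's vertical axis:

```
electrolyte bulk (pH 6, Na+, Cl-, H+, OH-)
      | ion-selective membrane (lumped partition)
diffuse double layer (Gouy-Chapman / 1D PNP)
      | Stern capacitor C_st
oxide surface sites (site binding with Cl- adsorption)  -> psi0
      | threshold-voltage ladder                        -> V_TH
transistor (compact square law / 2D drift-diffusion)    -> I_DS
```

Only steady state is modeled. Lateral uniformity of the electrolyte over
the gate is assumed (the gate is ~1.3 µm wide versus a Debye length of
~1 nm at sweat ionic strength), so the electrolyte is solved in 1D.

## Electrolyte: bulk composition

The bath carries four species, H⁺, OH⁻, Na⁺, Cl⁻ (all monovalent;
a divalent-sodium variant is available for completeness but has no physical
use). Given pH and a target chloride level c₀:
c(H⁺) = 10^(3−pH), c(OH⁻) = 10^(3−(14−pH)) mol/m³, c(Cl⁻) = c₀, and Na⁺
closes bulk electroneutrality — sodium being the natural counter-ion in
sweat. Default diffusivities are infinite-dilution literature values at
25 °C (H⁺ 9.31e-9, OH⁻ 5.27e-9, Na⁺ 1.33e-9, Cl⁻ 2.03e-9 m²/s); activity
coefficients and ion pairing are out of scope. Defaults: T = 298.15 K,
ε_r(water) = 78.5.

## Electrolyte: double layer

The 1D Poisson–Nernst–Planck system is discretized by finite volumes on a
geometrically stretched grid (first cell ≈ λ_D/50 at the outer Helmholtz
plane, domain ≥ 30 λ_D — beyond that length the profiles are flat to reporting
precision). Nernst–Planck fluxes use exponential fitting
(Scharfetter–Gummel), which preserves positivity and reproduces the
Boltzmann equilibrium exactly on any grid when fluxes vanish. The coupled
system (potential + four concentrations per node) is solved by damped
Newton with an analytic sparse Jacobian; steps are shortened to keep
concentrations positive, with a damping floor of 1e-8 treated as failure.
Convergence: scaled residual < 1e-10, ≤ 200 iterations; in practice 2–4
iterations from the Gouy–Chapman initial guess.

The surface boundary is blocking (zero normal flux), so the converged state
is the Poisson–Boltzmann double layer and the Grahame equation

σ = sqrt(8 ε₀ε_r kT N_Av c) · sinh(qψ_d / 2kT)

is an independent closed-form oracle: the integrated diffuse charge agrees
with it to <0.1% on the default 201-node grid, with the error falling
monotonically under refinement. The Stern layer is never meshed — it is the
lumped capacitor of the surface-chemistry closure.

## Surface chemistry

Site binding with chloride adsorption gives the surface charge σ₀(ψ₀)
(README shows the formula). Conventions:

* Concentrations in mol/m³ throughout; K_a·K_b carries (mol/m³)²,
  K_b carries mol/m³, K_c is dimensionless. In pH terms, a constant K
  expressed in mol/m³ corresponds to pK = 3 − log₁₀K of the molar
  convention.
* The anion Boltzmann factor uses ψ₀ = φ_M − φ_l,bulk directly
  (Cl_S = Cl_B e^{qψ₀/kT}); the proton relation is the standard
  site-binding counterpart H_S = H_B e^{−qψ₀/kT}.

**Stern-ladder sign.** The self-consistent closure demands
φ_M − φ_OHP = σ₀/C_st: the surface sits below the OHP potential when the
surface charge is negative, so adsorption depresses further adsorption
(negative feedback) and the solution is unique. The opposite orientation
(Δφ_St = φ_OHP − φ_M = σ₀/C_st, which one reading of the boundary-condition
equation would give) makes the loop a positive feedback that runs away to
site saturation and kills the chloride response; it is not implemented.
The solver root-finds on the OHP potential ψ_d — which stays within the
double layer's own few-tens-of-mV scale regardless of how stiff the site
chemistry is — via Brent's method, with the diffuse charge supplied either
by the Grahame form (`analytic_GCS`, default) or by the PNP solver
(`full_PNP`, bracketed around the analytic solution). The two couplings
agree on ψ₀ to ~1e-7 relative at default conditions; the charge-closure
residual |σ₀ + σ_diffuse| is below 1e-12 C/m².

**Defaults** (the device description prints none of these): point of zero
charge at pH 7 (sqrt(K_a·K_b) = 1e-4 mol/m³) with an amphoteric spread of
two decades (K_a = 1e-5, K_b = 1e-3 mol/m³), K_c = 0.1,
C_st = 0.20 F/m² (20 µF/cm²), and N_S = 1e19 m⁻² (10 sites/nm², the upper
end of oxide-surface literature values). The high site density keeps the
surface strongly buffered: the chloride signal then exceeds the
ionic-strength feedthrough of a chloride-blind (K_c = 0) surface by more
than two orders of magnitude, and the pH response of the K_c = 0
configuration approaches the Nernst limit (59.16 mV/pH at 298.15 K) within
2%. All constants are config-overridable, and `calibrate` treats K_c and
N_S as free parameters anyway.

**Electrode ladder.** The gate drives the liquid through an Ag/AgCl
reference electrode: φ_l,bulk = V_ga − W_Ag − E_eq with W_Ag = 4.6 V and
E_eq = 0.197 V (Ag/AgCl vs SHE). This ladder is a reconstruction — the
absolute liquid potential does not affect ψ₀, which depends only on the
chemistry/double-layer balance; the electrode terms enter the compact
threshold expression instead.

## Ion-selective membrane

A lumped partition: c_down = K_i · c_up, K_i ∈ [0, 1] per species
(default: K_Cl = 1, all others 0.05 — a chloride-selective PVC membrane
with strong but imperfect rejection). The alternative literal-ratio reading
K_i = c_up/c_down is available behind `mode="literal_ratio"`; the two
readings conflict in the source material and the attenuating one is taken
as primary because only it is compatible with K_i ∈ [0, 1] acting as a
filter. The raw downside composition is generally not electroneutral; the
net charge is reported as a diagnostic, and the device chain re-closes
neutrality through the Na⁺ counter-ion before the diffuse-layer solve
(both diffuse-layer models require a neutral far field). Donnan potentials,
ionophore equilibria and in-membrane transport are out of scope; per-species
membrane diffusivities are accepted in the spec of the membrane but unused.

## Transistor

**Compact level.** V_TH = E_ref − ψ₀ + χ_sol − ϕ_Si − (Q_ox+Q_ss+Q_B)/C_ox
+ 2ϕ_f + v_cal, with ϕ_f = (kT/q)ln(N_A/n_i), Q_B = sqrt(4 ε_Si q N_A ϕ_f)
auto-computed at strong inversion, and v_cal a constant operating-point
offset (the residual of work functions, fixed charges and packaging that a
compact model cannot resolve; it is one of the three calibration knobs).
dV_TH/dψ₀ = −1 exactly. The square law returns 0 below threshold, the
triode branch K(2V_ov·V_DS − V_DS²) below saturation and K·V_ov² above,
continuous at the boundary, K = ½μ_n C_ox W/L.

**Polarity.** With anion adsorption, ψ₀ falls and V_TH rises as c₀ grows.
An n-style overdrive V_GS − V_TH would then *lose* current with chloride;
the modeled sensor's response direction (current rising with c₀) is
obtained with a p-channel-style overdrive V_GS − |V_TH| = V_GS + V_TH,
V_TH < 0 at the calibrated operating point (default v_cal = −2.73 V puts
the device near 0.5 V of overdrive at V_GS = 1.6 V). The polarity is a
device-level convention; `ids_compact` exposes both.

**Drift-diffusion level.** 2D finite volumes on a structured 61×41 mesh
over the 3 µm × 0.7 µm cross-section, geometrically refined to a 0.5 nm
first cell under the gate oxide (the inversion layer is a few nm deep at
N_A = 1e23 m⁻³). Source/drain are n⁺ wells (1e26 m⁻³, 0.15 µm deep)
reaching laterally from the 0.5 µm contacts to the gate edges, so the
metallurgical junction is self-aligned with the 1.3 µm gate. Boundary
conditions: ohmic contacts (charge neutrality + mass action) at source,
drain and the bottom body plane; a thin-insulator gate Robin condition
ε_Si ∂V/∂n = C_ox(φ_M − V_s) over the gate window; homogeneous Neumann
elsewhere. Operation is isothermal, so the ∇ln T thermal-diffusion terms of
the transport equations drop; recombination is neglected (no generation
path matters at these biases), which makes discrete terminal-current
conservation exact up to the linear-solver tolerance.

Solution by Gummel iteration: nonlinear Poisson (Newton with a smooth
tanh update limiter at 10 kT/q) with frozen quasi-Fermi potentials, then
linear Scharfetter–Gummel continuity solves for each carrier. Quasi-Fermi
levels recovered from the continuity solves are clamped to the contact
range [min(0, V_DS), max(0, V_DS)] — their physical bounds in steady state
without generation — which keeps direct-solver roundoff in carrier-starved
regions (densities span 17 decades) out of the convergence metric.
Convergence is declared on the potential update (< 1e-9 V); large biases
are reached by internal ramping in ≤ 0.25 V drain steps with warm starts.
Terminal currents sum the SG fluxes into each contact's nodes; source and
drain agree to ~1e-10 relative and the V_DS = 0 current is ~1e-9 of the
50 mV-bias current scale.

Threshold extraction uses maximum-transconductance extrapolation at
V_DS = 50 mV with the V_DS/2 triode correction; it recovers the threshold
of a synthetic square-law curve exactly and tracks a gate-potential
translation within a few mV. In saturation the DD current is linear in
(V_GS − V_TH)² with R² > 0.999 over a 0.3 V overdrive span, which is what
licenses using the compact level for the device experiments.

When the full chain runs at `model_level="dd"`, the chemistry's threshold
shift is translated onto the DD gate as φ_M = V_TH,DD + V_ov, i.e. the same
overdrive the compact model sees; the compact level is the default for all
sweeps.

**Semiconductor defaults** (unprinted in the source): N_A = 1e23 m⁻³,
n_i = 1e16 m⁻³, μ_n = 0.14, μ_p = 0.045 m²/Vs, ε_r,Si = 11.7, W = 1 µm,
L = 1.3 µm (the gate length), ϕ_Si = 4.05 V.

## Calibration

The source device description omits N_S, K_a, K_b, K_c, N_A, mobilities and
W, so its absolute currents are not independently reproducible; they are
reachable only through calibration. `calibrate` runs a bounded
least-squares fit of {log₁₀K_c, log₁₀N_S, v_cal} (bounds 1e-4…1e2,
1e16…1e20 m⁻², −4…0 V) from a fixed starting point — deterministic, no
stochastic search — against a sensitivity anchor and/or an absolute-current
anchor. Anchoring S = 1.2e-7 A·m³/mol at c₀ = 80 mol/m³ (mid-sweep,
the evaluation point being otherwise unspecified) yields a 50→110 mol/m³
current swing of 7.54 µA, within 4% of the 7.8 µA the anchor value itself
implies for a locally linear response — an internal-consistency check, not
an independent prediction. Anchors generated from an assembly's own
parameters are recovered in place (the fit starts at a zero of the
residual).

Sensitivity uses a central difference with step max(0.01·c₀, 0.1 mol/m³);
the limit of detection is Δc₀ = minΔI_DS / S with a default current floor
of 0.5 nA, so resolution·S = minΔI_DS holds exactly by construction.

## Oxide study

A built-in table carries literature permittivities for the nine studied
high-k insulators (SiO₂ 3.9 … TiO₂ 80, HfO₂ fixed at 25). Sensitivity at
fixed v_cal *rises* with permittivity in this model (K ∝ C_ox and the
threshold shift is permittivity-independent); the direction of this trend
depends on the unprinted parameters absorbed into the calibration, so it is
reported, never asserted. Low-k stacks may not conduct at the
HfO₂-calibrated bias at all; they report S = 0. The thickness trend is
parameter-robust and is asserted: at fixed ε_ins, sensitivity falls
strictly as d_ins grows (both K and the overdrive shrink).

## What the tests show, and what they do not

The suite checks the simulator against closed forms (Grahame, Nernst
limit, square law), against brute-force residual scans, against its own
cross-solver redundancy (analytic vs PNP coupling, compact vs DD), and
against exact algebraic identities (Stern contract, resolution identity,
membrane composability). The synthetic bath emulates sweat only as a
four-ion electrolyte at fixed pH: real sweat chemistry (lactate, urea,
proteins, fouling), electrode drift, hysteresis, temperature excursions and
noise-limited detection statistics are all outside the model, so passing
tests establish the internal consistency of the transduction model, not
clinical performance. Problem sizes used throughout (201-node electrolyte
grid, 61×41 device mesh, 4–9-point sweeps) are the package defaults chosen
to keep every experiment interactive on one CPU; all are config-overridable.

## Known limitations

* The compact current model has no subthreshold region, velocity
  saturation, or mobility degradation; the DD level has no recombination,
  field-dependent mobility, or quantum corrections.
* The membrane is a concentration filter only — no phase-boundary
  potential, so membrane selectivity does not itself generate a signal.
* Finite ion size (modified PNP), electro-osmosis and AC impedance are not
  modeled; the double layer is strictly steady-state and 1D.
* Whether the reference device's current is per-unit-width or fully 3D is
  unknown; W = 1 µm is an assumption absorbed by calibration.
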