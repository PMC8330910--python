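# Methods

## 1. State-resolved respiratory-chain model

The chain is modelled at the level of joint redox microstates of whole
complexes. Each complex is a list of centres (electron carriers and
ligand-binding sites) with a small number of levels; the model variables
are the amounts of complex occupying each joint configuration
(nmol per mg of mitochondrial protein). Chemistry is written as pattern
rules — a partial assignment of centre levels mapping to another — and
each rule is applied with the same rate constant to every matching
microstate, so 36 + 128 state variables are governed by ~45 constants.

Complex III implements the Mitchell Q-cycle: ubiquinol binds at Qo
(k_on = 700 (nmol/mg)⁻¹s⁻¹, the printed value); its first electron goes
to the lumped FeS/c₁ relay (2 H⁺ released to the positive side) leaving
the semiquinone SQ; the second goes to heme b_L or — the ROS channel —
to O₂, regenerating Q. The b_L→b_H transfer carries one charge across
the membrane; b_H reduces Qi-site quinone in two one-electron steps.
The downstream chain (c₁ → cytochrome c → complex IV → O₂) is lumped
into one irreversible oxidation of reduced FeS/c₁ translocating two
further charges per electron; O₂ is constant.

Complex II holds the flavin (FAD/FADH•/FADH₂), the dicarboxylate site
(empty/succinate/OAA) and a quinone site. Bound succinate reduces FAD
two-electron-wise (fumarate released); the flavin exchanges single
electrons with the site quinone in all four redox combinations (the
same two constants reused — omitting the "extra" combinations would
make |FAD,SQ⟩ a kinetic trap that absorbs the whole complex on the
1/k_ROS timescale). FADH• is the complex II ROS source
(flavin-site superoxide), with the producing transition reoxidising the
radical so electrons balance.

ROS formation is pseudo-first-order in site semiquinone,
k_ROS = 2·10⁻⁵ s⁻¹ (O₂ absorbed into the constant, per its printed
units). Charge-translocating steps carry symmetric voltage factors
exp(∓qαΔψ·F/RT) with α = 1/2.

### Rate constants

Printed constants are fixed: Qo ubiquinol binding 700 (nmol/mg)⁻¹s⁻¹;
succinate binding to complex II 175 (131/88/70 in the binding-constant
variation); k_ROS = 2·10⁻⁵ s⁻¹; myxothiazol remaining fractions
4·10⁻⁸…4·10⁻⁶; proton leak 2 (40 uncoupled) s⁻¹mV⁻¹; uniporter
P = 0.005 s⁻¹mV⁻¹; F/C = 500 mV·nmol⁻¹·mg. All other constants are
free parameters calibrated once (see `scripts/calibrate.py`) against two
anchors: the isolated complex II ROS peak near 50 µM succinate and a
glutamate bifurcation below 100 µM. Three calibration choices carry the
qualitative behaviour and deserve note:

* the flavin↔couple equilibrium (succinate + FAD ⇌ fumarate + FADH₂) has
  K_eq ≈ 1, so the flavin titrates with the succinate/fumarate couple
  and its semiquinone — the ROS source — peaks at half-reduction, near
  succinate ≈ the ambient fumarate level (the scenario buffers fumarate
  at 100 µM, a mid-assay value);
* the flavin→quinone-pool step is strongly downhill (K_eq ≈ 400), so
  complex II keeps pushing even against a reduced pool — the positive
  feedback needed for bistability;
* complex II's quinone site binds Q much more avidly (K_d 0.025 nmol/mg)
  than the Qi site (K_d 12.5 nmol/mg), so when free Q becomes scarce
  complex II wins the competition, starving complex III's acceptor site
  and locking the high-ROS state in place (hysteresis).

Amounts: complex II and III 0.25 nmol/mg each, total ubiquinone
4 nmol/mg, NAD(H) 2 nmol/mg. Matrix/chamber amounts use the convention
1 mM ≈ 1 nmol/mg (≈1 µL matrix water per mg protein), which makes the
printed (nmol/mg)⁻¹s⁻¹ constants directly applicable; µM figure axes
convert by /1000.

## 2. Matrix compartment and membrane

Succinate oxidation feeds fumarase and malate dehydrogenase (reversible
mass action; MDH equilibrium far toward malate), the aspartate
aminotransferase, and carriers: aspartate/glutamate exchange
(electrogenic, +1 charge inward), a glutamate/H⁺ symport, malate and
α-ketoglutarate efflux, an uncoupled aspartate efflux, and a small
poise-restoring NAD(H) turnover (the residual matrix NADH consumers
that keep a finite resting NAD⁺/NADH ratio under rotenone — without it
any sustained aminotransferase flux would pin the pool at one rail and
destroy the glutamate dose-response). Oxaloacetate inhibition of
complex II is tight competitive binding at the dicarboxylate site with
slow dissociation (K_d 0.1 µM, k_off 0.01 s⁻¹ in the
isolated-mitochondria set).

Membrane potential: dΔψ/dt = (F/C)·Σ(signed charge fluxes) − k_leak·Δψ,
with the leak written directly in voltage units to honour its printed
s⁻¹mV⁻¹ units. The Ca²⁺ uniporter evaluates the printed constant-field
expression verbatim with a global orientation sign (energised membrane
imports Ca²⁺) and an analytic Δψ→0 limit P·(RT/F/z)·Δ[Ca]; the standard
Goldman form (internal concentration weighted by the exponential) is
available as a configuration switch and shares the Δψ→0 limit. External
Ca²⁺ pulses are 20 nmol per chamber (≡ nmol/mg at 1 mg protein); matrix
Ca²⁺ is held constant. Temperature is 298.15 K, making RT/F the
conventional 25.693 mV.

## 3. EAAT transport cycle

Outer and inner ion binding (Na⁺, then H⁺/Na⁺, glutamate, Na⁺; K⁺
exclusive on the free carrier) is a fast-equilibrium binding polynomial;
the two conformational steps (loaded carrier inward, K⁺-bound carrier
outward) are slow and reversible. Using a true partition function —
rather than a product of independent saturation factors — makes every
state ratio exactly mass-action, and the cycle's zero-flux condition
then coincides exactly with the combined electrochemical equilibrium
(verified against the Nernst prediction to 10⁻¹¹ mV in the tests). The
voltage-coupled charge (+2 per cycle) is assigned entirely to the loaded
step, with the K⁺ return electroneutral: the reversal potential depends
only on the sum, and this split keeps uptake monotonically enhanced by
hyperpolarisation, as observed for these transporters. Default
dissociation constants put half-maximal uptake at ~20 µM external
glutamate.

## 4. In-situ cell model

Units: cytosolic species in mM of tissue water (1 g ≈ 1 mL, so
1 mM ≡ 1 µmol/g); with ρ = 20 mg mitochondrial protein per g of tissue,
one matrix event moves ρ/1000 = 0.02 mM on the cytosolic side. The
cytosol holds lumped glycolysis (constant glucose → 2 pyruvate + 2 ATP +
2 NADH, saturable in ADP), a pyruvate-dehydrogenase/citrate-synthase
entry consuming matrix oxaloacetate (the second OAA drain), an
α-ketoglutarate dehydrogenase limb closing the Krebs loop back to
succinate, the malate–aspartate shuttle (cytosolic AAT + MDH and the
two carriers), a lactate reservoir and a glycerol-phosphate-shuttle
stand-in (direct cytosolic NADH → ubiquinone) that guarantee cytosolic
NAD⁺ availability, ATP synthase (reversible, phenomenological
k(Δψ−Δψ_thr) with saturable nucleotide dependence), an integral ATPase
workload (Michaelis in ATP), and the EAAT. The Na⁺ load imported with
glutamate is cleared by the Na⁺/K⁺-ATPase at 1 ATP per 3 Na⁺ spread
over tens of minutes — tying the full cost instantaneously to uptake
would discharge Δψ during the stimulus and act as an uncoupler, which
is neither physiological on this timescale nor compatible with the
observed switch.

The in-situ assembly uses its own respiratory-chain/matrix parameter
variant (`INSITU_CHAIN_OVERRIDES` and friends): terminal capacity,
Qi-site affinity, dicarboxylate-site kinetics (same K_d, faster
exchange), faster AAT/MDH turnover (equilibria unchanged), and a lumped
complex-I input NADH + Q → NAD⁺ + QH₂ translocating 4 charges per
2 electrons with a shallow voltage split (α = 0.125 versus the
terminal step's effective exponent). That asymmetry is the mechanistic
reading of the workload protection: when ATP demand pulls Δψ down, the
terminal step gains capacity faster than complex I gains input, so the
quinone pool stays oxidised; at state-4 potentials the terminal is
throttled hardest and a sustained glutamate-driven input tips the pool
into the latched reduced state. Stimulation presets deliver 1 or
3 µmol glutamate per g tissue over 5 s through a buffered extracellular
square pulse whose height is solved numerically per preset.

## 5. Steady states, sweeps and protocols

Steady states are found by pseudo-transient continuation: stiff (BDF)
integration in growing time chunks damps the fast modes, then a
damped-Newton solve of the conservation-constrained algebraic system
(singular rows replaced by the occupancy/pool conservation equations,
clamps and accumulator pins) lands on the exact root; where the damped
Newton stalls on near-singular slow directions (modes of order k_ROS), a
Levenberg–Marquardt finisher with the analytic Jacobian completes the
solve. A polished root is accepted only if it is non-negative and on
the same branch (ubiquinol-fraction guard), so the polish cannot hop
between coexisting steady states. Default steady tolerance 10⁻⁶ on the
per-variable scaled residual (10⁻⁸ for the isolated complex II scans,
whose observable lives on the slow manifold); integrator tolerances
rtol 10⁻⁸ / atol 10⁻¹⁰; everything is deterministic (no RNG on the ODE
side), so runs are bit-reproducible.

Sweeps chain steady states over a monotone parameter grid, seeding each
point with the previous solution; a jump of the free-pool ubiquinol
fraction by more than 0.25 between adjacent points is recorded as the
bifurcation (midpoint convention). The ubiquinol fraction is used for
detection because it shows the cleanest discontinuity; the reported
fraction is that of the free pool (bound quinone is tracked separately
and a total-pool variant is exposed as a second observable). The
complex II succinate scans relax every grid point from the same fully
oxidised initial state: the blocked system latches near complete pool
reduction on the 1/k_ROS timescale, so warm-starting would mix branch
identities along the grid. Inhibitor protocols apply antimycin
(Qi binding and dissociation zeroed), myxothiazol (Qo ubiquinol binding
scaled) or buffered glutamate at scheduled times, integrating piecewise.

## 6. Tissue phantom and H₂O₂ transport

The phantom is a 16×17×19 µm box at 0.25 µm voxels holding 26
non-overlapping bodies: two spheres of radius 3.1 µm (the
glutamate-stimulated producers, 4.83% of the volume in closed form) and
24 rounded-box superellipsoids (exponent 6, closed-form volumes) on a
jittered 3×3×3 lattice, rescaled iteratively until the analytic cell
fraction is 0.60 ± 0.01 with at least one voxel of interstitial fluid
between any two surfaces. The two spheres sit on the central axis
(y = −5 µm, z = 0, centres x = ±3.35 µm), replacing the lattice row the
axis runs through, so the measurement axis penetrates the
high-production bodies. Generation is deterministic per seed; the seed
only jitters the surrounding bodies.

The transport equation is discretised by finite volumes: 7-point
diffusion stencil, first-order upwind convection along +x (cell Péclet
number 7·10⁻⁵), Danckwerts total-flux inflow at x = 0, zero diffusive
flux (convective outflow) at x = L, fixed concentration on the four
lateral faces. Implicit-Euler stepping (warm-started Jacobi-BiCGStab;
no CFL restriction) with per-step mass-balance closure to 10⁻⁸; the
steady state comes from one ILU-BiCGStab solve of the linear system.
Concentrations are carried in nM and lengths in µm (1 µM/min =
16.67 nM/s; D = 1830 µm²/s).

The pre-steady-state maximum along the axis occurs ~0.3 ms after the
start, while cell production still outruns the arriving cold front from
the 5 nM interstitial fluid; it is resolved with 0.1 ms steps (the
first-order scheme damps the sub-ms peak: 0.2/0.1/0.05 ms steps give
1.7/2.4/2.9% excess — the 0.1 ms default is the package's reporting
resolution, stated once here). Report times for field snapshots default
to 1, 5, 20, 100 ms plus the steady solve.

## 7. What the generators emulate — and what they do not

The scenario fixtures emulate the study conditions: inhibitor titrations
on 1–500 µM succinate, glutamate sweeps at four succinate-binding
constants, uncoupler contrast (leak 2 vs 40 s⁻¹mV⁻¹), inhibitor-order
protocols, 20-nmol Ca²⁺ pulse trains, the three uptake/workload presets,
and the normal/high-production phantom pair. They do not emulate:
probe chemistry or ROS scavenging (ROS accumulates without
inactivation), mitochondrial heterogeneity (the experimental glutamate
dose–response is a smoothed version of the model's sharp switch),
Ca²⁺ buffering/antiport (matrix Ca²⁺ constant), receptor signalling, or
the true ~8 nm interstitial clefts — phantom gaps are one voxel
(0.25 µm), which over-drains the producing bodies, so tissue-scale
excess values are systematically conservative. Passing tests therefore
demonstrate the mechanisms (bistability, hysteresis, workload
protection, pre-steady-state excess), not quantitative agreement with
any particular preparation.

## 8. Known limitations

* The two respiratory-chain parameter sets (isolated vs in-situ) are
  separate calibrations; a single set spanning both regimes was not
  found with this state-space reduction.
* The complete-block vs partial-block steepness contrast in the
  isolated complex II scan is a few-percent effect under these
  constants (strictly ordered, but far smaller than the experimental
  contrast).
* On the high-ROS branch the model's Δψ collapses and the Qo
  semiquinone saturates; with ROS inactivation absent, accumulated ROS
  grows linearly there.
* The fast-cycling (uncoupled) chain holds a standing flavin-radical
  population, so uncoupling lowers complex III and total ROS
  accumulation by orders of magnitude but not the complex II share; the
  uncoupler contrast is carried by complex III.
* The in-situ "glu" preset passes near the switching threshold and
  shows a transient complex III ROS excursion (two orders of magnitude,
  returning to baseline within minutes) even though it does not switch.
* First-order upwinding and implicit Euler are dissipative; the
  reported pre-steady-state excess is a lower bound at the stated step
  size (see §6).
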