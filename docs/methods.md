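# Methods

## Model

The tumour cord is a fixed cylindrical annulus: a capillary of radius
R_C = 10 µm feeding an interstitium that extends to the cord radius
R_T = 120 µm.  Cells are stationary, initially alive and uniformly
distributed; conditions are uniform before injection; cellular variability,
stochasticity, cell-cycle structure and cell–cell interaction are all outside
the model, which is deliberately a deterministic continuum skeleton.
Spatial variation is radial only, and interstitial convection is neglected
(the lumped Starling term K₁ at the wall is retained as a constant and
defaults to 0).

Three coupled layers (fields on the annulus):

* free extracellular drug E — radial diffusion (k_d), reversible albumin
  binding (k₃, k₄ — fast: equilibrium ratio B/E = 3), saturable cellular
  uptake/efflux (V₁ = V₂, Michaelis constants k₁, k₂), Kedem–Katchalsky
  exchange with the capillary at concentration S(t);
* bound drug B — slow diffusion (k_db), no transcapillary flux (complexes
  are described only in the interstitium, so the wall is sealed for B);
* intracellular drug I (per 10⁵ cells), switch intermediate R, apoptosis
  effector R₁, and cell density c_t per node.

Both cellular-exchange terms in the E equation carry the cell-density factor
c_t.  Per-cell fluxes (ng per 10⁵ cells per hour) convert to volumetric
concentration rates through Γ = c_scale/10⁵ cells·mm⁻³; with
E_ref = 0.001 µg/mm³ (= 1 µg/ml) and I_ref = 1 ng/10⁵ cells the bridge is
exactly Γ in reference units.

### Signalling modules and trigger semantics

The monostable module is a first-order Hill cascade: fully reversible, one
steady state per input; paired with an **irreversible** population trigger
(once R₁ ≥ R₁,th at a node, its growth collapse is latched).  The bistable
module has positive feedback with saturated degradation; with the default
parameters it is bistable at zero input (the lower saddle-node lies at
negative, unphysical input), so a switch to the upper branch is permanent
even after complete washout.  Its population trigger is therefore
**reversible**, tracking R₁ ≥ R₁,th instantaneously: the irreversibility is
supplied by the switch itself.  The two modules are parameter-matched: the
monostable steady-state threshold (input at which steady R₁ reaches R₁,th)
is 0.944, the bistable upper fold 1.009, and the times for R₁ to reach
threshold under the reference input I ≡ 2 are 2.33 h and 3.07 h
(`calibrate_module_match` recomputes and flags these; the reference input —
roughly twice threshold — is configurable, as the calibration point itself
is a convention).

### Population layer

Logistic growth: net rate (a₁ − a₂)c_t − b c_t², giving a carrying capacity
(a₁ − a₂)/b ≈ 1.003×10⁶ cells/mm³ with the defaults.  A fired trigger
replaces a₁ by a₁,triggered = 0 (complete growth shutdown — "sharply or
completely reduced"; any value below a₂ gives the same qualitative outcome).
The equivalent variant that instead adds a linear death term is available
(`SolverOptions.growth_variant="extra_death"`); by default its added rate is
chosen to match the reduced-growth collapse exactly.

## Nondimensionalization

Lengths are scaled by R_T, time by the free-drug diffusion time
t_scale = R_T²/k_d ≈ 91 s (this makes the dimensionless free-drug
diffusivity 1), E and S by E_ref, I by I_ref.  Mixed source units are
reconciled first: V₁, V₂ per minute → per hour, growth rates per day → per
hour; k₁ = 0.219 µg/ml equals 0.219 E_ref units because 1 µg/ml = E_ref.

The cell density is scaled by the **carrying capacity** (a₁−a₂)/b rather
than the nominal 10⁶ cells/mm³.  The two differ by 0.3% (the nominal value
is the capacity rounded to one significant figure), and the capacity scale
makes the untreated steady state exactly 1, which is both the stated initial
condition and the value the untreated cord must hold indefinitely.  The
nominal scale remains available (`density_scale="c_ref"`).
Nondimensionalization is a bijection; `redimensionalize` inverts it to
floating precision (property-tested).

## Wall permeability calibration

K and K₁ have no tabulated values.  K₁ defaults to 0 (no convective leak).
K is the one genuinely calibrated constant: K = 1.2 mm/hr (≈ 3×10⁻⁵ cm/s,
physiological for doxorubicin).  The calibration targets the model's own
reference behaviours, not a measured permeability: (a) the reference bolus
S = 4, T = 1.75 h must kill a wall-adjacent region while the cord rear
survives, and (b) a second identical bolus after a 48 h interval must be
visibly less effective than after 24 h.  Both pin K to a narrow window
(≈ 1.0–1.2 mm/hr) because the cord is strongly diffusively coupled: drug
taken up anywhere re-equilibrates through the shared extracellular bath
within tens of minutes, and the wall is the only exit, so the kill/no-kill
decision is close to collective.  Larger K floods the cord uniformly
(all-or-nothing in S); the chosen K leaves a genuine partial-kill regime.
With a sustained S the wall concentration equilibrates to S over a few
hours — slower than a naive permeability estimate would suggest, and
deliberately so, because fast equilibration erases the spatial selectivity
that the bolus experiments exhibit.

## Numerics

* Method of lines: conservative finite volumes on a uniform radial grid
  (default 61 nodes), so total drug changes exactly by the wall flux
  (asserted by a discrete divergence-theorem test).  The Laplacian is
  second-order in the interior; boundary closures are flux-based half cells.
* Stiff integration: BDF with an analytic sparse Jacobian (the binding pair
  k₃, k₄ and the diffusion spectrum make the system stiff); default
  tolerances rtol 1e-8 / atol 1e-10.  State packing order is fixed
  (`E | B | I | R | R1 | c_t`) for bit-exact regression.
* Dose discontinuities: the integrator restarts at every protocol edge
  (segments are closed-left, open-right), so pulse corners are never
  smoothed.
* Trigger events: R₁-threshold crossings are located by solver event
  detection and the integration restarts with the updated per-node growth
  mode, so the collapse takes effect at the crossing time, not at the next
  output sample.  Monostable crossings latch; bistable crossings are watched
  in both directions.
* Steady-state and bifurcation analysis: roots of the bistable rate are
  bracketed on a fixed 4001-point grid (guarding the K_m2 = 0.01 boundary
  layer) and polished with Brent's method; stability is the sign of ∂f/∂R,
  with |∂f/∂R| < 1e-10 reported as degenerate rather than guessed.  Folds
  are located by bisection on the steady-state branch count.  The monostable
  transient has a closed convolution form, evaluated with the exponential
  kept in shifted form exp(−k(t−w)) so it cannot overflow.
* Determinism: no stochastic component anywhere; identical configurations
  produce bitwise-identical CSV output.

## Kill-zone metrics

The population rates are day-scale: a condemned node's density decays by
only ~10% within the 12 h figure-style snapshots, reaching the extinction
floor (10⁻⁶) only after ~1000 h.  Snapshot kill zones are therefore located
from the trigger state, using a continuous margin field — the running
maximum of R₁ minus threshold for the monostable latch, the instantaneous
R₁ minus threshold for the bistable switch — with the interface
interpolated linearly between straddling nodes.  This makes boundary
positions smooth under mesh refinement (doubling the grid moves the
reference boundaries by ~0.1%).  The density-floor variant
(`kill_zone_boundary`) is the right metric for genuine long-time states and
is what the steady-state diagnostics use.  Disjoint dead regions (dead bands
separated by living tissue) are fully representable and reported as a list.

`fraction_dead` is the dead share of the *radial extent* of the annulus
(not of its cross-sectional area); boundary positions are dimensionless
radii in (R_C/R_T, 1].

## Scenario registry

Each figure-style experiment is a named, fully resolved configuration
(protocol, module, snapshot, sweep values).  Printed protocol values
(S = 4 with T = 1.75 h or 1.5 h; 24 h/48 h intervals; snapshots at 12, 36,
60 h) are used verbatim; sweep values that were never printed (the pulse
heights of fig4, durations of fig5/fig9, fractionation splits of fig10,
radii of fig7) are representative choices spanning the no-kill,
partial-kill and full-kill regimes, and are recorded as such in the
registry.

## What a green test establishes — and limitations

* The qualitative dose-response trends are reproduced for both signalling
  modules: a sharp sustained-concentration threshold; bolus-induced
  wall-adjacent kill zones growing non-linearly with pulse height and
  duration; an interior optimum of infusion time at fixed total dose; a
  second bolus that widens the zone with a benefit that decays with the
  interval; dilution of the effect in larger cords.  These are ordered
  outcomes, not digitized curve fits — the underlying figures print no
  numbers.
* The partial-kill band is narrow in every protocol parameter (narrower for
  the monostable module, as expected), because intracellular drug
  redistributes through the extracellular bath and the fate decision is
  nearly collective.  One published observation is *not* reproduced: killing
  regions separated by living tissue under monostable second-bolus
  fractionation.  In this calibrated regime the exposure field stays
  monotone in radius for every protocol scanned (heights 4–16, durations
  0.25–2 h, intervals 24/48 h, radii 120–300 µm), so the death front is
  always contiguous from the wall.  The metrics and data structures support
  disjoint regions; the model in this parameterization does not produce
  them.
* The day-scale population rates mean "dead at 12 h" is a statement about
  fate (trigger state), not about the density having reached zero; density
  extinction completes on the 1000 h scale.
* No pharmacokinetics (the capillary concentration is imposed, not derived
  from a whole-body model), no blood-flow modelling, no resistance,
  variability, cell cycle or migration, and no parameter fitting to data —
  the defaults are literature-scale constants for doxorubicin plus the one
  calibrated wall permeability.
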