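# Methods

## The model

`ngvsim` integrates a deterministic system of 33 ordinary differential
equations describing a representative neuron, a representative astrocyte, the
extracellular space and a capillary, coupled to a venous balloon.  All
concentrations are in mM, time in s, voltages in mV; every intracellular flux
is expressed per the volume of its own compartment, and inter-compartment
transfers are converted with the volume-fraction ratios (V_n = 0.45,
V_g = 0.25, V_e = 0.2, V_cap = 0.0055).  Neurons and astrocytes are further
split into cytosolic (1−ξ) and mitochondrial (ξ = 0.07) sub-volumes, which
carry separate NADH pools exchanging only through a saturable shuttle.

The building blocks and their main assumptions:

* **Excitability.** A single-compartment Hodgkin–Huxley neuron with
  instantaneous sodium activation (m∞³h), an n⁴ delayed rectifier, a
  high-threshold calcium current and a calcium-gated potassium current that
  produces spike-frequency adaptation.  The sodium and leak reversal
  potentials are recomputed continuously from intracellular sodium, so
  sustained activity feeds back on excitability.  The astrocyte is not
  excitable; its membrane voltage is the fixed parameter ψ_g = −70 mV.
* **Stimulus.** A presynaptic population of N_exc = 1500 neurons firing at a
  rate that decays from 3.2 Hz to a sustained 0.5 Hz with τ = 2.5 s.  It
  drives (i) an AMPA conductance g_exc = N_exc·ḡ·f(t) on the neuron, with
  the synaptic current written inward-positive so that it depolarizes and
  injects sodium (two thirds of the AMPA current is carried by Na⁺), and
  (ii) astrocytic sodium entry through glutamate uptake, 3 Na⁺ per glutamate.
  The voltage-gated sodium flux −I_Na contributes to the neuronal sodium
  balance at all times, not only during stimulation; this is required for the
  resting state to be a true fixed point of the full system.
* **Metabolism.** Glycolysis is lumped into three steps: an ATP-inhibited
  HK–PFK entry (Hill coefficient 4 on ATP), a PGK step producing cytosolic
  NADH and a PK step producing pyruvate.  LDH follows mass action in both
  directions, `J_LDH = k⁺·PYR·NADH_cyto − k⁻·LAC·(N − NADH_cyto)`.  The
  mitochondrion is reduced to a TCA input step (4 NADH per pyruvate) and an
  electron-transport output step consuming NADH, oxygen (0.6 O₂ per NADH
  oxidized) and producing 3.6 ATP per NADH; ADP exerts respiratory control.
  ADP and AMP are slaved to ATP through the adenylate-kinase equilibrium
  (convention ADP² = q_AK·ATP·AMP with q_AK = 0.92, pool A = 2.212 mM); the
  ATP balances carry the buffering factor (1 − dAMP/dATP)⁻¹.  Phosphocreatine
  buffers ATP through creatine kinase.  The astrocytic ATP balance includes
  an extra ¾-pump-equivalent cost above baseline
  (−7/4·J_pump,g + 3/4·J_pump,g⁰), representing glutamate uptake and
  glutamine cycling; it cancels exactly at rest.
* **Transport.** Glucose and lactate cross membranes by reversible,
  saturable carriers `T_max (s/(s+K_t) − d/(d+K_t))`; oxygen enters cells
  down the gradient between the plasma oxygen in equilibrium with hemoglobin
  (inverse Hill relation, n_h = 2.73, capacity 8.6 mM) and intracellular
  oxygen.  Capillary contents are refreshed advectively at rate 2F(t)/V_cap
  from arterial values.
* **Hemodynamics.** Blood flow is an input: baseline F₀ = 0.012 s⁻¹; in
  vivo it follows, after a 1 s delay, a biexponential transient (peak ≈ +59 %
  near 3 s after the delay) relaxing to a +10 % plateau, and decays back with
  τ = 5 s after the stimulation.  The venous balloon has a viscoelastic time
  constant τ_v = 35 s and a flow–volume exponent α_v = 0.5; its outflow is
  obtained by solving the implicit outflow/volume pair algebraically before
  integration.  The end-capillary oxygen entering the deoxyhemoglobin balance
  is taken as 2·O2_c − O2_a, i.e. the capillary state is read as the
  arterial/end-capillary average.  The BOLD signal uses k₁ = 2.22, k₂ = 0.46,
  k₃ = 0.43 with the baselines taken from the run's own resting state.
* **Scenarios.** The slice (in vitro) experiment holds the five
  capillary/vascular states (O2_c, GLC_c, LAC_c, V_v, dHb) at their resting
  values — a proxy for a perfused bath — by zeroing their derivatives, which
  keeps a single state layout across scenarios.  The in vivo rodent and human
  experiments clamp nothing and use the flow curve (no human-specific flow
  constants are published; the human scenario reuses the same shape, with
  every flow parameter overridable).

### Glycogen and other exclusions

The model deliberately contains no glycogen pathway, no pentose-phosphate
branch, no spatial diffusion and no explicit neurovascular signalling
cascade; blood flow is prescribed, not computed.

## Derived observables

Relative ("percent change") series are normalized to the run's own initial
(resting) state.  Tissue NADH weights the four sub-pools by cell volume times
sub-volume fraction ((1−ξ)V_n, ξV_n, (1−ξ)V_g, ξV_g); tissue lactate mixes
n/g/e/c by volume; "intra-parenchymal oxygen" is the V_n/V_g-weighted mean of
the two cellular oxygen concentrations (the model has no extracellular oxygen
state — this is a reconstruction of an under-specified read-out, and the
main residual ambiguity in the rodent comparisons).  CMR_glc is measured at
the committed HK–PFK step rather than at the (reversible) membrane
transport; CMR_O2 = 0.6·(V_n·J_mito,out,n + V_g·J_mito,out,g); OGI is their
ratio, flagged undefined where CMR_glc vanishes.  Spikes are upward crossings
of ψ_n through 0 mV located by event detection; the instantaneous firing
rate is the inverse inter-spike interval.

## Numerics

The system is stiff: gate time constants are ≈10⁻⁴ s while astrocytic sodium
and lactate pools relax over 10²–10³ s.  Integration uses LSODA with
per-state absolute tolerances (|y₀|·10⁻⁸ + 10⁻¹²) and rtol 10⁻⁶ by default.
While the stimulus is on and the membrane is firing, the maximum step is
capped at 10⁻⁴ s so every action potential is resolved; the cap is released
once a 5 s detection window passes without a spike.  Integration restarts at
the input breakpoints (stimulus onset/offset, flow delay) so the solver never
steps across a discontinuity.  Output is sampled at 1 ms during the capped
phase and 100 ms afterwards (both configurable); spike times come from exact
event detection and are independent of the sampling.  Halving the tolerances
changes the headline observables by < 0.5 % and leaves spike counts
unchanged (enforced by tests).  Two runs with identical inputs are
bit-identical.

Steady states are solved with MINPACK's hybrid Newton method on the state
scaled by the published resting values, seeded from those values; if the
direct solve fails (e.g. for strongly perturbed parameter sets) the system is
first relaxed onto its attractor by pseudo-time integration (horizons up to
4×10⁶ s, extended until the slow PCr/NADH pools settle) and then polished.
Stability is judged from the finite-difference Jacobian (central differences,
relative step 10⁻⁶): stable iff every eigenvalue has strictly negative real
part, marginal spectra counting as unstable.  Clamped directions are excluded.
Removable singularities of the gate rate functions at −33 and −34 mV are
evaluated by their first-order expansions within ±10⁻⁶ mV.

## Calibration

**Constrained parameters.** The resting concentrations are imposed and the
rate capacities are solved from the flux balances they enter.  The balances
alone underdetermine the set, so three partition fractions close it, encoding
the model's compartmentalization constraints: neurons take 33 % of total
glucose uptake (astrocytes the rest), neurons take 75 % of total oxygen, and
2.3 % of astrocytic glucose arrives directly from the capillary.  Total
glucose and oxygen consumption are fixed by the baseline blood supply
(2F₀·(arterial − capillary)).  The chain then yields, in order: the HK–PFK
rates and glucose-carrier capacities; the ETC capacities, oxygen-exchange
conductances and (via the combined pyruvate/NADH balances,
10·J_HKPFK − 5·J_LDH = J_mito,out) the LDH reverse rates, shuttle and TCA
capacities; the PGK/PK rates; the creatine-kinase reverse rates
(equilibrium at rest); the housekeeping ATPase loads; and the
extracellular→capillary lactate capacity plus the arterial lactate
concentration.  The three cell-membrane lactate capacities are kept as given:
their resting gradients are smaller than the rounding of the published
resting values, so solving for them is ill-conditioned — instead those
balances are satisfied at the true fixed point by micro-gradients below the
printed precision.  Solving twice is exactly idempotent, and the solved set
reproduces a fixed point with residual < 10⁻⁹ mM/s.

**Free parameters.** The optimized kinetic constants are fitted by
Nelder–Mead in log space (positivity by construction) minimizing the
unweighted sum of squared differences between simulated and target
relative-NADH curves (astrocytic cytosol, neuronal mitochondria, tissue) on
a common 0.5 s grid.  Each candidate re-runs the constrained solve, recomputes
the steady state, rejects unstable or failing candidates with a penalty, and
simulates the slice scenario.  The self-consistency test perturbs one free
parameter ×1.5, fits against curves generated by the model itself on a 30 s
horizon (coarsened tolerances, 10⁻³ s step cap) and recovers it to well
within 5 %; the reduced horizon keeps the whole calibration check around a
minute of compute while the NADH dip and early astrocytic rise — the
informative part of the objective — are fully contained in it.

**Synthetic targets.** The fixture generator emulates the published shape of
slice NADH recordings — a neuronal-mitochondrial dip of −10 % near 5 s with
recovery and a small late overshoot, a ≥10 s-delayed monophasic astrocytic
rise, and a declared weighted tissue mixture — as smooth exponential forms
with optional seeded Gaussian noise.  It reproduces shape, not measurement
noise structure, bleaching or optical cross-talk, so passing calibration
tests demonstrates correctness of the machinery, not fidelity to any
particular laboratory's data.

## Design choices where the problem was open

* The LDH reverse term uses the lactate concentration (standard mass
  action).  This is the only reading under which the published parameter set
  yields the documented resting sign structure — astrocytes export lactate,
  neurons import and oxidize it, a small surplus drains to the blood — and
  under which the published constrained capacities (e.g. the
  extracellular→capillary lactate capacity ≈ 0.25 mM/s and arterial lactate
  ≈ 0.506 mM) are recovered by the constraint solve.
* The synaptic current is written inward-positive, I_syn = g_exc(E_AMPA −
  ψ_n); with the conventional outward-positive form the printed plus sign in
  the voltage equation would make an AMPA input hyperpolarizing.
* The flow plateau factor is 1.1 and the transient amplitude 1.5 for both in
  vivo scenarios; the human profile has no separately published constants
  and simply reuses the shape with overridable parameters.
* The stability convention treats marginal (zero-real-part) spectra as
  unstable.

## Known limitations

* With the published parameter set, the late-stimulation tissue-oxygen
  plateau in the rodent scenario computes slightly **below** baseline
  (≈ −2 %) rather than the reported ≈ +2.4 %, and the post-stimulus
  undershoot is correspondingly deeper; the onset dip and overshoot are
  reproduced to within ≈ 0.7 and 1 percentage point.  No single value of the
  flow plateau reconciles all four oxygen metrics simultaneously, so the
  residual is attributed to the reconstruction of the flow curve and of the
  "intra-parenchymal oxygen" observable rather than to a single constant.
  The post-stimulus rise of lactate export to the blood computes ≈ +84 %
  against a reported ≈ +69 %.
* Enlarging the total NAD pool beyond ≈ 1.5× destroys the astrocytic
  glycolytic fixed point (GAP grows without bound) — a genuine property of
  the rate laws worth knowing before re-parameterizing the redox pools.
* The published resting table prints one rounded value for the GAP and PEP
  rows of both cell types; with the published (rounded) rate constants the
  astrocytic fixed point settles at different values for these two
  intermediates.  All other states land within the printed rounding.
* Under ±10 % randomization of all kinetic parameters the steady state
  remains stable and the NADH dip and astrocytic rise persist, but the
  astrocytic transient can become biphasic for some draws.
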