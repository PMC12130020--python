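# Methods

## Model

The core object is a two-compartment spiking neuron for layer-5-pyramidal-like
cells. The somatic/basal compartment follows adaptive exponential
integrate-and-fire (AdEx) dynamics:

    C_s dV_s/dt = g_Ls (E_Ls - V_s) + g_Ls Delta_T exp((V_s - V_ths)/Delta_T)
                  - g_w w + I_s(t) + g_C (V_d - V_s)
    tau_w dw/dt = a (V_s - E_Ls) - w,        w -> w + b at each spike

A spike is detected when V_s >= V_th; V_s is clamped at V_reset for t_ref
while the rest of the tree keeps integrating. Each spike also injects the
charge w_BAP into the distal compartment after a delay d_BAP — a
back-propagating action potential (BAP) reduced to its depolarizing charge.

The distal/apical compartment ("calcium hot zone") is passive except for a
high-voltage-activated Ca2+ channel, a Ca2+-activated K+ channel and a
calcium pool:

    C_d dV_d/dt = g_Ld (E_Ld - V_d) + I_Ca + I_KCa + I_d(t) + BAP
                  + g_C (V_s - V_d)
    I_Ca  = g_Ca m h (E_Ca - V_d),   m,h first-order with sigmoid steady states
    I_KCa = g_K m_K (E_K - V_d),     m_K_inf = 1/(1 + (Ca_th/[Ca])^const_KCa)
    d[Ca]/dt = phi_Ca I_Ca - ([Ca] - Ca_0)/tau_Ca

The coupling term appears with the sign +g_C(V_j - V_i) in **both** rows
(current conservation; the general tree form is the authoritative one).
The calcium pool relaxes **toward** its baseline: the relaxation term
carries a minus sign, consistent with tau_Ca being an extrusion time
constant. Any tree of such compartments can be built; the model graph is
always a tree, and arbitrary compartments may carry AMPA / GABA / NMDA /
AMPA+NMDA receptors (double-exponential conductance windows normalized so
one spike's peak equals the synaptic weight; the NMDA component is
multiplied by the magnesium-block sigmoid 1/(1 + 0.3 e^{-0.1V})).

## Numerics

Voltages advance by Crank-Nicolson with a single Taylor linearization of
the AdEx exponential around V(t) — one tree-structured linear solve (Hines
algorithm, O(N), exact, bitwise-deterministic) per step, no iteration.
Gating variables, the calcium pool, receptor states and w use exact
exponential propagators on a staggered (leap-frog) grid: state values at
t+h/2 enter both sides of the voltage update, and are then advanced by h
with the voltage held at V(t+h). Default step h = 0.1 ms; the scheme is
second-order on passive trees (verified by the convergence test).

Numerical safeguards, chosen for robustness without affecting spike times:

* the AdEx exponent is clamped at +10 (spike detection happens at V_th,
  far below where the clamp engages);
* the Taylor derivative of the exponential is capped at C/h so the CN
  diagonal stays positive during spike runaway (without the cap the
  one-step linearization changes sign near ignition and produces spurious
  non-monotone threshold behaviour);
* the NMDA magnesium-block factor is evaluated at V(t) and frozen over the
  step (the NMDA conductance itself is handled implicitly);
* events (presynaptic spikes, BAP deliveries) snap to the grid; the BAP
  charge is delivered as a one-step current w_BAP/h, making the delivered
  charge independent of h;
* spike times are recorded at the end of the step, not interpolated;
* w is integrated with V_s held at its post-solve value; b is added after
  the reset, and w keeps evolving during refractoriness.

The engine is batched: B independent instances of one tree topology
(optionally with per-instance parameters and stimulus amplitudes) advance
in lock-step as numpy vector operations. Transfer-surface scans, threshold
searches, network simulations and GA populations all run through this one
code path; a single simulation is the B = 1 special case.

## Stimulation protocols

**Pulse (BAC-firing) task.** Four cases probe coincidence detection, with
amplitudes from the reference experiment: (A) an EPSP-shaped
("beta", normalized double-exponential) current of 1345 pA peak into the
distal compartment — subthreshold, deflecting the soma by roughly 15 mV;
(B) a 1150 pA / 5 ms somatic step — exactly one spike; (C) B followed by A
at a 5 ms delay — BAC firing, a three-spike burst; (D) a distal-only beta
current strong enough to burst by itself (threshold located on a 10 pA
grid). The beta kinetics are part of the protocol definition; this package
uses tau_r = 2 ms, tau_d = 8 ms, a plausible dendritic EPSC time course
chosen once, together with the genome fit, so that the four cases and the
documented thresholds come out as stated. A "burst" is >= 2 spikes whose
first inter-spike interval is below 25 ms (configurable).

**Prolonged task.** DC current pairs (I_s, I_d) held for 2 s; the rate is
the spike count over the full stimulus window (no transient exclusion —
documented choice, configurable by changing the window). Every grid point
is an independent batched simulation started from rest, so the 3 s
inter-stimulus rest period of the wet-lab protocol carries no information
here and is omitted. The working domain of the fitted neuron is
I_s in [0, 600] pA, I_d in [0, 1000] pA.

**Ca-activation criterion.** A point counts as Ca-active when the
activation product m_Ca * h_Ca exceeds 0.5 at any time during the
stimulus (default), or — alternative criterion, also available — when the
calcium concentration rises at least halfway from its baseline Ca_0 to the
K_Ca half-activation threshold Ca_th. Both are exposed because the
underlying event (the regenerative dendritic Ca spike) has no unique
scalar signature.

## The reference genome

The shipped parameter set (`caadex/data/reference_genome.json`, 34
parameters) was produced with the package's own fitting machinery — the
fitness suite below plus local stochastic refinement — so that the fitted
neuron expresses the documented phenotype at h = 0.1 ms:

* pulse task: 0 / 1 / 3 spikes in cases A/B/C, ~15 mV somatic deflection
  in A, distal-only burst threshold ~1830 pA;
* distal-only (I_s = 0) scan: calcium activation, with a firing-rate jump,
  appearing at I_d = 550 pA on a 10 pA grid;
* no calcium activation anywhere on the I_d = 0 row (somatic input alone
  must not ignite the hot zone), with BAP trains at somatic rates up to
  the domain maximum summing below the ignition threshold;
* apical-amplification peak rate below ~80 Hz over the domain, while the
  apical-drive preset exceeds 100 Hz and apical isolation stays well
  below the amplification range (its apical input no longer reaches the
  soma at all).

Getting these properties simultaneously constrains the genome strongly;
the load-bearing mechanisms are (i) a distal membrane fast enough that
the BAC coincidence window is a few milliseconds wide, (ii) a BAP charge
large enough to ignite the hot zone on top of a subthreshold EPSP but
small enough that BAP trains without apical input stay subignition, and
(iii) subthreshold adaptation shaping the somatic threshold difference
between brief pulses and sustained drive.

**Target AdEx.** The reference single-compartment AdEx
(`caadex/data/target_adex.json`) is derived from the fitted soma: the
distal passive load is folded into the leak as the series conductance
g_C g_Ld/(g_C + g_Ld) and the resting potential follows from
conductance-weighted reversals; spike parameters are copied. With somatic
input only the two-compartment neuron then tracks this AdEx closely
(Earth-Mover's-Distance comparison in the fitness suite), and with
g_C = 0 the reduction is exact — the somatic spike train equals the pure
AdEx train bit for bit, which the tests assert.

## Fitness suite and evolutionary loop

Each fitness component maps a measured error to exp(-|error|/scale) in
(0, 1] with a documented scale, so the global fitness is a plain sum and
is maximal when all targets are met. Groups: pulse-case spike counts;
calcium opens/closes/never-somatic-only/not-everywhere guards; AdEx
matching (1-D EMD between rate curves, rheobase difference, final rate,
CV of inter-spike intervals, capacitance); gain & linearity of the active
region (post-activation level, per-row R^2, monotonicity-violation count,
activation-jump presence); pathological-rate, somatic-voltage-floor,
distal-rheobase-window and rate-jump guards. The 1-D EMD is the L1
distance between cumulative sums of mass-normalized curves times the grid
spacing (equal to the Wasserstein-1 distance; tested against an
independent implementation). A failed simulation scores the documented
worst value rather than aborting the generation.

The GA is generational with tournament selection (size 3), uniform
crossover (per-gene rate 0.5), per-gene Gaussian mutation (sigma = 10% of
the bound width, rate 0.2), clipping to bounds and elitism of one, so the
best-fitness trace is non-decreasing; runs are deterministic per seed.
Population 100 x 100 generations reproduces the published optimization
scale; tests and the acceptance script use reduced sizes (population
10-12, 5-6 generations, coarse scan grids with 400-500 ms stimuli) chosen
so the whole suite stays lightweight while the recovery property —
re-finding a 3-parameter perturbation to within 5% of the reference
global fitness across 3 seeds — is still informative.

## Brain-state presets

Neuromodulation proxies transform the genome: apical amplification (AA)
is the fitted genome itself; apical isolation (AI) sets b = 200 pA,
g_C = 0 and lowers both leak reversals by 5 mV (optionally replacing the
somatic block by the target AdEx, which makes the reduction exact);
apical drive (AD) sets b = 10 pA and lowers both reversals by 2 mV. The
transforms return copies and touch nothing else, which a test audits
field by field.

## Balanced-network benchmark

The network is Brunel-like: 4:1 excitatory/inhibitory populations, fixed
in-degree K per neuron (4/5 excitatory, 1/5 inhibitory presynaptic
partners drawn uniformly without self-connections — the literal reading
of "K input synapses per neuron"), inhibitory weight -g_ratio * J_exc,
conductance-based AMPA/GABA synapses on the soma, a fixed 1.5 ms delay,
and an external excitatory Poisson drive (the noise process, modeled as
homogeneous Poisson input per neuron). The published full-scale benchmark
(10000 + 2500 neurons, K = 1250, ~1.23 Hz) does not include the synaptic
weights, so the package ships a calibration routine instead of pretending
those constants are known: bisection on J_exc (rate decreases with J in
the inhibition-dominated regime) until the mean rate hits the target.
The shipped example calibrates a scaled-down 200 + 50 network (K = 50) to
1.23 +- 0.1 Hz and reports the mean CV-ISI as the irregularity summary.
Wall-clock timing comparisons are out of scope (hardware-bound).

## ThetaPlanes

Masks: M+ = Ca-active points, M- = inactive points with rate > nu_low
(default 10 Hz — at lower rates a 50 ms stimulus-scale percept induces at
most one plasticity-relevant spike, so precision there matters little);
both masks drop the band I_s > I_th (default 500 pA) to avoid
edge-of-domain curvature. Planes are ordinary least squares
(scikit-learn's LinearRegression) over each mask. The boundary line is an
OLS fit to the lowest active I_d per I_s column (columns without active
points are skipped, never imputed); the rheobase line is the zero locus
of the low plane. Heaviside convention Theta(0) = 1: boundary points
belong to the active side. The fit-error report compares each region
against its own plane with membership taken from the masks, so
one-grid-cell misclassification at the boundary does not inflate the
reported plane errors.

## Synthetic data and what the tests show

Test fixtures are generated programmatically: exactly piecewise-planar
surfaces with Heaviside activation masks (ThetaPlanes round-trip
recovery), random passive trees with closed-form or matrix-exponential
voltage responses (solver oracles), seeded Poisson spike trains
(statistics), and scaled-down network specs. These emulate the structure
of the real objects but none of the biological variability — real
dendrites are not two RC compartments, real calcium spikes are shaped by
many channel types, and real rate surfaces carry trial-to-trial noise
that the deterministic DC scans lack. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms and the fitted
phenotype of this model, not the biological fidelity of any particular
parameter value.

## Known limitations

* One calcium hot zone per tree (the engine refuses more); multiple
  NMDA-capable passive subunits are supported.
* No adaptive time stepping and no spike-time interpolation; at h = 0.1 ms
  near-coincident threshold crossings resolve to grid points.
* The single-linearization CN step is robust but first-order in the
  immediate vicinity of spike ignition; between spikes it is second-order.
* The distal-only burst threshold and the 550 pA activation point are
  properties of the shipped genome at h = 0.1 ms; other step sizes shift
  them by up to one 10 pA grid cell.
* Process-level parallelism is not implemented; all batching is
  vectorized within one process, and results are independent of batch
  composition.
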