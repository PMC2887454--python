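# Methods

This note records the scientific conventions, numerical choices and
known limitations of the `nml1` package in one place. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Unit systems

A document declares exactly one unit system, *SI Units* or
*Physiological Units*; mixing systems inside one file is a validation
error. The dialect names the Physiological family only loosely, so the
full table is fixed here as a package convention (`nml1.units` is the
single authoritative source):

| dimension            | SI unit  | Physiological unit |
|----------------------|----------|--------------------|
| voltage              | V        | mV                 |
| time                 | s        | ms                 |
| length (geometry)    | m        | µm                 |
| specific capacitance | F/m²     | µF/cm²             |
| specific conductance | S/m²     | mS/cm²             |
| conductance          | S        | µS                 |
| current              | A        | nA                 |
| concentration        | mol/m³   | mM (identical)     |
| temperature          | °C       | °C                 |
| resistivity          | Ω·m      | kΩ·cm              |

µS and nA were chosen for the absolute electrical quantities because
µS·mV = nA, so the simulator's internal arithmetic (mV, ms, µm, µS, nA,
nF, MΩ) needs no conversion factors. Every in-memory object stores
Physiological magnitudes; conversion happens only at the XML boundary,
as a single multiplication by an exact power of ten per dimension
(hence bijective to well below the 1e-12 tolerance the tests assert).

## Morphology conventions

* `fraction_along` is 0 at a segment's proximal point and 1 at its
  distal point.
* Path distance is measured from the root segment's proximal point. A
  spherical soma — a single-segment cable whose proximal and distal
  points coincide with positive diameter — has zero arc length and
  therefore contributes nothing to path distance. This is the
  unambiguous, testable choice; documents relying on a different soma
  convention will see distances offset by the soma radius.
* Zero-length segments are tolerated only as spherical somas; anywhere
  else they are integrity findings, as are discontinuities (an explicit
  proximal point more than 1e-6 µm from the parent's distal point),
  isolated elements, and parent cycles.
* Per-group quantities (capacitance, resistivity) resolve by "specific
  group label wins over `all`"; with several specific labels the first
  declared wins.

## Recompartmentalization

A cable with `internal_divisions = n` maps onto `n` equivalent
cylinders. The cable is split into spans of equal electrotonic weight,
implemented as equal increments of ∫ ds/√r(s) (the length-constant
proxy λ ∝ √r; membrane conductance is not known at morphology level).
For untapered cables this reduces to NEURON's equal-arc-length `nseg`
spans. Within a span all integrals are evaluated in closed form for
linearly tapering radii (frustum slant area; axial integral
l/(π·r_a·r_b)), so the three cable totals — length, lateral area,
integrated axial resistance — are conserved to machine precision, and
the tests assert 1e-9 relative.

A single cylinder has two free parameters (length, radius) but three
conservation targets, so each output compartment carries an *explicit*
axial-resistance contribution alongside its geometry: the length is the
span's exact arc length, the radius is chosen so 2πrL equals the span's
frustum area exactly, and the carried resistance is the exact integral.
The residual between the geometric cylinder's resistance (L/πr²) and
the carried value is reported per compartment (`axial_residual`) rather
than silently absorbed. This residual-reporting construction is this
package's design choice for an under-specified mapping.

Radii are clamped to 1e-6 µm inside 1/r integrals to keep degenerate
tapers finite.

## Rate laws and channels

The canonical ChannelML triad, with A in ms⁻¹, k in mV⁻¹ (sign carries
direction), d in mV and x = k(v−d):

* exponential: A·eˣ
* sigmoid: A/(1+eˣ)
* exp_linear (linoid): A·x/(1−e⁻ˣ), with the removable singularity at
  v = d filled by its limit A inside a ±1e-7 mV guard band.

In the XML the `scale` attribute is the voltage 1/k, matching the
ChannelML attribute convention. Arbitrary voltage/ligand/temperature
dependence (e.g. Ca²⁺-gated BK/SK rates) uses the generic-expression
form: a small arithmetic grammar over `v`, `ca`, `celsius` with
+ − × / ^, exp, log, sqrt, pow and parentheses — parsed by a
recursive-descent parser, never host-language evaluation.

Q10 scaling multiplies rates by `q10_factor^((T−T_exp)/10)` and is the
identity at the experimental temperature; a run with no configured
temperature disables it.

Markov schemes propagate occupancies with the exact matrix exponential
of the generator (rates frozen over the step), so the occupancy vector
remains a probability vector to 1e-12 for any dt; the two-state scheme
reproduces the HH gate trajectory, which the tests assert as the
"special case" equivalence.

The Ca²⁺ pool influx scaling φ is defined per compartment in
mM/(nA·ms), with inward calcium current taken positive; a per-area or
per-volume geometry factor, where needed, must be folded into φ. This
is a documented package convention.

## Synapses

Conductance waveforms are peak-normalized: `max_conductance` is the
literal single-event peak, so voltage-clamp amplitude comparisons read
directly off the parameter. The normalization constant is closed-form
for a single decay (peak at t* = τ_rτ_d/(τ_d−τ_r)·ln(τ_d/τ_r)), the
alpha-function limit when rise equals decay, and a bounded numerical
maximisation for two or three decay components. Events superpose
linearly; the simulator truncates each event's contribution after
rise + 10× the slowest decay.

Short-term plasticity follows the resource/utilisation two-variable
formulation. Between spikes x recovers toward 1 with τ_rec and u decays
toward U with τ_fac; at a spike u ← u + U(1−u) (only when τ_fac > 0),
release = u·x, then x ← x − u·x. The τ = 0 special cases are exact:
τ_rec = 0 restores x to 1 instantly, τ_fac = 0 pins u at U, and with
both zero every spike releases exactly U — the event conductance is
scaled by release/U so the no-plasticity configuration reproduces the
base synapse identically. The depressing (τ_rec = 120 ms) and
facilitating (τ_fac = 300 ms) protocol configurations are provided as
fixture constructors; since the protocol's U and base amplitudes are
not pinned down externally, the fixtures use documented values
(U = 0.5 depressing/control, U = 0.1 facilitating) and the tests assert
the monotonicity and fixed-point contracts, not absolute amplitudes.

STDP is the additive, all-to-all trace form: each stream carries an
exponentially decaying trace anchored at its own last event; a pre
(post) event samples the opposite trace and depresses (potentiates) by
a∓·w_max·trace, with the weight hard-clipped to [0, w_max] after every
update. The brute-force O(n²) pairwise replay in the tests is the
independent oracle.

NMDA block uses B(V) = 1/(1+η[Mg]e^(−γV)); the fixture defaults
(η = 0.28 mM⁻¹, γ = 0.062 mV⁻¹, 1 mM Mg²⁺) are package conventions in
the range conventional for cortical modelling, not values taken from a
specific dataset.

## The solver

* Default integration is a first-order implicit (backward-Euler)
  voltage solve over the whole compartment tree with channel
  conductances frozen at the current gate states, followed by exact
  exponential gate updates toward m_∞(V_new) and exact first-order
  Ca²⁺-pool updates. An explicit exponential-Euler mode is deliberately
  not offered — it requires time steps orders of magnitude smaller for
  the same accuracy. A semi-implicit second-order (Crank–Nicolson,
  θ = ½) option exists for convergence studies; the passive-charging
  tests confirm first-order error halving and the CN accuracy gain.
* Symmetric convention: voltage at compartment centres; the link
  between adjacent compartments is the sum of their half-resistances.
  Asymmetric convention: all of a compartment's axial resistance on its
  proximal side; voltage at the distal node. Node placement is fixed
  here and documented because the format itself states only where the
  resistance sits.
* Branch points: axial conductances sum at the junction node; no extra
  junction capacitance. A child cable attaches to the parent
  compartment containing its parent segment's distal end; mid-cable
  attachment uses that compartment's half-resistance under the
  symmetric convention (an approximation that vanishes with refinement).
* Voltage clamps replace the node's row in the linear system; the clamp
  current is recovered as the residual of the unclamped balance
  (capacitive + ionic + synaptic + axial − injected).
* Spike detection: upward crossings of a configurable threshold
  (default 0 mV) with linear interpolation between samples.
* The cross-run metric reports equal-count status and the maximum
  order-matched spike-time difference as a percentage of run time; when
  counts differ the discrepancy is reported as undefined (None) rather
  than silently matched — resolving transient count mismatches is left
  to the caller.
* Divergence guard: |V| > 1000 mV raises an error naming dt.
* Determinism: identical document + config + seed give bit-identical
  recordings. Every random stimulus draws from a generator keyed by
  (seed, stimulus name, target), so adding a recording or another
  stimulus never perturbs an existing noise stream.

## Fixtures: what they emulate and what they do not

The generator produces the study conditions used throughout the tests:
squid-axon HH kinetics (gNa 120, gK 36, leak 0.3 mS/cm²; ENa +50,
EK −77, E_leak −54.3 mV, rest −65 mV) on a point cell and on a
ball-and-stick cell (20 µm soma sphere, five 20 µm × 2 µm dendrite
segments, 40 internal divisions by default — fine enough that both
compartment conventions converge); a passive pair coupled by a 300 pS
gap junction with a 0.19 nA step; a passive voltage-clamp compartment
(leak 3.0e-9 mS/µm², capacitance 1e-8 µF/µm², i.e. 0.3 mS/cm² and
1 µF/cm², giving τ_m = c/g = 10/3 ms) receiving AMPA-only or NMDA-only
events at −80 and −20 mV holding; a spontaneously active
integrate-and-fire cell driving control/depressing/facilitating STP
synapses; and a 56-cell, five-population layer 2/3 skeleton
(20 + 6 + 10 + 10 + 10 cells placed uniformly at random in a cylinder
of radius 300 µm and height 200 µm, gap junctions of 2.1 nS = 0.7 × 3 nS
within each population, representative AMPA/GABA projections between
populations, and random current drive of 0.15–0.25 nA to the
fast-bursting cells, 0–0.2 nA to the low-threshold-spiking cells and
0–0.02 nA to the basket and axo-axonic cells).

The network fixture's cells are placeholder integrate-and-fire point
neurons: the full 22-conductance complement of the original cortical
cell models lives in external model files and is out of scope, so
passing tests demonstrate the format, instantiation, coupling and
execution machinery — not the electrophysiology of the original
network. Likewise the synthetic 173-cable / 2243-segment morphology
used in scale tests is procedurally generated (and labelled synthetic);
it exercises document size, not real dendritic geometry.

## Problem sizes used

The shipped test suite and acceptance script run desk-scale problems:
the convergence study uses the 41-compartment ball-and-stick cell for
200 ms at dt = 0.005 ms per convention; temporal-convergence checks use
the point cell for 60 ms over dt ∈ {0.02, 0.01, 0.005, 0.0025} ms; the
compactness check serializes a 10,000-cell population; the network
fixture runs 56 cells. These sizes were chosen so the whole suite
completes in a few minutes on one core while still exercising every
code path at convergent discretisation.

## Known limitations

* The XML dialect is a single-namespace profile of NeuroML v1.8.1 with
  a structural-envelope XSD; documents from other v1.x emitters that
  use per-component namespaces parse only if restructured. Unknown
  elements are preserved opaquely rather than understood.
* Camera-lucida MorphML elements (freePoints, features), the HDF5
  NetworkML dialect, simulator-script generation, stochastic
  single-channel placement and Nernst/GHK reversal computation are out
  of scope.
* `node_id` is parsed and preserved for partition export but never
  affects simulation semantics.
* Template-based networks support {box, cylinder} × uniform random
  placement and three connection rules; minimal-separation placement is
  off by default (overlapping somata are not forbidden) and uses
  rejection sampling capped at 10⁴ retries per cell.
* The dense tree solve is appropriate for the package's desk-scale
  networks (tens of cells, tens of compartments); very large models
  would need a sparse/Hines solver.
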