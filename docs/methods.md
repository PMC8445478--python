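# Methods

## The neuron model

All models are built from non-spiking leaky-integrator ("toy model")
neurons, τ·dy/dt = −y + f(Σ wᵢxᵢ + b), with all quantities
de-dimensionalized (time included).  τ sets the unit's slowness; as
τ → 0 the unit becomes a static perceptron, and the same is true of the
steady state under constant input.  Three activations are provided: a
symmetric piecewise-linear clip to [−1, 1] (a piecewise stand-in for
tanh), a positive clip to [0, 1], and the logistic sigmoid.  The
discrete-time form used by the ESN follows from a backward-difference
discretization with step T_s:

    x[n+1] = (I − A) x[n] + A f(W_res x[n] + W_in u[n] + b),

with per-unit leak rates α = (1 + τ/T_s)⁻¹ on the diagonal of A, so
α ∈ (0, 1] and α = 1 is memoryless.  Weight matrices are stored with
rows indexing targets (the recurrent drive is `W @ y`).

Integration is explicit forward Euler with default dt = 0.01
de-dimensionalized units.  This is the natural companion of the
difference form above; the suite checks that halving dt moves
threshold-crossing times by less than 0.05.  Forward Euler requires
dt ≲ τ; the simulator raises a divergence error naming the first
non-finite step rather than returning garbage.  Initial states default
to zero.  Stimuli are rectangular pulses, active on [onset,
onset + duration), and overlapping pulses on a channel *add* — which is
what the amplitude-ratio scans rely on.  Threshold crossings are located
by linear interpolation between samples; a sample exactly at threshold
counts as a crossing in the direction of the next movement, and a flat
run at threshold produces no event.

Fixed points of piecewise-linear circuits are enumerated exactly by
solving the affine system on every combination of linear pieces and
keeping self-consistent solutions; stability follows the eigenvalues of
the local Jacobian.  For the logistic activation only single units are
supported (grid bracketing plus Brent refinement).

## Backward masking

A single neuron with self-feedback w₁ = 1.5, input weight w₂ = 1.5,
τ = 1 and the symmetric clip is bistable: stable equilibria at y\* = ±1,
an unstable one at 0.  The undriven flow is the negative gradient of a
piecewise-parabolic potential V(y) (closed form in `potential_V`, fixed
by V(0) = 0) whose minima are the two percept states.  A trial applies a
unit-amplitude prime of duration 0.5 and a negative mask; "settling" is
simulated for 100 time units after the last stimulus and the outcome is
labelled by the terminal state (|y| > 0.9, else undecided).  Outcome is
monotone in both mask delay and mask amplitude (at most one switch
each), which the suite asserts.

## Order reversal

Four units in two chains (a₁→a₂, b₁→b₂) with τ = 2 for the first units
and τ = 10 for the outputs, input and chain weights 1, biases −0.5, the
positive-clip activation, inhibitory cross-couplings of −2 from each
input to the *opposite* chain's output, and a perception threshold of
0.5.  Each unit also carries excitatory self-feedback so that a
transient pulse latches; with bias −0.5 latching requires a self-weight
strictly above 1.5, and the packaged default is 2.0 for all four units.
The reversal-region extent is insensitive to this choice (self-weights
1.75–3.0 all give bounds within ±10–12), so it is exposed as a parameter
but not treated as a tuning knob.

A trial drives x_a and x_b with width-10 pulses separated by Δt_in
(the earlier pulse is always placed inside the simulated window) and
reads off the first up-crossings of y_a2 and y_b2.  The interval scan
reports the maximal contiguous region around Δt_in = 0 where
sign(Δt_out) = −sign(Δt_in); with unit amplitudes and dt = 0.01 the
measured region is [−11, +11].  The circuit is exactly symmetric under
exchanging the two branches, which makes the scan antisymmetric — the
suite asserts both the exact trajectory-level equivariance and the
numerical antisymmetry.  The 2-D amplitude-ratio scan holds
amp_a + amp_b = 1.5 and propagates missing crossings as NaN so it can
cover extinction regimes.

## Phi circuit

Fifteen units: three chains of four (relay → two intermediates →
output), one per "pixel", plus one primer per chain.  The a and c chains
are mirror copies of b.  Only the relative structure of this circuit is
published; the numeric parameters are packaged defaults stored in
`src/phidyn/data/phi_circuit_default.json` (versioned) and are **not**
claimed to equal any published values.  The defaults: chain weights 2.0,
biases −0.5, chain τ ascending 1, 2, 3, 4 along the chain (so percepts
propagate with delay and decay after the stimulus); primers with τ = 2,
drive weight 2.0 from their chain's relay, self-feedback 0.9 and *no*
negative bias, giving fast activation and a slow exponential decay with
effective time constant τ/(1 − w_self) = 20 — about five times the
output τ; primer→adjacent-output couplings of 0.8.  Since a saturated
primer contributes at most 0.8 and the output bias is −0.5, a single
primer alone can drive an undriven output only to 0.3 < 0.5: the ghost
requires *combined* priming.  `build_phi_circuit` rejects parameter sets
violating this invariant.

With width-10 unit pulses on x_a and then x_c, the packaged defaults
give: a ghost on y_b for onset intervals up to ≈ 25, none from ≈ 30 on;
when present under fast stimulation the ghost's onset falls after y_a's
threshold up-crossing and before y_c's; and simultaneous stimulation of
both outer pixels also produces the ghost — a documented failure mode of
this hand-built model (a real observer would see the two outer dots
only).  The originally reported ghost time (near t = 115 on that model's own
time axis) depends on the unpublished weights and stimulus schedule and
is deliberately not a target of this package.

## ESN and the color phi phenomenon

Reservoirs follow the published recipe: N = 200, W_res ~ N(0, 1) with
80% of entries zeroed then rescaled to spectral radius 0.9 (achieved to
1e-6), W_in ~ N(0, 0.5) at sparsity 0.8, α ~ U(0.1, 0.3), logistic
units.  The bias distribution is only described as "a constant random
bias vector"; the package uses N(0, 0.5), matching the input scale, and
exposes it in the config.  All draws come from independent substreams
spawned from one seed, so any component is reproducible on its own.

The readout solves X W ≈ Y_desired by minimum-norm least squares
(`numpy.linalg.lstsq`; ridge-stabilized normal equations as a numerical
fallback), where X stacks the reservoir states with a constant-1 column.
A 200-step washout is excluded from the regression by default; passing
`washout=0` gives the plain textbook normal-equations fit.

Training protocol (timing is published only graphically; these are the
package defaults, all exposed in config): pulses of 120 steps separated
by 180 quiet steps so the reservoir settles between conditions; total
length K = 20 000 with valid single-channel conditions up to step 13 000
and invalid multi-channel conditions (all 15 channel pairs plus the
all-on condition, cycled) after; desired outputs mirror the stimulus
with a 20-step onset shift and are identically zero for invalid
conditions.  Valid conditions are drawn uniformly, rejecting any draw
that would form an opposite-color left↔right transition with its
predecessor — the CPP stimulus is thereby excluded from training, which
the suite verifies by exhaustive scan.  The probe alternates left-red
and right-blue 120-step pulses with gaps shrinking 150 → 0 by 10, never
overlapping.  Detection scans a 200-step window after each jump for the
conjunction: middle output > 0.5, destination-position output < 0.5,
destination-color output > 0.5 (the color requirement can be disabled
with a flag).

### What the screen measures, and a caution

`screen_population` derives one seed per network from a master seed,
shares a single training sequence and probe across the population, and
streams per-network rows (CPP flag, detection step, α summary, E/I
ratio, LDFF count, top eigenvalue) to CSV.  Characteristics reuse the
eigenvalues already computed during spectral-radius scaling.  The
comparison of characteristics between networks with and without the CPP
is purely descriptive (fixed 50-bin histograms and a total-variation
distance); no hypothesis test is attached, since the interesting claim
is the *absence* of a clear difference.

At the packaged defaults the measured CPP fraction is ≈ 73% of 1000
networks — far above the originally reported 1.87% of 100 000.  The
package reports this honestly rather than tuning toward the published
number, and the discrepancy is diagnosed in the test suite's terms: with
long settled conditions the training state matrix is numerically
low-rank (condition number ~1e8 with a smooth singular spectrum), the
exact least-squares readout is correspondingly enormous (coefficient
norms ~1e5), and the fast probe jumps — input patterns deliberately
absent from training — drive the linear readout far out of its
interpolation regime, to outputs of magnitude 10³–10⁴ that satisfy the
detector's threshold conjunction in most networks.  This is not a
protocol-timing artifact (pulse/gap settings of 30/70, 40/60 and 60/90
give fractions of 0.70–0.83, with every network showing |Y| > 5
excursions) and truncated-SVD readouts still explode out of
distribution.  The CPP *signature itself* is reproduced — individual
networks show the middle-then-color-before-position pattern inside
post-jump windows — but the population *rate* is dominated by readout
conditioning, and under this package's protocol the published rate is
not recovered.  Treat absolute fractions from `screen_population` as
protocol-specific; the relative trends across hyperparameter sweeps and
the per-network qualitative demonstrations are the robust outputs.

### LDFF counting

A connection i → j counts as a positive long-distance feedforward motif
when the direct weight is positive *and* a positive indirect path
exists.  The published definition does not bound the indirect path
length; the default counts two-hop paths i → k → j (k ∉ {i, j}, both
weights positive), the shortest possible reading, and a
`mode="reachability"` variant accepts any all-positive path of length
≥ 2.  Both are validated against brute-force enumeration on random
matrices up to 6×6.

## Problem sizes and determinism

The suite runs the circuit analyses at full scale (dt = 0.01, the
published grids) and the population screen at n = 1000 networks — the
scaled-down counterpart of the full 100 000-network experiment, chosen
so a complete run stays in the minutes range on a single CPU; the Wald
interval at n = 1000 is wide enough (±2.7 percentage points at p = 0.02)
that a protocol reproducing the published regime would still be
distinguishable from zero.  Every random quantity is a pure function of
one master seed (per-network and per-matrix substreams are spawned
deterministically), so identical seeds give bitwise-identical screens.

## Known limitations

* Spiking dynamics, noise-driven (drift) variants, adaptive ODE solvers
  and the plasticity rule sketched for future work are out of scope.
* The phi circuit's numeric parameters are package choices satisfying
  the qualitative contracts, not published values; quantities that
  depend on them (ghost times, the exact critical interval) are
  illustrative.
* The inhibitory input→output connections that would remove the phi
  model's simultaneous-stimulation failure mode are noted but not
  implemented, matching the original model's scope.
* The absolute CPP population fraction is protocol- and
  conditioning-sensitive (see the caution above).
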