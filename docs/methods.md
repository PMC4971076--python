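# Methods

`spikeloop` couples continuous (robotic) and spiking (neural) signal
domains in a single process: encoders turn bounded analog signals into
spike trains, decoders turn spike trains back into analog signals,
adapters reshape and normalize between sensor and neuron dimensions,
and a tick-based engine schedules all of it with the buffered-port
semantics of co-simulation middleware.  This note records the models,
their assumptions, the free parameters and their defaults, and the
numerical choices.

## Signal model and conventions

All times are seconds.  Continuous signals are sampled on uniform grids
and, at codec boundaries, are dimensionless in [-1, 1]; out-of-range
drive is clipped (robotic signals transiently overshoot after
normalization) and the clip is logged.  Simulation windows are
half-open `[t_start, t_stop)`, so concatenating windows never
double-counts a boundary spike.  Spike trains are per-neuron sorted
time lists; unsorted construction input is sorted, not rejected.

## Rate codecs

A drive value `I` maps to a firing rate

    rate(t) = v_min + (v_max - v_min) * (1 + I(t)) / 2,

so `I = -1` gives `v_min` and `I = +1` gives `v_max` (both free
parameters, Hz).  The interspike interval at constant drive is
`1/rate`.

**Regular encoder.**  Spikes are produced by rate integration (time
rescaling): the cumulative intensity `Phi(t) = ∫ rate dt` is
accumulated over the piecewise-constant sampled rate and a spike is
emitted at every integer crossing, with the crossing time interpolated
inside the sample.  For constant drive this reproduces `ISI = 1/rate`
exactly and the spike count over `T` is `floor(rate*T)` up to one
boundary spike.  It is causal and well defined when the drive changes
mid-interval, which a literal "ISI computed at spike time" rule is not.
Integrator phases are staggered uniformly across the population
(`Phi_n(0) = n/N`), so identically driven neurons tile the interval
instead of firing in lockstep; a population average of filtered
activities then approximates `rate * tau` with ripple suppressed by
1/N.  Single-neuron behavior is unchanged.

**Poisson encoder.**  The same cumulative intensity drives an
inhomogeneous Poisson process by inversion: unit-rate exponential
increments are accumulated in rescaled time and mapped back through
`Phi`.  This is exact for piecewise-constant rates (no `rate*dt`
discretization bias and no thinning rejection loop), reduces to exactly
exponential interspike intervals at constant drive, and is reproducible
from a seed (one child stream per neuron, so the train of neuron `n`
does not depend on how many neighbours it has).

An optional `align_to_grid` flag snaps emitted spike times up to the
next sample for parity with grid-based simulators; by default spike
times are continuous.  Refractoriness is deliberately omitted from the
rate codecs.

## NEF ensembles

A stimulus vector `I` (inside the unit ball) is encoded by a
heterogeneous LIF population with tuning curves

    a_n(I) = G[ gain_n * (e_n . I) + bias_n ],
    G(J)   = 1 / (t_ref - tau_m * ln(1 - 1/J))   for J > 1, else 0,

with `tau_m = 20 ms`, `t_ref = 2 ms` (the rate-mode LIF response).
Encoders `e_n` are drawn uniformly on the unit sphere (±1 in one
dimension), maximum rates uniform in [100, 200] Hz and intercepts
uniform in (-1, 1) — the unstated tuning distributions default to the
standard NEF reference choices.  Gain and bias are solved per neuron so
the curve crosses threshold (0 Hz) exactly at the intercept and reaches
the drawn maximum rate at projection 1; maximum rates at or above
`1/t_ref = 500 Hz` are infeasible and rejected.

**Decoder training.**  Linear decoders solve the ridge problem
`phi = argmin ||X - A phi||^2 + N sigma^2 ||phi||^2` with
`sigma = 0.1 * max(A)` by default — decoding noise proportional to peak
activity, the standard NEF scaling; the regularization constant is
exposed.  With 100 neurons, 200 training points and a held-out
500-point grid, the mean reconstruction RMSE is ≈ 0.5% of the stimulus
range radius (about 1% is the usual quote for this configuration; the
noiseless rate-mode evaluation sits somewhat below it).  With zero
regularization a singular normal system raises rather than silently
pseudo-inverting.

**Spiking encoding.**  Each neuron integrates the normalized membrane
equation `tau_m dv/dt = J(t) - v` (threshold 1, reset 0) exactly over
each 1 ms step, with two corrections that make the emitted rate match
the rate-mode tuning curve to a few percent: the threshold-crossing
time is interpolated in closed form inside the step, and the refractory
interval starts at the interpolated crossing (partial-step remainders
carry across step boundaries).  Without the interpolation, ISIs
quantize to the step and rates at 100–200 Hz would run 5–15% high.

## Linear decoder

Spike trains are filtered with the causal exponential kernel
`k(t) = exp(-t/tau_dec)`, one unit jump per spike (the kernel is
unnormalized; gain lives in the readout weights).  The filter is
implemented as a first-order recursion — per-sample decay
`exp(-dt/tau_dec)` plus each spike's kernel value at the first sample
at or after it — which equals the direct kernel sum to machine
precision.  A spike exactly on a grid point contributes from that
sample (k(0) = 1).  Readout channels are `z_k = sum_n a_n(t) phi_nk`.

Two numerical facts worth recording: (1) the sample mean of a filtered
stationary train is `rate * tau_dec * x/(1 - e^-x)` with `x =
dt/tau_dec`, i.e. it carries a `+dt/(2 tau_dec)` sampling bias relative
to the continuous-time mean (+5.1% at the 1 ms grid with a 10 ms
kernel), so continuous-time comparisons sample the trace finely
relative to `tau_dec`; (2) filtered activities are non-negative, so
readouts fitted against signals with negative excursions need an affine
term — `fit_readout` fits an intercept by default and stores it as the
readout bias, while the NEF encoder/decoder pairing needs none (its
tuning curves span both preferred directions).

## Adapters

Adapters map `m` input channels to `n` drive channels after optional
normalization.  `broadcast` assigns every output the *mean* over inputs
(the mean, not the sum, keeps the [-1, 1] encoder contract),
`hemisphere` averages the first ⌈m/2⌉ channels onto output 0 and the
rest onto output 1 (left/right split of a scan, beam 0 leftmost),
`matrix` is an arbitrary linear map, `identity` passes through.  Range
sensors are proximity-coded as `I = 1 - 2 d / d_max` (touching → +1,
free space → -1): obstacle avoidance wants near obstacles to drive
high rates.  The coding and `d_max` (default 5 m) are configurable.

## Spiking-network simulator

Delta-synapse LIF neurons advance by exact integration: the
subthreshold propagator

    V <- E_L + (V - E_L) e^{-dt/tau_m} + (I R)(1 - e^{-dt/tau_m}) + sum(jumps)

is error-free between events; synaptic events are instantaneous voltage
jumps applied at step boundaries.  Defaults (the common delta-synapse
point-neuron set): `tau_m` 10 ms, `V_th` -55 mV, `V_reset = E_L` -70 mV,
`C_m` 250 pF, `t_ref` 2 ms, `dt` 1 ms; rheobase 375 pA.  Parrot
neurons repeat each input spike after a delay, preserving multiplicity
— the minimal "neural simulator in the loop" load.

**Balanced random network.**  80% excitatory / 20% inhibitory neurons,
fixed in-degree of `0.1 * N` split proportionally between populations
(fixed in-degree rather than Bernoulli connectivity for variance
control), excitatory weight `w = 0.001 mV`, inhibitory `-g w` with
`g = 4`, delay 1 ms.  The recurrent weight is deliberately negligible:
activity is set by independent per-neuron external Poisson drive, which
keeps the mean rate comparable across network sizes.  The drive rate is
a free parameter with no published value; the default `ext_rate =
12,666 Hz` at `w_ext = 0.1 mV` was calibrated by bisection
(`calibrate_external_drive`, shipped) so the uncoupled network fires
≈ 5 spikes/s.  In this regime the raster is asynchronous (mean pairwise
10 ms spike-count correlation < 0.01) and irregular (mean ISI CV
≈ 0.8).  Summary estimators: rate = spikes/neuron/T; CV over neurons
with ≥ 5 spikes; correlation over a ≤ 200-neuron sample with
zero-variance rows excluded.

## Pipeline engine

A pipeline is a graph of components with typed ports (`continuous`
vectors with zero-order hold; `event` lists of `(neuron, time)`),
advanced on a global tick (`music_dt`).  Every connection buffers its
data for exactly one tick: a value produced at tick `k` is visible at
tick `k + 1`.  Consequences, both tested: feedback loops are always
well defined (every hop is buffered, so zero-delay cycles cannot be
expressed), and the step-response latency of a chain of `c` connections
is exactly `c * music_dt`, linear in the tick period.  Component tick
periods must be integer multiples of `music_dt`.  Spike counts are
conserved per connection and reported.

Two timing quantities are reported and deliberately kept distinct: the
*latency* is simulated-time (architectural: buffer hops × tick, plus
stimulus quantization) and therefore reproducible anywhere, while the
*real-time factor* `RTF = t_sim / t_run` is the wall-clock performance
of this process on this machine, measured around an explicit
build/run barrier, with `t_total = t_build + t_run + epsilon`.
Absolute wall-clock numbers from other hardware are not targets.

Configs are INI-style: top-level `music_dt`, one section per component
(`kind =`, `tick =`, parameters), and `connect src.port -> dst.port
[width]` lines; widths are validated against the declared ports, and
dangling endpoints, type mismatches, disconnected graphs and unknown
kinds are rejected with specific errors.

## Vehicle environment

The robot is a disc with unicycle kinematics driven by `(v, omega)`
commands — the skid-steer platform reduced to the command pair it
exposes.  Constant commands integrate exactly along circular arcs
(reducing to the straight-line update as `omega -> 0`), so there is no
integrator drift; commands are zero-order held between 20 Hz updates,
and there is no inertia or wheel slip.  A pose whose signed clearance
falls below the robot radius does not move (v forced to 0, collision
flagged and counted).  The laser has 100 beams over a 180° field of
view centered on the heading (FOV unpublished; configurable), 5 m
maximum range, 20 Hz updates, exact ray–segment and ray–circle
intersections, beam 0 leftmost.

**Braitenberg Vehicle III ("Explorer").**  The shipped demo closes the
loop with six components at `music_dt = 50 ms` (the 20 Hz sensor/motor
rate): environment → hemisphere adapter with proximity coding →
two-neuron regular rate encoder (0–100 Hz) → two parrot neurons →
exponential-filter decoder (`tau_dec` 100 ms) → motor wiring → back to
the environment.  The wiring is

    v     = max(v0 - k_v * (aL + aR), 0),
    omega = k_omega * (aR - aL),

so a nearer LEFT obstacle (higher `aL`) yields `omega < 0` — turn
right, away — and symmetric head-on activation slows the vehicle to a
stop rather than hitting the wall.  Gains (`v0` 0.4 m/s, `k_v` 0.12,
`k_omega` 0.9) and the arena (12 × 12 m walled box, three circular
pillars, start pose (2, 2) heading 45° with seed-controlled jitter
±0.5 rad) are package defaults documented here, not published values;
the demonstration's contract is behavioral — obstacle avoidance by two
neurons, zero collisions — not a specific trajectory.  The six-hop loop
gives an architectural reaction time of 300 ms, well inside the ~12 s
it takes to cross the 5 m sensing horizon at cruise speed.

## Synthetic data

No external data exists; all inputs are generated.  The fixture
generators (constant, step, sine, ramp, seeded random walk) cover the
drive regimes the codecs see in the closed loop: the step fixture is
the latency probe (a discontinuous switch from minimum to maximum
sensor range), the sine exercises codec tracking, the random walk gives
reproducible rough drive.  The laser scanner provides the only
"sensor-like" data.  What the fixtures do *not* emulate: sensor noise,
dropout, quantization, or nonstationary dynamics of real robots — so
passing tests demonstrate correctness of the conversion and scheduling
machinery and the behavioral viability of the control loop, not
robustness to real sensor pathologies.

## Problem sizes and runtimes

Chosen so the default suite runs in well under a minute of simulated
workload per property: NEF accuracy uses 10 ensembles of 100 neurons;
codec fidelity uses 100 s of a 50 Hz Poisson train; network properties
use N ∈ {1000, 2000, 5000} for 10 s at 1 ms resolution; the vehicle
demonstration runs 10 seeds × 60 s at 20 Hz.

## Known limitations

- No MPI or inter-process transport: the engine reproduces the
  *semantics* of buffered co-simulation ports in one process, not their
  parallel performance.
- Rate codecs are memoryless (no refractoriness, no adaptation).
- NEF decoding is identity-only (no function decoding), one ensemble at
  a time.
- The balanced network's drive rate, connectivity density and delays
  are calibrated package defaults, not published values; claims about
  it are property-based (rate flatness, asynchrony, irregularity).
- The vehicle model has no dynamics (mass, slip) and the arena is 2D
  with convex obstacles only.
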