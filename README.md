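# spikeloop

Closed-loop conversion between continuous and spiking signals, in one
self-contained package.  Robotic simulators speak continuous data
streams; spiking neural network simulators speak discrete action
potentials.  `spikeloop` provides the conversion layer between the two
— encoders, decoders and adapters — plus a buffered, tick-based
co-simulation engine, a minimal spiking-network simulator, and a 2D
robot environment, so that full sensory → spikes → neurons → spikes →
motor loops can be built, measured and tested without any external
middleware.

It is aimed at computational neuroscientists who want rich, closed-loop
sensory input for spiking models, and at roboticists who want to try
spiking controllers, in a form where every stage is inspectable and
deterministic under a seed.

## The core conversions

**Rate encoding** (regular or Poisson): a drive `I(t) ∈ [-1, 1]` sets a
firing rate

    rate(t) = v_min + (v_max − v_min) · (1 + I(t)) / 2

realized either deterministically (spikes at integer crossings of the
integrated rate, `ISI = 1/rate` at constant drive) or as an
inhomogeneous Poisson process with exponential interspike intervals.

**NEF encoding/decoding**: a heterogeneous LIF population with tuning
curves `a_n(I) = G[gain_n (e_n·I) + bias_n]` encodes a stimulus vector;
regularized least-squares decoders `φ` reconstruct it as
`Î = Σ_n a_n(I) φ_n`.  About 100 neurons per dimension give a
reconstruction RMSE on the order of 1% of the stimulus range.

**Linear decoding**: spike trains are filtered with the causal kernel
`k(t) = exp(−t/τ_dec)` giving activities `a_n(t) = Σ_i k(t − t_{i,n})`,
then combined as `z_k(t) = Σ_n a_n(t) φ_nk`.

**Pipeline semantics**: components run on a global tick; every
connection buffers its data for exactly one tick, so the sensory-motor
latency of a chain of `c` connections is exactly `c × music_dt` —
latency grows linearly with the tick period, and the trade-off against
throughput is explicit.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example: two neurons drive a robot

The shipped demo is a Braitenberg Vehicle III "Explorer": a disc robot
with a 100-beam laser (5 m range, 20 Hz) whose scan is proximity-coded,
split into left/right hemispheres, encoded by two rate neurons, passed
through two repeater neurons, decoded by an exponential filter, and
wired to the wheels so that obstacle proximity on one side steers the
vehicle to the other.

```python
import spikeloop as sl

res = sl.run_braitenberg_demo(T=60.0, seed=0)
print("collisions:", res["collisions"])
print("spike counts:", res["spikes"].counts())
print(f"RTF: {res['timings'].rtf:.1f}")
```

prints (exact spike counts vary with the seed's heading jitter):

```
collisions: 0
spike counts: [1501 1411]
RTF: 25.1
```

The vehicle covers ~11 m in 60 s, never collides, and its two
controlling neurons fire ~25 spikes/s each — more on whichever side is
closer to an obstacle.  `res["trajectory"]` is a DataFrame of
`time, x, y, theta, v, omega, collision_flag`.  The same pipeline is
declared in `src/spikeloop/demos/braitenberg.ini` and can be run from
the shell:

```bash
spikeloop run "$(python -c 'import spikeloop; print(spikeloop.demo_config_path())')" \
    -T 60 --seed 0 --outdir out/
```

which writes the trajectory, spike files, and a summary JSON with the
run's timing decomposition (`t_total = t_build + t_run + ε`) and
real-time factor (`RTF = t_sim / t_run`).

Other CLI entry points: `spikeloop encode` / `spikeloop decode` for
one-shot file conversion, `spikeloop latency` to measure a pipeline's
step-response latency, and `spikeloop sweep` to run a parameter grid.

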