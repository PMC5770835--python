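# exactlif

Lossless (necessary-and-sufficient) threshold-crossing detection for point
neurons with affine subthreshold dynamics, with an exact propagator, a
hybrid event/time-driven simulator, and benchmark experiments quantifying
how often the conventional endpoint test misses spikes.

## The problem

Time-driven and hybrid simulation schemes for spiking neuronal networks
evolve each neuron between *checkpoints* — global grid times plus the
arrival times of synaptic events — and test for a spike by asking whether
the membrane potential at the end of the interval is at or above threshold:

```
V(t0 + h) >= theta  =>  spike
```

This *standard test* is sufficient but not necessary: the voltage can rise
above threshold and fall back within the step (an even number of
crossings), so the first crossing — a real spike — is silently lost.

This package implements the geometric alternative for models with affine
subthreshold dynamics `ds/dt = A s + q`: instead of moving the state
forward and checking it against the threshold hyperplane `V = theta`, the
threshold hyperplane is propagated *backwards in time* over `[0, h]` and
the initial state is tested for membership in the swept volume.  For the
leaky integrate-and-fire neuron with exponentially decaying post-synaptic
currents,

```
dI/dt = -I/tau_s
dV/dt =  I/C - V/tau + I_e/C        (tau = 10 ms, C = 250 pF,
                                     tau_s = 2 ms, theta = 20 mV)
```

the swept volume is bounded by three curves in the `(I, V)` plane, and the
state spikes within `h` **iff** it violates the no-spike system

```
V < theta,   V < f(I),   (I outside envelope domain  or  V < b(I))
```

where `f` is the backpropagated threshold at lag `h` (a straight line:
`V >= f(I)` is exactly the standard test) and `b` is the *envelope* of all
intermediate backpropagated hyperplanes — the locus of critical points of
the extrusion map, tangent to each of them.  A cheap chord `g` through the
envelope's endpoints (`g <= b` by concavity) screens out the expensive
irrational power in `b` for the overwhelming majority of calls.  The test
is exact up to floating point; the two evaluation orderings
(`variant=1` branch sequence, `variant=2` composite condition) give
bit-identical verdicts.

Subthreshold states partition into four regions: `NS1` (deep no-spike),
`NS2` (between chord and envelope, no spike), `S1` (spike, caught by the
standard test) and `S2` (spike with a subthreshold endpoint — precisely the
spikes the standard test misses).

## Worked example: a spike the standard test misses

```python
import exactlif as xl

params = xl.ModelParameters(I_e=375.0)        # 15 mV across tau/C = 40 MOhm
system = xl.build_lif_exp_system(params)
state = xl.NeuronState(I=436.0, V=19.0)       # pA, mV
h = 5.0                                       # ms

print(xl.standard_test(state, h, system, params))   # False
print(xl.lossless_test(state, h, params))           # True
print(xl.classify_region(state, h, params).value)   # 'S2'
res = xl.find_crossing_time(state, h, system, params)
print(round(res.t_theta, 6))                        # 1.153271  (ms)
```

The voltage crosses threshold 1.153 ms into the step, peaks at 2.396 ms,
and ends the step at 19.71 mV — below threshold, so the endpoint test sees
nothing.  The same query from the shell:

```
$ exactlif classify --I 436 --V 19.0 --h 5 --I-e 375
S2 standard=False lossless=True t_theta=1.15327123
```

Running the hybrid simulator in the benchmark diffusion regime (one
excitatory and one inhibitory Poisson generator, mean 15 mV, variance
25 mV², coupling 0.1 mV — a composite 250,000 events/s):

```python
cfg = xl.diffusion_to_rates(15.0, 25.0, 0.1, xl.ModelParameters())
res = xl.run_hybrid(xl.ModelParameters(), cfg, 20_000.0,
                    scheme="lossless1", seed=1, census=True)
print(f"{res.rate_hz:.2f} spikes/s")   # 7.60 spikes/s
```

with the region census showing `NS1` occupied on more than 99.99% of the
~5 million test calls and no `S2` state — in this diffusion-like regime the
standard test essentially never misses a spike.  Shot-noise regimes (large
`J`, sparse events, long steps) do populate `S2`; `run_matched_schemes`
replays one event stream spike-for-spike through the standard and both
lossless schemes to count the disagreements.

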