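# Methods

## Model and state space

The package targets point-neuron models whose subthreshold dynamics is
affine, `ds/dt = A s + q`, with the membrane potential `V` as the last
state coordinate and a spike-and-reset rule at the threshold hyperplane
`V = theta` ("crossing" includes tangency).  The concrete model is the
leaky integrate-and-fire neuron with exponentially decaying post-synaptic
currents, a 2-D system in `(I, V)`:

```
A = [[-1/tau_s,      0   ],      q = [0, I_e/C]
     [ 1/C,      -1/tau  ]]
```

Internal units are fixed to ms, mV, pA, pF.  Then `pA/pF = mV/ms` and the
membrane resistance is `tau/C` (40 MOhm for the defaults), so no unit
conversion constants appear anywhere in the code.

Defaults: `tau = 10 ms`, `C = 250 pF`, `tau_s = 2 ms`, `theta = 20 mV`,
`V_reset = 0 mV`, `t_ref = 2 ms`, `I_e = 0 pA`.  The reset and refractory
values are the conventional choices for this model family and are
configurable.  `tau = tau_s` is rejected at construction: every closed
form below divides by `tau - tau_s`, and the degenerate limit is out of
scope.

## Exact propagator

Over a step `h` the dynamics generates the affine map
`s -> e^{hA} s + (e^{hA} - 1) A^{-1} q`.  The 2-D model uses the closed
form of the matrix exponential; generic dimensions use scipy's
scaling-and-squaring (Pade order 13) `expm`.  The affine offset is always
computed as the top-right block of the exponential of the augmented matrix
`[[hA, hq], [0, 0]]` (the `phi1` form), so a singular `A` — e.g. a perfect
integrator row — needs no inversion.  Negative `h` propagates backwards in
time; the same code path serves the threshold backpropagation.

## The no-spike system

Backpropagating the threshold by a lag `t` gives a hyperplane with normal
`k_t = (0,...,0,1) e^{tA}` and affine term
`kappa_t = theta - [m(t)]_V`, where `m(t)` is the forward affine offset.
Over `t in [0, h]` these hyperplanes sweep a volume whose boundary consists
of the `t = 0` plane (`V = theta`), the `t = h` plane (the `f` line), and
the envelope of the family: the image of the critical points of the
extrusion map, which satisfy `c.x + alpha theta + beta = 0` on the
threshold (`c`, `alpha`, `beta` are the voltage-row blocks of `(A, q)`).
For the 2-D model the envelope is the curve

```
b(I) = (tau/C) ( I_e + [tau I ((I_theta - I_e)/I)^{1 - tau_s/tau}
                        - tau_s I] / (tau - tau_s) )
```

on the domain `I in [I_theta - I_e, e^{h/tau_s}(I_theta - I_e)]`, where
`I_theta = theta C / tau` is the rheobase.  For subrheobase drive `b` lies
at or below `theta`; at or above `theta` for suprarheobase drive, in which
case the envelope inequality is vacuous below threshold and the system
reduces to `V < theta` and `V < f(I)`; at `I_e = I_theta` the envelope
degenerates to the point `(0, theta)`.

The state spikes within `(0, h]` iff it violates
`V < theta  and  V < f(I)  and  (I outside domain or V < b(I))`.
Because the simulation loop resets `V` after each spike, `V < theta`
always holds at test time and only the last two inequalities are
evaluated.

**The chord `g`.**  The auxiliary line `g` is *defined* as the chord
through the envelope endpoints `(I_lo, theta)` and `(I_hi, b(I_hi))`.
Concavity of the envelope guarantees `g <= b` on the domain, which is the
property the fast evaluation orderings rely on (`V < g` proves no-spike
without touching the irrational power in `b`).  Defining `g` by its
endpoints rather than by an expanded coefficient formula makes the
`g <= b` guarantee immediate and leaves no room for sign mistakes; the
endpoint/tangency identities (`g(I_lo) = theta`,
`g(I_hi) = b(I_hi) = f(I_hi)`) are enforced by tests.

**Evaluation orderings.**  Variant 1 is a branch sequence testing the
dominant region NS1 first (`V < f` and `V < g`), then S1 (`V >= f`), then
S2 via `b`; variant 2 is the composite condition
`V >= f or (V >= g and V >= b)`.  The orderings are treated purely as
evaluation-cost optimizations: the normative semantics of both variants is
logical equivalence to the negation of the no-spike system, and that
equivalence, plus bit-identity between the variants, is enforced by
randomized tests against an independent dense-sampling oracle.  Both orderings evaluate `g` at most
once per call.  `V = f` exactly (endpoint tangency) counts as a spike in
both variants and in the standard test, which is implemented as the same
`V >= f` comparison so the containment *standard implies lossless* holds
bit-for-bit.

## Crossing time and voltage maximum

For the 2-D model `V(t) = a e^{-t/tau} + b e^{-t/tau_s} + V_inf`, whose
derivative has at most one root; the interior maximum (if any) is located
by bracketed root finding on the analytic derivative.  Given a positive
spike test, the earliest root of `V(t) = theta` is bracketed on
`[0, t_max]` (double-crossing states) or `[0, h]` and solved by a
safeguarded bisection/secant method (`brentq`, time tolerance 1e-13 ms,
voltage within 1e-10 mV of threshold).  A state already at threshold
spikes immediately at the current checkpoint; a graze whose maximum is
within tolerance of threshold returns the tangent point.  Spike times are
reported as grid time plus floating-point offset.

## Conservative mesh

Where no closed form for the envelope exists (higher-dimensional models),
the locus `Gamma(y, t)` is sampled on a `(y, t)` grid and replaced by
chordal facets.  The locus is flat along the free coordinates (a ruled
surface) and concave, so every facet plane, shifted to pass at or below
its vertices, under-estimates the envelope on the cell footprint; a state
satisfying *all* facet inequalities plus the `t = 0` and `t = h`
half-spaces provably cannot spike.  Failure of the mesh test is
"undetermined", never a spike verdict — callers fall back to the full
system or an oracle.  In 2-D with two time slices the mesh reduces exactly
to `{V < theta, V < f, V < g}`.  For `N > 2` the caller supplies a bounding
box for the free coordinates (the locus is unbounded in them); states
projecting outside it are undetermined.  Refinement over *nested* time
grids is monotone: a state proved safe stays proved.

## Hybrid simulation and the synthetic input

The loop advances the state with the exact propagator between checkpoints
(grid points, default 0.1 ms, plus every input event), runs the configured
test on each interval, and on a spike locates the crossing, resets
`V := V_reset` and clamps it for `t_ref` while the synaptic current keeps
decaying and integrating input jumps (synaptic dynamics are independent of
the voltage clamp in this model class).

The benchmark input emulates a neuron in a recurrent network: one
excitatory and one inhibitory Poisson generator with couplings `J` and
`-J` plus a constant current.  A diffusion regime `(mu, sigma2, J)` in
voltage units maps to balanced rates `r_exc = r_inh = sigma2/(2 tau J^2)`
and `I_e = mu C / tau`; the composite rate is `sigma2/(tau J^2)` and the
mean checkpoint interval `tau J^2 / sigma2`.  For the reference regime
(15 mV, 25 mV², 0.1 mV) this yields 250,000 events/s, a 4e-3 ms mean step,
375 pA of constant drive, and an output rate near 7 spikes/s.  A coupling
`J` [mV] converts to a current jump `dI = J C / tau_s`, so the total
charge of one exponential PSC deflects the membrane by about `J` (the
conversion is configurable).  Event streams are materialized once, from
one named generator per stream seeded by fixed offsets from the master
seed, so matched-scheme comparisons replay identical input spike-for-spike.

What the generator does **not** emulate: recurrent feedback (the output
spikes do not re-enter the input), synaptic transmission delays,
heterogeneous couplings, and non-Poisson input statistics.  Passing tests
therefore validate the detection method and the simulator loop under
stationary Poisson bombardment, not network-level dynamics.

## Experiments and statistics

The region census counts the label of the pre-test state at every lossless
test call; occupation frequencies are counts over calls.  The S2 frequency
is the per-call missed-spike fraction of the standard test, and on a
matched stream it equals the number of per-call disagreements between the
standard and lossless schemes up to their first divergence.  Frequencies
of exactly zero are reported as 0 with a one-sided rule-of-three bound
`3/N` in the notes column.  Interval estimates use equal-tailed posterior
intervals under a symmetric Dirichlet prior with concentration `k = 0.05`
per category at 87% mass; a calibration test checks ~87% frequentist
coverage at large counts.  (`k` fixed rather than re-estimated by marginal
likelihood; the printed value is used.)

The combined S2+NS2 area is `(C/tau)(theta - mu)^2 B1(h) B2(h)` with
`h = tau J^2/sigma2`; the bounded regions form a triangle whose base times
height equals this expression exactly (the shoelace area is half of it),
and whose vertices are the envelope/threshold corner, the envelope/f
tangency point, and the f/threshold intersection.  The fourth-order
expansion in `x = J^2/sigma2` has coefficients `tau^2/(4 tau_s^2)` and
`tau^2 (tau + tau_s)/(8 tau_s^3)`, verified symbolically, and stays below
10% relative error for `x <= 0.15` at the default time constants.

## Problem sizes and determinism

The default validation sizes are chosen to give decisive statistics on a
single CPU: the oracle-equivalence sweep uses 108,000 randomized states
across twelve `(h, I_e)` conditions with a 2000-point dense oracle refined
by golden-section search; the reference-regime census runs 20 s of
simulated time (~5 million test calls); the shot-noise census 12 s.  All
randomness flows from explicit seeds (numpy `SeedSequence`), and hypothesis
property tests run derandomized.

## Known limitations

* The closed-form boundary functions cover the 2-D model only; higher
  dimensions go through the mesh (no closed-form envelope, by design).
* `tau_m = tau_s` is rejected rather than handled by the degenerate limit.
* The equivalent-current mapping `I_e = mu C/tau` is a reconstruction of
  the benchmark input; one printed summary figure for the mean input
  current (400 pA) is inconsistent with the stated mean and resistance
  (375 pA) and is not used as a constraint.
* Output spike times are exact up to the root tolerance; the scheme is
  retrospective and does not predict future spikes (no event queue).
* Single-neuron topology only: no networks, delays, or plasticity.
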