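"""Hybrid event/time-driven simulation of a single LIF-exp neuron.

The loop advances the state with the exact propagator between checkpoints.
Checkpoints are the global grid points (default resolution 0.1 ms) plus
every incoming synaptic event; the threshold test runs over each interval
between consecutive checkpoints, so the effective step ``h`` varies from
call to call.  Output spike times are located in continuous time and carry
a floating-point offset relative to the grid.

The benchmark input emulates a neuron embedded in a recurrent network: one
excitatory and one inhibitory Poisson generator with coupling J and -J plus
a constant current.  A diffusion regime (mu, sigma^2, J) -- mean and
variance of the input expressed in mV through the membrane resistance
tau_m/C_m -- maps to balanced generator rates

    r_exc = r_inh = sigma^2 / (2 tau_m J^2),     I_e = mu C_m / tau_m,

so the composite event rate is sigma^2/(tau_m J^2) and the mean interval
between checkpoints is h = tau_m J^2 / sigma^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import ModelParameters
from .detection import (
    CrossingResult,
    NeuronState,
    RegionLabel,
    _classify_scalar,
    _lossless_scalar,
    find_crossing_time,
)
from .core import build_lif_exp_system

__all__ = [
    "InputConfig",
    "SpikeEvent",
    "SimulationResult",
    "diffusion_to_rates",
    "poisson_events",
    "generate_event_stream",
    "run_hybrid",
    "run_matched_schemes",
    "SCHEMES",
]

SCHEMES = ("standard", "lossless1", "lossless2")


@dataclass(frozen=True)
class InputConfig:
    """Poisson-input regime: diffusion parameters and realized generator rates.

    ``mu`` [mV] and ``sigma2`` [mV^2] are the mean and variance of the
    composite input expressed in voltage units; ``J`` [mV] the coupling
    strength; ``r_exc``/``r_inh`` the generator rates [1/ms]; ``I_e_equiv``
    the constant current delivering the mean [pA].
    """

    mu: float
    sigma2: float
    J: float
    r_exc: float
    r_inh: float
    I_e_equiv: float

    @property
    def total_rate(self) -> float:
        """Composite event rate [1/ms]."""
        return self.r_exc + self.r_inh

    @property
    def mean_interval(self) -> float:
        """Expected interval between synaptic events [ms]."""
        return 1.0 / self.total_rate


def diffusion_to_rates(mu: float, sigma2: float, J: float,
                       params: ModelParameters) -> InputConfig:
    """Map a diffusion regime (mu, sigma2, J) to balanced generator rates."""
    if J == 0.0 or sigma2 <= 0.0:
        raise ValueError("need J != 0 and sigma2 > 0")
    r = sigma2 / (2.0 * params.tau_m * J * J)
    return InputConfig(mu=mu, sigma2=sigma2, J=J, r_exc=r, r_inh=r,
                       I_e_equiv=mu * params.C_m / params.tau_m)


def poisson_events(rate: float, T: float, seed) -> np.ndarray:
    """Sorted event times of a homogeneous Poisson process on [0, T)."""
    if rate < 0 or T <= 0:
        raise ValueError("need rate >= 0 and T > 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = rng.poisson(rate * T)
    return np.sort(rng.uniform(0.0, T, size=n))


def generate_event_stream(cfg: InputConfig, T: float, seed: int,
                          params: ModelParameters):
    """Materialize the merged excitatory/inhibitory event stream once.

    One named generator per stream, seeded from the master seed by fixed
    offsets, so matched-scheme runs replay identical input spike-for-spike.
    Returns (times [ms], weights [mV]) sorted by time.
    """
    ss = np.random.SeedSequence(seed)
    rng_exc, rng_inh = (np.random.default_rng(s) for s in ss.spawn(2))
    t_exc = poisson_events(cfg.r_exc, T, rng_exc)
    t_inh = poisson_events(cfg.r_inh, T, rng_inh)
    times = np.concatenate([t_exc, t_inh])
    weights = np.concatenate([np.full(t_exc.size, cfg.J),
                              np.full(t_inh.size, -cfg.J)])
    order = np.argsort(times, kind="stable")
    return times[order], weights[order]


@dataclass(frozen=True)
class SpikeEvent:
    """A grid-aligned event time with in-step floating offset."""

    grid_time: float
    offset: float
    weight: float | None = None

    @property
    def time(self) -> float:
        return self.grid_time + self.offset


@dataclass
class SimulationResult:
    out_spikes: list[SpikeEvent]
    n_test_calls: int
    census: dict[RegionLabel, int] | None
    duration: float
    seed: int | None
    scheme: str
    s2_times: list[float] = field(default_factory=list)

    @property
    def spike_times(self) -> np.ndarray:
        return np.array([ev.time for ev in self.out_spikes])

    @property
    def rate_hz(self) -> float:
        """Output rate in spikes/s (duration is in ms)."""
        return 1000.0 * len(self.out_spikes) / self.duration


def _weights_to_current_jumps(weights_mV: np.ndarray,
                              params: ModelParameters) -> np.ndarray:
    """Coupling J [mV] -> synaptic current jump dI = J C/tau_s [pA], so the
    total charge of one exponential PSC deflects the membrane by ~J."""
    return np.asarray(weights_mV, dtype=float) * params.C_m / params.tau_s


def run_hybrid(params: ModelParameters, inputs, T: float,
               scheme: str = "lossless1", grid: float = 0.1,
               seed: int | None = None, census: bool = False,
               initial_state: tuple[float, float] = (0.0, 0.0),
               collect_s2_times: bool = False) -> SimulationResult:
    """Simulate one neuron for ``T`` ms under the chosen detection scheme.

    ``inputs`` is an :class:`InputConfig` (events drawn internally from
    ``seed``) or an explicit pair ``(times, weights_mV)``.  ``I_e`` is taken
    from the input config when one is given, otherwise from ``params``.
    On a spike the crossing time is located retrospectively, the voltage is
    reset and clamped for ``t_ref`` while the synaptic current keeps
    decaying and integrating input jumps.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if grid <= 0:
        raise ValueError("grid resolution must be positive")

    if isinstance(inputs, InputConfig):
        ev_times, ev_w = generate_event_stream(inputs, T, seed, params)
        params = params.replace(I_e=inputs.I_e_equiv)
    else:
        ev_times, ev_w = inputs
        ev_times = np.asarray(ev_times, dtype=float)
        ev_w = np.asarray(ev_w, dtype=float)
    ev_dI = _weights_to_current_jumps(ev_w, params)

    system = build_lif_exp_system(params)
    tau, taus, C = params.tau_m, params.tau_s, params.C_m
    theta, Ie = params.theta, params.I_e
    Vres, tref = params.V_reset, params.t_ref
    k = tau * taus / (C * (tau - taus))
    Vinf = tau * Ie / C
    variant = 1 if scheme != "lossless2" else 2
    standard = scheme == "standard"
    exp = math.exp
    ev_t_list = ev_times.tolist()
    ev_dI_list = ev_dI.tolist()
    nev = len(ev_t_list)

    I, V = float(initial_state[0]), float(initial_state[1])
    t = 0.0
    ig = 1                      # next grid index; grid times are ig * grid
    next_grid = grid
    iev = 0
    ref_until = -1.0
    n_calls = 0
    counts = [0, 0, 0, 0]
    spikes: list[float] = []
    s2_times: list[float] = []
    inf = math.inf

    while t < T:
        t_ev = ev_t_list[iev] if iev < nev else inf
        t_next = t_ev if t_ev < next_grid else next_grid
        if t_next > T:
            t_next = T

        if t < ref_until:
            t_stop = ref_until if ref_until < t_next else t_next
            I *= exp(-(t_stop - t) / taus)
            V = Vres
            t = t_stop

        h = t_next - t
        if h > 0.0:
            n_calls += 1
            if standard:
                # endpoint test, same comparison as the S1 branch
                Etau = exp(h / tau)
                f = (Etau * theta + Ie * tau / C * (1.0 - Etau)
                     - I * k * (1.0 - Etau * exp(-h / taus)))
                spike = V >= f
            else:
                spike = _lossless_scalar(I, V, h, tau, taus, C, theta, Ie,
                                         variant)
            if census or collect_s2_times:
                region = _classify_scalar(I, V, h, tau, taus, C, theta, Ie) \
                    if V < theta else 2
                counts[region] += 1
                if region == 3 and collect_s2_times:
                    s2_times.append(t)
            if spike:
                res: CrossingResult = find_crossing_time(
                    NeuronState(I=I, V=V), h, system, params)
                t_th = t + res.t_theta
                spikes.append(t_th)
                I *= exp(-res.t_theta / taus)
                V = Vres
                ref_until = t_th + tref
                t = t_th
                if not (math.isfinite(I) and math.isfinite(V)):
                    raise FloatingPointError(
                        f"non-finite state at t={t}: I={I}, V={V}")
                continue
            # exact advance over the full step
            eI = exp(-h / taus)
            eV = exp(-h / tau)
            V = (V - Vinf + k * I) * eV - k * I * eI + Vinf
            I *= eI
            if not (math.isfinite(I) and math.isfinite(V)):
                raise FloatingPointError(
                    f"non-finite state at t={t_next}: I={I}, V={V}")
        t = t_next
        if iev < nev and ev_t_list[iev] <= t:
            while iev < nev and ev_t_list[iev] <= t:
                I += ev_dI_list[iev]
                iev += 1
            if not math.isfinite(I):
                raise FloatingPointError(f"non-finite input at t={t}: I={I}")
        while next_grid <= t:
            ig += 1
            next_grid = ig * grid

    out = [SpikeEvent(grid_time=math.floor(ts / grid) * grid,
                      offset=ts - math.floor(ts / grid) * grid)
           for ts in spikes]
    census_dict = None
    if census or collect_s2_times:
        census_dict = {RegionLabel.NS1: counts[0], RegionLabel.NS2: counts[1],
                       RegionLabel.S1: counts[2], RegionLabel.S2: counts[3]}
    return SimulationResult(out_spikes=out, n_test_calls=n_calls,
                            census=census_dict, duration=T, seed=seed,
                            scheme=scheme, s2_times=s2_times)


def run_matched_schemes(params: ModelParameters, input_config: InputConfig,
                        T: float, seed: int, grid: float = 0.1,
                        census: bool = True):
    """Run the standard, lossless-1 and lossless-2 schemes on one input.

    The event streams are generated once from ``seed`` and replayed into all
    three schemes, so every neuron receives exactly the same input,
    spike-for-spike.  The per-call agreement log is the list of checkpoint
    times at which the lossless run found the state in S2 -- exactly the
    calls where the standard test would declare no spike while a spike
    occurs (valid call-for-call up to the first divergence of the
    trajectories).
    """
    events = generate_event_stream(input_config, T, seed, params)
    params = params.replace(I_e=input_config.I_e_equiv)
    results = {}
    for scheme in SCHEMES:
        results[scheme] = run_hybrid(
            params, events, T, scheme=scheme, grid=grid, seed=seed,
            census=census, collect_s2_times=(scheme == "lossless1"))
    disagreement_log = results["lossless1"].s2_times
    return results, disagreement_log
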