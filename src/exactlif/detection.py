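"""Threshold-crossing tests.

The *standard test* declares a spike iff the state evolved to the end of the
step lies at or above threshold; it is sufficient but not necessary, because
the voltage can cross threshold an even number of times inside the step and
end below it.  The *lossless test* is the negation of the no-spike
inequality system derived from the backpropagated threshold geometry::

    no spike  <=>  V < theta  and  V < f(I)  and  (I outside envelope
                   domain  or  V < b(I))

(for subrheobase drive; for I_e >= I_theta the envelope constraint is
vacuous below threshold).  Because the simulation loop resets the voltage
after each spike, V < theta always holds for test inputs and the system
reduces to the last two inequalities.  Both published evaluation orderings
are provided; they are logically equivalent and differ only in expected
cost.  The cheap chord line g <= b provides a sufficient no-spike pre-test
that avoids the irrational power in b for the overwhelming majority of
calls.

Per-call region labels partition the subthreshold half-plane:

* ``S1``  -- spike, endpoint at/above threshold (caught by the standard test)
* ``S2``  -- spike, endpoint below threshold (double crossing; the missed-
  spike region of the standard test)
* ``NS1`` -- no spike, below the chord g (or outside the envelope domain)
* ``NS2`` -- no spike, between chord and envelope
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import AffineSystem, ModelParameters, NeuronState, _voltage_samples_2d
from .geometry import chord_g, envelope_domain, line_f, envelope_b, rheobase

__all__ = [
    "RegionLabel",
    "CrossingResult",
    "standard_test",
    "no_spike_system",
    "lossless_test",
    "classify_region",
    "voltage_max_time",
    "find_crossing_time",
    "brute_force_test",
    "brute_force_max",
]


class RegionLabel(enum.Enum):
    NS1 = "NS1"
    NS2 = "NS2"
    S1 = "S1"
    S2 = "S2"


@dataclass(frozen=True)
class CrossingResult:
    spike: bool
    t_theta: float | None = None
    evaluations: int = 0


# ---------------------------------------------------------------------------
# scalar fast paths (shared with the hybrid simulation loop)
# ---------------------------------------------------------------------------

def _f_value(I, h, tau, taus, C, theta, Ie):
    Etau = math.exp(h / tau)
    k = tau * taus / (C * (tau - taus))
    return (Etau * theta + Ie * tau / C * (1.0 - Etau)
            - I * k * (1.0 - Etau * math.exp(-h / taus)))


def _b_value(I, I0, tau, taus, C, Ie):
    # I0 = I_theta - I_e; valid for I0/I in (0, 1]
    return (tau / C) * (Ie + (tau * I * (I0 / I) ** (1.0 - taus / tau)
                              - taus * I) / (tau - taus))


def _lossless_scalar(I, V, h, tau, taus, C, theta, Ie, variant):
    """Spike verdict for one (I, V, h, I_e); both orderings, identical truth
    value.  Assumes nothing: V >= theta returns True immediately."""
    if V >= theta:
        return True
    Etau = math.exp(h / tau)
    k = tau * taus / (C * (tau - taus))
    base = Etau * theta + Ie * tau / C * (1.0 - Etau)
    slope = k * (1.0 - Etau * math.exp(-h / taus))
    f = base - I * slope
    I0 = theta * C / tau - Ie
    if I0 <= 0.0:  # I_e at/above rheobase: envelope vacuous below threshold
        return V >= f
    Etaus = math.exp(h / taus)
    I_hi = Etaus * I0
    f_hi = base - I_hi * slope           # = b(I_hi), the tangency point
    g = theta + (I - I0) * (f_hi - theta) / (I_hi - I0)
    if variant == 1:
        if V < f and V < g:              # NS1 fast path
            return False
        if V >= f:                       # S1
            return True
        return V >= _b_value(I, I0, tau, taus, C, Ie)   # S2 vs NS2
    # variant 2: composite or-and, S1 first, then S2 behind the g pre-test
    return V >= f or (V >= g and V >= _b_value(I, I0, tau, taus, C, Ie))


def _classify_scalar(I, V, h, tau, taus, C, theta, Ie):
    """Region label, as an index into (NS1, NS2, S1, S2)."""
    Etau = math.exp(h / tau)
    k = tau * taus / (C * (tau - taus))
    base = Etau * theta + Ie * tau / C * (1.0 - Etau)
    slope = k * (1.0 - Etau * math.exp(-h / taus))
    f = base - I * slope
    if V >= f:
        return 2                                      # S1
    I0 = theta * C / tau - Ie
    if I0 <= 0.0:
        return 0                                      # NS1 (reduced system)
    Etaus = math.exp(h / taus)
    I_hi = Etaus * I0
    if not (I0 <= I <= I_hi):
        return 0                                      # NS1, outside domain
    f_hi = base - I_hi * slope
    g = theta + (I - I0) * (f_hi - theta) / (I_hi - I0)
    if V < g:
        return 0                                      # NS1
    if V >= _b_value(I, I0, tau, taus, C, Ie):
        return 3                                      # S2 (missed spike)
    return 1                                          # NS2


_LABELS = (RegionLabel.NS1, RegionLabel.NS2, RegionLabel.S1, RegionLabel.S2)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def standard_test(state: NeuronState, h: float, system: AffineSystem,
                  params: ModelParameters) -> bool:
    """Endpoint test: spike iff the evolved V(h) is at/above threshold.

    Implemented as ``V >= f(I)`` (the backpropagated form), which is the
    same comparison bit-for-bit as the one inside the lossless test, so the
    containment standard => lossless holds exactly.
    """
    s = state.as_vector()
    return bool(s[-1] >= _f_value(s[0], h, params.tau_m, params.tau_s,
                                  params.C_m, params.theta, params.I_e))


def no_spike_system(state: NeuronState, h: float,
                    params: ModelParameters) -> bool:
    """The full three-inequality no-spike system (reference form).

    True iff the state provably stays below threshold throughout (0, h].
    """
    I, V = state.as_vector()
    p = params
    if V >= p.theta:
        return False
    if V >= line_f(I, h, p):
        return False
    if p.I_e >= rheobase(p):
        return True            # envelope constraint vacuous below threshold
    dom = envelope_domain(p, h)
    if not dom.contains(I):
        return True
    return V < envelope_b(I, p, h)


def lossless_test(state: NeuronState, h: float, params: ModelParameters,
                  variant: int = 1) -> bool:
    """Necessary-and-sufficient spike test (negation of the no-spike system).

    ``variant`` selects the evaluation ordering: 1 tests the dominant NS1
    region first (branch sequence), 2 uses a single composite or-and
    condition testing S1 first.  Both give identical verdicts; the chord g
    is evaluated at most once per call.
    """
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    I, V = state.as_vector()
    return bool(_lossless_scalar(I, V, h, params.tau_m, params.tau_s,
                                 params.C_m, params.theta, params.I_e,
                                 variant))


def classify_region(state: NeuronState, h: float,
                    params: ModelParameters) -> RegionLabel:
    """Which of NS1/NS2/S1/S2 contains the (subthreshold) state."""
    I, V = state.as_vector()
    if V >= params.theta:
        raise ValueError("region labels are defined below threshold only")
    return _LABELS[_classify_scalar(I, V, h, params.tau_m, params.tau_s,
                                    params.C_m, params.theta, params.I_e)]


def _voltage_coefficients(state: NeuronState, params: ModelParameters):
    """V(t) = a e^{-t/tau} + b e^{-t/tau_s} + V_inf."""
    I0, V0 = state.as_vector()
    tau, taus, C = params.tau_m, params.tau_s, params.C_m
    k = tau * taus / (C * (tau - taus))
    Vinf = tau * params.I_e / C
    return V0 - Vinf + k * I0, -k * I0, Vinf


def voltage_max_time(state: NeuronState, h: float, system: AffineSystem,
                     params: ModelParameters) -> float | None:
    """Interior time where dV/dt changes sign + to -, or None.

    The derivative is a two-exponential combination with at most one root;
    it is bracketed and located with a safeguarded root finder.  None means
    the voltage has no interior maximum in (0, h) (monotone, or an interior
    minimum only).
    """
    a, b, _ = _voltage_coefficients(state, params)
    tau, taus = params.tau_m, params.tau_s

    def dV(t):
        return -a / tau * math.exp(-t / tau) - b / taus * math.exp(-t / taus)

    d0, dh = dV(0.0), dV(h)
    if d0 == 0.0:
        return 0.0 if dh < 0.0 else None
    if d0 < 0.0 or dh >= 0.0:
        return None
    return float(brentq(dV, 0.0, h, xtol=1e-14, rtol=8.9e-16))


def find_crossing_time(state: NeuronState, h: float, system: AffineSystem,
                       params: ModelParameters,
                       tol: float = 1e-10) -> CrossingResult:
    """Earliest threshold-crossing time in (0, h], given a positive spike test.

    The root of V(t) = theta is bracketed on [0, t_max] (endpoint below
    threshold: double-crossing case) or [0, h] and located by a safeguarded
    bisection/secant iteration; |V(t_theta) - theta| <= tol on return.  A
    state already at threshold spikes immediately (t_theta = 0).
    """
    p = params
    a, b, Vinf = _voltage_coefficients(state, p)
    evals = [0]

    def V(t):
        evals[0] += 1
        return (a * math.exp(-t / p.tau_m) + b * math.exp(-t / p.tau_s)
                + Vinf)

    V0 = state.as_vector()[-1]
    if V0 >= p.theta:
        return CrossingResult(spike=True, t_theta=0.0, evaluations=0)
    t_max = voltage_max_time(state, h, system, params)
    t_up = h
    if t_max is not None and t_max > 0.0:
        t_up = min(t_max, h)
    V_up = V(t_up)
    if V_up < p.theta:
        if t_up < h and V(h) >= p.theta:
            t_up = h                     # max estimate degenerate; widen
        elif V_up >= p.theta - tol:
            # tangency: the maximum grazes the threshold
            return CrossingResult(spike=True, t_theta=float(t_up),
                                  evaluations=evals[0])
        else:
            raise RuntimeError(
                "no sign change of V - theta on the bracket; "
                "find_crossing_time requires a positive lossless test")
    t_theta = brentq(lambda t: V(t) - p.theta, 0.0, t_up,
                     xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return CrossingResult(spike=True, t_theta=float(t_theta),
                          evaluations=evals[0])


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


def brute_force_max(I0, V0, h: float, params: ModelParameters,
                    n: int = 10_000) -> np.ndarray:
    """Vectorized maximum of V(t) over (0, h] by dense exact sampling plus
    golden-section refinement around the best sample (3-cell window).

    ``I0`` and ``V0`` may be arrays; returns the per-state maxima.  This is
    the independent oracle the lossless test is checked against; it never
    calls the inequality system.
    """
    I0 = np.atleast_1d(np.asarray(I0, dtype=float))
    V0 = np.atleast_1d(np.asarray(V0, dtype=float))
    tau, taus, C, Ie = params.tau_m, params.tau_s, params.C_m, params.I_e
    ts = np.linspace(0.0, h, n + 1)
    best_t = np.zeros(I0.shape)
    best_v = np.full(I0.shape, -np.inf)
    chunk = max(1, int(2e7) // (n + 1))
    for lo in range(0, I0.size, chunk):
        sl = slice(lo, lo + chunk)
        Vs = _voltage_samples_2d(I0[sl], V0[sl], ts, tau, taus, C, Ie)
        idx = np.argmax(Vs, axis=-1)
        best_t[sl] = ts[idx]
        best_v[sl] = np.take_along_axis(Vs, idx[..., None], -1)[..., 0]
    # golden-section refinement on [t* - 1.5 cells, t* + 1.5 cells]
    cell = h / n
    lo = np.clip(best_t - 1.5 * cell, 0.0, h)
    hi = np.clip(best_t + 1.5 * cell, 0.0, h)
    for _ in range(70):
        x1 = hi - _GOLD * (hi - lo)
        x2 = lo + _GOLD * (hi - lo)
        f1 = _voltage_at(I0, V0, x1, params)
        f2 = _voltage_at(I0, V0, x2, params)
        take1 = f1 >= f2
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
    refined = _voltage_at(I0, V0, 0.5 * (lo + hi), params)
    return np.maximum(best_v, refined)


def _voltage_at(I0, V0, t, params):
    tau, taus, C = params.tau_m, params.tau_s, params.C_m
    k = tau * taus / (C * (tau - taus))
    Vinf = tau * params.I_e / C
    a = V0 - Vinf + k * I0
    b = -k * I0
    return a * np.exp(-t / tau) + b * np.exp(-t / taus) + Vinf


def brute_force_test(state: NeuronState, h: float, system: AffineSystem,
                     params: ModelParameters, n: int = 10_000) -> bool:
    """Oracle verdict: True iff the refined dense maximum of V over (0, h]
    reaches theta - 1e-9 mV."""
    I0, V0 = state.as_vector()
    vmax = brute_force_max(I0, V0, h, params, n=n)[0]
    return bool(vmax >= params.theta - 1e-9)
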