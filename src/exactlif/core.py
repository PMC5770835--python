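"""Affine subthreshold dynamics and the exact timestep propagator.

The state of a point neuron with affine subthreshold dynamics obeys

    ds/dt = A s + q

where ``s`` collects the synaptic current(s) and the membrane potential
(the voltage is the last coordinate by convention).  Over a finite step
``h`` this generates an affine map ``s -> M s + m`` with ``M = exp(h A)``,
which advances the state exactly -- no integration error beyond floating
point.  The concrete two-dimensional example is the leaky integrate-and-fire
neuron with exponentially decaying post-synaptic currents:

    dI/dt = -I / tau_s
    dV/dt =  I / C_m - V / tau_m + I_e / C_m

Internal units are fixed to ms, mV, pA, pF, so that pA/pF = mV/ms and the
membrane resistance tau_m/C_m is in GOhm-free form (MOhm * pA = uV); no
conversion constants appear anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ModelParameters",
    "AffineSystem",
    "NeuronState",
    "AffineMap",
    "build_lif_exp_system",
    "make_propagator",
    "evolve_state",
    "dense_voltage_trace",
]


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the neuron.

    Parameters
    ----------
    tau_m : float
        Membrane time constant [ms].
    C_m : float
        Membrane capacitance [pF].
    tau_s : float
        Synaptic time constant [ms].
    theta : float
        Spike threshold [mV].
    V_reset : float
        Reset potential after a spike [mV]; must lie below ``theta``.
    t_ref : float
        Absolute refractory period [ms].
    I_e : float
        Constant external current [pA].
    """

    tau_m: float = 10.0
    C_m: float = 250.0
    tau_s: float = 2.0
    theta: float = 20.0
    V_reset: float = 0.0
    t_ref: float = 2.0
    I_e: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_m > 0 and self.C_m > 0 and self.tau_s > 0):
            raise ValueError("tau_m, C_m and tau_s must be positive")
        if self.tau_m == self.tau_s:
            # every closed form below divides by tau_m - tau_s
            raise ValueError("tau_m == tau_s is not supported")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if not self.V_reset < self.theta:
            raise ValueError("V_reset must lie below theta")

    @property
    def R_m(self) -> float:
        """Membrane resistance tau_m / C_m [GOhm in ms/pF; numerically MOhm/1000]."""
        return self.tau_m / self.C_m

    def replace(self, **kw) -> "ModelParameters":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass(frozen=True)
class AffineSystem:
    """The matrix ``A`` and offset vector ``q`` of ``ds/dt = A s + q``.

    The block decomposition singles out the voltage row/column::

        A = [[B,   d],        q = [r,
             [c^T, alpha]]         beta]

    with ``B`` of shape (N-1, N-1), ``c`` and ``d`` of length N-1 and
    ``alpha``, ``beta`` scalars.  The voltage is the last coordinate.
    """

    A: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be a square matrix")
        if q.shape != (A.shape[0],):
            raise ValueError("q must be a vector matching A")
        if A.shape[0] < 2:
            raise ValueError("state space must be at least 2-dimensional")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "q", q)

    @property
    def dim(self) -> int:
        return self.A.shape[0]

    @property
    def voltage_index(self) -> int:
        return self.dim - 1

    # block components
    @property
    def B(self) -> np.ndarray:
        return self.A[:-1, :-1]

    @property
    def c(self) -> np.ndarray:
        return self.A[-1, :-1]

    @property
    def d(self) -> np.ndarray:
        return self.A[:-1, -1]

    @property
    def alpha(self) -> float:
        return float(self.A[-1, -1])

    @property
    def r(self) -> np.ndarray:
        return self.q[:-1]

    @property
    def beta(self) -> float:
        return float(self.q[-1])


@dataclass(frozen=True)
class NeuronState:
    """A point (I, V) in state space.

    ``I`` is the synaptic current [pA] (a vector for N > 2), ``V`` the
    membrane potential [mV].
    """

    I: float | np.ndarray
    V: float

    def __post_init__(self) -> None:
        vec = self.as_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("state components must be finite")

    def as_vector(self) -> np.ndarray:
        return np.append(np.atleast_1d(np.asarray(self.I, dtype=float)), self.V)

    @classmethod
    def from_vector(cls, s: np.ndarray) -> "NeuronState":
        s = np.asarray(s, dtype=float)
        I = s[:-1]
        if I.size == 1:
            return cls(I=float(I[0]), V=float(s[-1]))
        return cls(I=I.copy(), V=float(s[-1]))


@dataclass(frozen=True)
class AffineMap:
    """The exact propagator over a step ``h``: ``s -> M s + m``."""

    M: np.ndarray
    m: np.ndarray
    h: float

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return self.M @ np.asarray(s, dtype=float) + self.m

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Map applying ``other`` first, then ``self`` (step h_self + h_other)."""
        return AffineMap(M=self.M @ other.M, m=self.M @ other.m + self.m,
                         h=self.h + other.h)


def build_lif_exp_system(params: ModelParameters) -> AffineSystem:
    """Assemble ``(A, q)`` for the LIF neuron with exponential synaptic currents.

    ``A = [[-1/tau_s, 0], [1/C_m, -1/tau_m]]``, ``q = [0, I_e/C_m]``.
    """
    A = np.array([
        [-1.0 / params.tau_s, 0.0],
        [1.0 / params.C_m, -1.0 / params.tau_m],
    ])
    q = np.array([0.0, params.I_e / params.C_m])
    return AffineSystem(A=A, q=q)


def _phi1_times_hq(A: np.ndarray, q: np.ndarray, h: float) -> np.ndarray:
    """Affine offset m = (exp(hA) - 1) A^{-1} q without inverting A.

    Computed as the top-right block of exp of the augmented matrix
    [[hA, hq], [0, 0]], i.e. h * phi1(hA) q with phi1(z) = (e^z - 1)/z.
    Well defined for singular A.
    """
    n = A.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = h * A
    aug[:n, n] = h * q
    return expm(aug)[:n, n]


def _lif_closed_form(params: ModelParameters, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form exp(hA) and offset for the 2-D model (any sign of h)."""
    tau, taus, C = params.tau_m, params.tau_s, params.C_m
    eI = math.exp(-h / taus)
    eV = math.exp(-h / tau)
    # lower-left entry of exp(hA)
    p = tau * taus / (C * (tau - taus)) * (eV - eI)
    M = np.array([[eI, 0.0], [p, eV]])
    m = np.array([0.0, params.I_e * tau / C * (1.0 - eV)])
    return M, m


def make_propagator(system: AffineSystem, h: float,
                    params: ModelParameters | None = None) -> AffineMap:
    """Exact propagator ``AffineMap`` for a step ``h`` (negative h propagates
    backwards in time).

    When ``params`` is given and the system is the 2-D model, the closed-form
    matrix exponential is used; otherwise a scaling-and-squaring matrix
    exponential (Pade order 13) handles any dimension, and the affine offset
    is computed in phi1 form so that singular ``A`` needs no inversion.
    """
    if params is not None and system.dim == 2:
        M, m = _lif_closed_form(params, h)
        return AffineMap(M=M, m=m, h=h)
    M = expm(h * system.A)
    m = _phi1_times_hq(system.A, system.q, h)
    return AffineMap(M=M, m=m, h=h)


def evolve_state(state: NeuronState, pmap: AffineMap) -> NeuronState:
    """Apply the exact propagator: ``s' = M s + m``."""
    return NeuronState.from_vector(pmap(state.as_vector()))


def dense_voltage_trace(system: AffineSystem, state: NeuronState, h: float,
                        n: int, params: ModelParameters | None = None) -> np.ndarray:
    """Sample V(t) at ``n`` equispaced times in [0, h].

    Each sample is computed with the exact propagator from t = 0 (no error
    accumulation).  Returns an array of shape (n, 2) of rows (t, V).
    """
    if n < 2:
        raise ValueError("need at least the two endpoint samples")
    ts = np.linspace(0.0, h, n)
    s0 = state.as_vector()
    if params is not None and system.dim == 2:
        tau, taus, C = params.tau_m, params.tau_s, params.C_m
        I0, V0 = s0[0], s0[1]
        Vs = _voltage_samples_2d(I0, V0, ts, tau, taus, C, params.I_e)
        return np.column_stack([ts, Vs])
    out = np.empty((n, 2))
    for i, t in enumerate(ts):
        out[i, 0] = t
        out[i, 1] = make_propagator(system, float(t))(s0)[-1]
    return out


def _voltage_samples_2d(I0, V0, ts, tau, taus, C, Ie):
    """Vectorized V(t) for the 2-D model; I0, V0 may be arrays (broadcast
    against the time grid ``ts``)."""
    ts = np.asarray(ts, dtype=float)
    k = tau * taus / (C * (tau - taus))
    Vinf = tau * Ie / C
    a = np.asarray(V0) - Vinf + k * np.asarray(I0)   # e^{-t/tau} coefficient
    b = -k * np.asarray(I0)                          # e^{-t/tau_s} coefficient
    eV = np.exp(-ts / tau)
    eI = np.exp(-ts / taus)
    if np.ndim(a) == 0:
        return a * eV + b * eI + Vinf
    return a[..., None] * eV + b[..., None] * eI + Vinf
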