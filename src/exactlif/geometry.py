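"""State-space geometry of the spike / no-spike boundary.

A neuron state spikes within a step ``h`` iff the threshold hyperplane
``V = theta``, propagated backwards in time over [0, h], sweeps across it.
The swept volume is bounded by

* the threshold itself (lag t = 0),
* the backpropagated threshold at lag t = h (the ``f`` line), and
* the envelope of all intermediate backpropagated hyperplanes -- the locus
  of critical points of the extrusion map (the ``b`` curve).

For the 2-D leaky integrate-and-fire model with exponential synaptic
currents all three have closed forms; this module also provides the generic
N-dimensional constructions and a conservative simplicial-mesh approximation
of the envelope for models where no closed form exists.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    AffineSystem,
    ModelParameters,
    NeuronState,
    _phi1_times_hq,
    make_propagator,
)
from scipy.linalg import expm

__all__ = [
    "Hyperplane",
    "EnvelopeDomain",
    "BoundarySet",
    "SimplicialMesh",
    "threshold_hyperplane",
    "backpropagated_threshold",
    "extrusion_point",
    "critical_locus_point",
    "rheobase",
    "envelope_domain",
    "envelope_b",
    "line_f",
    "chord_g",
    "boundary_set",
    "build_envelope_mesh",
    "mesh_no_spike_test",
    "save_mesh",
    "load_mesh",
]


@dataclass(frozen=True)
class Hyperplane:
    """Hyperplane ``k . s = kappa``; ``k . s < kappa`` is the 'below' side."""

    k: np.ndarray
    kappa: float

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        if not np.any(k):
            raise ValueError("normal covector must be non-zero")
        object.__setattr__(self, "k", k)

    def value(self, s: np.ndarray) -> float:
        return float(self.k @ np.asarray(s, dtype=float) - self.kappa)

    def below(self, s: np.ndarray) -> bool:
        return self.value(s) < 0.0


@dataclass(frozen=True)
class EnvelopeDomain:
    """Current range on which the envelope curve constrains the state.

    For subrheobase drive (I_e < I_theta) the domain is
    ``[I_theta - I_e, e^{h/tau_s} (I_theta - I_e)]`` on the positive axis;
    for suprarheobase drive the analogous negative-axis interval.  When
    ``I_e = I_theta`` the envelope degenerates to the point (0, theta).
    """

    I_lo: float
    I_hi: float
    degenerate: bool = False
    empty_below_threshold: bool = False

    def contains(self, I: float) -> bool:
        return self.I_lo <= I <= self.I_hi


def threshold_hyperplane(params: ModelParameters, dim: int = 2) -> Hyperplane:
    """The threshold ``V = theta`` as a hyperplane (normal along V)."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    k = np.zeros(dim)
    k[-1] = 1.0
    return Hyperplane(k=k, kappa=params.theta)


def backpropagated_threshold(system: AffineSystem, params: ModelParameters,
                             t: float) -> Hyperplane:
    """Image of the threshold under backpropagation by lag ``t``.

    ``k_t = (0,...,0,1) e^{tA}`` and ``kappa_t = theta - [m(t)]_V`` where
    ``m(t)`` is the affine offset of the forward propagator over ``t``
    (the ``A^{-1}`` form is avoided so singular ``A`` is fine).
    A state below this hyperplane stays below threshold at lag ``t``.
    """
    if t < 0:
        raise ValueError("lag t must be non-negative")
    if system.dim == 2:
        tau, taus, C = params.tau_m, params.tau_s, params.C_m
        kI = tau * taus / (C * (tau - taus)) * (math.exp(-t / tau)
                                                - math.exp(-t / taus))
        kV = math.exp(-t / tau)
        kappa = params.theta - params.I_e * tau / C * (1.0 - kV)
        return Hyperplane(k=np.array([kI, kV]), kappa=kappa)
    k = expm(t * system.A)[-1, :]
    m_t = _phi1_times_hq(system.A, system.q, t)
    return Hyperplane(k=k, kappa=params.theta - float(m_t[-1]))


def extrusion_point(system: AffineSystem, params: ModelParameters,
                    x: float | np.ndarray, t: float) -> NeuronState:
    """Backpropagate the threshold point with current coordinates ``x`` by
    lag ``t``: ``E(x, t) = e^{-tA} (x, theta) + (e^{-tA} - 1) A^{-1} q``."""
    s_thr = np.append(np.atleast_1d(np.asarray(x, dtype=float)), params.theta)
    back = make_propagator(system, -t, params=params)
    return NeuronState.from_vector(back(s_thr))


def _pivot_solve(system: AffineSystem, params: ModelParameters,
                 y: np.ndarray | None) -> np.ndarray:
    """Solve ``c . x + alpha theta + beta = 0`` for the pivot coordinate
    (largest |c_i|) given the free coordinates ``y``."""
    c = system.c
    if not np.any(c):
        raise ValueError(
            "c = 0: the voltage row does not couple to the currents, so the "
            "extrusion map has no critical points (no envelope exists)")
    piv = int(np.argmax(np.abs(c)))
    n_free = system.dim - 2
    y = np.zeros(0) if y is None else np.atleast_1d(np.asarray(y, dtype=float))
    if y.size != n_free:
        raise ValueError(f"expected {n_free} free coordinates, got {y.size}")
    x = np.empty(system.dim - 1)
    free_idx = [i for i in range(system.dim - 1) if i != piv]
    x[free_idx] = y
    rhs = system.alpha * params.theta + system.beta
    x[piv] = -(c[free_idx] @ y + rhs) / c[piv]
    return x


def critical_locus_point(system: AffineSystem, params: ModelParameters,
                         y: np.ndarray | None, t: float) -> NeuronState:
    """Point ``Gamma(y, t)`` on the critical locus (envelope) of the extrusion.

    The critical points of the extrusion satisfy ``c . x + alpha theta +
    beta = 0`` on the threshold; the locus is their backpropagated image.
    For the 2-D model there are no free coordinates and
    ``Gamma(t) = E(I_theta - I_e, t)``.
    """
    x = _pivot_solve(system, params, y)
    return extrusion_point(system, params, x, t)


def rheobase(params: ModelParameters) -> float:
    """Rheobase current ``I_theta = theta C / tau``: the constant drive that
    reaches threshold only asymptotically."""
    return params.theta * params.C_m / params.tau_m


def envelope_domain(params: ModelParameters, h: float) -> EnvelopeDomain:
    """Current bounds of the envelope for a step ``h`` (2-D model)."""
    I0 = rheobase(params) - params.I_e
    if I0 == 0.0:
        return EnvelopeDomain(I_lo=0.0, I_hi=0.0, degenerate=True)
    Ih = math.exp(h / params.tau_s) * I0
    if I0 > 0:
        return EnvelopeDomain(I_lo=I0, I_hi=Ih)
    return EnvelopeDomain(I_lo=Ih, I_hi=I0, empty_below_threshold=True)


def envelope_b(I: float, params: ModelParameters, h: float) -> float:
    """Envelope ordinate ``b(I)`` on its domain [mV].

    ``b(I) = (tau/C) ( I_e + (tau I ((I_theta-I_e)/I)^{1-tau_s/tau}
    - tau_s I) / (tau - tau_s) )``; below theta for subrheobase drive,
    above theta for suprarheobase drive.
    """
    dom = envelope_domain(params, h)
    if dom.degenerate:
        raise ValueError("I_e equals the rheobase: envelope degenerates to "
                         "the point (0, theta)")
    if not dom.contains(I):
        raise ValueError(f"I={I} outside envelope domain "
                         f"[{dom.I_lo}, {dom.I_hi}]")
    tau, taus, C = params.tau_m, params.tau_s, params.C_m
    ratio = (rheobase(params) - params.I_e) / I
    return (tau / C) * (params.I_e
                        + (tau * I * ratio ** (1.0 - taus / tau) - taus * I)
                        / (tau - taus))


def line_f(I: float, h: float, params: ModelParameters) -> float:
    """Backpropagated threshold at lag ``h`` solved for V: the ``f`` line.

    ``V >= f(I)`` iff the state evolved forward by ``h`` ends at or above
    threshold.
    """
    tau, taus, C = params.tau_m, params.tau_s, params.C_m
    Etau = math.exp(h / tau)
    k = tau * taus / (C * (tau - taus))
    return (Etau * params.theta + params.I_e * tau / C * (1.0 - Etau)
            - I * k * (1.0 - Etau * math.exp(-h / taus)))


def chord_g(I: float, h: float, params: ModelParameters) -> float:
    """Auxiliary chord through the envelope endpoints: the ``g`` line.

    Defined as the straight line through ``(I_lo, theta)`` and
    ``(I_hi, b(I_hi))``; concavity of the envelope guarantees ``g <= b`` on
    the domain, so ``V < g`` is a cheap sufficient no-spike pre-test.  For
    suprarheobase drive the envelope does not constrain subthreshold states
    and +inf is returned (the inequality is vacuously satisfied).
    """
    dom = envelope_domain(params, h)
    if dom.degenerate or dom.empty_below_threshold:
        return math.inf
    I_lo, I_hi = dom.I_lo, dom.I_hi
    b_hi = line_f(I_hi, h, params)  # tangency: b(I_hi) = f(I_hi)
    return params.theta + (I - I_lo) * (b_hi - params.theta) / (I_hi - I_lo)


@dataclass(frozen=True)
class BoundarySet:
    """The three boundary functions f, b, g for a given (h, I_e)."""

    h: float
    params: ModelParameters
    domain: EnvelopeDomain

    def f(self, I: float) -> float:
        return line_f(I, self.h, self.params)

    def b(self, I: float) -> float:
        return envelope_b(I, self.params, self.h)

    def g(self, I: float) -> float:
        return chord_g(I, self.h, self.params)


def boundary_set(params: ModelParameters, h: float) -> BoundarySet:
    return BoundarySet(h=h, params=params, domain=envelope_domain(params, h))


# ---------------------------------------------------------------------------
# conservative simplicial mesh over the envelope
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimplicialMesh:
    """Linear inequalities conservatively approximating the no-spike region.

    ``inequalities`` rows are (covector..., affine term): a state ``s`` passes
    a row iff ``a . s <= const``.  The first two rows are the t = 0 and t = h
    boundary half-spaces; the remaining rows are chordal facets through
    envelope vertices.  Because the envelope is concave, satisfying ALL rows
    implies the state cannot spike within the step (one-sided test).
    ``y_box`` (N > 2 only) bounds the meshed patch of free coordinates;
    states projecting outside it are undetermined and fail the test.
    """

    vertices: np.ndarray          # (n_vertices, N) points on the envelope
    inequalities: np.ndarray      # (n_rows, N + 1)
    h: float
    n_t: int
    params_hash: str
    y_box: np.ndarray | None = None   # (N-2, 2) bounds, or None for 2-D
    free_idx: tuple[int, ...] = ()    # state indices of the free coordinates


def _params_hash(params: ModelParameters) -> str:
    text = repr(params).encode()
    return hashlib.md5(text).hexdigest()[:12]


def build_envelope_mesh(system: AffineSystem, params: ModelParameters,
                        h: float, n_t: int,
                        y_box: np.ndarray | None = None,
                        n_y: int = 5) -> SimplicialMesh:
    """Mesh the critical locus ``Gamma(y, t)`` on a (y, t) grid.

    The locus is flat along the free coordinates (a ruled surface), so
    chordal facets through grid vertices under-estimate the concave envelope
    and the resulting linear system is conservative.  For the 2-D model there
    is one facet per t-interval (``n_t = 2`` reduces to the single chord g);
    for N > 2 a ``y_box`` must be supplied and each (t-interval, y-cell)
    contributes a facet.
    """
    if n_t < 2:
        raise ValueError("n_t must be >= 2")
    N = system.dim
    if N > 2 and y_box is None:
        raise ValueError("y_box is required for N > 2 (the locus is "
                         "unbounded in the free coordinates)")
    _pivot_solve(system, params, np.zeros(N - 2))  # raises if c == 0

    ts = np.linspace(0.0, h, n_t)
    rows = []
    # boundary half-spaces: t = 0 (V < theta) and t = h
    thr = threshold_hyperplane(params, N)
    rows.append(np.append(thr.k, thr.kappa))
    bph = backpropagated_threshold(system, params, h)
    scale = bph.k[-1]  # positive; normalize so the V-component is +1
    rows.append(np.append(bph.k / scale, bph.kappa / scale))

    if N == 2:
        verts = np.array([critical_locus_point(system, params, None, t)
                          .as_vector() for t in ts])
        for j in range(n_t - 1):
            p0, p1 = verts[j], verts[j + 1]
            dI, dV = p1[0] - p0[0], p1[1] - p0[1]
            a = np.array([-dV, dI])      # normal to the chord
            if a[1] < 0:
                a = -a                   # orient 'below' along +V
            rows.append(np.append(a, a @ p0))
        return SimplicialMesh(vertices=verts, inequalities=np.array(rows),
                              h=h, n_t=n_t, params_hash=_params_hash(params))

    piv = int(np.argmax(np.abs(system.c)))
    free_idx = tuple(i for i in range(N - 1) if i != piv)
    y_box = np.asarray(y_box, dtype=float).reshape(N - 2, 2)
    grids = [np.linspace(lo, hi, n_y) for lo, hi in y_box]
    mesh_y = np.stack([g.ravel() for g in np.meshgrid(*grids, indexing="ij")],
                      axis=-1)
    verts = np.array([critical_locus_point(system, params, y, t).as_vector()
                      for t in ts for y in mesh_y])
    # facets: for each t-interval and each y-cell, fit the hyperplane through
    # the cell's vertices at both t values (affine least squares in V).
    vert_grid = verts.reshape(n_t, *(len(g) for g in grids), N)
    for j in range(n_t - 1):
        for cell in np.ndindex(*(len(g) - 1 for g in grids)):
            pts = []
            for dt in (0, 1):
                for corner in np.ndindex(*((2,) * (N - 2))):
                    idx = (j + dt,) + tuple(c + d for c, d in
                                            zip(cell, corner))
                    pts.append(vert_grid[idx])
            pts = np.array(pts)
            # V = w . (I-coords) + w0 through the cell vertices
            X = np.column_stack([pts[:, :-1], np.ones(len(pts))])
            coef, *_ = np.linalg.lstsq(X, pts[:, -1], rcond=None)
            a = np.append(-coef[:-1], 1.0)
            const = coef[-1]
            # conservative shift: the plane must not dip below any vertex
            const = min(const, float(np.min(a @ pts.T)))
            rows.append(np.append(a, const))
    return SimplicialMesh(vertices=verts, inequalities=np.array(rows), h=h,
                          n_t=n_t, params_hash=_params_hash(params),
                          y_box=y_box, free_idx=free_idx)


def mesh_no_spike_test(state: NeuronState, mesh: SimplicialMesh) -> bool:
    """True only if the state provably cannot cross threshold within the step.

    Checks all facet inequalities plus the t = 0 and t = h half-spaces; a
    False answer is 'undetermined' (the caller falls back to the full system
    or an oracle), never a spike verdict.
    """
    s = state.as_vector()
    if mesh.y_box is not None:
        y = s[list(mesh.free_idx)]
        lo, hi = mesh.y_box[:, 0], mesh.y_box[:, 1]
        if np.any(y < lo) or np.any(y > hi):
            return False
    a = mesh.inequalities[:, :-1]
    const = mesh.inequalities[:, -1]
    return bool(np.all(a @ s < const))


def save_mesh(mesh: SimplicialMesh, path) -> None:
    """Write the inequality rows as delimited text with a provenance header."""
    header = (f"h={mesh.h!r} params_hash={mesh.params_hash} n_t={mesh.n_t}\n"
              "columns: covector components..., affine term")
    np.savetxt(path, mesh.inequalities, header=header)


def load_mesh(path) -> SimplicialMesh:
    with open(path) as fh:
        first = fh.readline().lstrip("# ").split()
    meta = dict(item.split("=") for item in first)
    ineq = np.atleast_2d(np.loadtxt(path))
    return SimplicialMesh(vertices=np.empty((0, ineq.shape[1] - 1)),
                          inequalities=ineq, h=float(meta["h"]),
                          n_t=int(meta["n_t"]),
                          params_hash=meta["params_hash"])
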