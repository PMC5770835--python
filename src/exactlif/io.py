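"""Plain-text I/O: parameter files, event lists, spike trains, run configs.

All files are delimited text.  Units follow the internal convention
(ms, mV, pA, pF) and are documented in headers.
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np

from .core import ModelParameters
from .hybrid import InputConfig, diffusion_to_rates

__all__ = [
    "read_params",
    "write_params",
    "read_events",
    "write_events",
    "read_spike_times",
    "write_spike_times",
    "read_run_config",
]

_PARAM_KEYS = ("tau_m", "C_m", "tau_s", "theta", "V_reset", "t_ref", "I_e")


def read_params(path) -> ModelParameters:
    """Flat key/value parameter file: ``key value`` or ``key = value`` lines,
    '#' comments.  Values are parsed as decimal floats, bit-exactly."""
    kw = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("=", " ").split()
        if len(parts) != 2:
            raise ValueError(f"cannot parse parameter line: {raw!r}")
        key, value = parts
        if key not in _PARAM_KEYS:
            raise ValueError(f"unknown parameter {key!r}")
        kw[key] = float(value)
    return ModelParameters(**kw)


def write_params(params: ModelParameters, path) -> None:
    lines = ["# neuron parameters (ms, mV, pA, pF)"]
    lines += [f"{k} = {getattr(params, k)!r}" for k in _PARAM_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path):
    """Two-column input events: time [ms], weight [mV]."""
    data = np.atleast_2d(np.loadtxt(path))
    if data.size == 0:
        return np.empty(0), np.empty(0)
    return data[:, 0], data[:, 1]


def write_events(times, weights, path, header: str = "") -> None:
    head = "time_ms weight_mV" + (f"\n{header}" if header else "")
    np.savetxt(path, np.column_stack([times, weights]), header=head)


def read_spike_times(path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path))


def write_spike_times(times, path, header: str = "") -> None:
    head = "time_ms" + (f"\n{header}" if header else "")
    np.savetxt(path, np.asarray(times, dtype=float), header=head)


def read_run_config(path):
    """INI-style run configuration with [neuron], [input], [scheme], [run].

    [neuron] holds the flat parameter keys; [input] either a diffusion
    regime (mu, sigma2, J) or an ``events`` file path; [scheme] the test
    scheme and grid resolution; [run] duration, seed, census flag.
    Returns (params, input_spec, options dict).
    """
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    kw = {k: cp.getfloat("neuron", k) for k in _PARAM_KEYS
          if cp.has_option("neuron", k)}
    params = ModelParameters(**kw)

    if cp.has_option("input", "events"):
        input_spec = read_events(cp.get("input", "events"))
    else:
        input_spec = diffusion_to_rates(cp.getfloat("input", "mu"),
                                        cp.getfloat("input", "sigma2"),
                                        cp.getfloat("input", "J"), params)
    options = dict(
        scheme=cp.get("scheme", "scheme", fallback="lossless1"),
        grid=cp.getfloat("scheme", "grid", fallback=0.1),
        T=cp.getfloat("run", "T"),
        seed=cp.getint("run", "seed", fallback=0),
        census=cp.getboolean("run", "census", fallback=False),
    )
    return params, input_spec, options
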