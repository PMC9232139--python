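"""Voltage-gated channel kinetics for the enteric S-neuron model.

Five channels carry the action potential and control excitability:

* NaV1.3 — main inward current; activation m1^3, fast inactivation m2,
  slow inactivation m3 (with a floor M on availability).
* NaV1.7 — small inward current with sigmoidal rate laws.
* Kdr — delayed rectifier, the dominant repolarising current.
* KA — A-type potassium current with fixed time constants.
* Kv7.2 — M-current; slow, non-inactivating, converts tonic firing to
  phasic firing.

Each gate is described by a :class:`GateSpec` whose rate laws are built from
a small set of named functional forms; the constants ship in
``data/channels.yaml`` so that transcription ambiguities live in data, not in
code.  All rate functions are vectorised over membrane potential.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError, InputError, StateCorruptionError

__all__ = [
    "GateSpec",
    "ChannelModel",
    "gate_rates",
    "gate_steady_state",
    "gate_time_constant",
    "advance_gate",
    "channel_current",
    "load_channels",
    "default_channels",
]

_log = logging.getLogger(__name__)

#: Reference temperature (Celsius) at which NaV kinetics are reported.
T_REF = 24.0


# ---------------------------------------------------------------------------
# rate-law components
# ---------------------------------------------------------------------------

def _linexp(v, a, vh, k):
    """a*(v-vh) / (1 - exp(-(v-vh)/k)) with the removable singularity at
    v == vh replaced by its analytic limit a*k (L'Hopital)."""
    x = np.asarray(v, dtype=float) - vh
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        out = a * x / (-np.expm1(-x / k))
    small = np.abs(x) < 1e-7 * abs(k)
    # second-order Taylor: x/(1-e^(-x/k)) = k + x/2 + O(x^2)
    out = np.where(small, a * (k + 0.5 * x), out)
    return out


def _sigmoid(v, a, vh, k, c=0.0):
    x = (np.asarray(v, dtype=float) - vh) / k
    with np.errstate(over="ignore"):
        out = a / (1.0 + np.exp(x)) + c
    return out


def _coshratio(v, a, b, vh, k, sign):
    """exp(s*x)/(a + b*(exp(x)+exp(-x))) with x=(v-vh)/k; s=+1 forward,
    s=-1 backward.  Bounded by 1/b for all v."""
    x = (np.asarray(v, dtype=float) - vh) / k
    ex = np.exp(x)
    emx = np.exp(-x)
    num = ex if sign > 0 else emx
    return num / (a + b * (ex + emx))


def _logistic(v, vh, k):
    x = (np.asarray(v, dtype=float) - vh) / k
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(x))


def _sigtau(v, c, a, vh, k):
    return c + _sigmoid(v, a, vh, k)


def _nav13_slow_inf(v, vh, k, M):
    """Double-term steady state: logistic floor-lifted by M, the maximum
    fraction of channels that escape slow inactivation."""
    s = _logistic(v, vh, k)
    return s + M * (1.0 - s)


def _nav13_slow_tau(v, za, zb, v0, a0, T):
    """Boltzmann-factor time constant tau = beta / (a0 * (1 + alpha)) with
    alpha, beta = exp(z*(v-v0)/(R*(273.16+T))), R = 8.315."""
    denom = 8.315 * (273.16 + T)
    x = np.asarray(v, dtype=float) - v0
    alpha = np.exp(za * x / denom)
    beta = np.exp(zb * x / denom)
    return beta / (a0 * (1.0 + alpha))


_COMPONENTS = {
    "linexp": lambda v, p, T: _linexp(v, p["a"], p["vh"], p["k"]),
    "sigmoid": lambda v, p, T: _sigmoid(v, p["a"], p["vh"], p["k"], p.get("c", 0.0)),
    "coshratio_fwd": lambda v, p, T: _coshratio(v, p["a"], p["b"], p["vh"], p["k"], +1),
    "coshratio_bwd": lambda v, p, T: _coshratio(v, p["a"], p["b"], p["vh"], p["k"], -1),
    "logistic": lambda v, p, T: _logistic(v, p["vh"], p["k"]),
    "const": lambda v, p, T: np.full_like(np.asarray(v, dtype=float), p["value"]),
    "sigtau": lambda v, p, T: _sigtau(v, p["c"], p["a"], p["vh"], p["k"]),
    "nav13_slow_inf": lambda v, p, T: _nav13_slow_inf(v, p["vh"], p["k"], p["M"]),
    "nav13_slow_tau": lambda v, p, T: _nav13_slow_tau(
        v, p["za"], p["zb"], p["v0"], p["a0"], T
    ),
}


def _eval_component(spec: dict, v, T: float):
    try:
        form = spec["form"]
        fn = _COMPONENTS[form]
    except KeyError as exc:
        raise ConfigurationError(f"unknown rate-law component: {spec!r}") from exc
    return fn(v, spec, T)


# ---------------------------------------------------------------------------
# gate and channel types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation state variable of one channel.

    ``rate_form`` is ``"alpha_beta"`` (forward/backward rates; an optional
    ``inf`` component overrides the steady state while alpha+beta still sets
    the time constant) or ``"inf_tau"`` (steady state and time constant given
    directly).  ``q10`` marks gates whose rates scale with temperature as
    2^((T-24)/10).
    """

    name: str
    exponent: int
    rate_form: str
    params: dict = field(default_factory=dict)
    q10: bool = False

    def __post_init__(self):
        if self.exponent < 1:
            raise ConfigurationError(
                f"gate {self.name!r}: exponent must be >= 1, got {self.exponent}"
            )
        if self.rate_form not in ("alpha_beta", "inf_tau"):
            raise ConfigurationError(
                f"gate {self.name!r}: unknown rate_form {self.rate_form!r}"
            )


@dataclass(frozen=True)
class ChannelModel:
    """A named channel: maximum conductance density (S/cm^2), reversal
    potential (mV) and an ordered list of gates."""

    name: str
    gbar: float
    e_rev: float
    gates: tuple[GateSpec, ...]
    temperature_sensitive: bool = False

    def __post_init__(self):
        if self.gbar < 0:
            raise ConfigurationError(f"channel {self.name!r}: gbar must be >= 0")


def _check_v(v):
    if not np.all(np.isfinite(v)):
        raise InputError("membrane potential must be finite")


def temperature_factor(T: float) -> float:
    """Q10 = 2 rate multiplier relative to 24 degrees C."""
    return 2.0 ** ((T - T_REF) / 10.0)


def gate_rates(gate: GateSpec, v, T: float = T_REF):
    """Evaluate the printed rate law of one gate.

    Returns ``(alpha, beta)`` in 1/ms for ``alpha_beta`` gates and
    ``(m_inf, tau)`` (dimensionless, ms) for ``inf_tau`` gates.  Removable
    0/0 singularities are replaced by their analytic limits; rates are
    clamped at zero.
    """
    _check_v(v)
    if gate.rate_form == "alpha_beta":
        alpha = np.maximum(_eval_component(gate.params["alpha"], v, T), 0.0)
        beta = np.maximum(_eval_component(gate.params["beta"], v, T), 0.0)
        if gate.q10:
            q = temperature_factor(T)
            alpha = alpha * q
            beta = beta * q
        return alpha, beta
    minf = np.clip(_eval_component(gate.params["inf"], v, T), 0.0, 1.0)
    tau = _eval_component(gate.params["tau"], v, T)
    if gate.q10:
        tau = tau / temperature_factor(T)
    return minf, tau


def gate_steady_state(gate: GateSpec, v, T: float = T_REF):
    """Steady-state open fraction m_inf(v) in [0, 1]."""
    if gate.rate_form == "alpha_beta":
        if "inf" in gate.params:
            _check_v(v)
            return np.clip(_eval_component(gate.params["inf"], v, T), 0.0, 1.0)
        alpha, beta = gate_rates(gate, v, T)
        with np.errstate(invalid="ignore"):
            return np.clip(alpha / (alpha + beta), 0.0, 1.0)
    return gate_rates(gate, v, T)[0]


def gate_time_constant(gate: GateSpec, v, T: float = T_REF):
    """Relaxation time constant tau(v) in ms (tau = 1/(alpha+beta) for
    rate-pair gates)."""
    if gate.rate_form == "alpha_beta":
        alpha, beta = gate_rates(gate, v, T)
        return 1.0 / (alpha + beta)
    return gate_rates(gate, v, T)[1]


def advance_gate(state, gate: GateSpec, v, dt: float, T: float = T_REF):
    """Exact exponential update at frozen voltage:
    m(t+dt) = m_inf + (m - m_inf) * exp(-dt/tau).  Result clamped to [0, 1].
    """
    if dt <= 0:
        raise InputError(f"dt must be > 0, got {dt}")
    state = np.asarray(state, dtype=float)
    if np.any(state < 0) or np.any(state > 1):
        raise StateCorruptionError(f"gate {gate.name!r}: state outside [0, 1]")
    minf = gate_steady_state(gate, v, T)
    tau = gate_time_constant(gate, v, T)
    out = minf + (state - minf) * np.exp(-dt / tau)
    clipped = np.clip(out, 0.0, 1.0)
    excess = np.max(np.abs(out - clipped))
    if excess > 1e-9:
        _log.warning(
            "gate %s: clamped update by %.3g outside [0, 1]", gate.name, excess
        )
    return clipped


def channel_current(channel: ChannelModel, gate_values, v):
    """Membrane current density i = gbar * prod(m_j^p_j) * (v - E_rev) in
    mA/cm^2 (positive = outward)."""
    _check_v(v)
    gate_values = [np.asarray(g, dtype=float) for g in gate_values]
    if len(gate_values) != len(channel.gates):
        raise ConfigurationError(
            f"channel {channel.name!r}: expected {len(channel.gates)} gate values"
        )
    for g in gate_values:
        if np.any(g < 0) or np.any(g > 1):
            raise StateCorruptionError(
                f"channel {channel.name!r}: gate value outside [0, 1]"
            )
    open_frac = 1.0
    for g, spec in zip(gate_values, channel.gates):
        open_frac = open_frac * g**spec.exponent
    return channel.gbar * open_frac * (np.asarray(v, dtype=float) - channel.e_rev)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _gate_from_dict(d: dict) -> GateSpec:
    d = dict(d)
    try:
        name = d.pop("name")
        exponent = int(d.pop("exponent"))
        rate_form = d.pop("rate_form")
    except KeyError as exc:
        raise ConfigurationError(f"gate definition missing key {exc}") from exc
    q10 = bool(d.pop("q10", False))
    return GateSpec(name=name, exponent=exponent, rate_form=rate_form, params=d, q10=q10)


def _channel_from_dict(d: dict) -> ChannelModel:
    try:
        gates = tuple(_gate_from_dict(g) for g in d["gates"])
        return ChannelModel(
            name=d["name"],
            gbar=float(d["gbar"]),
            e_rev=float(d["e_rev"]),
            gates=gates,
            temperature_sensitive=bool(d.get("temperature_sensitive", False)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"channel definition missing key {exc}") from exc


def load_channels(path=None, overrides: dict | None = None) -> list[ChannelModel]:
    """Load channel definitions from a YAML file (the packaged default when
    *path* is None).

    ``overrides`` maps ``channel_name -> {gbar: ..., ...}`` shallow updates;
    ``{channel: None}`` removes a channel (used to study Kv7.2 omission).
    """
    if path is None:
        text = (
            resources.files("entsim").joinpath("data/channels.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    defs = {d["name"]: d for d in raw["channels"]}
    if overrides:
        for name, upd in overrides.items():
            if upd is None:
                defs.pop(name, None)
                continue
            if name not in defs:
                raise ConfigurationError(f"override for unknown channel {name!r}")
            defs[name] = {**defs[name], **upd}
    channels = [_channel_from_dict(d) for d in defs.values()]
    names = [c.name for c in channels]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate channel names: {names}")
    return channels


def default_channels(**overrides) -> list[ChannelModel]:
    """The Table-1 channel set; keyword form of :func:`load_channels`
    overrides, e.g. ``default_channels(kv7_2=None)``."""
    mapped = {k.replace("_", "."): v for k, v in overrides.items()}
    return load_channels(overrides=mapped or None)
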