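"""Convergent network construction, spike generators and weight calibration.

The modelled circuits are small feed-forward motifs: spike generators drive
input neurons one-to-one through a strong ("driving") fast synapse, and each
input neuron projects onto a single recording (output) neuron through one
synapse of a given type.  Because the wiring is acyclic the network is
simulated neuron-by-neuron: generator events -> input-neuron spike times ->
delayed synaptic events on the output neuron.

Synaptic weights onto the output neuron are calibrated by bisection to the
single-event spike threshold (5-pulse-train takeoff criterion for the slow
EPSP, whose conductance change develops over seconds) and then set to 0.95x
(subthreshold) or 1.05x (suprathreshold) of threshold, reproducing the
weight-setting procedure of the modelled experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import default_channels
from .errors import CalibrationError, ConfigurationError
from .neuron import (
    Neuron,
    build_neuron,
    detect_spikes,
    integrate,
)
from .synapses import BiexpSynapse, SlowEpspSynapse, fast_epsp, gabaa, gabac, slow_epsp

__all__ = [
    "SpikeGenerator",
    "Connection",
    "NetworkSpec",
    "NetworkResult",
    "generate_spike_train",
    "calibrate_weight",
    "build_and_run",
    "SYNAPSE_FACTORIES",
]

SYNAPSE_FACTORIES = {
    "fepsp": fast_epsp,
    "gabaa": gabaa,
    "gabac": gabac,
    "sepsp": slow_epsp,
}

#: Takeoff reference for the slow-EPSP calibration criterion (mV): the
#: membrane potential at which the default neuron's regenerative sodium
#: upstroke begins under fast synaptic drive.
V_TAKEOFF = -42.0

#: Driving synapses on input neurons are set to twice the input neuron's own
#: fast-EPSP threshold so that every generator event elicits exactly one
#: input spike.
DRIVING_FACTOR = 2.0

#: Default axonal + synaptic delay (ms) from input-neuron spike to
#: output-neuron conductance onset; equal across connections.
DEFAULT_DELAY = 3.0


@dataclass(frozen=True)
class SpikeGenerator:
    """Burst generator: n_events with i.i.d. uniform inter-spike intervals
    in isi_range (ms), truncated at max_duration; ``deterministic`` fixes the
    ISI at its minimum (a strict-50 Hz mode that removes sampling
    variability)."""

    n_events: int = 5
    isi_range: tuple = (20.0, 30.0)
    max_duration: float = 200.0
    start_time: float = 0.0
    seed: int = 0
    deterministic: bool = False

    def __post_init__(self):
        if self.isi_range[0] > self.isi_range[1]:
            raise ConfigurationError(
                f"isi_range min > max: {self.isi_range}"
            )


def generate_spike_train(gen: SpikeGenerator) -> np.ndarray:
    """Reproducible event times (ms) for one generator."""
    if gen.n_events < 1:
        return np.empty(0)
    if gen.deterministic:
        isis = np.full(gen.n_events - 1, gen.isi_range[0])
    else:
        rng = np.random.default_rng(gen.seed)
        isis = rng.uniform(gen.isi_range[0], gen.isi_range[1], gen.n_events - 1)
    times = gen.start_time + np.concatenate([[0.0], np.cumsum(isis)])
    return times[times - gen.start_time <= gen.max_duration]


@dataclass
class Connection:
    """One input neuron and its synapse onto the output neuron."""

    name: str
    syn_type: str  # fepsp | gabaa | gabac | sepsp
    weight_mode: str | float  # 'sub' | 'supra' | explicit weight
    generator: str
    delay: float = DEFAULT_DELAY
    params: dict = field(default_factory=dict)  # synapse overrides (g_sk, ...)

    def __post_init__(self):
        if self.syn_type not in SYNAPSE_FACTORIES:
            raise ConfigurationError(f"unknown synapse type {self.syn_type!r}")


@dataclass
class NetworkSpec:
    """A convergent motif: named generators, connections, one output neuron."""

    name: str
    connections: list
    generators: dict  # name -> generator config dict
    neuron: dict = field(default_factory=dict)  # build_neuron overrides

    def __post_init__(self):
        names = [c.name for c in self.connections]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate connection names: {names}")
        for c in self.connections:
            if c.generator not in self.generators:
                raise ConfigurationError(
                    f"connection {c.name!r} references unknown generator "
                    f"{c.generator!r}"
                )


@dataclass
class NetworkResult:
    """Traces and event logs from one network simulation."""

    output: object  # SimResult
    output_spikes: np.ndarray
    input_spikes: dict  # generator name -> input-neuron spike times
    generator_events: dict  # generator name -> event times
    weights: dict  # connection name -> weight (uS)
    t_stop: float
    dt: float
    seed: int


def _make_synapse(conn: Connection, weight: float) -> BiexpSynapse | SlowEpspSynapse:
    return SYNAPSE_FACTORIES[conn.syn_type](weight=weight, delay=conn.delay,
                                            **conn.params)


def _output_neuron(spec: NetworkSpec, weights: dict) -> Neuron:
    syns = [_make_synapse(c, weights.get(c.name, 0.0)) for c in spec.connections]
    return build_neuron(synapses=syns, **spec.neuron)


def _probe_events(syn_type: str) -> list:
    # biexp synapses: single-event probe; slow EPSP: the standard 5-pulse
    # 50 Hz train (its sub/supra distinction is a train response)
    if syn_type == "sepsp":
        return [300.0 + 20.0 * i for i in range(5)]
    return [300.0]


def _probe_spikes(spec: NetworkSpec, conn_name: str, weights: dict) -> bool:
    """True if a probe activation of the named connection (all other inputs
    silent) meets the spike / takeoff criterion."""
    conn = next(c for c in spec.connections if c.name == conn_name)
    neuron = _output_neuron(spec, weights)
    for s, c in zip(neuron.synapses, spec.connections):
        if c.name == conn_name:
            s.event_times = _probe_events(conn.syn_type)
    if conn.syn_type == "sepsp":
        t_stop = 6500.0
    else:
        t_stop = 700.0
    res = integrate(neuron, t_stop)
    if conn.syn_type == "sepsp":
        sel = res.t > 300.0
        return bool(res.v_soma[sel].max() >= V_TAKEOFF)
    return detect_spikes(res.t, res.v_soma).size > 0


_calibration_cache: dict = {}


def _cache_key(spec: NetworkSpec, conn: Connection) -> tuple:
    neuron_sig = tuple(sorted((k, repr(v)) for k, v in spec.neuron.items()))
    attached = tuple(
        sorted((c.syn_type, tuple(sorted(c.params.items()))) for c in spec.connections)
    )
    return (neuron_sig, attached, conn.syn_type, tuple(sorted(conn.params.items())))


def threshold_weight(
    spec: NetworkSpec,
    connection: str,
    *,
    w_start: float = 1e-3,
    w_max: float = 2048.0,
    tol: float = 0.01,
    use_cache: bool = True,
) -> float:
    """Bisection for the threshold weight w_th at which a probe activation of
    *connection* first meets the spike criterion, all other inputs silent.

    Raises :class:`CalibrationError` if no weight up to *w_max* evokes a
    response.
    """
    conn = next(c for c in spec.connections if c.name == connection)
    key = _cache_key(spec, conn)
    if use_cache and key in _calibration_cache:
        return _calibration_cache[key]

    weights = {c.name: 0.0 for c in spec.connections}
    lo, hi, w = 0.0, None, w_start
    while w <= w_max:
        weights[connection] = w
        if _probe_spikes(spec, connection, weights):
            hi = w
            break
        lo = w
        w *= 2.0
    if hi is None:
        raise CalibrationError(
            f"{spec.name}/{connection}: no spike up to weight {w_max} uS "
            f"(search bracket [{lo}, {w_max}])"
        )
    while (hi - lo) / hi > tol:
        mid = 0.5 * (lo + hi)
        weights[connection] = mid
        if _probe_spikes(spec, connection, weights):
            hi = mid
        else:
            lo = mid
    if use_cache:
        _calibration_cache[key] = hi
    return hi


def calibrate_weight(spec: NetworkSpec, connection: str, mode: str, **kw) -> float:
    """0.95 x threshold for 'sub', 1.05 x threshold for 'supra'."""
    if mode not in ("sub", "supra"):
        raise ConfigurationError(f"unknown weight mode {mode!r}")
    w_th = threshold_weight(spec, connection, **kw)
    return 0.95 * w_th if mode == "sub" else 1.05 * w_th


def resolve_weights(spec: NetworkSpec) -> dict:
    """Calibrated or explicit weight for every connection."""
    out = {}
    for c in spec.connections:
        if isinstance(c.weight_mode, (int, float)):
            out[c.name] = float(c.weight_mode)
        else:
            out[c.name] = calibrate_weight(spec, c.name, c.weight_mode)
    return out


_driving_cache: dict = {}


def _driving_weight(spec: NetworkSpec) -> float:
    """Weight of the generator->input-neuron driving synapse: twice the
    fast-EPSP threshold of a plain input neuron."""
    key = tuple(sorted((k, repr(v)) for k, v in spec.neuron.items()))
    if key not in _driving_cache:
        probe = NetworkSpec(
            name="_input_probe",
            connections=[Connection("drive", "fepsp", "supra", "g")],
            generators={"g": {}},
            neuron=dict(spec.neuron),
        )
        _driving_cache[key] = DRIVING_FACTOR * threshold_weight(probe, "drive")
    return _driving_cache[key]


def _input_neuron_spikes(
    spec: NetworkSpec, events: np.ndarray, t_stop: float, dt: float
) -> np.ndarray:
    syn = fast_epsp(weight=_driving_weight(spec), delay=1.0)
    syn.event_times = list(events)
    neuron = build_neuron(synapses=[syn], **spec.neuron)
    res = integrate(neuron, t_stop, dt=dt)
    return detect_spikes(res.t, res.v_soma)


def build_and_run(
    spec: NetworkSpec,
    t_stop: float,
    dt: float = 0.025,
    seed: int = 0,
    deterministic_isi: bool = False,
    weights: dict | None = None,
    generator_overrides: dict | None = None,
) -> NetworkResult:
    """Calibrate (unless explicit weights are given), simulate input neurons
    from their generators, deliver their spikes to the output neuron after
    the configured delays, and return all traces and event logs."""
    if weights is None:
        weights = resolve_weights(spec)

    seeds = np.random.SeedSequence(seed).spawn(len(spec.generators))
    gen_events: dict = {}
    input_spikes: dict = {}
    for sub, (gname, gcfg) in zip(seeds, sorted(spec.generators.items())):
        cfg = dict(gcfg)
        if generator_overrides and gname in generator_overrides:
            cfg.update(generator_overrides[gname])
        cfg.setdefault("deterministic", deterministic_isi)
        gen = SpikeGenerator(seed=sub.generate_state(1)[0] % (2**31), **cfg)
        events = generate_spike_train(gen)
        gen_events[gname] = events
        if events.size:
            input_spikes[gname] = _input_neuron_spikes(spec, events, t_stop, dt)
        else:
            input_spikes[gname] = np.empty(0)

    out_neuron = _output_neuron(spec, weights)
    for syn, conn in zip(out_neuron.synapses, spec.connections):
        syn.event_times = list(input_spikes[conn.generator])
    res = integrate(out_neuron, t_stop, dt=dt)
    out_spikes = detect_spikes(res.t, res.v_soma)
    return NetworkResult(
        output=res,
        output_spikes=out_spikes,
        input_spikes=input_spikes,
        generator_events=gen_events,
        weights=dict(weights),
        t_stop=t_stop,
        dt=dt,
        seed=seed,
    )
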