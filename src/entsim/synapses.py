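"""Event-driven synaptic conductances.

Three biexponential conductance synapses (the nicotinic-type fast EPSP and
the GABA_A / GABA_C chloride synapses) plus the slow-EPSP mechanism, in which
presynaptic spikes drive a cAMP -> PKA -> channel-phosphorylation cascade
that closes a resting potassium conductance and so depolarizes the neuron
for tens of seconds.

Biexponential conductances are peak-normalised: ``weight`` is the peak
conductance in uS reached after a single presynaptic event, which makes
synaptic weights comparable across synapse types with very different
kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InputError, StateCorruptionError

__all__ = [
    "BiexpSynapse",
    "CascadeState",
    "SlowEpspSynapse",
    "CASCADE_RATES",
    "fast_epsp",
    "gabaa",
    "gabac",
    "slow_epsp",
    "biexp_peak_time",
    "biexp_peak_factor",
    "biexp_conductance",
    "synapse_current",
    "cascade_step",
    "cascade_fixed_point",
    "slow_epsp_current",
]

#: Second-messenger cascade rates (1/s), cAMP production/removal, catalytic
#: subunit production/removal, phosphorylation and dephosphorylation.
CASCADE_RATES = {
    "alpha1": 0.22,
    "beta1": 0.41,
    "alpha2": 0.22,
    "beta2": 0.27,
    "alpha3": 0.22,
    "beta3": 0.12,
}


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time to peak of exp(-t/tau_decay) - exp(-t/tau_rise):
    t_p = tau_rise*tau_decay/(tau_decay-tau_rise) * ln(tau_decay/tau_rise)."""
    if not tau_decay > tau_rise > 0:
        raise ConfigurationError("need tau_decay > tau_rise > 0")
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    )


def biexp_peak_factor(tau_rise: float, tau_decay: float) -> float:
    """Unnormalised peak amplitude of the biexponential waveform."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    return math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)


@dataclass
class BiexpSynapse:
    """Biexponential conductance synapse.

    Single-event conductance (event at t_e, t >= t_e):
    g(t) = weight/N * (exp(-(t-t_e)/tau_decay) - exp(-(t-t_e)/tau_rise)),
    N the peak factor, so max g = weight.  Events sum linearly.
    """

    tau_rise: float
    tau_decay: float
    e_rev: float
    weight: float = 0.0
    delay: float = 0.0
    event_times: list = field(default_factory=list)
    name: str = "biexp"

    def __post_init__(self):
        if not self.tau_decay > self.tau_rise > 0:
            raise ConfigurationError(
                f"synapse {self.name!r}: need tau_decay > tau_rise > 0"
            )

    @property
    def peak_time(self) -> float:
        return biexp_peak_time(self.tau_rise, self.tau_decay)

    @property
    def peak_factor(self) -> float:
        return biexp_peak_factor(self.tau_rise, self.tau_decay)


def fast_epsp(weight: float = 0.0, delay: float = 0.0, **kw) -> BiexpSynapse:
    """Generic nicotinic/P2X/5-HT3 fast EPSP: tau 1/5 ms, reversal 0 mV."""
    p = {"tau_rise": 1.0, "tau_decay": 5.0, "e_rev": 0.0, "name": "fepsp"}
    p.update(kw)
    return BiexpSynapse(weight=weight, delay=delay, **p)


def gabaa(weight: float = 0.0, delay: float = 0.0, **kw) -> BiexpSynapse:
    """GABA_A chloride synapse: tau 0.285/5.6 ms, E_Cl = -35 mV."""
    p = {"tau_rise": 0.285, "tau_decay": 5.6, "e_rev": -35.0, "name": "gabaa"}
    p.update(kw)
    return BiexpSynapse(weight=weight, delay=delay, **p)


def gabac(weight: float = 0.0, delay: float = 0.0, **kw) -> BiexpSynapse:
    """GABA_C chloride synapse: ~8x slower kinetics than GABA_A
    (tau 20/50 ms), E_Cl = -35 mV."""
    p = {"tau_rise": 20.0, "tau_decay": 50.0, "e_rev": -35.0, "name": "gabac"}
    p.update(kw)
    return BiexpSynapse(weight=weight, delay=delay, **p)


def biexp_conductance(syn: BiexpSynapse, t) -> np.ndarray | float:
    """Total conductance (uS) at time(s) *t* from all delivered events
    (event arrival = event_time + delay).  Causal: zero before the first
    arrival."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("t must be finite")
    g = np.zeros_like(t)
    norm = syn.weight / syn.peak_factor
    for te in syn.event_times:
        dt = t - (te + syn.delay)
        active = dt >= 0
        g = g + np.where(
            active,
            norm * (np.exp(-np.where(active, dt, 0.0) / syn.tau_decay)
                    - np.exp(-np.where(active, dt, 0.0) / syn.tau_rise)),
            0.0,
        )
    return g if g.ndim else float(g)


def synapse_current(g, v, e_rev) -> np.ndarray | float:
    """i = g*(v - E_rev); g in uS, v in mV -> i in nA (positive = outward)."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise StateCorruptionError("synaptic conductance must be >= 0")
    out = g * (np.asarray(v, dtype=float) - e_rev)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# slow EPSP second-messenger cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeState:
    """The slow-EPSP second-messenger triple: D (cAMP), C (PKA catalytic
    subunit), P (unphosphorylated fraction of the slow potassium channel).

    dD/dt = alpha1*I(t) - beta1*D
    dC/dt = alpha2*D^2  - beta2*C
    dP/dt = -alpha3*C*P + beta3*(1 - P)

    Time is in seconds; at rest (I=0) the state is (0, 0, 1).
    """

    D: float = 0.0
    C: float = 0.0
    P: float = 1.0

    def __post_init__(self):
        self._check()

    def _check(self):
        if self.D < 0 or self.C < 0 or not (0.0 <= self.P <= 1.0):
            raise StateCorruptionError(
                f"cascade invariants violated: D={self.D}, C={self.C}, P={self.P}"
            )


def cascade_step(
    state: CascadeState, I: float, dt: float, params: dict | None = None
) -> CascadeState:
    """Advance the cascade by *dt* seconds with agonist level *I* held
    constant over the step.

    D is linear and solved exactly; C and P use exponential updates with the
    driving term frozen at the step's start (D^2 for C, C for P).  This
    preserves positivity of D and C and keeps P in [0, 1] for any
    non-negative agonist and step size.
    """
    if dt <= 0:
        raise InputError(f"dt must be > 0, got {dt}")
    if I < 0:
        raise InputError("agonist level must be >= 0")
    p = CASCADE_RATES if params is None else params
    a1, b1 = p["alpha1"], p["beta1"]
    a2, b2 = p["alpha2"], p["beta2"]
    a3, b3 = p["alpha3"], p["beta3"]

    # exact update of dD/dt = a1*I - b1*D with I constant
    d_inf = a1 * I / b1
    D = d_inf + (state.D - d_inf) * math.exp(-b1 * dt)
    # exponential update of C with source a2*D^2 frozen
    c_inf = a2 * state.D**2 / b2
    C = c_inf + (state.C - c_inf) * math.exp(-b2 * dt)
    # exponential update of P with C frozen: rate = a3*C + b3, target b3/rate
    rate = a3 * state.C + b3
    p_inf = b3 / rate
    P = p_inf + (state.P - p_inf) * math.exp(-rate * dt)
    return CascadeState(D=D, C=C, P=min(max(P, 0.0), 1.0))


def cascade_fixed_point(I: float, params: dict | None = None) -> CascadeState:
    """Closed-form fixed point under constant agonist:
    D* = a1*I/b1, C* = a2*D*^2/b2, P* = b3/(a3*C* + b3)."""
    p = CASCADE_RATES if params is None else params
    D = p["alpha1"] * I / p["beta1"]
    C = p["alpha2"] * D**2 / p["beta2"]
    P = p["beta3"] / (p["alpha3"] * C + p["beta3"])
    return CascadeState(D=D, C=C, P=P)


@dataclass
class SlowEpspSynapse:
    """Slow-EPSP mechanism: a standing potassium conductance g_sK * P that
    the cascade closes (P falls below 1) when agonist arrives.

    Each presynaptic spike contributes a rectangular agonist pulse of
    amplitude ``weight`` (arbitrary units) and duration ``pulse_duration``
    ms; overlapping pulses sum.  At rest P = 1 and the full g_sK contributes
    to the resting membrane balance, so a drop in P is depolarizing.
    """

    g_sk: float = 0.03  # uS; maximum (resting) slow-K conductance
    e_rev: float = -85.0
    weight: float = 0.0  # agonist pulse amplitude per presynaptic spike
    pulse_duration: float = 50.0  # ms
    delay: float = 0.0
    event_times: list = field(default_factory=list)
    cascade: CascadeState = field(default_factory=CascadeState)
    rates: dict = field(default_factory=lambda: dict(CASCADE_RATES))
    name: str = "sepsp"

    def agonist(self, t) -> np.ndarray | float:
        """Total agonist level I(t): sum of active rectangular pulses."""
        t = np.asarray(t, dtype=float)
        I = np.zeros_like(t)
        for te in self.event_times:
            on = te + self.delay
            I = I + self.weight * ((t >= on) & (t < on + self.pulse_duration))
        return I if I.ndim else float(I)

    @property
    def conductance(self) -> float:
        """Current slow-K conductance g_sK * P (uS)."""
        return self.g_sk * self.cascade.P


def slow_epsp(weight: float = 0.0, delay: float = 0.0, **kw) -> SlowEpspSynapse:
    return SlowEpspSynapse(weight=weight, delay=delay, **kw)


def slow_epsp_current(syn: SlowEpspSynapse, v, e_k: float | None = None):
    """i = g_sK * P * (v - E_K) in nA.  Depolarizing relative to rest when P
    has dropped below its resting value (potassium channels closed)."""
    e = syn.e_rev if e_k is None else e_k
    return synapse_current(syn.conductance, v, e)
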