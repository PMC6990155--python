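"""Two-gate Hodgkin-Huxley model of the rapid delayed rectifier current I_Kr.

The current through the hERG (Kv11.1) channel is modelled with the standard
Ohmic expression

    I_Kr = g_Kr * a * r * (V - E_K),

where ``a`` is an activation gate and ``r`` an inactivation gate, each
relaxing first-order towards a voltage-dependent steady state:

    da/dt = (a_inf - a) / tau_a,    dr/dt = (r_inf - r) / tau_r,
    a_inf = k1/(k1+k2), tau_a = 1/(k1+k2),
    r_inf = k4/(k3+k4), tau_r = 1/(k3+k4),
    k1 = p1 exp(p2 V), k2 = p3 exp(-p4 V),
    k3 = p5 exp(p6 V), k4 = p7 exp(-p8 V).

Units
-----
The public interface uses mV throughout.  Inside the rate equations V is in
*volts* (the p2, p4, p6, p8 parameters carry units of 1/V; time constants
come out in seconds) — conversions happen internally, so a 1000x error
cannot leak out.  Conductance g_Kr is in pS and current in pA with the
convention  I [pA] = g_Kr [pS] * a * r * (V - E_K) [mV] * 1e-3,
since 1 pS * 1 mV = 1e-3 pA.

Because the driving voltage is piecewise linear, both gate ODEs are scalar
linear ODEs with piecewise-smooth coefficients.  The simulator advances the
state with the exact exponential update at the voltage of each sampling
sub-interval's midpoint: exact (to machine precision) on constant-voltage
steps, second-order accurate on ramps, and trivially correct across segment
discontinuities because sampling intervals never straddle a boundary on the
default grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .protocol import VoltageProtocol

__all__ = [
    "KineticParameters",
    "GateState",
    "IonicEnvironment",
    "CurrentTrace",
    "nernst_potential",
    "read_trace",
    "write_trace",
    "transition_rates",
    "gate_steady_state",
    "steady_state_init",
    "simulate",
    "SimulationError",
]

GAS_CONSTANT = 8.314       # J / (K mol)
FARADAY = 96485.0          # C / mol

N_PARAMETERS = 9


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class KineticParameters:
    """The nine positive model parameters theta = {g_Kr, p1..p8}.

    g_Kr in pS; p1, p3, p5, p7 in 1/s; p2, p4, p6, p8 in 1/V.
    """

    g_kr: float
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("all nine parameters must be finite and > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.g_kr, self.p1, self.p2, self.p3, self.p4,
                         self.p5, self.p6, self.p7, self.p8], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "KineticParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_PARAMETERS,):
            raise ValueError(f"expected {N_PARAMETERS} parameters, got shape {theta.shape}")
        return cls(*theta)

    def log_transform(self) -> np.ndarray:
        """phi = ln(theta), elementwise."""
        return np.log(self.as_array())

    @classmethod
    def from_log(cls, phi) -> "KineticParameters":
        return cls.from_array(np.exp(np.asarray(phi, dtype=float)))


#: Room-temperature manual-patch parameter set (Beattie et al. cell #5),
#: converted to this module's s / V unit convention; used as the default
#: reference parameterisation for simulations and synthetic studies.
BEATTIE_REFERENCE = KineticParameters(
    g_kr=152400.0,   # pS  (0.1524 uS)
    p1=0.226,        # 1/s
    p2=69.9,         # 1/V
    p3=0.0345,       # 1/s
    p4=54.62,        # 1/V
    p5=87.3,         # 1/s
    p6=8.91,         # 1/V
    p7=5.15,         # 1/s
    p8=31.58,        # 1/V
)


@dataclass(frozen=True)
class GateState:
    a: float
    r: float

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.r <= 1.0):
            raise ValueError(f"gate occupancies must lie in [0, 1], got a={self.a}, r={self.r}")


@dataclass(frozen=True)
class IonicEnvironment:
    """Temperature and K+ concentrations fixing the Nernst potential."""

    temperature: float = 298.15  # K (25 C)
    k_out: float = 4.0           # mM, extracellular K+
    k_in: float = 110.0          # mM, intracellular K+
    valency: int = 1

    def __post_init__(self):
        if self.temperature <= 0 or self.k_out <= 0 or self.k_in <= 0:
            raise ValueError("temperature and concentrations must be > 0")


@dataclass(frozen=True)
class CurrentTrace:
    """A uniformly sampled current trace (times in s, currents in pA)."""

    times: np.ndarray
    currents: np.ndarray
    protocol_name: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.currents, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and currents must be equal-length 1-D arrays")
        if t.size >= 2:
            dt = np.diff(t)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be strictly increasing and uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "currents", c)

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.times >= t_start) & (self.times < t_end)

    def with_currents(self, currents) -> "CurrentTrace":
        return CurrentTrace(self.times, np.asarray(currents, float), self.protocol_name)


def write_trace(trace: CurrentTrace, path) -> None:
    """Write a trace as CSV with columns time_s, current_pA."""
    np.savetxt(path, np.column_stack([trace.times, trace.currents]),
               delimiter=",", header="time_s,current_pA", comments="", fmt="%.17g")


def read_trace(path, protocol_name: str = "") -> CurrentTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return CurrentTrace(data[:, 0], data[:, 1], protocol_name)


def nernst_potential(env: IonicEnvironment) -> float:
    """Reversal (Nernst) potential E_K in mV: (RT/zF) ln([K]o/[K]i)."""
    volts = (GAS_CONSTANT * env.temperature) / (env.valency * FARADAY) * math.log(
        env.k_out / env.k_in
    )
    return volts * 1e3


def transition_rates(theta: KineticParameters, v_mv: float):
    """The four voltage-dependent rates (1/s) at membrane voltage ``v_mv``."""
    v = v_mv * 1e-3  # rate equations take volts
    k1 = theta.p1 * math.exp(theta.p2 * v)
    k2 = theta.p3 * math.exp(-theta.p4 * v)
    k3 = theta.p5 * math.exp(theta.p6 * v)
    k4 = theta.p7 * math.exp(-theta.p8 * v)
    return k1, k2, k3, k4


def gate_steady_state(theta: KineticParameters, v_mv: float):
    """(a_inf, r_inf, tau_a, tau_r) at voltage ``v_mv`` (tau in seconds)."""
    k1, k2, k3, k4 = transition_rates(theta, v_mv)
    return k1 / (k1 + k2), k4 / (k3 + k4), 1.0 / (k1 + k2), 1.0 / (k3 + k4)


def steady_state_init(theta: KineticParameters, v_hold: float) -> GateState:
    a_inf, r_inf, _, _ = gate_steady_state(theta, v_hold)
    return GateState(a_inf, r_inf)


@njit(cache=True, fastmath=True)
def _integrate_gates(v_mid, dt, p1, p2, p3, p4, p5, p6, p7, p8, a0, r0):  # pragma: no cover
    """Exponential-integrator march of the two gates.

    ``v_mid[k]`` is the voltage (in volts) at the midpoint of the k-th
    sampling sub-interval; returns gate values on the n = len(v_mid)+1
    sample instants.
    """
    n = v_mid.size + 1
    a = np.empty(n)
    r = np.empty(n)
    a[0] = a0
    r[0] = r0
    for k in range(n - 1):
        v = v_mid[k]
        k1 = p1 * math.exp(p2 * v)
        k2 = p3 * math.exp(-p4 * v)
        k3 = p5 * math.exp(p6 * v)
        k4 = p7 * math.exp(-p8 * v)
        sa = k1 + k2
        sr = k3 + k4
        a_inf = k1 / sa
        r_inf = k4 / sr
        ea = math.exp(-dt * sa)
        er = math.exp(-dt * sr)
        a[k + 1] = a_inf + (a[k] - a_inf) * ea
        r[k + 1] = r_inf + (r[k] - r_inf) * er
    return a, r


def simulate(
    theta: KineticParameters,
    protocol: VoltageProtocol,
    env: IonicEnvironment | None = None,
    init: GateState | str = "steady",
    v_offset: float = 0.0,
):
    """Simulate I_Kr under ``protocol`` and return ``(CurrentTrace, gates)``.

    ``init="steady"`` starts the gates at their steady state for the
    protocol's first voltage.  ``v_offset`` (mV) is an additive voltage-clamp
    error applied to the voltage the channel experiences — the returned trace
    still reports nominal protocol timing, mirroring how a real amplifier
    records the commanded protocol.

    ``gates`` is an (n, 2) array of the a/r trajectories on the sample grid.
    """
    if env is None:
        env = IonicEnvironment()
    e_k = nernst_potential(env)
    times = protocol.times()
    if times.size < 2:
        raise SimulationError("protocol grid has fewer than 2 samples")
    dt = protocol.sampling_interval
    v_samp = protocol.voltages(times) + v_offset            # mV, channel-experienced
    v_mid = (protocol.voltages(times[:-1] + 0.5 * dt) + v_offset) * 1e-3  # volts

    if init == "steady":
        g0 = steady_state_init(theta, float(v_samp[0]))
    elif isinstance(init, GateState):
        g0 = init
    else:
        raise ValueError("init must be a GateState or 'steady'")

    a, r = _integrate_gates(
        v_mid, dt,
        theta.p1, theta.p2, theta.p3, theta.p4,
        theta.p5, theta.p6, theta.p7, theta.p8,
        g0.a, g0.r,
    )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(r))):
        bad = int(np.argmax(~(np.isfinite(a) & np.isfinite(r))))
        raise SimulationError(f"gate integration failed at t={times[bad]:.6f} s")
    current = theta.g_kr * a * r * (v_samp - e_k) * 1e-3  # pA
    trace = CurrentTrace(times, current, protocol.name)
    return trace, np.column_stack([a, r])
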