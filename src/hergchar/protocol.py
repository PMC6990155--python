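"""Piecewise-linear voltage-clamp protocols.

A protocol is an ordered list of segments, each either a constant-voltage
*step* or a linear *ramp*, matching the waveform classes that automated
patch-clamp platforms can execute.  Time is protocol-local, 0-based, and
segments are half-open: segment ``i`` owns ``[t_i, t_{i+1})`` except that
``voltage_at`` is left-continuous at interior boundaries (the boundary
instant reports the voltage the amplifier was holding up to it).

The module ships the 15 s "staircase" calibration protocol — an
information-rich sequence of 500 ms steps spanning -120 to +40 mV, bracketed
by a leak-estimation ramp (-120 to -80 mV over 400 ms) at the start and a
100 ms reversal-potential ramp at 14.41 s — plus simplified step/ramp
templates for classical validation protocols.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ProtocolSegment",
    "VoltageProtocol",
    "StaircaseConfig",
    "build_staircase",
    "build_activation_iv",
    "build_inactivation_iv",
    "build_ap_like",
    "read_protocol",
    "write_protocol",
    "ProtocolError",
    "ProtocolParseError",
]

#: Default sampling interval, 0.1 ms (10 kHz acquisition).
DEFAULT_SAMPLING_INTERVAL = 1e-4

#: Tolerance on total-duration bookkeeping: one microsecond.
DURATION_TOL = 1e-6


class ProtocolError(ValueError):
    """Invalid protocol configuration or out-of-domain query."""


class ProtocolParseError(ProtocolError):
    """Malformed protocol file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ProtocolSegment:
    """One step or ramp: ``kind`` is ``"step"`` or ``"ramp"``.

    Durations are in seconds, voltages in mV.  A step must have
    ``v_start == v_end``.
    """

    kind: str
    duration: float
    v_start: float
    v_end: float

    def __post_init__(self):
        if self.kind not in ("step", "ramp"):
            raise ProtocolError(f"unknown segment kind {self.kind!r}")
        if not (self.duration > 0) or not math.isfinite(self.duration):
            raise ProtocolError(f"segment duration must be > 0, got {self.duration}")
        if not (math.isfinite(self.v_start) and math.isfinite(self.v_end)):
            raise ProtocolError("segment voltages must be finite")
        if self.kind == "step" and self.v_start != self.v_end:
            raise ProtocolError(
                f"step segment requires v_start == v_end, got {self.v_start} != {self.v_end}"
            )

    def voltage(self, s: float) -> float:
        """Voltage at segment-local time ``s`` in ``[0, duration]``."""
        if self.kind == "step":
            return self.v_start
        return self.v_start + (self.v_end - self.v_start) * (s / self.duration)


def step(duration: float, v: float) -> ProtocolSegment:
    return ProtocolSegment("step", duration, v, v)


def ramp(duration: float, v_start: float, v_end: float) -> ProtocolSegment:
    return ProtocolSegment("ramp", duration, v_start, v_end)


@dataclass(frozen=True)
class VoltageProtocol:
    name: str
    segments: tuple[ProtocolSegment, ...]
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ProtocolError("protocol needs at least one segment")
        if not (self.sampling_interval > 0):
            raise ProtocolError("sampling_interval must be > 0")
        bounds = np.cumsum([s.duration for s in self.segments])
        object.__setattr__(self, "_bounds", bounds)

    @property
    def total_duration(self) -> float:
        return float(self._bounds[-1])

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times (seconds)."""
        return self._bounds.copy()

    def with_sampling_interval(self, dt: float) -> "VoltageProtocol":
        return replace(self, sampling_interval=dt)

    def segment_index(self, t: float) -> int:
        """Index of the segment owning time ``t`` (left-continuous)."""
        if not (0 <= t < self.total_duration):
            raise ProtocolError(
                f"t={t} outside [0, {self.total_duration}) for protocol {self.name!r}"
            )
        # side='left' makes the boundary instant belong to the earlier segment.
        i = int(np.searchsorted(self._bounds, t, side="left"))
        return min(i, len(self.segments) - 1)

    def voltage_at(self, t: float) -> float:
        """V(t) in mV; left-continuous at segment boundaries."""
        i = self.segment_index(t)
        t0 = 0.0 if i == 0 else float(self._bounds[i - 1])
        return self.segments[i].voltage(t - t0)

    def times(self) -> np.ndarray:
        """The sampling grid ``0, dt, 2dt, ...`` strictly inside the protocol."""
        n = int(round(self.total_duration / self.sampling_interval))
        t = np.arange(n) * self.sampling_interval
        return t[t < self.total_duration - 1e-12 * self.total_duration]

    def voltages(self, times: np.ndarray | None = None) -> np.ndarray:
        """Vectorised V(t) over ``times`` (defaults to the sampling grid)."""
        if times is None:
            times = self.times()
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < 0 or times.max() >= self.total_duration):
            raise ProtocolError("times outside protocol domain")
        idx = np.searchsorted(self._bounds, times, side="left")
        idx = np.minimum(idx, len(self.segments) - 1)
        starts = np.concatenate([[0.0], self._bounds[:-1]])
        v = np.empty_like(times)
        for i, seg in enumerate(self.segments):
            m = idx == i
            if not m.any():
                continue
            s = times[m] - starts[i]
            if seg.kind == "step":
                v[m] = seg.v_start
            else:
                v[m] = seg.v_start + (seg.v_end - seg.v_start) * (s / seg.duration)
        return v

    def segment_window(self, index: int) -> tuple[float, float]:
        """``(t_start, t_end)`` of segment ``index``."""
        t0 = 0.0 if index == 0 else float(self._bounds[index - 1])
        return t0, float(self._bounds[index])


def voltage_at(protocol: VoltageProtocol, t: float) -> float:
    return protocol.voltage_at(t)


# ---------------------------------------------------------------------------
# Staircase builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the 15 s staircase calibration protocol.

    The shipped defaults reproduce the protocol's described structure: a
    -120 to -80 mV leak ramp within the first second, a 1 s activation step
    to +40 mV before the main staircase, 500 ms staircase steps moving in
    20/40 mV increments between -120 and +40 mV, a +40 mV activation step
    immediately before the 100 ms reversal ramp starting at 14.41 s, and a
    return to the -80 mV holding potential at 15 s.  The per-step staircase
    voltages are a parameterised approximation of the published waveform
    (whose exact table is not in the main text).
    """

    holding: float = -80.0
    step_time: float = 0.5  # s, main staircase steps
    leak_ramp_duration: float = 0.4  # s
    leak_ramp_from: float = -120.0
    reversal_ramp_start: float = 14.41  # s
    reversal_ramp_duration: float = 0.1  # s
    reversal_ramp_from: float = -70.0
    reversal_ramp_to: float = -110.0
    activation_voltage: float = 40.0
    total_duration: float = 15.0
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL
    #: main staircase step voltages (mV), 500 ms each
    staircase_voltages: tuple[float, ...] = (
        -60.0, -80.0, -40.0, -60.0, -20.0, -40.0, 0.0, -20.0, 20.0, 0.0, 40.0,
        20.0, 40.0, 0.0, 20.0, -20.0, 0.0, -40.0, -20.0, -60.0, -40.0, -80.0,
    )


def build_staircase(config: StaircaseConfig | None = None) -> VoltageProtocol:
    """Assemble the staircase protocol from ``config`` (defaults shown above).

    Raises :class:`ProtocolError` if the configured pieces cannot fit the
    declared total duration.
    """
    c = config or StaircaseConfig()
    segs = [
        step(0.2, c.holding),
        step(0.05, c.leak_ramp_from),
        ramp(c.leak_ramp_duration, c.leak_ramp_from, c.holding),
        step(0.25, c.holding),
        step(1.0, c.activation_voltage),       # first +40 mV step (pre-staircase)
        step(0.5, -120.0),                     # deep deactivation; rectification window
        step(0.5, c.holding),
    ]
    for v in c.staircase_voltages:
        segs.append(step(c.step_time, v))
    t_now = sum(s.duration for s in segs)
    pre_ramp = c.reversal_ramp_start - t_now
    if pre_ramp <= 0:
        raise ProtocolError(
            f"staircase overruns the reversal ramp start ({t_now:.3f} s >= "
            f"{c.reversal_ramp_start} s); shorten the staircase"
        )
    segs.append(step(pre_ramp, c.activation_voltage))  # activation before reversal ramp
    segs.append(ramp(c.reversal_ramp_duration, c.reversal_ramp_from, c.reversal_ramp_to))
    tail = c.total_duration - (c.reversal_ramp_start + c.reversal_ramp_duration)
    if tail <= 0:
        raise ProtocolError("reversal ramp overruns the total duration")
    segs.append(step(tail, c.holding))
    proto = VoltageProtocol("staircase", tuple(segs), c.sampling_interval)
    if abs(proto.total_duration - c.total_duration) > DURATION_TOL:
        raise ProtocolError(
            f"assembled duration {proto.total_duration} != {c.total_duration}"
        )
    vs = [s.v_start for s in segs] + [s.v_end for s in segs]
    if min(vs) < -120.0 - 1e-9 or max(vs) > 40.0 + 1e-9:
        raise ProtocolError("staircase voltages outside [-120, +40] mV")
    return proto


# ---------------------------------------------------------------------------
# Simplified validation-protocol templates
# ---------------------------------------------------------------------------

def build_activation_iv(
    test_voltages=(-60.0, -40.0, -20.0, 0.0, 20.0, 40.0),
    holding: float = -80.0,
    activation_time: float = 2.0,
    tail_voltage: float = -40.0,
    tail_time: float = 1.0,
    sampling_interval: float = 1e-3,
) -> VoltageProtocol:
    """Classical activation I-V: hold, depolarising test step, tail at -40 mV.

    A simplified parameterised stand-in for the platform's activation
    protocol; one sweep concatenates all test potentials.
    """
    segs = []
    for v in test_voltages:
        segs += [step(0.5, holding), step(activation_time, v), step(tail_time, tail_voltage)]
    segs.append(step(0.5, holding))
    return VoltageProtocol("activation_iv", tuple(segs), sampling_interval)


def build_inactivation_iv(
    test_voltages=(-120.0, -100.0, -80.0, -60.0, -40.0, -20.0),
    holding: float = -80.0,
    activation_voltage: float = 40.0,
    activation_time: float = 1.0,
    test_time: float = 0.05,
    sampling_interval: float = 1e-3,
) -> VoltageProtocol:
    """Steady-state inactivation: open at +40 mV, brief test steps."""
    segs = []
    for v in test_voltages:
        segs += [step(0.5, holding), step(activation_time, activation_voltage),
                 step(test_time, v), step(0.5, holding)]
    return VoltageProtocol("inactivation_iv", tuple(segs), sampling_interval)


def build_ap_like(
    frequency_hz: float = 1.0,
    n_beats: int = 5,
    holding: float = -80.0,
    peak: float = 40.0,
    plateau: float = 20.0,
    sampling_interval: float = 1e-3,
) -> VoltageProtocol:
    """Action-potential-like clamp from ramps and steps (hardware-compatible).

    Each beat: fast upstroke ramp to ``peak``, brief plateau, repolarising
    ramp back to ``holding``, diastolic hold to fill the cycle length.
    """
    if frequency_hz <= 0 or n_beats < 1:
        raise ProtocolError("frequency and beat count must be positive")
    cycle = 1.0 / frequency_hz
    upstroke, plateau_t, repol = 0.01, 0.05, 0.25
    diastole = cycle - (upstroke + plateau_t + repol)
    if diastole <= 0:
        raise ProtocolError("cycle too short for the AP template")
    segs = [step(0.5, holding)]
    for _ in range(n_beats):
        segs += [
            ramp(upstroke, holding, peak),
            step(plateau_t, plateau),
            ramp(repol, plateau, holding),
            step(diastole, holding),
        ]
    return VoltageProtocol(f"ap_{frequency_hz:g}hz", tuple(segs), sampling_interval)


# ---------------------------------------------------------------------------
# File I/O: plain-text CSV, one row per segment
# ---------------------------------------------------------------------------

_HEADER = ["kind", "duration_s", "v_start_mV", "v_end_mV"]


def write_protocol(protocol: VoltageProtocol, path) -> None:
    """Write a protocol table (CSV: kind, duration_s, v_start_mV, v_end_mV).

    Durations are written at microsecond resolution, voltages to 3 d.p., so
    ``read_protocol(write_protocol(p))`` is the identity at that precision.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for s in protocol.segments:
            w.writerow([s.kind, f"{s.duration:.6f}", f"{s.v_start:.3f}", f"{s.v_end:.3f}"])


def read_protocol(path, name: str | None = None,
                  sampling_interval: float = DEFAULT_SAMPLING_INTERVAL) -> VoltageProtocol:
    """Read a protocol table written by :func:`write_protocol`.

    Raises :class:`ProtocolParseError` (naming the line) on a missing or
    wrong header, malformed fields, nonpositive durations, or a step whose
    start and end voltages differ.
    """
    import os

    segs = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ProtocolParseError("empty file", line=1) from None
        if [h.strip() for h in header] != _HEADER:
            raise ProtocolParseError(
                f"expected header {','.join(_HEADER)!r}, got {','.join(header)!r}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ProtocolParseError(f"expected 4 fields, got {len(row)}", line=lineno)
            kind = row[0].strip()
            try:
                duration, v0, v1 = (float(x) for x in row[1:])
            except ValueError:
                raise ProtocolParseError(f"non-numeric field in {row!r}", line=lineno) from None
            try:
                segs.append(ProtocolSegment(kind, duration, v0, v1))
            except ProtocolError as e:
                raise ProtocolParseError(str(e), line=lineno) from None
    if not segs:
        raise ProtocolParseError("no segments in file", line=2)
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return VoltageProtocol(name, tuple(segs), sampling_interval)
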