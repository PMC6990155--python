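"""Leak correction, blocker subtraction, and reversal-potential estimation.

The observed control-condition current is assumed to decompose as
I_obs = I_Kr + I_endogenous + I_leak, with the leak linear in voltage,
I_leak = g_leak (V - E_leak).  The leak conductance is estimated by
ordinary least squares of current against voltage over the protocol's leak
ramp (-120 to -80 mV, where hERG is essentially closed), separately for the
control and blocker sweeps; subtracting the leak-corrected blocker sweep
from the leak-corrected control sweep then removes the endogenous
background and yields I_Kr.

Two auxiliary operations mirror platform practice: a post-hoc leak
*rectification* that removes any residual linear leak by zeroing the mean
current over a window where I_Kr should vanish, and an estimator of the
reversal potential E_K from the sign change of the current-voltage relation
along the 100 ms reversal ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CurrentTrace
from .protocol import VoltageProtocol
from .synthetic import LeakModel

__all__ = [
    "TimeWindow",
    "LeakFit",
    "estimate_leak_from_ramp",
    "estimate_leak_from_step",
    "subtract_leak",
    "e4031_subtract",
    "rectify_leak",
    "estimate_reversal",
    "estimate_voltage_offset",
    "preprocess_well",
    "PreprocessError",
    "default_leak_ramp_window",
    "default_zero_window",
    "default_reversal_window",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class TimeWindow:
    t_start: float
    t_end: float

    def __post_init__(self):
        if not (0 <= self.t_start < self.t_end):
            raise PreprocessError(f"invalid window [{self.t_start}, {self.t_end})")


@dataclass(frozen=True)
class LeakFit:
    """Estimated leak model plus regression diagnostics."""

    leak: LeakModel
    r_squared: float
    residual_sd: float
    n_samples: int


def _find_ramp(protocol: VoltageProtocol, v_from: float, v_to: float) -> int:
    for i, seg in enumerate(protocol.segments):
        if seg.kind == "ramp" and seg.v_start == v_from and seg.v_end == v_to:
            return i
    raise PreprocessError(f"no {v_from}->{v_to} mV ramp in protocol {protocol.name!r}")


def default_leak_ramp_window(protocol: VoltageProtocol) -> TimeWindow:
    """The -120 to -80 mV leak-ramp span of the staircase protocol."""
    i = _find_ramp(protocol, -120.0, -80.0)
    t0, t1 = protocol.segment_window(i)
    return TimeWindow(t0, t1)


def default_reversal_window(protocol: VoltageProtocol) -> TimeWindow:
    """The 100 ms reversal-ramp span (the protocol's last ramp)."""
    ramps = [i for i, s in enumerate(protocol.segments) if s.kind == "ramp"]
    if not ramps:
        raise PreprocessError("protocol has no ramps")
    t0, t1 = protocol.segment_window(ramps[-1])
    return TimeWindow(t0, t1)


def default_zero_window(protocol: VoltageProtocol) -> TimeWindow:
    """Window where I_Kr ~ 0: the last 100 ms of the -120 mV step that
    follows the first +40 mV activation step (deactivation at -120 mV has a
    ~40 ms time constant, so the tail has fully decayed by then)."""
    segs = protocol.segments
    for i in range(1, len(segs)):
        if segs[i].kind == "step" and segs[i].v_start == -120.0 \
                and segs[i - 1].kind == "step" and segs[i - 1].v_start == 40.0:
            t0, t1 = protocol.segment_window(i)
            return TimeWindow(max(t0, t1 - 0.1), t1)
    raise PreprocessError("no -120 mV step following a +40 mV step")


def _window_arrays(trace: CurrentTrace, protocol: VoltageProtocol, window: TimeWindow):
    m = trace.window_mask(window.t_start, window.t_end)
    t = trace.times[m]
    return protocol.voltages(t), trace.currents[m]


def estimate_leak_from_ramp(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    ramp_window: TimeWindow | None = None,
) -> LeakFit:
    """OLS fit of I against V over the leak ramp.

    g_leak is the slope (nS) and E_leak = -intercept/slope (mV); if the
    slope is exactly zero the leak is a pure offset and E_leak is reported
    as 0 with the offset folded into a zero-conductance model.
    """
    if ramp_window is None:
        ramp_window = default_leak_ramp_window(protocol)
    # the window must lie inside a ramp segment
    for t_probe in (ramp_window.t_start, min(ramp_window.t_end, protocol.total_duration) - 1e-9):
        seg = protocol.segments[protocol.segment_index(t_probe + 1e-12)]
        if seg.kind != "ramp":
            raise PreprocessError("leak window must lie within the leak ramp")
    v, i = _window_arrays(trace, protocol, ramp_window)
    if v.size < 10:
        raise PreprocessError(f"need >= 10 samples in the leak window, got {v.size}")
    design = np.column_stack([v, np.ones_like(v)])
    (slope, intercept), *_ = np.linalg.lstsq(design, i, rcond=None)
    resid = i - (slope * v + intercept)
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if slope == 0.0:
        leak = LeakModel(0.0, 0.0)
    else:
        leak = LeakModel(float(slope), float(-intercept / slope))
    dof = max(v.size - 2, 1)
    return LeakFit(leak, r2, float(np.sqrt(np.sum(resid**2) / dof)), int(v.size))


def estimate_leak_from_step(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    window_a: TimeWindow,
    window_b: TimeWindow,
) -> LeakFit:
    """Two-plateau leak estimate (the platform's -80/-100 mV step method).

    Uses the mean current on two constant-voltage plateaus; intended for
    validation protocols that carry a leak step instead of a ramp.
    """
    va, ia = _window_arrays(trace, protocol, window_a)
    vb, ib = _window_arrays(trace, protocol, window_b)
    if va.size < 2 or vb.size < 2:
        raise PreprocessError("leak-step windows too small")
    v1, v2 = float(va.mean()), float(vb.mean())
    if v1 == v2:
        raise PreprocessError("leak-step windows have equal voltage")
    i1, i2 = float(ia.mean()), float(ib.mean())
    g = (i1 - i2) / (v1 - v2)
    e = v1 - i1 / g if g != 0 else 0.0
    leak = LeakModel(g, e) if g != 0 else LeakModel(0.0, 0.0)
    return LeakFit(leak, 1.0, float(np.sqrt((ia.var() + ib.var()) / 2)), int(va.size + vb.size))


def subtract_leak(trace: CurrentTrace, leak: LeakModel, protocol: VoltageProtocol) -> CurrentTrace:
    """I(t) - g_leak (V(t) - E_leak); linear, hence exactly invertible."""
    v = protocol.voltages(trace.times)
    return trace.with_currents(trace.currents - leak.current(v))


def e4031_subtract(control_corrected: CurrentTrace, blocker_corrected: CurrentTrace) -> CurrentTrace:
    """Leak-corrected control minus leak-corrected blocker sweep -> I_Kr."""
    if control_corrected.times.shape != blocker_corrected.times.shape or not np.allclose(
        control_corrected.times, blocker_corrected.times
    ):
        raise PreprocessError("control and blocker sweeps are on different grids")
    return control_corrected.with_currents(
        control_corrected.currents - blocker_corrected.currents
    )


def rectify_leak(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    zero_window: TimeWindow | None = None,
):
    """Remove residual linear leak g* (V + 80 mV) so the mean current over
    ``zero_window`` (where I_Kr should be ~0) is exactly zero.

    Returns ``(rectified trace, g_star)``.  Raises if the window's mean
    driving term V + 80 vanishes (g* unidentifiable there).
    """
    if zero_window is None:
        zero_window = default_zero_window(protocol)
    m = trace.window_mask(zero_window.t_start, zero_window.t_end)
    if not m.any():
        raise PreprocessError("zero window contains no samples")
    v = protocol.voltages(trace.times)
    drive = v + 80.0
    mean_drive = float(drive[m].mean())
    if mean_drive == 0.0:
        raise PreprocessError("mean(V + 80 mV) is zero on the window; g* unidentifiable")
    g_star = float(trace.currents[m].mean()) / mean_drive
    return trace.with_currents(trace.currents - g_star * drive), g_star


def estimate_reversal(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    ramp_window: TimeWindow | None = None,
    fit_halfwidth_mv: float = 10.0,
    degree: int = 3,
) -> float:
    """Estimate E_K (mV) from the current's sign change on the reversal ramp.

    Samples inside the window are mapped to (V, I) pairs through the ramp;
    a local polynomial (default cubic) is fitted to I(V) within
    ``fit_halfwidth_mv`` of the observed sign change and its real root
    nearest the crossing is returned.  Raises if the current does not
    change sign within the window.
    """
    if ramp_window is None:
        ramp_window = default_reversal_window(protocol)
    v, i = _window_arrays(trace, protocol, ramp_window)
    if v.size < degree + 2:
        raise PreprocessError("too few samples on the reversal ramp")
    order = np.argsort(v)
    v, i = v[order], i[order]
    signs = np.sign(i)
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    if crossings.size == 0:
        raise PreprocessError("current does not change sign within the reversal window")
    k = int(crossings[0])
    v_cross = 0.5 * (v[k] + v[k + 1])
    sel = np.abs(v - v_cross) <= fit_halfwidth_mv
    if sel.sum() < degree + 1:
        sel = slice(None)
    coeffs = np.polyfit(v[sel] - v_cross, i[sel], deg=degree)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8].real
    if real.size == 0:
        raise PreprocessError("polynomial fit has no real root near the crossing")
    return float(v_cross + real[np.argmin(np.abs(real))])


def estimate_voltage_offset(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    env=None,
    ramp_window: TimeWindow | None = None,
) -> float:
    """Estimated per-well voltage-clamp error Delta-V (mV).

    If the channel experiences V + Delta-V while the amplifier commands V,
    the observed zero crossing on the reversal ramp sits at
    E_K - Delta-V in command coordinates, so
    Delta-V = E_K(Nernst) - E_K(estimated).
    """
    from .model import IonicEnvironment, nernst_potential

    env = env or IonicEnvironment()
    return nernst_potential(env) - estimate_reversal(trace, protocol, ramp_window)


def preprocess_well(
    well,
    protocol: VoltageProtocol,
    sweep: int = 0,
    rectify: bool = False,
    true_leaks: tuple | None = None,
):
    """Standard staircase preprocessing for one well.

    Leak-corrects the chosen control/blocker sweep pair (ramp-regression
    estimates, or the supplied ``true_leaks=(leak_a, leak_b)``), subtracts
    the blocker sweep, and optionally applies post-hoc rectification.

    Returns ``(I_Kr trace, info dict)`` where info carries the leak fits
    and, when the reversal ramp is present and crossed, the E_K estimate.
    """
    control = well.control_sweeps[sweep]
    blocker = well.blocker_sweeps[sweep]
    info = {}
    if true_leaks is not None:
        leak_a, leak_b = true_leaks
    else:
        fit_a = estimate_leak_from_ramp(control, protocol)
        fit_b = estimate_leak_from_ramp(blocker, protocol)
        info["leak_fit_a"], info["leak_fit_b"] = fit_a, fit_b
        leak_a, leak_b = fit_a.leak, fit_b.leak
    corrected = e4031_subtract(
        subtract_leak(control, leak_a, protocol),
        subtract_leak(blocker, leak_b, protocol),
    )
    if rectify:
        corrected, g_star = rectify_leak(corrected, protocol)
        info["g_star"] = g_star
    try:
        info["e_k_estimate"] = estimate_reversal(corrected, protocol)
    except PreprocessError:
        info["e_k_estimate"] = None
    return corrected, info
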