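"""Automated quality control for staircase-protocol recordings (QC1-QC6).

Sixteen boolean sub-criteria, each a pure function of its inputs:

* QC1 — electrical health: R_seal in [0.1, 1000] GOhm, C_m in [1, 100] pF,
  R_series in [1, 25] MOhm (closed intervals).
* QC2 — signal-to-noise ratio over 25, on raw and subtracted traces, with
  SNR = var(trace) / var(noise).
* QC3 — sweep-to-sweep stability: RMSD of the two repeats below 0.2 x the
  mean RMSD-to-zero of the repeats, for raw, blocker, and subtracted traces.
* QC4 — R_seal / C_m / R_series drift before vs after blocker: two-point
  population std/mean < 0.5 (strict).
* QC5 — the blocker must actually remove current: max |I| in the second
  half of the staircase drops by >= 75%; RMSD-to-zero of the whole trace
  drops by >= 50% (QC5.1).
* QC6 — no leak overcorrection: the mean subtracted current during each of
  the three designated +40 mV steps must exceed -2 x the estimated noise
  level.

The estimated noise level is the SD of the subtracted current over the
first 200 ms at holding potential.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import CurrentTrace
from .preprocess import TimeWindow, preprocess_well
from .protocol import VoltageProtocol
from .synthetic import WellMetadata, WellRecording

__all__ = [
    "QCReport",
    "snr",
    "qc1",
    "qc3_stability",
    "qc4_drift",
    "qc5_block",
    "qc6_overcorrection",
    "run_qc",
    "NOISE_WINDOW",
    "SNR_THRESHOLD",
]

#: Quiet holding-potential window used to estimate the noise level.
NOISE_WINDOW = TimeWindow(0.0, 0.2)

SNR_THRESHOLD = 25.0

CRITERIA = (
    "QC1.Rseal", "QC1.Cm", "QC1.Rseries",
    "QC2.raw", "QC2.subtracted",
    "QC3.raw", "QC3.E4031", "QC3.subtracted",
    "QC4.Rseal", "QC4.Cm", "QC4.Rseries",
    "QC5.staircase", "QC5.1.staircase",
    "QC6.subtracted", "QC6.1.subtracted", "QC6.2.subtracted",
)


@dataclass(frozen=True)
class QCReport:
    """Pass/fail plus the measured statistic for every sub-criterion."""

    results: dict

    def __post_init__(self):
        missing = set(CRITERIA) - set(self.results)
        if missing:
            raise ValueError(f"missing criteria: {sorted(missing)}")

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.results.values())

    def failed_criteria(self):
        return [name for name in CRITERIA if not self.results[name][0]]

    def to_json(self, **kwargs) -> str:
        payload = {
            name: {"pass": bool(ok), "value": None if value is None or not math.isfinite(value) else float(value)}
            for name, (ok, value) in self.results.items()
        }
        payload["overall"] = self.passed
        return json.dumps(payload, sort_keys=True, **kwargs)


def snr(trace: CurrentTrace, noise_window: TimeWindow = NOISE_WINDOW) -> float:
    """var(full trace) / var(noise window); infinity if the window is flat."""
    m = trace.window_mask(noise_window.t_start, noise_window.t_end)
    if not m.any():
        raise ValueError("noise window contains no samples")
    noise_var = float(np.var(trace.currents[m]))
    if noise_var == 0.0:
        warnings.warn("zero noise variance; SNR is infinite")
        return math.inf
    return float(np.var(trace.currents)) / noise_var


def qc1(metadata: WellMetadata):
    """R_seal, C_m, R_series range checks (closed intervals)."""
    if metadata is None:
        raise ValueError("metadata required for QC1")
    return {
        "QC1.Rseal": (0.1 <= metadata.r_seal_gohm <= 1000.0, metadata.r_seal_gohm),
        "QC1.Cm": (1.0 <= metadata.c_m_pf <= 100.0, metadata.c_m_pf),
        "QC1.Rseries": (1.0 <= metadata.r_series_mohm <= 25.0, metadata.r_series_mohm),
    }


def _rmsd(a: np.ndarray, b) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def qc3_stability(sweep1: CurrentTrace, sweep2: CurrentTrace):
    """Pass iff RMSD(s1, s2) < 0.2 x mean(RMSD(s1, 0), RMSD(s2, 0)).

    Two identically-zero sweeps fail (the bound is zero and the comparison
    is strict) — a silent well is not a stable recording.
    """
    if sweep1.currents.shape != sweep2.currents.shape:
        raise ValueError("sweeps differ in length")
    d = _rmsd(sweep1.currents, sweep2.currents)
    bound = 0.2 * 0.5 * (_rmsd(sweep1.currents, 0.0) + _rmsd(sweep2.currents, 0.0))
    return d < bound, d, bound


def qc4_drift(value_before: float, value_after: float):
    """Two-point population std/mean < 0.5 (strict); nonpositive mean fails."""
    mean = 0.5 * (value_before + value_after)
    if mean <= 0:
        warnings.warn("nonpositive mean in QC4; failing")
        return False, math.inf
    ratio = abs(value_after - value_before) / 2.0 / mean
    return ratio < 0.5, ratio


def qc5_block(
    raw_control: CurrentTrace,
    raw_blocker: CurrentTrace,
    protocol: VoltageProtocol,
):
    """Blocker must remove current.

    QC5: max |I| during the second half of the staircase drops by >= 75%.
    QC5.1: RMSD-to-zero of the whole trace drops by >= 50%.
    """
    half = TimeWindow(protocol.total_duration / 2.0, protocol.total_duration)
    m = raw_control.window_mask(half.t_start, half.t_end)
    max_c = float(np.max(np.abs(raw_control.currents[m])))
    max_b = float(np.max(np.abs(raw_blocker.currents[m])))
    red_max = 1.0 - max_b / max_c if max_c > 0 else 0.0
    rms_c = _rmsd(raw_control.currents, 0.0)
    rms_b = _rmsd(raw_blocker.currents, 0.0)
    red_rms = 1.0 - rms_b / rms_c if rms_c > 0 else 0.0
    return {
        "QC5.staircase": (red_max >= 0.75, red_max),
        "QC5.1.staircase": (red_rms >= 0.5, red_rms),
    }


def _plus40_windows(protocol: VoltageProtocol, n: int = 3):
    """Time windows of the first ``n`` +40 mV steps (pre-staircase step,
    then the first and second +40 mV staircase steps)."""
    wins = []
    for i, seg in enumerate(protocol.segments):
        if seg.kind == "step" and seg.v_start == 40.0:
            wins.append(TimeWindow(*protocol.segment_window(i)))
            if len(wins) == n:
                break
    if len(wins) < n:
        raise ValueError(f"protocol has only {len(wins)} +40 mV steps, need {n}")
    return wins


def qc6_overcorrection(
    subtracted: CurrentTrace,
    protocol: VoltageProtocol,
    windows=None,
    noise_sd: float | None = None,
):
    """Mean subtracted current in each +40 mV window must exceed -2 sigma."""
    if windows is None:
        windows = _plus40_windows(protocol)
    if noise_sd is None:
        m = subtracted.window_mask(NOISE_WINDOW.t_start, NOISE_WINDOW.t_end)
        noise_sd = float(np.std(subtracted.currents[m]))
    names = ("QC6.subtracted", "QC6.1.subtracted", "QC6.2.subtracted")
    out = {}
    for name, w in zip(names, windows):
        mean = float(np.mean(subtracted.currents[subtracted.window_mask(w.t_start, w.t_end)]))
        out[name] = (mean > -2.0 * noise_sd, mean)
    return out


def run_qc(
    well: WellRecording,
    protocol: VoltageProtocol,
    subtracted_sweeps=None,
) -> QCReport:
    """Evaluate the full battery for one well and aggregate the verdict.

    ``subtracted_sweeps`` may supply the two preprocessed (leak-corrected,
    blocker-subtracted) traces; otherwise they are computed here with the
    standard ramp-regression pipeline.
    """
    if subtracted_sweeps is None:
        subtracted_sweeps = tuple(
            preprocess_well(well, protocol, sweep=s)[0] for s in (0, 1)
        )
    sub1, sub2 = subtracted_sweeps
    results = {}
    results.update(qc1(well.metadata))

    results["QC2.raw"] = _qc2(well.control_sweeps[0])
    results["QC2.subtracted"] = _qc2(sub1)

    for name, (a, b) in {
        "QC3.raw": well.control_sweeps,
        "QC3.E4031": well.blocker_sweeps,
        "QC3.subtracted": (sub1, sub2),
    }.items():
        ok, d, bound = qc3_stability(a, b)
        results[name] = (ok, d)

    md = well.metadata
    for name, before, after in (
        ("QC4.Rseal", md.r_seal_gohm, md.r_seal_gohm_after),
        ("QC4.Cm", md.c_m_pf, md.c_m_pf_after),
        ("QC4.Rseries", md.r_series_mohm, md.r_series_mohm_after),
    ):
        ok, ratio = qc4_drift(before, after)
        results[name] = (ok, ratio)

    results.update(qc5_block(well.control_sweeps[0], well.blocker_sweeps[0], protocol))
    results.update(qc6_overcorrection(sub1, protocol))
    return QCReport(results)


def _qc2(trace: CurrentTrace):
    value = snr(trace)
    return value > SNR_THRESHOLD, value
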