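"""Model validation and variability analysis.

Fits and predictions are scored with the relative root-mean-square error

    RRMSE = sqrt(sum (z - y)^2) / sqrt(sum y^2),

which normalises away the cell-to-cell conductance scale so scores are
comparable across wells (0 for a perfect fit, 1 for a model that predicts
zero current).  Panels of wells are summarised by the best, median and
90th-percentile scores (nearest-rank, ties broken by well id, so the
selection is deterministic).

The voltage-offset study probes the hypothesis that apparent cell-to-cell
kinetic variability is driven by a per-well voltage-clamp error Delta-V:
data are generated with the channel experiencing V + Delta-V, refitted
assuming the nominal V, and the induced displacement of the fitted
log-parameters is compared against the across-well scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import CurrentTrace, IonicEnvironment, KineticParameters, N_PARAMETERS, simulate
from .protocol import VoltageProtocol
from .preprocess import TimeWindow

__all__ = [
    "RRMSEScore",
    "PanelSummary",
    "OffsetStudyResult",
    "rrmse",
    "score_panel",
    "nearest_rank_index",
    "normalize_traces",
    "extract_iv",
    "voltage_offset_study",
    "leading_axis_alignment",
]


@dataclass(frozen=True)
class RRMSEScore:
    value: float
    protocol_name: str = ""
    well_id: str = ""

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("RRMSE is nonnegative")


def rrmse(model_trace: CurrentTrace, data_trace: CurrentTrace,
          protocol_name: str = "", well_id: str = "") -> RRMSEScore:
    """Root-mean-square misfit normalised by the data's root mean square."""
    z, y = model_trace.currents, data_trace.currents
    if z.shape != y.shape:
        raise ValueError("model and data traces differ in length")
    denom = float(np.sqrt(np.sum(y**2)))
    if denom == 0.0:
        raise ValueError("RRMSE undefined for identically zero data")
    value = float(np.sqrt(np.sum((z - y) ** 2))) / denom
    return RRMSEScore(value, protocol_name or model_trace.protocol_name, well_id)


def nearest_rank_index(n: int, percentile: float) -> int:
    """0-based nearest-rank index into a sorted sample of size n."""
    if not (0 < percentile <= 100) or n < 1:
        raise ValueError("percentile in (0, 100], n >= 1")
    return int(np.ceil(percentile / 100.0 * n)) - 1


@dataclass(frozen=True)
class PanelSummary:
    protocol_name: str
    scores: tuple            # (well_id, value) sorted by (value, well_id)
    best: str
    median: str
    p90: str


def score_panel(panel: dict) -> dict:
    """Summarise RRMSE distributions per protocol.

    ``panel`` maps protocol name -> {well_id: RRMSE value or RRMSEScore};
    returns protocol name -> :class:`PanelSummary` with the best, median
    and 90th-percentile wells selected by nearest rank.
    """
    out = {}
    for proto, by_well in panel.items():
        items = sorted(
            (wid, s.value if isinstance(s, RRMSEScore) else float(s))
            for wid, s in by_well.items()
        )
        items = sorted(items, key=lambda t: (t[1], t[0]))
        n = len(items)
        out[proto] = PanelSummary(
            protocol_name=proto,
            scores=tuple(items),
            best=items[0][0],
            median=items[nearest_rank_index(n, 50)][0],
            p90=items[nearest_rank_index(n, 90)][0],
        )
    return out


def normalize_traces(traces, reference: CurrentTrace, method: str = "l2"):
    """Scale each trace to match the reference: returns (scaled, factors).

    ``method="l2"`` uses the closed form s = <I, ref> / <I, I>; ``"l1"``
    minimises the summed absolute difference numerically.  A zero-energy
    trace is an error; a trace orthogonal to the reference gets s = 0 with
    a warning.
    """
    from scipy.optimize import minimize_scalar

    ref = reference.currents
    scaled, factors = [], []
    for tr in traces:
        i = tr.currents
        energy = float(i @ i)
        if energy == 0.0:
            raise ValueError("cannot normalise a zero-energy trace")
        if method == "l2":
            s = float(i @ ref) / energy
        elif method == "l1":
            res = minimize_scalar(lambda s_: float(np.abs(s_ * i - ref).sum()))
            s = float(res.x)
        else:
            raise ValueError("method must be 'l2' or 'l1'")
        if s == 0.0:
            warnings.warn("trace orthogonal to reference; scale factor 0")
        scaled.append(tr.with_currents(s * i))
        factors.append(s)
    return scaled, np.array(factors)


def extract_iv(trace: CurrentTrace, protocol: VoltageProtocol,
               measurement_windows, statistic: str = "peak"):
    """Per-step I-V summary points, ordered by step voltage.

    Each window must lie inside a single constant-voltage step; the
    summary is the signed peak (largest |I|) or the mean current within
    the window.
    """
    points = []
    for w in measurement_windows:
        i0 = protocol.segment_index(w.t_start)
        i1 = protocol.segment_index(w.t_end - 1e-12)
        if i0 != i1 or protocol.segments[i0].kind != "step":
            raise ValueError(f"window [{w.t_start}, {w.t_end}) is not inside a single step")
        v = protocol.segments[i0].v_start
        vals = trace.currents[trace.window_mask(w.t_start, w.t_end)]
        if vals.size == 0:
            raise ValueError("window contains no samples")
        if statistic == "peak":
            summary = float(vals[np.argmax(np.abs(vals))])
        elif statistic == "mean":
            summary = float(vals.mean())
        else:
            raise ValueError("statistic must be 'peak' or 'mean'")
        points.append((v, summary))
    return sorted(points)


@dataclass
class OffsetStudyResult:
    """Fits of voltage-offset-corrupted synthetic data.

    ``phi_fits[k]`` is the fitted log-parameter vector for ``dv_grid[k]``;
    missing (failed) fits are rows of NaN.
    """

    dv_grid: np.ndarray
    phi_fits: np.ndarray
    phi_ref: np.ndarray

    @property
    def displacements(self) -> np.ndarray:
        """Log-space displacement of each fit from the reference."""
        return self.phi_fits - self.phi_ref

    def direction(self, dv: float) -> np.ndarray:
        """Unit displacement direction in log space at offset ``dv``."""
        k = int(np.argmin(np.abs(self.dv_grid - dv)))
        d = self.displacements[k]
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("zero displacement; no direction")
        return d / norm


def voltage_offset_study(
    theta_ref,
    dv_grid,
    protocol: VoltageProtocol,
    env: IonicEnvironment | None = None,
    seed: int | None = None,
    fit_kwargs: dict | None = None,
) -> OffsetStudyResult:
    """Generate noiseless data with a voltage error and refit without it.

    For each Delta-V in ``dv_grid``, the channel model is simulated with
    V + Delta-V, and the nine parameters are refitted assuming the nominal
    protocol; fits are warm-started from the reference parameters (the
    perturbations are small, so this is a continuation of the Delta-V = 0
    optimum).  Failed fits are recorded as NaN rows with a warning.
    """
    from .inference import fit_map

    theta_ref = (
        theta_ref if isinstance(theta_ref, KineticParameters)
        else KineticParameters.from_array(theta_ref)
    )
    phi_ref = theta_ref.log_transform()
    dv_grid = np.asarray(dv_grid, dtype=float)
    kwargs = dict(n_restarts=2, maxiter=300, x0=phi_ref, x0_spread=0.05)
    kwargs.update(fit_kwargs or {})
    phi_fits = np.full((dv_grid.size, N_PARAMETERS), np.nan)
    rng = np.random.default_rng(seed)
    for k, dv in enumerate(dv_grid):
        trace, _ = simulate(theta_ref, protocol, env, v_offset=float(dv))
        try:
            fit = fit_map(trace, protocol, seed=int(rng.integers(2**31)),
                          env=env, **kwargs)
            phi_fits[k] = fit.phi
        except Exception as e:  # noqa: BLE001 — record and continue
            warnings.warn(f"fit failed at Delta-V={dv}: {e}")
    return OffsetStudyResult(dv_grid, phi_fits, phi_ref)


def leading_axis_alignment(phi_samples: np.ndarray, direction: np.ndarray) -> float:
    """|cosine| between the leading principal axis of the scatter of
    ``phi_samples`` (rows are wells) and ``direction``.

    Used to compare hierarchically inferred across-well scatter with the
    displacement direction predicted by the voltage-offset study.
    """
    phi_samples = np.asarray(phi_samples, dtype=float)
    direction = np.asarray(direction, dtype=float)
    cov = np.cov(phi_samples, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    cos = float(axis @ direction) / (np.linalg.norm(axis) * np.linalg.norm(direction))
    return abs(cos)
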