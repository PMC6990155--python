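"""Synthetic multi-well patch-clamp datasets with known ground truth.

Emulates the statistical structure of an automated-platform plate
experiment: each well carries its own kinetic parameter vector theta_j drawn
from a multivariate log-normal across-well distribution, a per-well noise
level sigma_j, independent linear leak currents before/after blocker
(control vs E-4031 sweeps), a small endogenous background current, an
optional per-well voltage-clamp offset Delta-V_j, and i.i.d. Gaussian
observation noise fresh in every sweep.  Full hERG block by the blocker is
assumed, so blocker sweeps contain no I_Kr.

A fraction of wells can be generated as deliberate quality-control failures
(low SNR, unstable repeat sweeps, weak block, out-of-range electrical
metadata); the truth manifest labels them so the QC battery can be tested
against designed verdicts.

All randomness flows through a single seeded :class:`numpy.random.Generator`
and regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from . import model as _model
from .model import (
    CurrentTrace,
    IonicEnvironment,
    KineticParameters,
    simulate,
    N_PARAMETERS,
)
from .protocol import VoltageProtocol, build_staircase

__all__ = [
    "LeakModel",
    "EndogenousModel",
    "WellMetadata",
    "WellTruth",
    "WellRecording",
    "PlateConfig",
    "SyntheticDataset",
    "draw_well_parameters",
    "synthesize_current",
    "synthesize_well",
    "generate_dataset",
    "load_dataset",
    "default_population",
]


@dataclass(frozen=True)
class LeakModel:
    """Linear (Ohmic) seal-leak current I = g_leak (V - E_leak).

    g_leak in nS, E_leak in mV, so the current comes out in pA.
    """

    g_leak: float = 0.0
    e_leak: float = 0.0

    def current(self, v_mv) -> np.ndarray:
        return self.g_leak * (np.asarray(v_mv, dtype=float) - self.e_leak)


@dataclass(frozen=True)
class EndogenousModel:
    """Small native background current of the host cell.

    Modelled as a linear-above-threshold conductance: zero below
    ``threshold`` (mV) and rising linearly to ``amplitude`` (pA) at +40 mV.
    This is a declared synthetic stand-in — it only needs to be
    voltage-dependent and removable by blocker subtraction.
    """

    amplitude: float = 0.0
    threshold: float = -20.0

    def current(self, v_mv) -> np.ndarray:
        v = np.asarray(v_mv, dtype=float)
        span = 40.0 - self.threshold
        return self.amplitude * np.clip(v - self.threshold, 0.0, None) / span


@dataclass(frozen=True)
class WellMetadata:
    """Per-well electrical quality metrics, before and after blocker."""

    r_seal_gohm: float
    c_m_pf: float
    r_series_mohm: float
    r_seal_gohm_after: float
    c_m_pf_after: float
    r_series_mohm_after: float

    def __post_init__(self):
        for v in asdict(self).values():
            if not v > 0:
                raise ValueError("metadata entries must be positive")


@dataclass(frozen=True)
class WellTruth:
    """Ground truth for one synthetic well (for recovery tests)."""

    well_id: str
    theta: np.ndarray            # 9 positive parameters
    sigma: float                 # pA, per-sweep noise SD
    leak_a: LeakModel            # control-sweep leak
    leak_b: LeakModel            # blocker-sweep leak
    v_offset: float              # mV, voltage-clamp error Delta-V_j
    endogenous: EndogenousModel
    designed_fail: str | None    # None or a QC failure mode label


@dataclass(frozen=True)
class WellRecording:
    """Paired control and blocker sweeps plus metadata for one well."""

    well_id: str
    control_sweeps: tuple
    blocker_sweeps: tuple
    metadata: WellMetadata
    protocol_name: str

    def __post_init__(self):
        sweeps = list(self.control_sweeps) + list(self.blocker_sweeps)
        t0 = sweeps[0].times
        for s in sweeps[1:]:
            if s.times.shape != t0.shape or not np.allclose(s.times, t0):
                raise ValueError("all sweeps of a well must share the time grid")


def default_population():
    """Default across-well distribution (mu, Sigma) on the log scale.

    mu is the log of the room-temperature reference parameter set; Sigma is
    diagonal with log-SD 0.3 for the conductance (expression level varies
    most) and 0.15 for the kinetic parameters.
    """
    mu = _model.BEATTIE_REFERENCE.log_transform()
    sd = np.array([0.3] + [0.15] * 8)
    return mu, np.diag(sd**2)


def draw_well_parameters(mu, sigma_cov, n_wells: int, seed_or_rng) -> np.ndarray:
    """Draw theta_j = exp(phi_j), phi_j ~ MVN(mu, Sigma); rows are wells.

    Sigma may be the zero matrix (point mass at exp(mu)); a non-positive-
    semidefinite Sigma raises ``numpy.linalg.LinAlgError``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma_cov = np.asarray(sigma_cov, dtype=float)
    if mu.shape != (N_PARAMETERS,) or sigma_cov.shape != (N_PARAMETERS, N_PARAMETERS):
        raise ValueError("mu must be length 9 and Sigma 9x9")
    rng = (
        np.random.default_rng(seed_or_rng)
        if isinstance(seed_or_rng, (int, np.integer))
        else seed_or_rng
    )
    if np.all(sigma_cov == 0.0):
        phi = np.tile(mu, (n_wells, 1))
    else:
        if not np.allclose(sigma_cov, sigma_cov.T):
            raise np.linalg.LinAlgError("Sigma must be symmetric")
        # cholesky rejects indefinite matrices; permit positive-semidefinite
        # limits via a tiny diagonal jitter only when exactly singular
        try:
            chol = np.linalg.cholesky(sigma_cov)
        except np.linalg.LinAlgError:
            eigvals = np.linalg.eigvalsh(sigma_cov)
            if eigvals.min() < -1e-12 * max(1.0, abs(eigvals.max())):
                raise
            chol = np.linalg.cholesky(sigma_cov + 1e-12 * np.eye(N_PARAMETERS))
        z = rng.standard_normal((n_wells, N_PARAMETERS))
        phi = mu + z @ chol.T
    return np.exp(phi)


def synthesize_current(
    theta,
    protocol: VoltageProtocol,
    env: IonicEnvironment | None = None,
    sigma: float = 0.0,
    rng=None,
    v_offset: float = 0.0,
) -> CurrentTrace:
    """Model current plus i.i.d. Gaussian noise — the bare statistical model.

    This is the construction used by single-distribution recovery studies:
    no leak, no endogenous current, no blocker subtraction.
    """
    theta = theta if isinstance(theta, KineticParameters) else KineticParameters.from_array(theta)
    trace, _ = simulate(theta, protocol, env, v_offset=v_offset)
    if sigma > 0:
        if rng is None:
            raise ValueError("rng is required when sigma > 0")
        trace = trace.with_currents(trace.currents + rng.normal(0.0, sigma, trace.currents.size))
    return trace


def _noise_sd_for_snr(noiseless_subtracted: np.ndarray, snr: float) -> float:
    """Per-sweep sigma so the *subtracted* trace has the target SNR.

    SNR is var(trace)/var(noise); subtraction of two sweeps doubles the
    noise variance, so var(sub) ~ var(signal) + 2 sigma^2 and
    SNR = (var(signal) + 2 sigma^2) / (2 sigma^2).
    """
    if snr <= 1:
        raise ValueError("target SNR must exceed 1")
    return float(np.sqrt(np.var(noiseless_subtracted) / (2.0 * (snr - 1.0))))


def synthesize_well(
    theta,
    protocol: VoltageProtocol,
    env: IonicEnvironment | None = None,
    sigma: float = 0.0,
    leak_a: LeakModel = LeakModel(),
    leak_b: LeakModel = LeakModel(),
    v_offset: float = 0.0,
    endogenous: EndogenousModel = EndogenousModel(),
    metadata: WellMetadata | None = None,
    rng=None,
    well_id: str = "well",
    block_remaining: float = 0.0,
    control_gain_sweep2: float = 1.0,
) -> WellRecording:
    """Generate paired control/blocker sweeps (two of each) for one well.

    Control sweeps:  I_Kr(theta; V + Delta-V) + I_endo + I_leak_a + noise.
    Blocker sweeps:  block_remaining * I_Kr + I_endo + I_leak_b + noise
    (``block_remaining=0`` is the full-block assumption).  The voltage
    offset is applied inside the channel model only; leak and endogenous
    components use the nominal command voltage, and the recorded protocol
    stays nominal.  ``control_gain_sweep2`` scales I_Kr in the second
    control sweep to emulate an unstable recording.
    """
    if sigma > 0 and rng is None:
        raise ValueError("rng is required when sigma > 0")
    theta = theta if isinstance(theta, KineticParameters) else KineticParameters.from_array(theta)
    trace, _ = simulate(theta, protocol, env, v_offset=v_offset)
    i_kr = trace.currents
    v = protocol.voltages(trace.times)
    i_endo = endogenous.current(v)
    base_control = i_endo + leak_a.current(v)
    base_blocker = block_remaining * i_kr + i_endo + leak_b.current(v)

    def noisy(arr):
        if sigma > 0:
            return arr + rng.normal(0.0, sigma, arr.size)
        return arr.copy()

    controls = (
        trace.with_currents(noisy(i_kr + base_control)),
        trace.with_currents(noisy(control_gain_sweep2 * i_kr + base_control)),
    )
    blockers = (
        trace.with_currents(noisy(base_blocker)),
        trace.with_currents(noisy(base_blocker)),
    )
    if metadata is None:
        metadata = WellMetadata(1.0, 20.0, 8.0, 1.0, 20.0, 8.0)
    return WellRecording(well_id, controls, blockers, metadata, protocol.name)


# ---------------------------------------------------------------------------
# Whole-plate generation
# ---------------------------------------------------------------------------

#: QC failure modes the generator can inject, in cycling order.
FAILURE_MODES = ("low_snr", "unstable", "weak_block", "bad_metadata")


@dataclass(frozen=True)
class PlateConfig:
    """Study conditions for a synthetic plate.

    Defaults emulate a small, desk-scale slice of a 384-well experiment:
    across-well parameters from the default multivariate log-normal
    population, designed-pass wells in a comfortably high SNR band with the
    designed low-SNR failures far below the QC2 threshold of 25, leak
    conductances of a few nS differing between control and blocker sweeps,
    an endogenous background of ~2% of the hERG peak, and per-well voltage
    offsets Delta-V_j ~ N(0, 1.5^2 mV^2).
    """

    n_wells: int = 16
    fail_fraction: float = 0.25
    mu: np.ndarray | None = None
    sigma_cov: np.ndarray | None = None
    sigma_pass_range: tuple = (0.8, 2.5)        # pA, log-uniform, designed-pass wells
    snr_fail_range: tuple = (5.0, 12.0)         # designed low-SNR band (< 25)
    leak_g_range: tuple = (0.4, 1.2)            # nS
    leak_e_sd: float = 5.0                      # mV
    leak_drift_sd: float = 0.2                  # nS change control -> blocker
    endo_fraction: float = 0.02                 # of hERG peak
    v_offset_sd: float = 1.5                    # mV
    weak_block_remaining: float = 0.6
    unstable_gain: float = 0.55
    sampling_interval: float = 5e-4             # s (2 kHz desk-scale grid)


@dataclass
class SyntheticDataset:
    wells: list
    truths: list
    protocol: VoltageProtocol
    env: IonicEnvironment
    seed: int
    config: PlateConfig

    @property
    def designed_pass_ids(self):
        return [t.well_id for t in self.truths if t.designed_fail is None]

    def truth_for(self, well_id: str) -> WellTruth:
        return next(t for t in self.truths if t.well_id == well_id)

    def manifest(self) -> dict:
        wells = []
        for t in self.truths:
            wells.append({
                "well_id": t.well_id,
                "theta": [float(x) for x in t.theta],
                "sigma_pA": float(t.sigma),
                "leak_a": {"g_leak_nS": t.leak_a.g_leak, "e_leak_mV": t.leak_a.e_leak},
                "leak_b": {"g_leak_nS": t.leak_b.g_leak, "e_leak_mV": t.leak_b.e_leak},
                "v_offset_mV": float(t.v_offset),
                "endogenous_amplitude_pA": float(t.endogenous.amplitude),
                "designed_fail": t.designed_fail,
            })
        return {
            "seed": self.seed,
            "protocol": self.protocol.name,
            "n_wells": len(self.truths),
            "wells": wells,
        }

    def write(self, out_dir) -> None:
        """Write per-well CSV traces plus the truth manifest (all text)."""
        os.makedirs(out_dir, exist_ok=True)
        for rec in self.wells:
            path = os.path.join(out_dir, f"{rec.well_id}.csv")
            t = rec.control_sweeps[0].times
            cols = np.column_stack(
                [t]
                + [s.currents for s in rec.control_sweeps]
                + [s.currents for s in rec.blocker_sweeps]
            )
            header = "time_s,control_1_pA,control_2_pA,blocker_1_pA,blocker_2_pA"
            np.savetxt(path, cols, delimiter=",", header=header, comments="", fmt="%.17g")
            meta_path = os.path.join(out_dir, f"{rec.well_id}.meta.json")
            with open(meta_path, "w") as fh:
                json.dump(asdict(rec.metadata), fh, sort_keys=True, indent=1)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(self.manifest(), fh, sort_keys=True, indent=1)


def generate_dataset(
    config: PlateConfig | None = None,
    seed: int = 0,
    protocol: VoltageProtocol | None = None,
    env: IonicEnvironment | None = None,
    out_dir=None,
) -> SyntheticDataset:
    """Generate a synthetic plate; optionally write it to ``out_dir``.

    The number of designed failures is ``round(n_wells * fail_fraction)``;
    failing wells are chosen at random (seeded) and cycle through
    :data:`FAILURE_MODES`.
    """
    config = config or PlateConfig()
    if config.n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    env = env or IonicEnvironment()
    if protocol is None:
        protocol = build_staircase().with_sampling_interval(config.sampling_interval)
    rng = np.random.default_rng(seed)

    mu, sigma_cov = config.mu, config.sigma_cov
    if mu is None or sigma_cov is None:
        d_mu, d_cov = default_population()
        mu = d_mu if mu is None else np.asarray(mu, float)
        sigma_cov = d_cov if sigma_cov is None else np.asarray(sigma_cov, float)

    thetas = draw_well_parameters(mu, sigma_cov, config.n_wells, rng)
    n_fail = int(round(config.n_wells * config.fail_fraction))
    fail_idx = rng.choice(config.n_wells, size=n_fail, replace=False) if n_fail else np.array([], int)
    modes = {int(i): FAILURE_MODES[k % len(FAILURE_MODES)] for k, i in enumerate(np.sort(fail_idx))}

    wells, truths = [], []
    for j in range(config.n_wells):
        well_id = f"W{j:03d}"
        mode = modes.get(j)
        theta = KineticParameters.from_array(thetas[j])
        v_offset = float(rng.normal(0.0, config.v_offset_sd))

        # leak: control-sweep model plus a drifted blocker-sweep model
        g_a = float(rng.uniform(*config.leak_g_range))
        e_a = float(rng.normal(0.0, config.leak_e_sd))
        leak_a = LeakModel(g_a, e_a)
        leak_b = LeakModel(max(0.1, g_a + float(rng.normal(0.0, config.leak_drift_sd))), e_a)

        # noise level: designed-pass wells draw sigma from a fixed low band;
        # designed low-SNR failures scale sigma to a target subtracted SNR
        clean, _ = simulate(theta, protocol, env, v_offset=v_offset)
        if mode == "low_snr":
            snr = float(np.exp(rng.uniform(*np.log(config.snr_fail_range))))
            sigma = _noise_sd_for_snr(clean.currents, snr)
        else:
            sigma = float(np.exp(rng.uniform(*np.log(config.sigma_pass_range))))

        endo = EndogenousModel(amplitude=config.endo_fraction * float(np.max(np.abs(clean.currents))))

        # electrical metadata, with a deliberate out-of-range R_series for
        # the bad-metadata failure mode
        r_seal = float(np.exp(rng.normal(0.0, 0.5)))            # ~1 GOhm
        c_m = float(np.clip(rng.normal(20.0, 5.0), 5.0, 80.0))  # pF
        r_series = float(np.exp(rng.normal(np.log(8.0), 0.3)))  # MOhm
        drift = 1.0 + rng.normal(0.0, 0.03, size=3)
        if mode == "bad_metadata":
            r_series = 40.0  # outside QC1's [1, 25] MOhm
        metadata = WellMetadata(
            r_seal, c_m, r_series,
            r_seal * float(drift[0]), c_m * float(drift[1]), r_series * float(drift[2]),
        )

        rec = synthesize_well(
            theta, protocol, env,
            sigma=sigma, leak_a=leak_a, leak_b=leak_b, v_offset=v_offset,
            endogenous=endo, metadata=metadata, rng=rng, well_id=well_id,
            block_remaining=config.weak_block_remaining if mode == "weak_block" else 0.0,
            control_gain_sweep2=config.unstable_gain if mode == "unstable" else 1.0,
        )
        wells.append(rec)
        truths.append(WellTruth(well_id, thetas[j], sigma, leak_a, leak_b,
                                v_offset, endo, mode))

    ds = SyntheticDataset(wells, truths, protocol, env, seed, config)
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def load_dataset(in_dir):
    """Read back the per-well CSVs and manifest written by ``write``.

    Returns ``(list of WellRecording, manifest dict)``.
    """
    with open(os.path.join(in_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    wells = []
    for entry in manifest["wells"]:
        wid = entry["well_id"]
        data = np.loadtxt(os.path.join(in_dir, f"{wid}.csv"), delimiter=",", skiprows=1)
        with open(os.path.join(in_dir, f"{wid}.meta.json")) as fh:
            meta = WellMetadata(**json.load(fh))
        t = data[:, 0]

        def mk(col):
            return CurrentTrace(t, data[:, col], manifest["protocol"])

        wells.append(WellRecording(wid, (mk(1), mk(2)), (mk(3), mk(4)), meta, manifest["protocol"]))
    return wells, manifest
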