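import numpy as np
import pytest

from hergchar.model import CurrentTrace, nernst_potential, simulate
from hergchar.preprocess import (
    PreprocessError,
    TimeWindow,
    default_leak_ramp_window,
    default_zero_window,
    e4031_subtract,
    estimate_leak_from_ramp,
    estimate_reversal,
    estimate_voltage_offset,
    preprocess_well,
    rectify_leak,
    subtract_leak,
)
from hergchar.synthetic import LeakModel, synthesize_well


def leak_only_trace(protocol, leak, noise_sd=0.0, rng=None):
    t = protocol.times()
    i = leak.current(protocol.voltages(t))
    if noise_sd:
        i = i + rng.normal(0, noise_sd, i.size)
    return CurrentTrace(t, i, protocol.name)


class TestLeakEstimation:
    def test_exact_recovery_from_pure_leak(self, staircase):
        leak = LeakModel(2.0, -5.0)
        fit = estimate_leak_from_ramp(leak_only_trace(staircase, leak), staircase)
        assert fit.leak.g_leak == pytest.approx(2.0, abs=1e-9)
        assert fit.leak.e_leak == pytest.approx(-5.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_trace_gives_zero_conductance(self, staircase):
        fit = estimate_leak_from_ramp(leak_only_trace(staircase, LeakModel(0.0, 0.0)), staircase)
        assert fit.leak.g_leak == 0.0

    def test_matches_normal_equations_oracle(self, staircase):
        rng = np.random.default_rng(0)
        trace = leak_only_trace(staircase, LeakModel(1.5, -3.0), noise_sd=1.0, rng=rng)
        w = default_leak_ramp_window(staircase)
        fit = estimate_leak_from_ramp(trace, staircase, w)
        # explicit normal equations, independent of the module's lstsq route
        m = trace.window_mask(w.t_start, w.t_end)
        v, i = staircase.voltages(trace.times[m]), trace.currents[m]
        sxx = np.sum((v - v.mean()) ** 2)
        slope = np.sum((v - v.mean()) * (i - i.mean())) / sxx
        intercept = i.mean() - slope * v.mean()
        assert fit.leak.g_leak == pytest.approx(slope, abs=1e-12)
        assert fit.leak.e_leak == pytest.approx(-intercept / slope, abs=1e-9)

    def test_step_method_recovers_leak_from_plateaus(self):
        from hergchar.preprocess import estimate_leak_from_step
        from hergchar.protocol import VoltageProtocol, step

        proto = VoltageProtocol(
            "leak_step", (step(0.1, -80.0), step(0.02, -100.0), step(0.1, -80.0)), 1e-3
        )
        leak = LeakModel(1.7, -6.0)
        fit = estimate_leak_from_step(
            leak_only_trace(proto, leak), proto,
            TimeWindow(0.0, 0.1), TimeWindow(0.1, 0.12),
        )
        assert fit.leak.g_leak == pytest.approx(1.7, abs=1e-9)
        assert fit.leak.e_leak == pytest.approx(-6.0, abs=1e-6)

    def test_window_outside_ramp_rejected(self, staircase):
        with pytest.raises(PreprocessError):
            estimate_leak_from_ramp(
                leak_only_trace(staircase, LeakModel(1.0, 0.0)),
                staircase,
                TimeWindow(2.0, 2.2),  # a step, not the ramp
            )


class TestSubtraction:
    def test_zero_leak_is_identity(self, staircase):
        tr = leak_only_trace(staircase, LeakModel(1.0, 0.0))
        out = subtract_leak(tr, LeakModel(0.0, 0.0), staircase)
        assert np.array_equal(out.currents, tr.currents)

    def test_subtract_then_add_is_identity(self, staircase):
        tr = leak_only_trace(staircase, LeakModel(1.0, 2.0))
        leak = LeakModel(0.7, -4.0)
        sub = subtract_leak(tr, leak, staircase)
        back = sub.with_currents(sub.currents + leak.current(staircase.voltages(tr.times)))
        assert np.allclose(back.currents, tr.currents, atol=1e-12)

    def test_e4031_identical_traces_cancel(self, staircase):
        tr = leak_only_trace(staircase, LeakModel(1.0, 0.0))
        assert np.allclose(e4031_subtract(tr, tr).currents, 0.0)

    def test_grid_mismatch_rejected(self, staircase):
        tr = leak_only_trace(staircase, LeakModel(1.0, 0.0))
        other = CurrentTrace(tr.times + 1.0, tr.currents)
        with pytest.raises(PreprocessError):
            e4031_subtract(tr, other)

    def test_noiseless_pipeline_with_true_leaks(self, ref_params, env, staircase):
        leak_a, leak_b = LeakModel(1.0, -3.0), LeakModel(1.4, -3.0)
        rec = synthesize_well(ref_params, staircase, env, leak_a=leak_a, leak_b=leak_b)
        out, _ = preprocess_well(rec, staircase, true_leaks=(leak_a, leak_b))
        model_trace, _ = simulate(ref_params, staircase, env)
        assert np.max(np.abs(out.currents - model_trace.currents)) < 1e-9

    def test_noise_propagation(self, ref_params, env, staircase):
        rng = np.random.default_rng(1)
        rec = synthesize_well(ref_params, staircase, env, sigma=2.0, rng=rng)
        out, _ = preprocess_well(rec, staircase, true_leaks=(LeakModel(), LeakModel()))
        model_trace, _ = simulate(ref_params, staircase, env)
        resid = out.currents - model_trace.currents
        assert np.std(resid) == pytest.approx(2.0 * np.sqrt(2), rel=0.2)


class TestRectify:
    def test_zero_mean_input_unchanged(self, staircase):
        t = staircase.times()
        tr = CurrentTrace(t, np.zeros(t.size), staircase.name)
        out, g = rectify_leak(tr, staircase)
        assert g == 0.0
        assert np.array_equal(out.currents, tr.currents)

    def test_window_mean_zero_after(self, staircase):
        rng = np.random.default_rng(0)
        t = staircase.times()
        tr = CurrentTrace(t, rng.normal(0, 5, t.size) + 30.0, staircase.name)
        out, _ = rectify_leak(tr, staircase)
        w = default_zero_window(staircase)
        m = out.window_mask(w.t_start, w.t_end)
        assert abs(out.currents[m].mean()) < 1e-10

    def test_recovers_injected_spurious_leak(self, ref_params, env, staircase):
        model_trace, _ = simulate(ref_params, staircase, env)
        v = staircase.voltages(model_trace.times)
        spoiled = model_trace.with_currents(model_trace.currents + 0.5 * (v + 80.0))
        _, g = rectify_leak(spoiled, staircase)
        assert g == pytest.approx(0.5, rel=0.01)

    def test_idempotent(self, ref_params, env, staircase):
        model_trace, _ = simulate(ref_params, staircase, env)
        once, g1 = rectify_leak(model_trace, staircase)
        twice, g2 = rectify_leak(once, staircase)
        assert g2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(twice.currents, once.currents)

    def test_unidentifiable_window(self, staircase):
        t = staircase.times()
        tr = CurrentTrace(t, np.ones(t.size), staircase.name)
        with pytest.raises(PreprocessError):
            rectify_leak(tr, staircase, TimeWindow(0.0, 0.1))  # V = -80 there


class TestReversal:
    def _subtracted(self, theta, env, staircase, v_offset=0.0):
        rec = synthesize_well(theta, staircase, env, v_offset=v_offset)
        out, _ = preprocess_well(rec, staircase, true_leaks=(LeakModel(), LeakModel()))
        return out

    def test_noiseless_estimate_near_nernst(self, ref_params, env, staircase):
        out = self._subtracted(ref_params, env, staircase)
        est = estimate_reversal(out, staircase)
        assert est == pytest.approx(nernst_potential(env), abs=0.5)

    def test_offset_shifts_estimate_one_to_one(self, ref_params, env, staircase):
        base = estimate_reversal(self._subtracted(ref_params, env, staircase), staircase)
        shifts = []
        for dv in (-5.0, -2.0, 2.0, 5.0):
            est = estimate_reversal(self._subtracted(ref_params, env, staircase, dv), staircase)
            shifts.append(est - base)
        slope = np.polyfit([-5, -2, 2, 5], shifts, 1)[0]
        # the channel crosses zero where V + dV = E_K: mirror-image shift
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_voltage_offset_estimator_recovers_applied_offset(self, ref_params, env, staircase):
        for dv in (-3.0, 0.0, 3.0):
            out = self._subtracted(ref_params, env, staircase, dv)
            assert estimate_voltage_offset(out, staircase, env) == pytest.approx(dv, abs=0.5)

    def test_no_sign_change_raises(self, staircase):
        t = staircase.times()
        tr = CurrentTrace(t, np.full(t.size, 5.0), staircase.name)
        with pytest.raises(PreprocessError):
            estimate_reversal(tr, staircase)
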