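"""Per-trajectory metric operators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erkpulse import Trajectory
from erkpulse.metrics import (classify_response, correlate_peak_vs_late,
                              erk_integral, normalize_baseline, peak_amplitude,
                              peak_duration, peak_window, pulse_maxima_decay)
from erkpulse.stimulus import make_pulse_train, make_sustained


def traj(values, t0=0.0, dt=1.0):
    v = np.asarray(values, dtype=float)
    return Trajectory(t0 + dt * np.arange(len(v)), v)


class TestNormalizeBaseline:
    def test_constant_trace_normalizes_to_one(self):
        tr = normalize_baseline(traj([3.0] * 20), stim_start=10)
        assert np.allclose(tr.erk, 1.0)

    def test_fold_change_arithmetic(self):
        tr = traj([2, 2, 2, 2, 2, 2.6, 2.6])
        out = normalize_baseline(tr, stim_start=5)
        assert out.erk[5] == pytest.approx(1.3)

    def test_idempotent_on_normalized_data(self):
        tr = normalize_baseline(traj(np.r_[np.full(5, 2.0), 2.8, 3.0]), 5)
        again = normalize_baseline(tr, 5)
        assert np.allclose(tr.erk, again.erk)

    def test_requires_enough_prestim_samples(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            normalize_baseline(traj([1, 1, 2, 3]), stim_start=2)

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_baseline(traj([0, 0, 0, 0, 0, 1]), stim_start=5)


class TestPeakAmplitude:
    def test_rise_and_decay(self):
        tr = traj([1.0] * 5 + [1.1, 1.25, 1.35, 1.3, 1.2, 1.1])
        assert peak_amplitude(tr, 4) == pytest.approx(0.35)

    def test_flat_trace_zero(self):
        assert peak_amplitude(traj([1.0] * 10), 3) == 0.0

    def test_matches_brute_force_scan_on_simulated_trace(self, full_params,
                                                         sustained_high_egf):
        """Exhaustive-scan oracle over the first-response window."""
        tr = sustained_high_egf
        i0, m, end = peak_window(tr.erk, tr.t, 10.0)
        brute = max(tr.erk[i] for i in range(i0, end + 1)) - tr.erk[i0]
        assert peak_amplitude(tr, 10.0) == pytest.approx(brute)


class TestPeakDuration:
    def test_triangle_half_max_rule(self):
        """Samples 0,.25,.5,.75,1,.75,.5,.25,0: the last sample below the
        half-maximum on the way up is t=1 and the first below on the way
        down is t=7, so the duration is 6 min."""
        tr = traj([0, .25, .5, .75, 1, .75, .5, .25, 0])
        dur, censored = peak_duration(tr, 0)
        assert (dur, censored) == (6.0, False)

    def test_symmetric_peak_symmetric_about_peak_time(self):
        v = np.exp(-0.5 * ((np.arange(41) - 20) / 5.0) ** 2)
        tr = traj(v)
        dur, _ = peak_duration(tr, 0)
        i0, m, _ = peak_window(tr.erk, tr.t, 0)
        # crossings equidistant from the peak for a symmetric pulse
        assert dur % 2 == 0.0

    def test_censored_when_no_descent(self):
        tr = traj(np.r_[np.zeros(5), np.linspace(0, 1, 20)])
        dur, censored = peak_duration(tr, 4)
        assert censored

    def test_subsampling_resolution_bound(self, full_params):
        """Sampling a smooth simulated peak at dt and dt/2 changes the
        half-max duration by at most dt."""
        from erkpulse import simulate_deterministic
        pr = make_sustained("EGF", 25, 10, 60)
        a = simulate_deterministic(full_params, pr, dt_out=1.0)
        b = simulate_deterministic(full_params, pr, dt_out=0.5)
        da, _ = peak_duration(a, 10.0)
        db, _ = peak_duration(b, 10.0)
        assert abs(da - db) <= 1.0


class TestClassifyResponse:
    def test_flat_trace_transient(self):
        assert classify_response(traj([1.0] * 60), 5) == "transient"

    def test_held_peak_sustained(self):
        v = np.r_[np.ones(5), np.full(55, 1.5)]
        assert classify_response(traj(v), 4) == "sustained"

    def test_model_sustained_phenotypes(self, sustained_high_egf, sustained_high_ngf):
        """Deterministic full model: sustained high EGF adapts (transient),
        sustained high NGF holds a plateau (sustained)."""
        assert classify_response(sustained_high_egf, 10.0) == "transient"
        assert classify_response(sustained_high_ngf, 10.0) == "sustained"


class TestPulseMaximaDecay:
    def test_decay_ratio_arithmetic(self):
        pr = make_pulse_train("EGF", 25, 2, 8, 0, 30)
        v = np.zeros(31)
        v[[1, 11, 21]] = [0.30, 0.24, 0.15]
        maxima, ratio = pulse_maxima_decay(traj(v), pr)
        assert maxima == [0.30, 0.24, 0.15]
        assert ratio == pytest.approx(0.5)

    def test_memoryless_trace_ratio_one(self):
        pr = make_pulse_train("EGF", 25, 2, 8, 0, 30)
        v = np.zeros(31)
        v[[1, 11, 21]] = 0.3
        _, ratio = pulse_maxima_decay(traj(v), pr)
        assert ratio == pytest.approx(1.0)

    def test_requires_two_pulses(self):
        pr = make_sustained("EGF", 25, 0, 30)
        with pytest.raises(ValueError):
            pulse_maxima_decay(traj(np.ones(31)), pr)

    def test_sparse_trains_decay_least(self, train_decay_ratios):
        """3'/60' trains desensitize less than 3'/10' trains at equal dose."""
        assert train_decay_ratios[(60.0, "egf_high")] > train_decay_ratios[(10.0, "egf_high")]


class TestErkIntegral:
    def test_constant_excess(self):
        v = np.r_[np.ones(5), np.full(65, 3.0)]
        tr = traj(v)
        assert erk_integral(tr, 4, 5, 65) == pytest.approx(120.0)

    def test_zero_excess(self):
        assert erk_integral(traj(np.ones(30)), 5, 5, 25) == 0.0

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            erk_integral(traj(np.ones(30)), 5, 20, 10)

    def test_against_fine_riemann_oracle(self, full_params):
        """Trapezoid on the 1-min grid within 0.1% of a 100x-finer
        Riemann sum of the same smooth simulated trace."""
        from erkpulse import simulate_deterministic
        pr = make_sustained("NGF", 50, 10, 70)
        coarse = simulate_deterministic(full_params, pr, dt_out=1.0)
        fine = simulate_deterministic(full_params, pr, dt_out=0.01)
        val = erk_integral(coarse, 10, 10, 70)
        i0 = int(np.searchsorted(fine.t, 10 - 1e-9))
        excess = np.clip(fine.erk - fine.erk[i0], 0, None)
        sel = fine.t >= 10 - 1e-9
        riemann = np.sum(excess[sel][:-1]) * 0.01
        assert val == pytest.approx(riemann, rel=1e-3)


class TestCorrelatePeakVsLate:
    def test_perfect_dependence(self):
        trs = []
        for a in (0.2, 0.5, 0.9, 1.4):
            v = np.r_[np.ones(5), 1 + a * np.ones(60)]
            trs.append(traj(v))
        rho, p = correlate_peak_vs_late(trs, 4)
        assert rho == pytest.approx(1.0)

    def test_permutation_null_gives_small_correlation(self):
        """Late activity independent of amplitude: |rho| small and p not
        extreme (permutation-style oracle with shuffled pairings)."""
        rng = np.random.default_rng(1)
        amps = rng.uniform(0.5, 1.0, 200)
        lates = rng.permutation(amps)
        trs = []
        for a, l in zip(amps, lates):
            # late plateau scaled below every peak so the first-response
            # maximum is always the early phase
            v = np.r_[np.ones(5), np.full(20, 1 + a), np.full(40, 1 + 0.3 * l)]
            trs.append(traj(v))
        rho, p = correlate_peak_vs_late(trs, 4)
        assert abs(rho) < 0.2
        assert p > 1e-3

    def test_degenerate_inputs_flagged(self):
        trs = [traj(np.ones(60)) for _ in range(5)]
        rho, p = correlate_peak_vs_late(trs, 4)
        assert np.isnan(rho)


class TestInvariances:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(-40, 200))
    def test_time_translation_invariance(self, shift):
        """All first-peak metrics are invariant under a uniform time shift
        of trace and stimulus start."""
        v = np.r_[np.ones(6), 1 + np.array([.2, .5, .4, .25, .1, .05, .02, 0, 0])]
        a = Trajectory(np.arange(len(v), dtype=float), v)
        b = Trajectory(shift + np.arange(len(v), dtype=float), v)
        assert peak_amplitude(a, 5) == peak_amplitude(b, 5 + shift)
        assert peak_duration(a, 5) == peak_duration(b, 5 + shift)

    def test_amplitude_scales_linearly(self):
        v = np.r_[np.zeros(5), .2, .5, .4, .2, .1, 0, 0]
        a, b = traj(v), traj(3 * v)
        assert peak_amplitude(b, 4) == pytest.approx(3 * peak_amplitude(a, 4))
        assert erk_integral(b, 4, 4, 11) == pytest.approx(3 * erk_integral(a, 4, 4, 11))
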