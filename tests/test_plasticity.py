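"""Cortical LTD/LTP dynamics and nuclear memory-transfer dynamics."""

import numpy as np
import pytest

from okrsim.plasticity import (
    MfVnPlasticity,
    MfVnPlasticityFull,
    PfPcPlasticity,
    mean_pf_weight,
)

MIN_MS = 60_000.0


def make_state(n_pf=4, n_pc=1, **kw):
    kw.setdefault("tau_w_ms", 2_000.0)
    kw.setdefault("tau_x_ms", 24_000.0)
    return PfPcPlasticity(n_pf, n_pc, **kw)


class TestPfPcRule:
    def test_free_decay_matches_closed_form(self):
        # with no spikes, x decays exponentially and w follows the
        # two-exponential solution of the coupled linear system
        tw, tx = 2_000.0, 24_000.0
        st = make_state(n_pf=1, tau_w_ms=tw, tau_x_ms=tx, w_min=None)
        x0 = -0.4
        st.x[:] = x0
        n = 4000
        zeros = np.zeros(1, dtype=bool)
        for _ in range(n):
            st.step(zeros, False)
        t = float(n)
        x_exact = x0 * np.exp(-t / tx)
        # w' = (1 + x - w)/tw with x(t) = x0 e^{-t/tx}:
        # w(t) = 1 + x0 tw/(tw - tx) (e^{-t/tw} - e^{-t/tx}) ... solve:
        a = x0 / (1.0 - tw / tx)
        w_exact = 1.0 + a * (np.exp(-t / tx) - (1.0) * np.exp(-t / tw)) + 0.0
        # forward-Euler at dt=1 against exact: tolerance ~dt/tau
        assert st.x[0, 0] == pytest.approx(x_exact, rel=2e-3)
        assert st.w[0, 0] == pytest.approx(w_exact, rel=2e-3, abs=2e-4)

    def test_cf_spike_depresses_by_n_times_ltd_step(self):
        # 3 PF spikes in the eligibility window before a CF spike
        st = make_state(n_pf=2, ltd_step=0.005, ltp_step=0.0)
        pf = np.array([1, 0], dtype=bool)
        st.step(pf, False)
        st.step(pf, False)
        st.step(pf, False)
        x_before = st.x.copy()
        st.step(np.zeros(2, dtype=bool), True)
        dx = st.x - x_before * (1 - 1.0 / st.tau_x_ms)
        assert dx[0, 0] == pytest.approx(-3 * 0.005)
        assert dx[0, 1] == pytest.approx(0.0)

    def test_ltp_step_per_pf_spike(self):
        st = make_state(n_pf=1, ltd_step=0.0, ltp_step=0.005)
        st.step(np.array([True]), False)
        assert st.x[0, 0] == pytest.approx(0.005)

    def test_window_holds_exactly_50_samples(self):
        # a spike 50 steps old has left the eligibility window
        st = make_state(n_pf=1)
        st.step(np.array([True]), False)
        for _ in range(49):
            st.step(np.array([False]), False)
        assert st.window_counts[0] == 1
        st.step(np.array([False]), False)
        assert st.window_counts[0] == 0

    def test_rest_balance_identity_of_default_steps(self):
        # defaults satisfy ltp_step = ltd_step * window * rest CF rate,
        # making rest input stationary in expectation
        st = PfPcPlasticity(1)
        window_s = 0.050
        assert st.ltp_step == pytest.approx(st.ltd_step * window_s * 1.0)

    def test_dt_must_divide_window(self):
        with pytest.raises(ValueError):
            make_state(dt_ms=3.0)

    def test_per_pc_cf_flags(self):
        st = make_state(n_pf=1, n_pc=2, ltd_step=0.1, ltp_step=0.0)
        st.step(np.array([True]), np.array([True, False]))
        assert st.x[0, 0] < 0.0
        assert st.x[1, 0] == pytest.approx(0.0)

    def test_superposition_linearity(self):
        # deviations driven by the sum of two input histories equal the
        # sum of deviations driven by each history (clipping disabled)
        rng = np.random.default_rng(9)
        n, steps = 8, 400
        h1 = rng.random((steps, n)) < 0.05
        h2 = rng.random((steps, n)) < 0.05
        cf1 = rng.random(steps) < 0.01
        cf2 = (rng.random(steps) < 0.01) & ~cf1  # disjoint CF streams

        def respond(pf_hist, cf_hist):
            st = make_state(n_pf=n, w_min=None)
            for t in range(steps):
                st.step(pf_hist[t], bool(cf_hist[t]))
            return st.w - 1.0, st.x

        # PF spike counts add; CF uses the union with summed window counts,
        # so use disjoint CF streams for exact linearity
        w12, x12 = respond((h1.astype(int) + h2.astype(int)), cf1 | cf2)
        # linear reference: drive with each history against the *summed*
        # spike counts is not separable when CF streams overlap; make them
        # disjoint for the check
        assume_disjoint = ~(cf1 & cf2)
        assert assume_disjoint.all()
        w1, x1 = respond(h1.astype(int), cf1)
        w2, x2 = respond(h2.astype(int), cf2)
        # cross terms: CF of stream 1 also sees PF spikes of stream 2
        st = make_state(n_pf=n, w_min=None, ltp_step=0.0)
        for t in range(steps):
            st.step(h2[t].astype(int), bool(cf1[t]))
        w_c1, x_c1 = st.w - 1.0, st.x
        st = make_state(n_pf=n, w_min=None, ltp_step=0.0)
        for t in range(steps):
            st.step(h1[t].astype(int), bool(cf2[t]))
        w_c2, x_c2 = st.w - 1.0, st.x
        np.testing.assert_allclose(x12, x1 + x2 + x_c1 + x_c2, atol=1e-12)
        np.testing.assert_allclose(w12, w1 + w2 + w_c1 + w_c2, atol=1e-12)

    def test_weight_clipped_at_zero(self):
        st = make_state(n_pf=1, tau_w_ms=2.0, ltd_step=10.0)
        pf = np.array([True])
        for _ in range(100):
            st.step(pf, True)
        assert st.w[0, 0] == 0.0

    def test_literal_form_relaxes_toward_x(self):
        st = make_state(n_pf=1, form="literal", tau_w_ms=10.0)
        zeros = np.zeros(1, dtype=bool)
        for _ in range(2000):
            st.step(zeros, False)
        # as printed, with x -> 0 the weight drains toward 0
        assert st.w[0, 0] < 0.1

    def test_mean_pf_weight(self):
        st = make_state(n_pf=4, n_pc=1)
        st.w[:] = [[0.8, 1.0, 0.8, 1.0]]
        assert mean_pf_weight(st) == pytest.approx(0.9)
        rng = np.random.default_rng(0)
        st.w[:] = rng.random((1, 4))
        assert mean_pf_weight(st) == pytest.approx(st.w.sum() / st.w.size)


class TestMfVnSimplified:
    def test_equilibrium_at_w_c(self):
        rule = MfVnPlasticity(tau_v_ms=MIN_MS)
        for _ in range(100):
            rule.step(1.0)
        assert rule.v == pytest.approx(1.0)

    def test_constant_drive_exact_integral(self):
        # w held at w_c - delta for duration D: v increases by delta*D/tau_v
        delta, steps, tau = 0.25, 5000, 600_000.0
        rule = MfVnPlasticity(tau_v_ms=tau)
        for _ in range(steps):
            rule.step(1.0 - delta)
        assert rule.v == pytest.approx(1.0 + delta * steps / tau, rel=1e-12)

    def test_nondecreasing_while_w_below_baseline(self):
        rng = np.random.default_rng(4)
        rule = MfVnPlasticity(tau_v_ms=MIN_MS)
        prev = rule.v
        for w in 1.0 - 0.3 * rng.random(500):
            rule.step(float(w))
            assert rule.v >= prev
            prev = rule.v

    def test_v_clipped_at_zero(self):
        rule = MfVnPlasticity(tau_v_ms=10.0, v_init=0.001)
        for _ in range(100):
            rule.step(2.0)
        assert rule.v == 0.0


class TestMfVnFull:
    def test_zero_mf_leaves_v_unchanged(self):
        rule = MfVnPlasticityFull(tau_v_ms=MIN_MS, window_ms=100.0)
        for _ in range(500):
            rule.accumulate(0.0, 30.0)
        assert rule.v == pytest.approx(1.0)

    def test_vn_at_threshold_gives_pure_decay(self):
        # VN pinned to its running average: Hebbian term vanishes and
        # v decays at rate <MF>/tau_v per window
        win, tau, mf = 100.0, 1_000_000.0, 15.0
        rule = MfVnPlasticityFull(tau_v_ms=tau, window_ms=win)
        n_windows = 40
        for _ in range(int(n_windows * win)):
            rule.accumulate(mf, 30.0)
        v_exact = 1.0
        for _ in range(n_windows):
            v_exact += (win / tau) * (-v_exact * mf)
        assert rule.v == pytest.approx(v_exact, rel=1e-9)

    def test_vn_step_above_threshold_potentiates(self):
        # quadrature oracle: replicate the per-window Euler map directly
        win, tau = 100.0, 1_000_000.0
        rule = MfVnPlasticityFull(tau_v_ms=tau, window_ms=win, theta_windows=10)
        mf, vn_lo, vn_hi = 15.0, 20.0, 60.0
        seq = [vn_lo] * 10 + [vn_hi] * 5 + [vn_lo] * 10
        for vn in seq:
            for _ in range(int(win)):
                rule.accumulate(mf, vn)
        # independent quadrature of the same window sequence
        v, theta = 1.0, None
        keep = np.exp(-1.0 / 10)
        for vn in seq:
            if theta is None:
                theta = vn
            v += (win / tau) * (-v * mf + (mf * vn - theta * mf))
            v = max(v, 0.0)
            theta = keep * theta + (1 - keep) * vn
        assert rule.v == pytest.approx(v, rel=1e-12)
        # and the step above threshold transiently raised v
        assert rule.v > 1.0 - 20 * 25 * (win / tau)
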