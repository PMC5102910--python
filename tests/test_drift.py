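"""Drift model, transient-epoch delimitation, and the two-stage drift fit."""

import numpy as np
import pytest

from catrace import (DriftParams, FixtureSpec, PipelineConfig, default_response,
                     generate_trace, standard_tr_fixture)
from catrace.drift import (Delimitation, delimit, drift_component,
                           drift_component_derivative, drift_index_set,
                           drift_weights, fit_drift_initial, fit_drift_weighted,
                           global_drift, global_drift_derivative)
from catrace.tv import tv_iterate


class TestDriftModel:
    def test_component_zero_at_origin(self):
        assert drift_component(0.0, a=2.0, tau=5.0, m=0.3) == 0.0

    def test_component_pure_line_when_a_zero(self, times_2hz):
        out = drift_component(times_2hz, a=0.0, tau=5.0, m=0.3)
        assert np.allclose(out, 0.3 * times_2hz)

    def test_component_plateau(self):
        # at t = 10*tau the exponential term is within 1e-4*a of its plateau
        assert abs(drift_component(50.0, a=2.0, tau=5.0, m=0.0) - 2.0) < 1e-4 * 2.0

    def test_component_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            drift_component(1.0, a=1.0, tau=0.0, m=0.0)

    def test_global_continuity_at_t2(self):
        p = DriftParams(a1=1.0, tau1=10.0, m1=0.01, a2=-0.5, tau2=5.0, m2=0.02,
                        t2=40.0, z=2.0)
        eps = 1e-9
        left = global_drift(np.array([40.0 - eps]), p)[0]
        right = global_drift(np.array([40.0 + eps]), p)[0]
        assert abs(left - right) < 1e-6

    def test_global_constant_offset(self, times_2hz):
        p = DriftParams(z=5.0, t2=np.inf)
        assert np.allclose(global_drift(times_2hz, p), 5.0)

    def test_pre_t2_independent_of_second_component(self, times_2hz):
        base = dict(a1=0.4, tau1=20.0, m1=-0.001, t2=60.0, z=1.0)
        p1 = DriftParams(**base, a2=0.0, tau2=1.0, m2=0.0)
        p2 = DriftParams(**base, a2=3.0, tau2=2.0, m2=0.5)
        early = times_2hz[times_2hz < 60.0]
        assert np.allclose(global_drift(early, p1), global_drift(early, p2))

    def test_analytic_derivative_matches_numeric(self):
        p = DriftParams(a1=0.5, tau1=12.0, m1=0.004, a2=-0.2, tau2=7.0, m2=-0.002,
                        t2=50.0, z=1.0)
        t = np.linspace(1.0, 119.0, 500)
        t = t[np.abs(t - 50.0) > 0.5]  # avoid the kink at t2
        h = 1e-6
        num = (global_drift(t + h, p) - global_drift(t - h, p)) / (2 * h)
        assert np.abs(global_drift_derivative(t, p) - num).max() < 1e-6


class TestDelimitation:
    def test_flat_trace_gives_empty_set(self, times_2hz):
        st = tv_iterate(np.full(times_2hz.size, 1.0), times_2hz)
        d = delimit(times_2hz, st)
        assert not d.has_activation

    @pytest.mark.parametrize("seed", range(6))
    def test_onset_and_peak_located(self, seed):
        """Activation index within 2 s of onset, peak index within 2 s of peak."""
        spec = standard_tr_fixture(seed=seed, snr=20, with_drift=False)
        trace, gt = generate_trace(spec)
        st = tv_iterate(trace.values, trace.times)
        d = delimit(trace.times, st)
        assert d.has_activation
        t_on = gt.tr.activation.t_on
        # true peak of the generating response
        tg = np.arange(t_on, trace.times[-1], 0.01)
        from catrace.transient import response_model
        t_peak = tg[np.argmax(np.atleast_1d(response_model(tg, gt.tr)))]
        assert abs(trace.times[d.i_act0] - t_on) <= 2.0
        assert abs(trace.times[d.i_max] - t_peak) <= 2.0

    def test_decaying_drift_peak_not_at_boundary(self):
        """Strong negative drift puts the global argmax at t=0; the epoch
        search must still land inside the transient."""
        spec = FixtureSpec(
            drift=DriftParams(a1=-1.5, tau1=15.0, z=2.5),
            tr=default_response(amplitude=0.6), noise_sd=0.02, seed=4)
        trace, gt = generate_trace(spec)
        assert np.argmax(trace.values) < 5  # construction: global max at start
        st = tv_iterate(trace.values, trace.times)
        d = delimit(trace.times, st)
        assert d.has_activation
        assert 10.0 < trace.times[d.i_max] < 40.0

    def test_invariant_to_additive_constant(self):
        """The index formulas see only derivative statistics and differences
        of the data estimate, so shifting the record leaves them unchanged."""
        from dataclasses import replace as dc_replace
        spec = standard_tr_fixture(seed=2, snr=20)
        trace, _ = generate_trace(spec)
        st1 = tv_iterate(trace.values, trace.times)
        st2 = dc_replace(st1, au=st1.au + 100.0)
        d1 = delimit(trace.times, st1)
        d2 = delimit(trace.times, st2)
        assert d1.i_act0 == d2.i_act0 and d1.i_max == d2.i_max \
            and d1.i_end0 == d2.i_end0


def _fit_setup(seed, drift, noise_sd, tr=None):
    spec = FixtureSpec(drift=drift, tr=tr, noise_sd=noise_sd, seed=seed)
    trace, gt = generate_trace(spec)
    st = tv_iterate(trace.values, trace.times)
    d = delimit(trace.times, st)
    return trace, gt, st, d


class TestDriftFitting:
    @pytest.mark.parametrize("seed", range(8))
    def test_parameter_recovery_on_pure_drift(self, seed):
        """(a1, m1, z) recovered within 10% when data follow the model."""
        truth = DriftParams(a1=0.4, tau1=25.0, m1=-0.0015, z=1.0)
        # noise at 1% of the drift's range keeps the exponential identifiable
        rng_range = np.ptp(global_drift(np.arange(0, 120, .5), truth))
        trace, _, st, d = _fit_setup(seed, truth, 0.01 * rng_range)
        fit = fit_drift_initial(trace.times, trace.values,
                                Delimitation(i_local=np.array([], dtype=int)),
                                st.clean_mask, two_components=False)
        assert abs(fit.a1 - truth.a1) / abs(truth.a1) < 0.10
        assert abs(fit.m1 - truth.m1) / abs(truth.m1) < 0.10
        assert abs(fit.z - truth.z) / abs(truth.z) < 0.10

    def test_pure_linear_data_small_exponential(self):
        truth = DriftParams(a1=0.0, tau1=10.0, m1=0.004, z=1.0)
        trace, _, st, _ = _fit_setup(0, truth, 0.005)
        fit = fit_drift_initial(trace.times, trace.values,
                                Delimitation(i_local=np.array([], dtype=int)),
                                st.clean_mask, two_components=False)
        assert abs(fit.a1) < 2 * max(st.sigma_minus, 0.005)

    def test_index_set_excludes_transient_epoch(self):
        spec = standard_tr_fixture(seed=1, snr=20)
        trace, gt = generate_trace(spec)
        st = tv_iterate(trace.values, trace.times)
        d = delimit(trace.times, st)
        k = drift_index_set(trace.n, d, st.clean_mask)
        peak_idx = np.argmax(trace.values)
        assert peak_idx not in k

    def test_perfect_theta0_keeps_weights_one(self, times_2hz):
        truth = DriftParams(a1=0.3, tau1=20.0, m1=0.001, z=1.0)
        u_exact = global_drift_derivative(times_2hz, truth)
        k = np.arange(times_2hz.size)
        w = drift_weights(times_2hz, u_exact, truth, k)
        assert np.allclose(w, 1.0)

    def test_weights_bounded_in_unit_interval(self):
        truth = DriftParams(a1=0.3, tau1=20.0, m1=0.001, z=1.0)
        trace, _, st, d = _fit_setup(3, truth, 0.01)
        k = drift_index_set(trace.n, d, st.clean_mask)
        w = drift_weights(trace.times, st.u, truth, k)
        assert np.all(w > 0.0) and np.all(w <= 1.0)

    def test_scale_equivariance(self):
        truth = DriftParams(a1=0.4, tau1=25.0, m1=-0.0015, z=1.0)
        trace, _, st, _ = _fit_setup(5, truth, 0.004)
        delim = Delimitation(i_local=np.array([], dtype=int))
        f1 = fit_drift_initial(trace.times, trace.values, delim, st.clean_mask,
                               two_components=False)
        c = 3.0
        f2 = fit_drift_initial(trace.times, c * trace.values, delim, st.clean_mask,
                               two_components=False)
        for name in ("a1", "m1", "z"):
            assert np.isclose(getattr(f2, name), c * getattr(f1, name),
                              rtol=0.05, atol=1e-3)

    def test_weighted_refit_downweights_early_shift(self):
        """A pre-activation baseline shift is ignored in favor of the later
        trend: post-activation residuals improve under the weighted fit."""
        t = np.arange(0.0, 120.0, 0.5)
        rng = np.random.default_rng(8)
        # early transient trend that dies by t=20, then a steady slow drift
        early = -0.5 * np.exp(-t / 6.0)
        late = 0.3 * (1 - np.exp(-t / 40.0))
        F = 1.0 + early + late + rng.normal(0, 0.01, t.size)
        st = tv_iterate(F, t)
        d = delimit(t, st)
        delim = Delimitation(i_local=np.array([], dtype=int))
        th0 = fit_drift_initial(t, F, delim, st.clean_mask, two_components=False)
        thw, w = fit_drift_weighted(t, F, st, delim, th0, PipelineConfig())
        assert np.all(w > 0) and np.all(w <= 1)
        lateband = t > 30
        res_w = np.abs(global_drift(t, thw) - (1.0 + late))[lateband].mean()
        res_0 = np.abs(global_drift(t, th0) - (1.0 + late))[lateband].mean()
        assert res_w <= res_0 + 0.01
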