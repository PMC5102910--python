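"""Deviation finding, bias/reliability weights, clustering, MPR metrics."""

import numpy as np
import pytest

from catrace import DriftParams, FixtureSpec, OscSpec, PipelineConfig, generate_trace
from catrace.mpr import (DeviationSet, bias_weights, cluster_coherent,
                         find_deviations, mpr_metrics, reliability_weights)
from catrace.io import characterize_trace
from catrace.tv import tv_iterate


def _event_set(peak_t, peak_h, peak_w, trough_t=(), trough_h=(), trough_w=()):
    return DeviationSet(
        peak_idx=np.arange(len(peak_t)), peak_times=np.asarray(peak_t, float),
        peak_heights=np.asarray(peak_h, float), peak_fwhm=np.asarray(peak_w, float),
        trough_idx=np.arange(len(trough_t)), trough_times=np.asarray(trough_t, float),
        trough_heights=np.asarray(trough_h, float), trough_fwhm=np.asarray(trough_w, float),
        coherent_peaks=np.zeros(len(peak_t), dtype=bool),
        coherent_troughs=np.zeros(len(trough_t), dtype=bool),
    )


class TestFindDeviations:
    def test_flat_residual_yields_no_events(self, times_2hz):
        spec = FixtureSpec(drift=DriftParams(z=1.0), noise_sd=0.01, seed=0)
        trace, _ = generate_trace(spec)
        st = tv_iterate(trace.values, trace.times)
        dev = find_deviations(trace.times, st, None, DriftParams(z=1.0))
        assert dev.n_tilde <= 1  # at most a stray noise bump

    def test_suprathreshold_train_counted(self):
        spec = FixtureSpec(drift=DriftParams(z=1.0), noise_sd=0.02, seed=1,
                           osc=OscSpec(period=12.0, amplitude=0.4, n_cycles=8,
                                       fwhm=3.0, start=12.0))
        trace, gt = generate_trace(spec)
        st = tv_iterate(trace.values, trace.times)
        dev = find_deviations(trace.times, st, None, DriftParams(z=1.0))
        assert dev.n_peak == 8
        # matched within a sample
        assert np.abs(dev.peak_times - gt.osc_times).max() <= 1.0

    def test_subthreshold_train_rejected(self):
        spec = FixtureSpec(drift=DriftParams(z=1.0), noise_sd=0.02, seed=1,
                           osc=OscSpec(period=12.0, amplitude=0.045, n_cycles=8,
                                       fwhm=3.0, start=12.0))
        trace, _ = generate_trace(spec)
        st = tv_iterate(trace.values, trace.times)
        # ~3 sigma_minus bumps: below the 6 sigma_minus height requirement
        assert spec.osc.amplitude < 6 * st.sigma_minus
        dev = find_deviations(trace.times, st, None, DriftParams(z=1.0))
        assert dev.n_peak == 0


class TestBiasWeights:
    def test_equal_first_heights(self):
        dev = _event_set([10, 20], [1.0, 1.0], [2, 2], [15], [1.0], [2])
        o_p, o_t = bias_weights(dev)
        assert np.isclose(o_p, np.exp(-1.0))
        assert np.isclose(o_t, np.exp(-1.0))

    def test_dominant_first_peak(self):
        dev = _event_set([10], [3.0], [2], [15], [1.0], [2])
        o_p, o_t = bias_weights(dev)
        assert np.isclose(o_p, np.exp(-81.0))
        assert np.isclose(o_t, np.exp(-1.0 / 81.0))

    def test_label_swap_symmetry(self):
        dev1 = _event_set([10], [2.0], [2], [15], [0.8], [2])
        dev2 = _event_set([15], [0.8], [2], [10], [2.0], [2])
        assert np.allclose(bias_weights(dev1),
                           tuple(reversed(bias_weights(dev2))), rtol=1e-12)


class TestReliabilityWeights:
    def test_omega_nonnegative_and_downweights_oscillations(self):
        spec = FixtureSpec(drift=DriftParams(z=1.0), noise_sd=0.02, seed=3,
                           osc=OscSpec(period=14.0, amplitude=0.4, n_cycles=6,
                                       fwhm=3.0, start=20.0))
        trace, gt = generate_trace(spec)
        st = tv_iterate(trace.values, trace.times)
        dev = find_deviations(trace.times, st, None, DriftParams(z=1.0))
        assert dev.n_peak >= 5
        from catrace.transient import ActivationParams, ResponseParams
        flat = ResponseParams(
            activation=ActivationParams(t_on=5.0, A_act=0.0, beta=1.0, n_act=1.0),
            t_de=6.0, sigma_act=0.1, sigma_de=0.1, A_de=0.0, gamma=5.0, n_de=2.0,
            t_end=trace.times[-1], drift=DriftParams(z=1.0))
        o_p, o_t = bias_weights(dev)
        omega = reliability_weights(trace.times, st, flat, dev, o_p, o_t)
        assert np.all(omega >= 0.0)
        t = trace.times
        on_osc = np.zeros(t.size, dtype=bool)
        for c in gt.osc_times:
            on_osc |= np.abs(t - c) < 0.75 * spec.osc.fwhm
        assert omega[on_osc].mean() < omega[~on_osc].mean()


class TestClustering:
    def test_strict_periodic_train_all_coherent(self):
        dev = _event_set(np.arange(8) * 12.0 + 10.0, np.full(8, 1.0), np.full(8, 3.0))
        dev = cluster_coherent(dev, seed=0)
        assert dev.coherent_peaks.all()
        m = mpr_metrics(dev, "coherent")
        assert m.sigma_T < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_outlier_spikes_excluded(self, seed):
        """Interspersed events with far-off (T, width) leave the coherent set."""
        rng = np.random.default_rng(seed)
        train_t = np.arange(8) * 12.0 + 10.0
        extra_t = rng.uniform(12.0, 100.0, 3)
        all_t = np.sort(np.concatenate([train_t, extra_t]))
        is_train = np.isin(all_t, train_t)
        widths = np.where(is_train, 3.0, 0.5)  # 6x separation in width
        dev = _event_set(all_t, np.ones(all_t.size), widths)
        dev = cluster_coherent(dev, seed=seed)
        # every train member kept, and the coherent subset tighter in period
        assert dev.coherent_peaks[is_train].mean() >= 0.8
        m_all = mpr_metrics(dev, "all")
        m_coh = mpr_metrics(dev, "coherent")
        assert m_coh.sigma_T <= m_all.sigma_T + 1e-12

    def test_chirped_train_reunited_by_trend_merge(self):
        # period grows 10% per cycle: EM tends to split; the linear trend
        # prediction should stitch the clusters back together
        periods = 8.0 * 1.1 ** np.arange(9)
        t = 10.0 + np.concatenate([[0.0], np.cumsum(periods)])
        widths = np.linspace(2.5, 4.5, t.size)
        dev = _event_set(t, np.ones(t.size), widths)
        dev = cluster_coherent(dev, seed=1)
        assert dev.coherent_peaks.mean() >= 0.8

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(5, 115, 12))
        dev1 = _event_set(t, np.ones(12), rng.uniform(1, 4, 12))
        dev2 = _event_set(t, dev1.peak_heights.copy(), dev1.peak_fwhm.copy())
        m1 = cluster_coherent(dev1, seed=7).coherent_peaks
        m2 = cluster_coherent(dev2, seed=7).coherent_peaks
        assert np.array_equal(m1, m2)


class TestMPRMetrics:
    def test_exact_arithmetic_regular_train(self):
        dev = _event_set(10.0 + 12.0 * np.arange(8), np.full(8, 0.7), np.full(8, 3.0))
        m = mpr_metrics(dev, "all")
        assert m.n_osc == 8
        assert m.period_T == 12.0
        assert m.sigma_T == 0.0
        assert m.persistence_l_osc == 84.0
        assert np.isclose(m.duty_cycle, 0.25)
        assert np.isclose(m.magnitude_E, 0.7)

    def test_jittered_periods_sample_std(self):
        t = np.array([0.0, 10.0, 22.0, 36.0])  # periods 10, 12, 14
        dev = _event_set(t, np.ones(4), np.full(4, 3.0))
        m = mpr_metrics(dev, "all")
        assert np.isclose(m.period_T, 12.0)
        assert np.isclose(m.sigma_T, 2.0)  # sample (N-1) standard deviation

    def test_too_few_peaks_gives_nan_period(self):
        dev = _event_set([10.0], [1.0], [2.0])
        m = mpr_metrics(dev, "all")
        assert m.n_osc == 1 and np.isnan(m.period_T)

    def test_coherent_subset_conservation(self):
        dev = _event_set(10.0 + 12.0 * np.arange(6), np.ones(6), np.full(6, 3.0))
        dev = cluster_coherent(dev, seed=0)
        assert mpr_metrics(dev, "coherent").n_osc <= mpr_metrics(dev, "all").n_osc


class TestWeightedRefit:
    def test_reliability_refit_reduces_median_amplitude_error(self):
        """With oscillations superimposed on a transient, the Omega-weighted
        refit reduces the median amplitude error relative to the unweighted
        fit (individual seeds already within noise may jitter slightly)."""
        from catrace import standard_tr_fixture
        from catrace.drift import delimit, fit_drift_initial, fit_drift_weighted
        from catrace.mpr import refit_response_weighted
        from catrace.transient import (detect_transient, fit_activation,
                                       fit_response, response_model)
        cfg = PipelineConfig()
        e0, e1 = [], []
        for seed in range(6):
            spec = standard_tr_fixture(seed=seed, snr=20)
            spec.osc = OscSpec(period=12.0, amplitude=0.5, n_cycles=6,
                               fwhm=3.0, start=45.0)
            trace, gt = generate_trace(spec)
            t, F = trace.times, trace.values
            st = tv_iterate(F, t, cfg)
            dl = delimit(t, st)
            th0 = fit_drift_initial(t, F, dl, st.clean_mask, cfg, True)
            thw, w = fit_drift_weighted(t, F, st, dl, th0, cfg)
            act = fit_activation(t, F, st, dl, thw, w, cfg)
            detected, _, best = detect_transient(t, F, st, dl, thw, act.drift, w, cfg)
            assert detected
            rp0 = fit_response(t, F, st, dl, act, cfg)
            dev = find_deviations(t, st, rp0, best, cfg)
            assert dev.n_tilde > 2
            o_p, o_t = bias_weights(dev)
            omega = reliability_weights(t, st, rp0, dev, o_p, o_t)
            rp1 = refit_response_weighted(t, F, st, dl, act, omega, cfg)
            a_true = gt.tr_metrics.amplitude
            e0.append(abs(float(np.max(np.atleast_1d(response_model(t, rp0)))) - a_true))
            e1.append(abs(float(np.max(np.atleast_1d(response_model(t, rp1)))) - a_true))
        assert np.median(e1) <= np.median(e0)


class TestEndToEndMPR:
    def test_transient_with_superimposed_train(self):
        from catrace import standard_tr_fixture
        spec = standard_tr_fixture(seed=1, snr=20)
        spec.osc = OscSpec(period=12.0, amplitude=0.5, n_cycles=6, fwhm=3.0, start=45.0)
        trace, gt = generate_trace(spec)
        res = characterize_trace(trace)
        assert res.report.detected
        assert res.report.mpr_all is not None
        coh = res.report.mpr_coherent
        assert coh is not None and coh.n_osc >= 5
        assert abs(coh.period_T - 12.0) < 1.0
        assert coh.sigma_T <= res.report.mpr_all.sigma_T
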