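import math

import numpy as np
import pytest
import scipy.signal as sig
import scipy.stats as sps
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

from hypnohrv import pphrv, synth
from hypnohrv.ecg import BeatSeries
from hypnohrv.pphrv import (HDIGFit, HDIGParams, SpectrumError, band_powers,
                            conditional_mean, fit_hdig, hrv_from_fit,
                            ig_density, instantaneous_moments,
                            instantaneous_spectrum, ks_rescaling_gof,
                            local_loglik)


class TestIgDensity:
    def test_value_at_the_mean(self):
        # exponent vanishes at t - u_k = mu for mu = shape = 1
        assert ig_density(1.0, 0.0, 1.0, 1.0) == pytest.approx(
            (2 * math.pi) ** -0.5, abs=1e-12)

    def test_normalizes_to_one(self):
        val, _ = quad(lambda t: ig_density(t, 0.0, 0.8, 2.0), 1e-9, 80)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_moments(self):
        rng = np.random.default_rng(0)
        x = rng.wald(0.9, 5.0, size=1_000_000)
        se_mean = x.std() / 1000
        assert abs(x.mean() - 0.9) < 3 * se_mean
        var_true = 0.9 ** 3 / 5.0
        se_var = np.std((x - x.mean()) ** 2) / 1000
        assert abs(x.var() - var_true) < 3 * se_var

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ig_density(0.5, 1.0, 0.8, 1.0)
        with pytest.raises(ValueError):
            ig_density(1.5, 0.0, -0.1, 1.0)


class TestConditionalMean:
    def test_intercept_only(self):
        theta = np.zeros(10)
        theta[0] = 0.8
        assert conditional_mean(np.full(9, 1.3), theta) == pytest.approx(0.8)

    def test_identity_regression(self):
        theta = np.zeros(10)
        theta[1] = 1.0
        hist = np.full(9, 0.6)
        hist[0] = 0.75
        assert conditional_mean(hist, theta) == pytest.approx(0.75)

    def test_two_lag_arithmetic(self):
        theta = np.array([0.4, 0.25, 0.25])
        assert conditional_mean([0.8, 0.8], theta) == pytest.approx(0.8)

    def test_nonpositive_mean_flagged(self):
        theta = np.array([-1.0, 0.1])
        with pytest.raises(ValueError, match="non-positive"):
            conditional_mean([0.5], theta)


class TestLocalLoglik:
    def test_matches_direct_summation_oracle(self, twenty_beat_series):
        beats = twenty_beat_series
        theta = np.concatenate([[0.5], np.full(9, 0.045)])
        params = HDIGParams(theta=theta, shape=600.0)
        t_now = beats.times[-1] + 0.3
        ll = local_loglik(params, beats, t_now)
        # independent oracle: plain-float direct summation, scipy survivor
        rr = np.diff(beats.times)
        acc = 0.0
        for k in range(9, rr.size):
            end = beats.times[k + 1]
            if end <= t_now - 90.0 or end > t_now:
                continue
            hist = rr[k - 9:k][::-1]
            mu = theta[0] + float(np.dot(theta[1:], hist))
            w = rr[k]
            pdf = math.sqrt(600.0 / (2 * math.pi * w ** 3)) * math.exp(
                -600.0 * (w - mu) ** 2 / (2 * mu * mu * w))
            acc += 0.98 ** (t_now - end) * math.log(pdf)
        mu_c = theta[0] + float(np.dot(theta[1:], rr[-9:][::-1]))
        acc += float(sps.invgauss.logsf(0.3, mu_c / 600.0, scale=600.0))
        assert ll == pytest.approx(acc, abs=1e-10)

    def test_zero_elapsed_censoring_term(self, twenty_beat_series):
        beats = twenty_beat_series
        theta = np.concatenate([[0.9], np.zeros(9)])
        params = HDIGParams(theta=theta, shape=500.0)
        t_at_beat = float(beats.times[-1])
        ll_at = local_loglik(params, beats, t_at_beat)
        ll_just_after = local_loglik(params, beats, t_at_beat + 1e-9)
        assert ll_just_after == pytest.approx(ll_at, abs=1e-4)

    def test_warmup_error(self, twenty_beat_series):
        params = HDIGParams(theta=np.concatenate([[0.9], np.zeros(9)]),
                            shape=500.0)
        with pytest.raises(ValueError, match="warm-up"):
            local_loglik(params, twenty_beat_series, 2.0)


class TestFit:
    def test_deterministic_given_identical_input(self, renewal_beats):
        f1 = fit_hdig(renewal_beats, delta=0.5, t_end=300.0)
        f2 = fit_hdig(renewal_beats, delta=0.5, t_end=300.0)
        assert np.array_equal(f1.theta, f2.theta)
        assert np.array_equal(f1.shape, f2.shape)

    def test_mean_rr_recovered(self, renewal_fit):
        v = renewal_fit.valid
        assert abs(np.mean(renewal_fit.mu[v]) - 0.9) < 0.01

    def test_sigma2_matches_sample_variance_on_renewal(self):
        # Monte-Carlo: both the trajectory average and the sample variance
        # fluctuate per realization, so compare replicate means
        sp = {i: synth.StageHDIG(mean_rr=0.9, theta_ar=np.zeros(1),
                                 shape=800.0) for i in range(5)}
        s2, sample = [], []
        for r in range(5):
            h = synth.gen_hypnogram(np.full((5, 5), 0.2), 1200, seed=40 + r)
            b = synth.gen_rr(h, sp, seed=90 + r, t_end=600.0)
            fit = fit_hdig(b, delta=0.5)
            s2.append(float(np.mean(fit.sigma2[fit.valid])))
            sample.append(float(np.var(np.diff(b.times))))
        assert abs(np.mean(s2) - np.mean(sample)) / np.mean(sample) < 0.10

    def test_sigma2_identity(self, renewal_fit):
        v = renewal_fit.valid
        expected = renewal_fit.mu[v] ** 3 / renewal_fit.shape[v]
        assert np.allclose(renewal_fit.sigma2[v], expected, rtol=1e-9)

    def test_pause_inside_mask(self):
        rng = np.random.default_rng(5)
        rr = rng.wald(0.9, 800.0, size=400)
        times = np.concatenate([[0.0], np.cumsum(rr)])
        mid = float(times[200])
        beats = BeatSeries(times=times, mask=((mid, mid + 20.0),))
        fit = fit_hdig(beats, delta=0.5, resume_after_s=5.0)
        inside = (fit.t >= mid) & (fit.t < mid + 25.0)
        assert inside.any()
        assert not fit.valid[inside].any()
        # frozen parameters: no update across the pause
        i0 = int(np.flatnonzero(inside)[0])
        i1 = int(np.flatnonzero(inside)[-1])
        assert np.array_equal(fit.theta[i0], fit.theta[i1])

    def test_moments_arithmetic(self):
        params = HDIGParams(theta=np.concatenate([[0.8], np.zeros(9)]),
                            shape=1000.0)
        mu, s2 = instantaneous_moments(params, np.full(9, 0.8))
        assert mu == pytest.approx(0.8)
        assert s2 * 1e6 == pytest.approx(512.0)  # ms^2
        big = HDIGParams(theta=params.theta, shape=1e12)
        assert instantaneous_moments(big, np.full(9, 0.8))[1] < 1e-12


class TestSpectrum:
    def test_white_case_flat_ratios(self):
        params = HDIGParams(theta=np.concatenate([[0.9], np.zeros(9)]),
                            shape=800.0)
        f, S = instantaneous_spectrum(params, 0.9)
        bp = band_powers(S, f)
        assert np.ptp(S) / S.mean() < 1e-9
        assert bp["lfn"] == pytest.approx(0.11 / 0.36, abs=1e-6)
        assert bp["hfn"] == pytest.approx(0.25 / 0.36, abs=1e-6)
        assert bp["lfhf"] == pytest.approx(0.44, abs=1e-6)

    def test_hf_pole_lands_in_hf_band(self):
        mu = 0.9
        ar = synth.ar_from_poles([(0.95, 0.25)], mu)
        theta = np.concatenate([[mu * (1 - ar.sum())], ar,
                                np.zeros(9 - ar.size)])
        params = HDIGParams(theta=theta, shape=800.0)
        f = np.arange(0.01, 0.4, 0.001)
        f, S = instantaneous_spectrum(params, mu, f_grid=f)
        peak = f[np.argmax(S)]
        assert 0.15 <= peak <= 0.40

    def test_integral_conserves_variance(self):
        mu = 0.9
        ar = synth.ar_from_poles([(0.9, 0.1), (0.8, 0.25)], mu)
        theta = np.concatenate([[mu * (1 - ar.sum())], ar,
                                np.zeros(9 - ar.size)])
        params = HDIGParams(theta=theta, shape=800.0)
        f = np.arange(0.002, 1 / (2 * mu), 0.002)
        f, S = instantaneous_spectrum(params, mu, f_grid=f)
        sigma2_ms2 = mu ** 3 / 800.0 * 1e6
        assert np.trapezoid(S, f) == pytest.approx(sigma2_ms2, rel=0.01)

    def test_unstable_ar_rejected(self):
        theta = np.concatenate([[0.9], [1.05], np.zeros(8)])
        params = HDIGParams(theta=theta, shape=800.0)
        with pytest.raises(SpectrumError):
            instantaneous_spectrum(params, 0.9)

    def test_band_powers_concentrated_and_grid_refinement(self):
        f = np.arange(0.01, 0.4 + 1e-12, 0.002)
        S = np.where((f >= 0.05) & (f <= 0.12), 100.0, 0.0)
        bp = band_powers(S, f)
        assert bp["lfn"] == pytest.approx(1.0)
        assert bp["hfn"] == pytest.approx(0.0)
        assert np.isnan(bp["lfhf"])
        # refinement: smooth AR spectrum integrates consistently
        mu = 0.9
        ar = synth.ar_from_poles([(0.9, 0.1)], mu)
        params = HDIGParams(
            theta=np.concatenate([[mu * (1 - ar.sum())], ar, np.zeros(7)]),
            shape=800.0)
        coarse_f, coarse_S = instantaneous_spectrum(params, mu)
        fine_f = np.arange(0.01, 0.4 + 1e-12, 1e-4)
        fine_f, fine_S = instantaneous_spectrum(params, mu, f_grid=fine_f)
        for key in ("vlf", "lf", "hf"):
            a = band_powers(coarse_S, coarse_f)[key]
            b = band_powers(fine_S, fine_f)[key]
            assert a == pytest.approx(b, rel=0.005)

    def test_hrv_from_fit_normalization_identity(self, renewal_fit):
        hrv = hrv_from_fit(renewal_fit)
        v = hrv.valid
        assert v.any()
        assert np.allclose(hrv.lfn[v] + hrv.hfn[v], 1.0, atol=1e-9)
        assert (hrv.vlf[v] >= 0).all() and (hrv.lf[v] >= 0).all()

    def test_welch_bridge_on_renewal_segment(self, renewal_beats, renewal_fit):
        hrv = hrv_from_fit(renewal_fit)
        v = hrv.valid
        lf_pp = float(np.nanmean(hrv.lf[v]))
        hf_pp = float(np.nanmean(hrv.hf[v]))
        t_rr = renewal_beats.times[1:]
        rr_ms = np.diff(renewal_beats.times) * 1e3
        grid = np.arange(t_rr[0], t_rr[-1], 0.25)
        x = CubicSpline(t_rr, rr_ms)(grid)  # conventional 4 Hz resampling
        f, P = sig.welch(x - x.mean(), fs=4.0, nperseg=1024)
        lf_w = np.trapezoid(P[(f >= 0.04) & (f <= 0.15)],
                            f[(f >= 0.04) & (f <= 0.15)])
        hf_w = np.trapezoid(P[(f >= 0.15) & (f <= 0.40)],
                            f[(f >= 0.15) & (f <= 0.40)])
        assert 0.8 <= lf_pp / lf_w <= 1.25
        assert 0.8 <= hf_pp / hf_w <= 1.25


class TestGof:
    def test_uniform_input_small_distance(self):
        rng = np.random.default_rng(0)
        n = 10_000
        z = np.sort(rng.random(n))
        up = np.arange(1, n + 1) / n - z
        lo = z - np.arange(0, n) / n
        assert max(up.max(), lo.max()) < 1.36 / 100

    def test_model_data_within_band_in_most_replicates(self):
        hits = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(3000 + r)
            rr = rng.wald(0.9, 800.0, size=350)
            beats = BeatSeries(times=np.concatenate([[0.0], np.cumsum(rr)]))
            fit = fit_hdig(beats, delta=0.5)
            hits += ks_rescaling_gof(beats, fit).within_95_band
        assert hits >= 9

    def test_misspecified_model_detected(self):
        rng = np.random.default_rng(8)
        # Poisson process (exponential intervals) vs near-deterministic model
        rr = rng.exponential(0.9, size=400)
        rr = np.clip(rr, 0.05, None)
        beats = BeatSeries(times=np.concatenate([[0.0], np.cumsum(rr)]))
        n = 200
        grid = np.linspace(10, beats.times[-1], n)
        theta = np.zeros((n, 10))
        theta[:, 0] = 0.9
        fit = HDIGFit(t=grid, theta=theta, shape=np.full(n, 1e5),
                      mu=np.full(n, 0.9), sigma2=np.full(n, 0.9 ** 3 / 1e5),
                      valid=np.ones(n, bool), converged=np.ones(n, bool),
                      order=9, delta=float(grid[1] - grid[0]),
                      window_s=90.0, forgetting=0.98)
        gof = ks_rescaling_gof(beats, fit)
        assert not gof.within_95_band

    def test_too_few_beats(self, renewal_fit):
        short = BeatSeries(times=np.arange(0, 9, 0.9))
        with pytest.raises(ValueError, match="insufficient"):
            ks_rescaling_gof(short, renewal_fit)
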