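import numpy as np
import pytest

from hypnohrv import markov, pphrv, synth
from hypnohrv.ecg import annotate_beats

N1, N2 = 1, 2


class TestGenHypnogram:
    def test_absorbing_identity_matrix(self):
        h = synth.gen_hypnogram(np.eye(5), 200, initial_stage=N2, seed=0)
        assert (h.stages == N2).all()

    def test_law_of_large_numbers_uniform(self):
        h = synth.gen_hypnogram(np.full((5, 5), 0.2), 100_000, seed=1)
        m = markov.estimate_matrix(markov.count_transitions(h))
        assert np.abs(m.probs - 0.2).max() < 0.01

    def test_seed_determinism(self):
        m = synth.matrix_from_self([0.8, 0.5, 0.9, 0.95, 0.9])
        a = synth.gen_hypnogram(m, 500, seed=3)
        b = synth.gen_hypnogram(m, 500, seed=3)
        c = synth.gen_hypnogram(m, 500, seed=4)
        assert np.array_equal(a.stages, b.stages)
        assert not np.array_equal(a.stages, c.stages)

    def test_non_stochastic_rejected(self):
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="stochastic"):
            synth.gen_hypnogram(bad, 10, seed=0)

    def test_hourly_matrix_switching(self):
        mats = np.stack([np.eye(5), np.full((5, 5), 0.2)])
        h = synth.gen_hypnogram(mats, 240, initial_stage=N2, seed=5)
        assert (h.stages[:120] == N2).all()
        assert len(np.unique(h.stages[120:])) > 1


class TestGenRr:
    def test_renewal_beat_count(self):
        sp = {i: synth.StageHDIG(mean_rr=1.0, theta_ar=np.zeros(1),
                                 shape=1000.0) for i in range(5)}
        h = synth.gen_hypnogram(np.full((5, 5), 0.2), 1200, seed=0)
        b = synth.gen_rr(h, sp, seed=1, t_end=600.0)
        sd = np.sqrt(600.0 * (1.0 / 1000.0))  # renewal counting approximation
        assert abs(b.n_beats - 600) <= 3 * sd + 2

    def test_seed_determinism(self):
        sp = synth.default_stage_params("CG")
        h = synth.gen_hypnogram(synth.default_transition_matrices("CG"),
                                600, seed=2)
        a = synth.gen_rr(h, sp, seed=9, t_end=300.0)
        b = synth.gen_rr(h, sp, seed=9, t_end=300.0)
        assert np.array_equal(a.times, b.times)

    def test_unstable_ar_named_stage(self):
        sp = {i: synth.StageHDIG(mean_rr=0.9, theta_ar=np.array([1.2]),
                                 shape=800.0) for i in range(5)}
        h = synth.gen_hypnogram(np.eye(5), 600, initial_stage=N2, seed=0)
        with pytest.raises(ValueError, match="N2"):
            synth.gen_rr(h, sp, seed=0, t_end=600.0)

    def test_hf_dominant_stage_recovered_by_pipeline(self):
        mean = 0.9
        ar = synth.ar_from_poles([(0.9, 0.25)], mean)  # HF pole only
        sp = {i: synth.StageHDIG(mean_rr=mean, theta_ar=ar, shape=3000.0)
              for i in range(5)}
        h = synth.gen_hypnogram(np.full((5, 5), 0.2), 1200, seed=3)
        b = synth.gen_rr(h, sp, seed=4, t_end=420.0)
        fit = pphrv.fit_hdig(b, delta=0.5)
        hrv = pphrv.hrv_from_fit(fit)
        v = hrv.valid
        assert np.nanmean(hrv.hfn[v]) > np.nanmean(hrv.lfn[v])


class TestGenEcg:
    def test_template_longer_than_min_rr_rejected(self):
        from hypnohrv.ecg import BeatSeries
        beats = BeatSeries(times=np.array([0.0, 0.05, 0.5]))
        with pytest.raises(ValueError, match="template"):
            synth.gen_ecg(beats)

    def test_noise_only_no_beats_detected(self):
        from hypnohrv.ecg import BeatSeries, detect_rpeaks
        rec = synth.gen_ecg(BeatSeries(times=np.empty(0)), noise_sd=0.05,
                            seed=0, duration_s=30.0)
        det = detect_rpeaks(rec)
        assert det.n_beats <= 3


class TestInjectArtifacts:
    def _clean_hour(self):
        sp = {i: synth.StageHDIG(mean_rr=0.9, theta_ar=np.zeros(1),
                                 shape=2000.0) for i in range(5)}
        h = synth.gen_hypnogram(np.full((5, 5), 0.2), 1200, seed=0)
        return synth.gen_rr(h, sp, seed=5, t_end=3600.0)

    def test_cleaner_recovers_injected_ectopics(self):
        beats = self._clean_hour()
        injected, truth = synth.inject_artifacts(beats, ectopic_rate=10,
                                                 missed_rate=0, seed=9)
        ann = annotate_beats(injected)
        ect = np.asarray(truth["ectopic_times"])
        assert ect.size >= 5
        hit = sum(any(a <= e < b for a, b in ann.mask) for e in ect)
        assert hit >= 0.9 * ect.size
        flagged = ann.times[ann.labels != "normal"]
        false = sum(np.abs(ect - t).min() > 2.0 for t in flagged)
        assert false / injected.n_beats < 0.01

    def test_zero_rates_identity(self):
        beats = self._clean_hour()
        out, truth = synth.inject_artifacts(beats, 0.0, 0.0, seed=1)
        assert np.array_equal(out.times, beats.times)
        assert truth == {"ectopic_times": [], "missed_times": []}

    def test_seed_determinism(self):
        beats = self._clean_hour()
        a, ta = synth.inject_artifacts(beats, 10, 5, seed=2)
        b, tb = synth.inject_artifacts(beats, 10, 5, seed=2)
        assert np.array_equal(a.times, b.times) and ta == tb

    def test_excessive_rates_rejected(self):
        beats = self._clean_hour()
        with pytest.raises(ValueError, match="too high"):
            synth.inject_artifacts(beats, 2000, 2000, seed=0)


class TestGenCohort:
    def test_default_sizes(self):
        cfg = synth.CohortConfig(hours=1, seed=0)
        cohort = synth.gen_cohort(cfg)
        groups = [s.hypnogram.group for s in cohort.subjects]
        assert len(groups) == 78
        assert groups.count("CG") == 24
        assert groups.count("iRBD") == 27
        assert groups.count("PD_RBD") == 27

    def test_empty_group_absent(self):
        cfg = synth.CohortConfig(group_sizes={"CG": 2, "iRBD": 2, "PD_RBD": 0},
                                 hours=1, seed=0)
        cohort = synth.gen_cohort(cfg)
        assert {s.hypnogram.group for s in cohort.subjects} == {"CG", "iRBD"}

    def test_byte_identical_outputs(self, tmp_path):
        cfg = synth.CohortConfig(group_sizes={"CG": 2, "iRBD": 1, "PD_RBD": 0},
                                 hours=1, seed=7)
        for d in ("a", "b"):
            synth.write_cohort(synth.gen_cohort(cfg), tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


class TestRoundTrips:
    def test_markov_estimator_converges_to_generator(self):
        truth = synth.default_transition_matrices("CG")[0]
        h = synth.gen_hypnogram(truth, 200_000, seed=6)
        m = markov.estimate_matrix(markov.count_transitions(h))
        assert np.nanmax(np.abs(m.probs - truth)[m.row_defined]) < 0.01

    def test_hdig_roundtrip_band_ordering(self):
        # LF-dominant generator parameters -> LF-dominant fitted indices
        mean = 0.9
        ar = synth.ar_from_poles([(0.92, 0.10)], mean)
        sp = {i: synth.StageHDIG(mean_rr=mean, theta_ar=ar, shape=3000.0)
              for i in range(5)}
        h = synth.gen_hypnogram(np.full((5, 5), 0.2), 1200, seed=8)
        b = synth.gen_rr(h, sp, seed=9, t_end=420.0)
        fit = pphrv.fit_hdig(b, delta=0.5)
        v = fit.valid
        assert abs(np.mean(fit.mu[v]) - mean) / mean < 0.02
        hrv = pphrv.hrv_from_fit(fit)
        assert np.nanmean(hrv.lfn[hrv.valid]) > np.nanmean(hrv.hfn[hrv.valid])
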