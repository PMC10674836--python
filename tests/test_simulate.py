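"""Rhythm and waveform generator contracts."""

import collections

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import irregular_af as ia
from irregular_af.simulate import RR_MAX, RR_MIN, RhythmParams


class TestRhythms:
    def test_noiseless_sinus_is_perfectly_regular(self):
        p = RhythmParams(mean_rr=1.0, rr_jitter_sd=0.0, resp_mod_amplitude=0.0)
        rr, types = ia.simulate_rr("sinus", p, 30.0)
        assert rr.n_intervals == 30
        assert np.all(rr.intervals == 1.0)
        assert set(types) == {"base"}

    def test_af_intervals_have_no_lag_structure(self):
        rr, _ = ia.simulate_rr("af", ia.default_params("af", seed=1), 60.0)
        iv = rr.intervals
        ac = np.corrcoef(iv[:-1], iv[1:])[0, 1]
        assert abs(ac) < 0.15
        assert iv.min() >= 0.4 and iv.max() <= 1.2

    def test_pac_lorenz_has_three_separated_groups(self):
        p = RhythmParams(
            mean_rr=1.0, coupling_fraction=0.65, pause_fraction=1.35,
            ectopy_period=3, seed=4,
        )
        rr, types = ia.simulate_rr("pac", p, 30.0)
        pts = ia.lorenz(rr).points
        # group points by the (interval type, next interval type) pair and
        # check pairwise group-centroid separations exceed 0.4 s
        groups = collections.defaultdict(list)
        for i in range(len(pts)):
            groups[(types[i], types[i + 1])].append(pts[i])
        cents = np.array([np.mean(g, axis=0) for g in groups.values()])
        assert len(cents) >= 3
        assert np.min(pdist(cents)) > 0.4

    def test_premature_interval_types_recur(self):
        for label in ("pac", "pvc"):
            p = ia.default_params(label, seed=2)
            if (p.ectopy_period or 99) > 5:
                p = ia.RhythmParams(
                    mean_rr=p.mean_rr, coupling_fraction=p.coupling_fraction,
                    pause_fraction=p.pause_fraction, ectopy_period=5, seed=2,
                )
            _, types = ia.simulate_rr(label, p, 30.0)
            counts = collections.Counter(types)
            assert counts["base"] >= 2
            assert counts["coupling"] >= 2
            assert counts["pause"] >= 2

    def test_avb_dropped_beats_double_the_interval(self):
        p = ia.default_params("avb", seed=3)
        rr, types = ia.simulate_rr("avb", p, 30.0)
        dropped = rr.intervals[[t == "dropped" for t in types]]
        base = rr.intervals[[t == "base" for t in types]]
        assert dropped.size >= 2
        assert np.allclose(dropped, 2 * p.mean_rr, atol=0.05)
        # Wenckebach 4:3 -> two base intervals per dropped one
        assert abs(base.size / dropped.size - (p.wenckebach_ratio[1] - 1)) <= 1

    def test_sss_pauses_exceed_two_seconds(self):
        rr, types = ia.simulate_rr("sss", ia.default_params("sss", seed=8), 60.0)
        pauses = rr.intervals[[t == "pause" for t in types]]
        assert pauses.size >= 1
        assert np.all(pauses >= 2.0)

    def test_physiology_bounds(self):
        for label in ("sinus", "af", "pac", "pvc", "avb"):
            for seed in range(5):
                rr, _ = ia.simulate_rr(label, ia.default_params(label, seed=seed), 30.0)
                assert rr.intervals.min() >= RR_MIN
                assert rr.intervals.max() <= RR_MAX

    def test_intervals_fit_within_duration(self):
        rr, _ = ia.simulate_rr("af", ia.default_params("af", seed=6), 30.0)
        assert rr.intervals.sum() <= 30.0

    def test_determinism(self):
        a, _ = ia.simulate_rr("af", ia.default_params("af", seed=11), 30.0)
        b, _ = ia.simulate_rr("af", ia.default_params("af", seed=11), 30.0)
        assert np.array_equal(a.intervals, b.intervals)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ia.InsufficientDuration):
            ia.simulate_rr("sinus", ia.default_params("sinus"), 5.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ia.ValidationError):
            RhythmParams(af_low=1.2, af_high=0.4)
        with pytest.raises(ia.ValidationError):
            RhythmParams(coupling_fraction=1.2)
        with pytest.raises(ia.ValidationError):
            RhythmParams(mean_rr=-1)


class TestWaveforms:
    def test_sample_count_and_annotations(self):
        p = RhythmParams(mean_rr=1.0, rr_jitter_sd=0.0, resp_mod_amplitude=0.0)
        rr, types = ia.simulate_rr("sinus", p, 30.0)
        rec = ia.simulate_ecg(rr, 512.0, interval_types=types, noise_sd=0.0)
        assert rec.samples.size == 15360
        assert rec.true_r_times.size == 30

    def test_noise_changes_samples_not_annotations(self):
        rr, types = ia.simulate_rr("sinus", ia.default_params("sinus", seed=5), 30.0)
        clean = ia.simulate_ecg(rr, 512.0, interval_types=types, noise_sd=0.0, seed=7)
        noisy = ia.simulate_ecg(rr, 512.0, interval_types=types, noise_sd=0.05, seed=7)
        assert np.array_equal(clean.true_r_times, noisy.true_r_times)
        assert not np.array_equal(clean.samples, noisy.samples)

    def test_af_records_carry_no_p_waves(self):
        # P bump sits ~200 ms before each R; in an AF record the samples
        # there should be near-isoelectric
        rr, types = ia.simulate_rr("af", ia.default_params("af", seed=5), 30.0)
        rec = ia.simulate_ecg(rr, 512.0, label="af", interval_types=types, noise_sd=0.0)
        fs = rec.sampling_rate
        for bt, prev in zip(rec.true_r_times[1:], rec.true_r_times[:-1]):
            if bt - prev < 0.6:
                continue  # T wave of previous beat may reach in
            i = int((bt - 0.20) * fs)
            assert abs(rec.samples[i]) < 0.06

    def test_morphology_overlap_rejected(self):
        rr = ia.RRSeries(np.full(40, 0.05), source_duration=30.0)
        with pytest.raises(ia.ValidationError, match="morphology overlap"):
            ia.simulate_ecg(rr, 512.0)


class TestCohorts:
    def test_cohort_is_reproducible(self):
        a = ia.simulate_cohort(2, 7)
        b = ia.simulate_cohort(2, 7)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra.record_id == rb.record_id
            assert np.array_equal(ra.samples, rb.samples)
            assert np.array_equal(ra.true_r_times, rb.true_r_times)

    def test_cohort_is_class_balanced(self):
        records = ia.simulate_rr_cohort(10, 1)
        counts = collections.Counter(lab for _, lab, _ in records)
        assert len(records) == 60
        assert all(v == 10 for v in counts.values())

    def test_af_count_rr_below_other_classes(self, rr_cohort):
        by_class = collections.defaultdict(list)
        for _, lab, rr in rr_cohort:
            by_class[lab].append(ia.count_rr(rr))
        af = np.median(by_class[ia.RhythmLabel.AF])
        others = [v for k, vs in by_class.items() if k is not ia.RhythmLabel.AF for v in vs]
        assert af < np.median(others)
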