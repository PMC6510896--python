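import dataclasses

import numpy as np
import pytest
from scipy import stats

import bloodspec as bs
from bloodspec.biomarkers import _local_maxima
from bloodspec.exceptions import DesignError, ParameterError


def _two_class_subject_dataset(axis, n_a, n_b, rng, effect=None):
    """Subject-level dataset (one spectrum per subject) of pure noise plus an
    optional (index, delta) effect in the second class."""
    rows, metas = [], []
    for i in range(n_a):
        rows.append(rng.normal(size=axis.size))
        metas.append(bs.SampleMeta(f"H{i}", "HC", "none_assigned", "serum", 0, 0))
    for i in range(n_b):
        y = rng.normal(size=axis.size)
        if effect is not None:
            j, delta = effect
            y[j] += delta
        rows.append(y)
        metas.append(bs.SampleMeta(f"C{i}", "CVID", "complications", "serum", 0, 0))
    return bs.SpectralDataset(axis, np.vstack(rows), metas)


class TestTTestTrack:
    def test_known_truth_argmax(self, fingerprint_axis):
        rng = np.random.default_rng(0)
        j_star = 100
        ds = _two_class_subject_dataset(fingerprint_axis, 30, 21, rng, effect=(j_star, 5.0))
        track = bs.ttest_track(ds)
        assert abs(int(np.argmax(track.score)) - j_star) <= 1
        assert track.score.size == fingerprint_axis.size
        assert track.signs[j_star] > 0  # effect was up in CVID

    def test_subject_level_n(self, default_study):
        """p-values come from n = subjects, not n = spectra: the track on the
        full replicate dataset equals the track on its subject averages."""
        ds, _ = default_study
        sub = bs.select_region(ds, (1000.0, 1100.0))
        direct = bs.ttest_track(sub)
        averaged = bs.ttest_track(bs.average_replicates(sub))
        assert np.allclose(direct.score, averaged.score)

    def test_single_class_rejected(self, fingerprint_axis):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(4, fingerprint_axis.size))
        metas = [bs.SampleMeta(f"S{i}", "HC", spot=0, replicate=0) for i in range(4)]
        ds = bs.SpectralDataset(fingerprint_axis, rows, metas)
        with pytest.raises(DesignError):
            bs.ttest_track(ds)

    def test_relabeling_invariance(self, fingerprint_axis):
        rng = np.random.default_rng(2)
        ds = _two_class_subject_dataset(fingerprint_axis, 10, 8, rng, effect=(50, 2.0))
        t1 = bs.ttest_track(ds)
        flipped = np.array(["x" if r.group == "HC" else "y" for r in ds.records])
        t2 = bs.ttest_track(ds, labels=flipped)
        assert np.allclose(t1.score, t2.score)


class TestFFSTrack:
    def test_counting_bounds(self, fingerprint_axis):
        rng = np.random.default_rng(3)
        ds = _two_class_subject_dataset(fingerprint_axis, 10, 8, rng, effect=(60, 3.0))
        track = bs.ffs_track(ds, rounds=25, seed=0)
        assert track.score.max() <= 25
        assert track.score.sum() <= 6 * 25

    def test_single_informative_wavenumber(self, fingerprint_axis):
        """With one strongly informative wavenumber, nearly every bootstrap
        round selects it."""
        rng = np.random.default_rng(4)
        ds = _two_class_subject_dataset(fingerprint_axis, 20, 15, rng, effect=(120, 6.0))
        track = bs.ffs_track(ds, rounds=100, seed=1)
        assert track.score[120] >= 95

    def test_null_has_no_consensus(self, fingerprint_axis):
        rng = np.random.default_rng(5)
        ds = _two_class_subject_dataset(fingerprint_axis, 15, 15, rng)
        track = bs.ffs_track(ds, rounds=50, seed=2)
        assert track.score.max() < 0.6 * 50

    def test_rounds_validation(self, tiny_dataset):
        with pytest.raises(ParameterError):
            bs.ffs_track(tiny_dataset, rounds=0)


class TestDetectPeaks:
    def test_six_separated_maxima(self, fingerprint_axis):
        score = np.zeros(fingerprint_axis.size)
        centers = [10, 50, 90, 130, 170, 210]
        for rank, j in enumerate(centers):
            score[j] = 10.0 - rank
        track = bs.FeatureScoreTrack("ttest", fingerprint_axis, score)
        panel = bs.detect_peaks(track)
        assert [p.wavenumber for p in panel.peaks] == [float(fingerprint_axis[j]) for j in centers]

    def test_close_pair_keeps_higher(self, fingerprint_axis):
        score = np.zeros(fingerprint_axis.size)
        score[100] = 5.0
        score[102] = 4.0  # 8 cm^-1 away
        track = bs.FeatureScoreTrack("ttest", fingerprint_axis, score)
        panel = bs.detect_peaks(track)
        assert panel.wavenumbers().tolist() == [float(fingerprint_axis[100])]
        assert len(panel.omitted) == 1

    def test_monotone_track_single_endpoint_peak(self, fingerprint_axis):
        track = bs.FeatureScoreTrack("ttest", fingerprint_axis,
                                     np.linspace(0, 1, fingerprint_axis.size))
        panel = bs.detect_peaks(track)
        assert panel.wavenumbers().tolist() == [float(fingerprint_axis[-1])]

    def test_plateau_takes_lowest_wavenumber(self):
        score = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        assert _local_maxima(score) == [1]

    def test_separation_invariant(self, fingerprint_axis):
        rng = np.random.default_rng(6)
        track = bs.FeatureScoreTrack("ttest", fingerprint_axis,
                                     np.abs(rng.normal(size=fingerprint_axis.size)))
        panel = bs.detect_peaks(track, k=6, min_separation=10.0)
        w = np.sort(panel.wavenumbers())
        assert len(panel.peaks) <= 6
        assert np.all(np.diff(w) > 10.0)


class TestMergePanels:
    def _panel(self, method, wns, scores):
        peaks = [bs.BiomarkerPeak(w, method, s, methods=(method,)) for w, s in zip(wns, scores)]
        return bs.BiomarkerPanel(peaks)

    def test_shared_wavenumber_corroborated(self):
        panels = [self._panel(m, [1034.0], [5.0]) for m in ("ttest", "cluster_vector", "ffs")]
        merged = bs.merge_panels(panels)
        assert len(merged.peaks) == 1
        assert set(merged.peaks[0].methods) == {"ttest", "cluster_vector", "ffs"}
        assert merged.peaks[0].corroborated

    def test_proximity_omissions_recorded(self):
        a = self._panel("ttest", [1034.0, 1100.0], [5.0, 4.0])
        b = self._panel("ffs", [1040.0, 1200.0], [50.0, 30.0])
        merged = bs.merge_panels([a, b])
        wns = merged.wavenumbers()
        assert len(merged.omitted) == 1  # 1040 or 1034 collapses into the other
        assert np.all(np.diff(np.sort(wns)) > 10.0)

    def test_empty_input(self):
        merged = bs.merge_panels([])
        assert merged.peaks == [] and merged.omitted == []


class TestSubjectIntensity:
    def test_identical_replicates_mean(self, fingerprint_axis):
        rows, metas = [], []
        for subj, grp, sub in (("H1", "HC", "none_assigned"), ("H2", "HC", "none_assigned"),
                               ("C1", "CVID", "complications"), ("C2", "CVID", "complication_free")):
            val = {"H1": 1.0, "H2": 2.0, "C1": 3.0, "C2": 5.0}[subj]
            for rep in range(1, 21):
                rows.append(np.full(fingerprint_axis.size, val))
                metas.append(bs.SampleMeta(subj, grp, sub, "serum", 1 + rep % 2, 1 + rep // 2))
        ds = bs.SpectralDataset(fingerprint_axis, np.vstack(rows), metas)
        panel = bs.BiomarkerPanel([bs.BiomarkerPeak(1034.0, "ttest", 1.0)])
        out = bs.subject_intensity_analysis(ds, panel, contrasts=[("HC", "CVID")])
        comp = out[0]
        assert comp.mean_a == pytest.approx(1.5)  # HC subject means 1, 2
        assert comp.mean_b == pytest.approx(4.0)  # CVID subject means 3, 5
        assert comp.n_a == 2 and comp.n_b == 2
        assert comp.direction == "up_in_CVID"

    def test_implanted_collagen_band_detected(self, default_study):
        """The +delta effect at 1034 cm^-1 shows up as a significant
        up_in_CVID difference at the generator's default n and noise."""
        ds, _ = default_study
        pre = bs.apply_recipe(ds, bs.PreprocessRecipe(variant="A"))
        panel = bs.BiomarkerPanel([bs.BiomarkerPeak(1034.0, "ttest", 1.0)])
        out = bs.subject_intensity_analysis(pre, panel)
        hc_cvid = next(c for c in out if (c.group_a, c.group_b) == ("HC", "CVID"))
        assert hc_cvid.direction == "up_in_CVID"
        assert hc_cvid.p_value < 0.05
        assert hc_cvid.n_a == 30 and hc_cvid.n_b == 21
        lo, hi = hc_cvid.ci95
        assert lo <= hc_cvid.mean_a - hc_cvid.mean_b <= hi

    def test_unknown_group_label(self, default_study):
        ds, _ = default_study
        panel = bs.BiomarkerPanel([bs.BiomarkerPeak(1034.0, "ttest", 1.0)])
        with pytest.raises(DesignError):
            bs.subject_intensity_analysis(ds, panel, contrasts=[("HC", "sick")])


class TestPower:
    def test_monotone_in_effect_size(self):
        ns = [bs.power_min_n(0.0, 1.0, d, 1.0).n_b for d in (0.5, 1.0, 2.0)]
        assert ns[0] >= ns[1] >= ns[2]

    def test_equal_means_rejected(self):
        with pytest.raises(ParameterError):
            bs.power_min_n(1.0, 1.0, 1.0, 2.0)

    def test_minimality_boundary(self):
        r = bs.power_min_n(0.0, 1.0, 1.0, 1.0)
        assert r.achieved_power >= 0.80
        from statsmodels.stats.power import TTestIndPower
        below = TTestIndPower().power(effect_size=1.0, nobs1=r.n_a - 1, ratio=1.0, alpha=0.05)
        assert below < 0.80

    def test_unequal_ratio(self):
        r = bs.power_min_n(0.0, 1.0, 0.8, 1.0, ratio=30 / 21)
        assert r.n_a > r.n_b
        assert r.achieved_power >= 0.80
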