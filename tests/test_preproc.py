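"""Optical preprocessing: OD, CV quality control, SSR, MBLL, ROIs."""

import numpy as np
import pytest

import spafnirs as sp
from spafnirs.preproc import (
    MBLLParams,
    average_rois,
    ChannelQuality,
    channel_quality_cv,
    intensity_to_od,
    od_to_concentration,
    preprocess_subject,
    short_separation_regress,
)
from spafnirs.registry import default_montage
from spafnirs.synthetic import forward_mbll, generate_dyad

from conftest import small_config


class TestIntensityToOD:
    def test_constant_intensity_gives_zero(self):
        assert np.allclose(intensity_to_od(np.full(100, 3.7)), 0.0)

    def test_hand_computed_example(self):
        od = intensity_to_od(np.array([1.0, 2.0, 4.0]))
        expected = -np.log(np.array([1.0, 2.0, 4.0]) / (7.0 / 3.0))
        assert np.allclose(od, expected)

    def test_scale_invariance(self, rng):
        I = rng.uniform(0.5, 2.0, 200)
        assert np.allclose(intensity_to_od(I), intensity_to_od(17.3 * I))

    def test_nonpositive_sample_flagged(self):
        with pytest.raises(ValueError, match="nonpositive"):
            intensity_to_od(np.array([1.0, 0.0, 2.0]))


class TestChannelQualityCV:
    def test_constant_series_included(self):
        cv, inc = channel_quality_cv(np.full(50, 2.0))
        assert cv == 0.0 and inc

    def test_two_point_example(self):
        # sd([9,11]) = sqrt(2), mean 10 -> CV = 14.14% > 7.5 -> excluded
        cv, inc = channel_quality_cv(np.array([9.0, 11.0]))
        assert cv == pytest.approx(100 * np.sqrt(2) / 10)
        assert not inc

    def test_threshold_is_strictly_above(self, rng):
        # exclusion triggers only *above* the threshold: a series whose CV
        # equals the threshold exactly stays included
        I = rng.uniform(0.9, 1.1, 100)
        cv, _ = channel_quality_cv(I)
        _, inc_at = channel_quality_cv(I, threshold_percent=cv)
        _, inc_below = channel_quality_cv(I, threshold_percent=np.nextafter(cv, 0))
        assert inc_at and not inc_below

    def test_monotone_in_threshold(self, rng):
        I = rng.uniform(0.5, 1.5, 100)
        included = [channel_quality_cv(I, th)[1] for th in (1, 5, 10, 50)]
        # once included at some threshold, included at every higher one
        assert included == sorted(included)


class TestShortSeparationRegression:
    def test_proportional_short_fully_removed(self, rng):
        short = rng.standard_normal(500)
        corrected, alpha = short_separation_regress(2.0 * short, short)
        assert alpha == pytest.approx(2.0)
        assert np.allclose(corrected - corrected.mean(), 0.0, atol=1e-12)

    def test_alpha_recovery_with_orthogonal_deep(self, rng):
        # orthogonalise the mean-centred series, since the regression
        # operates on centred data
        deep = rng.standard_normal(2000)
        deep -= deep.mean()
        short = rng.standard_normal(2000)
        short -= short.mean()
        short -= short @ deep / (deep @ deep) * deep
        long = deep + 0.5 * short
        corrected, alpha = short_separation_regress(long, short)
        assert alpha == pytest.approx(0.5, abs=1e-9)
        assert np.corrcoef(corrected, deep)[0, 1] > 0.99
        # cross-check alpha with the least-squares oracle
        ls = np.linalg.lstsq(
            np.column_stack([short - short.mean()]), long - long.mean(), rcond=None
        )[0][0]
        assert alpha == pytest.approx(ls)

    def test_constant_short_returns_long_unchanged(self, rng):
        long = rng.standard_normal(100)
        corrected, alpha = short_separation_regress(long, np.full(100, 5.0))
        assert alpha == 0.0
        assert np.array_equal(corrected, long)

    def test_corrected_orthogonal_to_short(self, rng):
        long = rng.standard_normal(300)
        short = rng.standard_normal(300)
        corrected, _ = short_separation_regress(long, short)
        assert (corrected - corrected.mean()) @ (short - short.mean()) == pytest.approx(
            0.0, abs=1e-8
        )


class TestMBLLInversion:
    def test_zero_od_gives_zero_concentration(self):
        conc = od_to_concentration(np.zeros((2, 30)))
        assert np.allclose(conc, 0.0)

    def test_round_trip_recovers_concentrations(self, rng):
        dc = rng.normal(0, 0.5, size=(400, 2))  # uM
        I = forward_mbll(dc, distance_cm=3.0, dpf=6.0, baseline_intensity=1.0)
        od = np.stack([intensity_to_od(I[w]) for w in range(2)])
        # re-reference the OD from the temporal mean to the true baseline:
        # -ln(I/I0) = -ln(I/mean) - ln(mean/I0)
        od_baseline = od - np.log(I.mean(axis=1) / 1.0)[:, None]
        rec = od_to_concentration(od_baseline, MBLLParams(distance_cm=3.0))
        assert np.allclose(rec[:, :2], dc, rtol=1e-6, atol=1e-9)

    def test_thb_additivity_exact(self, rng):
        od = rng.standard_normal((2, 100)) * 0.01
        conc = od_to_concentration(od)
        assert np.array_equal(conc[:, 2], conc[:, 0] + conc[:, 1])


class TestROIAveraging:
    def _quality(self, montage, excluded=()):
        return [
            ChannelQuality(c.index, (1.0, 1.0), c.index not in excluded)
            for c in montage.long_channels
        ]

    def test_identical_channels_pass_through(self, rng):
        montage = default_montage()
        v = rng.standard_normal((50, 3))
        conc = {c.index: v.copy() for c in montage.long_channels}
        out = average_rois(conc, self._quality(montage), montage, "corrected")
        assert len(out) == 9
        for series in out.values():
            assert np.allclose(series, v[:, 0]) or np.allclose(
                series, v[:, 1]
            ) or np.allclose(series, v[:, 2])

    def test_exclusion_changes_mean(self, rng):
        montage = default_montage()
        conc = {c.index: rng.standard_normal((30, 3)) for c in montage.long_channels}
        out = average_rois(conc, self._quality(montage, excluded={0}), montage, "raw")
        left_members = [c.index for c in montage.roi_channels("left") if c.index != 0]
        direct = np.mean([conc[i][:, 0] for i in left_members], axis=0)
        assert np.allclose(out["O2Hb_left_raw"], direct)

    def test_empty_roi_omitted(self, rng):
        montage = default_montage()
        conc = {c.index: rng.standard_normal((30, 3)) for c in montage.long_channels}
        left = {c.index for c in montage.roi_channels("left")}
        out = average_rois(conc, self._quality(montage, excluded=left), montage, "raw")
        assert not any(k.endswith("_left_raw") for k in out)
        assert any(k.endswith("_right_raw") for k in out)


class TestSessionChain:
    def test_full_chain_yields_29_signals_and_4686_samples(self, default_pre):
        for subj in default_pre.signals:
            assert len(subj) == 29
        hr = default_pre.signals[0]["O2Hb_left"]
        seg = default_pre.segments["eyes_closed"]
        n = ((hr.time >= seg[0]) & (hr.time < seg[1])).sum()
        assert n == 4686  # 600 s at 7.81 Hz
        assert hr.time[0] >= 60.0  # prebaseline discarded
        assert default_pre.segments["eye_contact"] == (660.0, 1260.0)

    def test_ssr_improves_deep_recovery(self, rng):
        # synthetic subject with known deep and scalp components: the
        # corrected ROI series must track the deep signal better than the
        # uncorrected one
        montage = default_montage()
        n = 2000
        deep = rng.standard_normal(n)
        scalp = rng.standard_normal(n)
        intensity = np.empty((24, 2, n))
        for row, ch in enumerate(montage.channels):
            if ch.kind == "long":
                conc = np.column_stack([deep + 0.8 * scalp, -0.3 * deep + 0.8 * scalp])
            else:
                conc = np.column_stack([scalp, scalp])
            intensity[row] = forward_mbll(
                conc * 0.05, distance_cm=ch.distance_cm, baseline_intensity=1.0
            )
        signals, quality = preprocess_subject(np.arange(n) / 7.81, intensity, montage)
        assert all(q.included for q in quality)
        r_corr = abs(np.corrcoef(signals["O2Hb_both"], deep)[0, 1])
        r_raw = abs(np.corrcoef(signals["O2Hb_both_raw"], deep)[0, 1])
        assert r_corr > r_raw

    def test_short_series_rejected(self):
        session = generate_dyad(small_config(seed=2))
        session.subjects[0].physio["HR"] = (
            session.subjects[0].physio["HR"][0][:100],
            session.subjects[0].physio["HR"][1][:100],
        )
        with pytest.raises(ValueError, match="HR"):
            sp.synchronize_and_segment(session)
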