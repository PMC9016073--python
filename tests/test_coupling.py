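"""Condition statistics: ART ANOVA, FDR, surrogate pairs, rank-sum."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spafnirs as sp
from spafnirs.coupling import (
    art_anova,
    compare_true_vs_surrogate,
    condition_average,
    corpus_condition_records,
    fdr_adjust,
    surrogate_pair_ensemble,
)
from spafnirs.registry import BANDS
from spafnirs.synthetic import LatentCouplingSpec, generate_corpus
from spafnirs.wtc import BandCoherenceSeries

from conftest import small_config

SEGMENTS = {"eyes_closed": (0.0, 10.0), "eye_contact": (10.0, 20.0)}


def _series(values, rate=1.0):
    t = np.arange(len(values)) / rate
    return BandCoherenceSeries("HR", BANDS["LF1"], t, np.asarray(values, float), rate)


class TestConditionAverage:
    def test_step_series_splits_into_conditions(self):
        v = [0.2] * 10 + [0.8] * 10
        avg = condition_average(_series(v), SEGMENTS)
        assert avg == {"eyes_closed": 0.2, "eye_contact": 0.8}

    def test_constant_series(self):
        avg = condition_average(_series([0.5] * 20), SEGMENTS)
        assert avg["eyes_closed"] == avg["eye_contact"] == 0.5

    def test_masked_mean_matches_oracle(self, rng):
        v = rng.uniform(0, 1, 20)
        v[rng.choice(20, 6, replace=False)] = np.nan
        avg = condition_average(_series(v), SEGMENTS)
        ec = v[:10]
        assert avg["eyes_closed"] == pytest.approx(np.nanmean(ec))

    def test_fully_masked_segment_missing(self):
        v = [np.nan] * 10 + [0.4] * 10
        avg = condition_average(_series(v), SEGMENTS)
        assert np.isnan(avg["eyes_closed"]) and avg["eye_contact"] == 0.4


def _null_frame(rng, n_dyads=24):
    rows = []
    for d in range(n_dyads):
        g = "familiar" if d < n_dyads // 2 else "unfamiliar"
        for c in ("eyes_closed", "eye_contact"):
            rows.append(
                {"dyad_id": d, "group": g, "condition": c, "coherence": rng.normal()}
            )
    return pd.DataFrame(rows)


class TestARTAnova:
    def test_strong_condition_effect_detected_others_null(self, rng):
        hits = 0
        for _ in range(20):
            df = _null_frame(rng)
            df.loc[df.condition == "eye_contact", "coherence"] += 5.0
            res = art_anova(df)
            hits += res["condition"][1] < 0.001
        assert hits == 20

    def test_invariance_under_affine_transform(self, rng):
        # alignment subtracts cell means before ranking, so the procedure
        # is exactly invariant under positive affine rescalings of the
        # response (nonlinear monotone maps change the alignment itself)
        df = _null_frame(rng)
        res1 = art_anova(df)
        df2 = df.copy()
        df2["coherence"] = 3.7 * df2["coherence"] + 11.0
        res2 = art_anova(df2)
        for effect in res1:
            assert res1[effect][0] == pytest.approx(res2[effect][0])

    def test_identical_responses_give_null_result(self):
        df = _null_frame(np.random.default_rng(0))
        df["coherence"] = 0.5
        res = art_anova(df)
        assert res["condition"] == (0.0, 1.0)

    def test_single_group_agrees_with_paired_rank_oracle(self, rng):
        # with the group factor collapsed, the condition decision must
        # match a Wilcoxon signed-rank test on clear effect / clear null
        agree = 0
        for k in range(50):
            df = _null_frame(rng, n_dyads=16)
            df["group"] = "familiar"
            if k % 2 == 0:  # strong effect half the time
                df.loc[df.condition == "eye_contact", "coherence"] += 4.0
            res = art_anova(df)
            wide = df.pivot_table(
                index="dyad_id", columns="condition", values="coherence"
            )
            w_p = stats.wilcoxon(wide["eye_contact"], wide["eyes_closed"]).pvalue
            agree += (res["condition"][1] < 0.05) == (w_p < 0.05)
        assert agree >= 48


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_all_equal_stay_equal(self):
        adj = fdr_adjust(np.full(7, 0.2))
        assert np.allclose(adj, 0.2)

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_direct_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, 25)
        m = p.size
        order = np.argsort(p)
        stepped = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        assert np.allclose(fdr_adjust(p), oracle)


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        U, p = compare_true_vs_surrogate([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_disjoint_samples_exact_enumeration(self):
        U, p = compare_true_vs_surrogate([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_statistic_matches_brute_force_count(self, rng):
        for _ in range(100):
            x = rng.integers(0, 6, rng.integers(2, 8)).astype(float)
            y = rng.integers(0, 6, rng.integers(2, 8)).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            U, _ = compare_true_vs_surrogate(x, y)
            brute = sum(
                1.0 if xi > yi else 0.5 if xi == yi else 0.0
                for xi in x
                for yi in y
            )
            assert U == pytest.approx(brute)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_true_vs_surrogate([], [1.0])


@pytest.fixture(scope="module")
def tiny_corpus():
    specs = (LatentCouplingSpec("HR", BANDS["LF1"], 1.0, 0.2),)
    sessions = generate_corpus(4, small_config(coupling_spec=specs), seed=77)
    return [sp.synchronize_and_segment(s) for s in sessions]


class TestSurrogateEnsemble:
    def test_ensemble_size_and_reproducibility(self, tiny_corpus):
        surr = surrogate_pair_ensemble(
            tiny_corpus, n_surrogates=6, seed=3, signal_types=("HR",)
        )
        # one row per surrogate x band x condition for the one signal
        assert (surr.groupby(["band", "condition"]).size() == 6).all()
        surr2 = surrogate_pair_ensemble(
            tiny_corpus, n_surrogates=6, seed=3, signal_types=("HR",)
        )
        pd.testing.assert_frame_equal(surr, surr2)

    def test_true_pairs_dominate_surrogates_when_coupled(self, tiny_corpus):
        # coupling exists only within true dyads, so true coherence must
        # stochastically dominate the shuffled-pair ensemble
        true = corpus_condition_records(tiny_corpus, signal_types=("HR",))
        surr = surrogate_pair_ensemble(
            tiny_corpus, n_surrogates=20, seed=5, signal_types=("HR",)
        )
        tv = true[(true.band == "LF1")]["coherence"]
        sv = surr[(surr.band == "LF1")]["coherence"]
        U, p = compare_true_vs_surrogate(tv.to_numpy(), sv.to_numpy())
        assert np.median(tv) > np.median(sv)
        assert p < 0.01

    def test_single_dyad_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match=">= 2"):
            surrogate_pair_ensemble(tiny_corpus[:1], n_surrogates=2, seed=0)
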