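"""Agreement statistics, zonal error grid, subgroups and classification."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pulsebp.evaluation import (
    DEFAULT_ZONE_FRACTIONS,
    PairedMeasurements,
    ZONES,
    bland_altman,
    classify_hypertension,
    delong_auc_ci,
    error_grid,
    spearman_corr,
    subgroup_errors,
    zone_boundaries,
    zone_of,
)


def _pairs(ref_s, pred_s, ref_d=None, pred_d=None):
    ref_s = np.asarray(ref_s, float)
    pred_s = np.asarray(pred_s, float)
    ref_d = np.asarray(ref_d, float) if ref_d is not None else ref_s - 45.0
    pred_d = np.asarray(pred_d, float) if pred_d is not None else pred_s - 45.0
    return PairedMeasurements(ref_sbp=ref_s, ref_dbp=ref_d,
                              pred_sbp=pred_s, pred_dbp=pred_d)


class TestBlandAltman:
    def test_hand_computed_differences(self):
        """Differences (2, -3, 1): bias 0 and sd sqrt(7)."""
        p = _pairs([100, 100, 100], [102, 97, 101])
        rep = bland_altman(p, "sbp")
        assert rep.bias == pytest.approx(0.0)
        assert rep.sd == pytest.approx(math.sqrt(7.0))

    def test_identical_methods_degenerate(self):
        rep = bland_altman(_pairs([110, 120, 130], [110, 120, 130]), "sbp")
        assert rep.bias == 0.0 and rep.sd == 0.0
        assert math.isnan(rep.t_p)
        assert rep.ci_low == rep.ci_high == 0.0

    def test_constant_offset(self):
        rep = bland_altman(_pairs([110, 120, 130], [115, 125, 135]), "sbp")
        assert rep.bias == pytest.approx(5.0)
        assert rep.sd == 0.0
        assert rep.loa_low == rep.loa_high == pytest.approx(5.0)

    def test_permutation_invariance(self, rng):
        ref = rng.uniform(100, 160, 25)
        pred = ref + rng.normal(0, 3, 25)
        a = bland_altman(_pairs(ref, pred), "sbp")
        perm = rng.permutation(25)
        b = bland_altman(_pairs(ref[perm], pred[perm]), "sbp")
        for k in ("bias", "sd", "ci_low", "ci_high", "t_p"):
            assert getattr(a, k) == pytest.approx(getattr(b, k))

    def test_loa_contain_95pct_of_differences(self, rng):
        ref = rng.uniform(100, 160, 400)
        pred = ref + rng.normal(0.0, 2.0, 400)
        rep = bland_altman(_pairs(ref, pred), "sbp")
        d = np.asarray(rep.diffs)
        frac = np.mean((d >= rep.loa_low) & (d <= rep.loa_high))
        assert frac >= 0.93  # binomial tolerance around 95%

    def test_ci_contains_bias(self, rng):
        ref = rng.uniform(100, 160, 50)
        rep = bland_altman(_pairs(ref, ref + rng.normal(1, 2, 50)), "sbp")
        assert rep.ci_low <= rep.bias <= rep.ci_high


class TestSpearman:
    def test_monotone_map_gives_unity(self):
        ref = np.array([100, 110, 125, 140, 160], float)
        r, _ = spearman_corr(_pairs(ref, np.exp(ref / 50.0) + 40))
        assert r == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        ref = np.array([100, 110, 125, 140, 160], float)
        r, _ = spearman_corr(_pairs(ref, ref[::-1]))
        assert r == pytest.approx(-1.0)

    def test_matches_rank_formula_on_fixture(self, rng):
        ref = rng.uniform(90, 175, 10)
        pred = ref + rng.normal(0, 8, 10)
        r, _ = spearman_corr(_pairs(ref, pred))
        # independent route: Pearson correlation of mid-ranks
        rr = stats.rankdata(ref)
        rp = stats.rankdata(pred)
        brute = float(np.corrcoef(rr, rp)[0, 1])
        assert r == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_reported_null(self):
        r, p = spearman_corr(_pairs([120, 120, 120], [118, 121, 119]))
        assert math.isnan(r) and math.isnan(p)


class TestZoneGrid:
    def test_paper_worked_example_boundaries_for_140(self):
        b = zone_boundaries(140.0)
        assert b["A"] == (128.3, 151.7)
        assert b["B"] == (116.7, 163.3)
        assert b["C"] == (93.3, 186.7)
        assert b["D"] == (81.7, 198.3)

    def test_boundaries_symmetric_about_reference(self):
        b = zone_boundaries(120.0)
        for lo, hi in b.values():
            assert hi - 120.0 == pytest.approx(120.0 - lo, abs=0.05 + 1e-9)

    @pytest.mark.parametrize(
        "ref,pred,zone",
        [
            (140.0, 140.0, "A"),
            (140.0, 100.0, "C"),   # worked example: C spans 93.3-116.7
            (140.0, 80.0, "E"),    # below 81.7 -> extreme error
            (140.0, 128.35, "A"),  # just inside 140 * 11/12 = 128.33...
            (140.0, 128.30, "B"),  # just outside
            (140.0, 163.4, "C"),
        ],
    )
    def test_zone_assignment(self, ref, pred, zone):
        assert zone_of(ref, pred) == zone

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            zone_of(0.0, 100.0)

    @given(
        ref=st.floats(60, 220),
        d1=st.floats(0, 1.2),
        d2=st.floats(0, 1.2),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_zone_monotone_and_symmetric(self, ref, d1, d2, sign):
        """Larger |deviation| never yields an earlier zone; the sign of
        the deviation is irrelevant."""
        lo_d, hi_d = sorted([d1, d2])
        z_lo = zone_of(ref, ref * (1 + sign * lo_d))
        z_hi = zone_of(ref, ref * (1 + sign * hi_d))
        assert ZONES.index(z_lo) <= ZONES.index(z_hi)
        assert zone_of(ref, ref * (1 + hi_d)) == zone_of(ref, ref * (1 - hi_d))

    def test_perfect_predictions_all_zone_a(self, rng):
        ref = rng.uniform(90, 175, 40)
        res = error_grid(_pairs(ref, ref), "sbp")
        assert res.percentages["A"] == 100.0

    def test_one_pair_engineered_per_zone(self):
        ref = np.full(5, 140.0)
        pred = np.array([140.0, 155.0, 170.0, 190.0, 210.0])
        res = error_grid(_pairs(ref, pred), "sbp")
        assert res.labels == ["A", "B", "C", "D", "E"]
        assert all(res.counts[z] == 1 for z in ZONES)

    def test_percentages_sum_to_100(self, rng):
        ref = rng.uniform(90, 175, 33)
        pred = ref * rng.uniform(0.5, 1.5, 33)
        res = error_grid(_pairs(ref, pred), "sbp")
        assert sum(res.percentages.values()) == pytest.approx(100.0)


class TestSubgroups:
    def test_identical_methods_give_zero_errors(self):
        ref = np.array([100, 120, 150, 125], float)
        refd = np.array([65, 78, 95, 80], float)
        df = subgroup_errors(_pairs(ref, ref, refd, refd))
        all_rows = df[df.group == "all"]
        assert (all_rows["mean"] == 0).all()
        assert (all_rows["median"] == 0).all()
        assert all_rows["wilcoxon_p"].isna().all()

    def test_hand_computed_subgroup_statistics(self):
        """Errors (1..5) in one subgroup: mean 3, median 3, IQR [2, 4]."""
        ref = np.full(5, 120.0)
        refd = np.full(5, 80.0)
        pred = ref + np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = subgroup_errors(_pairs(ref, pred, refd, refd))
        row = df[(df.group == "110/70-140/90") & (df.target == "sbp")].iloc[0]
        assert row["mean"] == pytest.approx(3.0)
        assert row["median"] == pytest.approx(3.0)
        assert (row["q25"], row["q75"]) == (2.0, 4.0)
        assert row["n"] == 5

    def test_subgroup_sizes_partition_cohort(self, rng):
        ref_s = rng.uniform(90, 175, 60)
        ref_d = rng.uniform(55, 105, 60)
        df = subgroup_errors(_pairs(ref_s, ref_s + 1, ref_d, ref_d + 1))
        sizes = df[(df.group != "all") & (df.target == "sbp")]["n"]
        assert sizes.sum() == 60

    def test_empty_subgroup_warned_and_null(self):
        ref = np.array([120.0, 125.0, 130.0])
        refd = np.array([80.0, 82.0, 85.0])
        with pytest.warns(UserWarning, match="empty subgroup"):
            df = subgroup_errors(_pairs(ref, ref + 1, refd, refd + 1))
        low = df[(df.group == "<110/70") & (df.target == "sbp")].iloc[0]
        assert low["n"] == 0 and math.isnan(low["mean"])


class TestClassification:
    def test_perfect_agreement_scores_100(self):
        ref_s = np.array([120.0, 150.0, 135.0, 160.0, 110.0])
        ref_d = np.array([75.0, 95.0, 88.0, 100.0, 70.0])
        rep = classify_hypertension(
            _pairs(ref_s, ref_s, ref_d, ref_d), "hypertension"
        )
        assert rep.sensitivity_pct == 100.0
        assert rep.specificity_pct == 100.0
        assert rep.accuracy_pct == 100.0

    def test_confusion_table_arithmetic(self):
        """TP=8, FN=2, TN=85, FP=5 -> sensitivity 80%, specificity 94.4%."""
        ref_s = np.r_[np.full(10, 150.0), np.full(90, 120.0)]
        pred_s = np.r_[np.full(8, 150.0), np.full(2, 120.0),
                       np.full(85, 120.0), np.full(5, 150.0)]
        ref_d = np.full(100, 80.0)
        rep = classify_hypertension(
            _pairs(ref_s, pred_s, ref_d, ref_d), "hypertension"
        )
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (8, 2, 85, 5)
        assert rep.sensitivity_pct == pytest.approx(80.0)
        assert rep.specificity_pct == pytest.approx(100 * 85 / 90, abs=0.05)
        assert rep.accuracy_pct == pytest.approx(93.0)

    def test_prehypertension_uses_130_85(self):
        ref_s = np.array([132.0, 128.0, 120.0])
        ref_d = np.array([80.0, 86.0, 80.0])
        rep = classify_hypertension(
            _pairs(ref_s, ref_s, ref_d, ref_d), "prehypertension"
        )
        assert (rep.tp, rep.tn) == (2, 1)

    def test_single_class_reference_warns(self):
        ref_s = np.full(5, 120.0)
        ref_d = np.full(5, 75.0)
        with pytest.warns(UserWarning, match="single-class"):
            rep = classify_hypertension(
                _pairs(ref_s, ref_s, ref_d, ref_d), "hypertension"
            )
        assert math.isnan(rep.sensitivity_pct)

    def test_degenerate_score_gives_auc_half(self):
        scores = np.zeros(10)
        labels = np.r_[np.ones(4), np.zeros(6)].astype(bool)
        auc, _, _ = delong_auc_ci(scores, labels)
        assert auc == pytest.approx(0.5)

    def test_delong_matches_proc_reference_values(self):
        """Frozen oracle: same fixture evaluated with R pROC
        (ci.auc method='delong') gives auc 0.7916666667,
        CI (0.6076419170, 0.9756914163), variance 0.008815689575."""
        scores = np.array([
            1.244, 0.168, 1.6, 1.752, -0.561, -0.042, 1.102, 0.747, 0.987,
            0.318, 1.704, 1.622, -0.532, 0.186, 0.093, 0.175, 0.697, 0.179,
            0.543, 0.054, 0.231, 0.505, -1.166, -0.256, -0.376, -0.511,
            -0.22, 1.196, -0.693, 0.775,
        ])
        labels = np.r_[np.ones(12), np.zeros(18)].astype(bool)
        auc, se, (lo, hi) = delong_auc_ci(scores, labels)
        assert auc == pytest.approx(0.7916666667, abs=1e-9)
        assert se**2 == pytest.approx(0.008815689575, abs=1e-10)
        assert lo == pytest.approx(0.6076419170, abs=1e-9)
        assert hi == pytest.approx(0.9756914163, abs=1e-9)
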