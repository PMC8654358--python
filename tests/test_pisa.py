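"""Pooling, fold changes, %CV filter, SAM permutation test, window prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import solvshift as sv
from solvshift.curves import SigmoidParams, melt_model, soluble_fraction
from solvshift.pisa import (
    WINDOW2_VARIANT,
    WINDOWS,
    cv_filter,
    pisa_fold_changes,
    pool_channels,
    predict_window_fc,
    sam_permutation_test,
)
from solvshift.simulate import shifted_params


class TestWindows:
    def test_default_windows_match_design(self):
        np.testing.assert_allclose(WINDOWS[1].gradients, np.arange(0, 22, 3))
        np.testing.assert_allclose(WINDOWS[2].gradients, np.arange(9, 20, 1.5))
        np.testing.assert_allclose(WINDOWS[3].gradients, np.arange(11, 20, 1.25))
        np.testing.assert_allclose(WINDOWS[4].gradients, np.arange(14.25, 20, 0.75))
        np.testing.assert_allclose(WINDOW2_VARIANT.gradients, np.arange(9, 19, 1.375))

    def test_rejects_degenerate_windows(self):
        with pytest.raises(ValueError):
            sv.WindowDesign((5.0,))
        with pytest.raises(ValueError):
            sv.WindowDesign((5.0, 5.0))


class TestPooling:
    def test_mean(self):
        assert pool_channels([1.0, 0.8, 0.2, 0.0]) == pytest.approx(0.5)

    def test_order_invariant(self):
        vals = np.random.default_rng(0).uniform(0, 1, 8)
        assert pool_channels(vals) == pool_channels(vals[::-1])

    def test_missing_makes_pool_missing(self):
        assert math.isnan(pool_channels([1.0, np.nan, 0.2]))

    def test_matches_trapezoid_auc(self):
        """Equal-volume pooling approximates the curve AUC per unit width
        when the transition is sampled by the window."""
        p = SigmoidParams(0, 130, 10)  # transition at 13 %AEA, mid-window
        w = WINDOWS[2]
        pooled = pool_channels(melt_model(np.asarray(w.gradients), p), w)
        fine = np.linspace(w.gradients[0], w.gradients[-1], 2001)
        auc = np.trapezoid(melt_model(fine, p), fine) / (fine[-1] - fine[0])
        assert pooled == pytest.approx(auc, rel=0.03)


class TestFoldChanges:
    def test_reference_values(self):
        pooled = pd.DataFrame({"v1": [10.0], "v2": [10.0], "t1": [10.0], "t2": [20.0]})
        fc = pisa_fold_changes(pooled, ["v1", "v2"])
        assert fc["log2fc_t1"].iloc[0] == pytest.approx(0.0)
        assert fc["log2fc_t2"].iloc[0] == pytest.approx(1.0)

    def test_nonpositive_vehicle_mean_flagged(self):
        pooled = pd.DataFrame({"v1": [0.0], "v2": [0.0], "t1": [5.0]})
        fc = pisa_fold_changes(pooled, ["v1", "v2"])
        assert fc.iloc[0].isna().all()

    def test_requires_two_vehicle_samples(self):
        with pytest.raises(ValueError):
            pisa_fold_changes(pd.DataFrame({"v1": [1.0]}), ["v1"])


class TestCvFilter:
    groups = {"treated": ["t1", "t2", "t3"], "vehicle": ["v1", "v2", "v3"]}

    def make(self, t, v):
        return pd.DataFrame({"t1": t[0], "t2": t[1], "t3": t[2],
                             "v1": v[0], "v2": v[1], "v3": v[2]}, index=["P"])

    def test_zero_variance_kept(self):
        kept, cvs = cv_filter(self.make([10, 10, 10], [5, 5, 5]), self.groups)
        assert "P" in kept.index and cvs.loc["P"].eq(0).all()

    def test_either_group_above_threshold_removed(self):
        kept, cvs = cv_filter(self.make([10, 14, 6], [5, 5, 5]), self.groups)
        assert cvs.loc["P", "treated"] > 15 and "P" not in kept.index

    def test_exactly_15_percent_kept(self):
        # sd/mean = 0.15 exactly: the rule removes only strictly above 15%
        m, sd = 10.0, 1.5
        x = np.array([m - sd, m, m + sd])
        scale = sd / x.std(ddof=1)
        vals = m + (x - m) * scale
        kept, cvs = cv_filter(self.make(list(vals), [5, 5, 5]), self.groups)
        assert cvs.loc["P", "treated"] == pytest.approx(15.0)
        assert "P" in kept.index

    def test_peptide_filter(self):
        pooled = self.make([10, 10, 10], [5, 5, 5])
        kept, _ = cv_filter(pooled, self.groups, peptides=pd.Series({"P": 1}))
        assert len(kept) == 0


class TestSamPermutation:
    def test_s0_zero_equals_t_statistic(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(0, 1, (50, 4)))
        v = pd.DataFrame(rng.normal(0, 1, (50, 4)))
        res = sam_permutation_test(t, v, s0=0.0, n_perm=10, seed=1)
        oracle = stats.ttest_ind(t, v, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(res["d"], oracle, rtol=1e-10)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.normal(0, 1, (100, 4)))
        v = pd.DataFrame(rng.normal(0, 1, (100, 4)))
        a = sam_permutation_test(t, v, seed=7)
        b = sam_permutation_test(t, v, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_null_calibration(self):
        """Same-distribution groups: significant fraction within the
        binomial envelope of the nominal FDR."""
        rng = np.random.default_rng(11)
        n = 2000
        t = pd.DataFrame(rng.normal(10, 0.2, (n, 4)))
        v = pd.DataFrame(rng.normal(10, 0.2, (n, 4)))
        res = sam_permutation_test(t, v, s0=0.1, fdr=0.05, n_perm=250, seed=11)
        frac = res["significant"].mean()
        assert frac <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n)

    def test_power_on_planted_effects(self):
        rng = np.random.default_rng(13)
        n, k = 1000, 50
        base = rng.normal(10, 0.1, (n, 8))
        base[:k, :4] += 1.0  # 50 proteins with true log2 FC = 1
        t = pd.DataFrame(base[:, :4])
        v = pd.DataFrame(base[:, 4:])
        res = sam_permutation_test(t, v, s0=0.1, fdr=0.05, n_perm=250, seed=13)
        assert res["significant"].iloc[:k].sum() >= 45

    def test_too_few_arrangements_rejected(self):
        t = pd.DataFrame([[1.0]])
        v = pd.DataFrame([[2.0]])
        with pytest.raises(ValueError):
            sam_permutation_test(t, v)


def _shift(p: SigmoidParams, delta: float) -> SigmoidParams:
    row = {"pl": p.pl, "a": p.a, "b": p.b}
    return shifted_params(row, delta)


class TestPredictWindowFc:
    def test_identical_curves_give_zero(self):
        p = SigmoidParams(0.1, 120, 10)
        for w in WINDOWS.values():
            assert predict_window_fc(p, p, w) == pytest.approx(0.0)

    def test_back_half_windows_amplify(self):
        # transition at 12 %AEA shifted by +2: later, narrower windows see
        # progressively larger pooled fold changes
        p = SigmoidParams(0, 120, 10)
        fcs = [predict_window_fc(p, _shift(p, 2.0), WINDOWS[w]) for w in (1, 2, 3, 4)]
        assert fcs == sorted(fcs)
        assert fcs[0] > 0

    def test_monotone_across_windows_for_midrange_melters(self):
        """Stabilizing shifts of low-plateau melters whose transition lies
        within the window span produce non-decreasing window-1..4 fold
        changes; once a window samples mostly plateau the gain saturates,
        so early melters and high plateaus are outside this regime."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            pl = rng.uniform(0, 0.1)
            b = rng.uniform(8, 12)
            cm = rng.uniform(13, 17)
            delta = rng.uniform(1.0, 4.0)
            p = SigmoidParams(pl, cm * (b - math.log(0.5 / (0.5 - pl))), b)
            fcs = [predict_window_fc(p, _shift(p, delta), WINDOWS[w]) for w in (1, 2, 3, 4)]
            assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(fcs, fcs[1:]))

    def test_accepts_raw_abundances(self):
        w = WINDOWS[4]
        v = np.full(len(w.gradients), 2.0)
        t = np.full(len(w.gradients), 4.0)
        assert predict_window_fc(v, t, w) == pytest.approx(1.0)

    def test_zero_vehicle_sum_flagged(self):
        w = WINDOWS[4]
        assert math.isnan(predict_window_fc(np.zeros(8), np.ones(8), w))


class TestPisaModelEndToEnd:
    def test_targets_detected_and_fdr_controlled(self, pisa_run):
        res, truth, shifts = pisa_run
        sig = set(res.significant.index)
        detected = len(sig & set(shifts))
        assert detected >= 0.9 * len(shifts)
        extras = len(sig - set(shifts))
        assert extras <= max(3, 0.1 * len(sig))

    def test_cv_envelope(self, pisa_run):
        res, _, _ = pisa_run
        frac = (res.cvs < 15).all(axis=1).mean()
        assert frac >= 0.95

    def test_measured_fc_matches_curve_prediction(self, pisa_run):
        """Pooled-sample fold changes agree with the prediction from the
        generating melting curves within 3x the noise standard error."""
        res, truth, shifts = pisa_run
        noise = sv.NoiseModel()
        w = WINDOWS[2]
        n_rep, n_chan = 4, len(w.gradients)
        se = noise.channel_cv / math.sqrt(n_rep * n_chan) / math.log(2)
        checked = 0
        for prot, delta in shifts.items():
            if prot not in res.table.index:
                continue
            row = truth.loc[prot]
            p = SigmoidParams(row["pl"], row["a"], row["b"])
            pred = predict_window_fc(p, shifted_params(row, delta), w)
            meas = res.table.loc[prot, "mean_log2fc"]
            assert abs(meas - pred) < 3 * se + 0.05
            checked += 1
        assert checked >= 30

    def test_null_pisa_near_empty(self):
        truth = sv.generate_proteome(800, seed=23)
        table = sv.simulate_pisa_tables(truth, WINDOWS[2], seed=23)
        res = sv.PisaModel.from_quant_table(table).fit(seed=23)
        assert res.counts["significant"] <= 0.05 * res.counts["retained"]
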