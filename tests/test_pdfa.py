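"""pDFA: inclusion rule, LDA vs brute-force oracle, nested permutation
uniformity, p-value behaviour and cross-validation."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import troopkit as tk
from troopkit import pdfa as pdfa_mod
from troopkit.synthetic import FEATURE_NAMES


def make_table(rng, n_per_class, n_classes=3, n_bouts_each=2, sep=0.0):
    """Small labelled table with optional class separation."""
    rows = []
    u = 0
    bout = 0
    for c in range(n_classes):
        per_bout = max(1, n_per_class // n_bouts_each)
        for b in range(n_bouts_each):
            bout += 1
            for _ in range(per_bout):
                u += 1
                feats = rng.standard_normal(5) + sep * c
                rows.append({"unit_id": f"U{u}", "bout_id": f"B{bout}",
                             "caller_id": f"C{c}"}
                            | dict(zip(FEATURE_NAMES, feats)))
    return pd.DataFrame(rows)


def brute_force_predict(table, query):
    """Independent pooled-covariance discriminant classifier: explicit
    per-class Gaussian score via numpy primitives only."""
    feats = list(FEATURE_NAMES)
    classes = sorted(table["caller_id"].unique())
    n = len(table)
    means, covs, priors = {}, 0.0, {}
    sw = np.zeros((5, 5))
    for c in classes:
        xc = table.loc[table["caller_id"] == c, feats].to_numpy(float)
        means[c] = xc.mean(axis=0)
        d = xc - means[c]
        sw = sw + d.T @ d
        priors[c] = len(xc) / n
    cov = sw / (n - len(classes)) + 1e-8 * np.eye(5)
    covi = np.linalg.inv(cov)
    preds = []
    for x in query[feats].to_numpy(float):
        best, best_s = None, -np.inf
        for c in classes:  # ascending order: ties keep the lowest id
            s = x @ covi @ means[c] - 0.5 * means[c] @ covi @ means[c] \
                + np.log(priors[c])
            if s > best_s:
                best, best_s = c, s
        preds.append(best)
    return np.array(preds)


class TestInclusion:
    def test_direct_rule(self):
        t = pd.DataFrame({
            "caller_id": ["A"] * 10 + ["B"] * 6 + ["C"] * 4,
            "bout_id": "x", "unit_id": range(20),
        })
        eligible, sub = tk.check_inclusion(t, n_params=5)
        assert eligible == ["A", "B"]
        assert set(sub["caller_id"]) == {"A", "B"}

    def test_all_eligible_when_counts_exceed_params(self, call_table):
        eligible, _ = tk.check_inclusion(call_table)
        assert len(eligible) == call_table["caller_id"].nunique()

    def test_too_few_eligible_raises(self):
        t = pd.DataFrame({"caller_id": ["A"] * 3 + ["B"] * 2,
                          "bout_id": "x", "unit_id": range(5)})
        with pytest.raises(ValueError, match="eligible"):
            tk.check_inclusion(t, n_params=5)


class TestLDA:
    def test_two_class_1d_midpoint_threshold(self):
        # equal-variance 1-D classes at -1 and +1: boundary at 0
        rows = []
        for i, (c, m) in enumerate([("A", -1.0), ("B", 1.0)] * 20):
            rows.append({"unit_id": i, "bout_id": f"B{i}", "caller_id": c,
                         "DFB1": m + (0.1 if i % 4 < 2 else -0.1)})
        t = pd.DataFrame(rows)
        model = tk.fit_lda(t, feature_names=("DFB1",))
        probe = pd.DataFrame({"caller_id": ["A", "B"], "DFB1": [-0.01, 0.01]})
        pred, _, _ = tk.classify(model, probe)
        assert list(pred) == ["A", "B"]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            t = make_table(rng, 10, n_classes=3, sep=rng.uniform(0, 2))
            model = tk.fit_lda(t)
            pred, _, _ = tk.classify(model, t)
            np.testing.assert_array_equal(pred, brute_force_predict(t, t))

    def test_resubstitution_perfect_on_zero_noise(self):
        spec = tk.CallSimSpec(n_callers=4, bouts_per_caller=2,
                              within_caller_sd=(0,) * 5, bout_sd=(0,) * 5,
                              seed=3)
        t = tk.gen_call_features(spec)
        model = tk.fit_lda(t)
        _, acc, per = tk.classify(model, t)
        assert acc == 1.0
        assert all(v == 1.0 for v in per.values())

    def test_matches_sklearn_reference(self, call_table):
        """Predictions agree with an established LDA implementation on a
        well-conditioned table."""
        sklda = pytest.importorskip("sklearn.discriminant_analysis")
        feats = list(FEATURE_NAMES)
        x = call_table[feats].to_numpy(float)
        y = call_table["caller_id"].to_numpy()
        ref = sklda.LinearDiscriminantAnalysis().fit(x, y).predict(x)
        model = tk.fit_lda(call_table)
        pred, _, _ = tk.classify(model, call_table)
        assert np.mean(pred == ref) >= 0.99

    def test_single_unit_at_class_mean(self, call_table):
        model = tk.fit_lda(call_table)
        for ci, c in enumerate(model.classes[:3]):
            probe = pd.DataFrame([{"caller_id": c}
                                  | dict(zip(FEATURE_NAMES,
                                             model.class_means[ci]))])
            pred, _, _ = tk.classify(model, probe)
            assert pred[0] == c


class TestPermuteNested:
    def test_units_of_a_bout_share_label_and_multiset_preserved(self, rng,
                                                                call_table):
        labels = call_table["caller_id"].to_numpy()
        bouts = call_table["bout_id"].to_numpy()
        bout_of = call_table.groupby("bout_id")["caller_id"].first()
        before = Counter(Counter(bout_of).values())
        for _ in range(20):
            perm = tk.permute_nested(labels, bouts, rng)
            df = pd.DataFrame({"bout_id": bouts, "caller_id": perm})
            per_bout = df.groupby("bout_id")["caller_id"].nunique()
            assert (per_bout == 1).all()
            after = Counter(Counter(df.groupby("bout_id")["caller_id"]
                                    .first()).values())
            assert after == before

    def test_uniform_over_six_assignments_of_three_bouts(self, rng):
        labels = np.array(["A", "A", "B", "C", "C", "C"])
        bouts = np.array(["b1", "b1", "b2", "b3", "b3", "b3"])
        counts = Counter()
        n_draws = 6000
        for _ in range(n_draws):
            counts[tuple(tk.permute_nested(labels, bouts, rng))] += 1
        assert len(counts) == 6
        chi = stats.chisquare(list(counts.values())).pvalue
        assert chi > 0.01
        # identity assignment frequency consistent with 1/6
        ident = counts[tuple(labels)] / n_draws
        assert abs(ident - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / n_draws)

    def test_bout_spanning_two_callers_rejected(self, rng):
        labels = np.array(["A", "B"])
        bouts = np.array(["b1", "b1"])
        with pytest.raises(ValueError, match="spans"):
            tk.permute_nested(labels, bouts, rng)


class TestPDFATest:
    def test_strong_effect_significant(self):
        spec = tk.CallSimSpec(
            between_caller_sd=(450, 450, 600, 600, 75),
            within_caller_sd=(150, 150, 200, 200, 25), seed=42)
        t = tk.gen_call_features(spec)
        res = tk.pdfa_test(t, n_perm=999, seed=1)
        assert res.p_value <= 0.001
        assert res.observed_accuracy > res.null_ci[1]
        assert res.null_ci[0] <= res.null_mean <= res.null_ci[1]

    def test_observed_below_null_mean_gives_large_p(self, rng):
        # permuted labels as "observed": accuracy sits inside the null
        t = make_table(rng, 12, n_classes=3, n_bouts_each=3, sep=0.0)
        res = tk.pdfa_test(t, n_perm=499, seed=7)
        if res.observed_accuracy < res.null_mean:
            assert res.p_value > 0.5

    def test_reproducible_bit_for_bit(self, call_table):
        r1 = tk.pdfa_test(call_table, n_perm=199, seed=5)
        r2 = tk.pdfa_test(call_table, n_perm=199, seed=5)
        assert r1.observed_accuracy == r2.observed_accuracy
        np.testing.assert_array_equal(r1.permuted_accuracies,
                                      r2.permuted_accuracies)
        assert r1.p_value == r2.p_value and r1.null_ci == r2.null_ci

    def test_one_bout_per_caller_rejected(self, rng):
        t = make_table(rng, 4, n_classes=3, n_bouts_each=1)
        with pytest.raises(ValueError, match="permutation"):
            tk.pdfa_test(t, n_perm=199, seed=1)

    def test_small_n_perm_warns(self, call_table):
        with pytest.warns(UserWarning, match="n_perm"):
            tk.pdfa_test(call_table, n_perm=99, seed=1)

    def test_monotone_power_in_effect_size(self):
        """Median p over replicates is non-increasing in the planted
        between-caller effect."""
        med_ps = []
        for mult in (0.0, 1.0, 2.0, 3.0):
            ps = []
            for s in range(15):
                spec = tk.CallSimSpec(
                    n_callers=5, bouts_per_caller=4, units_per_bout=(2, 6),
                    between_caller_sd=tuple(mult * v for v in
                                            (150, 150, 200, 200, 25)),
                    within_caller_sd=(150, 150, 200, 200, 25),
                    bout_sd=(50, 50, 60, 60, 8), seed=1000 + s)
                t = tk.gen_call_features(spec)
                ps.append(tk.pdfa_test(t, n_perm=299, seed=s).p_value)
            med_ps.append(np.median(ps))
        assert all(b <= a + 0.05 for a, b in zip(med_ps, med_ps[1:]))


class TestCrossValidated:
    def test_loo_perfect_on_zero_noise(self):
        spec = tk.CallSimSpec(n_callers=4, bouts_per_caller=3,
                              within_caller_sd=(0,) * 5, bout_sd=(0,) * 5,
                              seed=2)
        t = tk.gen_call_features(spec)
        res = tk.pdfa_crossvalidated(t, n_perm=199, seed=1)
        assert res.observed_accuracy == 1.0
        assert res.mode == "cross_validated"

    def test_loo_not_above_resubstitution_usually(self, rng):
        wins = 0
        n_tables = 50
        for _ in range(n_tables):
            t = make_table(rng, 8, n_classes=3, n_bouts_each=2,
                           sep=rng.uniform(0.3, 1.5))
            resub = tk.pdfa_test(t, n_perm=1, seed=0).observed_accuracy
            loo = tk.pdfa_crossvalidated(t, n_perm=1, seed=0).observed_accuracy
            if loo <= resub:
                wins += 1
        assert wins / n_tables >= 0.9

    def test_bout_holdout_kills_bout_leakage(self):
        """Strong bout effects, no caller effect: unit-level LOO looks
        better than chance, bout-level LOO does not."""
        spec = tk.CallSimSpec(
            n_callers=4, bouts_per_caller=4, units_per_bout=(4, 8),
            between_caller_sd=(0,) * 5,
            within_caller_sd=(30, 30, 40, 40, 5),
            bout_sd=(300, 300, 400, 400, 50), seed=8)
        t = tk.gen_call_features(spec)
        unit = tk.pdfa_crossvalidated(t, n_perm=1, seed=0, holdout="unit")
        bout = tk.pdfa_crossvalidated(t, n_perm=1, seed=0, holdout="bout")
        chance = 1 / 4
        assert unit.observed_accuracy > chance + 0.15
        assert bout.observed_accuracy < unit.observed_accuracy - 0.15
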