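import numpy as np
import pandas as pd
import pytest

from omicbridge.io import AbundanceTable, FeatureTable, SampleMetadata
from omicbridge.screening import (
    ScreenRecord,
    bh_adjust,
    differential_screen,
    filter_features,
    plsda_fit,
    rank_sum_test,
    reversal_screen,
    total_ion_normalize,
    trend_consistency,
    vip_scores,
)


class TestFilterFeatures:
    def _table(self, counts, taxa):
        samples = [f"s{i}" for i in range(len(counts))]
        return AbundanceTable(pd.DataFrame(counts, index=samples, columns=taxa))

    def test_sum_and_occurrence_rule(self):
        # sums [200, 80, 150]; occurrences [15, 15, 5] over one condition
        counts = np.zeros((15, 3), dtype=int)
        counts[:, 0] = [14] * 10 + [12] * 5  # sum 200, occ 15
        counts[:, 1] = [6] * 10 + [4] * 5  # sum 80, occ 15
        counts[:, 2] = [30] * 5 + [0] * 10  # sum 150, occ 5
        table = self._table(counts, ["a", "b", "c"])
        grouping = pd.Series("cond", index=table.samples)
        kept, discarded = filter_features(table, grouping, min_sum=120, min_occurrence=12)
        assert kept.taxa == ["a"]
        assert sorted(discarded) == ["b", "c"]

    def test_zero_thresholds_keep_everything_with_any_signal(self):
        counts = [[1, 0, 3], [2, 0, 1]]
        table = self._table(counts, ["a", "b", "c"])
        grouping = pd.Series("cond", index=table.samples)
        kept, discarded = filter_features(table, grouping, min_sum=0, min_occurrence=0)
        assert kept.taxa == ["a", "b", "c"] and discarded == []

    def test_all_zero_taxon_always_discarded(self):
        counts = [[5, 0], [5, 0]]
        table = self._table(counts, ["a", "zero"])
        grouping = pd.Series("cond", index=table.samples)
        kept, discarded = filter_features(table, grouping, min_sum=1, min_occurrence=1)
        assert discarded == ["zero"]

    def test_kept_if_any_condition_passes(self):
        counts = [[10, 10], [10, 10], [0, 0], [0, 0]]
        table = self._table(counts, ["a", "b"])
        grouping = pd.Series(["g1", "g1", "g2", "g2"], index=table.samples)
        kept, _ = filter_features(table, grouping, min_sum=20, min_occurrence=2)
        assert kept.taxa == ["a", "b"]


class TestTotalIonNormalize:
    def test_hand_values(self):
        ft = FeatureTable(pd.DataFrame([[2.0, 2.0, 4.0]], index=["s1"], columns=list("abc")))
        out = total_ion_normalize(ft)
        assert out.values.loc["s1"].tolist() == [0.25, 0.25, 0.5]

    def test_idempotent(self):
        ft = FeatureTable(pd.DataFrame([[0.25, 0.25, 0.5]], index=["s1"], columns=list("abc")))
        out = total_ion_normalize(total_ion_normalize(ft))
        assert np.allclose(out.values.values, [0.25, 0.25, 0.5])

    def test_row_sums_one(self, rng):
        vals = rng.uniform(0.1, 100, size=(20, 30))
        ft = FeatureTable(pd.DataFrame(vals, index=[f"s{i}" for i in range(20)],
                                       columns=[f"f{j}" for j in range(30)]))
        out = total_ion_normalize(ft)
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named(self):
        ft = FeatureTable(pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"],
                                       columns=["a", "b"]))
        with pytest.raises(ValueError, match="empty"):
            total_ion_normalize(ft)


class TestPlsda:
    def test_single_perfect_predictor(self):
        X = np.array([[1.0], [1.2], [0.9], [5.0], [5.1], [4.8]])
        y = np.array(["a"] * 3 + ["b"] * 3)
        model = plsda_fit(X, y, n_components=1)
        assert abs(model.weights[0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        y = np.array(["a"] * 15 + ["b"] * 15)
        model = plsda_fit(X, y, n_components=3)
        t = model.scores
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(t[:, a] @ t[:, b]) < 1e-8

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(20, 8))
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = plsda_fit(X, y, n_components=2)
        perm = rng.permutation(20)
        model_p = plsda_fit(X[perm], y[perm], n_components=2)
        assert np.allclose(model.weights, model_p.weights, atol=1e-10)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="two classes"):
            plsda_fit(X, np.array(["a"] * 10))

    def test_matches_sklearn_pls(self, rng):
        """Independent cross-check: weights and scores agree with sklearn's
        NIPALS PLS regression (up to component sign)."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(24, 10))
        y = np.array(["a"] * 12 + ["b"] * 12)
        model = plsda_fit(X, y, n_components=3)
        y_coded = np.where(y == "a", 1.0, -1.0)
        ref = PLSRegression(n_components=3, scale=True).fit(
            (X - X.mean(0)) / X.std(0, ddof=1), y_coded - y_coded.mean()
        )
        for a in range(3):
            w_mine, w_ref = model.weights[a], ref.x_weights_[:, a]
            flip = np.sign(w_mine @ w_ref)
            assert np.allclose(w_mine, flip * w_ref, atol=1e-8)
            assert np.allclose(model.scores[:, a], flip * ref.x_scores_[:, a], atol=1e-6)


class TestVip:
    def test_equal_weights_all_one(self):
        # symmetric one-component model: every VIP is exactly 1
        X = np.array(
            [[1.0, 1.0], [1.1, 1.1], [0.9, 0.9], [3.0, 3.0], [3.1, 3.1], [2.9, 2.9]]
        )
        y = np.array(["a"] * 3 + ["b"] * 3)
        vips = vip_scores(plsda_fit(X, y, n_components=1))
        assert np.allclose(vips, 1.0, atol=1e-10)

    def test_sum_of_squares_identity(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = plsda_fit(X, y, n_components=2)
        vips = vip_scores(model)
        assert (vips**2).sum() == pytest.approx(10.0, abs=1e-8)

    def test_direct_formula_oracle(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = plsda_fit(X, y, n_components=3)
        vips = vip_scores(model)
        p = model.n_features
        total = model.ssy.sum()
        for j in range(p):
            acc = 0.0
            for a in range(model.n_components):
                w = model.weights[a]
                acc += model.ssy[a] * (w[j] / np.linalg.norm(w)) ** 2
            assert vips[j] == pytest.approx(np.sqrt(p * acc / total), abs=1e-8)


class TestRankSumAndBH:
    def test_exact_regime_fully_separated(self):
        x = np.arange(6, dtype=float)
        y = np.arange(10, 16, dtype=float)
        # fully separated n=6 vs 6: exact two-sided p = 2/924
        assert rank_sum_test(x, y) == pytest.approx(2 / 924, rel=1e-9)

    def test_asymptotic_with_ties(self):
        x = np.array([1.0, 1.0, 2.0] * 4)
        y = np.array([1.0, 2.0, 2.0] * 4)
        p = rank_sum_test(x, y)
        assert 0 <= p <= 1

    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.04, 0.05], [0.015, 0.05, 0.05]),
        ],
    )
    def test_bh_hand_values(self, pvals, expected):
        assert np.allclose(bh_adjust(pvals), expected, atol=1e-12)

    def test_bh_equal_inputs_equal_outputs(self):
        q = bh_adjust([0.03] * 5)
        assert np.allclose(q, q[0])

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 60))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_bh_bounds_and_order(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_bh_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _two_group_frame(rng, effect=1.0, n=6, p=20, planted=0):
    X = rng.lognormal(0, 0.5, size=(2 * n, p))
    X[n:, :planted] *= effect
    idx = [f"s{i}" for i in range(2 * n)]
    values = pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(p)])
    grouping = pd.Series(["ctl"] * n + ["dis"] * n, index=idx)
    return values, grouping


class TestDifferentialScreen:
    def test_planted_feature_selected_with_direction(self, rng):
        values, grouping = _two_group_frame(rng, effect=4.0, planted=1)
        records = differential_screen(values, grouping, vip_threshold=1.0,
                                      p_threshold=0.05, case_group="dis")
        by_feature = {r.feature: r for r in records}
        assert by_feature["f0"].selected and by_feature["f0"].direction == 1

    def test_identical_groups_not_selected(self, rng):
        half = rng.lognormal(0, 0.5, size=(6, 10))
        X = np.vstack([half, half])  # disease group is an exact copy of control
        idx = [f"s{i}" for i in range(12)]
        values = pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(10)])
        grouping = pd.Series(["ctl"] * 6 + ["dis"] * 6, index=idx)
        records = differential_screen(values, grouping, vip_threshold=0.0,
                                      p_threshold=0.05, case_group="dis")
        assert all(r.p > 0.9 for r in records)
        assert not any(r.selected for r in records)
        assert all(r.direction == 0 for r in records)

    def test_zero_thresholds_select_all(self, rng):
        values, grouping = _two_group_frame(rng)
        records = differential_screen(values, grouping, vip_threshold=0.0,
                                      p_threshold=None, case_group="dis")
        assert all(r.selected for r in records)

    def test_vip_monotone_selection(self, rng):
        values, grouping = _two_group_frame(rng, effect=2.0, planted=3)
        low = differential_screen(values, grouping, 0.5, None, case_group="dis")
        high = differential_screen(values, grouping, 1.2, None, case_group="dis")
        sel_low = {r.feature for r in low if r.selected}
        sel_high = {r.feature for r in high if r.selected}
        assert sel_high <= sel_low

    def test_q_at_least_p(self, rng):
        values, grouping = _two_group_frame(rng)
        records = differential_screen(values, grouping, 0.7, None, case_group="dis")
        assert all(r.q >= r.p - 1e-15 for r in records)


def _record(feature, tp, direction, selected):
    return ScreenRecord(feature, tp, 1.0, 0.01, 0.02, direction, selected)


class TestTrendConsistency:
    @pytest.mark.parametrize(
        "dirs, sels, expect",
        [
            ([1, 1, 1], [True, True, True], True),
            ([1, 1, -1], [True, True, True], False),
            ([1, 1, 1], [True, True, False], False),
            ([0, 0, 0], [True, True, True], False),
        ],
    )
    def test_consistency_rules(self, dirs, sels, expect):
        screens = [[_record("f", t, d, s)] for t, (d, s) in enumerate(zip(dirs, sels))]
        result = trend_consistency(screens)[0]
        assert result.consistent is expect
        assert result.overall_direction == (dirs[0] if expect else 0)

    def test_missing_feature_counts_as_unselected(self):
        screens = [
            [_record("f", 0, 1, True), _record("g", 0, 1, True)],
            [_record("f", 1, 1, True)],
            [_record("f", 2, 1, True), _record("g", 2, 1, True)],
        ]
        by_feature = {r.feature: r for r in trend_consistency(screens)}
        assert by_feature["f"].consistent
        assert not by_feature["g"].consistent

    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError):
            trend_consistency([[_record("f", 0, 1, True)]])


class TestReversalScreen:
    def _setup(self, control_med, disease_med, treated_meds):
        rows, values = [], {}
        for tp_i, tp in enumerate((9, 10)):
            for g, med in (("WT", control_med), ("Tg", disease_med), ("TgR", treated_meds[tp_i])):
                for k in range(3):
                    s = f"{g}_{k}_t{tp}"
                    rows.append({"sample": s, "subject": f"{g}_{k}", "group": g, "timepoint": tp})
                    values[s] = med + 0.01 * (k - 1)
        meta = SampleMetadata(pd.DataFrame(rows).set_index("sample")[["subject", "group", "timepoint"]])
        frame = pd.DataFrame({"feat": values})
        return frame, meta

    def test_shrunk_at_both_timepoints_reversed(self):
        frame, meta = self._setup(1.0, 5.0, [2.0, 2.0])
        out = reversal_screen(frame, meta, ["feat"], [9, 10])
        assert bool(out.loc[0, "reversed"])
        assert out.loc[0, "shrinkage_t9"] == pytest.approx(0.25, abs=1e-9)

    def test_treated_equal_disease_not_reversed(self):
        frame, meta = self._setup(1.0, 5.0, [5.0, 5.0])
        assert not bool(reversal_screen(frame, meta, ["feat"], [9, 10]).loc[0, "reversed"])

    def test_reversed_at_one_timepoint_only_not_reversed(self):
        frame, meta = self._setup(1.0, 5.0, [2.0, 6.0])
        assert not bool(reversal_screen(frame, meta, ["feat"], [9, 10]).loc[0, "reversed"])

    def test_missing_group_errors(self):
        frame, meta = self._setup(1.0, 5.0, [2.0, 2.0])
        keep = meta.frame["group"] != "TgR"
        meta_missing = SampleMetadata(meta.frame[keep])
        with pytest.raises(ValueError, match="TgR"):
            reversal_screen(frame.loc[keep[keep].index], meta_missing, ["feat"], [9, 10])


class TestBHHypothesis:
    """Property-based checks of the step-up adjustment."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=60,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_bh_dominates_p_and_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)
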