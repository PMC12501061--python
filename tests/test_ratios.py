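import warnings
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexsig import ratios
from coexsig.io import ExpressionMatrix, SignatureDef
from coexsig.survival import SurvivalData


def _em(values, scale="raw", genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes,
                     columns=[f"S{i}" for i in range(values.shape[1])]),
        scale=scale,
    )


def _surv(time, event):
    return SurvivalData([f"S{i}" for i in range(len(time))],
                        np.asarray(time, float), np.asarray(event, int))


class TestNormalization:
    def test_invariants_after_each_step(self, rng):
        em = _em(rng.exponential(50, (30, 12)))
        norm = ratios.cluster3_normalize(em)
        assert np.abs(np.median(norm.values, axis=0)).max() < 1e-9
        assert np.abs(norm.values.std(axis=1, ddof=1) - 1.0).max() < 1e-9
        assert norm.scale == "normalized"
        assert "normalization" in norm.data.attrs

    def test_idempotent_on_normalized_values(self, rng):
        em = _em(rng.exponential(50, (30, 12)))
        once = ratios.cluster3_normalize(em)
        # re-apply steps 2-3 directly to the already-normalized values
        v = once.values.copy()
        v = v - np.median(v, axis=0, keepdims=True)
        v = v / v.std(axis=1, ddof=1, keepdims=True)
        assert np.allclose(v, once.values, atol=1e-9)

    def test_constant_matrix_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ratios.cluster3_normalize(_em(np.full((3, 5), 7.0)))
        assert np.allclose(out.values, 0.0)

    def test_rejects_non_raw(self, rng):
        with pytest.raises(ValueError, match="raw"):
            ratios.cluster3_normalize(_em(rng.random((3, 5)), scale="log2"))


class TestRatioScore:
    def test_sum_over_sum(self):
        em = _em([[1.0, 2.0], [1.0, 0.5], [1.0, 1.0]], scale="normalized")
        sig = SignatureDef("s", ["G0", "G1"], ["G2"])
        assert np.allclose(ratios.ratio_score(em, sig), [2.0, 2.5])

    def test_zero_denominator_guard(self):
        em = _em([[2.0, 2.0], [0.0, 1.0]], scale="normalized")
        sig = SignatureDef("s", ["G0"], ["G1"])
        with pytest.warns(UserWarning, match="excluded"):
            score = ratios.ratio_score(em, sig)
        assert np.isnan(score[0]) and score[1] == 2.0

    def test_invert_negates(self):
        em = _em([[2.0], [1.0]], scale="normalized")
        plain = ratios.ratio_score(em, SignatureDef("s", ["G0"], ["G1"]))
        inv = ratios.ratio_score(em, SignatureDef("s", ["G0"], ["G1"], invert=True))
        assert np.allclose(inv, -plain)

    def test_missing_gene_listed(self):
        em = _em([[1.0]], scale="normalized")
        with pytest.raises(KeyError, match="MISSING"):
            ratios.ratio_score(em, SignatureDef("s", ["G0"], ["MISSING"]))


class TestBinarizeOutcome:
    def test_rules(self):
        surv = _surv([300, 400, 200, 365], [1, 0, 0, 1])
        out = ratios.binarize_outcome(surv, 365)
        assert out[0] == 1.0  # death before horizon
        assert out[1] == 0.0  # alive past horizon
        assert np.isnan(out[2])  # censored before horizon: excluded
        assert out[3] == 1.0  # death at the horizon counts as death

    def test_positive_horizon_required(self):
        with pytest.raises(ValueError):
            ratios.binarize_outcome(_surv([1.0], [1]), 0)


class TestLogistic:
    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal(80)
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = ratios.fit_logistic(x, y)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.coef == pytest.approx(ref.params[1], abs=1e-6)
        assert np.allclose(fit.probs, ref.fittedvalues, atol=1e-6)

    def test_auc_of_fitted_probs_is_oriented_score_auc(self, rng):
        x = rng.standard_normal(60)
        y = (rng.uniform(size=60) < 0.4).astype(float)
        fit = ratios.fit_logistic(x, y)
        a_score = ratios.roc_auc(x, y)
        a_fit = ratios.roc_auc(fit.probs, y)
        assert a_fit == pytest.approx(max(a_score, 1 - a_score), abs=1e-12)

    def test_coefficient_sign_tracks_class_separation(self, rng):
        x = np.concatenate([rng.normal(1, 1, 40), rng.normal(-1, 1, 40)])
        y = np.concatenate([np.ones(40), np.zeros(40)])
        assert ratios.fit_logistic(x, y).coef > 0
        assert ratios.fit_logistic(-x, y).coef < 0

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.ones(10), -np.ones(10)])
        y = np.concatenate([np.ones(10), np.zeros(10)])
        with pytest.warns(UserWarning, match="separation"):
            fit = ratios.fit_logistic(x, y)
        assert fit.separated
        assert np.isfinite(fit.probs).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            ratios.fit_logistic(np.arange(5.0), np.ones(5))


class TestRocAuc:
    def test_hand_counted_concordance(self):
        # pairs: (2,1)+, (2,3)-, (4,1)+, (4,3)+ -> 3/4
        assert ratios.roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_perfect_and_constant(self):
        assert ratios.roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert ratios.roc_auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        x = rng.standard_normal(100)
        y = (rng.uniform(size=100) < 0.3).astype(int)
        assert ratios.roc_auc(x, y) == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=30),
           st.integers(0, 2**31 - 1))
    def test_invariant_under_strictly_increasing_transforms(self, scores, seed):
        scores = np.asarray(scores, dtype=float)
        y = np.random.default_rng(seed).integers(0, 2, len(scores))
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        base = ratios.roc_auc(scores, y)
        assert ratios.roc_auc(np.exp(scores / 50), y) == pytest.approx(base, abs=1e-12)
        assert ratios.roc_auc(3 * scores + 7, y) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ratios.roc_auc([1, 2], [1, 1])


class TestAucCi:
    def test_symmetric_data_p_near_one(self, rng):
        x = rng.standard_normal(200)
        y = (np.arange(200) % 2).astype(float)
        low, high, p = ratios.auc_ci(x, y)
        assert low < 0.5 < high
        assert p > 0.2

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (50, 100, 200, 400):
            rng = np.random.default_rng(7)
            x = np.concatenate([rng.normal(1, 1, n // 2), rng.normal(0, 1, n // 2)])
            y = np.repeat([1.0, 0.0], n // 2)
            low, high, _ = ratios.auc_ci(x, y)
            widths.append(high - low)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_degenerate_variance_widest_interval(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            low, high, p = ratios.auc_ci(x, y)
        assert (low, high) == (0.0, 1.0)
        assert np.isnan(p)


class TestEnumeration:
    def test_single_pair(self):
        combos = list(ratios.enumerate_combinations(["A"], ["B"]))
        assert len(combos) == 1
        assert combos[0].label() == "A/B"

    @pytest.mark.parametrize("n,m,expected", [(9, 5, 1875), (10, 10, 60625), (3, 2, 9)])
    def test_closed_form_matches_brute_force(self, n, m, expected):
        num = [f"N{i}" for i in range(n)]
        den = [f"D{i}" for i in range(m)]
        generated = sum(1 for _ in ratios.enumerate_combinations(num, den))
        assert generated == expected
        assert ratios.count_combinations(n, m) == expected
        assert expected == sum(comb(n, k) * comb(m, k) for k in range(1, 5))

    def test_oversized_k_skipped(self):
        combos = list(ratios.enumerate_combinations(["A", "B"], ["C"], max_side_size=4))
        assert all(len(c.numerator_genes) == 1 for c in combos)

    def test_deterministic_lexical_order(self):
        a = [c.label() for c in ratios.enumerate_combinations(["B", "A"], ["D", "C"],
                                                              max_side_size=2)]
        b = [c.label() for c in ratios.enumerate_combinations(["A", "B"], ["C", "D"],
                                                              max_side_size=2)]
        assert a == b
        assert a[0] == "A/C"

    def test_overlapping_sides_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            list(ratios.enumerate_combinations(["A"], ["A", "B"]))


@pytest.fixture(scope="module")
def eval_inputs():
    rng = np.random.default_rng(0)
    n = 120
    risk = rng.standard_normal(n)
    vals = np.vstack([
        9.0 - risk + 0.8 * rng.standard_normal((4, n)),   # protective genes
        9.0 + risk + 0.8 * rng.standard_normal((4, n)),   # hazardous genes
        8.0 + rng.standard_normal((4, n)),                # noise genes
        rng.uniform(1, 4, 24)[:, None] + 0.5 * rng.standard_normal((24, n)),
    ])
    em = _em(np.maximum(np.exp2(vals) - 1, 0.0))
    t = rng.exponential(1.0 / (6e-4 * np.exp(risk)))
    c = rng.exponential(2500, n)
    surv = _surv(np.minimum(t, c), (t <= c).astype(int))
    norm = ratios.cluster3_normalize(em)
    return norm, surv


class TestEvaluateAllRatios:
    def test_deterministic(self, eval_inputs):
        norm, surv = eval_inputs
        num, den = ["G0", "G1"], ["G4", "G5"]
        a = ratios.evaluate_all_ratios(norm, surv, num, den)
        b = ratios.evaluate_all_ratios(norm, surv, num, den)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_literal_per_combination_route(self, eval_inputs):
        """The vectorised rank path must reproduce the literal procedure:
        score -> binarize -> logistic fit -> AUC of fitted probabilities,
        with the DeLong CI computed on the oriented score."""
        norm, surv = eval_inputs
        num, den = ["G0", "G1", "G2"], ["G4", "G5", "G6"]
        table = ratios.evaluate_all_ratios(norm, surv, num, den, full_metrics=True)
        cfg = ratios.RatioSearchConfig()
        rng = np.random.default_rng(1)
        for _, row in table.sample(12, random_state=3).iterrows():
            sig = SignatureDef("x", row["numerator"].split("+"),
                               row["denominator"].split("+"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score = ratios.ratio_score(norm, sig)
            for t in cfg.timepoints_days:
                y = ratios.binarize_outcome(surv, t)
                ok = np.isfinite(score) & np.isfinite(y)
                if len(np.unique(y[ok])) < 2:
                    assert np.isnan(row[f"auc_{t}"])
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = ratios.fit_logistic(score[ok], y[ok])
                    expected_auc = ratios.roc_auc(fit.probs, y[ok])
                assert row[f"auc_{t}"] == pytest.approx(expected_auc, abs=1e-10)
                oriented = score[ok] if ratios.roc_auc(score[ok], y[ok]) >= 0.5 else -score[ok]
                low, high, p = ratios.auc_ci(oriented, y[ok])
                assert row[f"ci_low_{t}"] == pytest.approx(low, abs=1e-9)
                assert row[f"ci_high_{t}"] == pytest.approx(high, abs=1e-9)
                assert row[f"p_{t}"] == pytest.approx(p, abs=1e-9, nan_ok=True)

    def test_informative_genes_beat_noise(self, eval_inputs):
        norm, surv = eval_inputs
        table = ratios.evaluate_all_ratios(
            norm, surv, ["G0", "G1", "G2", "G3"], ["G4", "G5", "G6", "G7"],
            full_metrics=False,
        )
        noise = ratios.evaluate_all_ratios(
            norm, surv, ["G8", "G9"], ["G10", "G11"], full_metrics=False
        )
        assert table["mean_auc_all"].max() > 0.7
        assert abs(noise["mean_auc_all"].mean() - 0.5) < 0.1

    def test_youden_confusion_metrics_consistent(self, eval_inputs):
        norm, surv = eval_inputs
        table = ratios.evaluate_all_ratios(norm, surv, ["G0"], ["G4"], full_metrics=True)
        row = table.iloc[0]
        for t in (548, 1095):
            sens, spec, acc = row[f"sensitivity_{t}"], row[f"specificity_{t}"], row[f"accuracy_{t}"]
            assert 0 <= sens <= 1 and 0 <= spec <= 1
            assert sens + spec - 1 > 0  # Youden threshold beats chance here
            n1, n0 = row[f"n_events_{t}"], row[f"n_used_{t}"] - row[f"n_events_{t}"]
            assert acc == pytest.approx((sens * n1 + spec * n0) / (n1 + n0), abs=1e-9)


class TestRanking:
    def _table(self):
        return pd.DataFrame({
            "signature": ["a/x", "b/y", "c/z"],
            "numerator": ["a", "b", "c"],
            "denominator": ["x", "y", "z"],
            "mean_auc_all": [0.70, 0.72, 0.70],
            "mean_auc_excl-10y": [0.74, 0.70, 0.71],
        })

    def test_subset_ranking_can_reorder(self):
        t = self._table()
        by_all = ratios.rank_by_mean_auc(t, "all")
        by_sub = ratios.rank_by_mean_auc(t, "excl-10y")
        assert by_all["signature"].iloc[0] == "b/y"
        assert by_sub["signature"].iloc[0] == "a/x"

    def test_ties_break_by_full_mean_then_name(self):
        t = self._table()
        out = ratios.rank_by_mean_auc(t, "all")
        # b leads on mean; a and c tie on both means, broken by name
        assert out["signature"].tolist() == ["b/y", "a/x", "c/z"]

    def test_row_shuffle_stable(self):
        t = self._table()
        out1 = ratios.rank_by_mean_auc(t, "all")
        out2 = ratios.rank_by_mean_auc(t.iloc[[2, 0, 1]].reset_index(drop=True), "all")
        assert out1["signature"].tolist() == out2["signature"].tolist()

    def test_unknown_subset_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            ratios.rank_by_mean_auc(self._table(), "nope")


class TestTopGeneFrequency:
    def test_hand_built_counts(self):
        ranked = pd.DataFrame({
            "signature": [f"s{i}" for i in range(5)],
            "numerator": ["A+B", "A+C", "A+B", "D", "A"],
            "denominator": ["X", "Y", "X+Y", "X", "Z"],
        })
        cfg = ratios.RatioSearchConfig(top_k_for_frequency=6)
        with pytest.warns(UserWarning, match="using all"):
            freq = ratios.top_gene_frequency(ranked, cfg)
        f = freq.set_index(["side", "gene"])["frequency"]
        assert f[("num", "A")] == pytest.approx(0.8)
        assert f[("num", "B")] == pytest.approx(0.4)
        assert f[("den", "X")] == pytest.approx(0.6)
        sel = freq.set_index(["side", "gene"])["selected"]
        assert bool(sel[("num", "B")]) is True  # 0.4 > 0.2
        assert bool(sel[("num", "D")]) is False  # 0.2 not strictly above


class TestSurvivalCorrelatedSelection:
    def test_gene_equal_to_survival_time_tops_numerators(self, eval_inputs):
        norm, surv = eval_inputs
        spiked = norm.data.copy()
        spiked.iloc[11] = (surv.time - surv.time.mean()) / surv.time.std()
        em = ExpressionMatrix(spiked, scale="normalized")
        num, den, table = ratios.select_survival_correlated(em, surv, 1)
        assert num == ["G11"]
        assert table.iloc[0]["bicor_os_time"] > 0.95

    def test_planted_direction_recovery(self, eval_inputs):
        norm, surv = eval_inputs
        num, den, _ = ratios.select_survival_correlated(norm, surv, 4)
        protective = {"G0", "G1", "G2", "G3"}
        hazardous = {"G4", "G5", "G6", "G7"}
        assert len(set(num) & protective) >= 3
        assert len(set(den) & hazardous) >= 3

    def test_top_n_bounds(self, eval_inputs):
        norm, surv = eval_inputs
        with pytest.raises(ValueError, match="exceeds"):
            ratios.select_survival_correlated(norm, surv, 1000)
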