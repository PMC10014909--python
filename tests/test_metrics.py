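"""AUC, calibration, confusion arithmetic, cut-point search, variable ranking."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from conftest import auc_pairwise_oracle, cutoff_oracle, make_record
from nils.exceptions import NilsError, UndefinedMetricError
from nils.metrics import (
    ConfusionCounts,
    classification_metrics,
    confusion_at_cutoff,
    hosmer_lemeshow,
    permutation_importance,
    roc_auc,
    select_cutoff_max_fnr,
)


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = [True, True, False, False]
        auc, lo, hi = roc_auc(labels, [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_four_point_example(self):
        # 3 concordant of the 4 class-crossing pairs
        auc, _, _ = roc_auc([True, True, False, False], [0.9, 0.4, 0.6, 0.1])
        assert auc == pytest.approx(0.75)

    def test_matches_pairwise_oracle_and_sklearn(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            auc, _, _ = roc_auc(labels, scores)
            assert auc == pytest.approx(auc_pairwise_oracle(labels, scores), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_complement_scores_sum_to_one(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(12, bool), np.zeros(10, bool)]
        scores = rng.random(22)  # continuous: tie-free
        a1 = roc_auc(labels, scores)[0]
        a2 = roc_auc(labels, -scores)[0]
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_ci_brackets_estimate_within_unit_interval(self):
        rng = np.random.default_rng(8)
        labels = rng.random(80) < 0.6
        scores = rng.random(80) + 0.5 * labels
        auc, lo, hi = roc_auc(labels, scores)
        assert 0.0 <= lo <= auc <= hi <= 1.0
        assert hi - lo < 0.5

    def test_single_class_rejected(self):
        with pytest.raises(NilsError):
            roc_auc([True, True], [0.1, 0.2])


class TestHosmerLemeshow:
    def test_ten_groups_give_eight_df(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 200)
        y = rng.random(200) < p
        chi2, df, pval = hosmer_lemeshow(y, p, n_groups=10)
        assert df == 8
        assert chi2 >= 0 and 0 <= pval <= 1

    def test_exactly_calibrated_deciles_give_zero(self):
        # 10 groups, 20 patients each at probability i/20 with exactly i events
        probs, events = [], []
        for i in range(1, 11):
            probs += [i / 20.0] * 20
            events += [True] * i + [False] * (20 - i)
        chi2, df, _ = hosmer_lemeshow(events, probs, n_groups=10)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 8

    def test_two_group_toy_is_calibrated(self):
        probs = [0.2] * 10 + [0.8] * 10
        events = [True] * 2 + [False] * 8 + [True] * 8 + [False] * 2
        chi2, df, pval = hosmer_lemeshow(events, probs, n_groups=2)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 0 and np.isnan(pval)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, 120)
        y = rng.random(120) < p
        chi2_a, _, _ = hosmer_lemeshow(y, p)
        perm = rng.permutation(120)
        chi2_b, _, _ = hosmer_lemeshow(y[perm], p[perm])
        assert chi2_a == pytest.approx(chi2_b, abs=1e-9)

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(NilsError):
            hosmer_lemeshow([True] * 20, [0.0] * 20)


class TestConfusion:
    def test_cutoff_zero_predicts_everyone_n0(self):
        labels = np.r_[np.ones(6, bool), np.zeros(4, bool)]
        probs = np.linspace(0.1, 0.9, 10)
        c = confusion_at_cutoff(labels, probs, 0.0)
        assert (c.tp, c.fp) == (0, 0)
        assert c.fn == 4 and c.tn == 6

    def test_cutoff_above_max_predicts_everyone_npos(self):
        labels = np.r_[np.ones(6, bool), np.zeros(4, bool)]
        probs = np.linspace(0.1, 0.9, 10)
        c = confusion_at_cutoff(labels, probs, 0.95)
        assert (c.fn, c.tn) == (0, 0)
        assert c.tp == 4 and c.fp == 6

    def test_matches_elementwise_count(self):
        rng = np.random.default_rng(2)
        labels = rng.random(50) < 0.6
        probs = rng.random(50)
        c = confusion_at_cutoff(labels, probs, 0.55)
        tp = sum(1 for y, p in zip(labels, probs) if not y and p < 0.55)
        tn = sum(1 for y, p in zip(labels, probs) if y and p >= 0.55)
        fp = sum(1 for y, p in zip(labels, probs) if y and p < 0.55)
        fn = sum(1 for y, p in zip(labels, probs) if not y and p >= 0.55)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_published_count_arithmetic(self):
        # the deployed tool's confusion table
        m = classification_metrics(ConfusionCounts(tp=256, tn=177, fp=339, fn=28))
        assert m["sensitivity"] == pytest.approx(0.9014, abs=1e-4)
        assert m["specificity"] == pytest.approx(0.3430, abs=1e-4)
        assert m["fnr"] == pytest.approx(0.0986, abs=1e-4)
        assert m["slnb_reduction_rate"] == pytest.approx(0.2563, abs=1e-4)
        # the 15-variable prototype's table
        m = classification_metrics(ConfusionCounts(tp=258, tn=190, fp=324, fn=28))
        assert m["specificity"] == pytest.approx(0.3696, abs=1e-4)
        assert m["slnb_reduction_rate"] == pytest.approx(0.2725, abs=1e-4)

    def test_sensitivity_plus_fnr_is_one(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 50, 4)))
            m = classification_metrics(c)
            assert m["sensitivity"] + m["fnr"] == pytest.approx(1.0, abs=1e-12)

    def test_undefined_metric_names_itself(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            classification_metrics(ConfusionCounts(tp=0, tn=5, fp=5, fn=0))


class TestCutoffSelection:
    def test_separable_classes(self):
        labels = np.r_[np.ones(7, bool), np.zeros(5, bool)]
        probs = np.r_[np.linspace(0.6, 0.9, 7), np.linspace(0.1, 0.4, 5)]
        cut, counts = select_cutoff_max_fnr(labels, probs, 0.10)
        m = classification_metrics(counts)
        assert m["fnr"] == 0.0
        assert m["slnb_reduction_rate"] == pytest.approx(7 / 12)

    def test_zero_fnr_constraint_feasible(self):
        rng = np.random.default_rng(6)
        labels = rng.random(60) < 0.6
        probs = rng.random(60)
        cut, counts = select_cutoff_max_fnr(labels, probs, max_fnr=0.0)
        assert counts.fn == 0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            labels = rng.random(200) < 0.64
            probs = np.round(rng.random(200), 3)
            for max_fnr in (0.0, 0.05, 0.10):
                cut, counts = select_cutoff_max_fnr(labels, probs, max_fnr)
                oracle_cut, oracle_red = cutoff_oracle(labels, probs, max_fnr)
                assert cut == pytest.approx(oracle_cut, abs=1e-12)
                m = classification_metrics(counts)
                assert m["slnb_reduction_rate"] == pytest.approx(oracle_red, abs=1e-12)
                assert m["fnr"] <= max_fnr


class TestPermutationImportance:
    def test_informative_variable_ranked_first(self, complete_cohort):
        # surrogate model driven purely by tumor size: permuting size drops
        # the AUC, permuting anything else changes nothing at all
        sizes = np.array([r.tumor_size_mm for r in complete_cohort])
        mu, sd = sizes.mean(), sizes.std()

        def predict_fn(records):
            z = np.array([(r.tumor_size_mm - mu) / sd for r in records])
            return 1.0 / (1.0 + np.exp(1.2 * z))  # larger tumor -> lower p(N0)

        table = permutation_importance(predict_fn, complete_cohort, seed=0, n_permutations=3)
        assert table.loc[0, "variable"] == "tumor_size"
        assert table.loc[0, "position"] == 1
        assert table.loc[0, "auc_drop"] > 0.1

    def test_ignored_variables_have_zero_drop(self, complete_cohort):
        def predict_fn(records):
            return np.linspace(0.1, 0.9, len(records))  # fixed by list position

        table = permutation_importance(predict_fn, complete_cohort, seed=1, n_permutations=2)
        assert np.allclose(table["auc_drop"], 0.0, atol=1e-12)

    def test_trained_model_recovers_single_planted_signal(self):
        from nils.cohort import Variant
        from nils.ensemble import EnsembleConfig, encode_matrix, ensemble_predict, train_ensemble
        from nils.synthetic import GeneratorConfig, generate_cohort

        effects = {k: 0.0 for k in GeneratorConfig().effects}
        effects["tumor_size"] = 2.0
        cfg = GeneratorConfig(
            n=150, seed=31, effects=effects,
            missing_vi=0.0, missing_er=0.0, missing_pr=0.0, missing_ki67=0.0,
        )
        records = generate_cohort(cfg)
        labels = np.asarray([r.is_n0 for r in records], dtype=float)
        model = train_ensemble(
            records, labels, Variant.N0_FULL,
            EnsembleConfig(repeats=1, lambda_decay=0.01, seed=2, max_iterations=150),
        )

        def predict_fn(recs):
            return ensemble_predict(
                model, encode_matrix(recs, Variant.N0_FULL, model.normalization)
            )

        table = permutation_importance(predict_fn, records, seed=3, n_permutations=3)
        assert table.loc[0, "variable"] == "tumor_size"
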