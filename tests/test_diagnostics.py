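"""Rule classifiers, confusion metrics, NIR and McNemar tests, dilution pick."""

import math

import numpy as np
import pandas as pd
import pytest

from nsdt.diagnostics import (CANCER, CANCER_FREE, ConfusionMatrix,
                              RuleClassifier, classify, confusion,
                              evaluate_models, mcnemar, nir_test, report,
                              select_optimal_dilution)

CI_RULE = RuleClassifier("ci_rule")
PSA_RULE = RuleClassifier("psa_rule")
COMBINED = RuleClassifier("combined_rule")


class TestClassify:
    @pytest.mark.parametrize("ci,psa,rule,expected", [
        (0.2, None, CI_RULE, CANCER),          # CI > 0 calls cancer
        (-0.1, None, CI_RULE, CANCER_FREE),
        (0.0, None, CI_RULE, CANCER_FREE),     # exact zero -> cancer-free
        (None, 4.0, PSA_RULE, CANCER),         # threshold inclusive
        (None, 3.99, PSA_RULE, CANCER_FREE),
        # AND-rule truth table: cancer only for (CI+, PSA>=4)
        (0.2, 5.0, COMBINED, CANCER),
        (0.2, 3.0, COMBINED, CANCER_FREE),
        (-0.2, 5.0, COMBINED, CANCER_FREE),
        (-0.2, 3.0, COMBINED, CANCER_FREE),
    ])
    def test_rule_truth_table(self, ci, psa, rule, expected):
        assert classify(ci, psa, rule) == expected

    def test_missing_required_input_rejected(self):
        with pytest.raises(ValueError):
            classify(None, 5.0, CI_RULE)
        with pytest.raises(ValueError):
            classify(0.2, float("nan"), COMBINED)

    def test_unknown_rule_name_rejected(self):
        with pytest.raises(ValueError):
            RuleClassifier("roc_rule")


class TestConfusion:
    def test_perfect_predictions(self):
        truth = ["cancer"] * 21 + ["benign"] * 19 + ["negative_screen"] * 27
        preds = [CANCER] * 21 + [CANCER_FREE] * 46
        cm = confusion(preds, truth)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (21, 0, 0, 46)

    def test_all_cancer_predictor(self):
        truth = ["cancer"] * 21 + ["benign"] * 19 + ["negative_screen"] * 27
        cm = confusion([CANCER] * 67, truth)
        assert (cm.tp, cm.fp) == (21, 46) and cm.fn == cm.tn == 0

    def test_inverting_predictions_transposes_matrix(self, rng):
        truth = rng.choice(["cancer", "benign"], size=30).tolist()
        preds = rng.choice([CANCER, CANCER_FREE], size=30).tolist()
        cm = confusion(preds, truth)
        inv = [CANCER_FREE if p == CANCER else CANCER for p in preds]
        cm2 = confusion(inv, truth)
        assert (cm2.tp, cm2.fn, cm2.fp, cm2.tn) == (cm.fn, cm.tp, cm.tn, cm.fp)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion([CANCER], ["maybe"])
        with pytest.raises(ValueError):
            confusion(["yes"], ["cancer"])


class TestReport:
    def test_ci_model_worked_example(self):
        """The confusion matrix consistent with a 21/46 cohort: sens 76%,
        spec 67%, accuracy 70%, balanced accuracy 72%."""
        rep = report(ConfusionMatrix(tp=16, fn=5, fp=15, tn=31))
        assert rep.display == {"sensitivity": 76, "specificity": 67,
                               "accuracy": 70, "balanced_accuracy": 72,
                               "nir": 69}

    def test_combined_model_worked_example(self):
        rep = report(ConfusionMatrix(tp=15, fn=6, fp=7, tn=39))
        assert rep.display["sensitivity"] == 71
        assert rep.display["specificity"] == 85
        assert rep.display["accuracy"] == 81
        assert rep.display["balanced_accuracy"] == 78

    def test_balanced_accuracy_is_mean_of_sens_spec(self, rng):
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            rep = report(ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
            assert rep.balanced_accuracy == pytest.approx(
                (rep.sensitivity + rep.specificity) / 2)

    def test_no_positives_flags_sensitivity(self):
        rep = report(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
        assert math.isnan(rep.sensitivity)
        assert rep.specificity == pytest.approx(1.0)

    def test_metrics_match_per_patient_tally_oracle(self, rng):
        """Metrics agree with a brute-force per-patient count on random labels."""
        for _ in range(50):
            n = int(rng.integers(4, 20))
            truth = rng.choice(["cancer", "benign"], size=n).tolist()
            preds = rng.choice([CANCER, CANCER_FREE], size=n).tolist()
            mapped = [CANCER if t == "cancer" else CANCER_FREE for t in truth]
            if len(set(mapped)) < 2:
                continue
            rep = report(confusion(preds, truth))
            correct = sum(p == t for p, t in zip(preds, mapped))
            pos = mapped.count(CANCER)
            tp = sum(p == t == CANCER for p, t in zip(preds, mapped))
            tn = sum(p == t == CANCER_FREE for p, t in zip(preds, mapped))
            assert rep.accuracy == pytest.approx(correct / n)
            assert rep.sensitivity == pytest.approx(tp / pos)
            assert rep.specificity == pytest.approx(tn / (n - pos))

    def test_balanced_accuracy_invariant_to_class_upsampling(self):
        cm = ConfusionMatrix(tp=6, fn=2, fp=3, tn=9)
        up = ConfusionMatrix(tp=18, fn=6, fp=9, tn=27)  # both classes x3
        assert report(cm).balanced_accuracy == pytest.approx(
            report(up).balanced_accuracy)


class TestNIR:
    def test_majority_class_prevalence(self):
        nir, _ = nir_test(ConfusionMatrix(tp=16, fn=5, fp=15, tn=31))
        assert nir == pytest.approx(46 / 67)

    def test_accuracy_at_nir_not_significant(self):
        # 46 correct of 67 = exactly the majority-class rate
        _, p = nir_test(ConfusionMatrix(tp=0, fn=21, fp=0, tn=46))
        assert p >= 0.5

    def test_perfect_classifier_beats_nir(self):
        _, p = nir_test(ConfusionMatrix(tp=21, fn=0, fp=0, tn=46))
        assert p < 1e-6

    def test_p_in_unit_interval(self, rng):
        for _ in range(20):
            tp, fn, fp, tn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + fn + fp + tn == 0:
                continue
            _, p = nir_test(ConfusionMatrix(tp, fn, fp, tn))
            assert 0.0 <= p <= 1.0


class TestMcNemar:
    def test_corrected_statistic_hand_value(self):
        # b=15, c=1: (|15-1|-1)^2 / 16 = 10.5625
        preds = [CANCER] * 15 + [CANCER_FREE] * 1 + [CANCER] * 5
        refs = [CANCER_FREE] * 15 + [CANCER] * 1 + [CANCER] * 5
        stat, p = mcnemar(preds, refs)
        assert stat == pytest.approx(10.5625)
        assert p < 0.01

    def test_identical_vectors_p_one(self):
        v = [CANCER, CANCER_FREE, CANCER]
        assert mcnemar(v, v) == (0.0, 1.0)

    def test_symmetric_discordance_near_null(self):
        preds = [CANCER] * 5 + [CANCER_FREE] * 5
        refs = [CANCER_FREE] * 5 + [CANCER] * 5
        stat, p = mcnemar(preds, refs)
        assert p > 0.5

    def test_swap_invariance(self, rng):
        preds = rng.choice([CANCER, CANCER_FREE], 40).tolist()
        refs = rng.choice([CANCER, CANCER_FREE], 40).tolist()
        assert mcnemar(preds, refs)[1] == pytest.approx(mcnemar(refs, preds)[1])

    def test_exact_variant_matches_binomial_tail(self):
        preds = [CANCER] * 6 + [CANCER_FREE] * 1
        refs = [CANCER_FREE] * 6 + [CANCER] * 1
        from scipy.stats import binom
        _, p = mcnemar(preds, refs, exact=True)
        expected = 2 * binom.cdf(1, 7, 0.5)
        assert p == pytest.approx(min(1.0, expected))


class TestDilutionSelection:
    def test_accuracy_dominates(self):
        per = {"1:10": [(0.5, "cancer"), (0.4, "benign")],       # acc 0.5
               "1:100": [(0.5, "cancer"), (-0.4, "benign")]}     # acc 1.0
        best, table = select_optimal_dilution(per)
        assert best == "1:100"
        assert table.loc[table["selected"], "dilution"].iloc[0] == "1:100"

    def test_tie_broken_by_mean_difference(self):
        per = {"1:10": [(0.1, "cancer"), (-0.1, "benign")],
               "1:100": [(0.6, "cancer"), (-0.6, "benign")]}
        best, _ = select_optimal_dilution(per)
        assert best == "1:100"

    def test_full_tie_prefers_least_dilute(self):
        pairs = [(0.2, "cancer"), (-0.2, "benign")]
        best, _ = select_optimal_dilution({"1:10": list(pairs),
                                           "1:100": list(pairs)})
        assert best == "1:10"

    def test_single_dilution_rejected(self):
        with pytest.raises(ValueError):
            select_optimal_dilution({"1:10": [(0.2, "cancer"), (-0.2, "benign")]})

    def test_signal_dilution_found_reliably(self):
        """When exactly one dilution discriminates clearly, the screen selects
        it in at least 95% of simulated panels."""
        from nsdt import SimulationParams
        from nsdt.pipeline import cohort_to_frames, compute_patient_ci_table
        from nsdt.simulate import DILUTIONS, simulate_dilution_screen

        params = SimulationParams(mean_attraction={
            "negative_screen": -0.15, "benign": -0.15, "cancer": 0.35})
        effect = {d: (1.0 if d == "1:100" else 0.0) for d in DILUTIONS}
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            cohort = simulate_dilution_screen(params, seed=seed,
                                              dilution_effect=effect)
            assays, _ = cohort_to_frames(cohort)
            pci, _ = compute_patient_ci_table(
                assays, rng=np.random.default_rng(seed))
            per = {d: list(zip(sub["mean_ci"], sub["group"]))
                   for d, sub in pci.groupby("dilution", sort=False)}
            best, _ = select_optimal_dilution(per)
            hits += best == "1:100"
        assert hits >= 0.95 * n_runs

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            select_optimal_dilution({"1:10": [(0.2, "cancer")],
                                     "1:100": [(0.2, "cancer")]})


class TestEvaluateModels:
    @staticmethod
    def _tables(rng, n=40):
        groups = rng.choice(["cancer", "benign", "negative_screen"], size=n)
        pci = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "group": groups,
            "mean_ci": rng.uniform(-0.6, 0.6, n),
        })
        pts = pd.DataFrame({
            "patient_id": pci["patient_id"], "group": groups,
            "psa_ng_ml": rng.uniform(2.5, 20, n),
        })
        return pci, pts

    def test_and_rule_monotonicity(self, rng):
        """Combined rule never loses specificity nor gains sensitivity
        relative to either single rule."""
        for _ in range(10):
            pci, pts = self._tables(rng)
            if pci.groupby(pci["group"] == "cancer").ngroups < 2:
                continue
            rep = evaluate_models(pci, pts).set_index("model")
            comb = rep.loc["combined_rule"]
            for single in ("ci_rule", "psa_rule"):
                assert comb["specificity"] >= rep.loc[single, "specificity"] - 1e-12
                assert comb["sensitivity"] <= rep.loc[single, "sensitivity"] + 1e-12

    def test_missing_psa_excluded_from_psa_models_only(self, rng):
        pci, pts = self._tables(rng, n=30)
        pts.loc[:4, "psa_ng_ml"] = np.nan
        rep = evaluate_models(pci, pts).set_index("model")
        assert rep.loc["ci_rule", "n"] == 30
        assert rep.loc["psa_rule", "n"] == 25
        assert rep.loc["psa_rule", "n_excluded"] == 5
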