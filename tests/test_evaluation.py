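"""Evaluation metrics against enumeration oracles and hand arithmetic."""
import numpy as np
import pandas as pd
import pytest

import soyclass as sc
from soyclass.evaluation import ConfusionMatrix3, one_vs_rest_counts
from soyclass.selection_index import CLASS_ORDER, CLASS_RANK

from conftest import make_gblups


def random_preds(rng, n=60):
    labels = np.asarray(CLASS_ORDER, dtype=object)
    return pd.DataFrame({
        "genotype_id": [f"g{i}" for i in range(n)],
        "repetition": 0,
        "true_class": rng.choice(labels, n),
        "predicted_class": rng.choice(labels, n),
    })


def brute_force_counts(preds, focal):
    tp = tn = fp = fn = 0
    for t, p in zip(preds["true_class"], preds["predicted_class"]):
        if p == focal and t == focal:
            tp += 1
        elif p == focal and t != focal:
            fp += 1
        elif p != focal and t == focal:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        preds = pd.DataFrame({"true_class": list(CLASS_ORDER),
                              "predicted_class": list(CLASS_ORDER)})
        cm = sc.confusion_matrix(preds)
        assert np.all(cm.counts == np.eye(3, dtype=int))

    def test_single_record_lands_in_the_right_cell(self):
        cm = sc.confusion_matrix(pd.DataFrame(
            {"true_class": ["low"], "predicted_class": ["high"]}))
        expect = np.zeros((3, 3), dtype=int)
        expect[CLASS_RANK["low"], CLASS_RANK["high"]] = 1
        assert np.all(cm.counts == expect)

    def test_pooled_counts_are_additive_over_repetitions(self, rng):
        a, b = random_preds(rng, 40), random_preds(rng, 25)
        combined = pd.concat([a, b], ignore_index=True)
        assert np.all(sc.confusion_matrix(combined).counts ==
                      (sc.confusion_matrix(a) + sc.confusion_matrix(b)).counts)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            sc.confusion_matrix(pd.DataFrame(
                {"true_class": ["great"], "predicted_class": ["low"]}))


class TestMetricOracles:
    def test_metrics_match_per_record_enumeration(self):
        """100 random prediction sets: every metric equals a brute-force
        recount, and accuracy/kappa agree with scikit-learn."""
        from sklearn.metrics import accuracy_score, cohen_kappa_score

        for seed in range(100):
            rng = np.random.default_rng(seed)
            preds = random_preds(rng, n=int(rng.integers(10, 80)))
            cm = sc.confusion_matrix(preds)
            n = len(preds)
            for focal in CLASS_ORDER:
                tp, tn, fp, fn = brute_force_counts(preds, focal)
                m = sc.class_metrics(cm, focal)
                assert (m["tp"], m["tn"], m["fp"], m["fn"]) == (tp, tn, fp, fn)
                for name, num, den in [
                        ("sensitivity", tp, tp + fn), ("specificity", tn, tn + fp),
                        ("precision", tp, tp + fp), ("npv", tn, tn + fn),
                        ("prevalence", tp + fn, n), ("detection_rate", tp, n),
                        ("detection_prevalence", tp + fp, n)]:
                    if den == 0:
                        assert np.isnan(m[name]) and name in m["undefined"]
                    else:
                        assert m[name] == pytest.approx(num / den, abs=1e-12)
            overall = sc.overall_metrics(cm)
            assert overall.accuracy == pytest.approx(
                accuracy_score(preds["true_class"], preds["predicted_class"]))
            assert overall.kappa == pytest.approx(cohen_kappa_score(
                preds["true_class"], preds["predicted_class"],
                labels=list(CLASS_ORDER)), abs=1e-12)

    def test_macro_equals_unweighted_mean(self, rng):
        preds = random_preds(rng, 50)
        cm = sc.confusion_matrix(preds)
        table = sc.class_metrics_table(cm)
        overall = sc.overall_metrics(cm, table)
        for m in ("sensitivity", "specificity", "f1", "balanced_accuracy"):
            assert overall.macro[f"macro_{m}"] == pytest.approx(
                table[m].mean(), abs=1e-12)

    def test_detection_inequalities(self, rng):
        preds = random_preds(rng, 70)
        table = sc.class_metrics_table(sc.confusion_matrix(preds))
        assert (table["detection_rate"] <= table["prevalence"] + 1e-12).all()
        assert (table["detection_rate"] <= table["detection_prevalence"] + 1e-12).all()


class TestOverallMetrics:
    def test_kappa_limits(self):
        perfect = ConfusionMatrix3(np.diag([10, 20, 30]))
        assert sc.overall_metrics(perfect).kappa == pytest.approx(1.0)
        all_majority = ConfusionMatrix3(np.array(
            [[0, 10, 0], [0, 20, 0], [0, 5, 0]]))
        assert sc.overall_metrics(all_majority).kappa == pytest.approx(0.0)

    def test_mcnemar_arithmetic(self):
        # (low,moderate)=10 gives b=c=10 for both collapses -> chi2 = 0
        cm = ConfusionMatrix3(np.array([[5, 10, 0], [10, 5, 0], [0, 0, 5]]))
        rep = sc.overall_metrics(cm)
        assert rep.mcnemar.loc["low", "chi2"] == pytest.approx(0.0)
        # b=5, c=0 -> chi2 = 5
        cm2 = ConfusionMatrix3(np.array([[5, 0, 0], [5, 5, 0], [0, 0, 5]]))
        rep2 = sc.overall_metrics(cm2)
        t = one_vs_rest_counts(cm2, "low")
        assert (t["fp"], t["fn"]) == (5, 0)
        assert rep2.mcnemar.loc["low", "chi2"] == pytest.approx(5.0)
        # b + c = 0 -> undefined, flagged
        assert bool(sc.overall_metrics(ConfusionMatrix3(np.diag([4, 4, 4])))
                    .mcnemar.loc["low", "undefined"])

    def test_nir_and_ci_consistency(self, rng):
        preds = random_preds(rng, 90)
        cm = sc.confusion_matrix(preds)
        rep = sc.overall_metrics(cm)
        assert rep.nir == pytest.approx(cm.counts.sum(axis=1).max() / cm.total)
        lo, hi = rep.accuracy_ci95
        assert lo <= rep.accuracy <= hi
        # one-sided exact binomial direction is consistent with accuracy vs NIR
        if rep.accuracy > rep.nir:
            assert rep.p_acc_gt_nir < 0.5 + 1e-9


class TestSeverity:
    @pytest.mark.parametrize("t,p,kind", [
        ("low", "moderate", "mild"), ("low", "high", "extreme"),
        ("high", "low", "extreme"), ("moderate", "moderate", "correct")])
    def test_ordinal_distance_classification(self, t, p, kind):
        rep = sc.severity_analysis(pd.DataFrame(
            {"true_class": [t], "predicted_class": [p]}))
        assert rep.proportions[kind] == 1.0

    def test_consistent_with_confusion_offdiagonals(self, rng):
        for seed in range(20):
            preds = random_preds(np.random.default_rng(seed), 50)
            cm = sc.confusion_matrix(preds).to_frame()
            rep = sc.severity_analysis(preds)
            assert sum(rep.proportions.values()) == pytest.approx(1.0)
            assert rep.counts["extreme"] == cm.loc["low", "high"] + cm.loc["high", "low"]
            assert rep.counts["correct"] == np.trace(cm.to_numpy())


class TestDecisionRule:
    def test_threshold_boundaries(self):
        probs = pd.DataFrame({"genotype_id": ["a", "b", "c"],
                              "p_low": [0.75, 0.0, 0.70]})
        dec = sc.apply_decision_rule(probs, 0.70)
        got = dec.table.set_index("genotype_id")["decision"]
        assert got["a"] == "discard" and got["b"] == "advance"
        assert got["c"] == "discard"  # boundary inclusive
        assert dec.discard_fraction == pytest.approx(2 / 3)

    def test_invalid_threshold_rejected(self):
        probs = pd.DataFrame({"genotype_id": ["a"], "p_low": [0.5]})
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                sc.apply_decision_rule(probs, bad)

    def test_discard_set_has_lower_true_index_under_strong_signal(self):
        """Decision utility: screening probabilities from a quick forest on
        strongly genetic classes must concentrate low-index genotypes in the
        discard set (aggregated over 10 seeds)."""
        from sklearn.ensemble import RandomForestClassifier

        gaps = []
        for seed in range(10):
            cfg = sc.small_config(seed=seed, n_families=24, lines_per_family=8,
                                  n_markers=120, n_checks=6, sigma2_g=60_000.0,
                                  lambda_loadings=[40.0, 60.0, 80.0],
                                  psi_diag=[2000.0] * 3, sigma2_e=15_000.0)
            data = sc.simulate_dataset(cfg)
            lines = ~data.markers.genotype_meta["is_check"].to_numpy()
            X = data.markers_complete.subset_genotypes(lines).codes
            y = data.truth.true_class[lines]
            msi = data.truth.true_msi[lines]
            half = len(y) // 2
            clf = RandomForestClassifier(n_estimators=150, random_state=seed)
            clf.fit(X[:half], y[:half])
            p_low = clf.predict_proba(X[half:])[:, list(clf.classes_).index("low")]
            probs = pd.DataFrame({"genotype_id": np.arange(len(p_low)),
                                  "p_low": p_low})
            dec = sc.apply_decision_rule(probs, 0.5).table
            m = msi[half:]
            discard = dec["decision"].to_numpy() == "discard"
            if discard.any() and (~discard).any():
                gaps.append(m[~discard].mean() - m[discard].mean())
        assert np.mean(gaps) > 0


class TestDiversityDiagnostic:
    def _pca(self, points, ids):
        return sc.PCAResult(np.asarray(ids, dtype=object), np.asarray(points, float),
                            np.array([0.6, 0.3]))

    def _decisions(self, ids, decisions):
        table = pd.DataFrame({"genotype_id": ids, "p_low": 0.5,
                              "decision": decisions, "rule": "manual"})
        from soyclass.evaluation import DecisionTable
        return DecisionTable(table, 0.7, float(np.mean(
            np.asarray(decisions, dtype=object) == "discard")))

    def test_identical_groups_fully_overlap(self, rng):
        pts = rng.normal(size=(40, 2))
        pts[20:] = pts[:20]
        ids = [f"g{i}" for i in range(40)]
        div = sc.diversity_diagnostic(
            self._pca(pts, ids),
            self._decisions(ids, ["advance"] * 20 + ["discard"] * 20))
        # a 95th-percentile radius can exclude at most 5% of an identical cloud
        assert div.overlap_coefficient >= 0.95

    def test_separated_groups_do_not_overlap(self, rng):
        pts = np.vstack([rng.normal(0, 1, size=(20, 2)),
                         rng.normal(100, 1, size=(20, 2))])
        ids = [f"g{i}" for i in range(40)]
        div = sc.diversity_diagnostic(
            self._pca(pts, ids),
            self._decisions(ids, ["advance"] * 20 + ["discard"] * 20))
        assert div.overlap_coefficient == pytest.approx(0.0)

    def test_random_decisions_give_equal_dispersion(self):
        ratios = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = r.normal(size=(200, 2))
            ids = [f"g{i}" for i in range(200)]
            dec = np.asarray(["advance"] * 100 + ["discard"] * 100, dtype=object)
            r.shuffle(dec)
            div = sc.diversity_diagnostic(self._pca(pts, ids),
                                          self._decisions(ids, dec))
            ratios.append(div.dispersion["discard"] / div.dispersion["advance"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_small_group_flagged(self, rng):
        pts = rng.normal(size=(5, 2))
        ids = [f"g{i}" for i in range(5)]
        div = sc.diversity_diagnostic(
            self._pca(pts, ids),
            self._decisions(ids, ["advance"] * 3 + ["discard"] * 2))
        assert any("discard" in f for f in div.flags)
        assert np.isnan(div.dispersion["discard"])
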