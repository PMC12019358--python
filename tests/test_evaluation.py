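"""Micro-F1, Cohen's kappa, human-eval report, learning-curve harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, f1_score

from switchscope.evaluation import (
    auto_annotations,
    cohens_kappa,
    human_eval_report,
    learning_curve,
    micro_f1,
)


class TestMicroF1:
    def test_perfect_agreement(self):
        labels = ["Oral", "IUD", "Implant", "Oral"]
        p, r, f = micro_f1(labels, labels)
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_enumerated_counts(self):
        # TP=1 (first Oral), FP=1 (Oral on IUD gold), FN=2 (that IUD + missed Oral)
        p, r, f = micro_f1(["Oral", "Oral", None], ["Oral", "IUD", "Oral"])
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(1 / 3)
        assert f == pytest.approx(0.4)

    def test_all_none_predictions_score_zero(self):
        _, _, f = micro_f1([None, None], ["Oral", "IUD"])
        assert f == 0.0

    def test_none_on_none_is_not_rewarded(self):
        p, r, f = micro_f1([None, "Oral"], [None, "Oral"])
        assert (p, r, f) == (1.0, 1.0, 1.0)  # the none pair contributes nothing

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        pred = list(rng.choice(["Oral", "IUD", "none"], size=60))
        gold = list(rng.choice(["Oral", "IUD", "none"], size=60))
        base = micro_f1(pred, gold)
        for _ in range(5):
            perm = rng.permutation(60)
            assert micro_f1([pred[i] for i in perm], [gold[i] for i in perm]) == base

    def test_matches_sklearn_micro_average_on_all_positive_labels(self):
        rng = np.random.default_rng(1)
        pred = list(rng.choice(["Oral", "IUD", "Implant"], size=100))
        gold = list(rng.choice(["Oral", "IUD", "Implant"], size=100))
        _, _, f = micro_f1(pred, gold)
        assert f == pytest.approx(f1_score(gold, pred, average="micro"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            micro_f1(["Oral"], ["Oral", "IUD"])


class TestCohensKappa:
    def test_identical_vectors(self):
        assert cohens_kappa(["a", "b", "a"], ["a", "b", "a"]) == pytest.approx(1.0)

    def test_balanced_agreement_table_gives_zero(self):
        # 2x2 agreement table [[5,5],[5,5]]: p_o = p_e = 0.5
        a = ["x"] * 10 + ["y"] * 10
        b = ["x"] * 5 + ["y"] * 5 + ["x"] * 5 + ["y"] * 5
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_perfect_disagreement_balanced_marginals(self):
        a = ["x", "y"] * 10
        b = ["y", "x"] * 10
        assert cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_symmetry_and_relabel_invariance_vs_sklearn(self):
        rng = np.random.default_rng(2)
        a = list(rng.choice(["p", "q", "r"], size=200))
        b = list(rng.choice(["p", "q", "r"], size=200))
        k = cohens_kappa(a, b)
        assert k == pytest.approx(cohens_kappa(b, a))
        assert k == pytest.approx(cohen_kappa_score(a, b))
        relabel = {"p": "z1", "q": "z2", "r": "z3"}
        assert cohens_kappa([relabel[x] for x in a], [relabel[x] for x in b]) == pytest.approx(k)

    def test_constant_labels_undefined(self):
        assert cohens_kappa(["a", "a"], ["a", "a"]) is None

    def test_restriction_drops_pairs_with_none_reference(self):
        a = ["Oral", None, "IUD", None]
        b = ["Oral", "Oral", "IUD", "IUD"]
        # unrestricted: the none rows disagree; restricted: perfect agreement
        assert cohens_kappa(a, b) < 1.0
        assert cohens_kappa(a, b, restrict_to_relevant=True) == pytest.approx(1.0)
        assert cohens_kappa([None, None], ["a", "b"], restrict_to_relevant=True) is None


_LABELS = st.sampled_from(["Oral", "IUD", "Implant", "none"])
_PAIRS = st.lists(st.tuples(_LABELS, _LABELS), min_size=1, max_size=40)


@given(pairs=_PAIRS)
@settings(derandomize=True, max_examples=80)
def test_micro_f1_bounded_and_one_iff_positive_positions_match(pairs):
    pred, gold = zip(*pairs)
    p, r, f = micro_f1(pred, gold)
    assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f <= 1.0
    positive_positions = [(x, y) for x, y in pairs if x != "none" or y != "none"]
    all_match = bool(positive_positions) and all(x == y for x, y in positive_positions)
    assert (f == 1.0) == all_match


@given(pairs=_PAIRS)
@settings(derandomize=True, max_examples=80)
def test_kappa_symmetric_and_bounded(pairs):
    a, b = (list(x) for x in zip(*pairs))
    k = cohens_kappa(a, b)
    assert k == cohens_kappa(b, a)
    if k is not None:
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12


class TestHumanEvalReport:
    def _frames(self, n=93, n_halluc=2):
        ids = [f"N{i}" for i in range(n)]
        pred = pd.DataFrame({"note_id": ids, "stopped": "Oral", "started": "IUD"})
        ann = pd.DataFrame(
            {
                "note_id": ids,
                "gold_stopped": "Oral",
                "gold_started": "IUD",
                "reason_accurate": True,
                "hallucination": [i < n_halluc for i in range(n)],
            }
        )
        return pred, ann

    def test_accuracy_and_hallucination_fractions(self):
        pred, ann = self._frames()
        rep = human_eval_report(pred, ann)
        assert rep.accuracy == 1.0
        assert rep.hallucination_rate == pytest.approx(2 / 93)
        assert rep.n == 93
        assert rep.started["micro_f1"] == 1.0

    def test_missing_booleans_excluded_from_denominator(self):
        pred, ann = self._frames(n=10, n_halluc=0)
        ann.loc[:4, "reason_accurate"] = None
        rep = human_eval_report(pred, ann)
        assert rep.accuracy == 1.0  # only the 5 annotated records count

    def test_disjoint_ids_rejected(self):
        pred, ann = self._frames(n=4)
        ann["note_id"] = ["X1", "X2", "X3", "X4"]
        with pytest.raises(ValueError, match="overlap"):
            human_eval_report(pred, ann)


def test_auto_annotations_flags_fabricated_reason():
    pred = pd.DataFrame(
        {"note_id": ["N1", "N2"], "stopped": "Oral", "started": "IUD",
         "reason": ["documented spotting", "invented text"]}
    )
    gold = pd.DataFrame(
        {"note_id": ["N1", "N2"], "true_stopped": "Oral", "true_started": "IUD",
         "true_reason_topic": "t", "true_reason_text": ["documented spotting", "other reason"]}
    )
    notes = pd.DataFrame(
        {"note_id": ["N1", "N2"], "patient_id": "P", "encounter_date": 0,
         "text": ["... documented spotting ...", "... other reason ..."]}
    )
    ann = auto_annotations(pred, gold, notes)
    assert ann["reason_accurate"].tolist() == [True, False]
    assert ann["hallucination"].tolist() == [False, True]


class TestLearningCurve:
    def _separable_corpus(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        vocab = {"Oral": "pill tablet daily", "IUD": "device uterine coil", "Implant": "arm rod insert"}
        labels = list(rng.choice(list(vocab), size=n))
        texts = [f"{vocab[l]} visit note {rng.integers(5)}" for l in labels]
        return texts, labels

    def test_full_fraction_perfect_on_separable_corpus(self):
        texts, labels = self._separable_corpus()
        out = learning_curve(texts, labels, fractions=(1.0,), k=3, seed=0)
        assert out.loc[0, "mean_micro_f1"] == pytest.approx(1.0)

    def test_more_training_data_never_hurts_on_average(self):
        gains = 0
        for seed in range(10):
            texts, labels = self._separable_corpus(seed=seed)
            out = learning_curve(texts, labels, fractions=(1.0, 0.02), k=3, seed=seed)
            full, tiny = out["mean_micro_f1"].tolist()
            gains += full >= tiny or np.isnan(tiny)
        assert gains == 10

    def test_empty_fraction_list_gives_empty_report(self):
        out = learning_curve(["a b", "c d"], ["x", "y"], fractions=())
        assert out.empty

    def test_single_class_subsample_skipped_with_warning(self):
        texts = ["alpha"] * 50 + ["beta"] * 50
        labels = ["A"] * 50 + ["B"] * 50
        with pytest.warns(UserWarning, match="single class"):
            learning_curve(texts, labels, fractions=(0.01,), k=5, seed=0)
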