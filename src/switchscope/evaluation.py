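"""Scoring of note-level extractions against gold and silver labels.

Both tasks (contraceptive started, contraceptive stopped) are multi-class
over the six modalities with "none" excluded from the positive set:
micro-averaging pools true/false positives and false negatives across the
positive labels, so predicting none on a positive gold costs a false
negative and predicting a modality on gold none costs a false positive.
Cohen's kappa measures chance-corrected agreement between two label
sources (e.g. structured-data silver labels vs human annotation), with an
optional restriction that drops pairs where the human label is none.

The learning-curve harness trains generic bag-of-words / TF-IDF
classifiers on silver labels at decreasing training fractions under
repeated 70/10/20 resplits, the standard weak-supervision baseline for a
zero-shot extractor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline

__all__ = [
    "EvalReport",
    "micro_f1",
    "cohens_kappa",
    "human_eval_report",
    "learning_curve",
    "NONE_LABEL",
]

NONE_LABEL = "none"


def _canon(label) -> str:
    """Canonicalise a label: Modality / str / None / NaN -> plain string."""
    if label is None:
        return NONE_LABEL
    if isinstance(label, float) and np.isnan(label):
        return NONE_LABEL
    s = getattr(label, "value", label)
    s = str(s).strip()
    return s if s else NONE_LABEL


def micro_f1(
    predictions, gold, positive_labels=None
) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1) pooled over positive labels.

    ``positive_labels`` defaults to every label observed except none.
    F1 is 0 when there are no true positives.
    """
    pred = [_canon(x) for x in predictions]
    true = [_canon(x) for x in gold]
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(true)} gold")
    if positive_labels is None:
        positive = {x for x in pred + true if x != NONE_LABEL}
    else:
        positive = {_canon(x) for x in positive_labels} - {NONE_LABEL}
    tp = fp = fn = 0
    for p, t in zip(pred, true):
        if p in positive and p == t:
            tp += 1
        else:
            if p in positive:
                fp += 1
            if t in positive:
                fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    return precision, recall, f1


def cohens_kappa(labels_a, labels_b, *, restrict_to_relevant: bool = False):
    """Cohen's kappa = (p_o - p_e) / (1 - p_e), with p_e from marginals.

    ``labels_a`` is treated as the human/reference source: with
    ``restrict_to_relevant`` pairs where it is none are dropped before
    scoring. Returns None (undefined) when p_e = 1 or nothing remains
    after restriction.
    """
    a = [_canon(x) for x in labels_a]
    b = [_canon(x) for x in labels_b]
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if restrict_to_relevant:
        pairs = [(x, y) for x, y in zip(a, b) if x != NONE_LABEL]
        if not pairs:
            return None
        a, b = (list(t) for t in zip(*pairs))
    n = len(a)
    if n == 0:
        return None
    labels = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(l) / n) * (b.count(l) / n) for l in labels)
    if abs(1.0 - p_e) < 1e-12:
        return None
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class EvalReport:
    started: dict  # micro precision/recall/f1
    stopped: dict
    accuracy: float | None
    hallucination_rate: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "started": self.started,
            "stopped": self.stopped,
            "accuracy": self.accuracy,
            "hallucination_rate": self.hallucination_rate,
            "n": self.n,
        }


def _task_scores(pred, gold) -> dict:
    p, r, f = micro_f1(pred, gold)
    return {"micro_precision": p, "micro_recall": r, "micro_f1": f}


def human_eval_report(results: pd.DataFrame, annotations: pd.DataFrame) -> EvalReport:
    """Score extractions against human annotation records.

    ``results`` columns: note_id, stopped, started, (reason). ``annotations``
    columns: note_id, gold_stopped, gold_started, and optional boolean
    reason_accurate / hallucination columns whose missing values are
    excluded from their denominators.
    """
    merged = results.merge(annotations, on="note_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping note_ids between results and annotations")
    report = EvalReport(
        started=_task_scores(merged["started"], merged["gold_started"]),
        stopped=_task_scores(merged["stopped"], merged["gold_stopped"]),
        accuracy=None,
        hallucination_rate=None,
        n=len(merged),
    )
    for col, attr in (("reason_accurate", "accuracy"), ("hallucination", "hallucination_rate")):
        if col in merged.columns:
            vals = merged[col].dropna()
            if len(vals):
                setattr(report, attr, float(vals.astype(bool).mean()))
    return report


def auto_annotations(
    results: pd.DataFrame, gold: pd.DataFrame, notes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Adjudicate extracted reasons against note-level gold labels.

    Stands in for a human reviewer on synthetic data, where the gold
    records are exact: ``reason_accurate`` is whether the extracted reason
    matches the note's true reason (both empty counts as accurate), and
    ``hallucination`` is whether a non-empty extracted reason cannot be
    found verbatim in the source note.
    """
    g = gold.rename(columns={"true_stopped": "gold_stopped", "true_started": "gold_started"})
    merged = results.merge(
        g[["note_id", "gold_stopped", "gold_started", "true_reason_text"]],
        on="note_id",
        how="inner",
    )
    pred_reason = merged["reason"].fillna("").str.strip()
    true_reason = merged["true_reason_text"].fillna("").str.strip()
    merged["reason_accurate"] = pred_reason == true_reason
    if notes is not None:
        text = merged["note_id"].map(notes.set_index("note_id")["text"]).fillna("")
        merged["hallucination"] = [
            bool(r) and r not in t for r, t in zip(pred_reason, text)
        ]
    else:
        merged["hallucination"] = False
    return merged[
        ["note_id", "gold_stopped", "gold_started", "reason_accurate", "hallucination"]
    ]


_MODEL_SPECS = {
    "logreg-bow": lambda seed: make_pipeline(
        CountVectorizer(), LogisticRegression(max_iter=2000, random_state=seed)
    ),
    "logreg-tfidf": lambda seed: make_pipeline(
        TfidfVectorizer(), LogisticRegression(max_iter=2000, random_state=seed)
    ),
    "rf-bow": lambda seed: make_pipeline(
        CountVectorizer(), RandomForestClassifier(n_estimators=100, random_state=seed)
    ),
    "rf-tfidf": lambda seed: make_pipeline(
        TfidfVectorizer(), RandomForestClassifier(n_estimators=100, random_state=seed)
    ),
}


def learning_curve(
    texts,
    labels,
    fractions=(1.0, 0.5, 0.25, 0.10, 0.05, 0.01),
    model: str = "logreg-bow",
    *,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean/SD micro F1 per training fraction over k random 70/10/20 resplits.

    Each replicate draws a fresh 70/10/20 train/validation/test split, then
    subsamples the training portion to the requested fraction before
    fitting. A replicate in which the subsample collapses to fewer than two
    classes is skipped with a warning. ``model`` is a key of the built-in
    bag-of-words / TF-IDF specs or any estimator factory ``f(seed)``
    returning an object with fit/predict.
    """
    texts = list(texts)
    y = np.array([_canon(l) for l in labels])
    if len(texts) != len(y):
        raise ValueError("texts and labels length mismatch")
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")
    factory = _MODEL_SPECS[model] if isinstance(model, str) else model
    rows = []
    rng = np.random.default_rng(seed)
    for frac in fractions:
        scores = []
        for fold in range(k):
            fold_seed = int(rng.integers(0, 2**31 - 1))
            rs = np.random.default_rng(fold_seed)
            idx = rs.permutation(len(texts))
            n_train = int(round(0.7 * len(texts)))
            n_val = int(round(0.1 * len(texts)))
            train, test = idx[:n_train], idx[n_train + n_val :]
            m = max(1, int(round(frac * len(train))))
            sub = train[:m]
            if len(set(y[sub])) < 2:
                warnings.warn(
                    f"fraction {frac}, replicate {fold}: training subsample has a "
                    "single class; skipped"
                )
                continue
            clf = factory(fold_seed % (2**31 - 1))
            clf.fit([texts[i] for i in sub], y[sub])
            pred = clf.predict([texts[i] for i in test])
            _, _, f1 = micro_f1(pred, y[test])
            scores.append(f1)
        rows.append(
            {
                "fraction": frac,
                "mean_micro_f1": float(np.mean(scores)) if scores else np.nan,
                "sd_micro_f1": float(np.std(scores, ddof=1)) if len(scores) > 1 else np.nan,
                "n_folds": len(scores),
            }
        )
    return pd.DataFrame(rows, columns=["fraction", "mean_micro_f1", "sd_micro_f1", "n_folds"])
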