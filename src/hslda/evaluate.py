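"""Cross-validated classification metrics and topic-based risk stratification.

Protocol: stratified k-fold cross-validation (stratification matters because
diagnosis classes are heavily imbalanced — losing a 12-sample class from a
fold invalidates macro metrics); per-class precision/recall with 0/0 := 0;
macro scores are unweighted class means, macro-F1 the mean of per-class F1.
All metric values are on the percentage scale (accuracy 75.0, not 0.75).

Risk stratification ranks topics by the class coefficients η_c: the top
topics form the class's high-risk tier, the bottom ones the low-risk tier,
and within a tier feature-value pairs are scored by
Σ_k softplus(±η_{c,k}) · β_{k,v} · π_{k,feature(v)} — a reconstruction of the
tiered risk-factor tables this family of models is used to produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .corpus import Corpus, CorpusError, Document
from .model import FitConfig, FittedModel, fit, predict
from .preprocess import WeightingConfig, smote_oversample

__all__ = [
    "stratified_kfold",
    "macro_metrics",
    "cross_validate",
    "risk_factor_table",
    "RiskTable",
    "CVResult",
]


def stratified_kfold(corpus: Corpus, folds: int, seed: int) -> list[tuple[list[int], list[int]]]:
    """Deterministic stratified partition; per-class fold sizes differ by ≤ 1."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = []
    for doc in corpus.documents:
        if doc.label is None:
            raise CorpusError(f"document {doc.doc_id!r} is unlabeled")
        labels.append(doc.label)
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=corpus.n_classes)
    small = [corpus.class_names[c] for c in np.where(counts < folds)[0] if counts[c] > 0]
    if small or np.any(counts == 0):
        raise CorpusError(f"every class needs >= {folds} documents (too small: {small})")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [
        (train.tolist(), test.tolist())
        for train, test in skf.split(np.zeros(len(labels)), labels)
    ]


def macro_metrics(truth, predicted, C: int):
    """(accuracy, macro-P, macro-R, macro-F1, confusion matrix), percentages.

    Confusion rows are true classes, columns predictions.  Per-class scores
    with empty denominators are defined as 0; macro scores are unweighted
    means over all C classes.
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape or truth.size == 0:
        raise ValueError("truth and predicted must be equal-length, non-empty")
    cm = _sk_confusion(truth, predicted, labels=np.arange(C))
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / np.where(pred_tot > 0, pred_tot, 1.0), 0.0)
        rec = np.where(true_tot > 0, tp / np.where(true_tot > 0, true_tot, 1.0), 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1.0), 0.0)
    accuracy = 100.0 * tp.sum() / cm.sum()
    return (
        float(accuracy),
        float(100.0 * prec.mean()),
        float(100.0 * rec.mean()),
        float(100.0 * f1.mean()),
        cm,
    )


@dataclass
class CVResult:
    per_fold: pd.DataFrame
    means: dict
    confusion: np.ndarray  # summed over folds


def cross_validate(
    corpus: Corpus,
    config: FitConfig,
    folds: int = 5,
    seed: int = 0,
    smote_in_fold: bool = False,
    smote_config: WeightingConfig | None = None,
) -> CVResult:
    """Fit/predict over stratified folds; optionally SMOTE each training fold.

    With ``smote_in_fold=False`` the corpus is used as given (balance it
    beforehand to reproduce the balance-then-split protocol); with True, SMOTE
    runs on the training fold only, keeping synthetic points out of test sets.
    """
    rows = []
    confusion = np.zeros((corpus.n_classes, corpus.n_classes), dtype=int)
    for fold, (train_ids, test_ids) in enumerate(stratified_kfold(corpus, folds, seed)):
        train = corpus.subset(train_ids)
        if smote_in_fold:
            train = smote_oversample(train, smote_config or WeightingConfig(seed=seed))
        model = fit(train, config)
        truth, pred = [], []
        for i in test_ids:
            doc = corpus.documents[i]
            c, _, _ = predict(doc, model)
            truth.append(doc.label)
            pred.append(c)
        acc, mp, mr, mf1, cm = macro_metrics(truth, pred, corpus.n_classes)
        confusion += cm
        rows.append(
            {
                "fold": fold,
                "n_test": len(test_ids),
                "accuracy": acc,
                "macro_precision": mp,
                "macro_recall": mr,
                "macro_f1": mf1,
            }
        )
    per_fold = pd.DataFrame(rows)
    means = {
        k: float(per_fold[k].mean())
        for k in ("accuracy", "macro_precision", "macro_recall", "macro_f1")
    }
    return CVResult(per_fold, means, confusion)


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------


@dataclass
class RiskTable:
    """Per class: high/low risk tiers as ranked (value name, topic, score) lists."""

    tiers: dict[str, dict[str, list[tuple[str, int, float]]]] = field(default_factory=dict)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def risk_factor_table(model: FittedModel, top_topics: int = 1, top_pairs: int = 5) -> RiskTable:
    """Rank topics by η_c into high/low tiers and list each tier's dominant pairs.

    Pair score within a tier: Σ_{k∈tier} softplus(η_{c,k})·β_{k,v}·π_{k,f(v)}
    for the high tier (softplus(−η) for the low tier), so topics contribute in
    proportion to the rectified strength of their class coefficient and pairs
    in proportion to their generative probability under those topics.
    """
    params = model.params
    K = params.n_topics
    if 2 * top_topics > K:
        raise ValueError(f"2*top_topics={2 * top_topics} exceeds K={K}")
    vf = params.value_feature
    V = len(vf)
    table = RiskTable()
    for c, name in enumerate(model.class_names):
        order = np.argsort(params.eta[c])[::-1]
        high = order[:top_topics]
        low = order[-top_topics:]
        tiers = {}
        for tier_name, topics, sign in (("high", high, 1.0), ("low", low, -1.0)):
            weights = _softplus(sign * params.eta[c, topics])
            scores = np.zeros(V)
            for w, k in zip(weights, topics):
                scores += w * params.beta[k] * params.pi[k, vf]
            ranked = np.argsort(-scores, kind="stable")[:top_pairs]
            best_topic = {
                v: int(topics[np.argmax([params.beta[k, v] * params.pi[k, vf[v]] for k in topics])])
                for v in ranked
            }
            tiers[tier_name] = [
                (model.vocabulary.values[v], best_topic[v], float(scores[v])) for v in ranked
            ]
        table.tiers[name] = tiers
    return table


def risk_table_frame(table: RiskTable) -> pd.DataFrame:
    rows = []
    for cls, tiers in table.tiers.items():
        for tier, entries in tiers.items():
            for rank, (value, topic, score) in enumerate(entries, start=1):
                rows.append(
                    {"class": cls, "tier": tier, "rank": rank, "value": value,
                     "topic": topic, "score": score}
                )
    return pd.DataFrame(rows)
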