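"""Raw tabular data → weighted feature-value corpus.

Three stages, each optional and composable:

1. :func:`discretize` — map raw per-patient columns to feature-value tokens
   using a guideline-driven binning specification (categorical pass-through or
   half-open numeric intervals [lo, hi)).
2. :func:`tfidf_weight` — weight each token by tf · ln(D/df), tf being the
   within-document count of its pair and df the number of documents containing
   the pair; zero weights (ubiquitous pairs) are floored to 1e−8 so the
   weighted likelihood stays defined.
3. :func:`smote_oversample` — raise every minority class to the majority count
   by SMOTE interpolation in the dense per-document weight space over V.

Missing-data imputation is deliberately a pluggable pre-hook: pass the raw
table through your imputer (e.g. a random-forest imputer) before
:func:`discretize`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.neighbors import NearestNeighbors

from .corpus import Corpus, CorpusError, Document, Token, Vocabulary

__all__ = [
    "BinningSpec",
    "WeightingConfig",
    "discretize",
    "tfidf_weight",
    "smote_oversample",
]

WEIGHT_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# binning specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NumericBins:
    labels: tuple[str, ...]
    edges: tuple[float, ...]  # len(labels)+1 strictly increasing; bins [lo, hi)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.labels) + 1:
            raise CorpusError("numeric bins need len(labels)+1 edges")
        if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
            raise CorpusError("bin edges must be strictly increasing")

    def assign(self, x: float) -> int:
        for i in range(len(self.labels)):
            if self.edges[i] <= x < self.edges[i + 1]:
                return i
        raise CorpusError(f"value {x} outside all bins {self.edges}")


@dataclass(frozen=True)
class CategoricalBins:
    labels: tuple[str, ...]

    def assign(self, x) -> int:
        try:
            return self.labels.index(str(x))
        except ValueError:
            raise CorpusError(f"category {x!r} not in {self.labels}") from None


@dataclass
class BinningSpec:
    """Ordered per-feature binning rules (spec order fixes the vocabulary)."""

    features: dict[str, NumericBins | CategoricalBins] = field(default_factory=dict)

    def vocabulary(self) -> Vocabulary:
        pairs = []
        for feature, bins in self.features.items():
            for label in bins.labels:
                pairs.append((f"{feature}_{label}", feature))
        return Vocabulary.from_pairs(pairs)

    @classmethod
    def from_yaml(cls, path) -> "BinningSpec":
        """Load a spec file: a list of ``{name, type, values|bins}`` entries."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        features: dict[str, NumericBins | CategoricalBins] = {}
        for entry in raw["features"]:
            name = entry["name"]
            if entry["type"] == "categorical":
                features[name] = CategoricalBins(tuple(str(v) for v in entry["values"]))
            elif entry["type"] == "numeric":
                labels = tuple(b["label"] for b in entry["bins"])
                edges = [entry["bins"][0]["lo"]] + [b["hi"] for b in entry["bins"]]
                features[name] = NumericBins(labels, tuple(float(e) for e in edges))
            else:
                raise CorpusError(f"feature {name!r}: unknown type {entry['type']!r}")
        return cls(features)


@dataclass
class WeightingConfig:
    scheme: str = "tfidf"  # "none" | "tfidf"
    smote: bool = True
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("none", "tfidf"):
            raise ValueError("scheme must be 'none' or 'tfidf'")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def discretize(
    raw_table: pd.DataFrame,
    spec: BinningSpec,
    label_column: str | None = "label",
    class_names: tuple[str, ...] | None = None,
) -> Corpus:
    """One document per row, one token per feature named in the spec.

    Missing cells are a hard error (impute upstream); numeric values outside
    every bin are a hard error naming the row and column.
    """
    vocab = spec.vocabulary()
    feature_names = list(spec.features)
    for feature in feature_names:
        if feature not in raw_table.columns:
            raise CorpusError(f"raw table lacks column {feature!r}")
    value_offset: dict[str, int] = {}
    off = 0
    for feature, bins in spec.features.items():
        value_offset[feature] = off
        off += len(bins.labels)
    labels_raw = None
    if label_column is not None and label_column in raw_table.columns:
        labels_raw = raw_table[label_column].astype(str)
        if class_names is None:
            class_names = tuple(dict.fromkeys(s for s in labels_raw if s not in ("-", "nan")))
    class_names = class_names or ()
    label_index = {name: i for i, name in enumerate(class_names)}
    documents = []
    for i, (_, row) in enumerate(raw_table.iterrows()):
        tokens = []
        for f_idx, feature in enumerate(feature_names):
            cell = row[feature]
            if pd.isna(cell):
                raise CorpusError(
                    f"row {i}, column {feature!r}: missing value — impute before discretizing "
                    "(imputation is a pluggable pre-hook)"
                )
            bins = spec.features[feature]
            try:
                b = bins.assign(float(cell) if isinstance(bins, NumericBins) else cell)
            except CorpusError as exc:
                raise CorpusError(f"row {i}, column {feature!r}: {exc}") from None
            tokens.append(Token(f_idx, value_offset[feature] + b, 1.0))
        label = None
        if labels_raw is not None and labels_raw.iloc[i] not in ("-", "nan"):
            label = label_index[labels_raw.iloc[i]]
        documents.append(Document(str(i), tokens, label))
    return Corpus(vocab, documents, class_names)


def tfidf_weight(corpus: Corpus) -> Corpus:
    """Reweight every token by tf·idf, idf = ln(D/df); zero weights floored.

    tf is the within-document occurrence count of the token's (feature, value)
    pair; df the number of documents containing it.  The input corpus is left
    unmodified; duplicate tokens stay distinct (each carries the full tf·idf of
    its pair, and the model sums their sufficient statistics).
    """
    D = corpus.n_documents
    if D == 0:
        raise CorpusError("cannot weight an empty corpus")
    df: dict[int, int] = {}
    for doc in corpus.documents:
        for v in {t.value for t in doc.tokens}:
            df[v] = df.get(v, 0) + 1
    documents = []
    for doc in corpus.documents:
        tf: dict[int, int] = {}
        for t in doc.tokens:
            tf[t.value] = tf.get(t.value, 0) + 1
        tokens = []
        for t in doc.tokens:
            w = tf[t.value] * math.log(D / df[t.value])
            tokens.append(Token(t.feature, t.value, w if w > 0 else WEIGHT_FLOOR))
        documents.append(Document(doc.doc_id, tokens, doc.label))
    return Corpus(corpus.vocabulary, documents, corpus.class_names)


def _dense_vectors(corpus: Corpus) -> np.ndarray:
    X = np.zeros((corpus.n_documents, corpus.vocabulary.n_values))
    for i, doc in enumerate(corpus.documents):
        for t in doc.tokens:
            X[i, t.value] += t.weight
    return X


def smote_oversample(corpus: Corpus, config: WeightingConfig) -> Corpus:
    """Balance classes by SMOTE in the dense V-dimensional weight space.

    Each minority class is raised to the majority count with synthetic points
    x + u·(x_nn − x), u ~ Uniform(0,1), x_nn one of the k nearest same-class
    neighbors (Euclidean; k = min(k_neighbors, class size − 1), k = 0 means
    plain duplication).  Synthetic vectors are re-tokenized by keeping strictly
    positive coordinates.  Majority-class documents pass through untouched;
    output size is C · majority-count; deterministic under the config seed.
    """
    C = corpus.n_classes
    counts = np.zeros(C, dtype=int)
    for doc in corpus.documents:
        if doc.label is None:
            raise CorpusError(f"document {doc.doc_id!r} is unlabeled; SMOTE requires labels")
        counts[doc.label] += 1
    if np.any(counts == 0):
        empty = [corpus.class_names[c] for c in np.where(counts == 0)[0]]
        raise CorpusError(f"classes without samples: {empty}")
    target = int(counts.max())
    if np.all(counts == target):
        return corpus
    X = _dense_vectors(corpus)
    vf = np.asarray(corpus.vocabulary.value_feature)
    rng = np.random.default_rng(config.seed)
    documents = list(corpus.documents)
    for c in range(C):
        need = target - counts[c]
        if need == 0:
            continue
        idx = [i for i, doc in enumerate(corpus.documents) if doc.label == c]
        Xc = X[idx]
        k = min(config.k_neighbors, len(idx) - 1)
        if k >= 1:
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)  # column 0 is the point itself
        base_choices = rng.integers(0, len(idx), size=need)
        for j, b in enumerate(base_choices):
            x = Xc[b]
            if k >= 1:
                mate = Xc[neigh[b, 1 + rng.integers(0, k)]]
                x_new = x + rng.uniform() * (mate - x)
            else:
                x_new = x.copy()
            tokens = [
                Token(int(vf[v]), int(v), float(x_new[v]))
                for v in np.nonzero(x_new > 0)[0]
            ]
            documents.append(Document(f"smote_{corpus.class_names[c]}_{j}", tokens, c))
    return Corpus(corpus.vocabulary, documents, corpus.class_names)
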