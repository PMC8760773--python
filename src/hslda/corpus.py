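"""Domain types for hierarchical feature-value corpora.

A corpus is a collection of patient-level documents.  Each document is a bag
of weighted tokens, a token being a (feature, value) pair drawn from a
hierarchical vocabulary: the value set is partitioned into per-feature blocks
(e.g. the feature ``heart rhythm`` owns the values ``sinus`` and ``arrhythmia``).
Documents optionally carry a discrete class label (e.g. a diagnosis).

File formats (all UTF-8, TAB-separated, "." decimal point):

* vocabulary file — header ``value_name\tfeature_name``, one row per value;
  the feature list and the value→feature map are inferred from row order.
* corpus file — header line ``#classes\t<name>\t<name>...`` carrying the
  ordered class-name list, then one document per line:
  ``doc_id\tlabel_or_-\tfeature=value[:weight] ...`` with space-separated
  tokens; an omitted weight means 1.
* CSV matrix — wide table, one row per document, one column per
  ``feature=value`` pair holding the weight (0 = absent), plus a ``label``
  column (``-`` or empty = unlabeled) and an optional ``doc_id`` column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "CorpusError",
    "Vocabulary",
    "Token",
    "Document",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "read_csv_matrix",
    "summarize",
]

UNLABELED = "-"


class CorpusError(ValueError):
    """Raised when a corpus, vocabulary or file violates an invariant."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Vocabulary:
    """Hierarchical vocabulary: ``V`` values partitioned into ``F`` feature blocks."""

    features: tuple[str, ...]
    values: tuple[str, ...]
    value_feature: tuple[int, ...]  # value index -> feature index

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise CorpusError("duplicate feature names")
        if len(set(self.values)) != len(self.values):
            raise CorpusError("duplicate value names")
        if len(self.value_feature) != len(self.values):
            raise CorpusError("value_feature must map every value")
        owned: set[int] = set()
        for v, f in enumerate(self.value_feature):
            if not 0 <= f < len(self.features):
                raise CorpusError(f"value {self.values[v]!r} maps to feature index {f} out of range")
            owned.add(f)
        if owned != set(range(len(self.features))):
            empty = [self.features[f] for f in range(len(self.features)) if f not in owned]
            raise CorpusError(f"features without values: {empty}")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_values(self) -> int:
        return len(self.values)

    def block(self, f: int) -> list[int]:
        """Value indices owned by feature ``f``."""
        return [v for v, ff in enumerate(self.value_feature) if ff == f]

    def value_index(self, name: str) -> int:
        try:
            return self.values.index(name)
        except ValueError:
            raise CorpusError(f"unknown value name {name!r}") from None

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "Vocabulary":
        """Build from ``(value_name, feature_name)`` rows, preserving order."""
        features: list[str] = []
        values: list[str] = []
        value_feature: list[int] = []
        for value_name, feature_name in pairs:
            if feature_name not in features:
                features.append(feature_name)
            values.append(value_name)
            value_feature.append(features.index(feature_name))
        return cls(tuple(features), tuple(values), tuple(value_feature))


@dataclass(frozen=True)
class Token:
    """One (feature, value) occurrence with a positive weight."""

    feature: int
    value: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise CorpusError(f"token weight must be > 0, got {self.weight}")


@dataclass
class Document:
    doc_id: str
    tokens: list[Token] = field(default_factory=list)
    label: int | None = None

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def total_weight(self) -> float:
        return sum(t.weight for t in self.tokens)


@dataclass
class Corpus:
    vocabulary: Vocabulary
    documents: list[Document] = field(default_factory=list)
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vocab = self.vocabulary
        C = len(self.class_names)
        if len(set(self.class_names)) != C:
            raise CorpusError("duplicate class names")
        for doc in self.documents:
            if doc.label is not None and not 0 <= doc.label < C:
                raise CorpusError(f"document {doc.doc_id!r}: label {doc.label} out of range for C={C}")
            for t in doc.tokens:
                if not 0 <= t.value < vocab.n_values:
                    raise CorpusError(f"document {doc.doc_id!r}: value index {t.value} out of range")
                if t.feature != vocab.value_feature[t.value]:
                    raise CorpusError(
                        f"document {doc.doc_id!r}: value {vocab.values[t.value]!r} "
                        f"paired with wrong feature index {t.feature}"
                    )
            if doc.tokens and not doc.total_weight > 0:
                raise CorpusError(f"document {doc.doc_id!r}: nonpositive total weight")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "Corpus":
        """New corpus over the same vocabulary/classes with the selected documents."""
        return Corpus(self.vocabulary, [self.documents[i] for i in indices], self.class_names)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_vocabulary(path) -> Vocabulary:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["value_name", "feature_name"]:
        raise CorpusError(f"{path}: missing 'value_name\\tfeature_name' header")
    pairs = []
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CorpusError(f"{path}:{i}: expected 2 TAB-separated columns")
        pairs.append((parts[0], parts[1]))
    return Vocabulary.from_pairs(pairs)


def write_vocabulary(vocab: Vocabulary, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("value_name\tfeature_name\n")
        for v, name in enumerate(vocab.values):
            fh.write(f"{name}\t{vocab.features[vocab.value_feature[v]]}\n")


def _format_weight(w: float) -> str:
    return repr(w)  # shortest exact round-trip representation


def read_corpus(path, vocab_path) -> Corpus:
    """Read a corpus file against its vocabulary file.

    Raises :class:`CorpusError` naming the offending line for unknown values,
    value/feature mismatches and malformed weights.
    """
    vocab = read_vocabulary(vocab_path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#classes"):
        raise CorpusError(f"{path}: missing '#classes' header line")
    class_names = tuple(lines[0].split("\t")[1:])
    label_index = {name: i for i, name in enumerate(class_names)}
    documents: list[Document] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CorpusError(f"{path}:{lineno}: expected 'doc_id\\tlabel\\ttokens'")
        doc_id, label_name, token_field = parts
        if label_name == UNLABELED:
            label = None
        elif label_name in label_index:
            label = label_index[label_name]
        else:
            raise CorpusError(f"{path}:{lineno}: unknown class label {label_name!r}")
        tokens: list[Token] = []
        for tok in token_field.split(" ") if token_field else []:
            if "=" not in tok:
                raise CorpusError(f"{path}:{lineno}: malformed token {tok!r}")
            fv, _, wstr = tok.partition(":")
            feature_name, _, value_name = fv.partition("=")
            if value_name not in vocab.values:
                raise CorpusError(f"{path}:{lineno}: unknown value name {value_name!r}")
            v = vocab.values.index(value_name)
            f = vocab.value_feature[v]
            if vocab.features[f] != feature_name:
                raise CorpusError(
                    f"{path}:{lineno}: value {value_name!r} belongs to feature "
                    f"{vocab.features[f]!r}, not {feature_name!r}"
                )
            if wstr:
                try:
                    weight = float(wstr)
                except ValueError:
                    raise CorpusError(f"{path}:{lineno}: malformed weight {wstr!r}") from None
            else:
                weight = 1.0
            tokens.append(Token(f, v, weight))
        documents.append(Document(doc_id, tokens, label))
    return Corpus(vocab, documents, class_names)


def write_corpus(corpus: Corpus, path, vocab_path) -> None:
    """Write the canonical corpus + vocabulary files (deterministic bytes)."""
    corpus.validate()
    write_vocabulary(corpus.vocabulary, vocab_path)
    vocab = corpus.vocabulary
    buf = io.StringIO()
    buf.write("#classes")
    for name in corpus.class_names:
        buf.write(f"\t{name}")
    buf.write("\n")
    for doc in corpus.documents:
        label_name = UNLABELED if doc.label is None else corpus.class_names[doc.label]
        toks = []
        for t in doc.tokens:
            base = f"{vocab.features[t.feature]}={vocab.values[t.value]}"
            toks.append(base if t.weight == 1.0 else f"{base}:{_format_weight(t.weight)}")
        buf.write(f"{doc.doc_id}\t{label_name}\t{' '.join(toks)}\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_csv_matrix(path) -> Corpus:
    """Read a wide patient × feature-value weight matrix.

    Column headers other than ``label``/``doc_id`` must parse as
    ``feature=value``; a cell weight of 0 means the pair is absent.
    """
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise CorpusError(f"{path}: missing 'label' column")
    pair_cols = [c for c in df.columns if c not in ("label", "doc_id")]
    pairs = []
    for col in pair_cols:
        if "=" not in col:
            raise CorpusError(f"{path}: column {col!r} does not parse as 'feature=value'")
        feature_name, _, value_name = col.partition("=")
        pairs.append((value_name, feature_name))
    vocab = Vocabulary.from_pairs(pairs)
    labels_raw = df["label"].astype(str)
    class_names = tuple(dict.fromkeys(s for s in labels_raw if s not in (UNLABELED, "", "nan")))
    label_index = {name: i for i, name in enumerate(class_names)}
    documents = []
    for i, row in df.iterrows():
        doc_id = str(row["doc_id"]) if "doc_id" in df.columns else str(i)
        tokens = []
        for v, col in enumerate(pair_cols):
            w = float(row[col])
            if w != 0.0:
                tokens.append(Token(vocab.value_feature[v], v, w))
        raw = labels_raw.iloc[i]
        label = label_index.get(raw) if raw not in (UNLABELED, "", "nan") else None
        documents.append(Document(doc_id, tokens, label))
    return Corpus(vocab, documents, class_names)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def summarize(corpus: Corpus) -> dict:
    """Per-pair document frequencies, per-class counts, and corpus shape.

    Ratios are percentages of the document count, rounded to 2 decimals
    (e.g. a pair present in 404 of 420 documents has ratio 96.19).
    """
    D = corpus.n_documents
    if D == 0:
        raise CorpusError("cannot summarize an empty corpus")
    vocab = corpus.vocabulary
    pair_rows = []
    df_counts = [0] * vocab.n_values
    for doc in corpus.documents:
        for v in {t.value for t in doc.tokens}:
            df_counts[v] += 1
    for v in range(vocab.n_values):
        pair_rows.append(
            {
                "feature": vocab.features[vocab.value_feature[v]],
                "value": vocab.values[v],
                "frequency": df_counts[v],
                "ratio": round(100.0 * df_counts[v] / D, 2),
            }
        )
    class_rows = []
    for c, name in enumerate(corpus.class_names):
        count = sum(1 for doc in corpus.documents if doc.label == c)
        class_rows.append({"class": name, "count": count, "ratio": round(100.0 * count / D, 2)})
    return {
        "n_documents": D,
        "n_features": vocab.n_features,
        "n_values": vocab.n_values,
        "pairs": pd.DataFrame(pair_rows),
        "classes": pd.DataFrame(class_rows),
    }


def with_weights(doc: Document, weights) -> Document:
    """Copy of ``doc`` with token weights replaced."""
    if len(weights) != len(doc.tokens):
        raise CorpusError("weight list length mismatch")
    tokens = [replace(t, weight=float(w)) for t, w in zip(doc.tokens, weights)]
    return Document(doc.doc_id, tokens, doc.label)
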