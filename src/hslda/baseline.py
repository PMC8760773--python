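"""Multi-class sLDA baseline as the flat (single-feature) degenerate case.

The hierarchical model differs from three-layer multi-class sLDA only by the
topic→feature multinomial π layered above the topic→value multinomial.  With a
vocabulary of exactly one feature owning all values, π is the 1-point simplex
(π ≡ 1), its log-terms vanish from the ELBO, and the same inference code *is*
multi-class sLDA — so the baseline comparison isolates the hierarchy itself.
"""

from __future__ import annotations

from dataclasses import replace

from .corpus import Corpus, Document, Token, Vocabulary

__all__ = ["flatten", "PSEUDO_FEATURE"]

PSEUDO_FEATURE = "_all"


def flatten(corpus: Corpus) -> Corpus:
    """Re-parent every value under one pseudo-feature (idempotent).

    Values, weights, labels and document order are preserved; only the
    feature layer collapses.
    """
    vocab = corpus.vocabulary
    if vocab.n_features == 1:
        return corpus
    flat_vocab = Vocabulary(
        (PSEUDO_FEATURE,), vocab.values, tuple(0 for _ in vocab.values)
    )
    documents = [
        Document(doc.doc_id, [Token(0, t.value, t.weight) for t in doc.tokens], doc.label)
        for doc in corpus.documents
    ]
    return Corpus(flat_vocab, documents, corpus.class_names)
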