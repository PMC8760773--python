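import numpy as np
import pytest

from hslda import Corpus, Document, HsldaParams, Token, Vocabulary


@pytest.fixture
def tiny_vocab() -> Vocabulary:
    """2 features, 4 values: rhythm ∈ {sinus, afib}, rate ∈ {norm, abn}."""
    return Vocabulary.from_pairs(
        [("sinus", "rhythm"), ("afib", "rhythm"), ("norm", "rate"), ("abn", "rate")]
    )


def make_params(rng, K, F, values_per_feature, C, alpha=0.5, eta_scale=1.0) -> HsldaParams:
    """Random valid parameters over a block-structured vocabulary."""
    V = sum(values_per_feature)
    vf = np.concatenate([[f] * n for f, n in enumerate(values_per_feature)]).astype(int)
    pi = rng.dirichlet(np.ones(F), size=K)
    beta = np.zeros((K, V))
    for f in range(F):
        block = vf == f
        beta[:, block] = rng.dirichlet(np.ones(int(block.sum())), size=K)
    eta = eta_scale * rng.normal(size=(C, K))
    return HsldaParams(np.full(K, alpha), pi, beta, eta, vf)


def make_doc(rng, params, N, label=None, doc_id="doc", weights=None) -> Document:
    """Random document consistent with the vocabulary partition (unit weights)."""
    vf = params.value_feature
    tokens = []
    for n in range(N):
        v = int(rng.integers(len(vf)))
        w = 1.0 if weights is None else float(weights[n])
        tokens.append(Token(int(vf[v]), v, w))
    return Document(doc_id, tokens, label)


def vocab_from_params(params) -> Vocabulary:
    vf = params.value_feature
    pairs = []
    counts = {}
    for v, f in enumerate(vf):
        j = counts.get(int(f), 0)
        counts[int(f)] = j + 1
        pairs.append((f"f{f}_v{j}", f"f{f}"))
    return Vocabulary.from_pairs(pairs)


def make_corpus(rng, params, D, tokens_range=(3, 8), C=None) -> Corpus:
    C = C if C is not None else params.n_classes
    docs = [
        make_doc(
            rng,
            params,
            int(rng.integers(*tokens_range)),
            label=int(rng.integers(C)),
            doc_id=f"d{i}",
        )
        for i in range(D)
    ]
    return Corpus(vocab_from_params(params), docs, tuple(f"c{i}" for i in range(C)))
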