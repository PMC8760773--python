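"""Sample labeled corpora from the model's own generative process.

Used for simulation studies, parameter-recovery checks and as a stand-in for
clinical discharge-record data: the ``chd-like`` preset mirrors the shape of a
typical coronary-heart-disease record set (420 documents, 34 features, 79
feature-value pairs in blocks of 2–3, 4 heavily imbalanced diagnosis classes,
25–34 tokens per document).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .corpus import Corpus, Document, Token, Vocabulary
from .model import HsldaParams

__all__ = ["SyntheticSpec", "sample_params", "sample_corpus", "preset", "PRESETS"]


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give a small, quickly separable corpus."""

    k: int = 3
    values_per_feature: tuple[int, ...] = (3, 3, 3, 3, 3)
    d: int = 300
    tokens_per_doc: tuple[int, int] = (20, 40)
    c: int = 3
    alpha: float = 0.3
    concentration_pi: float = 0.5
    concentration_beta: float = 0.1
    eta_scale: float = 10.0
    class_prior: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k, self.d, self.c, *self.values_per_feature) < 1:
            raise ValueError("all counts must be >= 1")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.class_prior:
            self.class_prior = tuple([1.0 / self.c] * self.c)
        if len(self.class_prior) != self.c or not np.isclose(sum(self.class_prior), 1.0):
            raise ValueError("class_prior must be a C-simplex")
        if not 1 <= self.tokens_per_doc[0] <= self.tokens_per_doc[1]:
            raise ValueError("tokens_per_doc bounds must satisfy 1 <= min <= max")

    @property
    def f(self) -> int:
        return len(self.values_per_feature)

    @property
    def v(self) -> int:
        return int(sum(self.values_per_feature))

    def vocabulary(self) -> Vocabulary:
        pairs = []
        for f, n in enumerate(self.values_per_feature):
            for j in range(n):
                pairs.append((f"f{f}_v{j}", f"f{f}"))
        return Vocabulary.from_pairs(pairs)


def _class_names(c: int) -> tuple[str, ...]:
    if c == 4:
        return ("SAP", "UAP", "ICM", "AMI")
    return tuple(f"class{i}" for i in range(c))


def sample_params(spec: SyntheticSpec) -> HsldaParams:
    """Draw model parameters: Dirichlet topic multinomials and orthogonalized η.

    η rows are mutually orthogonal unit vectors scaled by ``eta_scale`` plus a
    per-class constant offset log(class_prior_c) − mean(log class_prior): since
    r̄ sums to 1, a constant row offset is exactly the GLM intercept, so the
    prior shapes the label marginals without leaving the model family.  With a
    uniform prior the offset is 0, and eta_scale=0 gives η ≡ 0.
    """
    rng = np.random.default_rng(spec.seed)
    K, F, C = spec.k, spec.f, spec.c
    pi = rng.dirichlet(np.full(F, spec.concentration_pi), size=K)
    beta = np.zeros((K, spec.v))
    vocab = spec.vocabulary()
    vf = np.asarray(vocab.value_feature)
    for f in range(F):
        block = np.where(vf == f)[0]
        beta[:, block] = rng.dirichlet(np.full(len(block), spec.concentration_beta), size=K)
    if C <= K:
        # orthonormal topic-aligned rows: class c owns topic σ(c), so every
        # class claims a region of the topic simplex at any separation scale
        sigma = rng.permutation(K)[:C]
        eta = np.zeros((C, K))
        eta[np.arange(C), sigma] = spec.eta_scale
    else:  # more classes than topics: orthogonality impossible, use unit rows
        raw = rng.standard_normal((C, K))
        eta = spec.eta_scale * raw / np.linalg.norm(raw, axis=1, keepdims=True)
    logp = np.log(np.asarray(spec.class_prior))
    eta = eta + (logp - logp.mean())[:, None]
    alpha = np.full(K, spec.alpha)
    return HsldaParams(alpha, pi, beta, eta, vf)


def sample_corpus(params: HsldaParams, spec: SyntheticSpec):
    """Sample (corpus, ground_truth) from the generative process.

    Per document: θ ~ Dir(α); per token r_n ~ Mult(θ), f_n ~ Mult(π_{r_n}),
    v_n ~ Mult(block of β_{r_n} for f_n); y ~ softmax(η · r̄) with r̄ the
    empirical one-hot mean of the realized assignments.  Unit token weights.
    The ground-truth dict carries θ, the assignments and r̄ per document.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    vocab = spec.vocabulary()
    vf = np.asarray(vocab.value_feature)
    blocks = [np.where(vf == f)[0] for f in range(spec.f)]
    K = params.n_topics
    documents = []
    truth = {"theta": [], "assignments": [], "r_bar": []}
    for d in range(spec.d):
        theta = rng.dirichlet(params.alpha)
        n = int(rng.integers(spec.tokens_per_doc[0], spec.tokens_per_doc[1] + 1))
        r = rng.choice(K, size=n, p=theta)
        tokens = []
        for rn in r:
            f = int(rng.choice(spec.f, p=params.pi[rn]))
            block = blocks[f]
            pv = params.beta[rn, block]
            v = int(rng.choice(block, p=pv / pv.sum()))
            tokens.append(Token(f, v, 1.0))
        r_bar = np.bincount(r, minlength=K) / n
        probs = softmax(params.eta @ r_bar)
        y = int(rng.choice(spec.c, p=probs))
        documents.append(Document(f"doc{d:05d}", tokens, y))
        truth["theta"].append(theta)
        truth["assignments"].append(r.tolist())
        truth["r_bar"].append(r_bar)
    corpus = Corpus(vocab, documents, _class_names(spec.c))
    truth["theta"] = np.stack(truth["theta"])
    truth["r_bar"] = np.stack(truth["r_bar"])
    truth["params"] = params
    return corpus, truth


def _chd_like_blocks() -> tuple[int, ...]:
    # 34 features, 79 values: 11 features with 3 values, 23 with 2
    return tuple([3] * 11 + [2] * 23)


PRESETS: dict[str, dict] = {
    "tiny": dict(
        k=2,
        values_per_feature=(2, 3, 2),
        d=40,
        tokens_per_doc=(5, 10),
        c=2,
        alpha=0.5,
        concentration_pi=0.5,
        concentration_beta=0.3,
        eta_scale=3.0,
    ),
    "separable": dict(
        k=3,
        values_per_feature=(3, 3, 3, 3, 3),
        d=300,
        tokens_per_doc=(20, 40),
        c=3,
        alpha=0.3,
        concentration_pi=0.5,
        concentration_beta=0.1,
        eta_scale=10.0,
    ),
    "chd-like": dict(
        k=10,
        values_per_feature=_chd_like_blocks(),
        d=420,
        tokens_per_doc=(25, 34),
        c=4,
        alpha=0.5,
        concentration_pi=0.5,
        concentration_beta=0.3,
        eta_scale=3.0,
        class_prior=(0.631, 0.233, 0.029, 0.107),
    ),
}


def preset(name: str, **overrides) -> SyntheticSpec:
    """Named study shapes: ``tiny``, ``separable``, ``chd-like``."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    settings = dict(PRESETS[name])
    settings.update(overrides)
    return SyntheticSpec(**settings)
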