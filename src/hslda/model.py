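"""Hierarchical supervised LDA: variational EM inference, prediction, ELBO.

The model is a four-layer supervised topic model over feature-value documents.
Per document: topic proportions θ ~ Dir(α); per token n a topic assignment
r_n ~ Mult(θ), a feature f_n ~ Mult(π_{r_n}) and a value v_n ~ Mult(β_{r_n}
restricted to the block of f_n); the class label y ~ softmax(η_y · r̄) with
r̄ the empirical mean of the one-hot topic assignments.

Inference is mean-field variational Bayes: q(θ, r) = Dir(θ|γ) Π_n Mult(r_n|φ_n),
with the softmax log-partition handled by the standard multi-class sLDA
linearization (the log of an expectation that is linear in each φ_n is bounded
by its first-order expansion h·φ_n around the current φ).  All per-token
formulas reduce exactly to the unit-weight model when token weights are 1;
with TF-IDF weights a token with weight w_n behaves as w_n fractional copies
(every per-token term of the objective, including the token entropy, scales by
w_n, and 1/N becomes w_n/W with W = Σ w_n).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp, psi, softmax

from .corpus import Corpus, CorpusError, Document, Vocabulary

__all__ = [
    "HsldaParams",
    "VariationalState",
    "FitConfig",
    "FittedModel",
    "alpha_curve",
    "expected_log_theta",
    "compute_h",
    "update_gamma",
    "update_phi",
    "doc_e_step",
    "elbo_doc",
    "oracle_log_evidence",
    "m_step_pi_beta",
    "m_step_eta",
    "fit",
    "predict",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class HsldaParams:
    """Model parameters: α (K), π (K×F simplex rows), β (K×V block-normalized), η (C×K)."""

    alpha: np.ndarray
    pi: np.ndarray
    beta: np.ndarray
    eta: np.ndarray
    value_feature: np.ndarray  # V-vector: value index -> owning feature

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.value_feature = np.asarray(self.value_feature, dtype=int)

    @property
    def n_topics(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_classes(self) -> int:
        return self.eta.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        if not np.all(self.alpha > 0):
            raise ValueError("alpha must be positive")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=atol):
            raise ValueError("pi rows must sum to 1")
        F = self.pi.shape[1]
        for f in range(F):
            block = self.value_feature == f
            if not np.allclose(self.beta[:, block].sum(axis=1), 1.0, atol=atol):
                raise ValueError(f"beta block for feature {f} must sum to 1 per topic")


@dataclass
class VariationalState:
    """Per-document variational parameters γ (K) and φ (N×K simplex rows)."""

    gamma: np.ndarray
    phi: np.ndarray
    phi_bar: np.ndarray  # weighted mean Σ_n w_n φ_n / W (simplex)

    @classmethod
    def build(cls, gamma, phi, weights) -> "VariationalState":
        phi = np.asarray(phi, dtype=float)
        weights = np.asarray(weights, dtype=float)
        W = weights.sum()
        phi_bar = (weights @ phi) / W if phi.shape[0] else np.full(gamma.shape, 1.0 / gamma.shape[0])
        return cls(np.asarray(gamma, dtype=float), phi, phi_bar)


@dataclass
class FitConfig:
    """Training settings.

    ``alpha_policy`` is either ``"fixed"`` (symmetric α = ``alpha_value``) or
    ``"curve"`` — the logistic schedule α(K) = c1 + 1/(1 + exp(c2·(K − V/2))).
    """

    k: int = 10
    alpha_policy: str = "fixed"
    alpha_value: float = 1.0
    curve_c1: float = 0.3
    curve_c2: float = 0.25
    smoothing: float = 1e-10
    e_step_max_iters: int = 100
    e_step_rel_tol: float = 1e-6
    em_max_iters: int = 100
    em_rel_tol: float = 1e-4
    cg_max_iters: int = 500
    cg_grad_tol: float = 1e-5
    l2_penalty: float = 0.01
    restarts: int = 1
    restart_screen_iters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha_policy not in ("fixed", "curve"):
            raise ValueError("alpha_policy must be 'fixed' or 'curve'")
        for name in ("e_step_rel_tol", "em_rel_tol", "cg_grad_tol", "smoothing"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("e_step_max_iters", "em_max_iters", "cg_max_iters",
                     "restarts", "restart_screen_iters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def resolve_alpha(self, n_values: int) -> np.ndarray:
        if self.alpha_policy == "fixed":
            value = self.alpha_value
        else:
            value = alpha_curve(self.k, n_values, self.curve_c1, self.curve_c2)
        return np.full(self.k, float(value))


@dataclass
class FittedModel:
    params: HsldaParams
    vocabulary: Vocabulary
    class_names: tuple[str, ...]
    elbo_trace: list[float] = field(default_factory=list)
    config: FitConfig = field(default_factory=FitConfig)
    variant: str = "hslda"


def alpha_curve(K: int, V: int, c1: float, c2: float) -> float:
    """Logistic Dirichlet-hyperparameter schedule: c1 + 1/(1 + exp(c2·(K − V/2)))."""
    if K < 1 or V < 1:
        raise ValueError("K and V must be >= 1")
    return float(c1 + expit(-c2 * (K - V / 2.0)))


# ---------------------------------------------------------------------------
# document access helpers
# ---------------------------------------------------------------------------


def _doc_arrays(doc: Document):
    f = np.array([t.feature for t in doc.tokens], dtype=int)
    v = np.array([t.value for t in doc.tokens], dtype=int)
    w = np.array([t.weight for t in doc.tokens], dtype=float)
    return f, v, w


def _log_pi_beta(params: HsldaParams, f: np.ndarray, v: np.ndarray) -> np.ndarray:
    """N×K matrix of log π_{k,f_n} + log β_{k,v_n} (parameters are ε-floored)."""
    return np.log(params.pi[:, f]).T + np.log(params.beta[:, v]).T


# ---------------------------------------------------------------------------
# E-step primitives
# ---------------------------------------------------------------------------


def expected_log_theta(gamma: np.ndarray) -> np.ndarray:
    """E_q[log θ_i] = Ψ(γ_i) − Ψ(Σ_l γ_l) under Dir(γ)."""
    gamma = np.asarray(gamma, dtype=float)
    if not np.all(gamma > 0):
        raise ValueError("gamma must be positive")
    return psi(gamma) - psi(gamma.sum())


def _log_token_factors(phi: np.ndarray, eta: np.ndarray, u: np.ndarray) -> np.ndarray:
    """C×N matrix log t_{l,n} with t_{l,n} = Σ_i φ_{n,i} exp(η_{l,i} u_n), u_n = w_n/W."""
    # A[l, i, n] = η_{l,i} * u_n
    A = eta[:, :, None] * u[None, None, :]
    with np.errstate(divide="ignore"):
        logphi = np.log(phi.T)[None, :, :]  # 1×K×N, −inf where φ=0
    return logsumexp(A + logphi, axis=1)


def compute_h(phi: np.ndarray, eta: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Linearization coefficients h for token ``n`` (recomputed from scratch).

    h_i = Σ_l [Π_{m≠n} Σ_j φ_{m,j} exp(η_{l,j} w_m/W)] · exp(η_{l,i} w_n/W).
    Only the direction of h matters to the updates (the update term is
    h_i / (h·φ_n)); the returned scale is the literal one, computed in
    log-space for stability.
    """
    phi = np.asarray(phi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    N = phi.shape[0]
    if not 0 <= n < N:
        raise IndexError(f"token index {n} out of range for N={N}")
    u = weights / weights.sum()
    logt = _log_token_factors(phi, eta, u)  # C×N
    log_a = logt.sum(axis=1) - logt[:, n]  # C: log Π_{m≠n} t_{l,m}
    # log h_i = logsumexp_l (log_a_l + η_{l,i} u_n)
    return np.exp(logsumexp(log_a[:, None] + eta * u[n], axis=0))


def update_gamma(alpha: np.ndarray, phi: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """γ = α + Σ_n w_n φ_n (the update does not involve the response)."""
    alpha = np.asarray(alpha, dtype=float)
    if len(phi) == 0:
        return alpha.copy()
    return alpha + np.asarray(weights, dtype=float) @ np.asarray(phi, dtype=float)


def update_phi(
    state: VariationalState,
    params: HsldaParams,
    doc: Document,
    label: int | None,
    n: int,
) -> np.ndarray:
    """Coordinate-ascent update of φ_n (exact maximizer of the linearized ELBO).

    φ_{n,i} ∝ π_{i,f_n} β_{i,v_n} exp(E[log θ_i] + η_{y,i}/W − (h·φ_n)⁻¹ h_i / w_n);
    with unit weights the exponent is E[log θ_i] + η_{y,i}/N − (h·φ_n)⁻¹ h_i.
    When ``label`` is None the two response-coupled terms are dropped
    (test-time E-step).
    """
    f, v, w = _doc_arrays(doc)
    if not 0 <= n < len(f):
        raise IndexError(f"token index {n} out of range")
    if label is not None and not 0 <= label < params.n_classes:
        raise ValueError(f"label {label} out of range")
    logits = expected_log_theta(state.gamma) + _log_pi_beta(params, f[n : n + 1], v[n : n + 1])[0]
    if label is not None:
        W = w.sum()
        h = compute_h(state.phi, params.eta, w, n)
        logits = logits + params.eta[label] / W - h / (h @ state.phi[n]) / w[n]
    return softmax(logits)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


def _log_partition_bound(phi: np.ndarray, eta: np.ndarray, u: np.ndarray) -> float:
    """log Σ_l Π_n Σ_i φ_{n,i} exp(η_{l,i} u_n) — the Jensen upper bound on
    E_q[log Σ_l exp(η_l · r̄)], whose subtraction keeps the ELBO a true bound."""
    logt = _log_token_factors(phi, eta, u)
    return float(logsumexp(logt.sum(axis=1)))


def elbo_doc(
    doc: Document,
    state: VariationalState,
    params: HsldaParams,
    use_label: bool,
) -> float:
    """Per-document evidence lower bound.

    Sum of the Dirichlet term, the token expectation terms (each scaled by the
    token weight), the entropy of q, and — when ``use_label`` — the response
    term η_y·φ̄ minus the linearization bound on the softmax log-partition.
    """
    f, v, w = _doc_arrays(doc)
    alpha, gamma, phi = params.alpha, state.gamma, state.phi
    el = expected_log_theta(gamma)
    # E[log p(θ|α)]
    val = gammaln(alpha.sum()) - gammaln(alpha).sum() + (alpha - 1.0) @ el
    # Dirichlet entropy of q(θ)
    val += -gammaln(gamma.sum()) + gammaln(gamma).sum() - (gamma - 1.0) @ el
    if len(f):
        # token terms: E[log p(r|θ)] + E[log p(f|r)] + E[log p(v|r,f)] + token entropy
        val += (w @ phi) @ el
        val += float(np.sum(w[:, None] * phi * _log_pi_beta(params, f, v)))
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(phi > 0, phi * np.log(np.where(phi > 0, phi, 1.0)), 0.0)
        val -= float(w @ plogp.sum(axis=1))
    if use_label:
        if doc.label is None:
            raise CorpusError(f"document {doc.doc_id!r} is unlabeled")
        W = w.sum()
        u = w / W
        val += params.eta[doc.label] @ state.phi_bar
        val -= _log_partition_bound(phi, params.eta, u)
    return float(val)


# ---------------------------------------------------------------------------
# exact evidence oracle (tiny instances)
# ---------------------------------------------------------------------------


def oracle_log_evidence(doc: Document, params: HsldaParams, use_label: bool) -> float:
    """Exact log p(f, v[, y]) by enumerating all K^N topic assignments.

    The θ integral is the Dirichlet-multinomial mass of the assignment counts:
    Γ(Σα)/Γ(Σα+N) Π_i Γ(α_i+c_i)/Γ(α_i).  Requires unit token weights and
    K^N ≤ 10⁶.
    """
    f, v, w = _doc_arrays(doc)
    if not np.allclose(w, 1.0):
        raise ValueError("oracle requires unit token weights")
    K = params.n_topics
    N = len(f)
    if K**N > 10**6:
        raise ValueError(f"instance too large: K^N = {K**N}")
    alpha = params.alpha
    logpb = _log_pi_beta(params, f, v)  # N×K
    if N == 0:
        if use_label:
            raise ValueError("cannot score a label on an empty document")
        return 0.0
    total = []
    for r in itertools.product(range(K), repeat=N):
        r = np.asarray(r)
        counts = np.bincount(r, minlength=K).astype(float)
        lp = (
            gammaln(alpha.sum())
            - gammaln(alpha.sum() + N)
            + (gammaln(alpha + counts) - gammaln(alpha)).sum()
        )
        lp += logpb[np.arange(N), r].sum()
        if use_label:
            if doc.label is None:
                raise CorpusError(f"document {doc.doc_id!r} is unlabeled")
            scores = params.eta @ (counts / N)
            lp += scores[doc.label] - logsumexp(scores)
        total.append(lp)
    return float(logsumexp(np.asarray(total)))


# ---------------------------------------------------------------------------
# per-document E-step
# ---------------------------------------------------------------------------


def doc_e_step(
    doc: Document,
    params: HsldaParams,
    use_label: bool,
    config: FitConfig,
    init_state: VariationalState | None = None,
) -> VariationalState:
    """Coordinate ascent on (φ, γ) for one document until the ELBO converges.

    Initialization: φ uniform, γ = α + W/K (or a warm-start state).  Labeled
    sweeps update tokens sequentially, maintaining the per-class running
    log-products needed for h incrementally; the public :func:`compute_h`
    recomputes the same quantity from scratch and the two routes agree to
    machine precision.
    """
    f, v, w = _doc_arrays(doc)
    K = params.n_topics
    alpha = params.alpha
    N = len(f)
    if use_label and doc.label is None:
        raise CorpusError(f"document {doc.doc_id!r} is unlabeled")
    if N == 0:
        return VariationalState.build(alpha.copy(), np.zeros((0, K)), w)
    W = w.sum()
    u = w / W
    if init_state is not None:
        phi = init_state.phi.copy()
        gamma = init_state.gamma.copy()
    else:
        phi = np.full((N, K), 1.0 / K)
        gamma = alpha + W / K
    logpb = _log_pi_beta(params, f, v)
    eta = params.eta
    y = doc.label if use_label else None
    prev = None
    for _ in range(config.e_step_max_iters):
        el = expected_log_theta(gamma)
        if y is None:
            # without the response the objective is separable across tokens
            phi = softmax(el[None, :] + logpb, axis=1)
        else:
            expE = np.exp(eta[:, :, None] * u[None, None, :])  # C×K×N
            t = np.einsum("nk,ckn->cn", phi, expE)
            logt = np.log(t)
            S = logt.sum(axis=1)  # per-class running log-product
            base = el[None, :] + logpb + eta[y][None, :] / W
            for n in range(N):
                log_a = S - logt[:, n]
                b = np.exp(log_a - log_a.max())
                h = b @ expE[:, :, n]  # rescaled h; h_i/(h·φ_n) is scale-free
                phi[n] = softmax(base[n] - h / (h @ phi[n]) / w[n])
                tn = expE[:, :, n] @ phi[n]
                S += np.log(tn) - logt[:, n]
                logt[:, n] = np.log(tn)
        gamma = update_gamma(alpha, phi, w)
        state = VariationalState.build(gamma, phi, w)
        bound = elbo_doc(doc, state, params, use_label)
        if prev is not None and abs(bound - prev) <= config.e_step_rel_tol * (abs(prev) + 1e-12):
            return state
        prev = bound
    warnings.warn(f"document {doc.doc_id!r}: E-step did not converge", RuntimeWarning)
    return state


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def m_step_pi_beta(
    corpus: Corpus,
    states: list[VariationalState],
    smoothing: float,
):
    """Closed-form maximizers of the π/β ELBO terms from weighted responsibilities.

    π_{k,f} ∝ ε + Σ_d Σ_n w_n 1[f_n=f] φ_{n,k}; β_{k,v} ∝ ε + the analogous
    value counts, normalized within each (topic, feature-block).
    """
    vocab = corpus.vocabulary
    F, V = vocab.n_features, vocab.n_values
    K = states[0].gamma.shape[0] if states else 0
    pi_acc = np.zeros((F, K))
    beta_acc = np.zeros((V, K))
    for doc, state in zip(corpus.documents, states):
        if not doc.tokens:
            continue
        f, v, w = _doc_arrays(doc)
        contrib = w[:, None] * state.phi
        np.add.at(pi_acc, f, contrib)
        np.add.at(beta_acc, v, contrib)
    pi = pi_acc.T + smoothing
    pi /= pi.sum(axis=1, keepdims=True)
    beta = beta_acc.T + smoothing
    vf = np.asarray(vocab.value_feature)
    for fidx in range(F):
        block = vf == fidx
        beta[:, block] /= beta[:, block].sum(axis=1, keepdims=True)
    return pi, beta


def _eta_objective(
    eta_flat: np.ndarray,
    C: int,
    K: int,
    phi_all: np.ndarray,
    u_all: np.ndarray,
    doc_starts: np.ndarray,
    doc_of_token: np.ndarray,
    phi_bar: np.ndarray,
    labels: np.ndarray,
    l2: float,
):
    """Negative penalized response objective and its gradient (for CG)."""
    eta = eta_flat.reshape(C, K)
    D = phi_bar.shape[0]
    expE = np.exp(eta[:, None, :] * u_all[None, :, None])  # C×T×K
    t = np.einsum("tk,ctk->ct", phi_all, expE)  # C×T
    logt = np.log(t)
    logS = np.add.reduceat(logt, doc_starts, axis=1) if len(u_all) else np.zeros((C, D))
    logZ = logsumexp(logS, axis=0)  # D
    obj = float(np.sum(eta[labels, :] * phi_bar)) - float(logZ.sum()) - l2 * float(np.sum(eta**2))
    # gradient
    p = np.exp(logS - logZ[None, :])  # C×D responsibilities
    grad = np.zeros((C, K))
    np.add.at(grad, labels, phi_bar)
    wt = p[:, doc_of_token] / t  # C×T
    grad -= np.einsum("ct,t,tk,ctk->ck", wt, u_all, phi_all, expE)
    grad -= 2.0 * l2 * eta
    return -obj, -grad.ravel()


def _stack_states(corpus: Corpus, states: list[VariationalState]):
    phis, us, starts, doc_of_token = [], [], [], []
    pos = 0
    for d, (doc, state) in enumerate(zip(corpus.documents, states)):
        _, _, w = _doc_arrays(doc)
        n = len(w)
        phis.append(state.phi)
        us.append(w / w.sum() if n else w)
        starts.append(pos)
        doc_of_token.extend([d] * n)
        pos += n
    phi_all = np.concatenate(phis) if phis else np.zeros((0, 0))
    u_all = np.concatenate(us) if us else np.zeros(0)
    return phi_all, u_all, np.asarray(starts), np.asarray(doc_of_token, dtype=int)


def m_step_eta(
    corpus: Corpus,
    states: list[VariationalState],
    eta_init: np.ndarray,
    config: FitConfig,
) -> np.ndarray:
    """Maximize the response terms of the corpus ELBO over η by conjugate gradient.

    Objective: Σ_d [η_{y_d}·φ̄_d − log Σ_l Π_n Σ_i φ_{n,i} exp(η_{l,i} w_n/W_d)]
    − λ‖η‖² (the L2 penalty fixes the softmax shift invariance).
    """
    labels = []
    for doc in corpus.documents:
        if doc.label is None:
            raise CorpusError(f"document {doc.doc_id!r} is unlabeled")
        labels.append(doc.label)
    labels = np.asarray(labels, dtype=int)
    C, K = eta_init.shape
    phi_all, u_all, starts, doc_of_token = _stack_states(corpus, states)
    phi_bar = np.stack([s.phi_bar for s in states])
    args = (C, K, phi_all, u_all, starts, doc_of_token, phi_bar, labels, config.l2_penalty)
    res = optimize.minimize(
        _eta_objective,
        np.asarray(eta_init, dtype=float).ravel(),
        args=args,
        jac=True,
        method="CG",
        options={"maxiter": config.cg_max_iters, "gtol": config.cg_grad_tol},
    )
    # CG never moves uphill in the negative objective; keep the better point
    f0, _ = _eta_objective(np.asarray(eta_init, dtype=float).ravel(), *args)
    if res.fun <= f0:
        return res.x.reshape(C, K)
    return np.asarray(eta_init, dtype=float).copy()


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _init_params(vocab: Vocabulary, config: FitConfig, n_classes: int, rng) -> HsldaParams:
    K, F, V = config.k, vocab.n_features, vocab.n_values
    eps = config.smoothing
    pi = rng.dirichlet(np.ones(F), size=K) + eps
    pi /= pi.sum(axis=1, keepdims=True)
    beta = np.zeros((K, V))
    vf = np.asarray(vocab.value_feature)
    for f in range(F):
        block = np.where(vf == f)[0]
        draws = rng.dirichlet(np.ones(len(block)), size=K) + eps
        beta[:, block] = draws / draws.sum(axis=1, keepdims=True)
    eta = np.zeros((n_classes, K))
    alpha = config.resolve_alpha(V)
    return HsldaParams(alpha, pi, beta, eta, vf)


def corpus_elbo(corpus: Corpus, states, params: HsldaParams, use_label: bool, l2: float) -> float:
    """Penalized corpus objective Σ_d ELBO_d − λ‖η‖² (the quantity EM ascends)."""
    total = sum(elbo_doc(doc, s, params, use_label) for doc, s in zip(corpus.documents, states))
    if use_label:
        total -= l2 * float(np.sum(params.eta**2))
    return float(total)


def _em(
    corpus: Corpus,
    params: HsldaParams,
    config: FitConfig,
    max_iters: int,
    states: list[VariationalState] | None = None,
    trace: list[float] | None = None,
):
    """Run (or resume) EM iterations in place; returns (params, states, trace)."""
    trace = [] if trace is None else trace
    for _ in range(max_iters):
        if trace:  # resume/continue: ascend parameters before re-inferring states
            params.pi, params.beta = m_step_pi_beta(corpus, states, config.smoothing)
            params.eta = m_step_eta(corpus, states, params.eta, config)
        states = [
            doc_e_step(doc, params, True, config, None if states is None else states[d])
            for d, doc in enumerate(corpus.documents)
        ]
        trace.append(corpus_elbo(corpus, states, params, True, config.l2_penalty))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= config.em_rel_tol * (
            abs(trace[-2]) + 1e-12
        ):
            break
    return params, states, trace


def fit(corpus: Corpus, config: FitConfig) -> FittedModel:
    """Variational EM: alternate per-document E-steps and closed-form/CG M-steps.

    α is set by policy (fixed or the logistic curve) and not re-estimated.
    With ``restarts > 1``, each seeded initialization is screened for
    ``restart_screen_iters`` EM iterations and the best-ELBO run continues to
    convergence (EM is a local ascent; restart selection by the objective is
    the standard remedy for poor modes).  The recorded ``elbo_trace``
    (penalized corpus ELBO after each E-step) is non-decreasing because
    E-steps warm-start from the previous states and every M-step ascends the
    same objective.
    """
    D = corpus.n_documents
    C = corpus.n_classes
    if D < C:
        raise CorpusError(f"need at least C={C} documents, got {D}")
    for doc in corpus.documents:
        if doc.label is None:
            raise CorpusError(f"document {doc.doc_id!r} is unlabeled; fit requires labels")
    runs = []
    screen = min(config.restart_screen_iters, config.em_max_iters)
    for r in range(config.restarts):
        rng = np.random.default_rng((config.seed + r) % (2**31 - 1))
        params = _init_params(corpus.vocabulary, config, C, rng)
        iters = screen if config.restarts > 1 else config.em_max_iters
        runs.append(_em(corpus, params, config, iters))
    params, states, trace = max(runs, key=lambda run: run[2][-1])
    if config.restarts > 1 and len(trace) < config.em_max_iters:
        params, states, trace = _em(
            corpus, params, config, config.em_max_iters - len(trace), states, trace
        )
    return FittedModel(params, corpus.vocabulary, corpus.class_names, trace, config)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(doc: Document, model: FittedModel):
    """Classify one document: label-free E-step, then argmax_c η_c · φ̄.

    Returns ``(class_index, phi_bar, scores)``; ties break toward the lowest
    class index.  An empty document is scored at the uniform φ̄ with a warning.
    """
    params = model.params
    if not doc.tokens:
        warnings.warn(f"document {doc.doc_id!r} is empty; scoring uniform topic mixture")
        phi_bar = np.full(params.n_topics, 1.0 / params.n_topics)
    else:
        state = doc_e_step(doc, params, False, model.config)
        phi_bar = state.phi_bar
    scores = params.eta @ phi_bar
    return int(np.argmax(scores)), phi_bar, scores


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _vocab_hash(vocab: Vocabulary) -> str:
    payload = json.dumps([list(vocab.values), list(vocab.features), list(vocab.value_feature)])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_model(model: FittedModel, path) -> None:
    """Serialize to a single JSON document (floats round-trip bit-exactly)."""
    vocab = model.vocabulary
    doc = {
        "variant": model.variant,
        "config": vars(model.config).copy(),
        "class_names": list(model.class_names),
        "vocabulary": {
            "features": list(vocab.features),
            "values": list(vocab.values),
            "value_feature": list(vocab.value_feature),
        },
        "vocabulary_hash": _vocab_hash(vocab),
        "alpha": model.params.alpha.tolist(),
        "pi": model.params.pi.tolist(),
        "beta": model.params.beta.tolist(),
        "eta": model.params.eta.tolist(),
        "elbo_trace": list(model.elbo_trace),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> FittedModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    vocab = Vocabulary(
        tuple(doc["vocabulary"]["features"]),
        tuple(doc["vocabulary"]["values"]),
        tuple(doc["vocabulary"]["value_feature"]),
    )
    params = HsldaParams(
        np.asarray(doc["alpha"]),
        np.asarray(doc["pi"]),
        np.asarray(doc["beta"]),
        np.asarray(doc["eta"]),
        np.asarray(doc["vocabulary"]["value_feature"]),
    )
    model = FittedModel(
        params,
        vocab,
        tuple(doc["class_names"]),
        list(doc["elbo_trace"]),
        FitConfig(**doc["config"]),
        doc.get("variant", "hslda"),
    )
    return model
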