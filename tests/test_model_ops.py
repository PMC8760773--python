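"""Unit tests for the variational primitives against independent oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln, logsumexp, softmax

from hslda import (
    Document,
    FitConfig,
    HsldaParams,
    Token,
    VariationalState,
    alpha_curve,
    elbo_doc,
    oracle_log_evidence,
)
from hslda.model import (
    compute_h,
    m_step_eta,
    m_step_pi_beta,
    update_gamma,
    update_phi,
)

from conftest import make_corpus, make_doc, make_params


# ---------------------------------------------------------------------------
# expected_log_theta
# ---------------------------------------------------------------------------


def test_expected_log_theta_digamma_identity_and_symmetry():
    from hslda.model import expected_log_theta

    np.testing.assert_allclose(expected_log_theta(np.array([1.0, 1.0])), [-1.0, -1.0])
    out = expected_log_theta(np.full(5, 2.7))
    assert np.ptp(out) == 0.0 and np.all(out < 0)
    with pytest.raises(ValueError):
        expected_log_theta(np.array([1.0, 0.0]))


def test_expected_log_theta_matches_quadrature():
    from hslda.model import expected_log_theta

    a, b = 0.5, 1.5
    norm = np.exp(gammaln(a + b) - gammaln(a) - gammaln(b))

    def integrand(t):
        return np.log(t) * norm * t ** (a - 1) * (1 - t) ** (b - 1)

    expected_1, _ = integrate.quad(integrand, 0, 1)
    out = expected_log_theta(np.array([a, b]))
    assert out[0] == pytest.approx(expected_1, abs=1e-8)


# ---------------------------------------------------------------------------
# compute_h
# ---------------------------------------------------------------------------


def test_h_is_class_count_when_eta_zero():
    rng = np.random.default_rng(0)
    phi = rng.dirichlet(np.ones(3), 4)
    h = compute_h(phi, np.zeros((5, 3)), np.ones(4), 2)
    np.testing.assert_allclose(h, 5.0, atol=1e-12)


def test_h_single_token_single_class_is_exp_eta():
    eta = np.array([[0.3, -1.2]])
    h = compute_h(np.array([[0.5, 0.5]]), eta, np.ones(1), 0)
    np.testing.assert_allclose(h, np.exp(eta[0]))  # empty product over other tokens


def test_h_matches_direct_evaluation():
    rng = np.random.default_rng(42)
    N, K, C = 3, 2, 3
    phi = rng.dirichlet(np.ones(K), N)
    eta = rng.normal(size=(C, K))
    w = np.ones(N)
    full = sum(
        np.prod([phi[m] @ np.exp(eta[l] / N) for m in range(N)]) for l in range(C)
    )
    for n in range(N):
        h = compute_h(phi, eta, w, n)
        direct = sum(
            np.prod([phi[m] @ np.exp(eta[l] / N) for m in range(N) if m != n])
            * np.exp(eta[l] / N)
            for l in range(C)
        )
        np.testing.assert_allclose(h, direct, rtol=1e-12)
        assert h @ phi[n] == pytest.approx(full)
    with pytest.raises(IndexError):
        compute_h(phi, eta, w, N)


# ---------------------------------------------------------------------------
# update_gamma / update_phi
# ---------------------------------------------------------------------------


def test_update_gamma_closed_form():
    alpha = np.array([0.5, 0.5])
    np.testing.assert_allclose(update_gamma(alpha, np.zeros((0, 2)), np.zeros(0)), alpha)
    phi = np.array([[1.0, 0.0], [0.0, 1.0]])
    np.testing.assert_allclose(update_gamma(alpha, phi, np.ones(2)), [1.5, 1.5])
    rng = np.random.default_rng(1)
    phi = rng.dirichlet(np.ones(3), 6)
    w = rng.uniform(0.1, 2.0, 6)
    brute = np.full(3, 0.2) + sum(w[n] * phi[n] for n in range(6))
    np.testing.assert_allclose(update_gamma(np.full(3, 0.2), phi, w), brute)


def test_update_phi_degenerate_and_symmetric_cases():
    rng = np.random.default_rng(2)
    p1 = make_params(rng, K=1, F=2, values_per_feature=[2, 2], C=2)
    doc = make_doc(rng, p1, 3, label=0)
    state = VariationalState.build(np.array([3.5]), np.ones((3, 1)), np.ones(3))
    np.testing.assert_allclose(update_phi(state, p1, doc, 0, 1), [1.0])

    # fully symmetric parameters, no label -> uniform responsibilities
    K = 3
    pi = np.full((K, 2), 0.5)
    beta = np.full((K, 4), 0.5)
    params = HsldaParams(np.ones(K), pi, beta, np.zeros((2, K)), [0, 0, 1, 1])
    doc = Document("d", [Token(0, 0), Token(1, 2)], None)
    state = VariationalState.build(np.full(K, 2.0), np.full((2, K), 1 / K), np.ones(2))
    np.testing.assert_allclose(update_phi(state, params, doc, None, 0), np.full(K, 1 / K))


def test_update_phi_maximizes_restricted_objective_on_grid():
    """The new φ_n beats every point of a fine simplex grid.

    Unlabeled: the token's restricted ELBO is exact.  Labeled: the update
    maximizes the linearized surrogate (log-partition replaced by its
    first-order bound around φ_old), so the surrogate is what the grid scans.
    """
    rng = np.random.default_rng(3)
    params = make_params(rng, K=2, F=2, values_per_feature=[2, 2], C=2, eta_scale=1.5)
    doc = make_doc(rng, params, 2, label=1)
    gamma = np.array([0.8, 1.7])
    phi0 = rng.dirichlet(np.ones(2), 2)
    state = VariationalState.build(gamma, phi0, np.ones(2))
    n = 0
    f_n, v_n = doc.tokens[n].feature, doc.tokens[n].value
    from hslda.model import expected_log_theta

    el = expected_log_theta(gamma)
    base = el + np.log(params.pi[:, f_n]) + np.log(params.beta[:, v_n])
    grid = np.linspace(1e-6, 1 - 1e-6, 10_000)

    def entropy(p):
        return -(p * np.log(p)).sum()

    # unlabeled: exact restricted ELBO
    new_unlab = update_phi(state, params, doc, None, n)
    vals = np.array([(p * base[0] + (1 - p) * base[1]) + entropy(np.array([p, 1 - p])) for p in grid])
    best = vals.max()
    got = new_unlab @ base + entropy(new_unlab)
    assert got >= best - 1e-6

    # labeled: surrogate with h fixed at phi_old
    h = compute_h(phi0, params.eta, np.ones(2), n)
    coef = base + params.eta[1] / 2.0 - h / (h @ phi0[n])
    new_lab = update_phi(state, params, doc, 1, n)
    vals = np.array([(p * coef[0] + (1 - p) * coef[1]) + entropy(np.array([p, 1 - p])) for p in grid])
    got = new_lab @ coef + entropy(new_lab)
    assert got >= vals.max() - 1e-6


# ---------------------------------------------------------------------------
# elbo_doc / oracle
# ---------------------------------------------------------------------------


def test_elbo_single_topic_single_class_closed_form():
    rng = np.random.default_rng(4)
    params = make_params(rng, K=1, F=2, values_per_feature=[2, 3], C=1)
    params.eta[:] = 0.0
    doc = make_doc(rng, params, 4, label=0)
    state = VariationalState.build(
        update_gamma(params.alpha, np.ones((4, 1)), np.ones(4)), np.ones((4, 1)), np.ones(4)
    )
    expected = sum(
        np.log(params.pi[0, t.feature]) + np.log(params.beta[0, t.value]) for t in doc.tokens
    )
    assert elbo_doc(doc, state, params, False) == pytest.approx(expected)
    # label term adds -log C = 0 for C=1
    assert elbo_doc(doc, state, params, True) == pytest.approx(expected)


def test_elbo_uniform_dirichlet_empty_document_is_zero():
    params = HsldaParams(np.ones(2), np.ones((2, 1)), np.full((2, 2), 0.5),
                         np.zeros((1, 2)), [0, 0])
    doc = Document("d", [], 0)
    state = VariationalState.build(np.ones(2), np.zeros((0, 2)), np.zeros(0))
    assert elbo_doc(doc, state, params, False) == pytest.approx(0.0, abs=1e-12)


def test_oracle_single_token_closed_form():
    # uniform symmetric everything: p(f, v) = (1/F) * (1/|block(f)|)
    K, F = 2, 3
    vf = [0, 0, 1, 1, 1, 2]
    pi = np.full((K, F), 1 / F)
    beta = np.zeros((K, 6))
    for f in range(F):
        block = [v for v in range(6) if vf[v] == f]
        beta[:, block] = 1 / len(block)
    params = HsldaParams(np.ones(K), pi, beta, np.zeros((2, K)), vf)
    doc = Document("d", [Token(1, 3)], None)
    expected = np.log(1 / F * 1 / 3)
    assert oracle_log_evidence(doc, params, False) == pytest.approx(expected)


def test_oracle_matches_monte_carlo_estimate():
    rng = np.random.default_rng(5)
    params = make_params(rng, K=2, F=2, values_per_feature=[2, 2], C=2, eta_scale=1.0)
    doc = make_doc(rng, params, 2, label=1)
    exact = oracle_log_evidence(doc, params, True)
    # MC: sample theta ~ Dir(alpha), r ~ Mult(theta), average the likelihood
    M = 200_000
    theta = rng.dirichlet(params.alpha, M)
    logw = np.zeros(M)
    r_counts = np.zeros((M, 2))
    for t in doc.tokens:
        probs = theta  # K=2
        r = (rng.uniform(size=M) > probs[:, 0]).astype(int)
        logw += np.log(params.pi[r, t.feature]) + np.log(params.beta[r, t.value])
        r_counts[np.arange(M), r] += 1
    r_bar = r_counts / len(doc.tokens)
    scores = r_bar @ params.eta.T
    logw += scores[:, doc.label] - logsumexp(scores, axis=1)
    est = logsumexp(logw) - np.log(M)
    w = np.exp(logw - logw.max())
    se = np.std(w) / (np.mean(w) * np.sqrt(M))  # relative SE of the mean
    assert abs(est - exact) <= 3 * se + 1e-3


def test_oracle_rejects_oversized_and_weighted_instances():
    rng = np.random.default_rng(6)
    params = make_params(rng, K=10, F=2, values_per_feature=[2, 2], C=2)
    doc = make_doc(rng, params, 7, label=0)
    with pytest.raises(ValueError, match="too large"):
        oracle_log_evidence(doc, params, False)
    params2 = make_params(rng, K=2, F=2, values_per_feature=[2, 2], C=2)
    doc2 = make_doc(rng, params2, 2, label=0, weights=[0.5, 2.0])
    with pytest.raises(ValueError, match="unit"):
        oracle_log_evidence(doc2, params2, False)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def test_m_step_point_mass_concentrates_pi():
    rng = np.random.default_rng(7)
    params = make_params(rng, K=3, F=2, values_per_feature=[2, 2], C=2)
    corpus = make_corpus(rng, params, D=1, tokens_range=(1, 2))
    doc = corpus.documents[0]
    phi = np.zeros((1, 3))
    phi[0, 0] = 1.0
    states = [VariationalState.build(params.alpha + 1, phi, np.ones(1))]
    pi, beta = m_step_pi_beta(corpus, states, smoothing=1e-10)
    f0, v0 = doc.tokens[0].feature, doc.tokens[0].value
    assert pi[0, f0] == pytest.approx(1.0, abs=1e-8)
    assert beta[0, v0] == pytest.approx(1.0, abs=1e-8)


def test_m_step_hard_assignments_reduce_to_count_tables():
    rng = np.random.default_rng(8)
    K = 2
    params = make_params(rng, K=K, F=2, values_per_feature=[2, 3], C=2)
    corpus = make_corpus(rng, params, D=12, tokens_range=(2, 7))
    states = []
    pi_counts = np.zeros((K, 2))
    beta_counts = np.zeros((K, 5))
    for doc in corpus.documents:
        N = doc.n_tokens
        hard = rng.integers(0, K, N)
        phi = np.eye(K)[hard]
        states.append(VariationalState.build(params.alpha + 1, phi, np.ones(N)))
        for n, t in enumerate(doc.tokens):
            pi_counts[hard[n], t.feature] += 1
            beta_counts[hard[n], t.value] += 1
    pi, beta = m_step_pi_beta(corpus, states, smoothing=1e-10)
    np.testing.assert_allclose(pi, pi_counts / pi_counts.sum(1, keepdims=True), atol=1e-8)
    vf = np.asarray(corpus.vocabulary.value_feature)
    for f in range(2):
        block = vf == f
        expect = beta_counts[:, block] / beta_counts[:, block].sum(1, keepdims=True)
        np.testing.assert_allclose(beta[:, block], expect, atol=1e-8)


def test_m_step_eta_symmetric_data_gives_equal_rows():
    rng = np.random.default_rng(9)
    params = make_params(rng, K=2, F=1, values_per_feature=[3], C=2)
    corpus = make_corpus(rng, params, D=4, tokens_range=(3, 4))
    # identical phi-bar everywhere, balanced labels
    for i, doc in enumerate(corpus.documents):
        doc.label = i % 2
    N = corpus.documents[0].n_tokens
    states = [
        VariationalState.build(params.alpha + 1, np.full((d.n_tokens, 2), 0.5),
                               np.ones(d.n_tokens))
        for d in corpus.documents
    ]
    eta = m_step_eta(corpus, states, np.zeros((2, 2)), FitConfig(k=2))
    np.testing.assert_allclose(eta[0], eta[1], atol=1e-6)


def test_m_step_eta_separates_orthogonal_classes():
    rng = np.random.default_rng(10)
    K = C = 3
    params = make_params(rng, K=K, F=1, values_per_feature=[4], C=C)
    corpus = make_corpus(rng, params, D=C, tokens_range=(2, 3))
    states = []
    for c, doc in enumerate(corpus.documents):
        doc.label = c
        phi = np.zeros((doc.n_tokens, K))
        phi[:, c] = 1.0  # one-hot phi-bar per class
        states.append(VariationalState.build(params.alpha + 1, phi, np.ones(doc.n_tokens)))
    eta = m_step_eta(corpus, states, np.zeros((C, K)), FitConfig(k=K))
    for c, s in enumerate(states):
        assert int(np.argmax(eta @ s.phi_bar)) == c


# ---------------------------------------------------------------------------
# alpha curve
# ---------------------------------------------------------------------------


def test_alpha_curve_midpoint_monotonicity_asymptote():
    c1, c2, V = 0.3, 0.25, 79
    assert alpha_curve(39.5, V, c1, c2) == pytest.approx(c1 + 0.5)
    values = [alpha_curve(k, V, c1, c2) for k in range(1, 200)]
    assert all(a >= b for a, b in zip(values, values[1:]))  # monotone in K
    strict = [alpha_curve(k, V, c1, c2) for k in range(10, 71)]  # experimental range
    assert all(a > b for a, b in zip(strict, strict[1:]))
    assert alpha_curve(10_000, V, c1, c2) == pytest.approx(c1)
    with pytest.raises(ValueError):
        alpha_curve(0, V, c1, c2)
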