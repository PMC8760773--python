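# Methods

## Model

`hslda` implements a four-layer supervised topic model for patient records
represented as bags of *feature-value pairs*. A hierarchical vocabulary
partitions the V values into blocks owned by F features (e.g. the feature
*heart rhythm* owns *sinus* and *arrhythmia*). Per document d with N tokens:

1. topic proportions θ ~ Dirichlet(α), α ∈ R₊ᴷ;
2. for each token n: topic r_n ~ Mult(θ); feature f_n ~ Mult(π_{r_n}) with
   π ∈ R^{K×F}, rows on the simplex; value v_n ~ Mult(β_{r_n} restricted to
   the block of f_n) with β ∈ R^{K×V} normalized within each (topic, block);
3. a class label y ~ softmax(η r̄), η ∈ R^{C×K}, where r̄ is the empirical
   mean of the one-hot topic assignments.

Compared with three-layer multi-class supervised LDA, the extra π layer
factorizes "which clinical attribute appears" from "which level it takes".
With F = 1 the model *is* multi-class sLDA; `baseline.flatten` exploits this
so the baseline comparison runs through the identical inference code.

## Inference

Mean-field variational Bayes with q(θ, r) = Dir(θ|γ) Π_n Mult(r_n|φ_n).
The E-step alternates

- γ ← α + Σ_n w_n φ_n,
- φ_{n,i} ∝ π_{i,f_n} β_{i,v_n} exp(E[log θ_i] + η_{y,i}/W − (h·φ_n)⁻¹ h_i / w_n),

where E[log θ_i] = Ψ(γ_i) − Ψ(Σγ) and h_i = Σ_l [Π_{m≠n} Σ_j φ_{m,j}
exp(η_{l,j} w_m/W)] exp(η_{l,i} w_n/W) is the standard multi-class sLDA
linearization of the softmax log-partition. Because the log of a
token-linear expectation is concave, replacing E_q[log Σ_l exp(η_l·r̄)] by
log E_q[Σ_l exp(η_l·r̄)] = log Σ_l Π_n Σ_i φ_{n,i} exp(η_{l,i} w_n/W) keeps
the objective a true lower bound on the log evidence; the further first-order
expansion h·φ_n around the current φ makes each token update an exact
coordinate-ascent step. Both properties are tested: the converged bound never
exceeds exact enumeration on tiny instances, and every E-step/EM trace is
non-decreasing.

The M-step is closed-form for π and β (ε-smoothed weighted responsibilities,
β normalized per topic-block) and conjugate-gradient (scipy's Polak–Ribière
CG) for η, with an L2 penalty λ‖η‖² (default λ = 0.01, configurable, λ = 0
supported) that pins down the softmax shift invariance. The recorded EM trace
is therefore the *penalized* corpus ELBO Σ_d ELBO_d − λ‖η‖², the quantity the
algorithm actually ascends. E-steps after the first EM iteration warm-start
from the previous variational states, which makes the trace provably
monotone (each step is coordinate ascent from the previous point).

Test-time inference (prediction) drops the two response-coupled terms from
the φ update — the label is unknown — and classifies by
argmax_c η_c·φ̄ with φ̄ = Σ_n w_n φ_n / W, ties broken toward the lowest
class index. An empty document is scored at the uniform φ̄ with a warning.

### Token weights

All formulas are stated for weighted tokens because the TF-IDF stage
reweights them. The convention is *fractional copies*: every per-token term
of the objective, including the token entropy, scales by w_n, and 1/N
becomes w_n/W (W = Σ w_n). With unit weights every expression reduces to the
textbook unweighted form. This convention (rather than leaving the token
entropy unscaled) is the only one under which the φ update above is the
exact maximizer of the weighted objective, which the grid-search and
monotonicity tests require.

### Numerical choices

- ε = 10⁻¹⁰ smoothing in M-step numerators keeps log π, log β finite;
  configurable.
- h and the log-partition are computed in log-space (logsumexp); inside the
  per-document sweep the per-class log-products Σ_m log t_{l,m} are
  maintained incrementally (O(NKC) per sweep instead of O(N²KC)); the public
  `compute_h` recomputes from scratch and a test pins the two routes to
  1e−10 agreement.
- Initialization: φ uniform, γ = α + W/K, η = 0, π/β from seeded
  symmetric-Dirichlet draws. α is set by policy — a fixed symmetric value or
  the logistic schedule α(K) = c1 + 1/(1 + exp(c2·(K − V/2))) (defaults
  c1 = 0.3, c2 = 0.25) — and never re-estimated during EM.
- Tolerances: E-step relative ELBO change 10⁻⁶ (max 100 sweeps), EM 10⁻⁴
  (max 100 iterations), CG gradient ∞-norm 10⁻⁵ (max 500 iterations).
- The Ψ′(γ) that sometimes appears in print for the φ update is treated as
  the digamma difference Ψ(γ_i) − Ψ(Σγ): only that choice makes the update a
  coordinate ascent on the ELBO whose θ-terms use E[log θ].

## Exact-evidence oracle

For instances with unit weights and K^N ≤ 10⁶, `oracle_log_evidence`
enumerates all topic assignments; the θ integral collapses to the
Dirichlet-multinomial mass Γ(Σα)/Γ(Σα+N) Π_i Γ(α_i+c_i)/Γ(α_i). It exists
purely as an independent ceiling for the variational bound and is never used
in training.

## Preprocessing

- **Discretization**: guideline-driven bins (categorical pass-through or
  half-open numeric intervals [lo, hi)); one token per feature per row;
  missing cells are a hard error — imputation is a pluggable upstream hook,
  deliberately not implemented here.
- **TF-IDF**: weight = tf · ln(D/df) with tf the within-document pair count
  and df the pair's document frequency; weights that come out 0 (ubiquitous
  pairs) are floored to 10⁻⁸ because tokens must stay in the likelihood.
  The simplest variant consistent with "assign each term a weight" was
  chosen; duplicates of a pair each carry the full tf·idf and the model sums
  their sufficient statistics.
- **SMOTE**: minority classes are raised to the majority count with
  x + u·(x_nn − x), u ~ U(0,1), x_nn one of the k = 5 (configurable,
  Chawla's default) nearest same-class neighbors by Euclidean distance in
  the dense V-dimensional document-weight space — the space actually fed to
  the model. Synthetic vectors are re-tokenized from their positive
  coordinates. In cross-validation SMOTE defaults to the training fold only
  (leakage guard); balancing the whole corpus before splitting is available
  to reproduce protocols that report balanced totals.

## Synthetic data

The generator samples from the model's own generative process, so ground
truth (θ, r, r̄, parameters) is available for every corpus. Labels are drawn
from softmax(η r̄) of the *realized* assignments, not from θ, matching the
conditional p(y | r_{1:N}, η). η rows are topic-aligned orthonormal one-hot
vectors scaled by `eta_scale`; a per-class constant offset
log(prior_c) − mean(log prior) implements an arbitrary class prior exactly
within the model family (r̄ sums to 1, so constant row offsets are GLM
intercepts). Topic-aligned rows — rather than arbitrary random orthogonal
rows — guarantee every class owns a region of the topic simplex, so high
`eta_scale` yields separable classes instead of empty ones.

Presets:

- `tiny` — D = 40, K = 2, F = 3, V = 7, C = 2, 5–10 tokens: smoke tests and
  monotonicity checks.
- `separable` — D = 300, K = 3, F = 5, V = 15, C = 3, eta_scale = 10,
  sparse topics (block concentration 0.1), α = 0.3: classification and
  recovery experiments.
- `chd-like` — D = 420, F = 34, V = 79 (blocks of 2–3), C = 4, class prior
  (0.631, 0.233, 0.029, 0.107), 25–34 tokens: mirrors the shape of a typical
  coronary-heart-disease discharge-record dataset.

What the generator does **not** emulate: correlated features, missingness,
annotation noise, real TF-IDF weight distributions, and label noise beyond
the softmax. Passing tests therefore demonstrate correctness of the
inference machinery and the experimental protocol on model-faithful data,
not clinical performance.

## Evaluation

Stratified k-fold cross-validation (plain folds can lose a 12-sample class
entirely under 63% majority imbalance); macro precision/recall with
0/0 := 0; macro-F1 as the mean of per-class F1 (the common convention — the
harmonic-of-macro-P/R alternative is deliberately not the default). Metrics
are percentages.

The risk-stratification table is a reconstruction: topics ranked by η_c give
each class's high tier (top topics) and low tier (bottom topics); within a
tier, pairs are scored by Σ_k softplus(±η_{c,k})·β_{k,v}·π_{k,f(v)} —
rectified coefficient strength times generative probability. No canonical
definition of such tables exists; this one is deterministic, permutation-
invariant, and recovers planted discriminative values in the seeded test.

## Problem sizes in tests and the acceptance script

The simulation experiments run at D = 100–500 documents, K ≤ 3 topics,
V = 15 values, 20–40 tokens per document — sizes chosen so the entire suite
and the acceptance script each complete in minutes on one CPU while leaving
the measured quantities (bound violations, recovery error, cross-validated
accuracy) stable across seeds. The oracle-bound check uses N ≤ 4, K ≤ 3 so
that exact enumeration stays trivially cheap.

## Known limitations

- The per-token sequential φ sweep is O(NKC) per token via incremental
  caching but still Python-loop bound; corpora beyond ~10⁴ documents or
  K ≫ 50 would want a compiled kernel.
- α is never estimated; only the fixed and logistic-curve policies exist.
- The η objective is concave in η only jointly with fixed φ; EM can still
  reach local optima of the overall bound. `FitConfig.restarts` screens
  several seeded initializations for a few EM iterations and continues the
  best-ELBO run — the standard remedy; the recovery experiments use 3
  restarts, selection made purely by the objective.
- Gibbs sampling, real-valued responses and α Newton updates are out of
  scope.
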