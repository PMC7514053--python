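# Methods

## The model

HO-VGAE is a variational graph auto-encoder for undirected, unweighted
protein–protein interaction networks, using network topology only. Its
single modelling idea is to replace the 1-hop neighborhood aggregation
of a plain graph convolution with the personalized-PageRank (PPR)
influence operator

    S = α (I − (1 − α) A_norm)⁻¹,   A_norm = D̃^(−1/2)(A + I)D̃^(−1/2),

inside every encoder layer. A random walker restarts at its root node
with probability α, so α controls the locality/globality trade-off: at
α = 1 the operator is the identity (no propagation, the encoder
degenerates to an MLP on the node features); as α → 0 the operator
approaches a global stationary distribution. Because S is dense, layers
use the truncated power iteration H_{k+1} = (1 − α) A_norm H_k + α Z
(H_0 = Z, K steps), which preserves sparsity and converges geometrically
at rate (1 − α)·ρ(A_norm); the exact dense solve is retained for small
graphs and as the oracle in tests. A `standard_1hop` mode replaces the
operator with a single A_norm multiplication, giving the reference
two-layer VGAE used as the ablation baseline.

The encoder stacks L − 1 shared ReLU layers and two parallel linear
heads for μ and log σ (linear because log σ must take negative values).
The latent embedding is sampled with the reparameterization trick,
Z = μ + σ ⊙ ε, and decoded by inner products, p(a_ij = 1) = σ(z_iᵀz_j).
Inference uses μ deterministically.

Self-loops are never stored in the graph container; they enter only
where the model needs them — the A + I inside normalization, and the
all-ones diagonal of the reconstruction target (a config switch can
exclude the diagonal for sensitivity analysis).

## Objective

Training minimizes

    L = L̃_A + L_KL + v·L_reg

where L̃_A is the class-balanced reconstruction cross-entropy over all
n² ordered pairs (positives weighted 1/d, negatives 1/(1 − d), with d
the density of the target adjacency including the diagonal), L_KL is the
KL divergence of the factorized Gaussian posterior from N(0, I), and
L_reg = ½ Σ‖W^l‖²_F. The log-likelihood forms are negated so the sum is
a proper minimization objective. Cross-entropy is computed from logits
via softplus; probabilities are never logged directly.

With A³ co-training (`cotrain_t` > 0) the t strongest unconnected pairs
by raw 3-hop walk count — deliberately the raw count, not the
degree-normalized L3 score — are added to the reconstruction target as
pseudo-positives. Candidate counts are computed on the training graph
only, never on held-out edges. Propagation stays on the observed graph
by default (`cotrain_in_propagation` covers the other reading).

## Optimization and numerical choices

* **Full-batch Adam**, learning rate 0.01, float64 throughout.
  Gradients are hand-derived; the propagation operator is linear and
  self-adjoint (a polynomial in the symmetric A_norm), so its adjoint in
  the backward pass is the operator itself. Correctness is pinned by
  central-difference checks (relative error < 1e−4 asserted; measured
  ~1e−7).
* **Initialization.** Hidden layers after the first use Glorot uniform.
  The first layer is initialized at unit variance instead: with identity
  node features it is an embedding-lookup table, and each one-hot input
  row carries unit total energy rather than the n unit-variance
  coordinates Glorot's fan-in term assumes. Glorot scaling there shrinks
  first-layer activations by ~1/√n and leaves deep encoders in a
  vanishing-signal regime that roughly triples the iterations needed to
  converge.
* **Iteration budget.** Training runs until the early-stopping rule
  fires, with a safety cap of 300 iterations (`max_iters`). The
  validation rule is the effective stopping criterion; typical runs on
  the 100-node test bed stop after 30–90 iterations.
* **Early stopping.** The monitored quantity is the mean cross-entropy
  of the deterministic μ-based scores on the validation pairs. Dropout
  and reparameterization noise make the raw per-iteration value jitter,
  so the rule — stop when the loss fails to decrease for
  `early_stop_window` = 2 consecutive iterations — is applied to an
  exponentially smoothed copy (smoothing 0.7, a time constant of about
  three iterations), is armed only after a 10-iteration warm-up (the
  first Adam steps overshoot before the loss starts falling), and
  returns the best-validation weights seen, the classic restore-best
  form. Monitoring validation AUPR instead was evaluated and rejected:
  its per-iteration estimate on small validation sets is noisier still
  and stalls training earlier.
* **Dropout** 0.5 on hidden activations only, inverted scaling, training
  mode only.
* **Defaults:** 3-layer encoder 256–128–64, α = 0.1, K = 10 (the
  approximation plateau — K = 20 is statistically indistinguishable),
  v = 1e−5, dropout 0.5. The grid-search driver exposes
  α ∈ {0.05, 0.1, 0.2, 0.3, 0.5}, K ∈ {2, 5, 10, 20}, t up to |E| and
  v ∈ {0, 1e−5, 1e−4}. α is dataset-dependent; on the two-community
  test bed α = 0.3 maximizes validation AUPR.
* **Ties and determinism.** A³ candidate ranking breaks ties
  lexicographically; precision@k uses a stable sort on (score
  descending, pair ascending); every random draw flows from a single
  seeded generator, making splits, training and evaluation bitwise
  reproducible.

## Heuristic scores

CN, PA and AA follow their textbook definitions (degrees from A without
self-loops). L3 is the degree-normalized length-3 walk sum
Σ_{u,v} a_xu a_uv a_vy / √(k_u k_v) = (A·D^(−1/2)AD^(−1/2)·A)_xy.

CH2-L3 follows the local-community paradigm of the Cannistraci CH2
family, a definition taken from that external literature rather than
derived here: for a queried pair (x, y) the local community LC is the
set of intermediate nodes on simple length-3 paths x–z1–z2–y; each path
contributes √((1+i_z1)(1+i_z2)) / √((1+e_z1)(1+e_z2)), where i_z counts
links from z to other LC members and e_z counts links from z to nodes
outside LC excluding the seeds x, y (seed links are neither internal nor
external). The implementation is verified against an independent
path-enumeration oracle on random graphs.

## Evaluation protocol

Edges are split 80/10/10 into train/validation/test positives
(round(fraction·|E|) to the held-out sets, remainder to train).
Negatives are non-edges of the full graph: `matched` draws as many as
there are positives, `ratio_1_10` ten test negatives per positive,
`all_unknown` uses every unconnected pair (validation negatives
excluded, so no pair is used twice). AUPR is step-wise average precision
with tied scores grouped per threshold (scikit-learn's implementation,
cross-checked against an independent step-wise reference); note AP has a
small upward bias under random ranking that decays with list length.
precision@k uses k = number of test positives. A leakage guard asserts
that the adjacency any scorer sees contains no held-out positive.

Robustness sweeps remove a fraction of edges uniformly at random, rerun
the standard split on the remainder, and evaluate with all unknown pairs
as negatives and co-training off. Removed edges are discarded, not
recycled as extra test positives.

## Synthetic data

The stochastic block model is the primary test bed because its
p_in/p_out gap gives a controllable link-prediction signal; the standard
instance is two blocks of 50 with p_in = 0.25, p_out = 0.02, and a
strong-signal variant (p_in = 0.3, p_out = 0.005) is used for end-to-end
recovery checks. The duplication–divergence generator (duplicate a
uniform node, retain each parent edge with p_retain = 0.4, link copy to
parent with p_new = 0.3) supplies the heavy-tailed degree distributions
of real proteomes and exercises the degree normalization. Neither
generator emulates the ascertainment biases of real screens (bait/prey
asymmetry, study bias toward well-known proteins, false positives), so
passing tests demonstrate correct mechanics and sane behavior under
community structure and degree heterogeneity — not performance on real
interactomes.

Replication levels used by the standard checks, chosen to keep runs on
one CPU short while bounding Monte-Carlo error: 10 random splits for
accuracy comparisons, 40 for the robustness curve (whose all-unknown
AUPR values are small, a few percent, and correspondingly noisy), 5 for
the parameter sweeps.

## Known limitations

* **Small dense graphs blunt the higher-order advantage.** On a 100-node
  two-block SBM at 13% density, a block-membership oracle reaches only
  ~0.67 matched-scenario AUPR (about 44% of matched negatives are
  within-block pairs statistically identical to held-out positives);
  methods exceed that ceiling only through local common-neighbor signal,
  which strong PPR smoothing (α = 0.1) deliberately attenuates. There
  the 1-hop ablation and L3 match or beat the higher-order model, and
  under the all-unknown scenario L3/CH2-L3 lead it — consistent with
  the behavior of these methods on dense, locally saturated graphs. The
  higher-order design targets large sparse interactomes where 1-hop
  evidence is scarce.
* **Validation signal at small |E|.** With only tens of validation
  pairs, the early-stopping loss saturates before test-set ranking
  quality has converged; the smoothed rule mitigates but does not remove
  this, and small-graph runs can stop 0.03–0.1 AUPR short of their
  converged value. On networks of realistic size the validation set is
  orders of magnitude larger and the effect vanishes.
* The exact dense PPR solve is capped at 5000 nodes; larger graphs must
  use power mode. Training is full-batch and O(n²) in memory through the
  reconstruction target, appropriate up to interactome scale
  (~10⁴ nodes) but not beyond.
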