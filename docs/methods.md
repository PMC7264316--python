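# Methods

## Model

The data model is a tripartite heterogeneous network: entity catalogs for
drugs, diseases and protein targets; a symmetric intrinsic similarity
matrix per type with entries in [0, 1] and an ignored (zeroed) diagonal;
and three bipartite association layers with entries in [0, 1], where a
nonzero entry means a known relation with that confidence. All matrices are
stored sparse (CSR): realistic datasets in this domain reach ~10^4 entities
per type with very sparse edges, and every inference step here is built on
sparse products.

Inference proceeds in three stages.

**Projection.** The topological similarity of two same-type nodes is the
weighted Jaccard index of their association profiles in a bipartite layer:
`T_ij = Σ_k min(a_ik, a_jk) / Σ_k max(a_ik, a_jk)`, with `T_ij = 0` when
both profiles are empty and `T_ii = 0`. This operator was chosen because it
is bounded in [0, 1] without any normalization constant, reduces to the set
Jaccard index on binary data, is invariant to permutation and zero-padding
of the opposite side, and degrades gracefully with degree imbalance. Each
entity type receives topological similarity from both of the layers that
touch it (drugs: drug–disease and drug–target; diseases: drug–disease and
disease–target; targets: drug–target and disease–target).

**Fusion.** Intrinsic and the two topological similarities are combined
element-wise. The default is the maximum: it is parameter-free, keeps
[0, 1], is commutative/associative/idempotent, and encodes "strongest
evidence wins" — an edge supported strongly by any one source is kept at
full strength. A mean fusion (`fusion: mean`) is available for users who
prefer evidence averaging; it shrinks edges supported by only one source.

**Label propagation.** Each fused similarity is normalized symmetrically,
`S̄ = D^{-1/2} S D^{-1/2}` with `D` the diagonal of row sums; rows of
isolated nodes map to zero instead of dividing by zero. `S̄` is symmetric
with spectral radius ≤ 1, so for mixing parameter α ∈ (0, 1) the label
spreading iteration `F(t+1) = α S̄ F(t) + (1 − α) Y` is a contraction with
unique fixed point `(1 − α)(I − α S̄)^{-1} Y`. A relation is scored from
both sides — the association matrix propagated over the row-type graph and
its transpose over the column-type graph — and the two results averaged,
so evidence from both entity neighborhoods contributes symmetrically.
Final scores are clipped to [0, 1]. Clipping rather than rescaling is
deliberate: it preserves the absolute meaning of the prediction threshold
(below), whereas per-matrix rescaling would make the threshold depend on
the score distribution of each run.

The closed form is implemented (`solve_closed_form`, dense LU) purely as a
test oracle; production scoring uses the sparse iteration, which handles
sizes the dense inverse cannot.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | fraction of score diffused from neighbors per step; 1−α retained from the labels. Larger α diffuses further and converges slower (iterations grow roughly like log tol / log α). 0.5 balances the two with no evidence favoring either extreme. |
| `tol` | 1e-6 | convergence tolerance on the max absolute score change; the distance to the fixed point is bounded by α/(1−α)·tol. |
| `max_iter` | 1000 | iteration cap; at the defaults convergence takes a few dozen iterations, so the cap only triggers at α near 1. |
| `tau` | 0.005 | prediction weight threshold; links scoring ≥ τ and absent from the input are reported as novel. 0.005 is the conventional cutoff for these probability-style weights. |
| `fusion` | max | max or mean similarity fusion (above). |
| `dthybrid_lambda` | 0.5 | degree-tuning exponent of the baseline's resource allocation; 0.5 splits the degree penalty evenly between the two endpoints. |
| `dthybrid_alpha` | 0.5 | weight of the a-priori similarity blend in the baseline; 0 is pure structural network-based inference. |

"Known" for the novelty filter means any nonzero input weight — a
partial-confidence input (0 < w < 1) is still an existing relation, and
re-reporting it would not be a discovery. Ties in the ranked output are
broken lexicographically by identifier so reports are byte-reproducible.

## DT-Hybrid baseline

The comparison method is the canonical degree-tuned two-phase resource
allocation on a bipartite layer with multiplicative similarity blending:
`w_ij = Γ(i)^{λ−1} Γ(j)^{−λ} Σ_l a_il a_jl / Γ'(l)`, then
`w'_ij = w_ij (α_dt s_ij + 1 − α_dt)` and `R = W' A`. It is implemented as
a faithful-in-spirit baseline of that family, parameterized by λ and α_dt,
not as a bit-exact port of any particular release. Degrees are weighted
(row/column sums), which coincides with link counts on the binary layers
the method is actually run on. Because the projection is undefined at
degree 0, the baseline requires harmonization: every entity must have at
least one nonzero entry in its similarity matrix and in both of its
association layers ("active"); the network is restricted to those common
entities before fitting, and an empty intersection is an error stating the
baseline is inapplicable. Recommendation scores are min-max rescaled to
[0, 1] by default so the same τ threshold applies; raw scores are available
with `rescale=False`.

## Synthetic generator

The generator emulates the structure of real tripartite repositioning
datasets — three sparse similarity graphs plus three very sparse, mutually
correlated association layers with only partially overlapping identifier
lists — without matching any real dataset's exact degree distributions.
Entities of all three types are assigned uniformly to `n_blocks` shared
modules; associations are Bernoulli(p_in) for same-block pairs and
Bernoulli(p_out) otherwise; intrinsic similarity is 0.8 for same-block
pairs plus Uniform(0, sim_noise) noise, symmetrized and clipped. The 0.8
plateau leaves headroom so noise does not saturate at 1. Cross-layer block
alignment is the point: the method's premise is that similarity and
association evidence reinforce, and a generator without that correlation
could not test for signal. `overlap_frac < 1` subsamples each layer's
identifier list independently, exercising union alignment and
harmonization. A single seed drives everything; per-layer streams are
spawned from one `SeedSequence`, so adding a layer never perturbs another
layer's draw.

Default conditions (50 drugs × 40 diseases × 30 targets, 5 blocks,
p_in = 0.6, p_out = 0.02, sim_noise = 0.1, overlap_frac = 1) are the study
conditions used by the test suite and the acceptance script: small enough
to evaluate in seconds, structured enough that holdout AUC cleanly
separates the propagation method (~0.85–0.9) from a degree-product
popularity baseline (~0.5).

What passing on synthetic data does **not** show: real similarity matrices
(chemical structure, disease semantics, sequence) are not block-uniform,
real association layers have heavy-tailed degrees and annotation biases,
and real identifier overlap is structured rather than random. Synthetic
results validate the machinery and the relative ordering of methods under
planted signal, not absolute performance on any real dataset.

## Evaluation machinery

Holdout splits remove `round(fraction · nnz)` links uniformly at random
from one relation layer and sample equally many true-zero pairs as
negatives; AUC is the rank-based probability that a held-out positive
outscores a sampled negative, ties counting one half (computed via
scikit-learn's ROC AUC). The degree-product baseline scores a pair by the
product of its endpoints' degrees in the train layer — the natural
"popularity" null for link prediction.

## Numerical choices and degenerate inputs

- Conflicting duplicate cells in an input file are an error (with the line
  number); opposite-direction duplicates in a similarity edge list are
  resolved by `max` — strongest evidence, deterministic.
- Self-edges in similarity files are dropped; the diagonal is structurally
  zero.
- Isolated nodes survive normalization as zero rows: their scores stay
  exactly `(1 − α) Y` from the opposite side's propagation.
- An empty association file loads as a 0×0 matrix with a warning rather
  than an error, so partially populated datasets can still be aligned.
- Propagation residuals (infinity norm of the score change) are recorded
  per iteration. They decay geometrically in the limit but the infinity
  norm is not contracted by α S̄ step-by-step, so monotonicity is only
  asserted after a 5-iteration burn-in in the diagnostics tests.
- Non-convergence at `max_iter` is reported (flag + warning), never raised:
  a partial score matrix is still useful and the manifest records it.

## Known limitations

- The projection densifies one chunk of the pairwise-minimum computation at
  a time; memory is O(chunk · n · m), fine to a few thousand entities per
  type, but the full ~10^4-scale regime would need a sparser min/max kernel.
- Two-sided averaging weights both entity types equally; no attempt is made
  to learn per-side weights.
- The novelty filter trusts the input layers completely: a relation absent
  because it was never curated is indistinguishable from a true negative.
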