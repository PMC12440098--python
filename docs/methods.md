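# Methods

## Generative model and inference

We observe `m = 2` modalities `X = {x_1, x_2}` on shared spots with 2-D
coordinates. The generative assumption is
`p(X, z_s, z_p) = p(z_s) Π_i p(x_i | z_s, z_p_i) p(z_p_i)` with standard
normal priors: `z_s` holds structure common to both modalities, `z_p_i`
holds structure unique to modality `i`, and all latents are mutually
independent.

Per modality, two independent encoders produce Gaussian posteriors
`q(z_s|x_i)` and `q(z_p_i|x_i)`. Each encoder is a 2-layer graph
attention stack (single head, ELU activations) over a mixed neighbor
graph; the second layer emits `2d` channels split into a mean and a
softplus-transformed scale floored at `σ_min = 1e-4` (preventing
posterior collapse to zero variance). The shared posterior over the
dataset is the uniform mixture of experts
`q(z_s|X) ≈ (1/m) Σ_i q(z_s|x_i)`.

The phase-1 objective per epoch (full batch, one Monte-Carlo sample per
term) is

```
L = (1/m) Σ_j [ w_j·L_self_j + Σ_{i≠j} ( w_i·L_cross_{j,i} + α_i·Var(M_ij(z_p_i)) ) ]
    + KL( q(z_s|X) ‖ N(0,I) ) + Σ_i KL( q(z_p_i|x_i) ‖ N(0,I) )
```

* `L_self_j` is the negative reconstruction log-likelihood of `x_j` from
  `[z_s, z_p_j]` with the shared posterior **detached** before sampling:
  its gradient reaches the private encoder and the decoder only.
* `L_cross_{j,i}` reconstructs `x_i` from the shared posterior of the
  *other* modality `j`, with the private slot filled by fresh
  `r_i ~ N(0, I)` noise. This is the only path training the shared
  encoders, so they must capture everything shared.
* `Var(M_ij(z_p_i))` is the across-spot output variance (population
  denominator, summed over output dimensions) of the measurement MLP,
  evaluated with frozen MLP weights — it penalizes the private encoder
  whenever `z_p_i` predicts anything about the other modality. The MLPs
  themselves are trained separately by MSE on detached latents. The
  variance term enters the total only once measurement training has
  begun (after `start_epoch`): before that the MLPs are untrained random
  maps whose output variance would indiscriminately suppress all
  private-latent variance, which is exactly what the warm-up exists to
  avoid.
* The private KLs are closed-form Gaussian; the mixture KL has no closed
  form and is estimated by stratified Monte Carlo (one reparameterized
  draw per expert, mixture log-density by logsumexp).

Training runs 400 epochs of Adam (gradient norm clipped at 5).
Measurement models start training after a warm-up (`start_epoch` = 200 in
clustering mode, 10 in topic mode), take one inner MSE epoch per outer
epoch, and are re-initialized and re-trained for 100 inner epochs
whenever the epoch index is divisible by 100; the main model is held
fixed during inner epochs. Topic mode adds a second 400-epoch phase that
freezes the private encoders (they are excluded from the optimizer) and
adds `Σ_i Σ_j HSIC(z_s_i, z_p_j)` with the biased estimator
`trace(K H L H)/(N−1)²`, unit-bandwidth Gaussian kernels
`K_mn = exp(−‖z_m − z_n‖²)` exactly as specified (no bandwidth
heuristic), `H = I − 11ᵀ/N`, and `N` equal to the full spot count
(spatial datasets here are at most a few thousand spots, so full-batch
HSIC is affordable; a subsampling hook exists for larger data).

## Decoders

**Clustering mode.** `p(x_i | z) = N(D_i([z_s, z_p_i]), σ_i)` with a
2-layer MLP mean and a learnable per-feature scale; inputs are the
dimensionally reduced matrices, so a Gaussian likelihood is appropriate.

**Topic mode.** Each feature count follows a Gamma-Poisson (negative
binomial) law with mean
`μ_i^f = l_i · softmax([z_s, z_p_i])ᵀ softmax(β_i)` — `l_i` the per-spot
library size, `β_i` a features × topics loading matrix whose columns are
softmax-normalized to probability distributions over features — and
per-feature dispersion `α_i^f` (Gamma shape; variance `μ + μ²/α`). A
regularized horseshoe prior sparsifies the loadings:

```
β_i^{f,j} ~ N( r_f,  c²δ_f²τ_j²λ_{f,j}² / (c² + δ_f²τ_j²λ_{f,j}²) )
r_f ~ N(log x̄_i^f, 1),  c ~ InvGamma(1/2, 1/2),  δ_f, τ_j, λ_{f,j} ~ HalfCauchy(1)
```

`β` and `log α` are point parameters; the scale hierarchy and `r_f`
carry mean-field guides — log-normal for the positive scales, normal for
`r_f` — sampled once per step with analytic guide entropies (lower
variance than sampled log-q terms). Guide locations initialize at the
prior-natural values (`r_f` at `log x̄_f`, scales at 1) with guide scale
0.1; `β` initializes at `log x̄_f` plus small noise so every topic starts
near the mean count profile.

The topic dimension per modality is `d_s + d_p`; the shared block is
common across modalities, giving `d_s + m·d_p` distinct topics overall.

## Preprocessing

Clustering mode (per modality kind):

| kind | recipe |
|---|---|
| transcriptome | drop genes in < 20 spots and spots with < 100 expressed genes; top 3000 HVGs; total-count normalize; log1p; PCA (50) |
| proteome | CLR, then PCA |
| epigenome peaks | TF-IDF (log-scaled IDF) + truncated SVD, first component dropped, 50 components |
| epigenome gene-activity | top 3000 HVGs on the pre-normalized matrix; log1p; PCA |
| metabolome | transcriptome recipe without the HVG step |

Topic mode: features in < 1% of spots and spots with < 1% of features are
removed (jointly across modalities so spot order stays aligned); then
proteome → CLR, transcriptome/metabolome → top 1000 HVGs on raw counts
followed by normalize + log1p, gene-activity → HVG selection only. The
filtered raw counts and their per-spot totals (library sizes) are kept
for the count decoder; library sizes are computed on the same feature set
the decoder reconstructs, so the likelihood mean is on the right scale.
Spots left with an empty library after feature selection are dropped with
a warning.

Notable choices: HVG selection runs before normalization (matching the
clustering-mode ordering) and uses the dispersion-based selector on a
log1p-normalized copy of the counts, after which the raw counts are
subset. CLR follows the Seurat convention
`log1p(x / exp(mean(log1p(x))))` with the mean across features of each
spot (a `margin` flag switches to per-feature). The spot filter applies
only to transcriptome-kind modalities; a 100-expressed-features threshold
is meaningless for a 100-feature panel.

**Neighbor graphs.** Per modality: union of (a) spatial adjacency — rook
(4-neighbor) adjacency when coordinates form an integer lattice,
otherwise the 6 nearest spatial neighbors (Visium-like default) — and
(b) k = 10 nearest neighbors by Euclidean distance in the preprocessed
data space, ties broken by spot index; symmetrized, self-loops handled by
the attention layer. Each edge records its provenance (spatial / knn /
both); Moran's I uses the spatial-only subgraph.

## Post-processing

* **Domain clustering**: full-covariance Gaussian mixture (EM, k-means
  initialization with 20 restarts, fixed seed) on `[z_s, z_p_1, z_p_2]`
  posterior means, with `z_s` the mixture mean across experts. A
  full-covariance GMM is the model family behind the classical
  mclust-style approach. Covariance regularization is relative to the
  data scale (`1e-4 ×` mean per-dimension variance): trained latent
  embeddings legitimately live at small amplitudes where an absolute
  floor would drown the covariance structure.
* **Topic pruning**: per latent dimension, Moran's I on row-standardized
  spatial weights with the normality-assumption variance gives a z-score.
  If the minimum z is below 0.3, a 1-D 2-means split of the z-scores
  prunes the lower cluster; independently, dimensions with pre-softmax
  standard deviation below 1 are pruned. Flags are recomputed from the
  full topic set, making pruning idempotent. Reported weights are the
  row-softmax of the concatenated posterior means (the same softmax the
  decoder applies).
* **Feature ranking**: columns of the column-softmaxed `β_i`, descending,
  ties by index.

## Evaluation metrics

* **Jaccard neighborhood similarity**: mean over spots of
  `|kNN_emb ∩ kNN_data| / |kNN_emb ∪ kNN_data|` (Euclidean, default
  k = 50, reported alongside scores). "Data space" defaults to the mode's
  preprocessed representation.
* **Fold change of top correlations**: for topic `z_k`,
  `d = log2( mean top-m1 r(z_k, x_1 features) / mean top-m2 r(z_k, x_2 features) )`
  with m = 5 for proteomics panels and 10 otherwise, selection by signed
  `r`. Positive `d` attributes the topic to modality 1. If either
  top-mean correlation is non-positive the ratio is undefined and NaN is
  returned with a warning.
* **Supervised scores**: ARI, MI, AMI, NMI, homogeneity, V-measure as
  thin wrappers over scikit-learn.

## The simulator

A `FactorLayout` partitions a grid into disjoint square zones, each
carrying a factor tagged shared / private-1 / private-2; uncovered spots
are background. The default: 36×36 spots, nine 6×6 zones on an evenly
spaced 3×3 arrangement, zone 0 private to modality 1, zone 8 private to
modality 2, seven shared. Zone coordinates are a documented fixed choice
(only the counts and sizes are prescribed); two alternative presets
(`default2`, `default3`) move the zones and the private assignments.

Each feature is assigned uniformly to one factor present in its modality
(background has no features; the other modality's private factor is
excluded). Counts are Gamma-Poisson: mean 20.2 where the feature's
factor is assigned to the spot ("active"), 0.2 elsewhere, shared Gamma
shape ("dispersion") 10, so `Var = μ + μ²/10`. Modality 1 (1000
features) additionally zeroes every entry independently with probability
0.5, recording the mask; the rule applies to all entries, active and
inactive. Modality 2 (100 features) has no inflation. Each background
spot independently fires a 5% "non-zero" event; when it fires, all
features of both modalities at that spot draw from the active
distribution (a `background_per_entry` flag switches to independent
per-entry events). Every decision — factor map, feature assignment,
activity, inflation and background masks — is returned, so tests can
verify claims exactly rather than statistically where possible.

What the simulation emulates: spatially coherent domains, modality-
specific structure, overdispersed zero-rich counts, unbalanced feature
panels. What it does not: continuous intensity modalities, spatial
gradients within domains, batch effects, segmentation noise, or
correlated features within a factor. Passing the recovery tests therefore
demonstrates the disentangling mechanics, not robustness to all real-data
pathologies.

## Defaults and design decisions

| parameter | default | rationale |
|---|---|---|
| latent dims `d_s`, `d_p` | 32/32 (clustering), 10/10 (topic) | topic counts are reported post-pruning, so the pre-pruning dimension is a capacity choice |
| hidden width / heads | 128 / 1 | standard small-graph capacity |
| learning rate | 3e-3 (Adam), 1e-3 (measurement) | fastest stable convergence on the simulation benchmarks |
| `w_i` | `max_j n_features_j / n_features_i` | a modality's log-likelihood scales with its feature count; without balancing, a 100-feature modality contributes ~10× less gradient than a 1000-feature one against the same KL pull, and its private structure emerges much later. Explicit `w` overrides. |
| `α_i` | 1.0 | no stated value; unit weight |
| epochs | 400 + 400 (topic phase 2), warm-up 200/10 | the prescribed schedule |
| σ floor | 1e-4 | avoids degenerate posterior scales |
| gradient clip | norm 5 | guards the count likelihood early in training |
| KL warm-up | none | none prescribed |
| Var denominator | N (population) | convention choice |
| measurement input | posterior sample (not mean) | keeps the variance penalty stochastic |
| fold-change base | 2 | attribution is reported as log2 throughout |

Numerical notes: the Gamma-Poisson log-likelihood and the HSIC penalty
are fused autodiff ops with analytic gradients, verified against scipy
and finite differences; `lgamma(x+1)` over the fixed count matrix is
cached. PCA/SVD signs follow a largest-|loading|-positive convention so
preprocessing is bit-reproducible. All randomness flows from explicit
seeds; identical seeds give bit-identical simulations, initializations
and loss histories.

Problem sizes used by the automated checks: distributional checks use
≥ 1e5 draws with 4-standard-error bands; oracle equivalences run at
N ≤ 50 (HSIC) and lattices ≤ 10×10 (Moran's I) at tight tolerances;
end-to-end recovery runs the full 1296-spot default simulation at a
reduced schedule of 100 + 100 epochs, where clustering reaches ARI ≥ 0.8
and both private topics are recovered on at least 2 of 3 seeds.

## Known limitations

* Two modalities only; the shared/private decomposition with subset-
  shared latents for m > 2 is out of scope.
* Full-batch training assumes datasets of at most a few thousand spots.
* The measurement-model variance penalty is a proxy for mutual
  information; a constant map has zero variance but so does a collapsed
  private latent — the reconstruction terms are what keep the private
  latents informative.
* Count modalities only in topic mode (the Gamma-Poisson likelihood);
  continuous modalities should use clustering mode.
* Histology images, peak calling, gene-activity computation and pathway
  scoring are out of scope; gene-activity matrices are consumed as given.
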