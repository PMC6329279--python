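# Methods

## Model

exprembed represents every gene *a* and every sample *i* of a bulk
expression matrix as an m-dimensional vector (default m = 50), plus one
scalar bias each. The predicted log2 expression of gene *a* in sample
*i* is

    Ĝ_ai = G_a · S_i + b_a + b_i

i.e. biased matrix factorization, the collaborative-filtering
formulation in which every cell of the n × k matrix is one training
example. The model makes no distributional assumption beyond "log2
expression is approximately low-rank plus per-gene and per-sample
offsets"; everything it learns comes from the matrix itself, not from
any curated knowledge base.

Input matrices are preprocessed by flooring values at 1 (counts below 1
are treated as quantification noise) and log2-transforming, so a
preprocessed value of 0 means "at or below the noise floor". TCGA-style
sample-type codes whose first character is `1` mark normal samples,
which are typically excluded before training a tumor model.

## Training

All weights are initialized i.i.d. uniform on [-0.05, 0.05]. Training
minimizes the mean squared error over cells with mini-batch Adam
(batch 64, β₁ = 0.9, β₂ = 0.999, ε = 1e-8, no weight decay by default —
these Adam moments are the standard defaults; the original description
of this setup does not state them). Each epoch shuffles all training
cells with a seeded generator. Gradients are the exact analytic
gradients of the batch MSE, hand-coded in numpy and verified against
central finite differences (relative error ≤ 1e-5 in the test suite).

Adam state is *lazy*: first/second moments and bias-correction step
counts advance only for the rows of G, S and the biases actually
touched by a batch. This matches sparse-Adam practice for embedding
tables and keeps updates independent of the number of untouched rows.

A seeded random fraction of cells (default 10%) is held out and scored
once per epoch; this cell-level holdout is how the package reports
generalization. Sample-level holdout would be an equally defensible
design; cell-level is implemented because the training example *is* a
cell.

The learning rate is deliberately a free parameter with a range test
(`lr_find`): one pass of mini-batches under geometrically increasing
rates, recording smoothed batch loss, suggesting the rate one order of
magnitude below the loss minimum. The library default of 1e-2 works
well on the synthetic problems shipped with the package; real matrices
should use `lr-find`.

Determinism: given identical config and seed, two runs produce
byte-identical serialized models (all floats are written with `%.17g`,
which round-trips float64 exactly; models are re-read with
round-trip-precise float parsing).

### Exchange symmetry

The factorization is symmetric in genes and samples. Exact
batch-for-batch symmetry under transposition additionally requires the
initial weights and the cell enumeration to be mapped through the
transpose; `train(..., initial_model=)` exposes the hook, and the
property is verified in full-batch mode where the enumeration is
irrelevant.

## Geometry

Relatedness between entities is Euclidean distance between their
vectors. "Close neighbors" of an anchor are all entities at distance
*strictly* below a threshold, 0.1 by default — the strict inequality is
deliberate and tested at the boundary. Neighbor lists are sorted by
distance with lexicographic id tie-breaks for reproducibility. Queries
are exact pairwise computations: at k ≈ 20k genes × m = 50 an
approximate index would buy nothing.

A sample group's *centroid* is the coordinate-wise mean of its member
sample vectors; multiplying it with the gene entity matrix gives the
group's *predicted profile*, one scalar per gene. Biases are excluded
from profiles by default (a flag adds the gene bias plus the mean
member sample bias); profile *differences* between genes are unaffected
by the sample-side terms either way.

## Dimension interpretation and subtyping

- Group-by-dimension matrix: one centroid row per sample group.
- "Hot" dimensions for a group: standardized group-vs-rest contrast
  (group coordinate minus mean of the other groups, divided by the
  across-group population SD; 0 when all groups coincide). Chosen as
  the simplest quantitative stand-in for what is otherwise a visual
  heatmap judgement.
- Top genes per dimension: ranked by signed or absolute coordinate
  (absolute by default; both signs are exposed because a dimension can
  be informative at either end).
- Over-representation analysis: one-sided Fisher test computed as the
  hypergeometric upper tail P(X ≥ overlap) (scipy), Benjamini–Hochberg
  step-up FDR implemented directly (q_i = min_{j≥i} p_(j)·T/j, clipped
  to 1) and cross-checked against statsmodels in the tests. A term is
  significant iff p < 0.01 and FDR < 0.05. The default universe is all
  genes in the model; it is overridable because the appropriate
  background is analysis-specific.
- Signature dimensions: each signature gene maps to the dimension with
  its largest absolute coordinate (ties to the lower index) — the
  simplest rule that yields a one-dimension-per-gene mapping.
- SD filter: keep dimensions whose across-sample SD strictly exceeds
  the mean of the per-dimension SDs.
- UPGMA subtyping: average-linkage agglomerative clustering on
  Euclidean distances (scipy linkage, which implements the unweighted
  mean of cross-pair distances), flat labels by cutting at a requested
  cluster count. The cluster count is a parameter because no principled
  cut rule exists for this use. Tests verify agreement with an
  independent O(n³) naive UPGMA.

Dimension indices are 0-based in code; reports print 1-based labels.

## Biomarker discovery

Given responder and non-responder sample lists plus anchor genes
(e.g. the immune checkpoints PDCD1, CD274, CTLA4):

1. compute both group centroids and predicted profiles;
2. per anchor, profile neighbors = genes whose predicted value is
   strictly within the threshold of the anchor's. Profiles are
   one-dimensional per gene, so Euclidean distance reduces to absolute
   difference — the only reading under which the procedure is
   well-defined on the stated objects;
3. responder-exclusive neighbors = responder-profile neighbors minus
   non-responder-profile neighbors;
4. candidates = exclusive neighbors ∩ the anchor's close neighbors in
   gene-entity space, at the same threshold (only one threshold is
   defined in this workflow);
5. report per-candidate Pearson correlation with the anchor across
   responder samples (responders only, by design), plus a deduplicated
   union across anchors.

The candidate set is recomputed by an independent brute-force pass in
the tests on every fixture.

## Synthetic data

The generator emulates what the model assumes: latent gene vectors
G* (k × r) and sample vectors S* (n × r), biases, and i.i.d. Gaussian
noise on the log2 scale, with a constant shift to non-negativity
(shift, not clipping, to keep the planted rank exact). Structure:

- samples fall into groups; group centers are Gaussian with scale set
  so expected center-to-center distance equals `group_separation`
  (default 2.0 latent units); samples jitter isotropically around their
  center (sd 0.3);
- genes are background (i.i.d., coordinate sd 1/√r) or members of
  planted modules (module center + small spread, default 0.05), giving
  co-regulated blocks;
- defaults: n = 200 samples, k = 500 genes, rank 5, 4 groups, two
  25-gene modules, noise sd 0.1, gene/sample bias sd 0.5/0.25. These
  sizes give expression-like values (≈ 0–7 after shifting) and are the
  standing conditions for the recovery tests.

The responder scenario places the responder group center on latent
axis 1 and the non-responder center on axis 2 (separation 3.0), plants
the anchor's module at `module_effect` (default 1.0) along axis 1, and
offsets module members from the anchor along axis 2 by 0.065–0.09 —
strictly inside the 0.1 entity threshold, but projecting to > 0.1 on
the non-responder centroid. Responder samples get extra spread (sd 0.5)
along their own axis so module genes co-vary with the anchor
specifically in responders. By construction the module members are
exactly the genes that are entity-close and responder-exclusive
profile-close to the anchor, with margins (verified numerically across
seeds) that survive centroid jitter.

What the generator does **not** emulate: count-level sampling noise
(negative binomial), library-size and batch effects, RSEM
normalization artifacts, or gene-length biases. Passing the recovery
tests therefore shows the optimizer and the downstream procedures are
correct on data satisfying the model's assumptions — not that a
particular real cohort is well-approximated by them.

## Numerical and design notes

- Recovery checks train at m = 10 on rank-5 data for 30 epochs at
  lr 1e-2 (≈ 10 s per run on one CPU); held-out cell MSE lands at
  0.017–0.019 against a noise-variance floor of 0.01.
- A trained embedding is identified only up to an invertible linear
  map, so absolute distances (and the 0.1 threshold) are only
  meaningful within one trained model. Cross-model checks in the tests
  use scale-free quantities (distance ratios, within/between
  contrasts); threshold-exact discovery checks run on the ground-truth
  vectors.
- Genes with zero expression everywhere are kept; their vectors
  converge toward bias-only predictions. Dropping them is a caller
  decision via `filter_samples`/standard pandas tooling.
- Degenerate inputs are errors, not silent results: empty filters,
  empty groups, single-sample SD filters, zero-variance Pearson (NaN
  with a warning), non-finite training loss (error advising a lower
  learning rate).
- Composite `SYMBOL|ENTREZ` identifiers resolve to the symbol; unknown
  (`?`) or colliding symbols keep the full composite string so ids stay
  unique without dropping rows.

## Known limitations

- The trainer is single-threaded numpy; at TCGA scale (~10k samples ×
  20k genes) a run is hours, not minutes. The algorithm is unchanged by
  scale; only wall-clock differs.
- Mini-batch Adam at a fixed rate oscillates once the loss is near
  machine floor on noiseless problems; loss-floor comparisons in tests
  therefore use noisy data.
- `lr_find`'s suggestion is a heuristic (minimum/10 on a smoothed
  curve); inspect the curve for real data.
- Flat-cluster labels depend on the requested count; UPGMA trees are
  deterministic, but cluster numbering is by first appearance only.
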