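# Methods

## Model and assumptions

The package treats functional association between human genes as geometric
proximity in an embedding of the high-confidence PPI network. The underlying
assumptions are:

* edges with STRING-style confidence ≥ 800 are reliable enough to define the
  topology worth learning; lower-confidence edges are held out (and can serve
  as an evaluation set for the predicted scores);
* random-walk co-occurrence is a sufficient statistic for functional
  neighbourhood — two genes whose walk contexts overlap are functionally
  related even if not directly linked;
* a disease's cytokine involvement is summarised by the average association
  of its gene set with each cytokine, i.e. gene-set membership is treated as
  exchangeable and unweighted.

The per-disease raw averages are not comparable across diseases (they drift
with gene-set size) nor across cytokines (each cytokine has its own baseline
association level). The NAAS normalisation addresses both at once: diseases
are grouped into size bins (2–9, 10–19, 20–49, >49 genes) and each raw
average is replaced by its empirical-CDF rank *within bin, per cytokine*,
with a strict inequality so the bin minimum maps to 0 and tied values score 0
against each other. NAAS therefore lies in [0, (m−1)/m] for bin size m, is
monotone in the raw average, and is invariant under any strictly increasing
transform of the raw scores. A pooled-reference mode (one ECDF per bin over
all cytokines) is available for comparison; per-cytokine is the default
because it makes the 126 profile components comparable with each other.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| confidence cutoff | 800 (of 1000) | inclusive high-confidence edge filter |
| walks per node / walk length | 10 / 30 | corpus size per gene |
| p, q | 1.0, 1.0 | second-order walk bias (1,1 = unbiased walk) |
| dim / window / min_count | 64 / 10 / 1 | skip-gram geometry and context |
| epochs | 5 | SGNS passes over the corpus |
| score cutoff | 0.8 | strict Association Score threshold for subnetwork edges |
| cluster k | 6 | cytokine dendrogram cut (4 on the synthetic world) |
| alpha / correction | 0.05 / Bonferroni | validation significance |
| literature frequency cutoff | 0.005 | "known association" flag for recall |

The walk bias parameters p and q are exposed but default to the unbiased
walk; walks choose neighbours uniformly (all retained edges are already
high-confidence), with confidence-weighted transitions as an option. Dead
ends truncate a walk rather than erroring. Training runs single-threaded
from one seeded generator, so embeddings are bit-for-bit reproducible —
batch-order effects are part of the seed, not noise.

## Skip-gram trainer

The SGNS trainer is a vectorised numpy implementation: dynamic window
(uniform 1..window per centre, as in word2vec), unigram^0.75 negative
sampling, linearly decaying learning rate (0.025 → 1e-4), mini-batch SGD
with scatter-add updates. Because a mini-batch applies all its gradient
contributions at the same stale parameters, the batch size is capped at
0.5·V/(k·α₀) for vocabulary V, k negatives and initial rate α₀; without the
cap, small vocabularies receive hundreds of accumulated contributions per
row per batch and training diverges. Input-side vectors are the embedding.

## Synthetic worlds

The generator emulates the statistical features the analysis consumes, not
the marginals of any real resource:

* **Network**: planted-partition graph (default 8 modules × 62 genes,
  p_in = 0.5, p_out = 0.01) with within-module confidences uniform in
  800–1000 and between-module in 150–799, reproducing the high/low-confidence
  dichotomy at the 800 cutoff.
* **Cytokines**: 10 per module in 4 of the modules (40 total), one catalog
  category per family, plus 5 receptor genes per cytokine module.
* **Diseases**: 60 sets with bin mix (0.42, 0.28, 0.18, 0.12) — the bin-1
  share matches the observed predominance of small gene sets in real
  disease–gene resources; half the diseases are *enriched*, drawing 90% of
  their genes from one cytokine family's module.
* **True affinity**: the fraction of a disease's genes in the cytokine's
  home module; **literature frequency** = affinity + N(0, 0.05), clipped to
  [0, 1], with 10% of entries unsampled (identity monotone link — the
  simplest rank-preserving choice, since only ranks enter the validation).

What these worlds do *not* emulate: STRING's heavy-tailed degree
distribution, overlapping pathway membership, disease ontology structure,
annotation bias in literature frequencies, and cytokine pleiotropy (each
synthetic cytokine has exactly one home module). Passing recovery tests
therefore demonstrates that the pipeline's inference machinery is correct
and well-calibrated on its own modelling assumptions — not that those
assumptions hold for real data.

Note that "unenriched" diseases are random draws, not true negatives: a
random gene set still has a genuine (random) module composition, and the
literature frequencies track it, so many unenriched diseases validate too.
The planted contrast is that enriched diseases validate at a higher rate.

## Numerical choices

* **Spearman p-values**: exact enumeration only for n ≤ 10 (n! orderings);
  Monte-Carlo permutation with the add-one estimator (1+k)/(1+N) otherwise,
  seeded; asymptotic t-approximation as the default for realistic lengths.
  Two-sided by default; validated diseases additionally require ρ > 0. The
  add-one estimator is super-uniform; at short vector lengths (n ≈ 10) it is
  visibly conservative because the observed statistic ties with permuted
  replicates on the coarse support, so calibration is measured at length 25
  where tie probability is negligible.
* **Eigensolver**: dense symmetric decomposition below 500 nodes, sparse
  Lanczos above; eigenvalues below 1e-8 × the largest are treated as zero.
* **Disconnected subnetworks**: the zero eigenvalue is degenerate and no
  "smallest non-null" eigenvector separates components, so the partition
  uses the null-space direction orthogonal to the constant vector, which
  splits components exactly; the Fiedler value is reported as 0.
* **Sign-cut orientation**: the Fiedler vector's global sign is fixed so the
  positive (well-connected) class carries the larger total degree, with node
  count and then lexicographic order as tie-breaks; articulation tolerance
  defaults to 1e-6 × max|w|.
* **ICD**: edge weights d_pi are the Association Scores (weighted mode) by
  default, with a pure edge-count mode; only pathogenesis↔cytokine edges
  enter the sum. Disease genes that are themselves catalog cytokines sit on
  the cytokine side only, so they are never double-counted in N_p and N_i.
* **Self-exclusion**: when a cytokine is in its own disease set, its
  self-similarity of 1 is excluded from its raw average (disablable).
* **Duplicate edges** keep the maximum confidence (order-insensitive);
  self-loops are dropped with a warning.

## Known limitations

* On a *pure* complete-bipartite subnetwork (every pathogenesis gene linked
  to every cytokine, nothing else) the Fiedler eigenspace is supported on
  one node side only: the smaller side's entries split and the larger side
  sits at zero, so all pathogenesis genes can land in the articulation class
  and key-gene extraction is uninformative. This is intrinsic to the sign
  cut, not a solver artefact. Key-gene recovery is therefore meaningful — and
  tested — on subnetworks with a dense core *plus* peripheral structure,
  which is also the regime real disease subnetworks occupy.
* The sign cut coincides with the global minimum cut on two-block structures
  joined by a weak bridge (verified against brute-force enumeration), but
  not on arbitrary graphs, where the spectral cut prefers balanced
  partitions over minimum ones (e.g. stars).
* The trainer is CPU-only and intended for networks up to a few tens of
  thousands of nodes; no alternative embedders are provided.
* Recall and validated-disease counts depend on the literature table's
  coverage; cytokines never sampled in the literature are silently outside
  the comparison.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
496-gene default world (≈ 7,400 high-confidence edges, 40 cytokines,
60 diseases); the clustering-stability check repeats the embedding over five
seeds. Unit tests use worlds of 80–120 genes. These sizes were chosen so the
planted structure is unambiguous while the whole analysis, including five
embeddings, completes in minutes on one CPU.
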