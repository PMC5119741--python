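# Methods

## Problem and model

A profile-HMM database `Λ = [λ_1 … λ_N]` answers homology queries by
exhaustive sequential search: a query is aligned against every profile,
costing N profile–profile comparisons, and the targets scoring at or
above a threshold φ are the hits. Profile–profile scores are on a 0–100
percent scale (the "probability" score of profile–profile search tools,
combining alignment significance and secondary-structure agreement);
scores ≥ 95 are treated as near-certain homology, so φ defaults to 95.

`pclust` accelerates batch querying by remodeling the database as
clusters of mutually similar profiles:

1. **Similarity matrix.** All-against-all scores `s_ij = score(λ_i, λ_j)`
   are asymmetric (the score depends on which profile is the query), so
   the working matrix keeps `S_ij = max(s_ij, s_ji)`. The diagonal is
   forced to 100: self-homology is certain by definition, and the
   representative-selection argmax is invariant to any constant diagonal.
2. **Clustering.** Three crisp backends over S:
   - *connected components* of the graph with edges `S_ij ≥ ψ`;
   - *single-linkage* agglomeration of the rows of S/100 treated as
     N-dimensional feature vectors under Euclidean distance, dendrogram
     cut at ζ (criterion `distance`, or the inconsistency coefficient);
   - *k-means* on the same row embedding with squared Euclidean
     distance, careful (k-means++) seeding and Lloyd iterations.
3. **Representatives.** Each cluster of size ≥ 2 gets the member
   maximizing `f(λ_i) = Σ_{j∈cluster} S′(i, j)`, the within-cluster
   similarity sum (ties to the lexicographically smallest ID). Singleton
   clusters get no representative; their members form a pool of M
   profiles scanned exhaustively at query time.
4. **Overlapping re-assignment (optional, default on).** Every profile
   λ_j is scored against the K representatives; its personal threshold
   ϑ_j is the mean of those K scores, and λ_j joins every cluster whose
   representative scores it ≥ ϑ_j. Since the max of a finite vector is
   at least its mean, every profile lands in at least one cluster, so
   the singleton pool empties (M = 0). Crisp memberships of represented
   clusters are retained — the re-assignment only adds memberships — and
   representatives are unchanged.
5. **Retrieval.** A query is scored against the K representatives; the
   best one's cluster (ties: lowest cluster index) is searched in full;
   the singleton pool is scanned last. Hits are the stage-2/3 targets
   scoring ≥ φ. The comparison cost per query is exactly
   `NC = K + size(chosen cluster) + M` versus N for sequential search.

Because only a slice of the database is ever scored, the clustered hit
set is a subset of the sequential one: precision is trivially 1 and the
quality metric is recall. Per query, recall is `|β′ ∩ β| / |β′|` (β the
clustered hits, β′ the sequential hits; defined as 1 when β′ is empty).
Batch recall is `Σ|β| / Σ|β′|`, valid as an intersection ratio precisely
because of the subset property — the library raises a diagnostic error
if a subset violation reveals an inconsistent scorer. Cost reduction is
`1 − Σα/Σα′` on wall-clock times and, hardware-independently,
`1 − Σ NC_i / (T·N)` on comparison counts; the test surface uses the
comparison version, wall-clock being reported as informational only.

## Parameters

| parameter | meaning | scale | default | notes |
|---|---|---|---|---|
| φ | match threshold | 0–100 | 95 | ≥ comparison (hits include the boundary) |
| ψ | component edge threshold | 0–100 | 95 | edges with weight < ψ removed |
| ζ | dendrogram cutoff | row-embedding distance | 0.9 | see re-tuning note below |
| k | k-means cluster count | count | 160 | tuned to a 4284-profile corpus |
| criterion | dendrogram cut rule | — | `distance` | `inconsistency` also available |
| n_restarts | k-means restarts | count | 1 | seeded; best inertia wins |

The defaults k=160, ζ=0.9, ψ=95 are the operating point tuned on the
TIGRFAMs release 13.0 corpus (4284 profiles) and are **corpus-specific**.
ζ and k in particular do not transfer across database sizes: the row
embedding has one coordinate per database profile, so typical
inter-profile distances grow like √N and the useful ζ range scales with
the matrix. `scripts/acceptance.py` therefore re-tunes ζ for the
desk-scale benchmark with a small sweep (grid 3.0–4.0, scored by crisp
batch recall plus comparison reduction on a tuning query set), mirroring
the sweep exposed as `pclust sweep`; k is set to the planted block count.

## Numerical and design choices

- Scores are floats on the 0–100 scale everywhere; no 0–1 rescaling is
  exposed, to avoid silent mix-ups. Clustering internally divides by 100.
- The clustering feature space is the rows of S/100, not a 1−S/100
  pairwise dissimilarity. Treating row vectors as samples means two
  profiles are close when they relate similarly to the whole database,
  which is more robust to a single noisy pair but couples the geometry
  to N (see the ζ re-tuning note). The dissimilarity alternative was
  considered and rejected to keep one canonical embedding for both
  geometric backends.
- Single-linkage uses `scipy.cluster.hierarchy` (`linkage` +
  `fcluster`); the `distance` cut keeps leaves whose cophenetic distance
  is ≤ ζ. An O(N³) naive agglomeration oracle in the test suite pins the
  semantics.
- k-means seeding uses `sklearn.cluster.kmeans_plusplus`; the Lloyd loop
  is in-package so the within-cluster sum of squares can be traced per
  iteration (a monotonicity guarantee the tests assert; the reference
  `sklearn.KMeans` is the independent cross-check on separated data).
  Assignment ties break to the lowest centroid index; convergence is
  centroid movement ≤ 1e-6 with a 300-iteration cap; clusters that end
  up empty are dropped.
- Eq-style accounting: stage 2 scores every member of the chosen
  cluster, including its representative, as one scorer call each, so
  `cluster_comparisons == size(c_i)` exactly. Representatives can be
  reported as hits only via that stage-2 score.
- The overlapping rule is applied to all N profiles, including
  representatives themselves (a representative may join another
  cluster); the mean over K includes zero scores verbatim.
- Matrix text format: tab-separated with an ID header row and column,
  6 significant digits; a headerless square numeric dialect with an
  optional sidecar ID list is auto-detected. Symmetry is validated to
  1e-9; asymmetric input loads only with `symmetrize_on_load=True`.
  Missing pairs are not representable — the method is defined on a
  dense all-against-all matrix.
- Empty-baseline queries: per-query recall is defined as 1.0 (nothing
  to miss); in batch recall they contribute zero to both sums.

## Synthetic benchmark

`pclust.synthetic` generates planted-partition matrices: blocks of
profiles with within-block scores uniform on `within_range`, all other
pairs uniform on `between_range`, per-orientation asymmetry jitter, and
a fraction of planted singletons scoring in the between range against
everyone. Query vectors are a database row plus seeded Gaussian noise,
emulating an external sequence resembling one family. Uniform score
distributions were chosen over beta/Gaussian for analyzability: the
range endpoints are the knobs and separation statements become exact.

Two configurations matter:

- **Default desk-scale spec** (N=200, 12 blocks, 10% singletons, within
  96–100, between 0–60, jitter 2, seed 1337): separated, so thresholding
  at ψ=95 recovers the blocks exactly; small enough for the O(N³) test
  oracles.
- **Separated benchmark with narrow between range** (10 blocks of 20,
  between 24–26, jitter 0.5): every profile's score against a foreign
  representative is provably below its mean over all representatives,
  so the overlap step adds no memberships, clusters stay exactly the
  blocks, batch recall is exactly 1.0 and the comparison reduction is
  exactly `1 − (K + block_size)/N = 0.85`.

The acceptance script additionally uses a **noisy benchmark** (between
20–90, query noise 3) where between-block scores approach φ, so
sequential search finds cross-block hits that crisp retrieval misses;
this makes the recall cost of clustering, and the recall recovered by
overlapping, visible at desk scale.

What the synthetic data does *not* emulate: the heavy-tailed score
distributions of real profile–profile search, alignment-length effects,
the non-transitivity structure of real homology (synthetic blocks are
transitive by construction), and wall-clock costs of real alignment.
Passing tests demonstrate the combinatorial and accounting guarantees of
the method and its qualitative recall/cost trade-offs, not recall values
on any real corpus.

## Problem sizes

The test suite runs 200-profile benchmarks with ~100-query batches and
exhaustive N ≤ 30 oracle checks; the acceptance script uses two
200-profile matrices, 100 evaluation queries plus 30 tuning queries, and
a 6-point ζ sweep. These sizes keep every oracle exact and the whole
suite fast while exercising all code paths at a scale where cluster
structure, singletons and overlap effects all occur.

## Known limitations

- No sparse or out-of-core matrix: memory is O(N²). The 4284-profile
  scale of the original corpus is unproblematic; 10⁵+ profiles would
  need a different store.
- Only the single best representative's cluster is searched
  (`top_n_clusters` exists but > 1 is an extension beyond the validated
  design); a query equidistant between two clusters pays full recall
  cost for the wrong choice.
- The self-regulated overlap threshold is one heuristic; no alternative
  (quantile, fixed-count) is implemented.
- ζ's inconsistency-criterion variant is implemented and tested for
  plumbing but has no reference counts to validate against at desk
  scale.
- E-values, alignment coordinates and the MSA-based representative
  variant (building a consensus profile per cluster) are out of scope;
  the latter requires external MSA/profile-building tools and was the
  weaker variant in the original study.
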