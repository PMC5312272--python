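# Methods

## Ranked lists and signature reversion

The pipeline's single currency is a total order over unique feature ids
(probe sets or gene symbols), 1-based, rank 1 = most up-regulated. Rankings
are built from signed differential-expression scores by descending sort;
ties break lexicographically by feature id everywhere in the package, so
every operation is deterministic and seed-free. Reversal maps position i to
N−i+1 and negates any attached scores; it is an involution. Note that on
lists with tied scores, reversal flips the relative order of the tied
features, so attached scores are only required to be non-increasing along
the order — the lexicographic tie-break is a property of ranking
construction, not an invariant of the type.

Replicate rankings (multiple cell lines or dosages for one drug) are
aggregated into a prototype ranked list by Borda count: each feature scores
the sum of (N − position) over the inputs, and the sums are re-ranked. Borda
was chosen over hierarchical pairwise merging because it is
order-of-input-invariant, deterministic, and hand-checkable; the aggregation
scheme is isolated behind `merge_prl` so alternatives can be added.

## Cross-platform conversion

Step 1 (collapse): each gene takes the best (smallest) position among its
probes; genes are ordered by that position. Step 2 (expand): each target
probe inherits its gene's position as a provisional score; target probes
whose gene is absent from the gene ranking receive the center score
(M+1)/2, where M is the number of ranked genes — the arithmetic realization
of "place unmatched probes at the center of the ranking". The final order
sorts provisional scores ascending with lexicographic tie-break, so probes
sharing a gene, and the unmatched center block, are each contiguous and
alphabetical. Annotation maps must be many-probes-to-one-gene; probes
annotated to several genes are rejected at load time with their names.

A consequence worth knowing: with a many-to-one annotation, converting a
*reversed* ranking is not the reversal of the converted ranking, because
the best-rank rule picks a different witness probe per gene in each
direction. The two agree exactly when the source annotation is 1:1, and the
property test asserts it only there.

## Transcriptional distance

The enrichment score is the classic unweighted Kolmogorov–Smirnov running
sum (hits +1/|S|, misses −1/(N−|S|)), signed deviation of maximum
magnitude. Drug PRLs carry ranks only — there is no expression magnitude to
weight by — so the score-weighted GSEA variant is not applicable. The
running sum is evaluated in integer arithmetic on the k(N−k)-scaled lattice
(hits count N−k, misses −k), so the extreme and the declared tie rule — a
positive deviation beats a negative one of equal magnitude — are exact, and
only the final division is floating point. Identity assertions in the tests
therefore hold to 1e−12 trivially.

The total enrichment score TES(x → y) = 1 − (ES_up − ES_down)/2 maps
identical regulation to 0 and opposite regulation to 2; the distance is the
symmetric average of the two directions. Default extreme-set size s = 250
(configurable; tests use small s so 2s ≤ N holds on toy universes).

## Querying and enrichment

Neighbor selection uses d ≤ τ inclusive, τ = 0.86 by default. The threshold
is treated as inclusive deliberately; τ is a tunable and the boundary case
is documented rather than hidden. τ is accepted on (0, 2]; τ = 2 selects
every drug. Only community-labeled drug nodes can be neighbors — query
nodes never are, however close.

Community enrichment is the exact upper-tail hypergeometric probability
P(X ≥ k) of drawing k community members in n neighbor draws from the
universe of all community-labeled drugs (query nodes are not part of the
universe). It is evaluated by exact integer binomial sums with one final
division. The significance flag uses the raw p < α (default 0.05);
Benjamini–Hochberg adjusted values are reported in the same table but never
substituted into the flag.

Candidate target genes for a (reverse signature, drug PRL) pair are the
intersections of the two top-k and the two bottom-k extreme sets
(k_extreme = 100 by default), ordered by signature position — genes whose
predicted regulation under pathway inhibition the drug reproduces.

## Synthetic world

The generator emulates the structure the pipeline needs and nothing more: a
drug compendium partitioned into communities of correlated rankings, and
paired wild-type/mutant expression vectors with planted signal.

* Oncogene profile: wild-type baseline ~ N(7, 1) per gene (an arbitrary
  log-intensity-like scale; only the difference matters); the mutant adds
  +signal_strength to the planted up-set, −signal_strength to the down-set
  (signal_strength = 3.0), plus N(0, noise_sd) measurement noise in score
  units. Planted sets and baseline depend only on the seed; noise also
  depends on the replicate index, so replicates are independent readouts of
  one truth — mirroring a three-replicate query design.
* Drug network: each community has a latent prototype ranking — a random
  permutation, except the inhibitor community, whose prototype is the
  reverse of the oncogene signature. A member drug jitters the prototype's
  positions with Gaussian noise of sd = noise_sd × n_genes and re-ranks, so
  noise_sd is a dimensionless fraction of list length controlling rank
  concordance monotonically.

Defaults are the calibration world used by the acceptance tests: 1000
genes, 60 drugs, 6 communities, 5 inhibitors, 50+50 planted genes,
noise_sd = 0.3. Calibration measured before the tests were frozen: at this
configuration all 20/20 seeds recover the 5 planted inhibitors in the
three-node intersection at τ = 0.86 and rank the inhibitor community first
(inhibitor–query distances ≈ 0.42–0.46 against ≈ 0.85–1.1 for unrelated
drugs).

What a green synthetic benchmark does **not** establish: realistic cMAP
expression magnitudes, batch or platform noise, overlapping drug
mechanisms, community misassignment, or the literature-curated
post-selection a real repositioning study applies to its hit list. It
establishes that the machinery — reversal, distance, thresholding,
intersection, enrichment — does exactly what its definitions say at scale.

## Numerical and design notes

* Enrichment score and hypergeometric p are exact (integer arithmetic up to
  one final division); distances inherit ~1e−16 float error from the
  averaging, hence the 1e−12 tolerances.
* Neighbor monotonicity in τ, involution of reversal, permutation
  invariance of ranking/merging, and extremes-set disjointness are enforced
  as property tests.
* Whether query nodes should be built from single profiles or merged
  replicates is left to the caller: both `rank_from_scores` on one table
  and `merge_prl` over several rankings produce valid query nodes.
* The enrichment universe is defined as the community-labeled drugs; the
  alternative (all nodes including queries) would dilute every test by the
  number of query nodes while adding no information.

## Known limitations

* `build_network` computes the full pairwise distance matrix; at real
  compendium scale (~1300 drugs) a query-only distance computation would be
  preferable. The library functions (`distance`, `neighbors`) support that
  access pattern directly.
* GMT community files assign each drug to exactly one community; soft or
  overlapping memberships are rejected.
* The probe-conversion center rule places all unmatched target probes in a
  single lexicographic block; any information their source ranks carried is
  discarded by design.
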