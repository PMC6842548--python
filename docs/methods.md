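# Methods

## Problem setting and model

`purank` addresses candidate-gene prioritization when only positive
examples exist. The data model is a gene × feature matrix of boolean
indicators (a gene either carries an annotation — pathway membership,
ontology term, interaction with a known positive, expression signature —
or it does not), with the feature columns partitioned into named source
blocks mirroring the contributing databases. Labels are positive-unlabeled:
a seed set P of known positives and an unlabeled pool U that mixes
undiscovered positives with the (majority) negatives.

The base learner everywhere is Bernoulli naive Bayes: features are treated
as conditionally independent given the class, and a feature's *absence* is
evidence too (the encoding is total, so 0 is an observation, not missing
data). With Laplace smoothing a > 0,

    P(f=1 | c) = (count(f=1 in c) + a) / (n_c + 2a),

priors are training-class proportions, and every likelihood product is a
sum of logs — with feature spaces in the thousands the direct product
underflows double precision. Posteriors are normalized through
`logsumexp`. The decision rule is positive iff P(pos|x) > 0.5; an exact
tie classifies negative, the conservative choice when the costly error is
a false positive admitted into the reliable-negative set.

## Reliable-negative extraction and fusion

Three two-step extractors produce candidate RN sets:

- **Two-step NB.** Train NB with P vs all of U (U provisionally negative);
  RN is the subset of U the model still classifies negative. Deterministic.
- **Spy.** Hide ⌊s·|P|⌋ positives (default s = 0.15) inside U, train NB
  on P∖S vs U∪S, and use the spies' posterior distribution to calibrate
  the cut: the threshold is the noise-level quantile of spy posteriors
  (default noise level 0, i.e. the minimum), and RN is every unlabeled
  gene scoring strictly below it. The minimum-spy rule guarantees by
  construction that no RN member scores at or above any spy, but it is
  not a guarantee of zero contamination: the minimum of a handful of spy
  scores sits *inside* the positive score distribution, so an occasional
  hidden positive can fall below it. On default synthetic data this
  contamination is ~0.5% of RN (20-seed pilot), which is why tests assert
  purity ≥ 0.98 rather than exact cleanliness.
- **Rocchio.** Rows are L2-normalized; prototype vectors are
  α·mean(P̂) − β·mean(Û) for the positive class and symmetrically for the
  negative (defaults α = 16, β = 4, the conventional constants from the
  text-classification literature the method originates in). RN is every
  unlabeled gene strictly closer in cosine similarity to the negative
  prototype. All-zero rows have no direction; they are excluded from RN
  and logged rather than silently classified. **Roc-SVM** optionally
  refines an initial Rocchio RN by iteratively training a linear SVM on
  P vs RN and absorbing unlabeled genes classified negative, to a fixed
  point or an iteration cap (default 10); it returns the final iteration's
  RN without a best-iteration selection heuristic.

Because no extractor dominates, the pipeline fuses them: each algorithm
runs `runs_per_algorithm` times (default 5; the stochastic spy varies by
derived sub-seeds, the deterministic NB and Rocchio by seeded 90%
subsampling of U without replacement), RN memberships are tallied, and the
fused RN keeps genes with at least `fusion_threshold` votes (default 11 of
the 15 runs). The replicate-pool construction — how many runs per
algorithm and how the deterministic ones vary — is a design choice of this
package; all knobs live in `RunConfig`. Fusion is antitone in the
threshold by construction. Note the composition with later stages is *not*
monotone: lowering the fusion threshold enlarges RN, which shrinks the
residual pool and can remove would-be candidates.

## Consensus prediction and ranking

P ∪ RN is split into `consensus_folds` (default 10) seeded stratified
folds. Each fold model trains on the other folds with the larger class
downsampled to the smaller (seeded), so class priors are balanced and the
classifier carries no frequency bias. Every residual gene (U ∖ RN) is
scored by all models; the default consensus rule is unanimity
(`consensus_required_votes` = folds), configurable. Candidate sets are
nested as the vote requirement rises.

Ranking uses the seed feature-support vector s(j) = Σ_p Seed(p,j) and
scores each candidate W(i) = Σ_j Candidate(i,j)·s(j) — an exact integer.
Features and source blocks carry equal weight (an optional per-source
weight vector is deliberately not a default). Sorting is by descending W
with lexicographic gene-id tie-break, for byte-reproducible output. By
default only consensus candidates are ranked; `rank_residual=True` ranks
the whole residual pool, which the held-out-seed evaluation needs since a
held-out seed may not reach the consensus vote.

## Evaluation protocols

- `compute_metrics` reports confusion counts and FPR, FNR, precision,
  recall, F-measure and accuracy as percentages; any ratio with a zero
  denominator is absent (`None`), never coerced to 0. AUC uses the
  rank-sum (Mann–Whitney) estimator with midranks for ties.
- `benchmark_pu` hides a labeled dataset's majority class into U, reveals
  ⌊0.7·n_pos⌋ positives (the 70% split is the protocol default), runs an
  extractor, trains a balanced NB on P vs RN, and scores every instance
  outside P ∪ RN against the true labels; RN purity is reported alongside
  because the protocol's headline metrics conflate extractor and
  second-step classifier quality.
- `per_source_diagnostic` restricts the matrix to one source block at a
  time and runs seeded stratified 4-fold NB cross-validation with balanced
  training classes, pooling fold confusion counts.
- `holdout_rank_eval` splits the seeds into k = 3 folds, runs the full
  pipeline per fold with the held-out seeds hidden in U, ranks all
  residual genes, and reports each fold's average held-out rank and counts
  within the top {10, 50, 100, 500, 1000}. A held-out seed absorbed into
  RN is charged rank n_ranked + 1 (the worst), a deliberate penalty rather
  than an exclusion.

## Feature reduction

`pov_reduce` centers columns, takes the SVD, and retains the minimal
leading component prefix whose cumulative explained-variance fraction
reaches the target (default 0.98); signs are fixed by making each
component's largest-magnitude loading positive. It is an offline utility,
not a pipeline stage: principal components are real-valued and therefore
incompatible with the Bernoulli likelihood the pipeline's classifier uses.
`mrmr_select` is plug-in-MI greedy selection (0·log 0 = 0) under the
difference (MID, default) or quotient (MIQ) scheme; the quotient divides
by max(mean redundancy, 1e-12) to keep the first steps finite; ties break
to the earlier feature column. Selections are prefix-stable by
construction.

## Synthetic study conditions

The generator plants the "guilt by association" structure the method
assumes: n_genes = 1000, of which n_true_pos = 100 are truly positive and
only n_seeds = 30 revealed; 5 source blocks of 20 informative + 30 noise
features; informative features fire with p1 = 0.6 for true positives and
p0 = 0.1 for true negatives, noise features with q = 0.2 for everyone.
Features are independent given the class — matching the NB assumption; a
correlation knob r (default 0) copies noise features from informative ones
to stress-test that assumption. What the generator does *not* emulate:
real annotation sparsity patterns, PPI network topology, database-specific
block sizes, or label noise in the seed list — so passing tests
demonstrate correctness of the machinery under the model's own
assumptions, not performance on real genomes. The full-scale shape
(~19k genes × ~12k features, ~300 seeds) is reachable through
`SyntheticSpec` for profiling.

Under the default conditions the planted signal is strong: the three
extractors agree on nearly all true negatives, the fused RN at threshold
11 is ~89% of the gene universe with purity ≈ 1.0, and the residual pool
essentially coincides with the hidden true positives (consensus recall
and precision ≥ 0.9, asserted in tests). One consequence is that
"position in the top half of the residual ranking" is a weak statistic
here — when nearly every residual gene is a true positive, at most about
half of them can occupy the top half of their own ranking — so recovery is
better read from candidate recall/precision and from the held-out-seed
average rank.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from
  `RunConfig.random_seed` (or explicit `seed` arguments); derived
  sub-seeds stay below 2^31. Identical configs give byte-identical
  primary outputs.
- Problem sizes in tests and the acceptance script (hundreds to a
  thousand genes, a few hundred features, 5–20 replicates) were chosen so
  the whole suite runs in seconds while keeping binomial noise well below
  the asserted margins.
- Matrix I/O is strict: a missing or non-binary cell is an error naming
  the gene and feature, because the boolean encoding is total — absence
  of a value is a file defect, not a zero.
- Default smoothing is 1.0 (Laplace); the choice only matters for
  features unseen in a small class, and the smoothing → ∞ limit
  (posterior → prior) is covered by a test.

## Known limitations

- The fused RN size is sensitive to how the replicate pool is built;
  other constructions (per-fold runs, re-seeded deterministic extractors)
  would shift the vote distribution and hence the meaning of the
  threshold.
- Spy calibration with few seeds is coarse: ⌊0.15·30⌋ = 4 spies give a
  noisy minimum. Larger seed lists or a nonzero noise level stabilize it.
- `benchmark_pu` scores instances outside P ∪ RN, so extractors that
  absorb more of U are evaluated on fewer, harder instances; RN purity is
  the comparable supplementary figure.
- mRMR is O(k·F) MI evaluations per selection step with a running
  redundancy sum; it is intended for feature counts in the thousands, not
  millions.
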