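# purank

Positive-unlabeled (PU) learning for genome-wide candidate-gene
prioritization.

Gene-prioritization problems typically come with a short list of *seed*
genes known to be involved in a phenotype (e.g. aging) and thousands of
genes about which nothing is asserted — there is no curated negative set.
`purank` treats this as a PU-learning problem over a binary gene × feature
matrix (features grouped into named source blocks, one per annotation
database): it mines *reliable negatives* (RN) from the unlabeled pool,
trains consensus naive Bayes classifiers on seeds vs RN, and ranks the
predicted candidates by similarity to the seed set. A synthetic generator
with planted ground truth makes every stage testable without downloads.

## Method

1. **Reliable-negative extraction (step 1).** Three two-step PU algorithms
   run over the unlabeled pool U:
   - *two-step NB* — Bernoulli naive Bayes trained with all of U as the
     negative class; RN = unlabeled genes the model still calls negative;
   - *Spy* — a fraction of the positives P is hidden inside U; the spies'
     posterior scores calibrate a threshold *t* (noise level 0 → the
     minimum spy posterior) and RN = {u ∈ U : P(pos|u) < t};
   - *Rocchio* — class prototypes α·mean(P̂) − β·mean(Û) from L2-normalized
     rows; RN = unlabeled genes closer (cosine) to the negative prototype;
     an optional iterative linear-SVM refinement (Roc-SVM) grows RN to a
     fixed point.

   No single extractor dominates, so each runs several times and a gene
   enters the fused RN only when ≥ *threshold* runs agree (default 11
   votes out of 3 algorithms × 5 runs).

2. **Consensus classification (step 2).** P ∪ RN is split into 10
   stratified folds; each fold model is a Bernoulli NB (Laplace smoothing,
   log-space likelihoods) trained with balanced classes. A residual gene
   becomes a candidate only when all 10 models vote it positive.

3. **Ranking (step 3).** With binary indicators `Candidate(i,j)` and
   `Seed(p,j)`, each candidate is scored by

   ```
   W(i) = Σ_j Candidate(i,j) · Σ_p Seed(p,j)
   ```

   — every feature the candidate shares with the seed set contributes the
   number of seeds carrying it (guilt by association, equal weight per
   feature and source). Candidates are ranked by descending W.

Evaluation utilities cover the confusion metrics (FPR, FNR, precision,
recall, F-measure, accuracy, rank-statistic AUC), a hidden-label benchmark
on fully labeled data (majority class unlabeled, 70% of positives
revealed), per-source-block diagnostics by 4-fold NB cross-validation, and
a 3-fold held-out-seed ranking evaluation with top-{10,50,100,500,1000}
counts. `purank.reduce` adds variance-target PCA retention and mRMR
feature selection as offline utilities.

## Worked example

```sh
purank simulate --seed 42 --out-dir demo
purank prioritize --matrix demo/matrix.tsv --seeds demo/seeds.txt \
    --seed 42 --out-dir demo/run
```

```
INFO purank: wrote 1000 x 250 matrix with 30 seeds to demo
INFO purank.pul: fusion: 892 RN genes at threshold 11 (of 15 runs)
INFO purank.predict_rank: consensus: 70 candidates at 10/10 votes
INFO purank: pipeline: 892 RN, 70 candidates, 70 ranked
```

The simulated instance has 1000 genes, 100 of them truly positive but only
30 revealed as seeds. The fusion step votes 892 genes into the reliable
negative set (11-of-15 threshold), the 10 consensus models unanimously
call 70 residual genes positive — the 70 hidden true positives — and the
ranking orders them by seed similarity:

```
rank    gene_id weight
1       G0430   1463
2       G0772   1420
3       G0721   1410
```

A weight of 1463 means gene G0430's features are carried 1463 times in
total across the 30 seed genes. `demo/run/manifest.json` records the
effective configuration, input digests and per-stage counts.

The same steps are available as library calls
(`purank.generate`, `purank.run_pipeline`, `purank.rank_candidates`, ...).

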