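"""Metrics and evaluation protocols for the PU pipeline.

Four protocols are provided:

* :func:`compute_metrics` — confusion counts and the derived percentage
  metrics (FPR, FNR, precision, recall, F-measure, accuracy) plus a
  rank-statistic AUC when scores are available.  Ratios with a zero
  denominator are reported as absent (``None``), never as 0.
* :func:`benchmark_pu` — the hidden-label benchmark: in a fully labeled
  dataset the majority class is unlabeled, a fraction of the minority
  (positive) class is kept as P and the rest mixed into U, an extractor
  mines RN, a balanced NB classifier is trained on P vs RN and scored on
  the held-out instances against the true labels.
* :func:`per_source_diagnostic` — per-block stratified k-fold NB
  cross-validation (default 4 folds), quantifying how much signal each
  data source carries on its own.
* :func:`holdout_rank_eval` — seed genes are split into k folds (default
  3); each fold is hidden, the full pipeline runs on the rest, every
  residual gene is ranked, and the held-out seeds' ranks are summarized as
  a per-fold average rank and counts within top {10, 50, 100, 500, 1000}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .core_data import FeatureMatrix, LabelState, RunConfig
from .nb import posterior_pos_many, train_nb
from .pul import extract_rn_nb, extract_rn_rocchio, extract_rn_spy, rocchio_svm_refine
from .predict_rank import run_pipeline
from .synthetic import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "BenchmarkResult", "RankEvalReport", "compute_metrics",
           "benchmark_pu", "per_source_diagnostic", "holdout_rank_eval",
           "DEFAULT_CUTOFFS"]

DEFAULT_CUTOFFS = (10, 50, 100, 500, 1000)


@dataclass
class EvalReport:
    """Confusion counts and derived metrics as percentages in [0, 100].

    A metric whose denominator is zero is ``None`` (absent), as is AUC
    when no scores were supplied or the truth is single-class.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    fpr: float | None
    fnr: float | None
    precision: float | None
    recall: float | None
    f_measure: float | None
    accuracy: float | None
    auc: float | None = None


def _pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """AUC via the rank-sum (Mann-Whitney) estimator with midranks."""
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return 100.0 * u / (n_pos * n_neg)


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    scores: Sequence[float] | None = None) -> EvalReport:
    """Confusion counts and the six derived metrics (positive class = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    precision = _pct(tp, tp + fp)
    recall = _pct(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    auc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != y_true.shape:
            raise ValueError("scores length mismatch")
        auc = _auc_rank(y_true, scores)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        fpr=_pct(fp, fp + tn), fnr=_pct(fn, fn + tp),
        precision=precision, recall=recall, f_measure=f_measure,
        accuracy=_pct(tp + tn, tp + fp + tn + fn), auc=auc,
    )


@dataclass
class BenchmarkResult:
    report: EvalReport
    rn_purity: float | None
    n_pos_total: int
    n_p_train: int
    n_rn: int
    algorithm: str


_EXTRACTORS = ("nb", "spy", "rocchio", "roc-svm")


def _extract(matrix: FeatureMatrix, labels: LabelState, algorithm: str,
             config: RunConfig, seed: int) -> set[str]:
    if algorithm == "nb":
        return extract_rn_nb(matrix, labels, config.smoothing)
    if algorithm == "spy":
        return extract_rn_spy(matrix, labels, config.spy_fraction,
                              config.spy_noise_level, seed=seed,
                              smoothing=config.smoothing).rn_ids
    if algorithm == "rocchio":
        return extract_rn_rocchio(matrix, labels, config.rocchio_alpha,
                                  config.rocchio_beta)
    if algorithm == "roc-svm":
        rn0 = extract_rn_rocchio(matrix, labels, config.rocchio_alpha,
                                 config.rocchio_beta)
        if not rn0:
            return rn0
        return rocchio_svm_refine(matrix, labels.positives, rn0,
                                  labels.unlabeled - rn0, seed=seed)
    raise ValueError(f"unknown extractor {algorithm!r}; choose from {_EXTRACTORS}")


def benchmark_pu(data: LabeledDataset, algorithm: str = "nb",
                 train_frac: float = 0.7, seed: int = 0,
                 config: RunConfig | None = None) -> BenchmarkResult:
    """Hidden-label PU benchmark on a fully labeled dataset.

    The minority class plays the positive role; the majority class's
    labels are hidden into U.  ``floor(train_frac * n_pos)`` positives are
    revealed as P, the remaining positives are mixed into U, the chosen
    extractor mines RN, and a balanced NB classifier trained on P vs RN is
    scored on every instance outside P u RN against the true labels.
    RN purity (fraction of RN that is truly negative) is reported
    alongside.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0,1)")
    config = config or RunConfig()
    y = np.asarray(data.y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("benchmark dataset must contain both classes")
    # minority class is positive
    pos_label = 1 if (y == 1).sum() <= (y == 0).sum() else 0
    pos_ids = [g for g, lab in zip(data.ids, y) if lab == pos_label]
    rng = np.random.default_rng(seed)
    n_p_train = int(np.floor(train_frac * len(pos_ids)))
    if n_p_train < 1:
        raise ValueError("train_frac leaves no training positives")
    p_train = set(rng.choice(pos_ids, size=n_p_train, replace=False).tolist())
    from .core_data import FeatureMatrix as FM

    matrix = FM(gene_ids=list(data.ids), feature_ids=list(data.feature_ids),
                values=data.X)
    labels = LabelState(positives=p_train,
                        unlabeled=set(data.ids) - p_train)
    rn = _extract(matrix, labels, algorithm, config,
                  seed=int(rng.integers(0, 2**31 - 1)))
    if not rn:
        raise RuntimeError(f"protocol failure: extractor {algorithm!r} "
                           "returned an empty RN set")
    truth = {g: int(lab == pos_label) for g, lab in zip(data.ids, y)}
    rn_purity = sum(1 for g in rn if truth[g] == 0) / len(rn)
    # second-step classifier, balanced by downsampling the larger class
    p_ids, rn_ids = sorted(p_train), sorted(rn)
    n_bal = min(len(p_ids), len(rn_ids))
    p_bal = sorted(rng.choice(p_ids, size=n_bal, replace=False).tolist())
    rn_bal = sorted(rng.choice(rn_ids, size=n_bal, replace=False).tolist())
    model = train_nb(matrix.rows(p_bal), matrix.rows(rn_bal), config.smoothing)
    held = [g for g in data.ids if g not in p_train and g not in rn]
    if not held:
        raise RuntimeError("no held-out instances to score")
    scores = posterior_pos_many(model, matrix.rows(held))
    y_true = np.array([truth[g] for g in held])
    y_pred = (scores > 0.5).astype(int)
    report = compute_metrics(y_true, y_pred, scores)
    return BenchmarkResult(report=report, rn_purity=rn_purity,
                           n_pos_total=len(pos_ids), n_p_train=n_p_train,
                           n_rn=len(rn), algorithm=algorithm)


def per_source_diagnostic(matrix: FeatureMatrix, positives: set[str],
                          negatives: set[str], folds: int = 4,
                          seed: int = 0, smoothing: float = 1.0,
                          ) -> dict[str, EvalReport]:
    """Mean k-fold NB metrics per source block (default 4 folds).

    For each block the matrix is restricted to the block's features and a
    seeded stratified cross-validation with balanced training classes is
    run; the per-fold confusion counts are pooled into one report per
    block.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not positives or not negatives:
        raise ValueError("need non-empty positive and negative sets")
    if len(positives) < folds or len(negatives) < folds:
        raise ValueError("each class needs at least one gene per fold")
    out: dict[str, EvalReport] = {}
    for block, feats in matrix.source_blocks.items():
        if not feats:
            raise ValueError(f"source block {block!r} has zero features")
        sub = matrix.restrict_features(feats)
        rng = np.random.default_rng(seed)
        pos = np.array(sorted(positives))
        neg = np.array(sorted(negatives))
        rng.shuffle(pos)
        rng.shuffle(neg)
        y_true_all: list[int] = []
        y_pred_all: list[int] = []
        scores_all: list[float] = []
        for i in range(folds):
            test_pos, test_neg = pos[i::folds], neg[i::folds]
            train_pos = sorted(set(pos) - set(test_pos))
            train_neg = sorted(set(neg) - set(test_neg))
            from .predict_rank import _balanced

            train_pos, train_neg = _balanced(train_pos, train_neg, rng)
            model = train_nb(sub.rows(train_pos), sub.rows(train_neg), smoothing)
            test_ids = list(test_pos) + list(test_neg)
            s = posterior_pos_many(model, sub.rows(test_ids))
            y_true_all += [1] * len(test_pos) + [0] * len(test_neg)
            y_pred_all += (s > 0.5).astype(int).tolist()
            scores_all += s.tolist()
        out[block] = compute_metrics(y_true_all, y_pred_all, scores_all)
    return out


@dataclass
class RankEvalReport:
    """Held-out seed ranking summary, one entry per fold."""

    fold_avg_rank: list[float]
    fold_top_counts: list[dict[int, int]]
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    n_ranked: list[int] = field(default_factory=list)

    @property
    def mean_avg_rank(self) -> float:
        return float(np.mean(self.fold_avg_rank))

    def total_top_counts(self) -> dict[int, int]:
        return {c: sum(f[c] for f in self.fold_top_counts) for c in self.cutoffs}


def holdout_rank_eval(matrix: FeatureMatrix, seeds: set[str], k: int = 3,
                      cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
                      config: RunConfig | None = None) -> RankEvalReport:
    """k-fold held-out seed ranking evaluation (default k=3).

    Each fold of the seed set is hidden among the unlabeled genes, the
    full pipeline runs with the remaining seeds, all residual genes are
    ranked, and each held-out seed's rank is recorded.  A held-out seed
    that was absorbed into RN (and thus never ranked) is charged the
    worst possible rank, ``n_ranked + 1``.
    """
    config = config or RunConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    seed_list = sorted(seeds)
    if len(seed_list) < k:
        raise ValueError(f"need >= {k} seeds for {k}-fold evaluation")
    cutoffs = tuple(sorted(cutoffs))
    rng = np.random.default_rng(config.random_seed)
    arr = np.array(seed_list)
    rng.shuffle(arr)
    folds = [arr[i::k].tolist() for i in range(k)]
    avg_ranks: list[float] = []
    top_counts: list[dict[int, int]] = []
    n_ranked: list[int] = []
    universe = set(matrix.gene_ids)
    for i, held in enumerate(folds):
        if not held:
            raise ValueError(f"fold {i} holds out zero seeds")
        train_seeds = set(seed_list) - set(held)
        labels = LabelState(positives=train_seeds,
                            unlabeled=universe - train_seeds)
        fold_config = replace(config, random_seed=config.random_seed + 1000 + i)
        result = run_pipeline(matrix, labels, fold_config, rank_residual=True)
        rank_of = {r.gene_id: r.rank for r in result.ranking}
        worst = len(result.ranking) + 1
        ranks = [rank_of.get(g, worst) for g in held]
        avg_ranks.append(float(np.mean(ranks)))
        top_counts.append({c: sum(1 for r in ranks if r <= c) for c in cutoffs})
        n_ranked.append(len(result.ranking))
        logger.info("rank-eval fold %d: %d held-out seeds, avg rank %.1f",
                    i, len(held), avg_ranks[-1])
    return RankEvalReport(fold_avg_rank=avg_ranks, fold_top_counts=top_counts,
                          cutoffs=cutoffs, n_ranked=n_ranked)
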