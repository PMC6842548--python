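"""Reliable-negative extraction and vote-threshold fusion.

Two-step PU learning first mines confident negatives (RN) from the
unlabeled pool U, then trains an ordinary binary classifier on P vs RN.
Three first-step extractors are implemented:

* ``extract_rn_nb`` — train naive Bayes treating all of U as negative;
  keep the unlabeled genes the model still calls negative.
* ``extract_rn_spy`` — hide a fraction of P as "spies" inside U; the spies'
  posterior scores calibrate the threshold below which unlabeled genes are
  deemed negative.
* ``extract_rn_rocchio`` — nearest-prototype classification under cosine
  similarity, with the classic (alpha, beta) centroid weighting; an
  optional iterative linear-margin refinement (``rocchio_svm_refine``)
  grows RN until a fixed point.

No single extractor dominates, so their outputs are fused: each algorithm
is run several times, RN memberships are tallied, and a gene enters the
fused RN only when at least ``threshold`` runs agree (default 11 votes out
of 3 algorithms x 5 runs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import FeatureMatrix, LabelState, RunConfig
from .nb import posterior_pos_many, train_nb

logger = logging.getLogger(__name__)

__all__ = [
    "SpyResult",
    "RocchioPrototypes",
    "FusionTally",
    "extract_rn_nb",
    "extract_rn_spy",
    "extract_rn_rocchio",
    "rocchio_svm_refine",
    "fuse_negatives",
    "run_fusion_protocol",
]


@dataclass
class SpyResult:
    spy_ids: set[str]
    threshold: float
    rn_ids: set[str]
    posteriors: dict[str, float] = field(default_factory=dict)


@dataclass
class RocchioPrototypes:
    proto_pos: np.ndarray
    proto_neg: np.ndarray
    alpha: float
    beta: float


@dataclass
class FusionTally:
    """Per-gene count of extraction runs that placed it in RN."""

    counts: dict[str, int]
    total_runs: int
    threshold: int


def _check_pu(labels: LabelState) -> tuple[list[str], list[str]]:
    if not labels.positives:
        raise ValueError("no positive genes")
    if not labels.unlabeled:
        raise ValueError("no unlabeled genes")
    return sorted(labels.positives), sorted(labels.unlabeled)


def extract_rn_nb(matrix: FeatureMatrix, labels: LabelState,
                  smoothing: float = 1.0) -> set[str]:
    """Two-step NB extractor: U trains as negative, RN = still-negative U.

    Deterministic for fixed inputs.
    """
    pos_ids, unl_ids = _check_pu(labels)
    model = train_nb(matrix.rows(pos_ids), matrix.rows(unl_ids), smoothing)
    post = posterior_pos_many(model, matrix.rows(unl_ids))
    return {g for g, p in zip(unl_ids, post) if p <= 0.5}


def extract_rn_spy(matrix: FeatureMatrix, labels: LabelState,
                   spy_fraction: float = 0.15, noise_level: float = 0.0,
                   seed: int = 0, smoothing: float = 1.0) -> SpyResult:
    """Spy extractor: hidden positives calibrate the negativity threshold.

    A seeded fraction of P is moved into U as spies; NB is trained on the
    remaining P vs U + spies; the threshold is the ``noise_level``-quantile
    of spy posteriors (0 = the minimum spy posterior) and RN is every
    unlabeled gene scoring strictly below it.
    """
    if not 0 < spy_fraction < 1:
        raise ValueError("spy_fraction must be in (0,1)")
    if not 0 <= noise_level < 1:
        raise ValueError("noise_level must be in [0,1)")
    pos_ids, unl_ids = _check_pu(labels)
    n_spies = int(np.floor(spy_fraction * len(pos_ids)))
    if n_spies < 1:
        raise ValueError(
            f"spy set empty: fraction {spy_fraction} of {len(pos_ids)} positives"
        )
    rng = np.random.default_rng(seed)
    spies = set(rng.choice(pos_ids, size=n_spies, replace=False).tolist())
    train_pos = [g for g in pos_ids if g not in spies]
    mixed = unl_ids + sorted(spies)
    model = train_nb(matrix.rows(train_pos), matrix.rows(mixed), smoothing)
    post = posterior_pos_many(model, matrix.rows(mixed))
    scores = dict(zip(mixed, post.tolist()))
    spy_scores = np.array([scores[s] for s in sorted(spies)])
    if noise_level == 0:
        t = float(spy_scores.min())
    else:
        t = float(np.quantile(spy_scores, noise_level))
    rn = {g for g in unl_ids if scores[g] < t}
    return SpyResult(spy_ids=spies, threshold=t, rn_ids=rn, posteriors=scores)


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """L2-normalize rows; returns (normalized rows, mask of nonzero rows)."""
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    out = np.zeros_like(X, dtype=np.float64)
    out[ok] = X[ok] / norms[ok, None]
    return out, ok


def rocchio_prototypes(matrix: FeatureMatrix, labels: LabelState,
                       alpha: float = 16.0, beta: float = 4.0) -> RocchioPrototypes:
    pos_ids, unl_ids = _check_pu(labels)
    P, p_ok = _normalize_rows(matrix.rows(pos_ids).astype(np.float64))
    U, u_ok = _normalize_rows(matrix.rows(unl_ids).astype(np.float64))
    if not p_ok.all():
        logger.warning("dropping %d all-zero positive rows from prototypes",
                       int((~p_ok).sum()))
    mean_p = P[p_ok].mean(axis=0) if p_ok.any() else np.zeros(matrix.n_features)
    mean_u = U[u_ok].mean(axis=0) if u_ok.any() else np.zeros(matrix.n_features)
    return RocchioPrototypes(
        proto_pos=alpha * mean_p - beta * mean_u,
        proto_neg=alpha * mean_u - beta * mean_p,
        alpha=alpha, beta=beta,
    )


def _cosine(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    nv = np.linalg.norm(v)
    nX = np.linalg.norm(X, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (X @ v) / (nX * nv)
    sims[~np.isfinite(sims)] = -np.inf
    return sims


def extract_rn_rocchio(matrix: FeatureMatrix, labels: LabelState,
                       alpha: float = 16.0, beta: float = 4.0) -> set[str]:
    """Rocchio extractor: RN = unlabeled genes strictly nearer (by cosine)
    to the negative prototype than to the positive one.

    All-zero gene rows have no direction, hence no cosine: they are
    excluded from RN and logged, never silently classified.
    """
    protos = rocchio_prototypes(matrix, labels, alpha, beta)
    unl_ids = sorted(labels.unlabeled)
    U = matrix.rows(unl_ids).astype(np.float64)
    zero_rows = np.linalg.norm(U, axis=1) == 0
    if zero_rows.any():
        dropped = [g for g, z in zip(unl_ids, zero_rows) if z]
        logger.warning("excluding %d all-zero unlabeled rows from Rocchio RN: %s",
                       len(dropped), dropped[:5])
    sim_pos = _cosine(U, protos.proto_pos)
    sim_neg = _cosine(U, protos.proto_neg)
    keep = (sim_neg > sim_pos) & ~zero_rows
    return {g for g, k in zip(unl_ids, keep) if k}


def rocchio_svm_refine(matrix: FeatureMatrix, positives: set[str],
                       rn_initial: set[str], remaining_u: set[str],
                       max_iter: int = 10, seed: int = 0) -> set[str]:
    """Iterative linear-margin refinement of an initial RN set (Roc-SVM).

    Repeatedly trains a linear maximum-margin classifier on P vs the
    current RN and moves remaining unlabeled genes it classifies negative
    into RN, stopping at a fixed point or ``max_iter``.  The returned set
    always contains ``rn_initial``.
    """
    from sklearn.svm import LinearSVC

    if not rn_initial:
        raise ValueError("rn_initial must be non-empty")
    rn = set(rn_initial)
    remaining = set(remaining_u) - rn
    pos_ids = sorted(positives)
    P = matrix.rows(pos_ids).astype(np.float64)
    for _ in range(max_iter):
        if not remaining:
            break
        rn_ids = sorted(rn)
        X = np.vstack([P, matrix.rows(rn_ids).astype(np.float64)])
        y = np.concatenate([np.ones(len(pos_ids)), np.zeros(len(rn_ids))])
        clf = LinearSVC(random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings on tiny data
            clf.fit(X, y)
        rem_ids = sorted(remaining)
        pred = clf.predict(matrix.rows(rem_ids).astype(np.float64))
        moved = {g for g, c in zip(rem_ids, pred) if c == 0}
        if not moved:
            break
        rn |= moved
        remaining -= moved
    return rn


def fuse_negatives(tally: FusionTally) -> set[str]:
    """Genes whose RN vote count meets the threshold; antitone in threshold.

    A threshold exceeding the total run count yields an empty set with a
    warning rather than an error.
    """
    if not tally.counts:
        raise ValueError("empty tally")
    if tally.threshold < 1:
        raise ValueError("threshold must be >= 1")
    if tally.threshold > tally.total_runs:
        warnings.warn(
            f"fusion threshold {tally.threshold} exceeds total runs "
            f"{tally.total_runs}; fused RN is empty", stacklevel=2)
        return set()
    return {g for g, c in tally.counts.items() if c >= tally.threshold}


def _subsample_labels(labels: LabelState, frac: float,
                      rng: np.random.Generator) -> LabelState:
    """Bootstrap-style variation for the deterministic extractors: keep a
    seeded ``frac`` subsample of U (without replacement)."""
    unl = sorted(labels.unlabeled)
    keep = int(round(frac * len(unl)))
    sub = set(rng.choice(unl, size=max(keep, 1), replace=False).tolist())
    return LabelState(positives=set(labels.positives), unlabeled=sub)


def run_fusion_protocol(matrix: FeatureMatrix, labels: LabelState,
                        config: RunConfig) -> tuple[set[str], FusionTally]:
    """Run all three extractors repeatedly, tally RN votes, fuse.

    The spy extractor varies across runs by derived sub-seeds; the
    deterministic NB and Rocchio extractors vary by seeded 90% subsampling
    of U.  Everything is reproducible from ``config.random_seed``.
    """
    rng = np.random.default_rng(config.random_seed)
    counts: dict[str, int] = {g: 0 for g in labels.unlabeled}
    total = 0
    for _ in range(config.fusion_runs_per_algorithm):
        sub = _subsample_labels(labels, 0.9, rng)
        rn = extract_rn_nb(matrix, sub, config.smoothing)
        for g in rn:
            counts[g] += 1
        total += 1
    for _ in range(config.fusion_runs_per_algorithm):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = extract_rn_spy(matrix, labels, config.spy_fraction,
                             config.spy_noise_level, seed=sub_seed,
                             smoothing=config.smoothing)
        for g in res.rn_ids:
            counts[g] += 1
        total += 1
    for _ in range(config.fusion_runs_per_algorithm):
        sub = _subsample_labels(labels, 0.9, rng)
        rn = extract_rn_rocchio(matrix, sub, config.rocchio_alpha,
                                config.rocchio_beta)
        for g in rn:
            counts[g] += 1
        total += 1
    tally = FusionTally(counts=counts, total_runs=total,
                        threshold=config.fusion_threshold)
    fused = fuse_negatives(tally)
    logger.info("fusion: %d RN genes at threshold %d (of %d runs)",
                len(fused), tally.threshold, total)
    return fused, tally
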