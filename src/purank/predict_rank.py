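"""Consensus candidate prediction and seed-similarity ranking.

Stage two of the pipeline trains one naive Bayes model per cross-validation
fold of P (seeds) vs RN (fused reliable negatives), with classes balanced
by seeded downsampling so the classifier carries no prior bias.  Every
residual gene (unlabeled and not in RN) is scored by all fold models; a
gene becomes a candidate only when at least ``consensus_required_votes``
models call it positive (default: unanimity over 10 folds).

Stage three ranks candidates by similarity to the seed set.  With
``Candidate(i, j)`` and ``Seed(p, j)`` the binary feature indicators, each
candidate's weight is

    W(i) = sum_j Candidate(i, j) * sum_p Seed(p, j)

i.e. each feature the candidate carries contributes the number of seeds
carrying it — guilt by association, with equal weight per feature and per
source.  Candidates are sorted by descending W, ties broken
lexicographically by gene id for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import FeatureMatrix, LabelState, RunConfig
from .nb import NBModel, posterior_pos_many, train_nb
from .pul import run_fusion_protocol

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "RankedGene", "consensus_predict",
           "rank_candidates", "run_pipeline"]


@dataclass
class ConsensusResult:
    fold_models: list[NBModel]
    votes: dict[str, int]
    candidates: set[str]
    required_votes: int


@dataclass
class RankedGene:
    gene_id: str
    weight: int
    rank: int


def _stratified_folds(pos_ids: list[str], neg_ids: list[str], k: int,
                      rng: np.random.Generator) -> list[tuple[set[str], set[str]]]:
    """k seeded stratified folds over P u RN; each entry is (pos, neg) held out."""
    pos = np.array(pos_ids)
    neg = np.array(neg_ids)
    rng.shuffle(pos)
    rng.shuffle(neg)
    return [(set(pos[i::k].tolist()), set(neg[i::k].tolist())) for i in range(k)]


def _balanced(ids_a: list[str], ids_b: list[str],
              rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Downsample the larger of two id lists to the size of the smaller."""
    if len(ids_a) > len(ids_b):
        ids_a = sorted(rng.choice(ids_a, size=len(ids_b), replace=False).tolist())
    elif len(ids_b) > len(ids_a):
        ids_b = sorted(rng.choice(ids_b, size=len(ids_a), replace=False).tolist())
    return ids_a, ids_b


def consensus_predict(matrix: FeatureMatrix, positives: set[str], rn: set[str],
                      residual: set[str], config: RunConfig) -> ConsensusResult:
    """Vote residual genes positive across balanced fold models.

    P u RN is split into ``consensus_folds`` stratified folds; each model
    trains on the other folds with the larger class downsampled (seeded)
    and classifies every residual gene.  Candidates are the genes reaching
    ``consensus_required_votes`` positive votes.
    """
    k = config.consensus_folds
    if len(positives) < k or len(rn) < k:
        raise ValueError(
            f"need >= {k} genes in each class for {k}-fold consensus; "
            f"have |P|={len(positives)}, |RN|={len(rn)}"
        )
    rng = np.random.default_rng(config.random_seed + 1)
    pos_ids, rn_ids = sorted(positives), sorted(rn)
    folds = _stratified_folds(pos_ids, rn_ids, k, rng)
    res_ids = sorted(residual)
    X_res = matrix.rows(res_ids) if res_ids else np.empty((0, matrix.n_features))
    votes = np.zeros(len(res_ids), dtype=int)
    models: list[NBModel] = []
    for held_pos, held_neg in folds:
        train_pos = [g for g in pos_ids if g not in held_pos]
        train_neg = [g for g in rn_ids if g not in held_neg]
        train_pos, train_neg = _balanced(train_pos, train_neg, rng)
        model = train_nb(matrix.rows(train_pos), matrix.rows(train_neg),
                         config.smoothing)
        models.append(model)
        if res_ids:
            votes += (posterior_pos_many(model, X_res) > 0.5).astype(int)
    vote_map = dict(zip(res_ids, votes.tolist()))
    candidates = {g for g, v in vote_map.items()
                  if v >= config.consensus_required_votes}
    logger.info("consensus: %d candidates at %d/%d votes",
                len(candidates), config.consensus_required_votes, k)
    return ConsensusResult(fold_models=models, votes=vote_map,
                           candidates=candidates,
                           required_votes=config.consensus_required_votes)


def rank_candidates(matrix: FeatureMatrix, candidates: set[str],
                    seeds: set[str]) -> list[RankedGene]:
    """Rank candidates by W(i), the seed-supported feature weight.

    Precomputes the seed feature-support vector s(j) = number of seeds
    carrying feature j, then W(i) = candidate row . s.  Weights are exact
    integers; the list is sorted by descending W with gene-id ties broken
    lexicographically and ranks 1..C assigned in order.
    """
    if not candidates:
        raise ValueError("no candidate genes to rank")
    if not seeds:
        raise ValueError("no seed genes to rank against")
    seed_rows = matrix.rows(sorted(seeds)).astype(np.int64)
    support = seed_rows.sum(axis=0)
    cand_ids = sorted(candidates)
    weights = matrix.rows(cand_ids).astype(np.int64) @ support
    order = sorted(zip(cand_ids, weights.tolist()), key=lambda t: (-t[1], t[0]))
    return [RankedGene(gene_id=g, weight=int(w), rank=i + 1)
            for i, (g, w) in enumerate(order)]


@dataclass
class PipelineResult:
    rn: set[str]
    consensus: ConsensusResult
    ranking: list[RankedGene]
    manifest: dict = field(default_factory=dict)


def run_pipeline(matrix: FeatureMatrix, labels: LabelState, config: RunConfig,
                 rank_residual: bool = False) -> PipelineResult:
    """Chain RN fusion -> consensus prediction -> ranking.

    By default only consensus candidates are ranked; ``rank_residual=True``
    ranks every residual gene instead (used by held-out seed evaluation,
    where the held-out genes need a rank whether or not they reached the
    consensus vote).
    """
    labels.validate_against(matrix)
    rn, tally = run_fusion_protocol(matrix, labels, config)
    residual = labels.unlabeled - rn
    consensus = consensus_predict(matrix, labels.positives, rn, residual, config)
    pool = residual if rank_residual else consensus.candidates
    ranking = rank_candidates(matrix, pool, labels.positives) if pool else []
    manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "counts": {
            "positives": len(labels.positives),
            "unlabeled": len(labels.unlabeled),
            "reliable_negatives": len(rn),
            "residual": len(residual),
            "candidates": len(consensus.candidates),
            "ranked": len(ranking),
        },
        "fusion_total_runs": tally.total_runs,
        "rank_residual": rank_residual,
    }
    return PipelineResult(rn=rn, consensus=consensus, ranking=ranking,
                          manifest=manifest)
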