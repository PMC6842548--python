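"""Synthetic PU-structured binary matrices with planted ground truth.

The generator emulates the structure of a multi-database gene annotation
matrix: sparse binary features grouped into named source blocks, a minority
of "true positive" genes whose informative features fire at an enriched
rate, and only a subset of the true positives revealed as seeds.  Every
downstream stage — reliable-negative extraction, fusion, consensus
prediction, ranking, evaluation — is testable against the planted truth
without any external download.

Model: features are independent given the class (the naive Bayes
assumption).  Each block carries ``informative_per_block`` features drawn
Bernoulli(p1) for true positives and Bernoulli(p0) for true negatives, plus
``noise_per_block`` features drawn Bernoulli(q) for everyone.  An optional
correlation knob ``r`` copies each noise feature from a random informative
feature of its block with probability ``r``, to stress-test the
independence assumption (default 0 = fully independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import FeatureMatrix, LabelState

__all__ = ["SyntheticSpec", "GroundTruth", "LabeledDataset", "generate",
           "make_labeled_benchmark", "read_labeled_csv", "write_labeled_csv"]


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults give a desk-scale PU problem.

    ``p1``/``p0`` are the informative-feature firing rates for true
    positives / true negatives, ``q`` the rate of pure-noise features for
    both classes.  ``n_seeds`` of the ``n_true_pos`` genuinely positive
    genes are revealed as seeds; the rest hide in the unlabeled pool.
    """

    n_genes: int = 1000
    n_true_pos: int = 100
    n_seeds: int = 30
    n_blocks: int = 5
    informative_per_block: int = 20
    noise_per_block: int = 30
    p1: float = 0.6
    p0: float = 0.1
    q: float = 0.2
    r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_seeds <= self.n_true_pos <= self.n_genes):
            raise ValueError("need 0 < n_seeds <= n_true_pos <= n_genes")
        if not (0 <= self.p0 < self.p1 <= 1):
            raise ValueError("need 0 <= p0 < p1 <= 1")
        if not (0 <= self.q <= 1 and 0 <= self.r <= 1):
            raise ValueError("q and r must be probabilities")
        if self.n_blocks < 1 or self.informative_per_block < 0 or self.noise_per_block < 0:
            raise ValueError("block counts must be non-negative, n_blocks >= 1")
        if self.informative_per_block + self.noise_per_block == 0:
            raise ValueError("blocks must contain at least one feature")


@dataclass
class GroundTruth:
    true_pos_ids: set[str]
    true_neg_ids: set[str]
    informative_feature_ids: set[str] = field(default_factory=set)


@dataclass
class LabeledDataset:
    """Fully labeled binary dataset (the benchmark layout)."""

    ids: list[str]
    feature_ids: list[str]
    X: np.ndarray
    y: np.ndarray  # 1 = positive class


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _build(spec: SyntheticSpec) -> tuple[list[str], list[str], np.ndarray,
                                         dict[str, list[str]], np.ndarray,
                                         list[str], np.random.Generator]:
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    is_pos = np.zeros(spec.n_genes, dtype=bool)
    pos_idx = rng.choice(spec.n_genes, size=spec.n_true_pos, replace=False)
    is_pos[pos_idx] = True

    feature_ids: list[str] = []
    blocks: dict[str, list[str]] = {}
    informative: list[str] = []
    cols: list[np.ndarray] = []
    for b in range(1, spec.n_blocks + 1):
        name = f"block{b}"
        blocks[name] = []
        inf_cols: list[int] = []
        for j in range(1, spec.informative_per_block + 1):
            fid = f"{name}_inf{j:03d}"
            feature_ids.append(fid)
            blocks[name].append(fid)
            informative.append(fid)
            col = np.where(is_pos,
                           rng.random(spec.n_genes) < spec.p1,
                           rng.random(spec.n_genes) < spec.p0)
            inf_cols.append(len(cols))
            cols.append(col.astype(np.uint8))
        for j in range(1, spec.noise_per_block + 1):
            fid = f"{name}_noise{j:03d}"
            feature_ids.append(fid)
            blocks[name].append(fid)
            if inf_cols and spec.r > 0 and rng.random() < spec.r:
                src = int(rng.choice(inf_cols))
                cols.append(cols[src].copy())
            else:
                cols.append((rng.random(spec.n_genes) < spec.q).astype(np.uint8))
    values = np.column_stack(cols)
    return genes, feature_ids, values, blocks, is_pos, informative, rng


def generate(spec: SyntheticSpec) -> tuple[FeatureMatrix, LabelState, GroundTruth]:
    """Draw a PU instance: matrix, seed/unlabeled labels, and ground truth.

    Fully determined by ``spec.seed``: identical specs produce identical
    matrices, seed choices and truth.
    """
    genes, feature_ids, values, blocks, is_pos, informative, rng = _build(spec)
    matrix = FeatureMatrix(genes, feature_ids, values, blocks)
    pos_ids = [g for g, p in zip(genes, is_pos) if p]
    seed_ids = set(rng.choice(pos_ids, size=spec.n_seeds, replace=False).tolist())
    labels = LabelState(positives=seed_ids, unlabeled=set(genes) - seed_ids)
    truth = GroundTruth(
        true_pos_ids=set(pos_ids),
        true_neg_ids=set(genes) - set(pos_ids),
        informative_feature_ids=set(informative),
    )
    return matrix, labels, truth


def make_labeled_benchmark(spec: SyntheticSpec) -> LabeledDataset:
    """Same generative model but with all true labels exposed."""
    genes, feature_ids, values, _, is_pos, _, _ = _build(spec)
    return LabeledDataset(ids=genes, feature_ids=feature_ids, X=values,
                          y=is_pos.astype(np.int8))


def write_labeled_csv(data: LabeledDataset, path) -> None:
    """Generic labeled-CSV layout: id, features..., label (1 = positive)."""
    with open(path, "w") as fh:
        fh.write("id," + ",".join(data.feature_ids) + ",label\n")
        for gid, row, lab in zip(data.ids, data.X, data.y):
            fh.write(gid + "," + ",".join(str(int(v)) for v in row) + f",{int(lab)}\n")


def read_labeled_csv(path) -> LabeledDataset:
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "id" or df.columns[-1] != "label":
        raise ValueError("labeled CSV must have first column 'id' and last 'label'")
    feats = list(df.columns[1:-1])
    X = df[feats].to_numpy(dtype=np.uint8)
    y = df["label"].to_numpy(dtype=np.int8)
    return LabeledDataset(ids=list(df["id"]), feature_ids=feats, X=X, y=y)
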