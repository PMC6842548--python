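"""Offline feature-space reduction: variance-target PCA and mRMR selection.

These utilities are not part of the default prioritization pipeline — the
final classifier stays a Bernoulli naive Bayes on the original binary
features (principal components are real-valued and incompatible with a
Bernoulli likelihood) — but they quantify the redundancy of the feature
space and provide compact feature subsets for other learners.

``pov_reduce`` retains the minimal leading set of principal components
whose cumulative explained-variance fraction reaches a target (default
0.98).  ``mrmr_select`` greedily picks features maximizing mutual
information with the label while penalizing redundancy with the already
selected set, under either the difference (MID, default) or quotient (MIQ)
scheme.
"""

from __future__ import annotations

import warnings
from typing import Literal, Sequence

import numpy as np

from .core_data import FeatureMatrix

__all__ = ["pov_reduce", "mrmr_select", "mutual_information_binary"]


def pov_reduce(matrix: FeatureMatrix | np.ndarray, pov_target: float = 0.98,
               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Principal-component retention to a cumulative-variance target.

    Columns are centered, principal axes computed by SVD, and the minimal
    leading prefix whose cumulative variance fraction reaches
    ``pov_target`` is retained.  Component signs are fixed by making each
    component's largest-magnitude loading positive, so the decomposition
    is deterministic.

    Returns ``(loadings, transformed, retained)`` where ``loadings`` is
    ``(n_features, retained)``, ``transformed`` is ``(n_genes, retained)``.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    X = X.astype(np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    if not 0 < pov_target <= 1:
        raise ValueError("pov_target must be in (0, 1]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("constant matrix: zero total variance")
    # drop numerically-zero components so pov_target=1 returns the rank
    rank = int((s > s[0] * max(X.shape) * np.finfo(float).eps).sum())
    var = var[:rank]
    cum = np.cumsum(var) / total
    retained = int(np.searchsorted(cum, pov_target - 1e-12) + 1)
    retained = min(retained, rank)
    comps = Vt[:retained]
    # sign convention: largest-magnitude loading of each component positive
    for i in range(retained):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return comps.T, Xc @ comps.T, retained


def mutual_information_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two binary vectors.

    Symmetric by construction; 0*log(0) terms contribute 0.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    n = len(a)
    mi = 0.0
    for va in (0, 1):
        pa = (a == va).mean()
        for vb in (0, 1):
            pj = ((a == va) & (b == vb)).sum() / n
            if pj > 0:
                pb = (b == vb).mean()
                mi += pj * np.log(pj / (pa * pb))
    return max(mi, 0.0)


def mrmr_select(matrix: FeatureMatrix | np.ndarray, y: Sequence[int],
                k: int = 500,
                scheme: Literal["difference", "quotient"] = "difference",
                feature_ids: Sequence[str] | None = None) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance feature selection.

    The first feature maximizes I(f; y); each subsequent pick maximizes
    relevance minus (difference scheme) or divided by (quotient scheme)
    the mean mutual information with the already selected features.  Ties
    break by feature-id order.  ``k`` beyond the feature count truncates
    with a warning.
    """
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        feature_ids = list(matrix.feature_ids)
    else:
        X = np.asarray(matrix)
        feature_ids = list(feature_ids) if feature_ids is not None else [
            f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_feat = X.shape[1]
    if k > n_feat:
        warnings.warn(f"k={k} exceeds {n_feat} features; truncating", stacklevel=2)
        k = n_feat
    relevance = np.array([mutual_information_binary(X[:, j], y)
                          for j in range(n_feat)])
    selected: list[int] = []
    remaining = list(range(n_feat))
    # running sum of I(f; f_s) over selected s, per remaining feature
    red_sum = np.zeros(n_feat)
    for _ in range(k):
        if not selected:
            score = relevance[remaining]
        else:
            red_mean = red_sum[remaining] / len(selected)
            if scheme == "difference":
                score = relevance[remaining] - red_mean
            elif scheme == "quotient":
                score = relevance[remaining] / np.maximum(red_mean, 1e-12)
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
        best = remaining[int(np.argmax(score))]  # argmax takes first = id order
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            red_sum[j] += mutual_information_binary(X[:, j], X[:, best])
    return [feature_ids[j] for j in selected]
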