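"""Bernoulli naive Bayes over binary features, computed in log space.

This is the base learner for every stage of the PU pipeline: the two-step
reliable-negative extractors, the consensus fold models, and the per-source
diagnostics.  The event model is Bernoulli — a feature's absence (0) is
evidence too, not merely its presence — because the feature encoding is a
total boolean indicator per gene and database entry.

With Laplace smoothing ``a``::

    P(f=1 | c) = (count(f=1 in c) + a) / (n_c + 2a)

and priors are the class proportions of the training rows.  All likelihood
products are accumulated as log sums so that matrices with thousands of
features cannot underflow double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = ["NBModel", "train_nb", "posterior_pos", "classify", "save_model", "load_model"]


@dataclass
class NBModel:
    """Fitted Bernoulli naive Bayes parameters (all in log space)."""

    log_prior_pos: float
    log_prior_neg: float
    log_p1_pos: np.ndarray  # log P(f=1 | pos), per feature
    log_p0_pos: np.ndarray  # log P(f=0 | pos)
    log_p1_neg: np.ndarray
    log_p0_neg: np.ndarray
    smoothing: float

    @property
    def n_features(self) -> int:
        return self.log_p1_pos.shape[0]


def train_nb(pos_rows: np.ndarray, neg_rows: np.ndarray, smoothing: float = 1.0) -> NBModel:
    """Fit the model from binary row sets of the two classes.

    Raises ``ValueError`` on an empty class, mismatched feature dimension,
    or non-positive smoothing.
    """
    pos_rows = np.asarray(pos_rows, dtype=np.float64)
    neg_rows = np.asarray(neg_rows, dtype=np.float64)
    if pos_rows.size == 0 or neg_rows.size == 0:
        raise ValueError("both classes must be non-empty")
    pos_rows = np.atleast_2d(pos_rows)
    neg_rows = np.atleast_2d(neg_rows)
    if pos_rows.shape[1] != neg_rows.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {pos_rows.shape[1]} vs {neg_rows.shape[1]}"
        )
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    n_pos, n_neg = pos_rows.shape[0], neg_rows.shape[0]
    p1_pos = (pos_rows.sum(axis=0) + smoothing) / (n_pos + 2 * smoothing)
    p1_neg = (neg_rows.sum(axis=0) + smoothing) / (n_neg + 2 * smoothing)
    return NBModel(
        log_prior_pos=float(np.log(n_pos / (n_pos + n_neg))),
        log_prior_neg=float(np.log(n_neg / (n_pos + n_neg))),
        log_p1_pos=np.log(p1_pos),
        log_p0_pos=np.log1p(-p1_pos),
        log_p1_neg=np.log(p1_neg),
        log_p0_neg=np.log1p(-p1_neg),
        smoothing=float(smoothing),
    )


def _log_joint(model: NBModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    lj_pos = model.log_prior_pos + X @ model.log_p1_pos + (1 - X) @ model.log_p0_pos
    lj_neg = model.log_prior_neg + X @ model.log_p1_neg + (1 - X) @ model.log_p0_neg
    return lj_pos, lj_neg


def posterior_pos_many(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Vector of P(pos | x) for each row of X, normalized in log space."""
    lj_pos, lj_neg = _log_joint(model, X)
    denom = logsumexp(np.stack([lj_pos, lj_neg]), axis=0)
    return np.exp(lj_pos - denom)


def posterior_pos(model: NBModel, x: np.ndarray) -> float:
    """P(pos | x) for a single binary vector; always finite and in [0, 1]."""
    return float(posterior_pos_many(model, np.atleast_2d(x))[0])


def classify(model: NBModel, x: np.ndarray) -> str:
    """Decision rule: ``"pos"`` iff posterior > 0.5, ties classify ``"neg"``.

    The tie rule is deliberately conservative: in reliable-negative
    extraction a false positive admitted into RN is the costly error.
    """
    return "pos" if posterior_pos(model, x) > 0.5 else "neg"


def classify_many(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Boolean array, True where the row is classified positive."""
    return posterior_pos_many(model, X) > 0.5


def save_model(model: NBModel, path: str | Path) -> None:
    """Serialize to a plain-text key/value file (repr-precision floats)."""
    lines = [
        f"smoothing\t{model.smoothing!r}",
        f"log_prior_pos\t{model.log_prior_pos!r}",
        f"log_prior_neg\t{model.log_prior_neg!r}",
    ]
    for name in ("log_p1_pos", "log_p0_pos", "log_p1_neg", "log_p0_neg"):
        vec = getattr(model, name)
        lines.append(name + "\t" + ",".join(repr(float(v)) for v in vec))
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> NBModel:
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        key, _, val = line.partition("\t")
        fields[key] = val
    return NBModel(
        log_prior_pos=float(fields["log_prior_pos"]),
        log_prior_neg=float(fields["log_prior_neg"]),
        log_p1_pos=np.array([float(v) for v in fields["log_p1_pos"].split(",")]),
        log_p0_pos=np.array([float(v) for v in fields["log_p0_pos"].split(",")]),
        log_p1_neg=np.array([float(v) for v in fields["log_p1_neg"].split(",")]),
        log_p0_neg=np.array([float(v) for v in fields["log_p0_neg"].split(",")]),
        smoothing=float(fields["smoothing"]),
    )
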