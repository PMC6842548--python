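"""Data model and I/O for binary gene-feature matrices and PU label sets.

The central objects are a :class:`FeatureMatrix` (genes in rows, binary
features in columns, features partitioned into named source blocks mirroring
the underlying databases) and a :class:`LabelState` tracking the disjoint
gene sets of a positive-unlabeled problem: seeds (P), unlabeled (U),
reliable negatives (RN) and predicted candidates.

File formats are deliberately plain: tab-separated text with a header row
of feature ids and a first column of gene ids (comma accepted by sniffing),
a two-column block map, and one-id-per-line seed lists.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "LabelState",
    "RunConfig",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_ranking",
    "read_source_map",
]


class MatrixFormatError(ValueError):
    """Raised for malformed matrix, label or block-map files."""


@dataclass
class FeatureMatrix:
    """Binary gene x feature matrix with a source-block partition.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (opaque strings).
    feature_ids
        Ordered, unique feature identifiers.
    values
        ``(n_genes, n_features)`` array of 0/1 indicators.
    source_blocks
        Map from block name to the list of feature ids it contains.  The
        blocks must partition ``feature_ids``; when omitted a single block
        named ``"all"`` covering every feature is created.
    """

    gene_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    source_blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.feature_ids)):
            raise MatrixFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.feature_ids)} features"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixFormatError("duplicate gene ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise MatrixFormatError("duplicate feature ids")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            gi, fi = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"non-binary value {self.values[gi, fi]!r} at gene "
                f"{self.gene_ids[gi]!r}, feature {self.feature_ids[fi]!r}"
            )
        self.values = self.values.astype(np.uint8)
        if not self.source_blocks:
            self.source_blocks = {"all": list(self.feature_ids)}
        self._check_blocks()
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    def _check_blocks(self) -> None:
        seen: set[str] = set()
        for name, feats in self.source_blocks.items():
            fset = set(feats)
            if len(fset) != len(feats):
                raise MatrixFormatError(f"block {name!r} lists a feature twice")
            if overlap := (fset & seen):
                raise MatrixFormatError(
                    f"block {name!r} overlaps another block on {sorted(overlap)[:3]}"
                )
            if unknown := (fset - set(self.feature_ids)):
                raise MatrixFormatError(
                    f"block {name!r} names unknown features {sorted(unknown)[:3]}"
                )
            seen |= fset
        if seen != set(self.feature_ids):
            missing = sorted(set(self.feature_ids) - seen)
            raise MatrixFormatError(
                f"source blocks do not cover features {missing[:3]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"gene id {gene_id!r} not in matrix") from None

    def rows(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Rows for the given gene ids, in the given order."""
        idx = [self.gene_index(g) for g in gene_ids]
        return self.values[idx]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def feature_columns(self, feature_ids: Sequence[str]) -> np.ndarray:
        idx = [self._feature_index[f] for f in feature_ids]
        return self.values[:, idx]

    def restrict_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """A new matrix keeping only the named features (single block)."""
        return FeatureMatrix(
            gene_ids=list(self.gene_ids),
            feature_ids=list(feature_ids),
            values=self.feature_columns(feature_ids),
            source_blocks={"all": list(feature_ids)},
        )


@dataclass
class LabelState:
    """Disjoint gene sets of a PU problem, bound to a matrix's gene universe."""

    positives: set[str]
    unlabeled: set[str]
    reliable_negatives: set[str] = field(default_factory=set)
    candidates: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.positives:
            raise MatrixFormatError("no positive (seed) genes: PU learning undefined")
        if self.positives & self.unlabeled:
            raise MatrixFormatError("positives and unlabeled overlap")
        if not self.reliable_negatives <= self.unlabeled:
            raise MatrixFormatError("reliable negatives must be drawn from unlabeled")
        if self.candidates & (self.positives | self.reliable_negatives):
            raise MatrixFormatError("candidates overlap positives or negatives")

    def validate_against(self, matrix: FeatureMatrix) -> None:
        universe = set(matrix.gene_ids)
        for name, ids in (
            ("positives", self.positives),
            ("unlabeled", self.unlabeled),
            ("reliable_negatives", self.reliable_negatives),
            ("candidates", self.candidates),
        ):
            if unknown := (ids - universe):
                raise MatrixFormatError(
                    f"{name} contain ids absent from the matrix: {sorted(unknown)[:3]}"
                )


@dataclass
class RunConfig:
    """Knobs of the full prioritization pipeline.

    Defaults encode the published protocol where it states a value
    (fusion threshold 11 replicates; 10-fold consensus with unanimous
    votes) and conventional choices where it does not (Laplace smoothing
    1, spy fraction 0.15 with a minimum-posterior threshold, Rocchio
    alpha=16 / beta=4).
    """

    random_seed: int = 0
    smoothing: float = 1.0
    spy_fraction: float = 0.15
    spy_noise_level: float = 0.0
    rocchio_alpha: float = 16.0
    rocchio_beta: float = 4.0
    fusion_runs_per_algorithm: int = 5
    fusion_threshold: int = 11
    consensus_folds: int = 10
    consensus_required_votes: int = 10

    def __post_init__(self) -> None:
        if self.smoothing <= 0:
            raise ValueError("smoothing must be positive")
        if not 0 < self.spy_fraction < 1:
            raise ValueError("spy_fraction must be in (0,1)")
        if not 0 <= self.spy_noise_level < 1:
            raise ValueError("spy_noise_level must be in [0,1)")
        if self.rocchio_alpha <= 0 or self.rocchio_beta <= 0:
            raise ValueError("rocchio alpha/beta must be positive")
        if self.fusion_runs_per_algorithm < 1 or self.fusion_threshold < 1:
            raise ValueError("fusion runs and threshold must be >= 1")
        if self.fusion_threshold > 3 * self.fusion_runs_per_algorithm:
            raise ValueError(
                "fusion_threshold exceeds the total number of extraction runs "
                f"(3 x {self.fusion_runs_per_algorithm})"
            )
        if self.consensus_required_votes > self.consensus_folds:
            raise ValueError("consensus_required_votes exceeds consensus_folds")

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        if unknown := (set(data) - known):
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in data.items()})  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# I/O

def _sniff_sep(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_matrix(path: str | Path, source_map_path: str | Path | None = None) -> FeatureMatrix:
    """Read a delimited binary matrix (header = feature ids, col 1 = gene id).

    Tab-separated is canonical; comma is accepted by sniffing the first
    line.  Any missing or non-binary cell is a hard error naming the gene,
    feature and offending token — absence is not imputed as 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    text = path.read_text()
    sep = _sniff_sep(text.split("\n", 1)[0])
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    feature_ids = [str(f) for f in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise MatrixFormatError(f"duplicate gene id rows: {dupes[:3]}")
    if len(set(feature_ids)) != len(feature_ids):
        raise MatrixFormatError("duplicate feature id columns")
    values = np.empty(df.shape, dtype=np.uint8)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = raw[i, j]
            if tok is None or (isinstance(tok, float) and np.isnan(tok)):
                raise MatrixFormatError(
                    f"missing cell at gene {gene_ids[i]!r}, feature {feature_ids[j]!r}"
                )
            tok = str(tok).strip()
            if tok not in ("0", "1"):
                raise MatrixFormatError(
                    f"non-binary value {tok!r} at gene {gene_ids[i]!r}, "
                    f"feature {feature_ids[j]!r}"
                )
            values[i, j] = int(tok)
    blocks = read_source_map(source_map_path) if source_map_path else {}
    return FeatureMatrix(gene_ids, feature_ids, values, blocks)


def read_source_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (block name, feature id) -> block map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"source map not found: {path}")
    blocks: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MatrixFormatError(
                f"{path}:{lineno}: expected 'block<TAB>feature', got {line!r}"
            )
        blocks.setdefault(parts[0].strip(), []).append(parts[1].strip())
    return blocks


def write_matrix(matrix: FeatureMatrix, path: str | Path,
                 source_map_path: str | Path | None = None) -> None:
    """Write the matrix as canonical TSV (and optionally its block map)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.feature_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    if source_map_path is not None:
        with Path(source_map_path).open("w") as fh:
            for block, feats in matrix.source_blocks.items():
                for f in feats:
                    fh.write(f"{block}\t{f}\n")


def read_labels(path: str | Path, matrix: FeatureMatrix) -> LabelState:
    """Read a seed list (one gene id per line) into a LabelState.

    Every listed id must exist in the matrix; the remaining genes become
    the unlabeled set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"seed list not found: {path}")
    universe = set(matrix.gene_ids)
    positives: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        gid = line.strip()
        if not gid:
            continue
        if gid not in universe:
            raise MatrixFormatError(
                f"{path}:{lineno}: seed gene {gid!r} not in matrix"
            )
        positives.add(gid)
    if not positives:
        raise MatrixFormatError(f"{path}: empty seed list; PU learning undefined")
    state = LabelState(positives=positives, unlabeled=universe - positives)
    state.validate_against(matrix)
    return state


def write_labels(state: LabelState, path: str | Path) -> None:
    """Write the positive (seed) set, one id per line, sorted."""
    Path(path).write_text("".join(f"{g}\n" for g in sorted(state.positives)))


def write_ranking(results: Sequence, path: str | Path) -> None:
    """Write a ranked candidate list as TSV (rank, gene_id, weight).

    Deterministic byte output for a fixed input; an empty list yields a
    header-only file.
    """
    rows = ["rank\tgene_id\tweight"]
    last_rank = 0
    for r in results:
        if r.rank <= last_rank:
            raise ValueError("results must be sorted by increasing rank")
        last_rank = r.rank
        rows.append(f"{r.rank}\t{r.gene_id}\t{r.weight}")
    Path(path).write_text("\n".join(rows) + "\n")
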