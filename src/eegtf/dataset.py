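"""Pairwise dataset assembly and min-max normalization.

Subjects of two groups are stacked into a subjects x columns matrix with
binary labels (group_a -> 0, group_b -> 1).  Each column is then rescaled to
[0, 1] by its observed range over the whole pair matrix — the same
leak-prone-but-faithful convention the discrimination stage expects by
default; fold-wise normalization is available in the classification stage
for honest evaluation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compress import CompressedVector

logger = logging.getLogger(__name__)


@dataclass
class PairwiseDataset:
    """Feature matrix and labels for one two-group comparison."""

    pair: tuple[str, str]
    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    subject_ids: list[str]
    normalization: dict[str, tuple[float, float]] | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.subject_ids), len(self.column_names)):
            raise ValueError("X shape inconsistent with labels")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("labels must contain both classes")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def build_pairwise(vectors: list[CompressedVector], group_a: str,
                   group_b: str) -> PairwiseDataset:
    """Stack the subjects of two groups (group_a first, original order kept)."""
    a = [v for v in vectors if v.group == group_a]
    b = [v for v in vectors if v.group == group_b]
    if not a or not b:
        missing = group_a if not a else group_b
        raise ValueError(f"no subjects found for group {missing!r}")
    chosen = a + b
    cols = chosen[0].column_names
    for v in chosen[1:]:
        if v.column_names != cols:
            raise ValueError("inconsistent columns across subjects")
    ids = [v.subject_id for v in chosen]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id across groups")
    X = np.vstack([v.values for v in chosen])
    y = np.array([0] * len(a) + [1] * len(b))
    return PairwiseDataset(pair=(group_a, group_b), X=X, y=y,
                           column_names=list(cols), subject_ids=ids)


def minmax_normalize(ds: PairwiseDataset) -> PairwiseDataset:
    """Rescale every column to [0, 1] by its range over the full pair matrix.

    Constant columns map to 0 (kept, not dropped) with a diagnostic; the
    per-column (min, max) pairs are stored for audit.
    """
    mins = ds.X.min(axis=0)
    maxs = ds.X.max(axis=0)
    span = maxs - mins
    constant = span == 0
    n_const = int(constant.sum())
    if n_const:
        logger.info("%d constant columns mapped to 0 during min-max normalization",
                    n_const)
    safe = np.where(constant, 1.0, span)
    Xn = (ds.X - mins) / safe
    Xn[:, constant] = 0.0
    norm = {name: (float(lo), float(hi))
            for name, lo, hi in zip(ds.column_names, mins, maxs)}
    return PairwiseDataset(pair=ds.pair, X=Xn, y=ds.y.copy(),
                           column_names=list(ds.column_names),
                           subject_ids=list(ds.subject_ids),
                           normalization=norm)


def write_normalization_audit(ds: PairwiseDataset, path: str | Path) -> None:
    """JSON sidecar with the per-column (min, max) used for normalization."""
    if ds.normalization is None:
        raise ValueError("dataset has not been normalized")
    Path(path).write_text(json.dumps(ds.normalization))
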