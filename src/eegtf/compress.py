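"""Temporal compression: collapse each per-channel feature series to 10 statistics.

For every (channel, feature) pair the window-indexed series is reduced to
mean, median, min, max, SD, variance and the 25th/50th/75th/95th quantiles.
Median and the 50th quantile coincide by construction; both are emitted so
the flat vector keeps its documented channels x features x 10 factorization
(19 x 43 x 10 = 8170 for the standard montage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureCube

#: Names and order of the 10 temporal compressors.
COMPRESSOR_NAMES: tuple[str, ...] = (
    "mean", "median", "min", "max", "std", "variance",
    "q25", "q50", "q75", "q95",
)


@dataclass
class CompressedVector:
    """One subject's flat feature vector (channel-major, then feature, then statistic)."""

    subject_id: str
    group: str
    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != len(self.column_names):
            raise ValueError("values and column_names lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("compressed vector contains non-finite values")


def compress_series(series: np.ndarray) -> dict[str, float]:
    """The 10 summary statistics of one feature time series.

    Population (divisor-N) variance; quantiles use linear interpolation.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compress an empty series")
    q25, q50, q75, q95 = np.percentile(x, [25, 50, 75, 95])
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "std": float(x.std()),
        "variance": float(x.var()),
        "q25": float(q25), "q50": float(q50), "q75": float(q75), "q95": float(q95),
    }


def compress_cube(cube: FeatureCube) -> CompressedVector:
    """Flatten a feature cube into a channels x features x compressors vector."""
    n_ch, n_win, n_feat = cube.values.shape
    if n_win < 1:
        raise ValueError("feature cube has no windows")
    x = cube.values  # (channel, window, feature)
    q = np.percentile(x, [25, 50, 75, 95], axis=1)  # (4, channel, feature)
    stats = np.stack([
        x.mean(axis=1), np.median(x, axis=1), x.min(axis=1), x.max(axis=1),
        x.std(axis=1), x.var(axis=1), q[0], q[1], q[2], q[3],
    ], axis=-1)  # (channel, feature, statistic)
    names = [
        f"{ch}|{feat}|{stat}"
        for ch in cube.channel_names
        for feat in cube.feature_names
        for stat in COMPRESSOR_NAMES
    ]
    return CompressedVector(
        subject_id=cube.subject_id,
        group=cube.group,
        values=stats.reshape(-1),
        column_names=names,
    )


def vectors_to_frame(vectors: list[CompressedVector]) -> pd.DataFrame:
    """Wide table: one row per subject, named feature columns plus subject_id/group."""
    if not vectors:
        raise ValueError("no vectors to tabulate")
    cols = vectors[0].column_names
    for v in vectors[1:]:
        if v.column_names != cols:
            raise ValueError("inconsistent column names across subjects")
    frame = pd.DataFrame([v.values for v in vectors], columns=cols)
    frame.insert(0, "group", [v.group for v in vectors])
    frame.insert(0, "subject_id", [v.subject_id for v in vectors])
    return frame


def write_vectors_csv(vectors: list[CompressedVector], path: str | Path) -> None:
    vectors_to_frame(vectors).to_csv(path, index=False)


def read_vectors_csv(path: str | Path) -> list[CompressedVector]:
    frame = pd.read_csv(path)
    cols = [c for c in frame.columns if c not in ("subject_id", "group")]
    return [
        CompressedVector(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            values=row[cols].to_numpy(dtype=float), column_names=cols,
        )
        for _, row in frame.iterrows()
    ]
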