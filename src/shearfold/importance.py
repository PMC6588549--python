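"""Aggregation and reporting of Gini feature importances.

Forests consume 3N raw bead-position components plus 17 per-segment
conformational features; for reporting, the per-bead components are
summed into three aggregate indices (all x, all y, all z) so that every
model input maps onto one reported feature index.  This module turns a
forest's raw mean-decrease-in-impurity vector into: per-index
importances, top-k cumulative fractions, per-bead importance profiles
along the contour, and ranked tables annotated with each feature's
segment of origin (whose off-target entries expose correlated segment
dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_SYMBOLS, n_reported_indices

__all__ = [
    "aggregate_reported_indices",
    "top_k_cumulative",
    "position_profile",
    "rank_with_segment_origin",
    "describe_index",
    "ImportanceReport",
]

_AXIS_AGGREGATES = {1: "sum_r_X", 2: "sum_r_Y", 3: "sum_r_Z"}
_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


def describe_index(index: int, resolution: int) -> tuple[str, int | None]:
    """(feature symbol, 1-based segment) for a reported index.

    The three position aggregates carry no segment annotation — they
    transcend segment classification.
    """
    if index in _AXIS_AGGREGATES:
        return _AXIS_AGGREGATES[index], None
    f, s = divmod(index - 4, resolution)
    if not 0 <= f < len(FEATURE_SYMBOLS):
        raise ValueError(f"index {index} out of range for resolution {resolution}")
    return FEATURE_SYMBOLS[f], s + 1


def aggregate_reported_indices(raw_importances, index_map) -> pd.Series:
    """Sum raw per-input importances into reported feature indices.

    Every model input must be mapped; the aggregate exactly conserves
    the raw total.  Returns a Series indexed by reported feature index
    (1-based, dense through the resolution's final index).
    """
    raw = np.asarray(raw_importances, dtype=float)
    idx = np.asarray(index_map, dtype=int)
    if raw.shape != idx.shape:
        raise ValueError("every model input needs a reported index")
    if idx.min(initial=1) < 1:
        raise ValueError("reported indices are 1-based")
    n_idx = int(idx.max())
    agg = np.zeros(n_idx)
    np.add.at(agg, idx - 1, raw)
    return pd.Series(agg, index=np.arange(1, n_idx + 1), name="importance")


def top_k_cumulative(per_index: pd.Series, k: int) -> float:
    """Sum of the k largest per-index importances (ties to lower index)."""
    if not 1 <= k <= len(per_index):
        raise ValueError("k out of range")
    order = sorted(per_index.index, key=lambda i: (-per_index[i], i))
    return float(sum(per_index[i] for i in order[:k]))


def position_profile(raw_importances, axis, n_beads: int) -> np.ndarray:
    """Per-bead importance curve for one position axis, length N.

    The curve's sum equals that axis's aggregated reported index, so
    summing all three profiles recovers the combined weight of the
    three position aggregates.
    """
    raw = np.asarray(raw_importances, dtype=float)
    ax = _AXES[axis]
    return raw[ax * n_beads : (ax + 1) * n_beads].copy()


def rank_with_segment_origin(
    per_index: pd.Series,
    resolution: int,
    target_segment: int | None = None,
) -> pd.DataFrame:
    """Descending importance table with segment-of-origin annotation.

    ``cross_segment`` flags features measured in a segment other than
    the prediction target — the signature of correlated segment
    dynamics.  Position aggregates are never flagged (no segment).
    Ties are broken by lower reported index.
    """
    order = sorted(per_index.index, key=lambda i: (-per_index[i], i))
    rows = []
    for rank, idx in enumerate(order, start=1):
        sym, seg = describe_index(int(idx), resolution)
        rows.append({
            "rank": rank,
            "index": int(idx),
            "feature": sym,
            "segment": seg,
            "importance": float(per_index[idx]),
            "cross_segment": (
                seg is not None
                and target_segment is not None
                and seg != target_segment
            ),
        })
    return pd.DataFrame(rows)


@dataclass
class ImportanceReport:
    """Importance tables for every fitted segment at one resolution."""

    resolution: int
    per_index: dict[str, pd.Series]
    profiles: dict[str, pd.DataFrame]   # long format: axis, bead, importance
    ranked: dict[str, pd.DataFrame]

    @classmethod
    def from_results(cls, results, k: int = 14) -> "ImportanceReport":
        """Collect aggregates, contour profiles and ranked tables."""
        res = results.dataset.resolution
        per_index, profiles, ranked = {}, {}, {}
        for target in results.forests:
            per_index[target] = results.importance_report(target)
            frames = []
            for axis in "xyz":
                curve = results.position_profile(target, axis)
                frames.append(pd.DataFrame({
                    "axis": axis,
                    "bead": np.arange(len(curve)),
                    "importance": curve,
                }))
            profiles[target] = pd.concat(frames, ignore_index=True)
            ranked[target] = results.ranked_features(target, k=k)
        return cls(res, per_index, profiles, ranked)

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        for target, series in self.per_index.items():
            series.rename_axis("index").to_csv(out / f"importance_{target}.csv")
            self.profiles[target].to_csv(
                out / f"position_profile_{target}.csv", index=False
            )
            self.ranked[target].to_csv(out / f"ranked_{target}.csv", index=False)
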