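"""Binary A2 domain state from FENE spring tension.

An A2 domain is labeled unfolded (1) when the instantaneous tension in
its FENE spring strictly exceeds the unfolding threshold, 11 pN by
default — the most likely unfolding force observed in single-molecule
pulling experiments.  A contour segment is unfolded if any of its
constituent springs is; the chain-level state is the OR over all
springs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import Partitioning

__all__ = ["LabelConfig", "ResponseVector", "a2_state", "partition_response"]


@dataclass(frozen=True)
class LabelConfig:
    """Unfolding threshold on FENE spring tension, pN."""

    unfold_threshold: float = 11.0

    def __post_init__(self) -> None:
        if self.unfold_threshold <= 0:
            raise ValueError("unfold_threshold must be positive")


@dataclass(frozen=True)
class ResponseVector:
    """Per-segment binary states plus the chain-level OR."""

    segment_states: np.ndarray  # (n_segments,) of {0, 1}
    chain_state: int

    def __post_init__(self) -> None:
        seg = np.asarray(self.segment_states, dtype=int)
        object.__setattr__(self, "segment_states", seg)
        if not np.isin(seg, (0, 1)).all():
            raise ValueError("segment states must be 0 or 1")
        if self.chain_state != int(seg.max(initial=0)):
            raise ValueError("chain state must be the OR of segment states")


def a2_state(tension, cfg: LabelConfig = LabelConfig()):
    """1 if tension strictly exceeds the threshold, else 0.

    Ties at exactly the threshold are labeled folded ("past" the
    threshold is read as a strict excursion).  Accepts scalars or
    arrays; negative tensions are rejected.
    """
    t = np.asarray(tension, dtype=float)
    if np.any(t < 0):
        raise ValueError("tension must be >= 0")
    out = (t > cfg.unfold_threshold).astype(int)
    return out if out.ndim else int(out)


def partition_response(spring_states, partitioning: Partitioning) -> ResponseVector:
    """OR the per-spring states into per-segment and chain-level responses.

    Spring ``i`` (beads 2i, 2i+1) belongs to the segment containing its
    beads; a partition boundary may not split a monomer.
    """
    states = np.asarray(spring_states, dtype=int)
    n_springs = partitioning.n_beads // 2
    if states.shape != (n_springs,):
        raise ValueError(f"expected {n_springs} spring states")
    if partitioning.beads_per_segment % 2:
        raise ValueError("partition boundary would split a monomer")
    springs_per_seg = partitioning.beads_per_segment // 2
    seg = states.reshape(partitioning.resolution, springs_per_seg).max(axis=1)
    return ResponseVector(seg, int(seg.max(initial=0)))


def label_tensions(
    tensions: np.ndarray,
    partitioning: Partitioning,
    cfg: LabelConfig = LabelConfig(),
) -> np.ndarray:
    """Vectorized per-segment responses for a (F, N/2) tension array."""
    t = np.asarray(tensions, dtype=float)
    states = a2_state(t, cfg)
    springs_per_seg = partitioning.beads_per_segment // 2
    return states.reshape(t.shape[0], partitioning.resolution, springs_per_seg).max(axis=2)
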