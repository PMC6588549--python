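"""Observation sampling, class balancing and train/test splitting.

Feature observations are consecutive-frame pairs drawn from the
trajectory ensemble every ``stride`` sampled frames, with the stride
chosen at or above the measured decorrelation lag of the total radius
of gyration so that successive observations are effectively
uncorrelated.  The pool is then balanced at the chain level — half of
the rows have no unfolded A2 domain, half have at least one — and split
70/30 into train and test, stratified on the chain-level state.
Per-segment class imbalance is deliberately preserved: unfolding is
concentrated near the chain center, so terminal segments stay scarce in
unfolded examples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import feature_index_map, feature_names, featurize_frames, partition_chain
from .labels import LabelConfig, a2_state, label_tensions
from .simulation import Trajectory

__all__ = [
    "Dataset",
    "sample_observations",
    "estimate_decorrelation_stride",
    "balance_by_chain_state",
    "split",
    "build_dataset",
    "build_datasets",
]

logger = logging.getLogger(__name__)


def sample_observations(
    trajectories: Sequence[Trajectory],
    stride: int,
    burn_frames: int = 0,
) -> pd.DataFrame:
    """Index frames usable as observations, every ``stride`` frames.

    Each observation pairs a sampled frame with its immediate
    predecessor (needed for velocity features), so the first frame of
    every trajectory is never an observation; ``burn_frames`` initial
    frames per trajectory are additionally discarded as the transient
    between the quiescent globule and the sheared steady state.
    Returns a provenance table with columns ``traj`` (position in the
    input sequence), ``replica``, ``frame`` and ``time``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if burn_frames < 0:
        raise ValueError("burn_frames must be >= 0")
    rows = []
    for t_idx, traj in enumerate(trajectories):
        if burn_frames + stride > len(traj) - 1:
            raise ValueError(
                f"stride {stride} exceeds usable length of trajectory {t_idx} "
                f"({len(traj)} frames after {burn_frames} burn-in)"
            )
        frames = np.arange(burn_frames + 1, len(traj), stride)
        rows.append(pd.DataFrame({
            "traj": t_idx,
            "replica": traj.replica,
            "frame": frames,
            "time": traj.times[frames],
        }))
    return pd.concat(rows, ignore_index=True)


def _autocorr(series: np.ndarray, max_lag: int) -> np.ndarray:
    x = series - series.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(max_lag + 1)
    return np.array([x[: len(x) - k] @ x[k:] / denom for k in range(max_lag + 1)])


def estimate_decorrelation_stride(
    trajectories: Sequence[Trajectory],
    threshold: float = 0.2,
    max_lag: int | None = None,
) -> int:
    """Smallest frame lag at which RG_TOT autocorrelation drops below threshold.

    Computed per replica from the total radius of gyration of the whole
    chain and maximized over replicas, so that observations taken at
    this stride have pairwise RG_TOT autocorrelation below the
    threshold.  Used as the operational definition of "uncorrelated"
    observations.
    """
    worst = 1
    for traj in trajectories:
        dev = traj.positions - traj.positions.mean(axis=1, keepdims=True)
        rg = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=1))
        lag_cap = max_lag if max_lag is not None else max(2, len(rg) // 4)
        acf = _autocorr(rg, lag_cap)
        below = np.where(acf < threshold)[0]
        lag = int(below[0]) if len(below) else lag_cap
        # 25% safety factor: at the bare crossing the autocorrelation sits
        # right at the threshold, so estimator noise would leave stride-spaced
        # observations marginally correlated
        worst = max(worst, max(1, int(np.ceil(1.25 * lag))))
    logger.info("decorrelation stride (RG_TOT acf < %.2f): %d frames", threshold, worst)
    return worst


def balance_by_chain_state(
    observations: pd.DataFrame,
    chain_state: np.ndarray,
    n_total: int,
    seed: int,
) -> pd.DataFrame:
    """Draw n_total/2 folded-chain and n_total/2 unfolded-chain rows.

    Sampling is without replacement with a fixed seed; a deficient
    class raises with the class named.
    """
    if n_total % 2:
        raise ValueError("n_total must be even")
    state = np.asarray(chain_state, dtype=int)
    if len(state) != len(observations):
        raise ValueError("chain_state length must match observations")
    half = n_total // 2
    rng = np.random.default_rng(seed)
    picks = []
    for cls, name in ((0, "folded"), (1, "unfolded")):
        idx = np.flatnonzero(state == cls)
        if len(idx) < half:
            raise ValueError(
                f"insufficient {name}-chain observations: need {half}, have {len(idx)}"
            )
        picks.append(rng.choice(idx, size=half, replace=False))
    sel = np.sort(np.concatenate(picks))
    out = observations.iloc[sel].reset_index(drop=True)
    out["chain_state"] = state[sel]
    return out


def _stratified_split(chain_state: np.ndarray, train_frac: float, seed: int) -> np.ndarray:
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    state = np.asarray(chain_state, dtype=int)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(state), dtype=object)
    for cls in np.unique(state):
        idx = np.flatnonzero(state == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        assignment[idx[:n_train]] = "train"
        assignment[idx[n_train:]] = "test"
    return assignment.astype(str)


@dataclass
class Dataset:
    """Balanced, split feature/response table for one resolution."""

    X: pd.DataFrame
    Y: pd.DataFrame
    resolution: int
    split: np.ndarray
    provenance: pd.DataFrame
    seed: int
    stride: int
    reported_indices: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.Y) or len(self.X) != len(self.split):
            raise ValueError("X, Y and split must have equal length")
        if not set(np.unique(self.split)) <= {"train", "test"}:
            raise ValueError("split labels must be 'train'/'test'")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def targets(self) -> list[str]:
        return [c for c in self.Y.columns if c.startswith("y_")]

    def rows(self, subset: str) -> np.ndarray:
        return self.split == subset

    def features(self, subset: str) -> np.ndarray:
        return self.X.values[self.rows(subset)]

    def response(self, target: str, subset: str) -> np.ndarray:
        return self.Y[target].values[self.rows(subset)]

    def class_fraction(self, target: str, subset: str = "train") -> float:
        """Fraction of subset rows whose response for ``target`` is 1."""
        return float(self.response(target, subset).mean())

    def manifest(self) -> dict:
        counts = {
            t: {s: int(self.response(t, s).sum()) for s in ("train", "test")}
            for t in self.targets
        }
        return {
            "n_rows": len(self),
            "resolution": self.resolution,
            "seed": self.seed,
            "stride": self.stride,
            "n_train": int(self.rows("train").sum()),
            "n_test": int(self.rows("test").sum()),
            "unfolded_counts": counts,
        }

    def to_csv(self, path: str | Path) -> None:
        """Write features+responses+split as CSV with a JSON manifest sidecar."""
        path = Path(path)
        table = pd.concat(
            [self.X, self.Y, pd.Series(self.split, name="split")], axis=1
        )
        table.to_csv(path, index=False)
        path.with_suffix(".manifest.json").write_text(
            json.dumps(self.manifest(), indent=2)
        )


def split(dataset: Dataset, train_frac: float = 0.7, seed: int | None = None) -> Dataset:
    """Re-assign the train/test split, stratified on the chain-level state."""
    seed = dataset.seed if seed is None else seed
    dataset.split = _stratified_split(dataset.Y["y_chain"].values, train_frac, seed)
    return dataset


def build_datasets(
    trajectories: Sequence[Trajectory],
    resolutions: Sequence[int],
    n_total: int,
    stride: int | str = "auto",
    train_frac: float = 0.7,
    seed: int = 0,
    label_config: LabelConfig = LabelConfig(),
    burn_frames: int = 0,
) -> dict[int, Dataset]:
    """Build datasets for several resolutions from one shared row selection.

    The observation pool, the chain-level balancing and the stratified
    split are computed once (they depend only on spring tensions), so
    the per-resolution datasets describe the same physical observations
    with different contour resolution.
    """
    params = trajectories[0].params
    if stride == "auto":
        stride = estimate_decorrelation_stride(trajectories)
    pool = sample_observations(trajectories, int(stride), burn_frames)
    tensions = np.stack([
        trajectories[t].tensions[f] for t, f in zip(pool["traj"], pool["frame"])
    ])
    chain_state = np.asarray(a2_state(tensions, label_config)).max(axis=1)
    chosen = balance_by_chain_state(pool, chain_state, n_total, seed)
    assignment = _stratified_split(chosen["chain_state"].values, train_frac, seed + 1)

    # gather the chosen frame pairs, trajectory by trajectory
    n_beads = params.n_beads
    pos_t = np.empty((len(chosen), n_beads, 3))
    pos_prev = np.empty_like(pos_t)
    ten = np.empty((len(chosen), n_beads // 2))
    for t_idx in chosen["traj"].unique():
        rows = np.flatnonzero(chosen["traj"].values == t_idx)
        fr = chosen["frame"].values[rows]
        traj = trajectories[t_idx]
        pos_t[rows] = traj.positions[fr]
        pos_prev[rows] = traj.positions[fr - 1]
        ten[rows] = traj.tensions[fr]

    out: dict[int, Dataset] = {}
    for res in resolutions:
        X = pd.DataFrame(
            featurize_frames(pos_t, pos_prev, params, res),
            columns=feature_names(n_beads, res),
        )
        part = partition_chain(n_beads, res)
        seg = label_tensions(ten, part, label_config)
        Y = pd.DataFrame({f"y_s{s + 1}": seg[:, s] for s in range(res)})
        Y["y_chain"] = chosen["chain_state"].values
        out[res] = Dataset(
            X=X,
            Y=Y,
            resolution=res,
            split=assignment.copy(),
            provenance=chosen[["traj", "replica", "frame", "time"]].copy(),
            seed=seed,
            stride=int(stride),
            reported_indices=feature_index_map(n_beads, res),
        )
    return out


def build_dataset(
    trajectories: Sequence[Trajectory],
    resolution: int,
    n_total: int,
    stride: int | str = "auto",
    train_frac: float = 0.7,
    seed: int = 0,
    label_config: LabelConfig = LabelConfig(),
    burn_frames: int = 0,
) -> Dataset:
    """Single-resolution convenience wrapper around :func:`build_datasets`."""
    return build_datasets(
        trajectories, [resolution], n_total, stride, train_frac, seed,
        label_config, burn_frames,
    )[resolution]
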