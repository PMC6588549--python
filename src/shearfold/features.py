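"""Macromolecular conformational features along the multimer contour.

The chain is partitioned into contiguous equal segments at three
resolutions (chain-level, 5-segment, 10-segment) and, for each
partition, seventeen conformational descriptors are computed from a
pair of consecutive sampled frames: center-of-mass velocity components,
flow-induced displacement, per-axis maximum spans, end-to-end distance,
radii of gyration, the flow variation fraction, local chain
concentration, and the flow-direction projections of the three
principal axes.  Raw per-bead position components (3N values) are
included as model inputs alongside the per-segment descriptors; for
reporting they are aggregated into three indices (sum over x, y and z
components respectively), so the reported feature count is
``3 + 17 * n_segments`` (20, 88 and 173 for the three resolutions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulation import Frame, SimParams

__all__ = [
    "FEATURE_SYMBOLS",
    "LCC_THRESHOLD_RADII",
    "Partitioning",
    "FeatureVector",
    "partition_chain",
    "max_axis_extent",
    "end_to_end",
    "gyration",
    "variation_fraction_flow",
    "local_chain_concentration",
    "pca_flow_projections",
    "com_velocity",
    "flow_induced_displacement",
    "extract_features",
    "featurize_frames",
    "feature_names",
    "feature_index_map",
    "n_reported_indices",
]

#: Per-segment feature symbols in reported index order.
FEATURE_SYMBOLS = (
    "v_X", "v_Y", "v_Z", "dr",
    "MAX_X", "MAX_Y", "MAX_Z", "EE",
    "RG_X", "RG_Y", "RG_Z", "RG_TOT",
    "VFF", "LCC",
    "PCA_1", "PCA_2", "PCA_3",
)

#: Local-chain-concentration threshold distance, in bead radii, keyed by
#: partition resolution.  The ratio of threshold (in bead radii) to
#: beads per partition is 1/2 at every resolution.
LCC_THRESHOLD_RADII = {1: 50.0, 5: 10.0, 10: 5.0}

RESOLUTIONS = (1, 5, 10)


@dataclass(frozen=True)
class Partitioning:
    """Contiguous equal-length contour segments (0-based, half-open)."""

    n_beads: int
    ranges: tuple[tuple[int, int], ...]

    @property
    def resolution(self) -> int:
        return len(self.ranges)

    @property
    def beads_per_segment(self) -> int:
        return self.n_beads // self.resolution

    def segment_of_spring(self, spring: int) -> int:
        """Segment owning FENE spring ``spring`` (beads 2s, 2s+1)."""
        return (2 * spring) // self.beads_per_segment


def partition_chain(n_beads: int, n_segments: int) -> Partitioning:
    """Split ``n_beads`` into ``n_segments`` contiguous equal ranges."""
    if n_segments < 1 or n_beads % n_segments:
        raise ValueError(f"{n_segments} segments do not evenly divide {n_beads} beads")
    size = n_beads // n_segments
    ranges = tuple((s * size, (s + 1) * size) for s in range(n_segments))
    return Partitioning(n_beads, ranges)


# ---------------------------------------------------------------------------
# single-partition operations


def max_axis_extent(positions: np.ndarray, axis: int) -> float:
    """Largest coordinate difference between any two beads on one axis."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 1:
        raise ValueError("empty partition")
    c = pos[:, axis]
    return float(c.max() - c.min())


def end_to_end(positions: np.ndarray) -> float:
    """Distance between the first and last bead of the partition."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("end-to-end distance needs at least two beads")
    return float(np.linalg.norm(pos[-1] - pos[0]))


def gyration(positions: np.ndarray) -> tuple[float, float, float, float]:
    """Per-axis and total radii of gyration (RG_X, RG_Y, RG_Z, RG_TOT)."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 1:
        raise ValueError("empty partition")
    dev = pos - pos.mean(axis=0)
    var = np.mean(dev**2, axis=0)
    return (*np.sqrt(var), float(np.sqrt(var.sum())))


def variation_fraction_flow(rg_x: float, rg_y: float, rg_z: float) -> float:
    """Flow-direction share of spatial variation, RG_X / (RG_X+RG_Y+RG_Z)."""
    total = rg_x + rg_y + rg_z
    if total == 0.0:
        warnings.warn("degenerate point partition: VFF defined as 0", stacklevel=2)
        return 0.0
    return float(rg_x / total)


def local_chain_concentration(
    all_positions: np.ndarray,
    segment_range: tuple[int, int],
    resolution: int,
    bead_radius: float,
) -> float:
    """Fraction of all chain beads within the threshold of the segment COM.

    The threshold distance is 50, 10 and 5 bead radii at chain-level,
    5-segment and 10-segment resolution respectively; beads of the
    segment itself are counted.
    """
    if resolution not in LCC_THRESHOLD_RADII:
        raise ValueError(f"unknown resolution {resolution}")
    pos = np.asarray(all_positions, dtype=float)
    a, b = segment_range
    com = pos[a:b].mean(axis=0)
    thr = LCC_THRESHOLD_RADII[resolution] * bead_radius
    dist = np.linalg.norm(pos - com, axis=1)
    return float(np.count_nonzero(dist <= thr) / pos.shape[0])


def _order_axes(evals: np.ndarray, evecs: np.ndarray) -> np.ndarray:
    """Columns of evecs sorted by descending eigenvalue.

    Near-degenerate eigenvalues are tie-broken deterministically by
    preferring stronger alignment with x, then y, then z.
    """
    scale = max(abs(float(evals.max())), 1e-300)
    q = np.round(evals / (scale * 1e-9))
    keys = np.lexsort((
        -np.abs(evecs[2]), -np.abs(evecs[1]), -np.abs(evecs[0]), -q,
    ))
    return evecs[:, keys]


def pca_flow_projections(positions: np.ndarray) -> tuple[float, float, float]:
    """|cosine| between each principal axis and the flow direction.

    Principal axes are the eigenvectors of the 3x3 bead-position
    covariance (1/n normalization), ordered by descending eigenvalue;
    the returned values are the absolute x-components of the unit
    eigenvectors, each in [0, 1].
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 3:
        raise ValueError("PCA needs at least three beads")
    dev = pos - pos.mean(axis=0)
    cov = dev.T @ dev / pos.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    ordered = _order_axes(evals, evecs)
    return tuple(np.abs(ordered[0, :]))


def com_velocity(
    frame_t: Frame,
    frame_prev: Frame,
    segment_range: tuple[int, int],
    sample_interval: float | None = None,
) -> tuple[float, float, float]:
    """Finite-difference COM velocity of the segment over one sampling interval."""
    dt = frame_t.time - frame_prev.time
    if dt <= 0:
        raise ValueError("frames must be time-ordered and distinct")
    if sample_interval is not None and abs(dt - sample_interval) > 1e-9 * sample_interval:
        raise ValueError("frames are not consecutive samples")
    a, b = segment_range
    v = (frame_t.positions[a:b].mean(axis=0) - frame_prev.positions[a:b].mean(axis=0)) / dt
    return tuple(v)


def flow_induced_displacement(
    frame: Frame,
    segment_range: tuple[int, int],
    shear_rate: float,
    sample_interval: float,
) -> float:
    """COM displacement magnitude from the undisturbed field over one interval.

    The ambient field is pure x-advection, so the magnitude is
    |shear_rate * mean z * dt|.
    """
    a, b = segment_range
    z_com = frame.positions[a:b, 2].mean()
    return float(abs(shear_rate * z_com * sample_interval))


# ---------------------------------------------------------------------------
# reported-index bookkeeping


def n_reported_indices(resolution: int) -> int:
    return 3 + len(FEATURE_SYMBOLS) * resolution


def feature_names(n_beads: int, resolution: int) -> list[str]:
    """Model-input column names: raw positions then per-segment features."""
    names = [f"{ax}_b{i}" for ax in "xyz" for i in range(n_beads)]
    for sym in FEATURE_SYMBOLS:
        for s in range(resolution):
            names.append(f"{sym}_s{s + 1}")
    return names


def feature_index_map(n_beads: int, resolution: int) -> np.ndarray:
    """Reported (reported) feature index for each model-input column.

    Raw x/y/z position components map to aggregate indices 1/2/3; the
    per-segment feature ``f`` (0-based) of segment ``s`` (0-based) maps
    to ``4 + f * resolution + s``, so e.g. at 5-segment resolution the
    per-axis maximum span in x occupies indices 24-28 and the last PCA
    projection ends at index 88.
    """
    idx = [np.full(n_beads, ax + 1) for ax in range(3)]
    for f in range(len(FEATURE_SYMBOLS)):
        idx.append(4 + f * resolution + np.arange(resolution))
    return np.concatenate(idx).astype(int)


@dataclass(frozen=True)
class FeatureVector:
    """One observation's model inputs plus the reported-index map."""

    values: np.ndarray        # (3N + 17*resolution,)
    names: tuple[str, ...]
    reported_indices: np.ndarray
    resolution: int
    n_beads: int

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    @property
    def n_reported(self) -> int:
        return int(self.reported_indices.max())


# ---------------------------------------------------------------------------
# batch extraction


def featurize_frames(
    positions: np.ndarray,
    prev_positions: np.ndarray,
    params: SimParams,
    resolution: int,
) -> np.ndarray:
    """Feature matrix (F, 3N + 17*resolution) for F frame pairs.

    ``positions`` and ``prev_positions`` hold the sampled frames and
    their immediate predecessors (spacing = one sample interval), shape
    (F, N, 3) each.
    """
    pos = np.asarray(positions, dtype=float)
    prev = np.asarray(prev_positions, dtype=float)
    if pos.shape != prev.shape or pos.ndim != 3:
        raise ValueError("positions and prev_positions must share shape (F, N, 3)")
    nf, n_beads, _ = pos.shape
    part = partition_chain(n_beads, resolution)
    dt = params.sample_interval
    thr = LCC_THRESHOLD_RADII[resolution] * params.bead_radius

    raw = np.concatenate([pos[:, :, 0], pos[:, :, 1], pos[:, :, 2]], axis=1)
    cols = {sym: np.empty((nf, resolution)) for sym in FEATURE_SYMBOLS}
    for s, (a, b) in enumerate(part.ranges):
        seg = pos[:, a:b, :]
        com = seg.mean(axis=1)
        com_prev = prev[:, a:b, :].mean(axis=1)
        v = (com - com_prev) / dt
        cols["v_X"][:, s], cols["v_Y"][:, s], cols["v_Z"][:, s] = v.T
        cols["dr"][:, s] = np.abs(params.shear_rate * com[:, 2] * dt)
        spans = seg.max(axis=1) - seg.min(axis=1)
        cols["MAX_X"][:, s], cols["MAX_Y"][:, s], cols["MAX_Z"][:, s] = spans.T
        cols["EE"][:, s] = np.linalg.norm(seg[:, -1] - seg[:, 0], axis=1)
        dev = seg - com[:, None, :]
        var = np.mean(dev**2, axis=1)
        rg = np.sqrt(var)
        cols["RG_X"][:, s], cols["RG_Y"][:, s], cols["RG_Z"][:, s] = rg.T
        cols["RG_TOT"][:, s] = np.sqrt(var.sum(axis=1))
        rg_sum = rg.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vff = np.where(rg_sum > 0, rg[:, 0] / np.where(rg_sum > 0, rg_sum, 1.0), 0.0)
        cols["VFF"][:, s] = vff
        dist = np.linalg.norm(pos - com[:, None, :], axis=2)
        cols["LCC"][:, s] = np.count_nonzero(dist <= thr, axis=1) / n_beads
        cov = np.einsum("fni,fnj->fij", dev, dev) / seg.shape[1]
        evals, evecs = np.linalg.eigh(cov)
        proj = _batched_flow_projections(evals, evecs)
        cols["PCA_1"][:, s], cols["PCA_2"][:, s], cols["PCA_3"][:, s] = proj.T
    seg_block = np.concatenate([cols[sym] for sym in FEATURE_SYMBOLS], axis=1)
    return np.concatenate([raw, seg_block], axis=1)


def _batched_flow_projections(evals: np.ndarray, evecs: np.ndarray) -> np.ndarray:
    """|x-component| of eigenvectors ordered by descending eigenvalue.

    ``np.linalg.eigh`` returns ascending order; frames with
    near-degenerate eigenvalues are re-ordered individually with the
    deterministic x-then-y-then-z tie-break.
    """
    nf = evals.shape[0]
    order = np.argsort(-evals, axis=1, kind="stable")
    proj = np.abs(np.take_along_axis(evecs[:, 0, :], order, axis=1))
    scale = np.maximum(np.abs(evals).max(axis=1), 1e-300)
    gaps = np.diff(np.sort(evals, axis=1), axis=1) / scale[:, None]
    degenerate = np.where((gaps < 1e-9).any(axis=1))[0]
    for f in degenerate:
        ordered = _order_axes(evals[f], evecs[f])
        proj[f] = np.abs(ordered[0, :])
    return proj


def extract_features(
    frame_t: Frame,
    frame_prev: Frame,
    params: SimParams,
    resolution: int,
) -> FeatureVector:
    """Full feature vector for one observation (a consecutive frame pair)."""
    if resolution not in RESOLUTIONS:
        raise ValueError(f"resolution must be one of {RESOLUTIONS}")
    if frame_t.n_beads != frame_prev.n_beads:
        raise ValueError("frames disagree on chain size")
    dt = frame_t.time - frame_prev.time
    if dt <= 0 or abs(dt - params.sample_interval) > 1e-9 * params.sample_interval:
        raise ValueError("frames are not consecutive samples")
    vals = featurize_frames(
        frame_t.positions[None], frame_prev.positions[None], params, resolution
    )[0]
    n = frame_t.n_beads
    return FeatureVector(
        values=vals,
        names=tuple(feature_names(n, resolution)),
        reported_indices=feature_index_map(n, resolution),
        resolution=resolution,
        n_beads=n,
    )
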