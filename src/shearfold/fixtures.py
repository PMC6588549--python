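"""Synthetic conformation fixtures with prescribed tensions.

These stand in for simulation output when testing the feature, label,
dataset and forest stages: each archetype produces a consecutive frame
pair whose conformational features are known in closed form (a rod
along the flow axis has PCA_1 = 1 and RG_Y = RG_Z = 0; a compact
globule has chain-level LCC = 1), and whose per-spring tensions are
exactly the prescribed values rather than being derived from the
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulation import Frame

__all__ = ["FixtureSpec", "generate_fixture"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic synthetic frame pair.

    archetype
        ``"globule"``, ``"rod"`` (straight chain along ``axis``),
        ``"two-arm-pulled"`` (hairpin in the xz-plane, both arms
        stretched along x) or ``"custom"`` (explicit ``coordinates``).
    tensions
        Per-spring tensions (pN), length ``n_beads // 2``; defaults to
        all zero.  Honored exactly in both frames.
    velocity
        Uniform translation velocity (nm/s) applied between the two
        frames, so segment COM velocities equal it exactly.
    """

    archetype: str
    n_beads: int = 100
    tensions: tuple[float, ...] | None = None
    seed: int = 0
    axis: str = "x"
    spacing: float = 30.0            # nm, bead spacing for rod/hairpin
    radius: float = 300.0            # nm, globule radius
    bead_radius: float = 15.0        # nm
    velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sample_interval: float = 1.96e-5   # s, matches SimParams default
    coordinates: tuple | None = None

    def resolved_tensions(self) -> np.ndarray:
        n_springs = self.n_beads // 2
        if self.tensions is None:
            return np.zeros(n_springs)
        t = np.asarray(self.tensions, dtype=float)
        if t.shape != (n_springs,):
            raise ValueError(f"need {n_springs} tensions, got {t.shape}")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("tensions must be finite and >= 0")
        return t


def _rod(spec: FixtureSpec) -> np.ndarray:
    if spec.axis not in _AXES:
        raise ValueError(f"unknown axis {spec.axis!r}")
    pos = np.zeros((spec.n_beads, 3))
    pos[:, _AXES[spec.axis]] = spec.spacing * np.arange(spec.n_beads)
    return pos


def _globule(spec: FixtureSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    direction = rng.standard_normal((spec.n_beads, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = spec.radius * rng.random(spec.n_beads) ** (1.0 / 3.0)
    pos = direction * r[:, None]
    return pos - pos.mean(axis=0)


def _two_arm(spec: FixtureSpec) -> np.ndarray:
    n = spec.n_beads
    half = n // 2
    pos = np.zeros((n, 3))
    # descending arm then ascending arm, apex at the chain midpoint
    pos[:half, 0] = spec.spacing * np.arange(half)[::-1]
    pos[:half, 2] = 0.2 * spec.spacing * np.arange(half)[::-1]
    pos[half:, 0] = spec.spacing * np.arange(n - half)
    pos[half:, 2] = -0.2 * spec.spacing * np.arange(n - half)
    return pos


def generate_fixture(spec: FixtureSpec) -> tuple[Frame, Frame]:
    """Build the (previous, current) frame pair for a fixture spec."""
    if spec.n_beads < 2 or spec.n_beads % 2:
        raise ValueError("n_beads must be even and >= 2")
    builders = {"rod": _rod, "globule": _globule, "two-arm-pulled": _two_arm}
    if spec.archetype == "custom":
        if spec.coordinates is None:
            raise ValueError("custom archetype requires coordinates")
        pos = np.asarray(spec.coordinates, dtype=float)
        if pos.shape != (spec.n_beads, 3):
            raise ValueError("coordinates must have shape (n_beads, 3)")
    elif spec.archetype in builders:
        pos = builders[spec.archetype](spec)
    else:
        raise ValueError(f"unknown archetype {spec.archetype!r}")
    tensions = spec.resolved_tensions()
    shift = np.asarray(spec.velocity) * spec.sample_interval
    frame_prev = Frame(0.0, pos - shift, tensions)
    frame_t = Frame(spec.sample_interval, pos, tensions)
    return frame_prev, frame_t
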