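"""Brownian dynamics of a coarse-grained vWF multimer in simple shear.

The multimer is a bead-spring chain of ``N`` beads representing ``N/2``
monomers.  Within monomer ``i`` the beads ``(2i, 2i+1)`` are joined by a
finitely extensible nonlinear elastic (FENE) spring standing in for the
force-sensitive A2 domain; consecutive monomers are joined by a stiff
harmonic bond representing the inter-monomer disulfide link.  Attractive
truncated Lennard-Jones interactions between non-bonded beads collapse
the chain into a globule at rest; an imposed simple shear flow
``v_x = shear_rate * z`` drives tumbling, unraveling and internal
tension.

Dynamics are overdamped (Euler-Maruyama) with free-draining Stokes
mobility by default; a pairwise Rotne-Prager-Yamakawa mobility is
available behind ``hi_mode="pairwise"`` for small systems.  Both bonded
interactions are advanced semi-implicitly by operator splitting over
their disjoint bead pairs: harmonic bonds relax toward rest in closed
form, and FENE spring lengths solve a cubic that keeps them strictly
below the finite-extensibility limit R0 at any tension the flow
produces (see :mod:`shearfold._kernels`).

All public quantities are in physical units: nm, pN, s, K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "BOLTZMANN_PN_NM",
    "SimParams",
    "Frame",
    "Trajectory",
    "fene_tension",
    "shear_velocity",
    "a2_tensions",
    "bd_step",
    "equilibrate",
    "simulate",
    "radius_of_gyration",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM = 1.380649e-23 * 1e21


class OverExtensionError(ValueError):
    """A FENE spring reached or exceeded its maximum extension R0.

    Under the semi-implicit integrator this indicates a corrupted or
    externally constructed frame rather than an unstable timestep.
    """


@dataclass(frozen=True)
class SimParams:
    """Physical and numerical parameters of the bead-spring model.

    Defaults describe a 100-bead (50-monomer) multimer at the strong
    shear rate used throughout, 5e5 1/s, at which centrally located A2
    springs regularly exceed the 11 pN unfolding threshold while
    terminal ones rarely do, and the rest state is a collapsed globule.
    With a 12 nm bead in water-like solvent the bead diffusion time is
    7.9 us, so the reduced shear rate (Weissenberg number) is about 3.9.
    The FENE spring is soft, reaching the 11 pN threshold at 65% of its
    60 nm maximum extension.  All values are model defaults exposed
    here, not experimentally fitted constants.
    """

    n_beads: int = 100
    bead_radius: float = 12.0          # nm
    fene_k: float = 0.0825             # pN/nm
    fene_r0: float = 60.0              # nm
    harmonic_k: float = 4.125          # pN/nm, 50x fene_k ("stiff")
    harmonic_r0: float = 24.0          # nm, one bead diameter
    lj_eps: float = 4.0                # well depth, units of kBT
    lj_sigma: float = 24.0             # nm, one bead diameter
    lj_cutoff: float = 36.0            # nm, 1.5 sigma (short-range attraction)
    pair_force_cap: float = 50.0       # pN, soft-core cap on LJ repulsion
    shear_rate: float = 5.0e5          # 1/s
    temperature: float = 300.0         # K
    viscosity: float = 1.0e-3          # Pa s
    dt: float = 1.4e-8                 # s
    sample_interval: float = 1.96e-5   # s (1400 steps, about 2.5 bead times)
    hi_mode: str = "free-draining"     # or "pairwise"
    n_replicas: int = 22
    n_samples: int = 2000              # sampled frames per replica
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 2 or self.n_beads % 2:
            raise ValueError("n_beads must be even and >= 2")
        if self.fene_r0 <= 0 or self.fene_k <= 0:
            raise ValueError("FENE parameters must be positive")
        if self.shear_rate < 0:
            raise ValueError("shear_rate must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = self.sample_interval / self.dt
        if steps < 1 - 1e-9 or abs(steps - round(steps)) > 1e-6 * steps:
            raise ValueError("sample_interval must be a positive multiple of dt")
        if self.hi_mode not in ("free-draining", "pairwise"):
            raise ValueError(f"unknown hi_mode {self.hi_mode!r}")

    # -- derived physical scales ------------------------------------
    @property
    def kbt(self) -> float:
        """Thermal energy, pN nm."""
        return BOLTZMANN_PN_NM * self.temperature

    @property
    def zeta(self) -> float:
        """Stokes drag coefficient 6 pi eta a, pN s / nm."""
        return 6.0 * math.pi * self.viscosity * self.bead_radius * 1e-6

    @property
    def diffusivity(self) -> float:
        """Single-bead diffusion coefficient kBT / zeta, nm^2 / s."""
        return self.kbt / self.zeta

    @property
    def bead_time(self) -> float:
        """Bead diffusion time a^2 / D, s (the natural time unit)."""
        return self.bead_radius**2 / self.diffusivity

    @property
    def steps_per_sample(self) -> int:
        return int(round(self.sample_interval / self.dt))

    @property
    def n_springs(self) -> int:
        return self.n_beads // 2

    @property
    def contour_length(self) -> float:
        """Fully stretched chain length, nm (all bonds at maximum)."""
        n_mono = self.n_springs
        return n_mono * self.fene_r0 + (n_mono - 1) * self.harmonic_r0

    def replaced(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Frame:
    """One sampled configuration: bead positions and A2 spring tensions."""

    time: float
    positions: np.ndarray      # (N, 3) nm; x = flow, y = vorticity, z = gradient
    a2_tensions: np.ndarray    # (N/2,) pN

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ten = np.asarray(self.a2_tensions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "a2_tensions", ten)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if ten.shape != (pos.shape[0] // 2,):
            raise ValueError("need exactly N/2 A2 tensions")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite positions")
        if not (np.all(np.isfinite(ten)) and np.all(ten >= 0)):
            raise ValueError("tensions must be finite and >= 0")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


class Trajectory:
    """Uniformly sampled frames from one replica.

    Stores positions ``(F, N, 3)``, tensions ``(F, N/2)`` and times
    ``(F,)`` as arrays; iterate or index to obtain :class:`Frame`
    objects.
    """

    def __init__(
        self,
        times: np.ndarray,
        positions: np.ndarray,
        tensions: np.ndarray,
        params: SimParams,
        replica: int = 0,
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.positions = np.asarray(positions, dtype=float)
        self.tensions = np.asarray(tensions, dtype=float)
        self.params = params
        self.replica = int(replica)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if len(self.times) != len(self.positions) or len(self.times) != len(self.tensions):
            raise ValueError("times, positions, tensions lengths differ")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.any(np.abs(dt - dt[0]) > 1e-9 * dt[0] + 1e-18)):
            raise ValueError("frame times must increase with uniform spacing")

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.times[i], self.positions[i], self.tensions[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self[i]


# ---------------------------------------------------------------------------
# elementary operations


def fene_tension(r, k: float, r0: float):
    """FENE restoring force F(r) = k r / (1 - (r/r0)^2), pN.

    Strictly increasing in ``r`` and divergent as ``r -> r0``; raises
    :class:`OverExtensionError` at or beyond the maximum extension,
    which in a running simulation signals a timestep problem.
    Accepts scalars or arrays.
    """
    if k <= 0 or r0 <= 0:
        raise ValueError("k and r0 must be positive")
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise ValueError("extension must be >= 0")
    if np.any(arr >= r0):
        raise OverExtensionError(f"FENE extension >= R0 = {r0} nm")
    out = k * arr / (1.0 - (arr / r0) ** 2)
    return out if out.ndim else float(out)


def shear_velocity(z, shear_rate: float):
    """Undisturbed flow velocity v_x = shear_rate * z (nm/s)."""
    out = np.asarray(z, dtype=float) * shear_rate
    return out if out.ndim else float(out)


def a2_tensions(positions: np.ndarray, params: SimParams) -> np.ndarray:
    """Per-monomer FENE tensions from bead positions, length N/2."""
    pos = np.asarray(positions, dtype=float)
    ext = np.linalg.norm(pos[1::2] - pos[0::2], axis=1)
    return np.asarray(fene_tension(ext, params.fene_k, params.fene_r0))


def radius_of_gyration(positions: np.ndarray) -> float:
    """Total radius of gyration of a bead cloud, nm."""
    pos = np.asarray(positions, dtype=float)
    return float(np.sqrt(np.mean(np.sum((pos - pos.mean(axis=0)) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# forces (NumPy reference path; the production loop uses _kernels)


def _lj_pair_forces(pos: np.ndarray, p: SimParams) -> np.ndarray:
    """Truncated, repulsion-capped LJ forces, pN (bonded pairs excluded)."""
    n = pos.shape[0]
    f = np.zeros_like(pos)
    eps = p.lj_eps * p.kbt
    diff = pos[None, :, :] - pos[:, None, :]
    r2 = np.sum(diff**2, axis=-1)
    i, j = np.triu_indices(n, k=2)
    sel = (r2[i, j] < p.lj_cutoff**2) & (r2[i, j] > 1e-12)
    i, j = i[sel], j[sel]
    r2ij = r2[i, j]
    s6 = (p.lj_sigma**2 / r2ij) ** 3
    fr = 24.0 * eps * (2.0 * s6**2 - s6) / r2ij
    # soft-core cap on the repulsive branch
    fr = np.minimum(fr, p.pair_force_cap / np.sqrt(r2ij))
    fij = fr[:, None] * diff[i, j]  # force on j from i (repulsive positive)
    np.add.at(f, j, fij)
    np.add.at(f, i, -fij)
    return f


def _harmonic_forces(pos: np.ndarray, p: SimParams) -> np.ndarray:
    """Explicit harmonic-bond forces, pN (used by the pairwise-HI path)."""
    n = pos.shape[0]
    f = np.zeros_like(pos)
    a = np.arange(1, n - 1, 2)
    d = pos[a + 1] - pos[a]
    r = np.linalg.norm(d, axis=1)
    mask = r > 1e-12
    fmag = np.zeros_like(r)
    fmag[mask] = p.harmonic_k * (r[mask] - p.harmonic_r0) / r[mask]
    fb = fmag[:, None] * d
    np.add.at(f, a, fb)
    np.add.at(f, a + 1, -fb)
    return f


def _fene_forces(pos: np.ndarray, p: SimParams) -> np.ndarray:
    """Explicit FENE spring forces (used only by the pairwise-HI path)."""
    f = np.zeros_like(pos)
    d = pos[1::2] - pos[0::2]
    r = np.linalg.norm(d, axis=1)
    t = np.asarray(fene_tension(r, p.fene_k, p.fene_r0))
    mask = r > 1e-12
    fvec = np.zeros_like(d)
    fvec[mask] = (t[mask] / r[mask])[:, None] * d[mask]
    f[0::2] += fvec
    f[1::2] -= fvec
    return f


def _rpy_mobility(pos: np.ndarray, p: SimParams) -> np.ndarray:
    """Rotne-Prager-Yamakawa pairwise mobility matrix, (3N, 3N), nm/(pN s)."""
    n = pos.shape[0]
    a = p.bead_radius
    mu0 = 1.0 / p.zeta
    m = np.zeros((3 * n, 3 * n))
    eye = np.eye(3)
    for i in range(n):
        m[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = mu0 * eye
        for j in range(i + 1, n):
            d = pos[j] - pos[i]
            r = np.linalg.norm(d)
            if r < 1e-12:
                blk = mu0 * eye
            elif r >= 2 * a:
                e = np.outer(d, d) / r**2
                blk = mu0 * (3 * a / (4 * r)) * ((1 + 2 * a**2 / (3 * r**2)) * eye
                                                 + (1 - 2 * a**2 / r**2) * e)
            else:
                e = np.outer(d, d) / r**2
                blk = mu0 * ((1 - 9 * r / (32 * a)) * eye + (3 * r / (32 * a)) * e)
            m[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = blk
            m[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = blk
    return m


def _solve_fene_lengths(d: np.ndarray, alpha: float, r0: float) -> np.ndarray:
    out = np.empty_like(d)
    for s, ds in enumerate(d):
        out[s] = _kernels.solve_fene_length(ds, alpha, r0)
    return out


def bd_step(frame: Frame, params: SimParams, rng: np.random.Generator) -> Frame:
    """Advance one overdamped timestep and return the new frame.

    Drift is mobility times conservative force plus the undisturbed
    shear velocity at each bead's z; the stochastic displacement has
    covariance 2 kBT M dt (fluctuation-dissipation consistent with the
    chosen mobility).  In free-draining mode the FENE springs are
    advanced semi-implicitly; with the pairwise mobility they are
    explicit, and over-extension raises an integration error.
    """
    p = params
    pos = frame.positions.copy()
    n = pos.shape[0]
    if p.hi_mode == "pairwise":
        forces = _lj_pair_forces(pos, p) + _harmonic_forces(pos, p) + _fene_forces(pos, p)
        mob = _rpy_mobility(pos, p)
        drift = (mob @ forces.ravel()).reshape(n, 3) * p.dt
        chol = np.linalg.cholesky(2.0 * p.kbt * p.dt * mob)
        noise = (chol @ rng.standard_normal(3 * n)).reshape(n, 3)
        adv = p.dt * p.shear_rate * pos[:, 2]
        pos += drift + noise
        pos[:, 0] += adv
    else:
        forces = _lj_pair_forces(pos, p)
        noise = math.sqrt(2.0 * p.diffusivity * p.dt) * rng.standard_normal((n, 3))
        adv = p.dt * p.shear_rate * pos[:, 2]
        pos += (p.dt / p.zeta) * forces + noise
        pos[:, 0] += adv
        # implicit harmonic bonds: relax toward rest length
        b = np.arange(1, n - 1, 2)
        d = pos[b + 1] - pos[b]
        dlen = np.linalg.norm(d, axis=1)
        beta = 2.0 * p.harmonic_k * p.dt / p.zeta
        mask = dlen > 1e-12
        new_len = (dlen + beta * p.harmonic_r0) / (1.0 + beta)
        shrink = np.zeros_like(dlen)
        shrink[mask] = 0.5 * (1.0 - new_len[mask] / dlen[mask])
        pos[b] += shrink[:, None] * d
        pos[b + 1] -= shrink[:, None] * d
        # semi-implicit FENE contraction about each spring midpoint
        d = pos[1::2] - pos[0::2]
        dlen = np.linalg.norm(d, axis=1)
        alpha = 2.0 * p.fene_k * p.dt / p.zeta
        new_len = _solve_fene_lengths(dlen, alpha, p.fene_r0)
        mask = dlen > 1e-12
        shrink = np.zeros_like(dlen)
        shrink[mask] = 0.5 * (1.0 - new_len[mask] / dlen[mask])
        pos[0::2] += shrink[:, None] * d
        pos[1::2] -= shrink[:, None] * d
    tensions = a2_tensions(pos, p)  # raises OverExtensionError if r >= R0
    return Frame(frame.time + p.dt, pos, tensions)


# ---------------------------------------------------------------------------
# equilibration and production


def _initial_positions(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Compact start: monomer blobs on a serpentine lattice.

    Monomer centers sit on a dense grid (spacing near the LJ minimum)
    with the two beads of each monomer offset a few nm about their
    center, so FENE springs begin near their contracted rest state and
    no non-bonded pair overlaps hard.
    """
    n_mono = params.n_springs
    spacing = 2.0 ** (1.0 / 6.0) * params.lj_sigma
    side = max(2, int(math.ceil(n_mono ** (1.0 / 3.0))))
    centers = np.empty((n_mono, 3))
    idx = 0
    for iz in range(side):
        for iy in range(side):
            for ix in range(side):
                if idx >= n_mono:
                    break
                x = ix if (iy % 2 == 0) else side - 1 - ix
                y = iy if (iz % 2 == 0) else side - 1 - iy
                centers[idx] = (x * spacing, y * spacing, iz * spacing)
                idx += 1
    off = rng.standard_normal((n_mono, 3))
    off *= 2.5 / np.linalg.norm(off, axis=1, keepdims=True)
    pos = np.empty((params.n_beads, 3))
    pos[0::2] = centers - off
    pos[1::2] = centers + off
    return pos - pos.mean(axis=0)


class _NeighborState:
    """Verlet-list state carried across kernel chunks."""

    def __init__(self, n_beads: int):
        self.pairs = np.empty((n_beads * (n_beads - 1) // 2, 2), dtype=np.int32)
        self.ref_pos = np.zeros((n_beads, 3), dtype=np.float32)
        # [pair count, steps since build]; zero steps forces the first build
        self.n_pairs = np.zeros(2, dtype=np.int64)


_NOISE_CHUNK = 4096


_EMPTY_POS = np.empty((0, 0, 3), dtype=np.float32)
_EMPTY_TEN = np.empty((0, 0), dtype=np.float32)


def _advance(
    pos32: np.ndarray,
    params: SimParams,
    n_steps: int,
    shear_rate: float,
    rng: np.random.Generator,
    state: _NeighborState,
    sample_every: int = 0,
    out_pos: np.ndarray = _EMPTY_POS,
    out_ten: np.ndarray = _EMPTY_TEN,
) -> None:
    """Advance float32 positions in place by n_steps, noise in blocks.

    With ``sample_every > 0``, positions and tensions are written into
    the float32 output arrays after every ``sample_every``-th step;
    ``n_steps`` must then be a multiple of ``sample_every``.
    """
    done = 0
    written = 0
    block = _NOISE_CHUNK
    if sample_every > 0:
        block = max(1, _NOISE_CHUNK // sample_every) * sample_every
    while done < n_steps:
        m = min(block, n_steps - done)
        noise = rng.standard_normal((m, params.n_beads, 3), dtype=np.float32)
        written += _kernels.advance_chunk(
            pos32,
            noise,
            params.dt,
            params.zeta,
            params.kbt,
            shear_rate,
            params.fene_k,
            params.fene_r0,
            params.harmonic_k,
            params.harmonic_r0,
            params.lj_eps * params.kbt,
            params.lj_sigma,
            params.lj_cutoff,
            params.pair_force_cap,
            0.5 * params.lj_sigma,
            1,
            state.pairs,
            state.ref_pos,
            state.n_pairs,
            sample_every,
            out_pos[written:],
            out_ten[written:],
        )
        done += m


def _run_kernel(
    pos: np.ndarray,
    params: SimParams,
    n_steps: int,
    sample_every: int,
    shear_rate: float,
    rng: np.random.Generator,
    state: _NeighborState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    n_samples = n_steps // sample_every
    out_pos = np.empty((n_samples, params.n_beads, 3), dtype=np.float32)
    out_ten = np.empty((n_samples, params.n_springs), dtype=np.float32)
    if state is None:
        state = _NeighborState(params.n_beads)
    pos32 = np.ascontiguousarray(pos, dtype=np.float32)
    _advance(pos32, params, n_samples * sample_every, shear_rate, rng, state,
             sample_every, out_pos, out_ten)
    pos[:] = pos32
    return out_pos.astype(float), out_ten.astype(float)


def equilibrate(
    params: SimParams,
    seed: int | None = None,
    rg_tol: float = 0.01,
    window_steps: int = 10_000,
    max_steps: int = 2_000_000,
) -> Frame:
    """Relax the chain at zero shear into its rest-state globule.

    Runs quiescent Brownian dynamics from a compact lattice start until
    the total radius of gyration plateaus (relative change below
    ``rg_tol`` across three consecutive windows of ``window_steps``
    steps).  Raises ``RuntimeError`` if the plateau is not reached
    within ``max_steps``.
    """
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence([int(seed), 917])
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    rng = np.random.default_rng(ss.spawn(2)[1])
    pos = np.ascontiguousarray(_initial_positions(params, init_rng), dtype=np.float32)
    state = _NeighborState(params.n_beads)
    n_meas = 10  # average Rg over the window to suppress thermal noise
    sub = max(1, window_steps // n_meas)
    rg_prev = radius_of_gyration(pos)
    streak = 0
    steps_done = 0
    while steps_done < max_steps:
        acc = 0.0
        for _ in range(n_meas):
            _advance(pos, params, sub, 0.0, rng, state)
            acc += radius_of_gyration(pos)
        steps_done += n_meas * sub
        rg = acc / n_meas
        if abs(rg - rg_prev) < rg_tol * rg_prev:
            streak += 1
            if streak >= 3:
                out = pos.astype(float)
                return Frame(0.0, out, a2_tensions(out, params))
        else:
            streak = 0
        rg_prev = rg
    raise RuntimeError(f"equilibration did not converge within {max_steps} steps")


def simulate(params: SimParams, replicas: Sequence[int] | None = None) -> list[Trajectory]:
    """Run ``n_replicas`` independent sheared chains from equilibrated globules.

    Each replica equilibrates at zero shear under its own sub-seed, then
    runs ``n_samples * steps_per_sample`` production steps at
    ``shear_rate``, sampling every ``sample_interval``.  Replicas do not
    interact; identical ``(params, seed)`` reproduce bit-identical
    trajectories.
    """
    if params.hi_mode == "pairwise":
        return _simulate_pairwise(params, replicas)
    if replicas is None:
        replicas = range(params.n_replicas)
    out = []
    for rep in replicas:
        try:
            frame0 = equilibrate(params, seed=_sub_seed(params.seed, rep, 0))
            pos = frame0.positions.copy()
            n_steps = params.n_samples * params.steps_per_sample
            rng = np.random.default_rng(
                np.random.SeedSequence([params.seed, rep, 1])
            )
            out_pos, out_ten = _run_kernel(
                pos, params, n_steps, params.steps_per_sample,
                params.shear_rate, rng,
            )
            if not np.all(np.isfinite(out_pos)):
                raise OverExtensionError("non-finite positions")
            times = params.sample_interval * np.arange(1, params.n_samples + 1)
            out.append(Trajectory(times, out_pos, out_ten, params, replica=rep))
        except Exception as exc:
            raise RuntimeError(f"replica {rep} failed: {exc}") from exc
    return out


def _simulate_pairwise(params: SimParams, replicas: Sequence[int] | None) -> list[Trajectory]:
    """Slow reference path stepping bd_step with the RPY mobility."""
    if replicas is None:
        replicas = range(params.n_replicas)
    out = []
    for rep in replicas:
        frame = equilibrate(params, seed=_sub_seed(params.seed, rep, 0))
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, rep, 1]))
        times, poss, tens = [], [], []
        for s in range(params.n_samples):
            for _ in range(params.steps_per_sample):
                frame = bd_step(frame, params, rng)
            times.append(frame.time)
            poss.append(frame.positions)
            tens.append(frame.a2_tensions)
        out.append(Trajectory(np.array(times), np.array(poss), np.array(tens),
                              params, replica=rep))
    return out


def _sub_seed(root: int, replica: int, stage: int) -> int:
    """Deterministic 31-bit sub-seed per (root seed, replica, stage)."""
    ss = np.random.SeedSequence([int(root), int(replica), int(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
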