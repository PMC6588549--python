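"""Numba kernels for the Brownian-dynamics integrator.

Everything here runs in physical units: lengths in nm, forces in pN,
energies in pN*nm, times in s.  The chain topology is fixed by
convention: beads (2i, 2i+1) are joined by the FENE spring of monomer i
(the A2 domain), beads (2i+1, 2i+2) by a stiff harmonic bond (the
inter-monomer disulfide link).  Directly bonded pairs are excluded from
the nonbonded pair potential.

The driver in :mod:`shearfold.simulation` advances the chain in chunks:
Gaussian noise for a whole chunk is drawn by NumPy at C speed and
handed to :func:`advance_chunk`, which integrates one overdamped
Euler-Maruyama step per noise row.  Both bonded interactions are
advanced semi-implicitly by operator splitting over disjoint bead
pairs: the explicit update carries only the nonbonded forces, shear
advection and noise; each harmonic bond then relaxes toward its rest
length in closed form, and each FENE spring's new length is the root of
a cubic in (0, R0), which keeps every spring strictly below its
finite-extensibility limit for any timestep.  A Verlet neighbor list
with half-skin displacement triggering limits the pair loop, and the
repulsive branch of the pair force is capped (soft core) so that hard
collisions cannot overshoot at the working timestep.

State arrays are float32: Brownian position increments (about 1 nm per
step) dwarf single-precision rounding at the coordinate magnitudes this
system reaches, and the narrower state roughly doubles pair-loop
throughput.
"""

import numpy as np
from numba import njit

__all__ = ["advance_chunk", "build_neighbor_list", "fene_force_scalar", "solve_fene_length"]


@njit(cache=True, fastmath=True)
def fene_force_scalar(r, k, r0):
    """FENE restoring force magnitude k*r / (1 - (r/r0)^2), pN."""
    x = r / r0
    return k * r / (1.0 - x * x)


@njit(cache=True, fastmath=True)
def solve_fene_length(d, alpha, r0):
    """Root in [0, r0) of the semi-implicit FENE update.

    Solves  l + alpha * l / (1 - (l/r0)^2) = d  for the new spring
    length l, where d >= 0 is the explicitly updated bead separation and
    alpha = 2*k*dt/zeta is the dimensionless spring parameter.
    Equivalent cubic: l^3 - d*l^2 - (1+alpha)*r0^2*l + d*r0^2 = 0.
    The bracket (0, r0) always contains exactly one root.
    """
    if d <= 0.0:
        return 0.0
    lo = 0.0
    hi = r0
    r02 = r0 * r0
    # good starting guess: ignore the nonlinearity at the explicit length
    u0 = min(d / r0, 0.999)
    l = d / (1.0 + alpha / max(1.0 - u0 * u0, 1e-3))
    if l >= r0:
        l = 0.5 * r0
    for _ in range(60):
        u2 = l * l / r02
        one_m = 1.0 - u2
        f = l * one_m + alpha * l - d * one_m
        if f > 0.0:
            hi = l
        else:
            lo = l
        df = one_m + alpha - 2.0 * l * (l - d) / r02
        if df > 0.0:
            ln = l - f / df
            if ln <= lo or ln >= hi:
                ln = 0.5 * (lo + hi)
        else:
            ln = 0.5 * (lo + hi)
        if abs(ln - l) < 1e-10 * r0:
            return ln
        l = ln
    return l


@njit(cache=True, fastmath=True)
def build_neighbor_list(pos, list_cut2, pairs, n_beads):
    """Candidate LJ pairs within cutoff+skin, excluding bonded neighbors."""
    n_pairs = 0
    for i in range(n_beads):
        for j in range(i + 2, n_beads):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < list_cut2:
                pairs[n_pairs, 0] = i
                pairs[n_pairs, 1] = j
                n_pairs += 1
    return n_pairs


@njit(cache=True, fastmath=True)
def _lj_forces(pos, forces, eps, sigma, rcut2, fcap, pairs, n_pairs):
    """Truncated LJ pair forces over the neighbor list (bonded terms split off).

    All arithmetic in float32 — mixing in double constants forces
    conversions in the hot loop.
    """
    forces[:] = np.float32(0.0)
    sig2 = np.float32(sigma * sigma)
    c24 = np.float32(24.0) * np.float32(eps)
    two = np.float32(2.0)
    one = np.float32(1.0)
    zero = np.float32(0.0)
    fcap2 = np.float32(fcap * fcap)
    fcap32 = np.float32(fcap)
    rc2 = np.float32(rcut2)
    rmin2 = np.float32(1e-6)
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2 and r2 > rmin2:
            inv = one / r2
            s2 = sig2 * inv
            s6 = s2 * s2 * s2
            # dU/dr / r with U = 4 eps (s^12 - s^6); positive => repulsive
            fr = c24 * (two * s6 * s6 - s6) * inv
            # soft-core cap on the repulsive branch (numerical regularization)
            if fr > zero and fr * fr * r2 > fcap2:
                fr = fcap32 / np.sqrt(r2)
            forces[i, 0] -= fr * dx
            forces[i, 1] -= fr * dy
            forces[i, 2] -= fr * dz
            forces[j, 0] += fr * dx
            forces[j, 1] += fr * dy
            forces[j, 2] += fr * dz
    return forces


@njit(cache=True, fastmath=True)
def advance_chunk(
    pos,
    noise,
    dt,
    zeta,
    kbt,
    shear_rate,
    fene_k,
    fene_r0,
    harm_k,
    harm_r0,
    eps,
    sigma,
    rcut,
    fcap,
    skin,
    lj_every,
    pairs,
    ref_pos,
    n_pairs_state,
    sample_every,
    out_pos,
    out_ten,
):
    """Advance one timestep per row of ``noise`` (n_steps, N, 3), in place.

    ``pairs``, ``ref_pos`` and the two-element ``n_pairs_state`` carry
    the Verlet list between chunks.  ``pos``, ``noise``, ``ref_pos``
    are float32.  When ``sample_every`` is positive, positions and FENE
    tensions are recorded into ``out_pos`` / ``out_ten`` after every
    ``sample_every``-th step (the chunk length must then be a multiple
    of ``sample_every``).  Returns the number of samples written.
    """
    n_steps = noise.shape[0]
    n_beads = pos.shape[0]
    n_springs = n_beads // 2
    n_written = 0
    forces = np.zeros((n_beads, 3), dtype=np.float32)
    noise_amp = np.float32(np.sqrt(2.0 * (kbt / zeta) * dt))
    alpha = 2.0 * fene_k * dt / zeta
    beta = 2.0 * harm_k * dt / zeta
    beta_r0 = np.float32(beta * harm_r0)
    harm_relax = np.float32(1.0 / (1.0 + beta))
    mob_dt = np.float32(dt / zeta)
    adv = np.float32(dt * shear_rate)
    r_list = rcut + skin
    list_cut2 = np.float32(r_list * r_list)
    rcut2 = np.float32(rcut * rcut)
    for step in range(n_steps):
        # The soft nonbonded forces vary little over one timestep, so
        # they are recomputed only every lj_every steps (multiple
        # time-stepping); bonded terms, advection and noise advance
        # every step.
        if step % lj_every == 0:
            # Rebuild check in the shear-co-advected frame.  A pair's
            # separation can change by at most 2*max_dev (diffusion and
            # forces) plus gamma*t*(r_list + 2*max_dev) (differential
            # advection of pairs close enough in z to ever interact),
            # so the list stays valid while that bound is below the
            # skin.
            moved = np.float32(0.0)
            strain = adv * np.float32(n_pairs_state[1])
            for i in range(n_beads):
                ddx = pos[i, 0] - ref_pos[i, 0] - strain * ref_pos[i, 2]
                ddy = pos[i, 1] - ref_pos[i, 1]
                ddz = pos[i, 2] - ref_pos[i, 2]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 > moved:
                    moved = d2
            dev = np.sqrt(moved)
            if n_pairs_state[1] == 0 or 2.0 * dev + strain * (r_list + 2.0 * dev) > skin:
                ref_pos[:] = pos
                n_pairs_state[0] = build_neighbor_list(pos, list_cut2, pairs, n_beads)
                n_pairs_state[1] = 0
            _lj_forces(pos, forces, eps, sigma, rcut2, fcap, pairs, n_pairs_state[0])
        n_pairs_state[1] += 1
        for i in range(n_beads):
            pos[i, 0] += mob_dt * forces[i, 0] + adv * pos[i, 2] + noise_amp * noise[step, i, 0]
            pos[i, 1] += mob_dt * forces[i, 1] + noise_amp * noise[step, i, 1]
            pos[i, 2] += mob_dt * forces[i, 2] + noise_amp * noise[step, i, 2]
        # implicit harmonic bonds (2i+1, 2i+2): relax toward rest length
        for b in range(1, n_beads - 1, 2):
            dx = pos[b + 1, 0] - pos[b, 0]
            dy = pos[b + 1, 1] - pos[b, 1]
            dz = pos[b + 1, 2] - pos[b, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > 1e-6:
                l = (d + beta_r0) * harm_relax
                shrink = np.float32(0.5) * (np.float32(1.0) - np.float32(l) / d)
                pos[b, 0] += shrink * dx
                pos[b, 1] += shrink * dy
                pos[b, 2] += shrink * dz
                pos[b + 1, 0] -= shrink * dx
                pos[b + 1, 1] -= shrink * dy
                pos[b + 1, 2] -= shrink * dz
        # implicit FENE springs (2i, 2i+1)
        for s in range(n_springs):
            p = 2 * s
            q = p + 1
            dx = pos[q, 0] - pos[p, 0]
            dy = pos[q, 1] - pos[p, 1]
            dz = pos[q, 2] - pos[p, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > 1e-6:
                l = solve_fene_length(np.float64(d), alpha, fene_r0)
                # keep strictly inside R0 after the float32 round-trip
                if l > 0.999999 * fene_r0:
                    l = 0.999999 * fene_r0
                shrink = np.float32(0.5) * (np.float32(1.0) - np.float32(l) / d)
                pos[p, 0] += shrink * dx
                pos[p, 1] += shrink * dy
                pos[p, 2] += shrink * dz
                pos[q, 0] -= shrink * dx
                pos[q, 1] -= shrink * dy
                pos[q, 2] -= shrink * dz
        if sample_every > 0 and (step + 1) % sample_every == 0:
            k = n_written
            for i in range(n_beads):
                out_pos[k, i, 0] = pos[i, 0]
                out_pos[k, i, 1] = pos[i, 1]
                out_pos[k, i, 2] = pos[i, 2]
            for s in range(n_springs):
                p = 2 * s
                q = p + 1
                dx = pos[q, 0] - pos[p, 0]
                dy = pos[q, 1] - pos[p, 1]
                dz = pos[q, 2] - pos[p, 2]
                r = np.float64(np.sqrt(dx * dx + dy * dy + dz * dz))
                out_ten[k, s] = fene_force_scalar(r, fene_k, fene_r0)
            n_written += 1
    return n_written
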