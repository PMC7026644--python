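"""Numba kernels for Metropolis Monte Carlo over pair sets.

Each step draws one candidate position pair uniformly from the fixed set
of geometric candidates (j - i - 1 >= min_loop, any base combination).  If
the candidate is currently a pair the move destroys it; if both bases are
free the move creates it; otherwise the step is a no-op.  Destruction and
creation of any given pair are proposed with the same probability, so the
plain Metropolis acceptance exp(-dE/T) satisfies detailed balance and a
fixed-temperature chain (``sample_kernel``) samples the exact Boltzmann
distribution of the energy function.

``anneal_kernel`` runs the same chain under a geometric cooling schedule
and returns the lowest-energy state visited (annealing elitism): near-
degenerate minima keep exchanging at the final temperature, so the best
state seen, not the last, is the search result.

Energy bookkeeping is incremental: a move changes only the local terms of
the touched pair and its two diagonal neighbors, so every step is O(1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# mirrors energy.pair_local_energy; kept in lockstep by tests


@njit(cache=True, inline="always")
def _local_term(partner, seq, pt_table, stack, i0, au_end, lone_pen, nc_pen, rest):
    j0 = partner[i0]
    L = partner.shape[0]
    t = pt_table[seq[i0], seq[j0]]
    e = 0.0
    inner = i0 + 1 < L and j0 - 1 >= 0 and partner[i0 + 1] == j0 - 1
    outer = i0 - 1 >= 0 and j0 + 1 < L and partner[i0 - 1] == j0 + 1
    if t == -1:
        e += nc_pen
    else:
        if inner:
            t_in = pt_table[seq[i0 + 1], seq[j0 - 1]]
            if t_in != -1:
                e += stack[t, t_in]
        if (t == 0 or t == 3 or t == 4 or t == 5) and not (inner and outer):
            e += au_end
    if not inner and not outer:
        e += lone_pen
    e -= rest[i0, j0]
    return e


@njit(cache=True)
def total_energy(partner, seq, pt_table, stack, au_end, lone_pen, nc_pen, rest):
    e = 0.0
    for i0 in range(partner.shape[0]):
        if partner[i0] > i0:
            e += _local_term(partner, seq, pt_table, stack, i0, au_end, lone_pen, nc_pen, rest)
    return e


@njit(cache=True, inline="always")
def _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest):
    """Local terms of (a,b) if currently paired plus its diagonal neighbors."""
    L = partner.shape[0]
    e = 0.0
    if partner[a] == b:
        e += _local_term(partner, seq, pt_table, stack, a, au_end, lone_pen, nc_pen, rest)
    if a - 1 >= 0 and b + 1 < L and partner[a - 1] == b + 1:
        e += _local_term(partner, seq, pt_table, stack, a - 1, au_end, lone_pen, nc_pen, rest)
    if a + 1 < L and b - 1 >= 0 and partner[a + 1] == b - 1:
        e += _local_term(partner, seq, pt_table, stack, a + 1, au_end, lone_pen, nc_pen, rest)
    return e


@njit(cache=True, inline="always")
def _metropolis_step(partner, seq, pt_table, stack, au_end, lone_pen, nc_pen, rest, min_loop, t):
    """One candidate draw plus Metropolis accept/reject.  Returns 0 (no-op),
    +1 (pair added) or -1 (pair removed)."""
    L = partner.shape[0]
    # uniform candidate with j - i - 1 >= min_loop, by rejection
    while True:
        a = int(np.random.random() * L)
        b = int(np.random.random() * L)
        if a > b:
            a, b = b, a
        if b - a > min_loop:
            break
    if partner[a] == b:
        # destruction move
        e_before = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        partner[a] = -1
        partner[b] = -1
        e_after = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        d_e = e_after - e_before
        if d_e <= 0.0 or np.random.random() < np.exp(-d_e / t):
            return -1
        partner[a] = b
        partner[b] = a
        return 0
    elif partner[a] == -1 and partner[b] == -1:
        # creation move
        e_before = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        partner[a] = b
        partner[b] = a
        e_after = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        d_e = e_after - e_before
        if d_e <= 0.0 or np.random.random() < np.exp(-d_e / t):
            return 1
        partner[a] = -1
        partner[b] = -1
        return 0
    return 0


@njit(cache=True, inline="always")
def _metropolis_step_tracked(
    partner, seq, pt_table, stack, au_end, lone_pen, nc_pen, rest, min_loop, t
):
    """One symmetric-candidate Metropolis step; returns the energy change
    of the committed move (0.0 for rejections and no-ops)."""
    L = partner.shape[0]
    while True:
        a = int(np.random.random() * L)
        b = int(np.random.random() * L)
        if a > b:
            a, b = b, a
        if b - a > min_loop:
            break
    if partner[a] == b:
        e_before = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        partner[a] = -1
        partner[b] = -1
        e_after = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        d_e = e_after - e_before
        if d_e <= 0.0 or np.random.random() < np.exp(-d_e / t):
            return d_e
        partner[a] = b
        partner[b] = a
        return 0.0
    elif partner[a] == -1 and partner[b] == -1:
        e_before = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        partner[a] = b
        partner[b] = a
        e_after = _affected_energy(partner, seq, pt_table, stack, a, b, au_end, lone_pen, nc_pen, rest)
        d_e = e_after - e_before
        if d_e <= 0.0 or np.random.random() < np.exp(-d_e / t):
            return d_e
        partner[a] = -1
        partner[b] = -1
        return 0.0
    return 0.0


@njit(cache=True)
def anneal_kernel(
    seq,
    pt_table,
    stack,
    au_end,
    lone_pen,
    nc_pen,
    rest,
    min_loop,
    t0,
    cooling,
    t_end,
    steps_per_t,
    seed,
    partner_init,
):
    """Simulated annealing from ``partner_init``; returns the lowest-energy
    partner array visited.  Fully deterministic given ``seed``."""
    np.random.seed(seed)
    partner = partner_init.copy()
    e_cur = total_energy(partner, seq, pt_table, stack, au_end, lone_pen, nc_pen, rest)
    e_best = e_cur
    best = partner.copy()
    t = t0
    while t >= t_end:
        for _ in range(steps_per_t):
            e_cur += _metropolis_step_tracked(
                partner, seq, pt_table, stack, au_end, lone_pen, nc_pen, rest, min_loop, t
            )
            if e_cur < e_best - 1e-12:
                e_best = e_cur
                best[:] = partner
        # resynchronize the incremental energy against float drift
        e_cur = total_energy(partner, seq, pt_table, stack, au_end, lone_pen, nc_pen, rest)
        t *= cooling
    return best


@njit(cache=True)
def sample_kernel(
    seq,
    pt_table,
    stack,
    au_end,
    lone_pen,
    nc_pen,
    rest,
    min_loop,
    temperature,
    n_steps,
    record_every,
    seed,
):
    """Fixed-temperature chain recording pair occupancy; returns an LxL
    matrix of occupancy counts and the number of samples taken.  Used for
    equilibrium (detailed-balance) checks."""
    np.random.seed(seed)
    L = seq.shape[0]
    partner = np.full(L, -1, dtype=np.int64)
    occupancy = np.zeros((L, L), dtype=np.float64)
    n_samples = 0
    for step in range(n_steps):
        _metropolis_step(
            partner, seq, pt_table, stack, au_end, lone_pen, nc_pen, rest, min_loop, temperature
        )
        if step % record_every == record_every - 1:
            n_samples += 1
            for i0 in range(L):
                j0 = partner[i0]
                if j0 > i0:
                    occupancy[i0, j0] += 1.0
    return occupancy, n_samples
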