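"""Compiled core of the spatial stochastic simulation.

Direct-method SSA over the chamber lattice: every chamber carries the
total propensity of its local reaction channels plus the diffusion
propensity of the molecules it holds; chambers are sampled through a
binary sum tree, the channel within a chamber by linear scan.  Chamber
totals are updated incrementally from per-species propensity deltas
(with a periodic full rebuild to cancel floating-point drift), which is
what makes multi-billion-event runs affordable.  Hops move one molecule
to one of the four nearest neighbours (periodic in x/y);
cluster-confined species only hop between chambers carrying the same
mask label.  The scheduler is statistically exact (equivalent in
distribution to next-reaction variants).

Status codes returned by :func:`run_ssa`: 0 ok, 1 negative count
(internal inconsistency), 2 event budget exceeded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NEGATIVE = 1
STATUS_BUDGET = 2


@njit(cache=True, inline="always")
def _next_u64(state):
    # xorshift128+ step; state is a 2-element uint64 array
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _uniform(state):
    # float64 in [0, 1)
    return (_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _seed_state(seed):
    # splitmix64 expansion of a single integer seed
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z += np.uint64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = x ^ (x >> np.uint64(31))
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _chamber_propensity(j, counts, hop_dir_rate, conf, ndirs, r1, r2, kprop):
    total = 0.0
    n_sp = counts.shape[1]
    for s in range(n_sp):
        c = counts[j, s]
        if c > 0 and hop_dir_rate[s] > 0.0:
            total += c * hop_dir_rate[s] * ndirs[conf[s], j]
    for rr in range(r1.shape[0]):
        c1 = counts[j, r1[rr]]
        if c1 > 0:
            if r2[rr] >= 0:
                if r2[rr] == r1[rr]:
                    total += kprop[rr] * c1 * (c1 - 1)
                else:
                    total += kprop[rr] * c1 * counts[j, r2[rr]]
            else:
                total += kprop[rr] * c1
    return total


@njit(cache=True)
def _rebuild_tree(counts, hop_dir_rate, conf, ndirs, r1, r2, kprop,
                  ctot, tree, P):
    n_ch = counts.shape[0]
    for i in range(2 * P):
        tree[i] = 0.0
    for j in range(n_ch):
        ctot[j] = _chamber_propensity(j, counts, hop_dir_rate, conf, ndirs,
                                      r1, r2, kprop)
        tree[P + j] = ctot[j]
    for i in range(P - 1, 0, -1):
        tree[i] = tree[2 * i] + tree[2 * i + 1]


@njit(cache=True, inline="always")
def _update_leaf(tree, P, j, val):
    tree[P + j] = val
    node = (P + j) >> 1
    while node >= 1:
        tree[node] = tree[2 * node] + tree[2 * node + 1]
        node >>= 1


@njit(cache=True, inline="always")
def _apply_change(j, s, dc, counts, hop_dir_rate, conf, ndirs,
                  r1, r2, kprop, rxs_ptr, rxs_idx):
    """Change counts[j, s] by dc and return the propensity delta of
    chamber j.  Must be called one species change at a time."""
    c_old = counts[j, s]
    c_new = c_old + dc
    d = dc * hop_dir_rate[s] * ndirs[conf[s], j]
    for ii in range(rxs_ptr[s], rxs_ptr[s + 1]):
        rr = rxs_idx[ii]
        if r1[rr] == r2[rr]:
            d += kprop[rr] * (c_new * (c_new - 1) - c_old * (c_old - 1))
        else:
            other = r2[rr] if r1[rr] == s else r1[rr]
            if other >= 0:
                d += kprop[rr] * dc * counts[j, other]
            else:
                d += kprop[rr] * dc
    counts[j, s] = c_new
    return d


@njit(cache=True)
def run_ssa(counts, neighbors, ndirs, allowmask, conf, hop_dir_rate,
            r1, r2, kprop, nprod, prods, rxs_ptr, rxs_idx,
            sample_times, seed, totals_out, grids_out, record_grid,
            max_events):
    n_ch, n_sp = counts.shape
    n_rx = r1.shape[0]
    n_samp = sample_times.shape[0]
    t_end = sample_times[n_samp - 1]

    rng = _seed_state(seed)
    P = 1
    while P < n_ch:
        P <<= 1
    tree = np.zeros(2 * P)
    ctot = np.zeros(n_ch)
    _rebuild_tree(counts, hop_dir_rate, conf, ndirs, r1, r2, kprop,
                  ctot, tree, P)

    totals = np.zeros(n_sp, dtype=np.int64)
    for j in range(n_ch):
        for s in range(n_sp):
            totals[s] += counts[j, s]

    t = 0.0
    si = 0
    n_events = np.int64(0)
    while si < n_samp:
        R = tree[1]
        if R <= 1e-300:
            t_next = t_end + 1.0
        else:
            u = _uniform(rng)
            t_next = t + (-np.log(1.0 - u)) / R
        while si < n_samp and sample_times[si] <= t_next:
            for s in range(n_sp):
                totals_out[si, s] = totals[s]
            if record_grid:
                for j in range(n_ch):
                    for s in range(n_sp):
                        grids_out[si, j, s] = counts[j, s]
            si += 1
        if si >= n_samp or t_next > t_end:
            break
        t = t_next
        if n_events >= max_events:
            return STATUS_BUDGET, n_events
        n_events += 1
        if (n_events & np.int64(0xFFFFF)) == 0:
            _rebuild_tree(counts, hop_dir_rate, conf, ndirs, r1, r2, kprop,
                          ctot, tree, P)

        # ---- select chamber ------------------------------------------
        target = _uniform(rng) * tree[1]
        node = 1
        while node < P:
            node <<= 1
            if target >= tree[node]:
                target -= tree[node]
                node += 1
        j = node - P
        if j >= n_ch:
            j = n_ch - 1

        # ---- select channel within chamber ---------------------------
        target = _uniform(rng) * ctot[j]
        acc = 0.0
        chosen_sp = -1
        chosen_rx = -1
        for s in range(n_sp):
            c = counts[j, s]
            if c > 0 and hop_dir_rate[s] > 0.0:
                acc += c * hop_dir_rate[s] * ndirs[conf[s], j]
                if acc > target:
                    chosen_sp = s
                    break
        if chosen_sp < 0:
            for rr in range(n_rx):
                c1 = counts[j, r1[rr]]
                if c1 > 0:
                    if r2[rr] >= 0:
                        if r2[rr] == r1[rr]:
                            acc += kprop[rr] * c1 * (c1 - 1)
                        else:
                            acc += kprop[rr] * c1 * counts[j, r2[rr]]
                    else:
                        acc += kprop[rr] * c1
                    if acc > target:
                        chosen_rx = rr
                        break

        if chosen_sp >= 0:
            # ---- diffusion hop ---------------------------------------
            cc = conf[chosen_sp]
            nd = ndirs[cc, j]
            if nd == 0:
                ctot[j] = _chamber_propensity(j, counts, hop_dir_rate, conf,
                                              ndirs, r1, r2, kprop)
                _update_leaf(tree, P, j, ctot[j])
                continue
            pick = int(_uniform(rng) * nd)
            if pick >= nd:
                pick = nd - 1
            d = 0
            seen = 0
            for dd in range(4):
                if allowmask[cc, j, dd]:
                    if seen == pick:
                        d = dd
                        break
                    seen += 1
            j2 = neighbors[j, d]
            if counts[j, chosen_sp] <= 0:
                return STATUS_NEGATIVE, n_events
            ctot[j] += _apply_change(j, chosen_sp, -1, counts, hop_dir_rate,
                                     conf, ndirs, r1, r2, kprop,
                                     rxs_ptr, rxs_idx)
            ctot[j2] += _apply_change(j2, chosen_sp, 1, counts, hop_dir_rate,
                                      conf, ndirs, r1, r2, kprop,
                                      rxs_ptr, rxs_idx)
            _update_leaf(tree, P, j, ctot[j])
            _update_leaf(tree, P, j2, ctot[j2])
        elif chosen_rx >= 0:
            # ---- reaction --------------------------------------------
            rr = chosen_rx
            if counts[j, r1[rr]] <= 0 or (r2[rr] >= 0 and counts[j, r2[rr]] <= 0):
                return STATUS_NEGATIVE, n_events
            dtot = _apply_change(j, r1[rr], -1, counts, hop_dir_rate, conf,
                                 ndirs, r1, r2, kprop, rxs_ptr, rxs_idx)
            totals[r1[rr]] -= 1
            if r2[rr] >= 0:
                dtot += _apply_change(j, r2[rr], -1, counts, hop_dir_rate,
                                      conf, ndirs, r1, r2, kprop,
                                      rxs_ptr, rxs_idx)
                totals[r2[rr]] -= 1
            for p in range(nprod[rr]):
                dtot += _apply_change(j, prods[rr, p], 1, counts, hop_dir_rate,
                                      conf, ndirs, r1, r2, kprop,
                                      rxs_ptr, rxs_idx)
                totals[prods[rr, p]] += 1
            ctot[j] += dtot
            _update_leaf(tree, P, j, ctot[j])
        else:
            # numerical drift: refresh this chamber and carry on
            ctot[j] = _chamber_propensity(j, counts, hop_dir_rate, conf,
                                          ndirs, r1, r2, kprop)
            _update_leaf(tree, P, j, ctot[j])

    return STATUS_OK, n_events
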