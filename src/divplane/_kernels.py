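"""Numba kernels for the lattice Metropolis dynamics.

The 3D kernel runs single-site toggle dynamics (non-conserved labels, the
volume-ratio enforced by an energy term); the 2D kernel runs Kawasaki-type
site exchanges (label counts exactly conserved, interface term only).
Adjacency between occupied sites is passed in CSR form so the hot loop
never touches the full grid.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _hv(v1, n_sites, v1_target, v2_target):
    d1 = v1 - v1_target
    d2 = (n_sites - v1) - v2_target
    return (d1 * d1 + d2 * d2) ** (1.0 / 3.0)


@numba.njit(cache=True)
def _hv_table(n_sites, v1_target, v2_target):
    table = np.empty(n_sites + 1, dtype=np.float64)
    for v1 in range(n_sites + 1):
        table[v1] = _hv(v1, n_sites, v1_target, v2_target)
    return table


@numba.njit(cache=True)
def discordant_pairs(labels, nbr_ptr, nbr_idx):
    """Number of unordered neighbor pairs with different labels."""
    count = 0
    for i in range(labels.size):
        li = labels[i]
        for p in range(nbr_ptr[i], nbr_ptr[i + 1]):
            j = nbr_idx[p]
            if j > i and labels[j] != li:
                count += 1
    return count


@numba.njit(cache=True)
def metropolis_toggle(
    labels,
    nbr_ptr,
    nbr_idx,
    v1_target,
    v2_target,
    alpha_a2,
    kT,
    n_cycles,
    seed,
    early_stop,
    stop_window,
    stop_rtol,
):
    """Single-site toggle Metropolis minimization of H = H_V + H_A.

    ``labels`` (int8, values 1/2 per occupied site) is modified in place.
    Returns (v1, boundary_pair_count, per-cycle energy trace, cycles_run).
    """
    np.random.seed(seed)
    n = labels.size
    v1 = 0
    for i in range(n):
        if labels[i] == 1:
            v1 += 1
    hv = _hv_table(n, v1_target, v2_target)
    bpairs = discordant_pairs(labels, nbr_ptr, nbr_idx)
    trace = np.empty(n_cycles, dtype=np.float64)
    prev_avg = np.inf
    cycles_run = n_cycles
    inv_kT = 1.0 / kT
    # moves costing more than 20 kT have acceptance < 3e-9: reject
    # without spending an exp() and a uniform draw
    reject_cut = 20.0 * kT
    for cycle in range(n_cycles):
        for _ in range(n):
            i = int(np.random.random() * n)
            li = labels[i]
            m = nbr_ptr[i + 1] - nbr_ptr[i]
            d = 0
            for p in range(nbr_ptr[i], nbr_ptr[i + 1]):
                if labels[nbr_idx[p]] != li:
                    d += 1
            dv1 = -1 if li == 1 else 1
            dH = alpha_a2 * (m - 2 * d) + hv[v1 + dv1] - hv[v1]
            if dH > reject_cut:
                continue
            if dH <= 0.0 or np.random.random() < np.exp(-dH * inv_kT):
                labels[i] = 3 - li
                v1 += dv1
                bpairs += m - 2 * d
        trace[cycle] = hv[v1] + alpha_a2 * bpairs
        if early_stop and (cycle + 1) % stop_window == 0:
            avg = 0.0
            for c in range(cycle + 1 - stop_window, cycle + 1):
                avg += trace[c]
            avg /= stop_window
            if np.abs(avg - prev_avg) <= stop_rtol * max(np.abs(prev_avg), 1e-12):
                cycles_run = cycle + 1
                break
            prev_avg = avg
    return v1, bpairs, trace[:cycles_run], cycles_run


@numba.njit(cache=True, inline="always")
def _local_discordant(labels, nbr_ptr, nbr_idx, i):
    li = labels[i]
    m = 0
    d = 0
    for p in range(nbr_ptr[i], nbr_ptr[i + 1]):
        m += 1
        if labels[nbr_idx[p]] != li:
            d += 1
    return m, d


@numba.njit(cache=True)
def metropolis_exchange(
    labels,
    nbr_ptr,
    nbr_idx,
    alpha_a2,
    kT,
    n_cycles,
    seed,
):
    """Kawasaki exchange dynamics minimizing the interface term only.

    Each move swaps the labels of one site drawn from each daughter, so the
    label counts never change. Returns (boundary_pair_count, trace).
    """
    np.random.seed(seed)
    n = labels.size
    # index lists per label, with positions for O(1) membership swaps
    v1 = 0
    for i in range(n):
        if labels[i] == 1:
            v1 += 1
    sites1 = np.empty(v1, dtype=np.int64)
    sites2 = np.empty(n - v1, dtype=np.int64)
    pos = np.empty(n, dtype=np.int64)
    c1 = 0
    c2 = 0
    for i in range(n):
        if labels[i] == 1:
            sites1[c1] = i
            pos[i] = c1
            c1 += 1
        else:
            sites2[c2] = i
            pos[i] = c2
            c2 += 1
    bpairs = discordant_pairs(labels, nbr_ptr, nbr_idx)
    trace = np.empty(n_cycles, dtype=np.float64)
    for cycle in range(n_cycles):
        for _ in range(n):
            a = sites1[np.random.randint(0, sites1.size)]
            b = sites2[np.random.randint(0, sites2.size)]
            # sequential local deltas: toggle a, then b; their sum is the
            # exact total energy change even when a and b are adjacent
            ma, da = _local_discordant(labels, nbr_ptr, nbr_idx, a)
            delta_a = ma - 2 * da
            labels[a] = 2
            mb, db = _local_discordant(labels, nbr_ptr, nbr_idx, b)
            delta_b = mb - 2 * db
            dH = alpha_a2 * (delta_a + delta_b)
            if dH <= 0.0 or np.random.random() < np.exp(-dH / kT):
                labels[b] = 1
                bpairs += delta_a + delta_b
                # swap membership
                pa, pb = pos[a], pos[b]
                sites1[pa] = b
                sites2[pb] = a
                pos[b] = pa
                pos[a] = pb
            else:
                labels[a] = 1  # revert
        trace[cycle] = alpha_a2 * bpairs
    return bpairs, trace


def build_adjacency(occupancy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CSR adjacency of occupied sites under full (26- or 8-) connectivity.

    Returns (site_indices, nbr_ptr, nbr_idx) where ``site_indices`` is the
    (n_sites, ndim) array of grid indices in enumeration order and
    ``nbr_idx[nbr_ptr[i]:nbr_ptr[i+1]]`` lists the occupied neighbors of
    site i as positions into that enumeration.
    """
    occ = np.asarray(occupancy, dtype=bool)
    ndim = occ.ndim
    site_indices = np.argwhere(occ)
    n = site_indices.shape[0]
    site_id = -np.ones(occ.shape, dtype=np.int64)
    site_id[occ] = np.arange(n)
    offsets = _full_connectivity_offsets(ndim)
    padded_id = np.pad(site_id, 1, constant_values=-1)
    nbr_lists = []
    counts = np.zeros(n, dtype=np.int64)
    shifted = np.empty((len(offsets), n), dtype=np.int64)
    base = site_indices + 1
    for k, off in enumerate(offsets):
        pts = base + off
        shifted[k] = padded_id[tuple(pts.T)]
    counts = (shifted >= 0).sum(axis=0)
    nbr_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=nbr_ptr[1:])
    nbr_idx = np.empty(nbr_ptr[-1], dtype=np.int32)
    fill = nbr_ptr[:-1].copy()
    for k in range(len(offsets)):
        row = shifted[k]
        ok = row >= 0
        idx = np.nonzero(ok)[0]
        nbr_idx[fill[idx]] = row[idx]
        fill[idx] += 1
    return site_indices, nbr_ptr, nbr_idx


def _full_connectivity_offsets(ndim: int) -> np.ndarray:
    grids = np.meshgrid(*([[-1, 0, 1]] * ndim), indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    return offs[np.any(offs != 0, axis=1)]
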