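"""Numba kernels for the Monte Carlo sweep and boundary scans.

The sweep kernel mirrors :func:`luadmorph.energy.delta_hamiltonian`
exactly; the pure-Python path is the bookkeeping oracle in the tests.
Randomness comes from an explicit xorshift128+ state so that runs are
bit-reproducible from the seed alone, independent of numpy's global
state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64


@njit(cache=True, inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << _U64(23)
    s1 ^= s1 >> _U64(17)
    s1 ^= s0
    s1 ^= s0 >> _U64(26)
    state[1] = s1
    return state[0] + state[1]


@njit(cache=True, inline="always")
def _next_double(state):
    return (_next_u64(state) >> _U64(11)) * (1.0 / 9007199254740992.0)


def seed_state(seed: int) -> np.ndarray:
    """Expand an integer seed into an xorshift128+ state (splitmix64)."""
    mask = (1 << 64) - 1
    state = np.empty(2, dtype=np.uint64)
    x = (int(seed) + 0x9E3779B97F4A7C15) & mask
    for i in range(2):
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        state[i] = (z ^ (z >> 31)) & mask
        x = (x + 0x9E3779B97F4A7C15) & mask
    if state[0] == 0 and state[1] == 0:
        state[0] = _U64(1)
    return state


@njit(cache=True, inline="always")
def _pair_energy(a_id, b_id, comp_cluster, comp_label, j_ext, j_int):
    if a_id == b_id:
        return 0.0
    la = comp_label[a_id]
    lb = comp_label[b_id]
    if comp_cluster[a_id] == comp_cluster[b_id]:
        return j_int[la, lb]
    return j_ext[la, lb]


@njit(cache=True, inline="always")
def _local_split_guard(site_map, comp_cluster, r, c, t_id, h, w, periodic):
    """True if removing site (r, c) from compartment ``t_id`` would locally
    disconnect it.  Walks the 8-ring around the site and counts runs of
    same-compartment members under 8-connectivity of the remainder."""
    ring_r = (-1, -1, -1, 0, 1, 1, 1, 0)
    ring_c = (-1, 0, 1, 1, 1, 0, -1, -1)
    member = np.zeros(8, dtype=np.uint8)
    n_member = 0
    for k in range(8):
        rr = r + ring_r[k]
        cc = c + ring_c[k]
        if periodic:
            rr = rr % h
            cc = cc % w
        elif rr < 0 or rr >= h or cc < 0 or cc >= w:
            continue
        if site_map[rr, cc] == t_id:
            member[k] = 1
            n_member += 1
    if n_member == 0:
        return False  # last local pixel: removal cannot split anything here
    # count transitions non-member -> member around the ring; one run of
    # members means the local remainder stays connected
    runs = 0
    for k in range(8):
        prev = member[(k + 7) % 8]
        if member[k] == 1 and prev == 0:
            runs += 1
    if runs != 1:
        return True
    # a run that spans a diagonal-only corner can still break 4-connectivity;
    # accept the cheap approximation: diagonal-linked runs count as connected
    return False


@njit(cache=True)
def run_sweep(
    site_map,
    comp_cluster,
    comp_label,
    comp_volume,
    comp_target,
    comp_lambda,
    j_ext,
    j_int,
    offsets,
    temperature,
    n_attempts,
    state,
    periodic,
    connectivity_guard,
):
    """One batch of copy attempts; mutates site_map/volumes in place.

    Returns (attempts, accepted, summed dH of accepted copies) -- the
    last lets callers check the incremental energy bookkeeping against a
    full recomputation.
    """
    h, w = site_map.shape
    n_off = offsets.shape[0]
    accepted = 0
    dh_total = 0.0
    for _ in range(n_attempts):
        u = _next_u64(state)
        idx = u % _U64(h * w)
        r = int(idx // _U64(w))
        c = int(idx % _U64(w))
        k = int(_next_u64(state) % _U64(n_off))
        nr = r + int(offsets[k, 0])
        nc = c + int(offsets[k, 1])
        if periodic:
            nr = nr % h
            nc = nc % w
        elif nr < 0 or nr >= h or nc < 0 or nc >= w:
            continue  # counted as a rejected attempt
        s_id = site_map[nr, nc]  # source: random neighbor
        t_id = site_map[r, c]  # target: picked site, to be overwritten
        if s_id == t_id:
            continue
        if connectivity_guard and t_id != 0:
            if _local_split_guard(
                site_map, comp_cluster, r, c, t_id, h, w, periodic
            ):
                continue
        d_h = 0.0
        for m in range(n_off):
            mr = r + int(offsets[m, 0])
            mc = c + int(offsets[m, 1])
            if periodic:
                mr = mr % h
                mc = mc % w
            elif mr < 0 or mr >= h or mc < 0 or mc >= w:
                continue
            n_id = site_map[mr, mc]
            d_h += _pair_energy(
                s_id, n_id, comp_cluster, comp_label, j_ext, j_int
            ) - _pair_energy(t_id, n_id, comp_cluster, comp_label, j_ext, j_int)
        lam_t = comp_lambda[t_id]
        if lam_t != 0.0:
            dv = comp_volume[t_id] - comp_target[t_id]
            d_h += lam_t * (-2.0 * dv + 1.0)
        lam_s = comp_lambda[s_id]
        if lam_s != 0.0:
            dv = comp_volume[s_id] - comp_target[s_id]
            d_h += lam_s * (2.0 * dv + 1.0)
        if d_h <= 0.0 or _next_double(state) < np.exp(-d_h / temperature):
            site_map[r, c] = s_id
            comp_volume[t_id] -= 1
            comp_volume[s_id] += 1
            accepted += 1
            dh_total += d_h
    return n_attempts, accepted, dh_total


@njit(cache=True)
def comp_contact_counts(site_map, comp_cluster, comp_label, offsets, n_comps, n_labels, periodic):
    """Per-compartment boundary-pair counts toward each contact label,
    counting only pairs that cross a cluster boundary."""
    h, w = site_map.shape
    out = np.zeros((n_comps, n_labels), dtype=np.int64)
    n_off = offsets.shape[0]
    for r in range(h):
        for c in range(w):
            a = site_map[r, c]
            ca = comp_cluster[a]
            for m in range(n_off):
                rr = r + int(offsets[m, 0])
                cc = c + int(offsets[m, 1])
                if periodic:
                    rr = rr % h
                    cc = cc % w
                elif rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                b = site_map[rr, cc]
                if b != a and comp_cluster[b] != ca:
                    out[a, comp_label[b]] += 1
    return out


@njit(cache=True)
def cluster_boundary_counts(site_map, comp_cluster, offsets_half, n_clusters, periodic):
    """Symmetric cluster x cluster boundary-pair counts (unordered pairs)."""
    h, w = site_map.shape
    out = np.zeros((n_clusters, n_clusters), dtype=np.int64)
    n_off = offsets_half.shape[0]
    for r in range(h):
        for c in range(w):
            ca = comp_cluster[site_map[r, c]]
            for m in range(n_off):
                rr = r + int(offsets_half[m, 0])
                cc = c + int(offsets_half[m, 1])
                if periodic:
                    rr = rr % h
                    cc = cc % w
                elif rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                cb = comp_cluster[site_map[rr, cc]]
                if cb != ca:
                    out[ca, cb] += 1
                    out[cb, ca] += 1
    return out


@njit(cache=True)
def cluster_contact_flags(
    site_map, comp_cluster, clus_row, epi_cluster, comp_label,
    cancer_basal_label, offsets, n_rows, periodic,
):
    """Per live cluster (compact rows): does it touch another epithelial
    cluster, and does it touch a cancer basal membrane?  Output size is
    the number of live clusters, so the scan cost does not grow with
    simulation history."""
    h, w = site_map.shape
    touches_epi = np.zeros(n_rows, dtype=np.uint8)
    touches_basal = np.zeros(n_rows, dtype=np.uint8)
    n_off = offsets.shape[0]  # half offsets: each unordered pair visited once
    for r in range(h):
        for c in range(w):
            a = site_map[r, c]
            ca = comp_cluster[a]
            for m in range(n_off):
                rr = r + int(offsets[m, 0])
                cc = c + int(offsets[m, 1])
                if periodic:
                    rr = rr % h
                    cc = cc % w
                elif rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                b = site_map[rr, cc]
                cb = comp_cluster[b]
                if cb == ca:
                    continue
                row_a = clus_row[ca]
                row_b = clus_row[cb]
                if row_a >= 0:
                    if epi_cluster[cb]:
                        touches_epi[row_a] = 1
                    if comp_label[b] == cancer_basal_label:
                        touches_basal[row_a] = 1
                if row_b >= 0:
                    if epi_cluster[ca]:
                        touches_epi[row_b] = 1
                    if comp_label[a] == cancer_basal_label:
                        touches_basal[row_b] = 1
    return touches_epi, touches_basal
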