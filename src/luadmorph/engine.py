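"""Metropolis dynamics: single copy attempts and the Monte Carlo Step loop.

One Monte Carlo Step (MCS) is width x height copy attempts: pick a random
site and a random neighbor within the neighbor order; if they belong to
different compartments, propose overwriting the site with the neighbor's
id and accept with probability min(1, exp(-dH/T)).  After each sweep the
registered behavior hooks (growth, death, secretion, mitosis, ...) fire
in order.  One MCS represents about 2 simulated hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .energy import ContactEnergyMatrix, delta_hamiltonian
from .lattice import Lattice, PottsParams, offsets_array

HOURS_PER_MCS = 2.0

# hook signature: hook(lattice, mcs, rng) -> optional list of event dicts
Hook = Callable[[Lattice, int, np.random.Generator], list | None]


def simulated_time(n_steps: int) -> float:
    """Simulated hours represented by ``n_steps`` MCS (2 h per MCS)."""
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    return n_steps * HOURS_PER_MCS


@dataclass
class AttemptResult:
    accepted: bool
    site: tuple[int, int]
    source: tuple[int, int]
    delta_h: float
    null_move: bool


def attempt_copy(
    lattice: Lattice,
    params: PottsParams,
    J: ContactEnergyMatrix,
    rng: np.random.Generator,
    J_internal: ContactEnergyMatrix | None = None,
) -> AttemptResult:
    """One Metropolis copy attempt (reference Python path).

    The Monte Carlo loop uses a compiled kernel with identical semantics;
    this function is the slow, transparent form used for unit testing and
    stepping by hand.
    """
    h, w = lattice.height, lattice.width
    r = int(rng.integers(h))
    c = int(rng.integers(w))
    offs = offsets_array(params.neighbor_order)
    k = int(rng.integers(len(offs)))
    nr, nc = r + int(offs[k, 0]), c + int(offs[k, 1])
    if lattice.boundary_mode == "periodic":
        nr, nc = nr % h, nc % w
    elif not (0 <= nr < h and 0 <= nc < w):
        return AttemptResult(False, (r, c), (nr, nc), 0.0, True)
    s_id = int(lattice.site_map[nr, nc])
    t_id = int(lattice.site_map[r, c])
    if s_id == t_id:
        return AttemptResult(False, (r, c), (nr, nc), 0.0, True)
    d_h = delta_hamiltonian(lattice, (nr, nc), (r, c), J, params, J_internal)
    accept = d_h <= 0.0 or rng.random() < np.exp(-d_h / params.temperature)
    if accept:
        lattice.set_site((r, c), s_id)
    return AttemptResult(accept, (r, c), (nr, nc), d_h, False)


@dataclass
class Trajectory:
    """Recorded output of one simulation run."""

    n_steps: int
    seed: int
    records: list = field(default_factory=list)  # MetricsRecord per interval
    snapshots: list = field(default_factory=list)  # (mcs, label image copy)
    events: list = field(default_factory=list)  # behavior event dicts
    n_attempts: int = 0
    n_accepted: int = 0
    accepted_dh_sum: float = 0.0


def run_mcs(
    lattice: Lattice,
    params: PottsParams,
    J: ContactEnergyMatrix,
    n_steps: int,
    *,
    J_internal: ContactEnergyMatrix | None = None,
    hooks: Sequence[Hook] = (),
    record_interval: int = 0,
    snapshot_interval: int = 0,
    connectivity_guard: bool = False,
    collect_metrics: bool = True,
) -> Trajectory:
    """Run ``n_steps`` Monte Carlo Steps with behavior hooks.

    ``record_interval`` > 0 stores a MetricsRecord every that many MCS
    (and at the final step); ``snapshot_interval`` likewise stores label
    images.  Fully reproducible from (state, params.rng_seed).
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    from .metrics import compute_metrics  # deferred: metrics imports lattice

    j_ext = J.to_dense()
    j_int = J_internal.to_dense() if J_internal is not None else j_ext
    _require_complete(j_ext, j_int, lattice)
    offs = offsets_array(params.neighbor_order)
    state = _kernels.seed_state(params.rng_seed)
    hook_rng = np.random.default_rng(np.random.PCG64(params.rng_seed + 1))
    periodic = lattice.boundary_mode == "periodic"
    traj = Trajectory(n_steps=n_steps, seed=params.rng_seed)
    attempts_per_mcs = lattice.width * lattice.height

    for mcs in range(1, n_steps + 1):
        lattice._grow_comp_arrays(lattice.n_comps)
        att, acc, dh_sum = _kernels.run_sweep(
            lattice.site_map,
            lattice.comp_cluster,
            lattice.comp_label,
            lattice.comp_volume,
            lattice.comp_target,
            lattice.comp_lambda,
            j_ext,
            j_int,
            offs,
            params.temperature,
            attempts_per_mcs,
            state,
            periodic,
            connectivity_guard,
        )
        traj.n_attempts += att
        traj.n_accepted += acc
        traj.accepted_dh_sum += dh_sum
        for hook in hooks:
            evts = hook(lattice, mcs, hook_rng)
            if evts:
                traj.events.extend(evts)
        _purge_empty_clusters(lattice)
        last = mcs == n_steps
        if collect_metrics and record_interval and (mcs % record_interval == 0 or last):
            traj.records.append(compute_metrics(lattice, mcs, params.neighbor_order))
        if snapshot_interval and (mcs % snapshot_interval == 0 or last):
            traj.snapshots.append((mcs, lattice.site_map.copy()))
    return traj


def _purge_empty_clusters(lattice: Lattice) -> None:
    """Remove dead clusters whose compartments have all shrunk to volume 0."""
    for cid in list(lattice.cluster_comps):
        if cid == 0 or lattice.clus_alive[cid]:
            continue
        comps = lattice.cluster_comps[cid]
        if all(lattice.comp_volume[c] == 0 for c in comps):
            lattice.remove_cluster(cid)


def _require_complete(j_ext, j_int, lattice: Lattice) -> None:
    """Fail fast if any label pair that can occur lacks a J entry.

    The external table must cover every pair of labels present on the
    lattice; the internal table only pairs within one cell type (internal
    boundaries cannot join different cell types).
    """
    from .lattice import LABEL_NAMES

    present = np.unique(lattice.comp_label[np.unique(lattice.site_map)])
    sub = j_ext[np.ix_(present, present)]
    if np.isnan(sub).any():
        i, j = np.argwhere(np.isnan(sub))[0]
        raise KeyError(
            "J has no entry for label pair "
            f"({LABEL_NAMES[int(present[i])]!r}, {LABEL_NAMES[int(present[j])]!r})"
        )
    # only compartmentalized cell types (dotted labels) have internal boundaries
    celltype = [
        LABEL_NAMES[int(k)].split(".")[0] if "." in LABEL_NAMES[int(k)] else None
        for k in present
    ]
    for i, a in enumerate(present):
        for j, b in enumerate(present):
            if celltype[i] is not None and celltype[i] == celltype[j] and np.isnan(j_int[a, b]):
                raise KeyError(
                    "J_internal has no entry for label pair "
                    f"({LABEL_NAMES[int(a)]!r}, {LABEL_NAMES[int(b)]!r})"
                )
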