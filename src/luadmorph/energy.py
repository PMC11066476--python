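"""Contact + volume energy of a configuration, total and incremental.

The Hamiltonian is the standard cellular Potts energy

    H = sum_{neighbor pairs (i,j), comp_i != comp_j} J(label_i, label_j)
      + sum_{compartments c} lambda_c (V_c - V*_c)^2

where a site's *label* is its (cell type, compartment type) pair and the
neighbor sum runs over all pairs within the configured neighbor order.
Two J tables are used: ``J`` for boundaries between different clusters
(cell-cell and cell-medium adhesion) and ``J_internal`` for boundaries
between compartments of the same cluster (what keeps a compartmentalized
cell in one piece).  Boundaries inside one compartment carry no energy.

``total_hamiltonian`` is the plain vectorized definition and doubles as
the bookkeeping oracle for the incremental ``delta_hamiltonian`` used by
the Monte Carlo kernel.
"""

from __future__ import annotations

import math

import numpy as np

from .lattice import (
    LABEL_INDEX,
    LABEL_NAMES,
    N_LABELS,
    Lattice,
    PottsParams,
    half_offsets,
    neighbor_offsets,
)


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    for name in (a, b):
        if name not in LABEL_INDEX:
            raise KeyError(
                f"unknown contact label {name!r}; valid labels: {LABEL_NAMES}"
            )
    return (a, b) if a <= b else (b, a)


class ContactEnergyMatrix:
    """Symmetric contact energies keyed by (cell type[.compartment]) labels.

    Entries are set per unordered label pair; lookups of a pair with no
    entry raise rather than defaulting silently.
    """

    def __init__(self, entries: dict | None = None):
        self._table: dict[tuple[str, str], float] = {}
        if entries:
            for key, value in entries.items():
                if isinstance(key, str):
                    a, b = key.split("|")
                else:
                    a, b = key
                self.set(a, b, value)

    @classmethod
    def full(cls, value: float) -> "ContactEnergyMatrix":
        """Matrix with every label pair set to one value."""
        m = cls()
        for i, a in enumerate(LABEL_NAMES):
            for b in LABEL_NAMES[i:]:
                m.set(a, b, value)
        return m

    def set(self, a: str, b: str, value: float) -> None:
        self._table[_norm_pair(a, b)] = float(value)

    def get(self, a: str, b: str) -> float:
        key = _norm_pair(a, b)
        if key not in self._table:
            raise KeyError(f"no contact energy entry for label pair {key}")
        return self._table[key]

    def __contains__(self, pair) -> bool:
        return _norm_pair(*pair) in self._table

    def copy(self) -> "ContactEnergyMatrix":
        m = ContactEnergyMatrix()
        m._table = dict(self._table)
        return m

    def to_dict(self) -> dict[str, float]:
        return {f"{a}|{b}": v for (a, b), v in sorted(self._table.items())}

    def to_dense(self) -> np.ndarray:
        """(N_LABELS, N_LABELS) array; missing entries are NaN."""
        dense = np.full((N_LABELS, N_LABELS), np.nan)
        for (a, b), v in self._table.items():
            i, j = LABEL_INDEX[a], LABEL_INDEX[b]
            dense[i, j] = dense[j, i] = v
        return dense


def _dense_tables(
    J: ContactEnergyMatrix, J_internal: ContactEnergyMatrix | None
) -> tuple[np.ndarray, np.ndarray]:
    ext = J.to_dense()
    # with no internal table, same-cluster boundaries use the external one
    intern = J_internal.to_dense() if J_internal is not None else ext
    return ext, intern


def _check_missing(
    dense: np.ndarray, labels_a: np.ndarray, labels_b: np.ndarray
) -> None:
    vals = dense[labels_a, labels_b]
    if np.isnan(vals).any():
        k = int(np.flatnonzero(np.isnan(vals))[0])
        raise KeyError(
            "no contact energy entry for label pair "
            f"({LABEL_NAMES[int(labels_a[k])]!r}, {LABEL_NAMES[int(labels_b[k])]!r})"
        )


def volume_energy(lattice: Lattice) -> float:
    n = lattice.n_comps
    dv = lattice.comp_volume[:n] - lattice.comp_target[:n]
    return float(np.sum(lattice.comp_lambda[:n] * dv * dv))


def contact_energy(
    lattice: Lattice,
    J: ContactEnergyMatrix,
    params: PottsParams,
    J_internal: ContactEnergyMatrix | None = None,
) -> float:
    ext, intern = _dense_tables(J, J_internal)
    sm = lattice.site_map
    labels = lattice.comp_label[sm]
    clusters = lattice.comp_cluster[sm]
    total = 0.0
    periodic = lattice.boundary_mode == "periodic"
    for dr, dc in half_offsets(params.neighbor_order):
        if periodic:
            a_ids, b_ids = sm, np.roll(np.roll(sm, -dr, axis=0), -dc, axis=1)
            a_lab, b_lab = labels, np.roll(np.roll(labels, -dr, 0), -dc, 1)
            a_cl, b_cl = clusters, np.roll(np.roll(clusters, -dr, 0), -dc, 1)
        else:
            h, w = sm.shape
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            a_sl = (slice(r0, r1), slice(c0, c1))
            b_sl = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
            a_ids, b_ids = sm[a_sl], sm[b_sl]
            a_lab, b_lab = labels[a_sl], labels[b_sl]
            a_cl, b_cl = clusters[a_sl], clusters[b_sl]
        het = a_ids != b_ids
        same_cluster = a_cl == b_cl
        for table, mask in (
            (ext, het & ~same_cluster),
            (intern, het & same_cluster),
        ):
            la, lb = a_lab[mask], b_lab[mask]
            _check_missing(table, la, lb)
            total += float(table[la, lb].sum())
    return total


def total_hamiltonian(
    lattice: Lattice,
    J: ContactEnergyMatrix,
    params: PottsParams,
    J_internal: ContactEnergyMatrix | None = None,
) -> float:
    """Full contact + volume energy of the current configuration."""
    return contact_energy(lattice, J, params, J_internal) + volume_energy(lattice)


def delta_hamiltonian(
    lattice: Lattice,
    source_site: tuple[int, int],
    target_site: tuple[int, int],
    J: ContactEnergyMatrix,
    params: PottsParams,
    J_internal: ContactEnergyMatrix | None = None,
) -> float:
    """Energy change if the target site were overwritten by the source's id.

    A null move (source and target already in the same compartment)
    returns exactly 0.  Computed locally: only the contact terms touching
    the target site and the two affected volume terms are evaluated.
    """
    sr, sc = source_site
    tr, tc = target_site
    sm = lattice.site_map
    s_id = int(sm[sr, sc])
    t_id = int(sm[tr, tc])
    if s_id == t_id:
        return 0.0
    ext, intern = _dense_tables(J, J_internal)
    h, w = sm.shape
    periodic = lattice.boundary_mode == "periodic"

    def pair_energy(a_id: int, b_id: int) -> float:
        if a_id == b_id:
            return 0.0
        la = int(lattice.comp_label[a_id])
        lb = int(lattice.comp_label[b_id])
        table = (
            intern
            if lattice.comp_cluster[a_id] == lattice.comp_cluster[b_id]
            else ext
        )
        v = table[la, lb]
        if math.isnan(v):
            raise KeyError(
                "no contact energy entry for label pair "
                f"({LABEL_NAMES[la]!r}, {LABEL_NAMES[lb]!r})"
            )
        return float(v)

    d_contact = 0.0
    for dr, dc in neighbor_offsets(params.neighbor_order):
        nr, nc = tr + dr, tc + dc
        if periodic:
            nr, nc = nr % h, nc % w
        elif not (0 <= nr < h and 0 <= nc < w):
            continue
        n_id = int(sm[nr, nc])
        d_contact += pair_energy(s_id, n_id) - pair_energy(t_id, n_id)

    d_volume = 0.0
    for comp, dv in ((t_id, -1), (s_id, +1)):
        lam = float(lattice.comp_lambda[comp])
        if lam == 0.0:
            continue
        v = float(lattice.comp_volume[comp])
        vt = float(lattice.comp_target[comp])
        d_volume += lam * ((v + dv - vt) ** 2 - (v - vt) ** 2)
    return d_contact + d_volume
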