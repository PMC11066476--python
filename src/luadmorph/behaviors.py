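"""Per-MCS biological update rules layered on the Potts dynamics.

Each rule is a plain function ``apply_*(lattice, ...)`` so it can be
tested in isolation; ``make_hooks`` wires the enabled rules into the
engine's hook list in the fixed order growth -> death -> mucus secretion
-> stromal growth -> mitosis (mitosis last, so daughters are consistent
when metrics or snapshots are taken).

Rate semantics: a growth rate ``g`` adds ``g`` pixels of target volume
per MCS to a cell's growing compartment (the cytosol for epithelial
cells, the single compartment otherwise).  A death rate ``d`` is a
per-MCS, per-cell Bernoulli probability of entering apoptosis, which
zeroes the cell's target volumes and lets the Potts dynamics shrink it
away.  Under mild contact inhibition, a cell touching another cancer or
normal epithelial cell grows at ``g * contact_inhibition_factor``
(0.997: 99.7 % of the set value).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from . import _kernels
from .lattice import (
    CANCER,
    CYTOSOL,
    ECM,
    EPITHELIAL_TYPES,
    GENERIC,
    GROWING_STROMAL,
    LABEL_INDEX,
    MEDIUM,
    MUCUS,
    N_LABELS,
    STROMA_SIDE_TYPES,
    APICAL,
    BASAL,
    LATERAL,
    Lattice,
    offsets_array,
)

_CANCER_BASAL = LABEL_INDEX["cancer.basal"]
_MEDIUM_LABEL = LABEL_INDEX["medium"]
_EPI_LABELS = np.array(
    [
        LABEL_INDEX[f"{p}.{s}"]
        for p in ("cancer", "normal_epithelial")
        for s in ("apical", "basal", "lateral", "cytosol")
    ]
)


@dataclass
class BehaviorRates:
    """Per-cell-type behavior parameters.

    growth_rate: target-volume increment, pixels/MCS.
    death_rate: apoptosis probability per MCS per cell.
    contact_inhibition_factor: growth multiplier while touching other
        epithelial cells (used only when contact inhibition is enabled).
    mucus_secretion_rate: mucus pixels created per cell per MCS.
    stromal_growth_rate: pixels/MCS for growing stroma / matrix.
    division_gain: volume gain since birth (pixels) that triggers
        division; None means divide at 2x the birth volume.
    """

    growth_rate: float = 0.0
    death_rate: float = 0.0
    contact_inhibition_factor: float = 0.997
    mucus_secretion_rate: float = 0.0
    stromal_growth_rate: float = 0.0
    division_gain: float | None = None

    def __post_init__(self) -> None:
        for name in ("growth_rate", "death_rate", "mucus_secretion_rate", "stromal_growth_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.contact_inhibition_factor <= 1.0:
            raise ValueError("contact_inhibition_factor must be in (0, 1]")

    def scaled_in_time(self, factor: float) -> "BehaviorRates":
        """Rates for a coarser clock where one MCS stands for ``factor`` MCS."""
        return replace(
            self,
            growth_rate=self.growth_rate * factor,
            death_rate=min(1.0, self.death_rate * factor),
            mucus_secretion_rate=self.mucus_secretion_rate * factor,
            stromal_growth_rate=self.stromal_growth_rate * factor,
        )


RatesMap = Mapping[int, BehaviorRates]


def _growing_comp(lattice: Lattice, cluster_id: int) -> int:
    """The compartment that receives growth: cytosol, or the single one."""
    comps = lattice.cluster_comps[cluster_id]
    for comp in comps:
        if lattice.comp_type[comp] == CYTOSOL:
            return comp
    return comps[0]


def _contact_counts(lattice: Lattice, order: int = 3) -> np.ndarray:
    return _kernels.comp_contact_counts(
        lattice.site_map,
        lattice.comp_cluster,
        lattice.comp_label,
        offsets_array(order),
        lattice.n_comps,
        N_LABELS,
        lattice.boundary_mode == "periodic",
    )


def contact_flags(
    lattice: Lattice, order: int = 3
) -> tuple[dict[int, bool], dict[int, bool]]:
    """Per alive cluster: (touches another epithelial cell, touches a
    cancer basal membrane).  One compact lattice scan serves both the
    contact-inhibition and the stromal-growth eligibility queries."""
    live = sorted(lattice.cluster_comps)
    clus_row = np.full(lattice.n_clusters, -1, dtype=np.int32)
    for i, cid in enumerate(live):
        clus_row[cid] = i
    epi_cluster = np.zeros(lattice.n_clusters, dtype=bool)
    for cid in lattice.alive_clusters(*EPITHELIAL_TYPES):
        epi_cluster[cid] = True
    from .lattice import half_offsets

    touch_epi, touch_basal = _kernels.cluster_contact_flags(
        lattice.site_map,
        lattice.comp_cluster,
        clus_row,
        epi_cluster,
        lattice.comp_label,
        _CANCER_BASAL,
        np.asarray(half_offsets(order), dtype=np.int64),
        len(live),
        lattice.boundary_mode == "periodic",
    )
    epi = {cid: bool(touch_epi[i]) for i, cid in enumerate(live)}
    basal = {cid: bool(touch_basal[i]) for i, cid in enumerate(live)}
    return epi, basal


def touches_epithelium(lattice: Lattice, contact=None) -> dict[int, bool]:
    """Per alive cluster: does it touch another cancer/normal cell?"""
    if contact is None:
        return contact_flags(lattice)[0]
    epi = contact[:, _EPI_LABELS].sum(axis=1)
    out = {}
    for cid in lattice.alive_clusters():
        out[cid] = any(epi[c] > 0 for c in lattice.cluster_comps[cid])
    return out


def apply_growth(
    lattice: Lattice,
    rates: RatesMap,
    contact_inhibition_enabled: bool = False,
    touching: dict[int, bool] | None = None,
) -> None:
    """Increment target volumes of growing cells for one MCS.

    The same increment accrues on the cell's growth progress, which is
    what triggers division once it reaches the division gain.
    ``touching`` (cluster -> touches another epithelial cell) may be
    precomputed with :func:`contact_flags`.
    """
    if contact_inhibition_enabled and touching is None:
        touching = contact_flags(lattice)[0]
    progress = lattice.clus_growth_progress
    for cid in lattice.alive_clusters():
        ct = int(lattice.clus_celltype[cid])
        r = rates.get(ct)
        if r is None or r.growth_rate == 0.0:
            continue
        g = r.growth_rate
        if contact_inhibition_enabled and touching.get(cid, False):
            g *= r.contact_inhibition_factor
        lattice.comp_target[_growing_comp(lattice, cid)] += g
        progress[cid] = progress.get(cid, 0.0) + g


def apply_death(
    lattice: Lattice, rates: RatesMap, rng: np.random.Generator
) -> list[int]:
    """Stochastic apoptosis: zero the target volumes of unlucky cells."""
    dying = []
    for cid in sorted(lattice.alive_clusters()):
        ct = int(lattice.clus_celltype[cid])
        r = rates.get(ct)
        if r is None or r.death_rate == 0.0:
            continue
        if rng.random() < r.death_rate:
            dying.append(cid)
    for cid in dying:
        for comp in lattice.cluster_comps[cid]:
            lattice.comp_target[comp] = 0.0
        lattice.clus_alive[cid] = False
    return dying


# --------------------------------------------------------------- mitosis
def _principal_axis(pixels: np.ndarray) -> np.ndarray:
    centered = pixels - pixels.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    return v[:, int(np.argmax(w))]


def _classify_epithelial_pixels(
    lattice: Lattice, pixels: np.ndarray, own_cluster: int
) -> np.ndarray:
    """Compartment type per pixel from what its 4-neighborhood touches:
    medium/mucus -> apical, stroma/matrix -> basal, another epithelial
    cluster -> lateral, interior -> cytosol."""
    h, w = lattice.height, lattice.width
    periodic = lattice.boundary_mode == "periodic"
    clus_map = lattice.cluster_of_site
    types = np.full(len(pixels), CYTOSOL, dtype=np.int8)
    stroma_side = set(STROMA_SIDE_TYPES)
    for i, (r, c) in enumerate(pixels):
        apical = basal = lateral = False
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if periodic:
                rr, cc = rr % h, cc % w
            elif not (0 <= rr < h and 0 <= cc < w):
                continue
            ncl = int(clus_map[rr, cc])
            if ncl == own_cluster:
                continue
            nct = int(lattice.clus_celltype[ncl])
            if nct in (MEDIUM, MUCUS):
                apical = True
            elif nct in stroma_side:
                basal = True
            elif nct in EPITHELIAL_TYPES:
                lateral = True
        if apical:
            types[i] = APICAL
        elif basal:
            types[i] = BASAL
        elif lateral:
            types[i] = LATERAL
    return types


def _slab_pixel_types(
    lattice: Lattice,
    pixels: np.ndarray,
    polarity: np.ndarray,
    target_by_type: dict[int, float],
    parent_cluster: int,
) -> np.ndarray:
    """Compartment type per pixel by geometry: apical and basal slabs at
    the ends of the polarity axis (sized by the birth profile's shares),
    lateral where the middle slab touches other epithelial cells, cytosol
    elsewhere.  This keeps daughters polar even deep inside a tissue."""
    n = len(pixels)
    proj = pixels.astype(float) @ polarity
    order = np.argsort(proj, kind="stable")
    total_target = sum(target_by_type.values()) or 1.0
    n_ap = max(1, round(n * target_by_type.get(APICAL, 0.0) / total_target))
    n_ba = max(1, round(n * target_by_type.get(BASAL, 0.0) / total_target))
    n_ap = min(n_ap, n - 1)
    n_ba = min(n_ba, n - n_ap - 1) if n - n_ap - 1 > 0 else 0
    types = np.full(n, CYTOSOL, dtype=np.int8)
    types[order[-n_ap:]] = APICAL  # high projection = apical end
    if n_ba:
        types[order[:n_ba]] = BASAL
    # lateral: middle-slab pixels whose 4-neighborhood touches another
    # epithelial cluster (the parent's own remaining pixels are skipped)
    contact = _classify_epithelial_pixels(lattice, pixels, own_cluster=parent_cluster)
    middle = types == CYTOSOL
    lateral = middle & (contact == LATERAL)
    types[lateral] = LATERAL
    if not (types == LATERAL).any() and middle.any():
        types[int(np.flatnonzero(middle)[0])] = LATERAL
    if not (types == CYTOSOL).any():
        # keep a cytosol core: reclaim from the largest compartment
        vals, counts = np.unique(types, return_counts=True)
        donor = int(vals[int(np.argmax(counts))])
        types[int(np.flatnonzero(types == donor)[-1])] = CYTOSOL
    return types


def _rebuild_cluster(
    lattice: Lattice,
    pixels: np.ndarray,
    cell_type: int,
    compartmental: bool,
    target_by_type: dict[int, float],
    lam_by_type: dict[int, float],
    fraction: float,
    parent_cluster: int,
    polarity=None,
) -> int:
    """Create a cluster (with compartments) over the given pixels.

    ``fraction`` is this daughter's share of the parent volume; targets
    are reset pro-rata.  ``parent_cluster`` is excluded from the boundary
    classification (its remaining pixels are the sibling-to-be)."""
    cid = lattice.new_cluster(cell_type, reference_volume=float(len(pixels)))
    if not compartmental:
        comp = lattice.new_compartment(
            cid,
            GENERIC,
            target_by_type.get(GENERIC, float(len(pixels))) * fraction,
            lam_by_type.get(GENERIC, 2.0),
        )
        lattice.paint(pixels[:, 0], pixels[:, 1], comp)
        return cid
    if polarity is not None:
        types = _slab_pixel_types(
            lattice, pixels, polarity, target_by_type, parent_cluster
        )
    else:
        types = _classify_epithelial_pixels(lattice, pixels, own_cluster=parent_cluster)
    comp_ids = {}
    for ctype in (APICAL, BASAL, LATERAL, CYTOSOL):
        comp_ids[ctype] = lattice.new_compartment(
            cid, ctype, 0.0, lam_by_type.get(ctype, 2.0)
        )
    # guarantee all four types are represented: steal from the commonest type
    present = set(int(t) for t in types)
    for ctype in (APICAL, BASAL, LATERAL, CYTOSOL):
        if ctype not in present:
            vals, counts = np.unique(types, return_counts=True)
            donor = int(vals[int(np.argmax(counts))])
            idx = int(np.flatnonzero(types == donor)[0])
            types[idx] = ctype
            present.add(ctype)
    for ctype, comp in comp_ids.items():
        sel = pixels[types == ctype]
        if len(sel):
            lattice.paint(sel[:, 0], sel[:, 1], comp)
        lattice.comp_target[comp] = target_by_type.get(ctype, 0.0) * fraction
    return cid


def _polarity_axis(lattice: Lattice, cluster_id: int) -> np.ndarray | None:
    """Apical-basal axis of an epithelial cell (basal -> apical centroid)."""
    apical = basal = None
    for comp in lattice.cluster_comps[cluster_id]:
        ctype = int(lattice.comp_type[comp])
        if ctype == APICAL and lattice.comp_volume[comp] > 0:
            apical = np.argwhere(lattice.site_map == comp).mean(axis=0)
        elif ctype == BASAL and lattice.comp_volume[comp] > 0:
            basal = np.argwhere(lattice.site_map == comp).mean(axis=0)
    if apical is None or basal is None:
        return None
    axis = apical - basal
    norm = np.linalg.norm(axis)
    return axis / norm if norm > 1e-9 else None


def divide_cluster(
    lattice: Lattice, cluster_id: int, full_size_daughters: bool = False
) -> tuple[int, int] | None:
    """Split a cluster through its center of mass into two daughters.

    Non-compartmental pseudo-cells are cut perpendicular to their longest
    principal axis.  Epithelial cells divide in-plane: the cut runs along
    the apical-basal polarity axis, so both daughters keep lumen and
    stroma contact and the monolayer lengthens (falling back to the
    principal-axis rule when polarity is degenerate).

    ``full_size_daughters`` resets each daughter's targets to the
    parent's birth profile (cells regrow to normal size before the next
    division); otherwise targets are split pro-rata.  Returns the two
    daughter ids, or None if the cut would leave an empty daughter (the
    split is retried on a later MCS).
    """
    pixels = lattice.cluster_pixels(cluster_id)
    if len(pixels) < 2:
        return None
    cell_type = int(lattice.clus_celltype[cluster_id])
    compartmental = cell_type in EPITHELIAL_TYPES
    axis = None
    polarity = None
    if compartmental:
        polarity = _polarity_axis(lattice, cluster_id)
        if polarity is not None:
            axis = np.array([-polarity[1], polarity[0]])  # in-plane direction
    if axis is None:
        axis = _principal_axis(pixels.astype(float))
    proj = (pixels - pixels.mean(axis=0)).astype(float) @ axis
    order = np.argsort(proj, kind="stable")
    half = len(pixels) // 2
    side_a, side_b = pixels[order[:half]], pixels[order[half:]]
    if len(side_a) == 0 or len(side_b) == 0:
        return None
    comps = lattice.cluster_comps[cluster_id]
    if full_size_daughters and cluster_id in lattice.clus_birth_targets:
        target_by_type = dict(lattice.clus_birth_targets[cluster_id])
    else:
        target_by_type = {
            int(lattice.comp_type[c]): float(lattice.comp_target[c])
            for c in comps
        }
    lam_by_type = {
        int(lattice.comp_type[c]): float(lattice.comp_lambda[c]) for c in comps
    }
    total = float(len(pixels))
    daughters = []
    for side in (side_a, side_b):
        fraction = 1.0 if full_size_daughters else len(side) / total
        did = _rebuild_cluster(
            lattice,
            side,
            cell_type,
            compartmental,
            target_by_type,
            lam_by_type,
            fraction=fraction,
            parent_cluster=cluster_id,
            polarity=polarity,
        )
        lattice.clus_birth_targets[did] = dict(target_by_type)
        lattice.clus_growth_progress[did] = 0.0
        daughters.append(did)
    # the parent is now empty: retire it
    lattice.clus_alive[cluster_id] = False
    lattice.remove_cluster(cluster_id)
    acc = lattice.mucus_accumulator
    if cluster_id in acc:
        acc[daughters[0]] = acc.pop(cluster_id)
    return daughters[0], daughters[1]


# a squeezed cell postpones division until it has physically regrown to
# this fraction of its target volume (mechanics gate on the growth clock)
DIVISION_VOLUME_GATE = 0.8


def apply_mitosis(
    lattice: Lattice,
    rng: np.random.Generator,
    rates: RatesMap | None = None,
    volume_gate: float = DIVISION_VOLUME_GATE,
) -> list[tuple[int, int, int]]:
    """Divide every alive cluster that has reached its division trigger.

    With no rates (or no division gain configured) the trigger is the 2x
    rule: actual volume >= 2x the volume at birth.  With a division gain
    g* the trigger is the growth clock -- cumulative target-volume growth
    since birth >= g* -- gated by the cell having physically reached
    ``volume_gate`` of its target volume, so squeezed cells wait.
    Daughters under the growth-clock rule are reborn with the parent's
    full birth-size target profile.

    Returns (parent, daughter_a, daughter_b) triples.
    """
    events = []
    for cid in sorted(lattice.alive_clusters()):
        ct = int(lattice.clus_celltype[cid])
        gain = None
        if rates is not None and ct in rates:
            gain = rates[ct].division_gain
        if gain is not None:
            if lattice.clus_growth_progress.get(cid, 0.0) < gain:
                continue
            total_target = sum(
                lattice.comp_target[c] for c in lattice.cluster_comps[cid]
            )
            if lattice.cluster_volume(cid) < volume_gate * total_target:
                continue
            out = divide_cluster(lattice, cid, full_size_daughters=True)
        else:
            ref = float(lattice.clus_ref_volume[cid])
            if ref <= 0 or lattice.cluster_volume(cid) < 2.0 * ref:
                continue
            out = divide_cluster(lattice, cid, full_size_daughters=False)
        if out is not None:
            events.append((cid, out[0], out[1]))
    return events


# ----------------------------------------------------------------- mucus
MUCUS_PSEUDOCELL_MAX = 9  # pixels per mucus pseudo-cell before a new one starts


def secrete_mucus(
    lattice: Lattice,
    rates: RatesMap,
    rng: np.random.Generator,
    order: int = 1,
) -> int:
    """Convert medium pixels at cancer apical boundaries into mucus.

    Fractional per-MCS rates accumulate per cell; each whole unit converts
    one medium pixel adjacent (4-neighborhood) to that cell's apical
    compartment.  New pixels join an adjacent mucus pseudo-cell until it
    reaches ~9 pixels, then seed a new one.  Returns pixels created.
    """
    created = 0
    h, w = lattice.height, lattice.width
    periodic = lattice.boundary_mode == "periodic"
    for cid in sorted(lattice.alive_clusters(CANCER)):
        r = rates.get(CANCER)
        if r is None or r.mucus_secretion_rate == 0.0:
            continue
        acc = lattice.mucus_accumulator.get(cid, 0.0) + r.mucus_secretion_rate
        apical_comps = [
            c
            for c in lattice.cluster_comps[cid]
            if lattice.comp_type[c] == APICAL
        ]
        while acc >= 1.0 and apical_comps:
            candidates = _secretion_sites(lattice, apical_comps, periodic, h, w)
            if len(candidates) == 0:
                break
            site = candidates[int(rng.integers(len(candidates)))]
            _place_mucus_pixel(lattice, tuple(site), periodic, h, w)
            created += 1
            acc -= 1.0
        lattice.mucus_accumulator[cid] = min(acc, 5.0)
    return created


def _dilate4(mask: np.ndarray, periodic: bool, h: int, w: int) -> np.ndarray:
    adj = np.zeros_like(mask)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        if periodic:
            adj |= np.roll(np.roll(mask, dr, 0), dc, 1)
        else:
            shifted = np.zeros_like(mask)
            src_r = slice(max(0, -dr), h - max(0, dr))
            dst_r = slice(max(0, dr), h - max(0, -dr))
            src_c = slice(max(0, -dc), w - max(0, dc))
            dst_c = slice(max(0, dc), w - max(0, -dc))
            shifted[dst_r, dst_c] = mask[src_r, src_c]
            adj |= shifted
    return adj


def _secretion_sites(lattice, apical_comps, periodic, h, w) -> np.ndarray:
    """Medium pixels reachable from the cell's apical membrane: directly
    adjacent to it, or adjacent to mucus that is itself attached to it
    (the secreted pool keeps growing outward from the apical surface)."""
    apical = np.isin(lattice.site_map, np.asarray(apical_comps))
    apical_adj = _dilate4(apical, periodic, h, w)
    celltypes = lattice.clus_celltype[lattice.comp_cluster[lattice.site_map]]
    mucus = celltypes == MUCUS
    attached = mucus & apical_adj
    # grow the attached-pool mask through the mucus region
    while True:
        grown = mucus & _dilate4(attached, periodic, h, w) | attached
        if (grown == attached).all():
            break
        attached = grown
    front = apical_adj | _dilate4(attached, periodic, h, w)
    return np.argwhere(front & (lattice.site_map == 0))


def _place_mucus_pixel(lattice, site, periodic, h, w) -> None:
    r, c = int(site[0]), int(site[1])
    target_comp = None
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rr, cc = r + dr, c + dc
        if periodic:
            rr, cc = rr % h, cc % w
        elif not (0 <= rr < h and 0 <= cc < w):
            continue
        comp = int(lattice.site_map[rr, cc])
        if comp == 0:
            continue
        ncl = int(lattice.comp_cluster[comp])
        if (
            lattice.clus_celltype[ncl] == MUCUS
            and lattice.comp_volume[comp] < MUCUS_PSEUDOCELL_MAX
        ):
            target_comp = comp
            break
    if target_comp is None:
        mcid = lattice.new_cluster(MUCUS, reference_volume=0.0)
        target_comp = lattice.new_compartment(mcid, GENERIC, 0.0, 2.0)
    lattice.set_site((r, c), target_comp)
    lattice.comp_target[target_comp] += 1.0
    lattice.clus_ref_volume[int(lattice.comp_cluster[target_comp])] += 1.0


def proliferate_stroma(
    lattice: Lattice, rates: RatesMap, touch_basal: dict[int, bool] | None = None
) -> list[int]:
    """Grow stroma/matrix pseudo-cells that touch cancer basal membranes."""
    rate = None
    for ct in (GROWING_STROMAL, ECM):
        r = rates.get(ct)
        if r is not None and r.stromal_growth_rate > 0:
            rate = r
            break
    if rate is None:
        return []
    if touch_basal is None:
        touch_basal = contact_flags(lattice)[1]
    grown = []
    for cid in lattice.alive_clusters(GROWING_STROMAL, ECM):
        if touch_basal.get(cid, False):
            ct = int(lattice.clus_celltype[cid])
            r = rates.get(ct, rate)
            g = r.stromal_growth_rate if r.stromal_growth_rate > 0 else rate.stromal_growth_rate
            lattice.comp_target[_growing_comp(lattice, cid)] += g
            lattice.clus_growth_progress[cid] = (
                lattice.clus_growth_progress.get(cid, 0.0) + g
            )
            grown.append(cid)
    return grown


# ------------------------------------------------------------------ hooks
def make_hooks(
    rates: RatesMap,
    *,
    contact_inhibition: bool = False,
    mucus: bool = False,
    stromal_growth: bool = False,
):
    """Hook list for the engine, in the canonical order."""

    def growth_hook(lattice, mcs, rng):
        touching = basal = None
        if contact_inhibition or stromal_growth:
            touching, basal = contact_flags(lattice)
        apply_growth(lattice, rates, contact_inhibition, touching)
        if stromal_growth:
            proliferate_stroma(lattice, rates, basal)
        return None

    def death_hook(lattice, mcs, rng):
        dying = apply_death(lattice, rates, rng)
        return [{"mcs": mcs, "event": "death", "cluster": d} for d in dying]

    def mucus_hook(lattice, mcs, rng):
        n = secrete_mucus(lattice, rates, rng)
        if n:
            return [{"mcs": mcs, "event": "secretion", "pixels": n}]
        return None

    def mitosis_hook(lattice, mcs, rng):
        events = apply_mitosis(lattice, rng, rates)
        return [
            {"mcs": mcs, "event": "division", "parent": p, "daughters": (a, b)}
            for p, a, b in events
        ]

    hooks = [growth_hook, death_hook]
    if mucus:
        hooks.append(mucus_hook)
    hooks.append(mitosis_hook)
    return hooks
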