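"""Synthetic fixtures with known ground truth.

Generators standing in for the study's raw measurements, each returning
its machine-readable ground truth so the quantification routines can be
round-trip tested:

* circular spheroid masks (smooth, like knockdown spheroids) and star
  masks with radial protrusion arms (like control spheroids);
* marker/region mask pairs with an exactly known positive fraction;
* 3D spot sets, either uniform in a sphere (evenly distributed cells)
  or Gaussian-clustered (patchy, peripheral cells), the latter built to
  have the larger dispersion of per-spot nearest-neighbor distances;
* small random lattices for exercising the Potts energy bookkeeping.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw

from .energy import ContactEnergyMatrix
from .lattice import GENERIC, Lattice
from .quantify import SpotSet


# ------------------------------------------------------------------ masks
def make_circle_mask(
    radius: float, margin: int = 10, center=None, shape=None
) -> tuple[np.ndarray, dict]:
    """Filled disc mask plus ground truth (exact pixel area, 0 arms)."""
    if radius < 2:
        raise ValueError("radius too small to rasterize (need >= 2 px)")
    size = int(2 * (radius + margin))
    shape = shape or (size, size)
    center = center or (shape[0] / 2.0, shape[1] / 2.0)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center, radius, shape=shape)
    mask[rr, cc] = True
    truth = {
        "kind": "mask_circle",
        "radius": float(radius),
        "area_px": int(mask.sum()),
        "n_arms": 0,
    }
    return mask, truth


def make_star_mask(
    radius: float,
    n_arms: int = 8,
    arm_length: float | None = None,
    margin: int = 10,
) -> tuple[np.ndarray, dict]:
    """Star-shaped mask: a disc with ``n_arms`` radial protrusions.

    The boundary is r(theta) = radius + arm_length * cos(n_arms * theta),
    rasterized as a polygon.
    """
    if radius < 2:
        raise ValueError("radius too small to rasterize (need >= 2 px)")
    if arm_length is None:
        arm_length = 0.4 * radius
    size = int(2 * (radius + arm_length + margin))
    center = size / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, max(720, 90 * n_arms), endpoint=False)
    r = radius + arm_length * np.cos(n_arms * theta)
    rows = center + r * np.sin(theta)
    cols = center + r * np.cos(theta)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    truth = {
        "kind": "mask_star",
        "radius": float(radius),
        "arm_length": float(arm_length),
        "area_px": int(mask.sum()),
        "n_arms": int(n_arms),
    }
    return mask, truth


def make_marker_pair(
    positive_fraction: float,
    region_shape: tuple[int, int] = (40, 40),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """(marker, region, true_fraction): a rectangular region holding
    exactly round(fraction * size) marker-positive pixels."""
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = region_shape
    pad = 5
    region = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    region[pad : pad + h, pad : pad + w] = True
    n_pos = round(positive_fraction * h * w)
    marker = np.zeros_like(region)
    flat = rng.choice(h * w, size=n_pos, replace=False)
    rows, cols = np.unravel_index(flat, (h, w))
    marker[rows + pad, cols + pad] = True
    return marker, region, n_pos / (h * w)


# ------------------------------------------------------------------ spots
def make_uniform_spots(
    n_points: int = 500,
    sphere_radius: float = 200.0,
    seed: int = 0,
    label: str = "uniform",
    k: int = 9,
) -> SpotSet:
    """Spots uniform in a sphere of the given radius (micrometers)."""
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while len(pts) < n_points:
        cand = rng.uniform(-sphere_radius, sphere_radius, size=(2 * n_points, 3))
        cand = cand[(cand**2).sum(axis=1) <= sphere_radius**2]
        pts = np.vstack([pts, cand])
    return SpotSet(label, pts[:n_points], k=k)


def make_clustered_spots(
    n_points: int = 500,
    sphere_radius: float = 200.0,
    n_clusters: int = 4,
    cluster_sd: float = 15.0,
    scattered_fraction: float = 0.15,
    seed: int = 0,
    label: str = "clustered",
    k: int = 9,
) -> SpotSet:
    """Spots in Gaussian clusters plus scattered peripheral points.

    The patchy-and-peripheral geometry: most spots sit in dense patches
    (tiny neighbor distances) while a scattered minority floats far from
    any patch (large neighbor distances), so the per-spot k-NN means
    spread much wider than in the uniform geometry at matched n.
    """
    rng = np.random.default_rng(seed)
    centers = rng.uniform(
        -0.6 * sphere_radius, 0.6 * sphere_radius, size=(n_clusters, 3)
    )
    n_scattered = int(round(scattered_fraction * n_points))
    n_clustered = n_points - n_scattered
    weights = rng.dirichlet(np.ones(n_clusters) * 1.5)
    counts = rng.multinomial(n_clustered, weights)
    pts = []
    for center, cnt in zip(centers, counts):
        pts.append(rng.normal(center, cluster_sd, size=(cnt, 3)))
    scattered = np.empty((0, 3))
    while len(scattered) < n_scattered:
        cand = rng.uniform(-sphere_radius, sphere_radius, size=(2 * n_scattered + 8, 3))
        cand = cand[(cand**2).sum(axis=1) <= sphere_radius**2]
        scattered = np.vstack([scattered, cand])
    pts.append(scattered[:n_scattered])
    return SpotSet(label, np.vstack(pts), k=k)


def make_spots(
    n_points: int = 500, seed: int = 0, k: int = 9, **kwargs
) -> tuple[SpotSet, SpotSet]:
    """One matched pair of spot sets: (uniform A, clustered B)."""
    return (
        make_uniform_spots(n_points, seed=seed, k=k, **kwargs),
        make_clustered_spots(n_points, seed=seed + 1, k=k, **kwargs),
    )


def make_spot_groups(
    n_spheroids: int = 8,
    n_points: int = 500,
    seed: int = 0,
    **kwargs,
) -> tuple[list[SpotSet], list[SpotSet]]:
    """Matched groups of spheroid spot sets: uniform (A) vs clustered (B)."""
    uniform, clustered = [], []
    for i in range(n_spheroids):
        uniform.append(
            make_uniform_spots(
                n_points, seed=seed * 1000 + i, label=f"uniform_{i}", **kwargs
            )
        )
        clustered.append(
            make_clustered_spots(
                n_points, seed=seed * 1000 + 500 + i, label=f"clustered_{i}", **kwargs
            )
        )
    return uniform, clustered


# --------------------------------------------------------------- lattices
def make_random_lattice(
    seed: int = 0,
    shape: tuple[int, int] = (20, 20),
    n_clusters: int = 6,
    max_comps_per_cluster: int = 3,
) -> tuple[Lattice, ContactEnergyMatrix, ContactEnergyMatrix]:
    """A random labeled lattice with random J tables and volume terms.

    Sites are dealt randomly to compartments (plus some medium), so the
    state is far from equilibrium -- exactly what the energy-bookkeeping
    oracle tests want.
    """
    rng = np.random.default_rng(seed)
    lattice = Lattice(shape[1], shape[0])
    comp_ids = [0]
    for _ in range(n_clusters):
        cell_type = int(rng.integers(3, 7))  # single-compartment types
        cid = lattice.new_cluster(cell_type)
        for _ in range(int(rng.integers(1, max_comps_per_cluster + 1))):
            comp = lattice.new_compartment(
                cid,
                GENERIC,
                target_volume=float(rng.integers(1, 40)),
                lambda_volume=float(rng.uniform(0.0, 3.0)),
            )
            comp_ids.append(comp)
    assignment = rng.choice(comp_ids, size=shape)
    lattice.site_map[:, :] = assignment
    counts = lattice.recount_volumes()
    lattice.comp_volume[: lattice.n_comps] = counts
    J = ContactEnergyMatrix.full(0.0)
    J_int = ContactEnergyMatrix.full(0.0)
    from .lattice import LABEL_NAMES

    for i, a in enumerate(LABEL_NAMES):
        for b in LABEL_NAMES[i:]:
            J.set(a, b, float(rng.uniform(0.0, 20.0)))
            J_int.set(a, b, float(rng.uniform(0.0, 5.0)))
    for cid in list(lattice.cluster_comps):
        if cid != 0 and lattice.cluster_volume(cid) == 0:
            lattice.clus_alive[cid] = False
            lattice.remove_cluster(cid)
    lattice.validate()
    return lattice, J, J_int
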