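"""Lattice state for the compartmental cellular Potts model.

A simulation state is a 2D grid of *compartment* ids.  Compartments are
grouped into *clusters*: a cluster is one biological object (an epithelial
cell with apical/basal/lateral/cytosol subdomains, or a single-compartment
pseudo-cell such as a stromal cell, a portion of extracellular matrix, or a
blob of mucus).  Compartment id 0 / cluster id 0 is the medium -- the
luminal space -- which carries no volume constraint.

Row/column convention: ``site_map[row, col]``; sites are addressed as
``(row, col)`` tuples.  Row 0 is the stromal side of the built epithelium
and the highest rows are the lumen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# compartment types
APICAL, BASAL, LATERAL, CYTOSOL, GENERIC = 0, 1, 2, 3, 4
COMPARTMENT_TYPE_NAMES = ("apical", "basal", "lateral", "cytosol", "generic")
EPITHELIAL_COMPARTMENTS = (APICAL, BASAL, LATERAL, CYTOSOL)

# cell types
MEDIUM, CANCER, NORMAL, STROMAL, GROWING_STROMAL, ECM, MUCUS = range(7)
CELL_TYPE_NAMES = (
    "medium",
    "cancer",
    "normal_epithelial",
    "stromal",
    "growing_stromal",
    "ecm",
    "mucus",
)
EPITHELIAL_TYPES = (CANCER, NORMAL)
STROMA_SIDE_TYPES = (STROMAL, GROWING_STROMAL, ECM)

# contact labels: (cell type, compartment type) pairs that can ever appear
# on a boundary.  These index the dense contact-energy matrices.
LABEL_NAMES: tuple[str, ...] = (
    "medium",
    "cancer.apical",
    "cancer.basal",
    "cancer.lateral",
    "cancer.cytosol",
    "normal_epithelial.apical",
    "normal_epithelial.basal",
    "normal_epithelial.lateral",
    "normal_epithelial.cytosol",
    "stromal",
    "growing_stromal",
    "ecm",
    "mucus",
)
N_LABELS = len(LABEL_NAMES)
LABEL_INDEX = {name: i for i, name in enumerate(LABEL_NAMES)}

# (cell_type, compartment_type) -> label code; -1 marks invalid combos
_LABEL_TABLE = np.full((7, 5), -1, dtype=np.int16)
_LABEL_TABLE[MEDIUM, GENERIC] = LABEL_INDEX["medium"]
for _ct, _prefix in ((CANCER, "cancer"), (NORMAL, "normal_epithelial")):
    for _cp, _suffix in zip(
        EPITHELIAL_COMPARTMENTS, ("apical", "basal", "lateral", "cytosol")
    ):
        _LABEL_TABLE[_ct, _cp] = LABEL_INDEX[f"{_prefix}.{_suffix}"]
for _ct, _name in (
    (STROMAL, "stromal"),
    (GROWING_STROMAL, "growing_stromal"),
    (ECM, "ecm"),
    (MUCUS, "mucus"),
):
    _LABEL_TABLE[_ct, GENERIC] = LABEL_INDEX[_name]


def label_of(cell_type: int, compartment_type: int) -> int:
    """Contact label code for a (cell type, compartment type) pair."""
    code = int(_LABEL_TABLE[cell_type, compartment_type])
    if code < 0:
        raise ValueError(
            f"cell type {CELL_TYPE_NAMES[cell_type]} has no "
            f"{COMPARTMENT_TYPE_NAMES[compartment_type]} compartment"
        )
    return code


@dataclass
class CompartmentInfo:
    """Read-only view of one compartment's registry entry."""

    id: int
    compartment_type: int
    cluster_id: int
    volume: int
    target_volume: float
    lambda_volume: float

    @property
    def compartment_type_name(self) -> str:
        return COMPARTMENT_TYPE_NAMES[self.compartment_type]


@dataclass
class ClusterInfo:
    """Read-only view of one cluster's registry entry."""

    cluster_id: int
    cell_type: int
    compartment_ids: list[int]
    alive: bool
    reference_volume: float

    @property
    def cell_type_name(self) -> str:
        return CELL_TYPE_NAMES[self.cell_type]


_INITIAL_CAPACITY = 64


class Lattice:
    """Mutable CPM state: site map plus compartment and cluster registries.

    Registry data lives in flat numpy arrays indexed by id so the Monte
    Carlo kernel can operate on them directly.  Ids are never reused;
    arrays grow by doubling.
    """

    def __init__(self, width: int, height: int, boundary_mode: str = "fixed"):
        if boundary_mode not in ("fixed", "periodic"):
            raise ValueError("boundary_mode must be 'fixed' or 'periodic'")
        self.width = int(width)
        self.height = int(height)
        self.boundary_mode = boundary_mode
        self.site_map = np.zeros((self.height, self.width), dtype=np.int32)

        cap = _INITIAL_CAPACITY
        self.comp_cluster = np.zeros(cap, dtype=np.int32)
        self.comp_type = np.full(cap, GENERIC, dtype=np.int8)
        self.comp_volume = np.zeros(cap, dtype=np.int64)
        self.comp_target = np.zeros(cap, dtype=np.float64)
        self.comp_lambda = np.zeros(cap, dtype=np.float64)
        self.comp_label = np.zeros(cap, dtype=np.int16)

        self.clus_celltype = np.zeros(cap, dtype=np.int8)
        self.clus_alive = np.zeros(cap, dtype=bool)
        self.clus_ref_volume = np.zeros(cap, dtype=np.float64)

        # id 0 on both registries is the medium
        self.n_comps = 1
        self.n_clusters = 1
        self.comp_volume[0] = self.width * self.height
        self.clus_alive[0] = False
        self.cluster_comps: dict[int, list[int]] = {0: [0]}
        # per-cluster fractional mucus secretion accumulator
        self.mucus_accumulator: dict[int, float] = {}
        # per-cluster cumulative growth since birth (the division clock)
        self.clus_growth_progress: dict[int, float] = {}
        # per-cluster target-volume profile at birth, {compartment_type: px};
        # daughters are reborn with this full-size profile
        self.clus_birth_targets: dict[int, dict[int, float]] = {}

    # ---------------------------------------------------------------- growth
    def _grow_comp_arrays(self, need: int) -> None:
        cap = len(self.comp_cluster)
        if need <= cap:
            return
        new = max(need, 2 * cap)
        for name in (
            "comp_cluster",
            "comp_type",
            "comp_volume",
            "comp_target",
            "comp_lambda",
            "comp_label",
        ):
            arr = getattr(self, name)
            out = np.zeros(new, dtype=arr.dtype)
            out[:cap] = arr
            setattr(self, name, out)

    def _grow_cluster_arrays(self, need: int) -> None:
        cap = len(self.clus_celltype)
        if need <= cap:
            return
        new = max(need, 2 * cap)
        for name in ("clus_celltype", "clus_alive", "clus_ref_volume"):
            arr = getattr(self, name)
            out = np.zeros(new, dtype=arr.dtype)
            out[:cap] = arr
            setattr(self, name, out)

    # ------------------------------------------------------------- creation
    def new_cluster(self, cell_type: int, reference_volume: float = 0.0) -> int:
        cid = self.n_clusters
        self._grow_cluster_arrays(cid + 1)
        self.clus_celltype[cid] = cell_type
        self.clus_alive[cid] = True
        self.clus_ref_volume[cid] = reference_volume
        self.cluster_comps[cid] = []
        self.n_clusters += 1
        return cid

    def new_compartment(
        self,
        cluster_id: int,
        compartment_type: int,
        target_volume: float = 0.0,
        lambda_volume: float = 0.0,
    ) -> int:
        comp_id = self.n_comps
        self._grow_comp_arrays(comp_id + 1)
        self.comp_cluster[comp_id] = cluster_id
        self.comp_type[comp_id] = compartment_type
        self.comp_volume[comp_id] = 0
        self.comp_target[comp_id] = target_volume
        self.comp_lambda[comp_id] = lambda_volume
        self.comp_label[comp_id] = label_of(
            int(self.clus_celltype[cluster_id]), compartment_type
        )
        self.cluster_comps[cluster_id].append(comp_id)
        self.n_comps += 1
        return comp_id

    # --------------------------------------------------------------- access
    def compartment(self, comp_id: int) -> CompartmentInfo:
        if not 0 <= comp_id < self.n_comps:
            raise KeyError(f"unknown compartment id {comp_id}")
        return CompartmentInfo(
            id=comp_id,
            compartment_type=int(self.comp_type[comp_id]),
            cluster_id=int(self.comp_cluster[comp_id]),
            volume=int(self.comp_volume[comp_id]),
            target_volume=float(self.comp_target[comp_id]),
            lambda_volume=float(self.comp_lambda[comp_id]),
        )

    def cluster(self, cluster_id: int) -> ClusterInfo:
        if cluster_id not in self.cluster_comps:
            raise KeyError(f"unknown cluster id {cluster_id}")
        return ClusterInfo(
            cluster_id=cluster_id,
            cell_type=int(self.clus_celltype[cluster_id]),
            compartment_ids=list(self.cluster_comps[cluster_id]),
            alive=bool(self.clus_alive[cluster_id]),
            reference_volume=float(self.clus_ref_volume[cluster_id]),
        )

    @property
    def cluster_of_site(self) -> np.ndarray:
        """(H, W) array of cluster ids."""
        return self.comp_cluster[self.site_map]

    def alive_clusters(self, *cell_types: int) -> list[int]:
        out = []
        for cid in self.cluster_comps:
            if cid == 0 or not self.clus_alive[cid]:
                continue
            if cell_types and int(self.clus_celltype[cid]) not in cell_types:
                continue
            out.append(cid)
        return out

    def cluster_volume(self, cluster_id: int) -> int:
        return int(
            sum(self.comp_volume[c] for c in self.cluster_comps[cluster_id])
        )

    def cluster_pixels(self, cluster_id: int) -> np.ndarray:
        """(n, 2) array of (row, col) sites belonging to the cluster."""
        mask = np.isin(self.site_map, np.asarray(self.cluster_comps[cluster_id]))
        return np.argwhere(mask)

    # ------------------------------------------------------------- painting
    def paint(self, rows, cols, comp_id: int) -> None:
        """Assign a block/selection of sites to a compartment, updating volumes."""
        old = self.site_map[rows, cols]
        ids, counts = np.unique(old, return_counts=True)
        np.subtract.at(self.comp_volume, ids, counts)
        self.site_map[rows, cols] = comp_id
        self.comp_volume[comp_id] += old.size

    def set_site(self, site: tuple[int, int], comp_id: int) -> None:
        r, c = site
        old = int(self.site_map[r, c])
        if old == comp_id:
            return
        self.comp_volume[old] -= 1
        self.comp_volume[comp_id] += 1
        self.site_map[r, c] = comp_id

    def remove_cluster(self, cluster_id: int) -> None:
        """Drop an empty cluster (and its compartments) from the registries."""
        if self.cluster_volume(cluster_id) != 0:
            raise ValueError(
                f"cluster {cluster_id} still occupies "
                f"{self.cluster_volume(cluster_id)} sites"
            )
        self.clus_alive[cluster_id] = False
        del self.cluster_comps[cluster_id]
        self.mucus_accumulator.pop(cluster_id, None)
        self.clus_growth_progress.pop(cluster_id, None)
        self.clus_birth_targets.pop(cluster_id, None)

    # ------------------------------------------------------------ integrity
    def recount_volumes(self) -> np.ndarray:
        """Recompute per-compartment volumes from the site map."""
        return np.bincount(self.site_map.ravel(), minlength=self.n_comps).astype(
            np.int64
        )

    def validate(self) -> None:
        """Check the registry invariants; raise AssertionError on breakage."""
        ids = np.unique(self.site_map)
        assert ids.max() < self.n_comps, "site map references unknown compartment"
        true_vol = self.recount_volumes()
        cached = self.comp_volume[: self.n_comps]
        assert np.array_equal(true_vol, cached), "cached volumes out of sync"
        seen: set[int] = set()
        for cid, comps in self.cluster_comps.items():
            for comp in comps:
                assert comp not in seen, f"compartment {comp} in two clusters"
                seen.add(comp)
                assert int(self.comp_cluster[comp]) == cid
        registered = {c for comps in self.cluster_comps.values() for c in comps}
        for comp_id in ids:
            assert int(comp_id) in registered, (
                f"compartment {comp_id} present on lattice but unregistered"
            )
        assert (self.comp_volume[: self.n_comps] >= 0).all()
        assert self.comp_lambda[0] == 0.0, "medium must have no volume constraint"


@dataclass
class PottsParams:
    """Potts dynamics parameters: temperature T, neighbor order, RNG seed."""

    temperature: float = 10.0
    neighbor_order: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("Potts temperature must be positive")
        if self.neighbor_order not in (1, 2, 3):
            raise ValueError("neighbor_order must be 1, 2 or 3")


# squared distances of the first three neighbor shells on a square lattice
_SHELL_D2 = (1, 2, 4)


def neighbor_offsets(order: int) -> list[tuple[int, int]]:
    """Lattice offsets of the first ``order`` neighbor shells.

    Order 1 is the von Neumann neighborhood (4 sites), order 2 the Moore
    neighborhood (8), order 3 adds the next shell at distance 2 for 12
    neighbors in total.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"unsupported neighbor order {order}; supported: 1, 2, 3")
    allowed = set(_SHELL_D2[:order])
    out = []
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            if (dr, dc) != (0, 0) and dr * dr + dc * dc in allowed:
                out.append((dr, dc))
    return out


def offsets_array(order: int) -> np.ndarray:
    return np.asarray(neighbor_offsets(order), dtype=np.int64)


def half_offsets(order: int) -> list[tuple[int, int]]:
    """One offset per unordered neighbor-pair direction (lexicographically
    positive representatives), so summing over them visits each pair once."""
    return [
        (dr, dc)
        for dr, dc in neighbor_offsets(order)
        if dr > 0 or (dr == 0 and dc > 0)
    ]
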