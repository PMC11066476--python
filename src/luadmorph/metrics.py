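"""Tissue-architecture scoring of simulated states.

Each alive cancer cell is assigned one of five contact categories from
the identities of its neighbors:

1. touches both luminal space and stromal tissue/mucus,
2. touches luminal space (but no stroma/mucus),
3. touches stromal tissue or mucus (but no lumen),
4. touches no other cancer cell at all,
5. touches only cancer cells.

Categories 4 and 5 take precedence (checked first), which makes the five
labels a partition of the cancer cells.  Normal-epithelial neighbors
count as stroma-side contact for the 2/3 split.  The second score is the
histogram of how many distinct cancer neighbors each cancer cell has.
Replicate tables of both scores, averaged, reproduce the published
heatmap layout; a rule-based classifier maps them to growth-pattern
labels (PPA/MPA/SPA/LPA-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import (
    CANCER,
    CELL_TYPE_NAMES,
    ECM,
    GROWING_STROMAL,
    MEDIUM,
    MUCUS,
    NORMAL,
    STROMAL,
    Lattice,
    half_offsets,
)

_LUMEN_TYPES = {MEDIUM}
_STROMA_MUCUS_TYPES = {STROMAL, GROWING_STROMAL, ECM, MUCUS, NORMAL}


@dataclass
class MetricsRecord:
    """Morphology scores for one snapshot."""

    mcs: int
    category_fractions: np.ndarray  # shape (5,)
    neighbor_histogram: dict[int, int]
    cell_counts: dict[str, int]

    @property
    def n_cancer(self) -> int:
        return sum(self.neighbor_histogram.values())

    @property
    def mean_cancer_neighbors(self) -> float:
        total = self.n_cancer
        if total == 0:
            return 0.0
        return sum(k * v for k, v in self.neighbor_histogram.items()) / total


class Adjacency:
    """Cluster adjacency with boundary lengths, over compacted ids.

    Cluster ids are never reused during a run, so a dense matrix indexed
    by raw id would grow quadratically with simulation length; ids are
    remapped to a compact range internally.
    """

    def __init__(self, counts: np.ndarray, ids: np.ndarray):
        self._counts = counts
        self._ids = ids  # compact index -> cluster id
        self._index = {int(c): i for i, c in enumerate(ids)}

    def neighbors(self, cluster_id: int) -> dict[int, int]:
        row = self._counts[self._index[int(cluster_id)]]
        return {
            int(self._ids[j]): int(row[j]) for j in np.flatnonzero(row)
        }


def cluster_adjacency(lattice: Lattice, order: int = 3) -> Adjacency:
    """Boundary-pair counts between every pair of touching clusters."""
    offs = np.asarray(half_offsets(order), dtype=np.int64)
    ids = np.asarray(sorted(lattice.cluster_comps), dtype=np.int64)
    remap = np.zeros(lattice.n_clusters, dtype=np.int32)
    remap[ids] = np.arange(len(ids), dtype=np.int32)
    comp_compact = remap[lattice.comp_cluster[: lattice.n_comps]]
    counts = _kernels.cluster_boundary_counts(
        lattice.site_map,
        comp_compact,
        offs,
        len(ids),
        lattice.boundary_mode == "periodic",
    )
    return Adjacency(counts, ids)


def cluster_neighbors(
    lattice: Lattice, cluster_id: int, order: int = 3, adjacency=None
) -> dict[int, int]:
    """Neighboring cluster ids with shared boundary lengths (pair counts).

    The medium (cluster 0) counts as a neighbor label like any other.
    """
    if cluster_id not in lattice.cluster_comps:
        raise KeyError(f"unknown cluster id {cluster_id}")
    if adjacency is None:
        adjacency = cluster_adjacency(lattice, order)
    return adjacency.neighbors(cluster_id)


def contact_category(
    lattice: Lattice, cancer_cluster_id: int, order: int = 3, adjacency=None
) -> int:
    """Contact category (1-5) of one alive cancer cell."""
    if int(lattice.clus_celltype[cancer_cluster_id]) != CANCER:
        raise ValueError(f"cluster {cancer_cluster_id} is not a cancer cell")
    neighbors = cluster_neighbors(lattice, cancer_cluster_id, order, adjacency)
    types = {int(lattice.clus_celltype[n]) for n in neighbors}
    if CANCER not in types:
        return 4
    non_cancer = types - {CANCER}
    if not non_cancer:
        return 5
    lumen = bool(non_cancer & _LUMEN_TYPES)
    stroma = bool(non_cancer & _STROMA_MUCUS_TYPES)
    if lumen and stroma:
        return 1
    if lumen:
        return 2
    return 3


def _alive_cancer(lattice: Lattice) -> list[int]:
    return lattice.alive_clusters(CANCER)


def category_fractions(
    lattice: Lattice, order: int = 3, adjacency=None
) -> np.ndarray:
    """Fraction of alive cancer cells in each contact category.

    Returns the zero vector when no cancer cell exists.
    """
    cancer = _alive_cancer(lattice)
    out = np.zeros(5)
    if not cancer:
        return out
    if adjacency is None:
        adjacency = cluster_adjacency(lattice, order)
    for cid in cancer:
        out[contact_category(lattice, cid, order, adjacency) - 1] += 1
    return out / len(cancer)


def neighbor_count_histogram(
    lattice: Lattice, order: int = 3, adjacency=None
) -> dict[int, int]:
    """Histogram of the number of distinct cancer neighbors per cancer cell."""
    cancer = _alive_cancer(lattice)
    if adjacency is None:
        adjacency = cluster_adjacency(lattice, order)
    hist: dict[int, int] = {}
    cancer_set = set(cancer)
    for cid in cancer:
        n = sum(1 for j in adjacency.neighbors(cid) if j in cancer_set)
        hist[n] = hist.get(n, 0) + 1
    return hist


def cell_counts(lattice: Lattice) -> dict[str, int]:
    out: dict[str, int] = {}
    for cid in lattice.alive_clusters():
        name = CELL_TYPE_NAMES[int(lattice.clus_celltype[cid])]
        out[name] = out.get(name, 0) + 1
    return out


def compute_metrics(lattice: Lattice, mcs: int, order: int = 3) -> MetricsRecord:
    """All morphology scores for one state with a single adjacency pass."""
    adjacency = cluster_adjacency(lattice, order)
    return MetricsRecord(
        mcs=mcs,
        category_fractions=category_fractions(lattice, order, adjacency),
        neighbor_histogram=neighbor_count_histogram(lattice, order, adjacency),
        cell_counts=cell_counts(lattice),
    )


def aggregate_replicates(records: list[MetricsRecord]) -> pd.DataFrame:
    """Mean and SD across replicate records, in the heatmap row layout:
    five category rows then one row per neighbor-count bin (fractions)."""
    if not records:
        raise ValueError("need at least one record")
    if len({len(r.category_fractions) for r in records}) != 1:
        raise ValueError("records have mixed schemas")
    max_bin = max((max(r.neighbor_histogram, default=0) for r in records), default=0)
    rows = []
    for r in records:
        total = max(1, r.n_cancer)
        hist = np.array(
            [r.neighbor_histogram.get(k, 0) / total for k in range(max_bin + 1)]
        )
        rows.append(np.concatenate([r.category_fractions, hist]))
    data = np.asarray(rows)
    index = [f"category_{i}" for i in range(1, 6)] + [
        f"neighbors_{k}" for k in range(max_bin + 1)
    ]
    return pd.DataFrame(
        {"mean": data.mean(axis=0), "sd": data.std(axis=0, ddof=0)}, index=index
    )


@dataclass
class ClassifierThresholds:
    """Explicit, tunable thresholds for the rule-based subtype labels."""

    dominance: float = 0.4  # a single fraction must reach this ...
    dominance_ratio: float = 1.5  # ... and exceed the runner-up by this factor
    pair_dominance: float = 0.5  # stricter bar for the summed 2+3 categories
    high_neighbors: float = 5.0  # mean cancer neighbors marking solid growth
    low_neighbors: float = 2.0  # mean cancer neighbors marking a monolayer


def classify_subtype(
    fractions: np.ndarray,
    histogram: dict[int, int],
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Rule-based growth-pattern label from the two scores."""
    t = thresholds or ClassifierThresholds()
    fractions = np.asarray(fractions, dtype=float)
    total = sum(histogram.values())
    mean_nb = (
        sum(k * v for k, v in histogram.items()) / total if total else 0.0
    )

    def dominant(value: float, others: list[float]) -> bool:
        runner = max(others) if others else 0.0
        return value >= t.dominance and value >= t.dominance_ratio * max(
            runner, 1e-12
        )

    f1, f2, f3, f4, f5 = fractions
    if dominant(f5, [f1, f2, f3, f4]) and mean_nb >= t.high_neighbors:
        return "SPA-like"
    pair = f2 + f3
    if (
        pair >= t.pair_dominance
        and pair >= t.dominance_ratio * max(f1, f4, f5, 1e-12)
        and t.low_neighbors <= mean_nb < t.high_neighbors
    ):
        return "MPA-like"
    if dominant(f1, [f2, f3, f4, f5]):
        if mean_nb < t.low_neighbors:
            return "LPA-like"
        if mean_nb < t.high_neighbors:
            return "PPA-like"
    return "indeterminate"
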