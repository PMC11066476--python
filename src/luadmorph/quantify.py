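"""Image and spot quantification statistics.

Three measurement families used alongside the simulations:

* **Spheroid shape index.**  From a binary mask, the perimeter P and
  area A give two independent radius estimates Rp = P/(2*pi) and
  Ra = sqrt(A/pi).  Normalizing by Ra yields nRp = Rp/Ra, nRa = 1, and
  the normalized perimeter/area nP = 2*pi*nRp, nA = pi*nRa^2 = pi.  The
  structural-complexity index nP/nA reduces algebraically to
  P / sqrt(pi * A): exactly 2 for an ideal circle, larger for any shape
  with protrusions, and invariant under rescaling.

* **Positive pixel ratio.**  The fraction of a segmented region's pixels
  that are marker-positive (e.g. KI67 or cleaved-Caspase-3 within a
  manually segmented tumor or stroma region).

* **3D spot statistics.**  Per fluorescent spot, the mean Euclidean
  distance to its k = 9 nearest neighbors; per spheroid and pooled
  summaries where the pooled mean comes from the total sum of distances
  over the total spot count and the pooled SD from the total sum of
  squared deviations.  Two-sample Student's t and variance-ratio F tests
  are assembled from those totals alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from skimage import measure


# ----------------------------------------------------------- shape index
@dataclass
class ShapeMeasures:
    """Perimeter/area measures and their normalized derivatives."""

    P: float
    A: float

    @property
    def Rp(self) -> float:
        return self.P / (2.0 * math.pi)

    @property
    def Ra(self) -> float:
        return math.sqrt(self.A / math.pi)

    @property
    def nRp(self) -> float:
        return self.Rp / self.Ra

    @property
    def nRa(self) -> float:
        return 1.0

    @property
    def nP(self) -> float:
        return 2.0 * math.pi * self.nRp

    @property
    def nA(self) -> float:
        return math.pi * self.nRa**2

    @property
    def index(self) -> float:
        return self.nP / self.nA


def perimeter_area(
    mask: np.ndarray, pixel_size: float = 1.0, method: str = "crofton"
) -> tuple[float, float]:
    """Perimeter and area of the (largest) foreground component.

    ``crofton`` (default) is the 4-direction Crofton-formula perimeter,
    the package's declared convention: like image-analysis tools'
    corner-corrected perimeters it converges to the true boundary length
    on smooth shapes (<1 % error on rasterized discs of radius >= 20).
    ``contour`` measures the marching-squares boundary polygon instead,
    and ``edge_count`` naively counts exposed pixel edges; both
    overestimate smooth boundaries (up to ~5 % and ~27 % on discs).
    """
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        warnings.warn(
            f"mask has {labels.max()} components; measuring the largest",
            stacklevel=2,
        )
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    area = float(mask.sum()) * pixel_size**2
    if method == "crofton":
        perim = float(measure.perimeter_crofton(mask, directions=4)) * pixel_size
    elif method == "contour":
        padded = np.pad(mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        lengths = [
            float(np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)).sum())
            for c in contours
        ]
        perim = max(lengths) * pixel_size
    elif method == "edge_count":
        perim = 0.0
        for axis in (0, 1):
            diff = np.diff(mask.astype(np.int8), axis=axis)
            perim += float(np.abs(diff).sum())
        for axis, edge in ((0, mask[0]), (0, mask[-1]), (1, mask[:, 0]), (1, mask[:, -1])):
            perim += float(edge.sum())
        perim *= pixel_size
    else:
        raise ValueError("method must be 'crofton', 'contour' or 'edge_count'")
    return perim, area


def shape_index(P: float, A: float) -> float:
    """Structural-complexity index nP/nA = P / sqrt(pi * A)."""
    if P <= 0 or A <= 0:
        raise ValueError("perimeter and area must be positive")
    return P / math.sqrt(math.pi * A)


def shape_measures(P: float, A: float) -> ShapeMeasures:
    if P <= 0 or A <= 0:
        raise ValueError("perimeter and area must be positive")
    return ShapeMeasures(P=P, A=A)


def mask_shape_index(
    mask: np.ndarray, pixel_size: float = 1.0, method: str = "crofton"
) -> ShapeMeasures:
    """Shape measures straight from a binary mask."""
    P, A = perimeter_area(mask, pixel_size, method)
    return ShapeMeasures(P=P, A=A)


# -------------------------------------------------------- positive ratio
def positive_ratio(marker_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """Fraction of region pixels that are marker-positive."""
    marker = np.asarray(marker_mask) != 0
    region = np.asarray(region_mask) != 0
    if marker.shape != region.shape:
        raise ValueError("marker and region masks must have the same shape")
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("empty region mask")
    return float((marker & region).sum()) / n_region


# ------------------------------------------------------- spot statistics
@dataclass
class SpotSet:
    """Labeled 3D spot coordinates with per-spot k-NN mean distances."""

    spheroid_label: str
    points: np.ndarray  # (n, 3) in micrometers
    k: int = 9
    distance_cutoff: float = 60.0  # visualization flag threshold, um
    per_spot_mean_distance: np.ndarray = field(default=None)
    threshold_flag: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.per_spot_mean_distance is None:
            self.per_spot_mean_distance, self.threshold_flag = knn_mean_distances(
                self.points, self.k, self.distance_cutoff
            )


def knn_mean_distances(
    points: np.ndarray, k: int = 9, cutoff: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per point, the mean distance to its k nearest other points.

    Points whose mean exceeds ``cutoff`` are flagged (the isolated-spot
    highlight rule).  The point itself is excluded from its neighbors.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    n = len(pts)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k} neighbors, got {n}")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    return mean_d, mean_d > cutoff


@dataclass
class PooledStats:
    """Per-spheroid and pooled summary of per-spot distances."""

    total_n: int
    total_mean: float
    total_sd: float
    per_spheroid: list[tuple[int, float, float]]


def pooled_stats(spotsets: list[SpotSet]) -> PooledStats:
    """Pool per-spot distances across spheroids from totals.

    The pooled mean is the total sum of distances over the total spot
    count; the pooled SD comes from the total sum of squared deviations
    about that mean (sample convention, n - 1).
    """
    if not spotsets:
        raise ValueError("need at least one spot set")
    per = []
    total_n = 0
    total_sum = 0.0
    for s in spotsets:
        d = s.per_spot_mean_distance
        n = len(d)
        per.append((n, float(d.mean()), float(d.std(ddof=1)) if n > 1 else 0.0))
        total_n += n
        total_sum += float(d.sum())
    total_mean = total_sum / total_n
    ss = 0.0
    for s in spotsets:
        d = s.per_spot_mean_distance
        ss += float(((d - total_mean) ** 2).sum())
    total_sd = math.sqrt(ss / (total_n - 1)) if total_n > 1 else 0.0
    return PooledStats(
        total_n=total_n, total_mean=total_mean, total_sd=total_sd, per_spheroid=per
    )


def two_sample_tests_from_totals(a: PooledStats, b: PooledStats) -> dict[str, float]:
    """Student's t (pooled variance) and variance-ratio F from summaries.

    The F statistic puts the larger variance in the numerator; both
    p-values are two-sided.
    """
    n1, n2 = a.total_n, b.total_n
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    v1, v2 = a.total_sd**2, b.total_sd**2
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both groups")
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t_stat = (a.total_mean - b.total_mean) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    t_p = 2.0 * stats.t.sf(abs(t_stat), n1 + n2 - 2)
    if v1 >= v2:
        f_stat, dfn, dfd = (v1 / v2 if v2 > 0 else math.inf), n1 - 1, n2 - 1
    else:
        f_stat, dfn, dfd = v2 / v1, n2 - 1, n1 - 1
    cdf = stats.f.cdf(f_stat, dfn, dfd)
    f_p = 2.0 * min(cdf, 1.0 - cdf)
    return {
        "t_statistic": float(t_stat),
        "t_p": float(t_p),
        "F_statistic": float(f_stat),
        "F_p": float(min(f_p, 1.0)),
    }


def spots_from_table(df: pd.DataFrame, k: int = 9, cutoff: float = 60.0) -> list[SpotSet]:
    """SpotSets from a table with columns spheroid, x_um, y_um, z_um."""
    required = {"spheroid", "x_um", "y_um", "z_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"spot table needs columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("spheroid", sort=True):
        pts = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        out.append(SpotSet(str(label), pts, k=k, distance_cutoff=cutoff))
    return out
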