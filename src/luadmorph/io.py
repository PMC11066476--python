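"""Reading and writing snapshots, metrics tables and run manifests.

Label snapshots are 16-bit single-channel PNG or TIFF images holding the
compartment id of each pixel, with a JSON sidecar mapping ids to their
cluster, cell type and compartment type.  Trajectory metrics go to TSV
(one row per recorded MCS) and the resolved configuration, seed included,
to a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .lattice import CELL_TYPE_NAMES, COMPARTMENT_TYPE_NAMES, Lattice


def write_snapshot(path, lattice: Lattice) -> None:
    """Write the label image (16-bit) and its JSON sidecar."""
    path = Path(path)
    if lattice.n_comps > np.iinfo(np.uint16).max:
        raise ValueError("too many compartments for a 16-bit label image")
    img = lattice.site_map.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    sidecar = {}
    for comp_id in np.unique(lattice.site_map):
        comp_id = int(comp_id)
        cluster = int(lattice.comp_cluster[comp_id])
        sidecar[str(comp_id)] = {
            "cluster": cluster,
            "cell_type": CELL_TYPE_NAMES[int(lattice.clus_celltype[cluster])],
            "compartment_type": COMPARTMENT_TYPE_NAMES[
                int(lattice.comp_type[comp_id])
            ],
        }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_snapshot(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return np.asarray(img), sidecar


def metrics_frame(records) -> pd.DataFrame:
    """Trajectory records as a flat table (one row per recorded MCS)."""
    rows = []
    for r in records:
        row = {"mcs": r.mcs}
        for i, f in enumerate(r.category_fractions, start=1):
            row[f"category_{i}"] = float(f)
        row["mean_cancer_neighbors"] = r.mean_cancer_neighbors
        row["n_cancer"] = r.n_cancer
        for name, count in sorted(r.cell_counts.items()):
            row[f"n_{name}"] = count
        row["neighbor_histogram"] = json.dumps(
            {str(k): v for k, v in sorted(r.neighbor_histogram.items())}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_metrics_tsv(records, path) -> None:
    metrics_frame(records).to_csv(path, sep="\t", index=False)


def _config_to_jsonable(config) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if hasattr(value, "to_dict"):
            out[f.name] = value.to_dict()
        elif dataclasses.is_dataclass(value):
            out[f.name] = dataclasses.asdict(value)
        elif isinstance(value, dict):
            out[f.name] = {
                str(k): (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in value.items()
            }
        else:
            out[f.name] = value
    return out


def write_manifest(config, path, seed: int | None = None) -> None:
    """Resolved run configuration (seed included) as JSON."""
    data = _config_to_jsonable(config)
    if seed is not None:
        data["seed"] = seed
    Path(path).write_text(json.dumps(data, indent=1, default=str))


def write_events_csv(events: list[dict], path) -> None:
    """Behavior event log (divisions, deaths, secretion) as CSV."""
    pd.DataFrame(events).to_csv(path, index=False)


def read_mask(path) -> np.ndarray:
    """Binary mask from a single-channel image file (nonzero = foreground)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img != 0


def read_spots_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"spheroid", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    return df
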