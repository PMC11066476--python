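"""Named model presets and initial-condition builders.

The base model reproduces the papillary growth pattern (PPA): a columnar
epithelial monolayer on a stromal bed, five cancer cells in the center,
cancer growth rate 0.03 px/MCS, contact energy 3 between tumor basal
membranes and stroma/matrix, and contact energy 40 between tumor apical
(and basal) membranes and the other tumor subdomains, run for 4000 MCS.
Every other preset is a small delta on this base:

==================  =========================================================
base_ppa            papillary reference model
mpa_growth3x        growth 0.09, 1400 MCS (micropapillary via fast growth)
mpa_low_adhesion    J(tumor basal, stroma/matrix) = 30 (detached papillae)
spa_growth10x       growth 0.3, 600 MCS (solid via very fast growth)
spa_low_polarity    J(tumor apical/basal, tumor subdomains) = 10
spa_uniform_j       all tumor subdomain pairs J = 10 (no polarity at all)
apa_mucus           base + mucus secretion (acinar)
lpa_v1              growth 0.022, death 0.00065 / 0.0001, 40000 MCS
lpa_v2              growth 0.3, death 0.002 / 0.001, contact inhibition
                    0.997, 37500 MCS (lepidic, second iteration)
ppa_stromal_growth  base + growing stroma/matrix at 0.02, 6000 MCS
spheroid_mixture    50:50 cancer/stromal disc in medium, equal growth
==================  =========================================================

Full-scale geometry is the 500 x 500 lattice with 10 x 30 columnar cells
and 10 replicates.  ``desk_scale`` shrinks a config to a 150 x 150
lattice with the step count divided by 4, leaving cell geometry and the
per-MCS rates untouched: desk runs show the same directional contrasts
between presets at proportionally smaller tumors, ~44x cheaper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .behaviors import BehaviorRates
from .energy import ContactEnergyMatrix
from .lattice import (
    APICAL,
    BASAL,
    CANCER,
    CYTOSOL,
    ECM,
    GENERIC,
    GROWING_STROMAL,
    LATERAL,
    NORMAL,
    STROMAL,
    Lattice,
    PottsParams,
)

PRESET_NAMES = (
    "base_ppa",
    "mpa_growth3x",
    "mpa_low_adhesion",
    "spa_growth10x",
    "spa_low_polarity",
    "spa_uniform_j",
    "apa_mucus",
    "lpa_v1",
    "lpa_v2",
    "ppa_stromal_growth",
    "spheroid_mixture",
)

# declared package defaults (baseline values are artifact choices; only the
# deltas between presets are taken from the source models)
BASELINE_J = 16.0
LAMBDA_VOLUME = 2.0
# Cumulative target-volume growth (px) that triggers division.  Chosen so
# the caption growth rates map to division times of ~330/110/33/455 MCS
# (base/3x/10x/lepidic-v1): fast enough that division outpaces the lepidic
# death rates (gain < growth/death for both lepidic models), slow enough
# that the base monolayer relaxes between divisions.
DIVISION_GAIN = 10.0


@dataclass
class ModelConfig:
    """One fully resolved simulation parameter set."""

    preset_name: str
    width: int = 500
    height: int = 500
    potts: PottsParams = field(default_factory=PottsParams)
    J: ContactEnergyMatrix = None
    J_internal: ContactEnergyMatrix = None
    rates: dict[int, BehaviorRates] = field(default_factory=dict)
    behavior_flags: dict[str, bool] = field(
        default_factory=lambda: {
            "contact_inhibition": False,
            "mucus": False,
            "stromal_growth": False,
        }
    )
    n_steps: int = 4000
    snapshot_interval: int = 500
    replicates: int = 10
    cell_width: int = 10
    cell_height: int = 30
    n_initial_cancer: int = 5
    stromal_bed_depth: int = 80
    boundary_mode: str = "fixed"
    connectivity_guard: bool = True
    spheroid_fill_fraction: float = 0.25
    adhesion_profile: str = "base"

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")


_EPI = ("cancer", "normal_epithelial")
_SUBDOMAINS = ("apical", "basal", "lateral", "cytosol")
_STROMA = ("stromal", "growing_stromal", "ecm")


def load_contact_config(path=None) -> tuple[ContactEnergyMatrix, ContactEnergyMatrix]:
    """The shipped (versioned) baseline contact-energy tables."""
    import json
    from importlib import resources

    if path is None:
        text = (
            resources.files("luadmorph") / "data" / "contact_energies_v1.json"
        ).read_text()
    else:
        text = open(path).read()
    data = json.loads(text)
    return (
        ContactEnergyMatrix(data["J"]),
        ContactEnergyMatrix(data["J_internal"]),
    )


def default_contact_matrix() -> ContactEnergyMatrix:
    """Baseline inter-cellular J table (artifact defaults; see module doc)."""
    J = ContactEnergyMatrix.full(BASELINE_J)
    # strong lateral-lateral adhesion stitches the epithelial sheet together
    for a in _EPI:
        for b in _EPI:
            J.set(f"{a}.lateral", f"{b}.lateral", 2.0)
    # apical membranes rest against the lumen
    for a in _EPI:
        J.set(f"{a}.apical", "medium", 4.0)
    # basal membranes adhere to the stromal bed; the other subdomains
    # avoid stroma (apico-basolateral polarity against the matrix)
    for a in _EPI:
        for s in _STROMA:
            J.set(f"{a}.basal", s, 3.0)
            for sub in ("apical", "lateral", "cytosol"):
                J.set(f"{a}.{sub}", s, 25.0)
    # the stromal bed and matrix hold together
    for i, a in enumerate(_STROMA):
        for b in _STROMA[i:]:
            J.set(a, b, 5.0)
    # mucus pools at apical surfaces
    for a in _EPI:
        J.set(f"{a}.apical", "mucus", 4.0)
    J.set("mucus", "mucus", 4.0)
    J.set("mucus", "medium", 8.0)
    return J


def default_internal_matrix() -> ContactEnergyMatrix:
    """Within-cell compartment adhesion: low J so cells stay in one piece."""
    J = ContactEnergyMatrix()
    for ct in _EPI:
        for i, a in enumerate(_SUBDOMAINS):
            for b in _SUBDOMAINS[i:]:
                J.set(f"{ct}.{a}", f"{ct}.{b}", 1.0)
    return J


def _set_tumor_apical_vs_subdomains(J: ContactEnergyMatrix, value: float) -> None:
    for sub in ("basal", "lateral", "cytosol"):
        J.set("cancer.apical", f"cancer.{sub}", value)


def _set_tumor_basal_vs_subdomains(J: ContactEnergyMatrix, value: float) -> None:
    for sub in ("apical", "lateral", "cytosol"):
        J.set("cancer.basal", f"cancer.{sub}", value)


def _set_tumor_basal_vs_stroma(J: ContactEnergyMatrix, value: float) -> None:
    for s in _STROMA:
        J.set("cancer.basal", s, value)


def _base_rates() -> dict[int, BehaviorRates]:
    return {
        CANCER: BehaviorRates(growth_rate=0.03, division_gain=DIVISION_GAIN),
        NORMAL: BehaviorRates(growth_rate=0.0, division_gain=DIVISION_GAIN),
        STROMAL: BehaviorRates(division_gain=DIVISION_GAIN),
        GROWING_STROMAL: BehaviorRates(division_gain=DIVISION_GAIN),
        ECM: BehaviorRates(division_gain=DIVISION_GAIN),
    }


def preset(name: str, **overrides) -> ModelConfig:
    """A fully resolved configuration for one named model."""
    if name not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    J, J_internal = load_contact_config()
    rates = _base_rates()
    flags = {"contact_inhibition": False, "mucus": False, "stromal_growth": False}
    n_steps = 4000

    # base model deltas (papillary reference)
    _set_tumor_apical_vs_subdomains(J, 40.0)
    _set_tumor_basal_vs_subdomains(J, 40.0)
    _set_tumor_basal_vs_stroma(J, 3.0)

    if name == "mpa_growth3x":
        rates[CANCER] = replace(rates[CANCER], growth_rate=0.09)
        n_steps = 1400
    elif name == "mpa_low_adhesion":
        _set_tumor_basal_vs_stroma(J, 30.0)
    elif name == "spa_growth10x":
        rates[CANCER] = replace(rates[CANCER], growth_rate=0.3)
        n_steps = 600
    elif name == "spa_low_polarity":
        _set_tumor_apical_vs_subdomains(J, 10.0)
        _set_tumor_basal_vs_subdomains(J, 10.0)
    elif name == "spa_uniform_j":
        for i, a in enumerate(_SUBDOMAINS):
            for b in _SUBDOMAINS[i:]:
                J.set(f"cancer.{a}", f"cancer.{b}", 10.0)
    elif name == "apa_mucus":
        flags["mucus"] = True
        rates[CANCER] = replace(rates[CANCER], mucus_secretion_rate=0.05)
    elif name == "lpa_v1":
        rates[CANCER] = replace(
            rates[CANCER], growth_rate=0.022, death_rate=0.00065
        )
        rates[NORMAL] = replace(rates[NORMAL], death_rate=0.0001)
        n_steps = 40000
    elif name == "lpa_v2":
        rates[CANCER] = replace(
            rates[CANCER],
            growth_rate=0.3,
            death_rate=0.002,
            contact_inhibition_factor=0.997,
        )
        rates[NORMAL] = replace(rates[NORMAL], death_rate=0.001)
        flags["contact_inhibition"] = True
        n_steps = 37500
    elif name == "ppa_stromal_growth":
        flags["stromal_growth"] = True
        rates[GROWING_STROMAL] = replace(
            rates[GROWING_STROMAL], stromal_growth_rate=0.02
        )
        rates[ECM] = replace(rates[ECM], stromal_growth_rate=0.02)
        n_steps = 6000
    elif name == "spheroid_mixture":
        profile = overrides.pop("adhesion_profile", "base")
        if profile == "low_adhesion":
            _set_tumor_basal_vs_stroma(J, 30.0)
        elif profile == "low_polarity":
            _set_tumor_apical_vs_subdomains(J, 10.0)
            _set_tumor_basal_vs_subdomains(J, 10.0)
        elif profile != "base":
            raise ValueError(
                "adhesion_profile must be base, low_adhesion or low_polarity"
            )
        # both cell types proliferate at the same rate
        rates[CANCER] = replace(rates[CANCER], growth_rate=0.03)
        rates[STROMAL] = replace(rates[STROMAL], growth_rate=0.03)
        overrides.setdefault("adhesion_profile", profile)

    config = ModelConfig(
        preset_name=name,
        J=J,
        J_internal=J_internal,
        rates=rates,
        behavior_flags=flags,
        n_steps=n_steps,
        **overrides,
    )
    return config


def desk_scale(
    config: ModelConfig,
    size: tuple[int, int] = (150, 150),
    step_factor: int = 4,
    stromal_bed_depth: int = 30,
) -> ModelConfig:
    """Shrink a full-scale config for desk-scale runs.

    The lattice shrinks to ``size`` and the run length divides by
    ``step_factor``; cell geometry and the per-MCS rates stay exactly as
    configured, so desk runs reproduce the direction of the inter-preset
    contrasts at proportionally smaller tumor sizes.
    """
    return replace(
        config,
        width=size[0],
        height=size[1],
        n_steps=max(1, config.n_steps // step_factor),
        snapshot_interval=max(1, config.snapshot_interval // step_factor),
        stromal_bed_depth=stromal_bed_depth,
    )


# --------------------------------------------------------------- builders
def _build_stromal_bed(lattice: Lattice, depth: int, growing_top: bool) -> None:
    """Tile rows [0, depth) with 10x10 stromal cells interleaved with 2x2
    blocks of 5x5 matrix pseudo-cells (checkerboard)."""
    tile = 10
    width = lattice.width
    for tr in range(depth // tile):
        for tc in range(width // tile):
            r0, c0 = tr * tile, tc * tile
            is_top_row = (tr + 1) * tile >= depth
            if (tr + tc) % 2 == 0:
                ct = GROWING_STROMAL if (growing_top and is_top_row) else STROMAL
                cid = lattice.new_cluster(ct, reference_volume=tile * tile)
                comp = lattice.new_compartment(
                    cid, GENERIC, float(tile * tile), LAMBDA_VOLUME
                )
                lattice.clus_birth_targets[cid] = {GENERIC: float(tile * tile)}
                lattice.clus_growth_progress[cid] = 0.0
                lattice.paint(
                    np.arange(r0, r0 + tile)[:, None],
                    np.arange(c0, c0 + tile)[None, :],
                    comp,
                )
            else:
                for sr in range(2):
                    for sc in range(2):
                        cid = lattice.new_cluster(ECM, reference_volume=25.0)
                        comp = lattice.new_compartment(
                            cid, GENERIC, 25.0, LAMBDA_VOLUME
                        )
                        lattice.clus_birth_targets[cid] = {GENERIC: 25.0}
                        lattice.clus_growth_progress[cid] = 0.0
                        lattice.paint(
                            np.arange(r0 + sr * 5, r0 + sr * 5 + 5)[:, None],
                            np.arange(c0 + sc * 5, c0 + sc * 5 + 5)[None, :],
                            comp,
                        )


def _build_columnar_cell(
    lattice: Lattice, cell_type: int, r0: int, c0: int, w: int, h: int
) -> int:
    """One columnar epithelial cell: basal rows at the bottom (stroma side),
    apical rows at the top (lumen side), 1-px lateral strips, cytosol core."""
    cid = lattice.new_cluster(cell_type, reference_volume=float(w * h))
    margin = 3
    comp_apical = lattice.new_compartment(cid, APICAL, 0.0, LAMBDA_VOLUME)
    comp_basal = lattice.new_compartment(cid, BASAL, 0.0, LAMBDA_VOLUME)
    comp_lateral = lattice.new_compartment(cid, LATERAL, 0.0, LAMBDA_VOLUME)
    comp_cytosol = lattice.new_compartment(cid, CYTOSOL, 0.0, LAMBDA_VOLUME)
    rows = np.arange(r0, r0 + h)[:, None]
    cols = np.arange(c0, c0 + w)[None, :]
    lattice.paint(rows, cols, comp_cytosol)
    lattice.paint(np.arange(r0, r0 + margin)[:, None], cols, comp_basal)
    lattice.paint(np.arange(r0 + h - margin, r0 + h)[:, None], cols, comp_apical)
    mid = np.arange(r0 + margin, r0 + h - margin)[:, None]
    lattice.paint(mid, np.array([[c0, c0 + w - 1]]), comp_lateral)
    for comp in (comp_apical, comp_basal, comp_lateral, comp_cytosol):
        lattice.comp_target[comp] = float(lattice.comp_volume[comp])
    lattice.clus_birth_targets[cid] = {
        int(lattice.comp_type[c]): float(lattice.comp_target[c])
        for c in (comp_apical, comp_basal, comp_lateral, comp_cytosol)
    }
    lattice.clus_growth_progress[cid] = 0.0
    return cid


def build_initial_epithelium(config: ModelConfig) -> Lattice:
    """Stromal bed, one row of columnar cells with the centered cancer
    clone, lumen above.  All compartments start at their target volume."""
    needed = config.stromal_bed_depth + config.cell_height + 10
    if config.height < needed:
        raise ValueError(
            f"lattice height {config.height} too small; need at least {needed} "
            "(stromal bed + epithelium + lumen)"
        )
    lattice = Lattice(config.width, config.height, config.boundary_mode)
    _build_stromal_bed(
        lattice,
        config.stromal_bed_depth,
        growing_top=config.behavior_flags.get("stromal_growth", False),
    )
    n_cells = config.width // config.cell_width
    first_cancer = (n_cells - config.n_initial_cancer) // 2
    for i in range(n_cells):
        cell_type = (
            CANCER
            if first_cancer <= i < first_cancer + config.n_initial_cancer
            else NORMAL
        )
        _build_columnar_cell(
            lattice,
            cell_type,
            config.stromal_bed_depth,
            i * config.cell_width,
            config.cell_width,
            config.cell_height,
        )
    lattice.validate()
    return lattice


def build_initial_spheroid_mixture(
    config: ModelConfig, rng: np.random.Generator
) -> Lattice:
    """A disc of randomly interleaved cancer and stromal cells (50:50) in
    medium, emulating a mixed-spheroid culture."""
    radius = math.sqrt(
        config.spheroid_fill_fraction * config.width * config.height / math.pi
    )
    cr, cc = config.height / 2.0, config.width / 2.0
    if radius > min(cr, cc):
        raise ValueError("spheroid disc does not fit on the lattice")
    rr, cc_grid = np.mgrid[0 : config.height, 0 : config.width]
    inside = (rr - cr + 0.5) ** 2 + (cc_grid - cc + 0.5) ** 2 <= radius**2
    tile = 10
    # assign every disc pixel to the 10x10 tile it falls in
    tile_id = (rr // tile) * (config.width // tile + 1) + (cc_grid // tile)
    tiles = {}
    for r, c in np.argwhere(inside):
        tiles.setdefault(int(tile_id[r, c]), []).append((r, c))
    # merge fragments smaller than a quarter cell into a neighboring tile
    min_size = tile * tile // 4
    keys = sorted(tiles)
    for key in keys:
        if len(tiles[key]) < min_size and len(tiles) > 1:
            pix = tiles.pop(key)
            neighbors = [k for k in (key - 1, key + 1) if k in tiles]
            target = neighbors[0] if neighbors else next(iter(tiles))
            tiles[target].extend(pix)
    cells = [np.asarray(p) for p in tiles.values()]
    n = len(cells)
    types = [CANCER] * ((n + 1) // 2) + [STROMAL] * (n // 2)
    types = list(rng.permutation(np.asarray(types, dtype=np.int8)))

    lattice = Lattice(config.width, config.height, config.boundary_mode)
    from .behaviors import _rebuild_cluster  # shared compartment rebuilder

    generic_first = []
    for pixels, ct in zip(cells, types):
        ct = int(ct)
        if ct == STROMAL:
            cid = lattice.new_cluster(STROMAL, reference_volume=float(len(pixels)))
            comp = lattice.new_compartment(
                cid, GENERIC, float(len(pixels)), LAMBDA_VOLUME
            )
            lattice.paint(pixels[:, 0], pixels[:, 1], comp)
        else:
            generic_first.append(pixels)
    # cancer cells second, so their boundary classification sees the stroma
    for pixels in generic_first:
        v = float(len(pixels))
        _rebuild_cluster(
            lattice,
            pixels,
            CANCER,
            compartmental=True,
            target_by_type={APICAL: v, BASAL: v, LATERAL: v, CYTOSOL: v},
            lam_by_type={t: LAMBDA_VOLUME for t in (APICAL, BASAL, LATERAL, CYTOSOL)},
            fraction=0.25,
            parent_cluster=-1,
        )
    # set targets to the built volumes so the start is mechanically relaxed
    n_comp = lattice.n_comps
    lattice.comp_target[1:n_comp] = lattice.comp_volume[1:n_comp].astype(float)
    for cid, comps in lattice.cluster_comps.items():
        if cid == 0:
            continue
        lattice.clus_birth_targets[cid] = {
            int(lattice.comp_type[c]): float(lattice.comp_target[c])
            for c in comps
        }
        lattice.clus_growth_progress[cid] = 0.0
    lattice.validate()
    return lattice


def build_initial_lattice(
    config: ModelConfig, rng: np.random.Generator | None = None
) -> Lattice:
    if config.preset_name == "spheroid_mixture":
        if rng is None:
            rng = np.random.default_rng(config.potts.rng_seed)
        return build_initial_spheroid_mixture(config, rng)
    return build_initial_epithelium(config)


def run_preset(
    config: ModelConfig,
    seed: int | None = None,
    record_interval: int | None = None,
    snapshot_interval: int | None = None,
):
    """Build the initial state for a config and run its full schedule."""
    from .engine import run_mcs

    potts = config.potts
    if seed is not None:
        potts = replace(potts, rng_seed=seed)
    rng = np.random.default_rng(potts.rng_seed)
    lattice = build_initial_lattice(config, rng)
    from .behaviors import make_hooks

    hooks = make_hooks(
        config.rates,
        contact_inhibition=config.behavior_flags.get("contact_inhibition", False),
        mucus=config.behavior_flags.get("mucus", False),
        stromal_growth=config.behavior_flags.get("stromal_growth", False),
    )
    traj = run_mcs(
        lattice,
        potts,
        config.J,
        config.n_steps,
        J_internal=config.J_internal,
        hooks=hooks,
        record_interval=record_interval
        if record_interval is not None
        else config.snapshot_interval,
        snapshot_interval=snapshot_interval or 0,
        connectivity_guard=config.connectivity_guard,
    )
    return lattice, traj
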