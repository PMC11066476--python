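# Methods

## Model

`luadmorph` simulates the growth patterns of lung adenocarcinoma (LUAD)
tissue — papillary (PPA), micropapillary (MPA), acinar (APA), solid
(SPA) and lepidic (LPA) — with a two-dimensional compartmental cellular
Potts model (CPM). A configuration assigns each lattice site to a
*compartment*; compartments group into *clusters*, where a cluster is
one biological object. Epithelial cells (cancer and normal) are
compartmentalized into apical, basal, lateral and cytosolic subdomains,
which is how apico-basolateral polarity enters the energy function.
Stromal cells, portions of extracellular matrix (ECM) and mucus are
single-compartment pseudo-cells. The medium (luminal space) is label 0
and carries no volume constraint.

The energy is the standard CPM Hamiltonian

    H = Σ_pairs J(label_i, label_j) · [comp_i ≠ comp_j]
      + Σ_comps λ (V − V*)²

with the neighbor sum over the first three neighbor shells (12 neighbors
per pixel), where a site's label is its (cell type, compartment type)
pair. Two contact tables are used: `J` for boundaries between different
clusters and `J_internal` (low, default 1) for boundaries between
compartments of the same cell, which keeps cells in one piece. No
surface-length constraint is applied to any object.

Dynamics are Metropolis copy attempts: pick a random site and a random
neighbor; if they belong to different compartments, overwrite the site
with the neighbor's id with probability min(1, exp(−ΔH/T)) at Potts
temperature T = 10. One Monte Carlo Step (MCS) is width×height attempts
and represents ≈2 h of tissue time. The ΔH used by the compiled sweep
kernel is checked against a full-recompute oracle in the tests (1e−9).

An optional local connectivity guard rejects copies that would split a
compartment (checked on the 8-ring around the target pixel). The tissue
presets enable it because the thin apical/lateral strips of columnar
cells fragment easily at T = 10; the plain CPM default (fragmentation
allowed) is available by flag.

Boundary conditions are no-flux: out-of-lattice neighbors simply do not
exist, for energy sums and site picks alike, so the tissue cannot wrap.
Periodic boundaries are available by configuration.

## Behaviors

Biological rules fire once per MCS after the attempt sweep, in the fixed
order growth → death → mucus secretion → stromal growth → mitosis
(mitosis last so daughters are consistent at snapshot time).

**Growth.** A growth rate g adds g pixels of target volume per MCS to
the cell's growing compartment (cytosol for epithelial cells). The same
increment accrues on a per-cell *growth clock*. Under contact
inhibition, a cell touching another cancer or normal epithelial cell
grows at 99.7% of its set rate (factor 0.997).

**Division.** A cell divides when its growth clock reaches the division
gain g\* (default 10 px), provided it has physically reached 80% of its
target volume (squeezed cells wait — mechanics gates the clock). The
division time of an unobstructed cell is therefore g\*/g MCS: ~330 MCS
at the papillary growth rate 0.03, ~110 at 0.09, ~33 at 0.3 and ~450 at
the lepidic rate 0.022. The gain is a declared calibration for a
quantity the source models do not print; it was chosen so that (i)
division outpaces death in both lepidic parameter sets (g\* < g/d for
g = 0.022, d = 6.5e−4 and for g = 0.3, d = 2e−3 — otherwise those
tissues are driven extinct, contrary to the published morphologies) and
(ii) the base monolayer has time to relax mechanically between
divisions. A pure 2× volume-doubling trigger is the function's default
when no gain is configured and is what the geometric division tests
exercise.

Epithelial cells divide *in plane*: the cut runs along the apical-basal
polarity axis (basal→apical compartment centroids), so both daughters
keep lumen and stroma contact and the monolayer lengthens — the driver
of the buckling/papillation mechanism. Non-compartmental pseudo-cells
are cut perpendicular to their longest principal axis. Daughters are
reborn with the parent's full birth-size target profile (they regrow to
normal size before the next division) and their compartments are
rebuilt geometrically: apical and basal slabs at the ends of the
polarity axis sized by the birth profile's shares, lateral where the
middle slab touches other epithelial cells, cytosol elsewhere, with a
one-pixel fallback so all four subdomains always exist.

**Death.** A death rate d is a per-MCS Bernoulli probability per cell.
Apoptosis zeroes the cell's target volumes (λ unchanged) so the Potts
dynamics shrinks it; empty clusters are purged from the registries.
Survival of non-dividing cells follows (1−d)^t exactly in expectation.

**Mucus secretion** (acinar model). Each cancer cell whose apical
membrane faces the lumen accumulates fractional secretion (default 0.05
px/cell/MCS, a declared default); each whole unit converts one medium
pixel adjacent to the apical membrane — or adjacent to mucus already
attached to it, so the secreted pool keeps growing outward — into a
mucus pseudo-cell pixel. Mucus aggregates into pseudo-cells of at most
9 px.

**Stromal growth** (papillary model, second iteration). Growing-stroma
and ECM pseudo-cells in neighbor-order contact with a cancer basal
membrane gain 0.02 px of target volume per MCS and divide by the same
mitosis rule.

## Presets

The base (papillary) model: 500×500 lattice, a stromal bed (10×10
stromal cells interleaved with 5×5 ECM pseudo-cells, bed depth 80 px), a
single row of 10×30 columnar epithelial cells, the centered 5 cells
cancerous, the rest lumen; cancer growth 0.03; J(tumor basal,
stroma/ECM) = 3; J(tumor apical, other tumor subdomains) = 40 and
likewise for tumor basal; 4000 MCS; 10 replicates. The other presets are
the documented deltas (growth 0.09/0.3/0.022, basal-stroma J 30,
polarity J 10, uniform tumor J 10, mucus on, death rates
0.00065/0.0001 and 0.002/0.001 with contact inhibition, stromal growth
0.02, and the 50:50 cancer/stromal spheroid-mixture disc).

Only the deltas are claims about the source models; the baseline matrix
is a declared package default: neutral J = 16, epithelial lateral-lateral
2 (the sheet's stitch), apical-medium 4, basal-stroma 3, non-basal
subdomains vs stroma 25 (polarity against the matrix), stroma-stroma 5,
mucus-apical 4. λ = 2 for every volume-constrained compartment.
Caption deltas that name tumor subdomain pairs are applied to the
*inter-cellular* table: an apical membrane with J = 40 to other tumor
subdomains repels neighboring cells, which is the polarity mechanism the
models rely on; applying them inside one cell would instead push a
cell's own subdomains apart.

`desk_scale` shrinks a preset to a 150×150 lattice with steps ÷ 4 and a
30 px bed, leaving cell geometry and the per-MCS rates untouched. Desk
runs therefore accumulate a quarter of the full-scale growth on ~1/11 of
the area — tumors are proportionally smaller, and what is preserved is
the *direction* of every inter-preset contrast (aggregation under 10×
growth, stromal detachment under low adhesion, neighborhood thinning in
the revised lepidic model), not the absolute scores. The tests and the
acceptance script run at desk scale with 5 seeds per preset; full scale
is available through the CLI.

## Morphology scores

Every alive cancer cell is scored by what it touches (two clusters are
neighbors if any of their pixels are within the neighbor order):
category 4 if it touches no other cancer cell; else 5 if it touches
only cancer; else 1/2/3 by whether it touches lumen and/or
stroma-or-mucus. This precedence makes the five categories a partition;
normal-epithelial contact counts as stroma-side for the 2/3 split. The
second score is the histogram of distinct cancer neighbors per cancer
cell. Replicate tables are aggregated element-wise (mean ± SD). The
rule-based subtype classifier (dominance 0.4 at 1.5× the runner-up,
pair dominance 0.5 for categories 2+3, high/low mean-neighbor bounds
5.0/2.0) uses declared, tunable thresholds calibrated on the package's
own desk-scale output; they are not claims about the source data.

## Quantification statistics

The spheroid shape index normalizes perimeter P and area A through two
radius estimates (Rp = P/2π, Ra = √(A/π)); the index nP/nA reduces to
P/√(πA): 2 for an ideal circle, larger with protrusions, scale
invariant. Mask perimeters default to the 4-direction Crofton estimate,
which converges to the true boundary length on smooth shapes (<1% on
discs of radius ≥20); a marching-squares contour length and a naive
edge count are available by flag (they overestimate discs by ~5% and
~27%).

Marker quantification is the positive-pixel fraction of a segmented
region. 3D spot analysis computes, per spot, the mean Euclidean
distance to its 9 nearest neighbors (the spot itself excluded; spots
above a 60 μm cutoff are flagged for display). Group summaries pool
across spheroids *from totals*: total mean = total sum of distances /
total spots; total SD from the total sum of squared deviations (sample
convention, n−1). The two-sample tests are assembled from those totals
alone: Student's pooled-variance t (Welch available by flag) and the
variance-ratio F with the larger variance in the numerator, df = n−1
each, two-sided p = 2·min(tail, 1−tail). Both are cross-checked against
scipy's reference distributions in the tests.

## Synthetic data

The fixture generators emulate the study's measured inputs with known
ground truth: rasterized discs (smooth knockdown-like spheroids) and
star masks r(θ) = R + a·cos(kθ) (protrusion-bearing control-like
spheroids); marker/region mask pairs holding exactly round(f·size)
positive pixels; and 3D spot sets — uniform in a 200 μm sphere versus
"patchy and peripheral": Gaussian clusters (4 clusters, SD 15 μm,
uneven sizes) plus a 15% scattered fraction, built so the per-spot 9-NN
means spread wider than the uniform geometry at matched n. Random
20×20 label lattices with random J and λ exercise the energy
bookkeeping. All generators are bit-reproducible from their seed.

What the generators do not emulate: imaging noise, point-spread
functions, segmentation errors, anisotropic voxels, or the biological
variability of real spheroids. Passing round-trip tests shows the
estimators recover known ground truth under ideal conditions, not that
they are robust to real microscopy artifacts.

## Numerical choices and reproducibility

The Monte Carlo kernel uses an explicit xorshift128+ generator seeded by
splitmix64 from the run seed; behavior hooks draw from a separately
seeded numpy generator in a fixed order. Runs are bit-reproducible from
(configuration, seed). ΔH ≤ 0 short-circuits the exponential, so no
overflow occurs under high pressure. Cluster ids are never reused;
adjacency computations remap live ids to a compact range so their cost
does not grow with simulation history. Degenerate division cuts (an
empty daughter) skip the split and retry on a later MCS; dividing cells
with degenerate polarity fall back to the principal-axis cut.

## Known limitations

- 2D only; no chemotaxis or diffusible fields (not used by the models
  reproduced here).
- Absolute time calibration is nominal: the division clock reproduces
  the *relative* ordering of the published growth rates, not a measured
  cell-cycle length.
- The baseline contact-energy matrix and λ are declared defaults, not
  fitted values; only the documented deltas are grounded in the source
  models.
- Desk-scale runs reproduce directional contrasts, not the absolute
  category fractions of full-scale runs.
- The subtype classifier is a convenience built on two summary scores;
  overlapping intermediate morphologies return "indeterminate".
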