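# Methods

## The landscape model

A landscape is a 2-D lattice of integer class codes with cell sizes
`(cell_width, cell_height)` in meters and an integer nodata code (default 0
when neither file metadata nor an override supplies one). Class codes are
categories: float rasters are rejected rather than cast, because a truncated
class code is a silent data error. The lattice is frozen at construction —
every expensive intermediate (patch labeling, patch geometry, adjacency
counts, nearest-neighbor distances) is cached on the instance, which is only
sound if the cells cannot change underneath the cache. Memory grows linearly
with the number of patches.

## Patches, perimeters, adjacency

**Segmentation.** A patch is a maximal connected set of same-class cells
under the chosen neighborhood rule. The default connectivity is 8
(diagonal neighbors merge), matching the FRAGSTATS convention; 4 is
available. Each class is labeled with `scipy.ndimage.label` and labels are
renumbered into row-major first-contact order so that patch ids are
reproducible and independent of class code ordering.

**Perimeter.** Perimeters are side-based: a cell side is exposed when the
rook neighbor belongs to a different class, is nodata, or lies off the
raster — the raster border therefore always counts toward patch perimeter.
Sides facing north/south measure `cell_width` meters, sides facing west/east
`cell_height`, so perimeters remain correct for rectangular cells.

**Adjacency.** The class adjacency table counts every interior shared cell
side exactly once per unordered cell pair, with nodata kept as a
pseudo-class and raster-border sides tallied separately per class.
Adjacencies are rook-only regardless of patch connectivity, because edge
metrics are side-length quantities by definition. The count is a single
vectorized pass (class codes encoded to small integers, neighbor pairs
mapped to canonical linear indices, `np.bincount`), O(#cells) in time and
memory. Per-direction counts are retained so side counts convert to meters
for rectangular cells.

**Nearest neighbors.** The Euclidean nearest-neighbor distance of a patch is
the minimum cell-center-to-cell-center distance to any other patch of the
same class, in meters. Only boundary cells are searched (the minimum between
disjoint cell sets is attained at boundary cells) using one k-d tree per
patch complement within the class; the result is contractually identical to
the all-pairs brute force, and the test suite verifies exact (bit-level)
agreement with an enumeration oracle. A class with a single patch has an
*undefined* distance, represented as NaN — never zero-filled — and dropped
from distribution statistics with a warning when a scope has no defined
value. Nearest-neighbor distances are by far the most expensive quantity;
they are computed only when a metric of the `euclidean_nearest_neighbor`
family is actually requested, which instrumentation counters
(`n_segmentation_runs`, `n_adjacency_runs`, `n_enn_runs`) make observable.

## Metric conventions

Defaults follow FRAGSTATS v4: `percent=True`, `hectares=True`,
`count_boundary=False` (edges between data and nodata cells, including the
raster boundary, are not counted unless asked for). Choices worth stating
explicitly:

- **Minimum perimeter.** With `a = ⌊√n⌋`, the maximally compact raster patch
  of `n` cells has perimeter `4a` (perfect square), `4a+2` when
  `n ≤ a(a+1)`, else `4a+4`. The shape index divides a patch's side count by
  this reference; the landscape shape index divides the boundary-inclusive
  edge-side total by the same reference evaluated at the scope's cell count
  (class-level LSI uses the class's own boundary-inclusive sides, the
  FRAGSTATS reading).
- **Side-count metrics and rectangular cells.** Shape index and landscape
  shape index are defined in side counts and therefore require square
  cells; for rectangular cells they return NaN with a warning rather than a
  silently unit-inconsistent number. All length- and area-based metrics
  remain defined.
- **Fractal dimension.** `2·ln(0.25·p)/ln(a)` with p in m and a in m². The
  formula is degenerate for a 1 m² patch (NaN) and carries a known
  small-patch bias (a single 100 m cell gives exactly 1, other resolutions
  do not); the raw formula value is returned.
- **Edge density units.** The per-m² form is the per-hectare form divided by
  10⁴ — implemented literally as that division so the two reported numbers
  are exact decimal shifts of one another. Patch density handles `hectares`
  the same way.
- **Standard deviations are population (ddof = 0)** standard deviations,
  matching FRAGSTATS; the coefficient of variation is `100·sd/mean`. The
  area-weighted mean `_am` weights each patch by its area. Landscape-level
  distribution statistics pool all patches regardless of class.
- **Contagion** uses the FRAGSTATS double-count row normalization: the
  ordered adjacency matrix counts every unordered like-pair from both cells
  (diagonal doubled) before rows are normalized, and nodata adjacencies are
  excluded. `CONTAG = [1 + Σ P₍g,k₎ ln P₍g,k₎ / (2 ln m)]·100` with
  `P₍g,k₎ = p_g · g₍g,k₎`; zero terms contribute zero and a single-class
  landscape is NaN. Note that a two-class checkerboard yields 50, not 0:
  the formula's minimum requires all m² adjacency states to be equally
  frequent (like adjacencies included), which an equal-share random mosaic
  approaches but a perfect checkerboard does not.
- **Empty scopes.** An all-nodata landscape yields empty patch/class tables
  and NaN (not errors) for undefined landscape aggregates; total area and
  patch counts are 0.

Metric functions are pure (summaries in, scalar out); the data-frame
builders are the only layer touching the cache. Requesting a subset of
metrics never changes any value — the subset table equals the column subset
of the full table. Labels valid at another level are silently dropped by the
class/landscape builders (Shannon diversity requested at class level simply
does not appear), while the patch builder rejects non-patch labels;
`metrics_kws` keys must name known labels with schema-valid options.

## Multi-landscape analyses

All four drivers reduce to "a list of landscapes plus an index scheme":
class tables are indexed `(class_val, dates)`, `(class_val, buffer_dist)` or
`(class_val, attribute)`, landscape tables by the ordinate alone, and the
spatiotemporal-buffer combination by `(buffer_dist, class_val, dates)` /
`(buffer_dist, dates)`. Dates are accepted as integers, ISO strings or
timestamps and are used purely as ordered labels — no date arithmetic.
Classes absent from an individual zone or snapshot produce NaN rows, so the
index is rectangular across the union of classes.

**Zone derivation.** A zone landscape is the input with out-of-mask cells
set to nodata. With the default `count_boundary=False` the zone border
therefore does not contribute to edge metrics, consistent with the
single-landscape boundary convention. Generic zones may overlap; each is an
independent masked landscape.

**Buffer rasterization.** Buffers are built with shapely and rasterized by
the cell-center-in-polygon rule: a cell belongs to a buffer iff its center
lies inside the buffer polygon. This rule is deterministic and makes ring
masks an exact partition of the outermost buffer (an all-touched rule would
not). Rings are the set differences of consecutive cumulative buffers, the
first running from the geometry itself (distance 0) to the first distance;
labels are `"start-end"` strings. For a polygon base geometry the rings
exclude the polygon's own cells; a leading distance of 0 yields the polygon
region itself as a zone. Geometries must be supplied in the grid's
coordinate reference system — the package performs no reprojection, and a
declared CRS mismatch raises rather than guessing.

## Synthetic landscapes and oracles

The shipped generators exist so that every algorithm can be audited without
external data. `blocks_landscape` paints rectangles whose patch count,
area and perimeter are known in closed form; `reference_patch_landscape` constructs
three free-form polyominoes with side counts 106/26/6 at cell counts
115/13/2 (a rectangle-plus-tail, a 2×2 block with a tail forming one cycle,
and a domino), chosen so that the patch table reproduces the reference
patch-metric values end-to-end from a raster rather than from a formula
call. `random_mosaic` draws each cell i.i.d. from a categorical
distribution with `numpy.random.default_rng` (PCG64), so seeds reproduce
across platforms.

I.i.d. mosaics are deliberately structureless: they exercise every code
path (many small patches, all adjacency states) but do not emulate the
spatial autocorrelation, patch-size distributions or class geometry of real
land-cover data. Passing tests on them demonstrates algorithmic
correctness — segmentation, counting, distances, identities — not realism
of any ecological interpretation; realistic neutral-landscape models are
out of scope.

The `oracle_*` functions are independent reference implementations —
stack-based flood fill, exhaustive side enumeration, all-pairs distance
minimization — that are quadratic and intended for lattices up to ~10⁴
cells. The acceptance suite checks exact agreement between the fast paths
and the oracles on 50 seeded mosaics up to 50×50 (mixed class counts,
nodata fractions and connectivities); consistency identities (PLAND summing
to 100, class edge totals double-counting the landscape total, NP and LPI
aggregation, SHDI limits) run on 20 seeded 30×30 mosaics. These sizes keep
the whole suite fast while covering every branch; all algorithms are
size-independent.

## Known limitations

- GeoTIFF support covers single-band integer rasters with axis-aligned
  georeferencing (pixel-scale/tiepoint or a model-transformation matrix);
  rotated affines can be read but not written, and there is no reprojection
  or resampling.
- Core-area, proximity, contiguity, aggregation-index, splitting/division
  and Simpson-diversity metric families are not implemented; neither are
  moving-window analyses, transition matrices between dates, or grain
  rescaling.
- Vector input is limited to shapely geometries, WKT and GeoJSON;
  Shapefile/GeoPackage readers are not bundled.
- Nearest-neighbor search is exact but per-patch; landscapes with very many
  patches of one class are the slow case.
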