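# patchstats

Landscape-pattern metrics on categorical rasters, for landscape ecologists
and anyone quantifying the spatial structure of a class mosaic (land use /
land cover maps, habitat maps, segmented imagery).

A landscape is modelled as a grid of integer class codes with a cell size in
meters and a nodata code. Maximal connected sets of same-class cells under a
4- or 8-neighbor rule are *patches*; from the patches, the cell-side
adjacency structure and the inter-patch nearest-neighbor distances,
`patchstats` computes the classic FRAGSTATS v4 family of metrics at three
levels:

- **patch level** — area *aᵢⱼ*, perimeter *pᵢⱼ*, perimeter–area ratio,
  shape index *pᵢⱼ / min-p(nᵢⱼ)* (where min-p(n) is the perimeter of the
  maximally compact arrangement of *n* cells), fractal dimension
  *2 ln(0.25 pᵢⱼ) / ln aᵢⱼ*, and Euclidean nearest neighbor *hᵢⱼ*
  (cell-center to cell-center, to the closest same-class patch);
- **class level** — total area CA, proportion of landscape PLAND = CA/A,
  number of patches NP, patch density PD = 100·NP/A, largest patch index
  LPI, total edge TE, edge density ED = TE/A, landscape shape index
  LSI = E*/min-p(n), plus six distribution statistics (mean `_mn`,
  area-weighted mean `_am`, median `_md`, range `_ra`, population standard
  deviation `_sd`, coefficient of variation `_cv`) of every patch metric;
- **landscape level** — the same aggregates pooled over all classes,
  Shannon's diversity index SHDI = −Σ pᵢ ln pᵢ, and contagion
  CONTAG, built from class proportions and cell-side adjacency frequencies
  *e₍g,k₎*.

In total the registry exposes 95 level-qualified metric labels. On top of the
single-landscape analysis sit four multi-landscape drivers: spatiotemporal
series, buffer gradients (and the rings between buffer distances) around a
feature of interest, generic zonal decomposition via boolean masks, and the
spatiotemporal-buffer combination — each producing a tidy `pandas` table
with a documented index scheme and a `plot_metric` trend plot.

## Worked example

```python
import patchstats as ps

ls = ps.reference_patch_landscape()          # three reference polyominoes at 100 m
print(ls.compute_patch_metrics_df())
```

```
          class_val   area  perimeter  perimeter_area_ratio  shape_index  fractal_dimension  euclidean_nearest_neighbor
patch_id
0                 1  115.0    10600.0             92.173913     2.409091           1.129654                  500.000000
1                 1   13.0     2600.0            200.000000     1.625000           1.100096                  223.606798
2                 1    2.0      600.0            300.000000     1.000000           1.011893                  223.606798
```

The first patch covers 115 cells (115 ha at 100 m resolution) with 106
exposed cell sides: its perimeter is 10,600 m, its shape index 106/44 =
2.409091 (44 being the minimum perimeter of a compact 115-cell patch), and
its fractal dimension 2·ln(2650)/ln(1.15·10⁶) = 1.129654. The two smaller
patches' closest cells sit one column and two rows apart, hence the
nearest-neighbor distance 100·√5 = 223.606798 m for both.

Metric keyword options control units and boundary handling, e.g.

```python
>>> ls.edge_density()                          # FRAGSTATS default: no nodata edges
0.0
>>> ls.edge_density(count_boundary=True)       # include nodata-facing + border sides
106.153846
```

A temporal series of rasters is analyzed the same way:

```python
sta = ps.SpatioTemporalAnalysis(
    [ps.random_mosaic((40, 40), (0.3, 0.7), seed=s) for s in (1, 2, 3)],
    dates=[2000, 2006, 2012],
)
print(sta.compute_class_metrics_df(
    metrics=["proportion_of_landscape", "number_of_patches"]).round(4))
```

```
                 proportion_of_landscape  number_of_patches
class_val dates
1         2000                   29.6250                 80
          2006                   31.1875                 86
          2012                   30.0625                 91
2         2000                   70.3750                  1
          2006                   68.8125                  2
          2012                   69.9375                  1
```

`sta.plot_metric("proportion_of_landscape", class_val=1)` draws the trend.

The same tables are available from the shell:

```bash
patchstats summarize map.tif --level class --metrics proportion_of_landscape,edge_density
patchstats buffer map.tif --point 2000,2000 --buffer-dists 10000,15000,20000 --rings
patchstats zonal map.tif --zones zones.tif --attribute-values 0-30,30-60,60-90
```

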