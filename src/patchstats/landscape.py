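"""The :class:`Landscape` class: an immutable categorical raster with cached
patch, adjacency and nearest-neighbor state.

A landscape is a 2-D lattice of integer land-use/land-cover class codes with a
cell size in meters, a nodata code, and optional georeferencing.  All
expensive intermediate results — the patch labeling, per-patch geometry, the
class adjacency table and the inter-patch nearest-neighbor distances — are
computed lazily on first access and cached for the lifetime of the instance
(the cells array is frozen to make this sound).  Memory therefore grows
linearly with the number of patches.  Nearest-neighbor distances are by far
the most expensive item and are only ever computed when a metric from the
``euclidean_nearest_neighbor`` family is requested.

The ``n_segmentation_runs`` / ``n_adjacency_runs`` / ``n_enn_runs`` counters
instrument the cache so callers (and tests) can verify that repeated metric
computations do not recompute the underlying state.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import patch as _patch

__all__ = ["Landscape", "read_landscape", "landscape_from_array"]


class Landscape:
    """A categorical land-use/land-cover raster at one point in time.

    Parameters
    ----------
    cells : array-like or path
        2-D integer lattice of class codes, or a path to a single-band
        integer raster file (GeoTIFF).
    res : (float, float), optional
        Cell size ``(x, y)`` in meters.  Required when ``cells`` is an
        array; read from file metadata otherwise.
    nodata : int, optional
        Class code marking cells with no data.  Defaults to the file's
        nodata tag, or 0 when neither a tag nor an override is given.
    transform : 6-tuple, optional
        Affine ``(a, b, c, d, e, f)`` mapping (col, row) to (x, y).
    crs : str, optional
        Coordinate reference system identifier (e.g. ``"EPSG:2056"``).
    connectivity : {8, 4}
        Neighborhood rule for patch segmentation (default 8, the FRAGSTATS
        convention).
    """

    def __init__(self, cells, res=None, nodata=None, transform=None, crs=None,
                 connectivity=8):
        if isinstance(cells, (str, Path)):
            f_cells, f_res, f_nodata, f_transform, f_crs = _io.read_geotiff(cells)
            cells = f_cells
            res = res if res is not None else f_res
            if nodata is None:
                nodata = f_nodata
            transform = transform if transform is not None else f_transform
            crs = crs if crs is not None else f_crs
        cells = np.asarray(cells)
        if cells.ndim != 2:
            raise ValueError(f"cells must be 2-D, got {cells.ndim}-D")
        if not np.issubdtype(cells.dtype, np.integer):
            raise TypeError(
                f"cells must be an integer array of class codes, got {cells.dtype}"
            )
        if res is None:
            raise ValueError("res=(x, y) cell sizes are required for array input")
        cell_width, cell_height = (float(res[0]), float(res[1])) if np.ndim(res) else (float(res), float(res))
        if cell_width <= 0 or cell_height <= 0:
            raise ValueError(f"cell sizes must be positive, got {res!r}")
        if connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {connectivity!r}")
        cells = cells.copy()
        cells.flags.writeable = False  # caching requires immutability
        self._cells = cells
        self.nodata = int(nodata) if nodata is not None else 0
        self.cell_width = cell_width
        self.cell_height = cell_height
        self.transform = tuple(float(v) for v in transform) if transform is not None else None
        self.crs = str(crs) if crs is not None else None
        self.connectivity = connectivity
        # instrumentation counters for the caching contract
        self.n_segmentation_runs = 0
        self.n_adjacency_runs = 0
        self.n_enn_runs = 0
        self._labeling = None
        self._patches = None
        self._adjacency = None
        self._enn = None

    # ------------------------------------------------------------------ basics
    @property
    def cells(self) -> np.ndarray:
        """Read-only class-code lattice."""
        return self._cells

    @property
    def shape(self):
        return self._cells.shape

    @property
    def res(self):
        return (self.cell_width, self.cell_height)

    @property
    def square_cells(self) -> bool:
        return self.cell_width == self.cell_height

    @property
    def cell_area_m2(self) -> float:
        return self.cell_width * self.cell_height

    @property
    def data_mask(self) -> np.ndarray:
        return self._cells != self.nodata

    @property
    def n_data_cells(self) -> int:
        return int(np.count_nonzero(self.data_mask))

    @property
    def classes(self) -> np.ndarray:
        """Sorted data class codes present in the landscape."""
        vals = np.unique(self._cells)
        return vals[vals != self.nodata]

    def __repr__(self):
        return (
            f"Landscape(shape={self.shape}, res=({self.cell_width:g}, "
            f"{self.cell_height:g}), nodata={self.nodata}, "
            f"classes={list(self.classes)})"
        )

    # ------------------------------------------------------------ cached state
    @property
    def labeling(self) -> _patch.PatchLabeling:
        if self._labeling is None:
            self.n_segmentation_runs += 1
            self._labeling = _patch.segment_patches(
                self._cells, self.nodata, self.connectivity
            )
        return self._labeling

    @property
    def patches(self) -> pd.DataFrame:
        """Per-patch geometry (class, cell count, area in ha, perimeter in m,
        exposed-side count), indexed by 0-based ``patch_id``."""
        if self._patches is None:
            self._patches = _patch.patch_geometry(
                self.labeling, self.cell_width, self.cell_height
            )
        return self._patches

    @property
    def adjacency(self) -> _patch.AdjacencyTable:
        if self._adjacency is None:
            self.n_adjacency_runs += 1
            self._adjacency = _patch.adjacency_table(
                self._cells, self.nodata, self.cell_width, self.cell_height
            )
        return self._adjacency

    @property
    def enn(self) -> np.ndarray:
        """Per-patch nearest-neighbor distances (m); NaN for single-patch
        classes.  Computed on demand only."""
        if self._enn is None:
            self.n_enn_runs += 1
            self._enn = _patch.nearest_neighbor_distances(
                self.labeling, self.cell_width, self.cell_height
            )
        return self._enn

    # ------------------------------------------------------------- metric API
    def compute_patch_metrics_df(self, metrics=None, metrics_kws=None):
        from . import metrics as _metrics

        return _metrics.compute_patch_metrics_df(self, metrics, metrics_kws)

    def compute_class_metrics_df(self, metrics=None, classes=None, metrics_kws=None):
        from . import metrics as _metrics

        return _metrics.compute_class_metrics_df(self, metrics, classes, metrics_kws)

    def compute_landscape_metrics_df(self, metrics=None, metrics_kws=None):
        from . import metrics as _metrics

        return _metrics.compute_landscape_metrics_df(self, metrics, metrics_kws)

    def compute_metric(self, label, class_val=None, **kwargs):
        """Compute one class-level (``class_val`` given) or landscape-level
        metric value."""
        from . import metrics as _metrics

        if class_val is None:
            return _metrics.landscape_metric_value(self, label, **kwargs)
        return _metrics.class_metric_value(self, label, class_val, **kwargs)

    def total_area(self, class_val=None, hectares=True):
        return self.compute_metric("total_area", class_val, hectares=hectares)

    def proportion_of_landscape(self, class_val, percent=True):
        return self.compute_metric("proportion_of_landscape", class_val, percent=percent)

    def number_of_patches(self, class_val=None):
        return self.compute_metric("number_of_patches", class_val)

    def patch_density(self, class_val=None, percent=True, hectares=True):
        return self.compute_metric("patch_density", class_val, percent=percent, hectares=hectares)

    def largest_patch_index(self, class_val=None, percent=True):
        return self.compute_metric("largest_patch_index", class_val, percent=percent)

    def total_edge(self, class_val=None, count_boundary=False):
        return self.compute_metric("total_edge", class_val, count_boundary=count_boundary)

    def edge_density(self, class_val=None, count_boundary=False, hectares=True):
        return self.compute_metric(
            "edge_density", class_val, count_boundary=count_boundary, hectares=hectares
        )

    def landscape_shape_index(self, class_val=None):
        return self.compute_metric("landscape_shape_index", class_val)

    def shannon_diversity_index(self):
        return self.compute_metric("shannon_diversity_index")

    def contagion(self, percent=True):
        return self.compute_metric("contagion", percent=percent)

    # --------------------------------------------------------------- plotting
    def plot_landscape(self, ax=None, cmap="viridis", **imshow_kws):
        """Show the class mosaic; nodata cells are masked out."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        arr = np.ma.masked_equal(self._cells, self.nodata)
        ax.imshow(arr, cmap=cmap, interpolation="none", **imshow_kws)
        return ax


def read_landscape(path, nodata_override=None, connectivity=8) -> Landscape:
    """Read a landscape from a single-band integer raster file.

    Cell sizes, georeferencing and the nodata code come from the file
    metadata; ``nodata_override`` wins when given, and nodata defaults to 0
    when the file carries no tag.
    """
    return Landscape(path, nodata=nodata_override, connectivity=connectivity)


def landscape_from_array(cells, res, nodata=0, transform=None, crs=None,
                         connectivity=8) -> Landscape:
    """Build a landscape from an in-memory lattice with explicit cell sizes."""
    return Landscape(cells, res=res, nodata=nodata, transform=transform,
                     crs=crs, connectivity=connectivity)
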