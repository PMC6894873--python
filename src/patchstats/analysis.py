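"""Multi-landscape analyses: spatiotemporal series, buffer and ring
gradients around a feature of interest, generic zonal decomposition, and the
spatiotemporal-buffer combination, plus metric trend plotting.

All analyses reduce to a list of landscapes plus an index scheme: class-level
tables are indexed by ``(class_val, <ordinate>)`` and landscape-level tables
by ``<ordinate>`` alone, where the ordinate column is ``dates`` for temporal
series, ``buffer_dist`` for buffers/rings and ``attribute`` for generic
zones.  Zone landscapes are derived by turning the cells outside the zone
mask into nodata, so with the default ``count_boundary=False`` the zone
border does not contribute to edge metrics — consistent with the
single-landscape boundary convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from . import metrics as _metrics
from .landscape import Landscape

__all__ = [
    "ZoneSpec",
    "buffer_masks",
    "MultiLandscapeAnalysis",
    "SpatioTemporalAnalysis",
    "BufferAnalysis",
    "ZonalAnalysis",
    "SpatioTemporalBufferAnalysis",
]


@dataclass(frozen=True)
class ZoneSpec:
    """One boolean cell mask plus its label (a buffer distance, a ring
    "d0-d1" string, or a free attribute value)."""

    mask: np.ndarray
    label: object


def _as_landscape(obj, **kwargs) -> Landscape:
    if isinstance(obj, Landscape):
        return obj
    return Landscape(obj, **kwargs)


def _as_geometry(geom) -> BaseGeometry:
    if isinstance(geom, BaseGeometry):
        return geom
    if isinstance(geom, str):
        return shapely.from_wkt(geom)
    raise TypeError(f"base geometry must be a shapely geometry or WKT string, got {type(geom)!r}")


def _normalize_crs(crs):
    return str(crs).strip().lower().replace(" ", "") if crs is not None else None


def _cell_centers(ls: Landscape):
    a, b, c, d, e, f = ls.transform
    rows, cols = ls.shape
    jj, ii = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
    return a * jj + b * ii + c, d * jj + e * ii + f


def buffer_masks(ls: Landscape, base_geometry, distances, geometry_crs=None,
                 rings=False):
    """Rasterize buffers of increasing distance around a geometry.

    The geometry (shapely object or WKT) must be expressed in the grid's
    coordinate reference system; a cell belongs to a buffer iff its center
    falls inside the buffer polygon (deterministic and partition-exact for
    rings).  With ``rings=True`` the masks are the annuli between
    consecutive distances, the first ring running from the geometry itself
    (distance 0) to the first distance, labeled ``"0-d1"``, ``"d1-d2"``, …

    Returns a list of :class:`ZoneSpec`.
    """
    if ls.transform is None:
        raise ValueError("buffer analysis requires a georeferenced landscape (transform)")
    geom = _as_geometry(base_geometry)
    g_crs, l_crs = _normalize_crs(geometry_crs), _normalize_crs(ls.crs)
    if g_crs is not None and l_crs is not None and g_crs != l_crs:
        raise ValueError(
            f"geometry CRS {geometry_crs!r} differs from the landscape CRS "
            f"{ls.crs!r}; reprojection is not supported — supply the geometry "
            "in the landscape's CRS"
        )
    labels = list(distances)
    distances = [float(d) for d in distances]
    if any(d1 >= d2 for d1, d2 in zip(distances, distances[1:])):
        raise ValueError(f"buffer distances must be strictly ascending: {distances}")
    if distances and distances[0] < 0:
        raise ValueError("buffer distances must be nonnegative")
    if distances and distances[0] == 0 and geom.area == 0:
        raise ValueError("a zero buffer distance is only meaningful for polygon geometries")
    xs, ys = _cell_centers(ls)

    def rasterize(polygon):
        if polygon.is_empty:
            return np.zeros(ls.shape, dtype=bool)
        return shapely.contains_xy(polygon, xs, ys)

    cumulative = []
    for dist in distances:
        polygon = geom if dist == 0 else geom.buffer(dist)
        mask = rasterize(polygon)
        if not mask.any():
            warnings.warn(
                f"buffer at distance {dist:g} does not cover any cell center "
                "(geometry outside the raster extent?)",
                UserWarning,
                stacklevel=2,
            )
        cumulative.append(mask)
    if not rings:
        return [ZoneSpec(mask, label) for mask, label in zip(cumulative, labels)]
    zones = []
    prev_mask = rasterize(geom if geom.area > 0 else shapely.Polygon())
    prev_dist = 0.0
    for mask, dist in zip(cumulative, distances):
        if dist == 0:
            prev_mask, prev_dist = mask, 0.0
            continue
        zones.append(ZoneSpec(mask & ~prev_mask, f"{prev_dist:g}-{dist:g}"))
        prev_mask, prev_dist = mask, dist
    return zones


def _masked_landscape(ls: Landscape, mask: np.ndarray) -> Landscape:
    if mask.shape != ls.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match the landscape shape {ls.shape}"
        )
    cells = ls.cells.copy()
    cells[~np.asarray(mask, dtype=bool)] = ls.nodata
    return Landscape(cells, res=ls.res, nodata=ls.nodata, transform=ls.transform,
                     crs=ls.crs, connectivity=ls.connectivity)


class MultiLandscapeAnalysis:
    """A sequence of landscapes with an index scheme.

    Subclasses set ``index_name`` and supply one landscape per index value;
    they inherit the class/landscape table builders and trend plotting.
    """

    index_name: str = "attribute"

    def __init__(self, landscapes, index_values):
        landscapes = list(landscapes)
        if not landscapes:
            raise ValueError("at least one landscape is required")
        index_values = list(index_values)
        if len(index_values) != len(landscapes):
            raise ValueError(
                f"{len(index_values)} index values for {len(landscapes)} landscapes"
            )
        if len(set(map(str, index_values))) != len(index_values):
            raise ValueError(f"index values must be unique: {index_values}")
        self.landscapes = landscapes
        self.index_values = index_values

    @property
    def present_classes(self):
        """Sorted union of the class codes over all landscapes."""
        values = np.concatenate([ls.classes for ls in self.landscapes]) if self.landscapes else np.empty(0)
        return np.unique(values)

    def compute_class_metrics_df(self, metrics=None, classes=None, metrics_kws=None):
        if classes is None:
            classes = list(self.present_classes)
        frames = []
        for ls in self.landscapes:
            frames.append(
                _metrics.compute_class_metrics_df(
                    ls, metrics, classes, metrics_kws, strict_classes=False
                )
            )
        df = pd.concat(frames, keys=self.index_values, names=[self.index_name])
        df = df.swaplevel(0, 1).sort_index(
            level=0, sort_remaining=False, kind="stable"
        )
        df.index.names = ["class_val", self.index_name]
        return df

    def compute_landscape_metrics_df(self, metrics=None, metrics_kws=None):
        frames = [
            _metrics.compute_landscape_metrics_df(ls, metrics, metrics_kws)
            for ls in self.landscapes
        ]
        df = pd.concat(frames, ignore_index=True)
        df.index = pd.Index(self.index_values, name=self.index_name)
        return df

    def plot_metric(self, metric, class_val=None, ax=None, metric_legend=True,
                    plot_kws=None):
        """Line-with-markers plot of one metric over the analysis ordinate.

        With ``class_val`` the metric is evaluated at the class level,
        otherwise at the landscape level; drawing onto a supplied ``ax``
        overlays series and ``plot_kws`` is forwarded to the line artist.
        """
        import matplotlib.pyplot as plt

        entry = _metrics.REGISTRY.get(metric)
        if entry is None:
            raise ValueError(f"unknown metric label {metric!r}")
        if class_val is not None and "class" not in entry.levels:
            raise ValueError(f"metric {metric!r} cannot be computed at the class level")
        if class_val is None and "landscape" not in entry.levels:
            raise ValueError(f"metric {metric!r} cannot be computed at the landscape level")
        if class_val is None:
            values = self.compute_landscape_metrics_df(metrics=[metric])[metric]
        else:
            df = self.compute_class_metrics_df(metrics=[metric], classes=[class_val])
            values = df.loc[class_val][metric]
        if ax is None:
            _, ax = plt.subplots()
        plot_kws = dict(plot_kws or {})
        plot_kws.setdefault("marker", "o")
        x = list(values.index)
        if any(isinstance(v, str) for v in x):
            x = [str(v) for v in x]
        ax.plot(x, values.to_numpy(), **plot_kws)
        ax.set_xlabel(self.index_name)
        if metric_legend:
            ax.set_ylabel(metric)
        return ax


def _check_congruent(landscapes):
    first = landscapes[0]
    for ls in landscapes[1:]:
        if ls.shape != first.shape or ls.res != first.res:
            raise ValueError(
                "all snapshots must share the same shape and resolution: "
                f"{ls.shape}@{ls.res} vs {first.shape}@{first.res}"
            )


class SpatioTemporalAnalysis(MultiLandscapeAnalysis):
    """A temporally-ordered sequence of landscape snapshots.

    No patch-level table is offered: patches appear and disappear between
    snapshots, so there is no common patch index.
    """

    index_name = "dates"

    def __init__(self, landscapes, dates=None, **landscape_kws):
        landscapes = [_as_landscape(ls, **landscape_kws) for ls in landscapes]
        _check_congruent(landscapes)
        if dates is None:
            dates = list(range(len(landscapes)))
        super().__init__(landscapes, dates)

    @property
    def dates(self):
        return self.index_values


class BufferAnalysis(MultiLandscapeAnalysis):
    """Metrics across buffers of increasing distance (or the rings between
    them) around a base geometry."""

    index_name = "buffer_dist"

    def __init__(self, landscape, base_geometry, buffer_dists, base_mask_crs=None,
                 buffer_rings=False, **landscape_kws):
        ls = _as_landscape(landscape, **landscape_kws)
        zones = buffer_masks(
            ls, base_geometry, buffer_dists, geometry_crs=base_mask_crs,
            rings=buffer_rings,
        )
        self.zones = zones
        super().__init__(
            [_masked_landscape(ls, zone.mask) for zone in zones],
            [zone.label for zone in zones],
        )

    @property
    def buffer_dists(self):
        return self.index_values


class ZonalAnalysis(MultiLandscapeAnalysis):
    """Metrics across a user-supplied decomposition of the landscape.

    Each zone is an independent masked landscape; zones may overlap.
    """

    index_name = "attribute"

    def __init__(self, landscape, masks, attribute_values=None, **landscape_kws):
        ls = _as_landscape(landscape, **landscape_kws)
        masks = [np.asarray(mask, dtype=bool) for mask in masks]
        if attribute_values is None:
            attribute_values = list(range(len(masks)))
        self.zones = [
            ZoneSpec(mask, label) for mask, label in zip(masks, attribute_values)
        ]
        super().__init__(
            [_masked_landscape(ls, mask) for mask in masks], list(attribute_values)
        )

    @property
    def attribute_values(self):
        return self.index_values


class SpatioTemporalBufferAnalysis:
    """Buffer (or ring) analysis of a temporally-ordered snapshot sequence.

    Class-level tables are indexed by ``(buffer_dist, class_val, dates)``
    and landscape-level tables by ``(buffer_dist, dates)``;
    :meth:`plot_metric` draws one temporal series per buffer distance.
    """

    def __init__(self, landscapes, base_geometry, buffer_dists, base_mask_crs=None,
                 buffer_rings=False, dates=None, **landscape_kws):
        snapshots = [_as_landscape(ls, **landscape_kws) for ls in landscapes]
        _check_congruent(snapshots)
        zones = buffer_masks(
            snapshots[0], base_geometry, buffer_dists, geometry_crs=base_mask_crs,
            rings=buffer_rings,
        )
        self.zones = zones
        self.buffer_dists = [zone.label for zone in zones]
        self.analyses = [
            SpatioTemporalAnalysis(
                [_masked_landscape(ls, zone.mask) for ls in snapshots], dates=dates
            )
            for zone in zones
        ]
        self.dates = self.analyses[0].dates if self.analyses else []

    def compute_class_metrics_df(self, metrics=None, classes=None, metrics_kws=None):
        if classes is None:
            classes = list(
                np.unique(np.concatenate([sta.present_classes for sta in self.analyses]))
            )
        frames = [
            sta.compute_class_metrics_df(metrics, classes, metrics_kws)
            for sta in self.analyses
        ]
        return pd.concat(frames, keys=self.buffer_dists, names=["buffer_dist"])

    def compute_landscape_metrics_df(self, metrics=None, metrics_kws=None):
        frames = [
            sta.compute_landscape_metrics_df(metrics, metrics_kws)
            for sta in self.analyses
        ]
        return pd.concat(frames, keys=self.buffer_dists, names=["buffer_dist"])

    def plot_metric(self, metric, class_val=None, ax=None, plot_kws=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for dist, sta in zip(self.buffer_dists, self.analyses):
            kws = dict(plot_kws or {})
            kws.setdefault("label", str(dist))
            sta.plot_metric(metric, class_val=class_val, ax=ax, plot_kws=kws)
        ax.legend(title="buffer_dist")
        return ax
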