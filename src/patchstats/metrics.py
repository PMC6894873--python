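"""Landscape metric formulas, the metric registry, and the data-frame builders.

Metrics follow the FRAGSTATS v4 definitions and defaults: edges between data
and nodata cells (including the raster boundary) are not counted unless
``count_boundary=True``, areas are reported in hectares unless
``hectares=False``, and proportions in percent unless ``percent=False``.

Standard deviations are *population* standard deviations (ddof=0), matching
FRAGSTATS — a classic divergence point from spreadsheet defaults.  The
coefficient of variation is reported in percent of the mean.

Three levels of metrics are distinguished:

* patch-level — one value per patch (area, perimeter, perimeter-area ratio,
  shape index, fractal dimension, Euclidean nearest neighbor);
* class-level — aggregates over the patches of one class, plus the six
  distribution statistics (``_mn`` mean, ``_am`` area-weighted mean, ``_md``
  median, ``_ra`` range, ``_sd`` standard deviation, ``_cv`` coefficient of
  variation) of each patch metric;
* landscape-level — aggregates over all patches, the same distribution
  statistics pooled across classes, plus Shannon's diversity index and
  contagion.

The registry exposes 95 level-qualified metric labels in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import Landscape
from .patch import AdjacencyTable, min_perimeter_cells, warn_rectangular

__all__ = [
    "PATCH_METRICS",
    "SUFFIXES",
    "CLASS_METRICS",
    "LANDSCAPE_METRICS",
    "MetricRegistryEntry",
    "REGISTRY",
    "available_metrics",
    "num_level_labels",
    "shape_index",
    "fractal_dimension",
    "perimeter_area_ratio",
    "proportion_of_landscape",
    "patch_density",
    "edge_density",
    "landscape_shape_index",
    "largest_patch_index",
    "shannon_diversity_index",
    "contagion",
    "distribution_statistic",
    "compute_patch_metrics_df",
    "compute_class_metrics_df",
    "compute_landscape_metrics_df",
]

PATCH_METRICS = (
    "area",
    "perimeter",
    "perimeter_area_ratio",
    "shape_index",
    "fractal_dimension",
    "euclidean_nearest_neighbor",
)
SUFFIXES = ("mn", "am", "md", "ra", "sd", "cv")

_CLASS_AGGREGATES = (
    "total_area",
    "proportion_of_landscape",
    "number_of_patches",
    "patch_density",
    "largest_patch_index",
    "total_edge",
    "edge_density",
    "landscape_shape_index",
)
_LANDSCAPE_AGGREGATES = (
    "total_area",
    "number_of_patches",
    "patch_density",
    "largest_patch_index",
    "total_edge",
    "edge_density",
    "landscape_shape_index",
    "shannon_diversity_index",
    "contagion",
)
_DISTRIBUTION_LABELS = tuple(
    f"{base}_{suffix}" for base in PATCH_METRICS for suffix in SUFFIXES
)
#: default column order at each level
CLASS_METRICS = _CLASS_AGGREGATES + _DISTRIBUTION_LABELS
LANDSCAPE_METRICS = _LANDSCAPE_AGGREGATES + _DISTRIBUTION_LABELS


@dataclass(frozen=True)
class MetricRegistryEntry:
    label: str
    levels: frozenset
    kwargs_schema: dict  # keyword name -> default


def _build_registry():
    base_schema = {
        "area": {"hectares": True},
        "perimeter": {},
        "perimeter_area_ratio": {"hectares": True},
        "shape_index": {},
        "fractal_dimension": {},
        "euclidean_nearest_neighbor": {},
    }
    registry = {}

    def add(label, levels, schema):
        registry[label] = MetricRegistryEntry(label, frozenset(levels), dict(schema))

    for label, schema in base_schema.items():
        add(label, {"patch"}, schema)
    for base in PATCH_METRICS:
        for suffix in SUFFIXES:
            add(f"{base}_{suffix}", {"class", "landscape"}, base_schema[base])
    add("total_area", {"class", "landscape"}, {"hectares": True})
    add("proportion_of_landscape", {"class"}, {"percent": True})
    add("number_of_patches", {"class", "landscape"}, {})
    add("patch_density", {"class", "landscape"}, {"percent": True, "hectares": True})
    add("largest_patch_index", {"class", "landscape"}, {"percent": True})
    add("total_edge", {"class", "landscape"}, {"count_boundary": False})
    add("edge_density", {"class", "landscape"}, {"count_boundary": False, "hectares": True})
    add("landscape_shape_index", {"class", "landscape"}, {})
    add("shannon_diversity_index", {"landscape"}, {})
    add("contagion", {"landscape"}, {"percent": True})
    return registry


REGISTRY = _build_registry()


def available_metrics(level=None):
    """Labels available at ``level`` ('patch'|'class'|'landscape'), or all."""
    if level is None:
        return list(REGISTRY)
    if level == "patch":
        return list(PATCH_METRICS)
    if level == "class":
        return list(CLASS_METRICS)
    if level == "landscape":
        return list(LANDSCAPE_METRICS)
    raise ValueError(f"unknown level {level!r}")


def num_level_labels() -> int:
    """Total number of (label, level) pairs exposed by the registry."""
    return sum(len(entry.levels) for entry in REGISTRY.values())


# --------------------------------------------------------------- pure formulas


def shape_index(n_cells, perimeter_sides):
    """Patch perimeter in cell sides over the minimum perimeter of a maximally
    compact patch of the same cell count; >= 1, equal to 1 for squares."""
    return perimeter_sides / min_perimeter_cells(n_cells)


def fractal_dimension(perimeter_m, area_m2):
    """2·ln(0.25·p)/ln(a) with perimeter in m and area in m².

    Close to 1 for simple compact shapes and approaching 2 for highly
    convoluted ones; the formula is degenerate for a 1 m² patch (ln a = 0)
    and carries a known small-patch bias at other resolutions.
    """
    if area_m2 <= 1:
        return np.nan
    return 2 * np.log(0.25 * perimeter_m) / np.log(area_m2)


def perimeter_area_ratio(perimeter_m, area):
    return perimeter_m / area


def proportion_of_landscape(class_area, total_area, percent=True):
    frac = class_area / total_area
    return frac * 100 if percent else frac


def patch_density(n_patches, total_area, percent=True, hectares=True):
    """Patches per unit area; with the defaults, patches per 100 ha."""
    dens = n_patches / total_area
    if not hectares:
        dens = dens / 1e4  # per m² is the per-ha form shifted by 1e4
    return dens * 100 if percent else dens


def edge_density(total_edge_m, total_area_ha, hectares=True):
    # the m-per-m² form is the m-per-ha form shifted by 1e4 (1 ha = 1e4 m²)
    value = total_edge_m / total_area_ha
    return value if hectares else value / 1e4


def landscape_shape_index(total_edge_sides, n_cells):
    """Boundary-inclusive edge sides over the minimum perimeter of a maximally
    compact patch of ``n_cells``; 1 for a single compact patch filling the
    landscape."""
    return total_edge_sides / min_perimeter_cells(n_cells)


def largest_patch_index(patch_areas, total_area, percent=True):
    frac = np.max(patch_areas) / total_area
    return frac * 100 if percent else frac


def shannon_diversity_index(proportions):
    """-Σ p ln p in nats over the class proportions present."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return np.nan
    return float(-np.sum(p * np.log(p)))


def contagion(adjacency: AdjacencyTable, proportions, percent=True):
    """Contagion: aggregation of the mosaic from class proportions and
    cell-side adjacency frequencies.

    Uses the FRAGSTATS double-count convention for the row normalisation of
    the adjacency matrix (each unordered like-adjacency counted from both
    cells, i.e. the diagonal doubled).  Undefined (NaN) for a single class;
    approaches 100 for maximally aggregated and 0 for maximally
    interspersed landscapes.
    """
    p = np.asarray(proportions, dtype=float)
    m = p.size
    if m < 2:
        return np.nan
    counts = adjacency.data_adjacency_counts().astype(float)
    ordered = counts + np.diag(np.diag(counts))  # double-count diagonal
    row_sums = ordered.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(row_sums > 0, ordered / np.where(row_sums == 0, 1, row_sums), 0.0)
    pgk = p[:, None] * g
    nz = pgk > 0
    entropy = float(np.sum(pgk[nz] * np.log(pgk[nz])))
    value = 1 + entropy / (2 * np.log(m))
    return value * 100 if percent else value


def distribution_statistic(values, weights=None, stat="mn"):
    """Distribution statistic of per-patch metric values.

    NaN values are dropped (e.g. undefined nearest-neighbor distances of
    single-patch classes); an all-NaN input yields NaN.  ``sd`` is the
    population standard deviation and ``cv`` is 100·sd/mean.
    """
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    values = values[keep]
    if values.size == 0:
        return np.nan
    if stat == "mn":
        return float(np.mean(values))
    if stat == "am":
        w = np.asarray(weights, dtype=float)[keep]
        return float(np.average(values, weights=w))
    if stat == "md":
        return float(np.median(values))
    if stat == "ra":
        return float(np.max(values) - np.min(values))
    if stat == "sd":
        return float(np.std(values))
    if stat == "cv":
        mean = np.mean(values)
        return float(100 * np.std(values) / mean) if mean != 0 else np.nan
    raise ValueError(f"unknown distribution statistic {stat!r}")


# ----------------------------------------------------- per-landscape evaluation


def patch_metric_values(ls: Landscape, label: str, **kwargs) -> np.ndarray:
    """Vector of one patch metric over all patches of the landscape."""
    patches = ls.patches
    if label == "area":
        hectares = kwargs.get("hectares", True)
        return patches["area"].to_numpy() * (1 if hectares else 1e4)
    if label == "perimeter":
        return patches["perimeter"].to_numpy(dtype=float)
    if label == "perimeter_area_ratio":
        hectares = kwargs.get("hectares", True)
        area = patches["area"].to_numpy() * (1 if hectares else 1e4)
        return patches["perimeter"].to_numpy() / area
    if label == "shape_index":
        if not ls.square_cells:
            warn_rectangular("shape_index")
            return np.full(len(patches), np.nan)
        mpc = np.array([min_perimeter_cells(n) for n in patches["n_cells"]])
        return patches["n_sides"].to_numpy() / mpc
    if label == "fractal_dimension":
        area_m2 = patches["area"].to_numpy() * 1e4
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 2 * np.log(0.25 * patches["perimeter"].to_numpy()) / np.log(area_m2)
        out[area_m2 <= 1] = np.nan
        return out
    if label == "euclidean_nearest_neighbor":
        return ls.enn.copy()
    raise ValueError(f"{label!r} is not a patch-level metric")


def _class_edge_quantities(ls: Landscape, class_val, count_boundary):
    adj = ls.adjacency
    lengths = adj.edge_length_matrix()
    sides = adj.side_count_matrix()
    i = adj.index_of(class_val)
    nd = len(adj.codes) - 1
    data = slice(0, nd)
    other = [j for j in range(nd) if j != i]
    te = lengths[i, other].sum()
    ts = sides[i, other].sum()
    if count_boundary:
        te += lengths[i, nd] + adj.border_lengths()[i]
        ts += sides[i, nd] + adj.border_side_counts()[i]
    return float(te), int(ts)


def _landscape_edge_quantities(ls: Landscape, count_boundary):
    adj = ls.adjacency
    lengths = adj.edge_length_matrix()
    sides = adj.side_count_matrix()
    nd = len(adj.codes) - 1
    iu = np.triu_indices(nd, k=1)
    te = lengths[:nd, :nd][iu].sum()
    ts = sides[:nd, :nd][iu].sum()
    if count_boundary:
        te += lengths[:nd, nd].sum() + adj.border_lengths()[:nd].sum()
        ts += sides[:nd, nd].sum() + adj.border_side_counts()[:nd].sum()
    return float(te), int(ts)


def _select_patches(ls: Landscape, class_val=None) -> pd.DataFrame:
    patches = ls.patches
    if class_val is None:
        return patches
    return patches[patches["class_val"] == class_val]


def class_metric_value(ls: Landscape, label: str, class_val, **kwargs):
    """One class-level metric value; NaN when undefined for this scope."""
    return _scoped_metric_value(ls, label, class_val, "class", **kwargs)


def landscape_metric_value(ls: Landscape, label: str, **kwargs):
    """One landscape-level metric value."""
    return _scoped_metric_value(ls, label, None, "landscape", **kwargs)


def _scoped_metric_value(ls, label, class_val, level, **kwargs):
    entry = REGISTRY.get(label)
    if entry is None:
        raise ValueError(f"unknown metric label {label!r}")
    if level not in entry.levels:
        raise ValueError(f"metric {label!r} is not available at the {level} level")
    _validate_kwargs(label, kwargs)

    base, _, suffix = label.rpartition("_")
    if suffix in SUFFIXES and base in PATCH_METRICS:
        values = patch_metric_values(ls, base, **kwargs)
        areas = ls.patches["area"].to_numpy()
        sel = slice(None) if class_val is None else (
            ls.patches["class_val"].to_numpy() == class_val
        )
        values, areas = values[sel], areas[sel]
        if values.size and np.all(np.isnan(values)) and base == "euclidean_nearest_neighbor":
            warnings.warn(
                "no defined nearest-neighbor distance in this scope "
                "(all classes have a single patch)",
                UserWarning,
                stacklevel=2,
            )
        return distribution_statistic(values, areas, suffix)

    total_area_ha = ls.n_data_cells * ls.cell_area_m2 / 1e4
    patches = _select_patches(ls, class_val)

    if label == "total_area":
        n = ls.n_data_cells if class_val is None else int(
            np.count_nonzero(ls.cells == class_val)
        )
        area = n * ls.cell_area_m2
        return area / 1e4 if kwargs.get("hectares", True) else area
    if label == "proportion_of_landscape":
        if total_area_ha == 0:
            return np.nan
        class_area = np.count_nonzero(ls.cells == class_val) * ls.cell_area_m2 / 1e4
        return proportion_of_landscape(class_area, total_area_ha, kwargs.get("percent", True))
    if label == "number_of_patches":
        return int(len(patches))
    if label == "patch_density":
        if total_area_ha == 0:
            return np.nan
        return patch_density(len(patches), total_area_ha, **{**{"percent": True, "hectares": True}, **kwargs})
    if label == "largest_patch_index":
        if len(patches) == 0 or total_area_ha == 0:
            return np.nan
        return largest_patch_index(
            patches["area"].to_numpy(), total_area_ha, kwargs.get("percent", True)
        )
    if label == "total_edge":
        cb = kwargs.get("count_boundary", False)
        if class_val is None:
            return _landscape_edge_quantities(ls, cb)[0]
        return _class_edge_quantities(ls, class_val, cb)[0]
    if label == "edge_density":
        if total_area_ha == 0:
            return np.nan
        cb = kwargs.get("count_boundary", False)
        te = (
            _landscape_edge_quantities(ls, cb)[0]
            if class_val is None
            else _class_edge_quantities(ls, class_val, cb)[0]
        )
        return edge_density(te, total_area_ha, kwargs.get("hectares", True))
    if label == "landscape_shape_index":
        if not ls.square_cells:
            warn_rectangular("landscape_shape_index")
            return np.nan
        if class_val is None:
            n = ls.n_data_cells
            sides = _landscape_edge_quantities(ls, True)[1]
        else:
            n = int(np.count_nonzero(ls.cells == class_val))
            sides = _class_edge_quantities(ls, class_val, True)[1]
        if n == 0:
            return np.nan
        return landscape_shape_index(sides, n)
    if label == "shannon_diversity_index":
        if ls.n_data_cells == 0:
            return np.nan
        counts = np.array([np.count_nonzero(ls.cells == c) for c in ls.classes], float)
        return shannon_diversity_index(counts / counts.sum())
    if label == "contagion":
        if ls.n_data_cells == 0:
            return np.nan
        counts = np.array([np.count_nonzero(ls.cells == c) for c in ls.classes], float)
        return contagion(ls.adjacency, counts / counts.sum(), kwargs.get("percent", True))
    raise AssertionError(f"unhandled metric {label!r}")  # pragma: no cover


def _validate_kwargs(label, kwargs):
    schema = REGISTRY[label].kwargs_schema
    for key in kwargs:
        if key not in schema:
            raise ValueError(
                f"keyword {key!r} is not a valid option for metric {label!r}; "
                f"allowed: {sorted(schema)}"
            )


def _resolve_metrics(metrics, level, strict_level):
    """Validate requested labels and drop those valid only at other levels.

    ``strict_level`` (patch builder) errors on any label of another level;
    otherwise labels that exist in the registry but not at this level are
    silently dropped (e.g. Shannon diversity requested at the class level).
    """
    defaults = available_metrics(level)
    if metrics is None:
        return list(defaults)
    out = []
    for label in metrics:
        entry = REGISTRY.get(label)
        if entry is None:
            raise ValueError(f"unknown metric label {label!r}")
        if level not in entry.levels:
            if strict_level:
                raise ValueError(
                    f"metric {label!r} is not available at the {level} level"
                )
            continue
        out.append(label)
    return out


def _resolve_metrics_kws(metrics_kws):
    if metrics_kws is None:
        return {}
    for label, kwargs in metrics_kws.items():
        if label not in REGISTRY:
            raise ValueError(f"unknown metric label in metrics_kws: {label!r}")
        _validate_kwargs(label, kwargs)
    return {k: dict(v) for k, v in metrics_kws.items()}


def compute_patch_metrics_df(ls: Landscape, metrics=None, metrics_kws=None) -> pd.DataFrame:
    """One row per patch, indexed by ``patch_id``, with ``class_val`` first
    and the requested patch metrics (default: all six) after."""
    labels = _resolve_metrics(metrics, "patch", strict_level=True)
    kws = _resolve_metrics_kws(metrics_kws)
    data = {"class_val": ls.patches["class_val"].to_numpy()}
    for label in labels:
        data[label] = patch_metric_values(ls, label, **kws.get(label, {}))
    return pd.DataFrame(data, index=ls.patches.index.copy())


def compute_class_metrics_df(
    ls: Landscape, metrics=None, classes=None, metrics_kws=None, strict_classes=True
) -> pd.DataFrame:
    """One row per class, indexed by ``class_val``.

    Landscape-only labels in ``metrics`` are silently dropped.  With
    ``strict_classes`` (the default for direct calls), requesting a class
    that is not present raises; the multi-landscape analyses disable this to
    produce NaN rows for classes absent from individual zones or snapshots.
    """
    labels = _resolve_metrics(metrics, "class", strict_level=False)
    kws = _resolve_metrics_kws(metrics_kws)
    present = set(ls.classes.tolist())
    if classes is None:
        classes = list(ls.classes)
    else:
        classes = list(classes)
        missing = [c for c in classes if c not in present]
        if missing and strict_classes:
            raise ValueError(f"classes not present in the landscape: {missing}")
    rows = {}
    for class_val in classes:
        if class_val in present:
            rows[class_val] = [
                class_metric_value(ls, label, class_val, **kws.get(label, {}))
                for label in labels
            ]
        else:
            rows[class_val] = [np.nan] * len(labels)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    df.index.name = "class_val"
    return df


def compute_landscape_metrics_df(ls: Landscape, metrics=None, metrics_kws=None) -> pd.DataFrame:
    """Single-row table of landscape-level metrics; class-only labels
    (proportion_of_landscape) are silently dropped from requests."""
    labels = _resolve_metrics(metrics, "landscape", strict_level=False)
    kws = _resolve_metrics_kws(metrics_kws)
    row = [landscape_metric_value(ls, label, **kws.get(label, {})) for label in labels]
    return pd.DataFrame([row], columns=labels, index=pd.RangeIndex(1))
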