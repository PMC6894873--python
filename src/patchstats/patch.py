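"""Patch segmentation, geometry, class adjacency and nearest-neighbor distances.

The operations in this module work on plain integer lattices; the
:class:`~patchstats.landscape.Landscape` class wraps them with caching.

Conventions
-----------
* A *patch* is a maximal connected set of same-class cells under 4- or
  8-connectivity (default 8, the FRAGSTATS convention).
* Adjacencies (shared cell sides) are always rook-only, independent of the
  patch connectivity: perimeters and edge metrics are side-based quantities.
* West-east neighbors (same row) share a *vertical* side of length
  ``cell_height``; north-south neighbors (same column) share a *horizontal*
  side of length ``cell_width``.
* Nearest-neighbor distances are cell-center to cell-center, in meters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "PatchLabeling",
    "AdjacencyTable",
    "segment_patches",
    "patch_geometry",
    "adjacency_table",
    "nearest_neighbor_distances",
    "min_perimeter_cells",
]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class PatchLabeling:
    """Connected-component labeling of a categorical lattice.

    ``labels`` holds 0 for nodata/background and 1..K for patches; patch ids
    are assigned in row-major first-contact order, so label ``i`` belongs to
    the ``i``-th patch encountered scanning the raster by rows.
    ``patch_class[i - 1]`` is the class code of patch ``i``.
    """

    labels: np.ndarray
    connectivity: int
    patch_class: np.ndarray

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)


@dataclass(frozen=True)
class AdjacencyTable:
    """Counts of shared cell sides between every pair of class codes.

    ``codes`` lists the data class codes in sorted order with the nodata code
    appended as a pseudo-class; the count matrices are symmetric and count
    every unordered interior cell pair exactly once.  Raster-border sides
    (cells on the outer edge of the lattice) are tallied separately per code.
    Per-direction counts are kept so that side counts convert to meters for
    rectangular cells.
    """

    codes: np.ndarray  # data classes sorted, nodata last
    nodata: int
    counts_we: np.ndarray  # west-east neighbor pairs (vertical sides)
    counts_ns: np.ndarray  # north-south neighbor pairs (horizontal sides)
    border_we: np.ndarray  # per-code sides on the left/right raster border
    border_ns: np.ndarray  # per-code sides on the top/bottom raster border
    cell_width: float
    cell_height: float

    @property
    def n_data_classes(self) -> int:
        return len(self.codes) - 1

    def index_of(self, class_val: int) -> int:
        data = self.codes[:-1]
        pos = np.searchsorted(data, class_val)
        if pos >= len(data) or data[pos] != class_val:
            raise ValueError(f"class {class_val!r} not present in the landscape")
        return int(pos)

    def side_count_matrix(self) -> np.ndarray:
        """Total shared-side counts (both directions), symmetric."""
        return self.counts_we + self.counts_ns

    def edge_length_matrix(self) -> np.ndarray:
        """Shared-side lengths in meters, symmetric."""
        return self.counts_we * self.cell_height + self.counts_ns * self.cell_width

    def border_side_counts(self) -> np.ndarray:
        return self.border_we + self.border_ns

    def border_lengths(self) -> np.ndarray:
        return self.border_we * self.cell_height + self.border_ns * self.cell_width

    def data_adjacency_counts(self) -> np.ndarray:
        """Side counts between data classes only (nodata row/column removed)."""
        return self.side_count_matrix()[:-1, :-1]


def segment_patches(cells: np.ndarray, nodata: int, connectivity: int = 8) -> PatchLabeling:
    """Label the patches of a categorical lattice.

    Each class is labeled independently with :func:`scipy.ndimage.label`;
    labels are then renumbered so that ids follow row-major first-contact
    order across all classes, making outputs reproducible regardless of class
    code ordering.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity!r}")
    cells = np.asarray(cells)
    structure = _STRUCTURES[connectivity]
    labels = np.zeros(cells.shape, dtype=np.int64)
    classes = []
    offset = 0
    for class_val in np.unique(cells):
        if class_val == nodata:
            continue
        mask = cells == class_val
        lab, n = ndimage.label(mask, structure=structure)
        if n:
            labels[mask] = lab[mask] + offset
            classes.extend([class_val] * n)
            offset += n
    patch_class = np.asarray(classes, dtype=cells.dtype if classes else np.int64)
    if offset == 0:
        return PatchLabeling(labels, connectivity, patch_class)
    # renumber in row-major first-contact order
    flat = labels.ravel()
    first = np.full(offset + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat, np.arange(flat.size))
    order = np.argsort(first[1:], kind="stable")  # old label-1 -> rank
    rank = np.empty(offset, dtype=np.int64)
    rank[order] = np.arange(offset)
    new_labels = np.zeros_like(labels)
    data = flat > 0
    new_labels.ravel()[data] = rank[flat[data] - 1] + 1
    return PatchLabeling(new_labels, connectivity, patch_class[order])


def _exposure_masks(labels: np.ndarray):
    """Boolean masks of patch cells whose N/S/W/E neighbor lies in a
    different patch, in nodata, or off-raster."""
    padded = np.pad(labels, 1, constant_values=0)
    core = padded[1:-1, 1:-1]
    data = core > 0
    north = (padded[:-2, 1:-1] != core) & data
    south = (padded[2:, 1:-1] != core) & data
    west = (padded[1:-1, :-2] != core) & data
    east = (padded[1:-1, 2:] != core) & data
    return north, south, west, east


def patch_geometry(
    labeling: PatchLabeling,
    cell_width: float,
    cell_height: float,
    hectares: bool = True,
) -> pd.DataFrame:
    """Per-patch cell counts, areas, perimeters and exposed-side counts.

    A side is exposed when the rook neighbor belongs to a different class,
    is nodata, or lies off the raster; the raster border therefore always
    counts toward the perimeter.  North/south-facing sides measure
    ``cell_width`` meters, west/east-facing sides ``cell_height``.

    Returns a data frame indexed by ``patch_id`` (0-based) with columns
    ``class_val``, ``n_cells``, ``area``, ``perimeter``, ``n_sides``.
    """
    labels = labeling.labels
    k = labeling.n_patches
    minlength = k + 1
    n_cells = np.bincount(labels.ravel(), minlength=minlength)[1:]
    north, south, west, east = _exposure_masks(labels)
    ns_sides = (
        np.bincount(labels[north], minlength=minlength)
        + np.bincount(labels[south], minlength=minlength)
    )[1:]
    we_sides = (
        np.bincount(labels[west], minlength=minlength)
        + np.bincount(labels[east], minlength=minlength)
    )[1:]
    perimeter = ns_sides * cell_width + we_sides * cell_height
    area = n_cells * (cell_width * cell_height)
    if hectares:
        area = area / 1e4
    return pd.DataFrame(
        {
            "class_val": labeling.patch_class,
            "n_cells": n_cells.astype(np.int64),
            "area": area,
            "perimeter": perimeter.astype(float),
            "n_sides": (ns_sides + we_sides).astype(np.int64),
        },
        index=pd.RangeIndex(k, name="patch_id"),
    )


def adjacency_table(
    cells: np.ndarray, nodata: int, cell_width: float, cell_height: float
) -> AdjacencyTable:
    """Count every interior shared cell side once per unordered cell pair.

    Single vectorized pass: class codes are encoded to small integers, each
    neighbor pair is mapped to a canonical (lo, hi) linear index, and counts
    come from ``np.bincount`` — O(#cells) time and memory.
    """
    cells = np.asarray(cells)
    data_codes = np.unique(cells[cells != nodata]) if cells.size else np.empty(0, int)
    codes = np.concatenate([data_codes, [nodata]]).astype(np.int64)
    k = len(codes)
    # encode each cell as its index in `codes`
    enc = np.searchsorted(data_codes, cells).astype(np.int64)
    enc[cells == nodata] = k - 1

    def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        lo = np.minimum(a, b).ravel()
        hi = np.maximum(a, b).ravel()
        flat = np.bincount(lo * k + hi, minlength=k * k).reshape(k, k)
        return flat + np.triu(flat, 1).T  # symmetrize off-diagonal

    counts_we = _pair_counts(enc[:, :-1], enc[:, 1:]) if cells.shape[1] > 1 else np.zeros((k, k), np.int64)
    counts_ns = _pair_counts(enc[:-1, :], enc[1:, :]) if cells.shape[0] > 0 and cells.shape[0] > 1 else np.zeros((k, k), np.int64)

    border_we = np.bincount(enc[:, 0], minlength=k) + np.bincount(enc[:, -1], minlength=k) if cells.size else np.zeros(k, np.int64)
    border_ns = np.bincount(enc[0, :], minlength=k) + np.bincount(enc[-1, :], minlength=k) if cells.size else np.zeros(k, np.int64)

    return AdjacencyTable(
        codes=codes,
        nodata=nodata,
        counts_we=counts_we,
        counts_ns=counts_ns,
        border_we=border_we.astype(np.int64),
        border_ns=border_ns.astype(np.int64),
        cell_width=float(cell_width),
        cell_height=float(cell_height),
    )


def nearest_neighbor_distances(
    labeling: PatchLabeling, cell_width: float, cell_height: float
) -> np.ndarray:
    """Euclidean nearest-neighbor distance (meters) per patch.

    For every patch, the minimum center-to-center distance to any cell of
    another patch of the same class.  NaN when the class has a single patch.
    Only patch boundary cells are searched (the minimum over disjoint cell
    sets is attained at boundary cells), via a per-class k-d tree; the result
    equals the all-pairs brute force.
    """
    labels = labeling.labels
    k = labeling.n_patches
    enn = np.full(k, np.nan)
    if k == 0:
        return enn
    north, south, west, east = _exposure_masks(labels)
    boundary = north | south | west | east
    rows, cols = np.nonzero(boundary)
    blabels = labels[rows, cols]
    coords = np.column_stack([cols * cell_width, rows * cell_height]).astype(float)
    patch_class = labeling.patch_class
    for class_val in np.unique(patch_class):
        patch_ids = np.nonzero(patch_class == class_val)[0] + 1  # labels
        if len(patch_ids) < 2:
            continue
        in_class = np.isin(blabels, patch_ids)
        cls_coords = coords[in_class]
        cls_labels = blabels[in_class]
        for pid in patch_ids:
            own = cls_labels == pid
            tree = cKDTree(cls_coords[~own])
            d, _ = tree.query(cls_coords[own], k=1)
            enn[pid - 1] = float(np.min(d))
    return enn


def min_perimeter_cells(n: int) -> int:
    """Side count of the perimeter of a maximally compact patch of ``n`` cells.

    This is the raster reference perimeter used by the shape and landscape
    shape indices: with ``a = floor(sqrt(n))`` the most compact arrangement of
    ``n`` square cells has perimeter ``4a`` when n is a perfect square,
    ``4a + 2`` when ``n <= a(a+1)``, and ``4a + 4`` otherwise.
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"cell count must be >= 1, got {n}")
    a = int(np.floor(np.sqrt(n)))
    # guard against floating point at perfect squares
    while (a + 1) * (a + 1) <= n:
        a += 1
    while a * a > n:
        a -= 1
    if n == a * a:
        return 4 * a
    if n <= a * (a + 1):
        return 4 * a + 2
    return 4 * a + 4


def warn_rectangular(metric: str) -> None:
    warnings.warn(
        f"{metric} is defined in cell-side counts and requires square cells; "
        "returning NaN for rectangular cells",
        UserWarning,
        stacklevel=3,
    )
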