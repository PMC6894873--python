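"""Deterministic synthetic landscapes and brute-force reference algorithms.

Every generated fixture carries a closed-form ground truth (cell counts,
areas, perimeters), and the ``oracle_*`` functions re-derive segmentation,
adjacency and nearest-neighbor results by exhaustive enumeration so that the
vectorized implementations in :mod:`patchstats.patch` can be audited on any
small landscape.  The oracles are intentionally naive (quadratic) and are
meant for lattices up to roughly 10⁴ cells.

Random mosaics draw each cell i.i.d. from a categorical distribution using
``numpy.random.default_rng`` (PCG64), so a given seed reproduces the same
grid on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .landscape import Landscape
from .patch import AdjacencyTable, PatchLabeling, adjacency_table

__all__ = [
    "BlockSpec",
    "blocks_landscape",
    "random_mosaic",
    "reference_patch_landscape",
    "two_patch_landscape",
    "oracle_segment",
    "oracle_adjacency",
    "oracle_enn",
]


@dataclass(frozen=True)
class BlockSpec:
    """An axis-aligned rectangle of cells of one class.

    Overlapping blocks resolve later-wins: blocks are painted in list order.
    """

    class_val: int
    row0: int
    col0: int
    height: int
    width: int


def blocks_landscape(canvas, blocks, res=(100.0, 100.0), nodata=0, **kwargs) -> Landscape:
    """Paint rectangular blocks onto a nodata canvas.

    An isolated ``h x w`` block has ``n = h*w`` cells, perimeter
    ``2*(h*cell_width + w*cell_height)`` meters and area
    ``h*w*cell_width*cell_height / 10^4`` hectares.
    """
    rows, cols = canvas
    cells = np.full((rows, cols), nodata, dtype=np.int64)
    for block in blocks:
        if (
            block.row0 < 0
            or block.col0 < 0
            or block.height < 1
            or block.width < 1
            or block.row0 + block.height > rows
            or block.col0 + block.width > cols
        ):
            raise ValueError(f"block {block} does not fit the {canvas} canvas")
        cells[
            block.row0 : block.row0 + block.height,
            block.col0 : block.col0 + block.width,
        ] = block.class_val
    return Landscape(cells, res=res, nodata=nodata, **kwargs)


def random_mosaic(
    canvas,
    class_probs,
    seed,
    res=(100.0, 100.0),
    nodata_prob=0.0,
    nodata=0,
    **kwargs,
) -> Landscape:
    """I.i.d. categorical mosaic: cell classes are 1..m with the given
    probabilities, plus optional nodata cells with ``nodata_prob``.

    ``class_probs`` plus ``nodata_prob`` must sum to 1.
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0 or np.any(probs < 0) or nodata_prob < 0:
        raise ValueError("class_probs must be a vector of nonnegative probabilities")
    total = probs.sum() + nodata_prob
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"probabilities must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    values = np.concatenate([[nodata], np.arange(1, probs.size + 1)])
    full_probs = np.concatenate([[nodata_prob], probs])
    full_probs = full_probs / full_probs.sum()
    cells = rng.choice(values, size=canvas, p=full_probs)
    return Landscape(cells.astype(np.int64), res=res, nodata=nodata, **kwargs)


def reference_patch_landscape(res=100.0, **kwargs) -> Landscape:
    """Three free-form class-1 polyominoes with known geometry.

    * patch 0 — 115 cells with 106 exposed sides (an 8x10 rectangle with a
      35-cell tail), i.e. perimeter 10,600 m and area 115 ha at 100 m cells;
    * patch 1 — 13 cells with 26 exposed sides (a 2x2 block with a 9-cell
      tail, one cycle);
    * patch 2 — a 2-cell domino, 6 exposed sides.

    The closest cell centers of patches 1 and 2 are offset by (2 rows,
    1 column), so both report a nearest-neighbor distance of ``res * sqrt 5``.
    """
    cells = np.zeros((18, 45), dtype=np.int64)
    cells[0:8, 0:10] = 1  # 8x10 rectangle
    cells[0, 10:45] = 1  # 35-cell tail -> 115 cells, 106 sides
    cells[12:14, 0:2] = 1  # 2x2 block
    cells[12, 2:11] = 1  # 9-cell tail -> 13 cells, 26 sides
    cells[15:17, 2] = 1  # domino -> 2 cells, 6 sides
    return Landscape(cells, res=(res, res), nodata=0, **kwargs)


def two_patch_landscape(offset=(2, 1), res=100.0, class_val=1, **kwargs) -> Landscape:
    """Two single-cell patches of one class at the given (row, col) cell
    offset; their nearest-neighbor distance is ``res * hypot(*offset)``."""
    dr, dc = offset
    if (abs(dr) <= 1 and abs(dc) <= 1):
        raise ValueError("offset must separate the cells into distinct patches")
    cells = np.zeros((abs(dr) + 1, abs(dc) + 1), dtype=np.int64)
    cells[0, 0] = class_val
    cells[dr, dc] = class_val
    return Landscape(cells, res=(res, res), nodata=0, **kwargs)


# --------------------------------------------------------------------- oracles


def oracle_segment(ls: Landscape, connectivity=None) -> PatchLabeling:
    """Stack-based flood fill; labels in row-major first-seen order."""
    if connectivity is None:
        connectivity = ls.connectivity
    if connectivity == 4:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity!r}")
    cells = ls.cells
    rows, cols = cells.shape
    labels = np.zeros(cells.shape, dtype=np.int64)
    classes = []
    next_label = 0
    for r in range(rows):
        for c in range(cols):
            if cells[r, c] == ls.nodata or labels[r, c]:
                continue
            next_label += 1
            class_val = cells[r, c]
            classes.append(class_val)
            stack = [(r, c)]
            labels[r, c] = next_label
            while stack:
                rr, cc = stack.pop()
                for dr, dc in moves:
                    nr, nc = rr + dr, cc + dc
                    if (
                        0 <= nr < rows
                        and 0 <= nc < cols
                        and not labels[nr, nc]
                        and cells[nr, nc] == class_val
                    ):
                        labels[nr, nc] = next_label
                        stack.append((nr, nc))
    return PatchLabeling(labels, connectivity, np.asarray(classes, dtype=cells.dtype))


def oracle_adjacency(ls: Landscape) -> AdjacencyTable:
    """Exhaustive enumeration of interior shared sides and border sides."""
    cells = ls.cells
    rows, cols = cells.shape
    data_codes = np.unique(cells[cells != ls.nodata])
    codes = np.concatenate([data_codes, [ls.nodata]]).astype(np.int64)
    idx = {int(v): i for i, v in enumerate(codes)}
    k = len(codes)
    counts_we = np.zeros((k, k), dtype=np.int64)
    counts_ns = np.zeros((k, k), dtype=np.int64)
    border_we = np.zeros(k, dtype=np.int64)
    border_ns = np.zeros(k, dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            a = idx[int(cells[r, c])]
            if c + 1 < cols:
                b = idx[int(cells[r, c + 1])]
                counts_we[min(a, b), max(a, b)] += 1
            if r + 1 < rows:
                b = idx[int(cells[r + 1, c])]
                counts_ns[min(a, b), max(a, b)] += 1
            if c == 0:
                border_we[a] += 1
            if c == cols - 1:
                border_we[a] += 1
            if r == 0:
                border_ns[a] += 1
            if r == rows - 1:
                border_ns[a] += 1
    counts_we = counts_we + np.triu(counts_we, 1).T
    counts_ns = counts_ns + np.triu(counts_ns, 1).T
    return AdjacencyTable(
        codes=codes,
        nodata=ls.nodata,
        counts_we=counts_we,
        counts_ns=counts_ns,
        border_we=border_we,
        border_ns=border_ns,
        cell_width=ls.cell_width,
        cell_height=ls.cell_height,
    )


def oracle_enn(labeling: PatchLabeling, cell_width: float, cell_height: float) -> np.ndarray:
    """All-pairs cell-center distances between every pair of same-class
    patches; NaN for single-patch classes."""
    labels = labeling.labels
    k = labeling.n_patches
    enn = np.full(k, np.nan)
    coords = {}
    for pid in range(1, k + 1):
        rows, cols = np.nonzero(labels == pid)
        coords[pid] = np.column_stack([cols * cell_width, rows * cell_height]).astype(float)
    for class_val in np.unique(labeling.patch_class):
        pids = np.nonzero(labeling.patch_class == class_val)[0] + 1
        if len(pids) < 2:
            continue
        for i, pid in enumerate(pids):
            best = np.inf
            for other in pids:
                if other == pid:
                    continue
                best = min(best, cdist(coords[pid], coords[other]).min())
            enn[pid - 1] = best
    return enn


def verify_adjacency_total(ls: Landscape) -> bool:
    """Counting identity: total shared sides equal
    ``rows*(cols-1) + cols*(rows-1)``."""
    adj = adjacency_table(ls.cells, ls.nodata, ls.cell_width, ls.cell_height)
    total = adj.side_count_matrix()
    # symmetric with unordered-pair counts: sum upper triangle incl diagonal
    s = int(np.triu(total).sum())
    rows, cols = ls.shape
    return s == rows * (cols - 1) + cols * (rows - 1)
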