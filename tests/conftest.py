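import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import patchstats as ps


@pytest.fixture
def reference_patches():
    """Three class-1 polyominoes reproducing the worked patch-level rows:
    (115 cells, 106 sides), (13, 26), (2, 6) at 100 m resolution."""
    return ps.reference_patch_landscape()


@pytest.fixture
def mosaic():
    """Factory for seeded random mosaics."""

    def _make(seed, canvas=(40, 40), probs=(0.4, 0.35, 0.25), **kwargs):
        return ps.random_mosaic(canvas, probs, seed=seed, **kwargs)

    return _make


@pytest.fixture
def georeferenced():
    """A 40x40 2-class landscape with an affine transform, origin top-left
    (0, 4000), 100 m cells."""
    ls = ps.random_mosaic((40, 40), (0.5, 0.5), seed=5)
    return ps.Landscape(
        ls.cells, res=(100, 100), transform=(100, 0, 0, 0, -100, 4000),
        crs="EPSG:32631",
    )


def assert_same_partition(labels_a, labels_b):
    """Two labelings are equivalent iff their nonzero labels are related by a
    bijection (same patches, possibly renumbered)."""
    assert np.array_equal(labels_a > 0, labels_b > 0)
    pairs = np.unique(
        np.column_stack([labels_a[labels_a > 0], labels_b[labels_a > 0]]), axis=0
    )
    assert len(np.unique(pairs[:, 0])) == len(pairs)
    assert len(np.unique(pairs[:, 1])) == len(pairs)
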