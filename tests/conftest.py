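import numpy as np
import pytest

import adiposeg as A


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_cfg():
    """Config sized for 64x64 phantom patches."""
    return A.RunConfig(patch_height=64, patch_width=64, patch_stride=64)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Twenty 64x64 phantoms, half adipose, shared across read-only tests."""
    return A.generate_arrays(20, 0.5, seed=77, height=64, width=64,
                             images_per_sample=2)


def voronoi_partition(rng, shape, n_regions):
    """Random connected partition: nearest-centre Voronoi cells."""
    from scipy.spatial import cKDTree
    from adiposeg.pseudolabel import (SuperpixelPartition,
                                      _adjacency_from_assignment)

    h, w = shape
    pts = np.column_stack([rng.uniform(0, h, n_regions),
                           rng.uniform(0, w, n_regions)])
    rr, cc = np.mgrid[0:h, 0:w]
    _, assign = cKDTree(pts).query(np.column_stack([rr.ravel(), cc.ravel()]))
    _, assign = np.unique(assign, return_inverse=True)
    assign = assign.reshape(shape).astype(np.int32)
    return SuperpixelPartition(assignment=assign,
                               adjacency=_adjacency_from_assignment(assign),
                               requested_count=n_regions)
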