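"""Superpixel seed propagation and Markov spatial regularization.

Masked CAM seeds are sparse; to turn them into dense pseudo labels the
image is partitioned into ~K SLIC superpixels and an entire superpixel is
labeled adipose if any of its pixels carries a seed. Two kinds of residual
error remain: seeds miss adipose regions, and noise/artifacts seed normal
regions. Because adipose cells cluster, a spatial regularization pass
flips the label of any superpixel when at least a quorum (default 80%,
inclusive) of its adjacent superpixels carry the opposite label; sweeps are
synchronous and repeat until a fixed point (at most ``max_iter``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic

from .boundary import detect_surface, mask_seeds
from .interface import BScan, RunConfig
from .localization import LocalizationNet, generate_seed_map

__all__ = [
    "SuperpixelPartition",
    "PseudoLabelMap",
    "compute_superpixels",
    "propagate_seeds",
    "spatial_regularize",
    "generate_pseudolabels",
    "pseudolabel_image",
]

# provenance codes
PROV_BACKGROUND = 0
PROV_FROM_SEED = 1
PROV_ADDED_BY_REG = 2


@dataclass
class SuperpixelPartition:
    """Pixel->superpixel assignment plus the superpixel adjacency graph."""

    assignment: np.ndarray            # int array, ids contiguous from 0
    adjacency: set[tuple[int, int]]   # unordered id pairs (a < b), 4-connected
    requested_count: int

    @property
    def n_superpixels(self) -> int:
        return int(self.assignment.max()) + 1

    def neighbor_lists(self) -> list[np.ndarray]:
        neigh: list[list[int]] = [[] for _ in range(self.n_superpixels)]
        for a, b in self.adjacency:
            neigh[a].append(b)
            neigh[b].append(a)
        return [np.array(sorted(v), dtype=int) for v in neigh]


@dataclass
class PseudoLabelMap:
    """Per-pixel class in {0, 1} plus a provenance flag per pixel."""

    labels: np.ndarray       # uint8 {0,1}
    provenance: np.ndarray   # uint8, PROV_* codes

    def __post_init__(self) -> None:
        if self.labels.shape != self.provenance.shape:
            raise ValueError("labels and provenance must share a shape")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("pseudo labels must be 0 or 1")


def _adjacency_from_assignment(assignment: np.ndarray) -> set[tuple[int, int]]:
    pairs = set()
    for a, b in ((assignment[:, :-1], assignment[:, 1:]),
                 (assignment[:-1, :], assignment[1:, :])):
        diff = a != b
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def compute_superpixels(image: BScan | np.ndarray, K: int,
                        compactness: float = 0.1,
                        sigma: float = 1.0) -> SuperpixelPartition:
    """SLIC partition of a grayscale image into ~K superpixels.

    ``sigma`` is a Gaussian pre-smoothing width that suppresses speckle so
    superpixel borders follow tissue boundaries rather than noise grains.
    Ids are relabeled to contiguous integers from 0; adjacency is derived
    from 4-connected borders of the final assignment.
    """
    px = image.pixels if isinstance(image, BScan) else np.asarray(image)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > px.size:
        raise ValueError("K exceeds the pixel count")
    if K == 1:
        assignment = np.zeros(px.shape, dtype=np.int32)
    else:
        seg = slic(px.astype(np.float64), n_segments=K,
                   compactness=compactness, channel_axis=None, start_label=0,
                   enforce_connectivity=True, sigma=sigma)
        _, assignment = np.unique(seg, return_inverse=True)
        assignment = assignment.reshape(px.shape).astype(np.int32)
    return SuperpixelPartition(assignment=assignment,
                               adjacency=_adjacency_from_assignment(assignment),
                               requested_count=K)


def propagate_seeds(seeds: np.ndarray, sp: SuperpixelPartition
                    ) -> PseudoLabelMap:
    """Label a whole superpixel adipose if it contains at least one seed."""
    seeds = np.asarray(seeds)
    if seeds.shape != sp.assignment.shape:
        raise ValueError("seed map and partition shapes differ")
    n = sp.n_superpixels
    seeded = np.bincount(sp.assignment.ravel(),
                         weights=seeds.ravel().astype(np.float64),
                         minlength=n) > 0
    labels = seeded[sp.assignment].astype(np.uint8)
    prov = np.where(labels == 1, PROV_FROM_SEED, PROV_BACKGROUND
                    ).astype(np.uint8)
    return PseudoLabelMap(labels=labels, provenance=prov)


def _superpixel_labels(labels: np.ndarray, sp: SuperpixelPartition) -> np.ndarray:
    n = sp.n_superpixels
    flat = sp.assignment.ravel()
    first = np.full(n, -1, dtype=np.int64)
    # any representative pixel works: labels are constant per superpixel
    first[flat[::-1]] = np.arange(labels.size - 1, -1, -1)
    sp_lab = labels.ravel()[first]
    counts = np.bincount(flat, weights=labels.ravel().astype(np.float64),
                         minlength=n)
    sizes = np.bincount(flat, minlength=n)
    if not np.array_equal(counts > 0, sp_lab.astype(bool)) or \
            not np.all((counts == 0) | (counts == sizes)):
        raise ValueError("labels are not constant within superpixels")
    return sp_lab.astype(np.uint8)


def spatial_regularize(labels: PseudoLabelMap | np.ndarray,
                       sp: SuperpixelPartition, quorum: float = 0.8,
                       max_iter: int = 10) -> tuple[PseudoLabelMap, int]:
    """Flip superpixels outvoted by >= ``quorum`` of their neighbours.

    Synchronous sweeps until no superpixel flips or ``max_iter`` sweeps.
    Returns the regularized map and the number of sweeps that changed
    something.
    """
    if not 0.0 < quorum <= 1.0:
        raise ValueError("quorum must lie in (0, 1]")
    if isinstance(labels, PseudoLabelMap):
        pix_labels = labels.labels
        prov_in = labels.provenance
    else:
        pix_labels = np.asarray(labels).astype(np.uint8)
        prov_in = np.where(pix_labels == 1, PROV_FROM_SEED, PROV_BACKGROUND
                           ).astype(np.uint8)
    sp_lab = _superpixel_labels(pix_labels, sp).astype(np.int8)
    neigh = sp.neighbor_lists()
    deg = np.array([len(v) for v in neigh], dtype=np.float64)
    sweeps = 0
    for _ in range(max_iter):
        opposite = np.zeros(sp_lab.shape[0], dtype=np.float64)
        for i, nb in enumerate(neigh):
            if len(nb):
                opposite[i] = np.count_nonzero(sp_lab[nb] != sp_lab[i])
        flip = np.zeros(sp_lab.shape[0], dtype=bool)
        has_nb = deg > 0
        flip[has_nb] = (opposite[has_nb] / deg[has_nb]) >= quorum
        if not flip.any():
            break
        sp_lab[flip] = 1 - sp_lab[flip]
        sweeps += 1
    out_labels = sp_lab.astype(np.uint8)[sp.assignment]
    prov = np.where(out_labels == 1,
                    np.where(prov_in == PROV_FROM_SEED, PROV_FROM_SEED,
                             PROV_ADDED_BY_REG),
                    PROV_BACKGROUND).astype(np.uint8)
    return PseudoLabelMap(labels=out_labels, provenance=prov), sweeps


def pseudolabel_image(image: BScan | np.ndarray, seeds: np.ndarray,
                      cfg: RunConfig, apply_boundary_mask: bool = True,
                      apply_regularization: bool = True) -> PseudoLabelMap:
    """Seeds -> boundary masking -> superpixel propagation -> regularization."""
    px = image.pixels if isinstance(image, BScan) else np.asarray(image)
    if apply_boundary_mask and seeds.any():
        surface = detect_surface(px, smooth_sigma=cfg.surface_smooth_sigma)
        seeds = mask_seeds(seeds, surface, margin=cfg.boundary_margin)
    if not seeds.any():
        zero = np.zeros(px.shape, dtype=np.uint8)
        return PseudoLabelMap(labels=zero, provenance=zero.copy())
    sp = compute_superpixels(px, cfg.superpixels_for(px.shape),
                             cfg.superpixel_compactness,
                             cfg.superpixel_sigma)
    pl = propagate_seeds(seeds, sp)
    if apply_regularization:
        pl, _ = spatial_regularize(pl, sp, cfg.regularization_quorum,
                                   cfg.regularization_max_iter)
    return pl


def generate_pseudolabels(images: list[np.ndarray], net: LocalizationNet,
                          cfg: RunConfig, apply_boundary_mask: bool = True,
                          apply_regularization: bool = True
                          ) -> list[PseudoLabelMap]:
    """Full first-stage run: CAM seeds, boundary masking, propagation,
    regularization, for every image.

    Images the classifier predicts non-adipose get all-zero pseudo masks.
    """
    out = []
    for image in images:
        seeds, label = generate_seed_map(net, image, cfg)
        if label == 0:
            zero = np.zeros(np.asarray(image).shape, dtype=np.uint8)
            out.append(PseudoLabelMap(labels=zero, provenance=zero.copy()))
            continue
        out.append(pseudolabel_image(image, seeds, cfg,
                                     apply_boundary_mask,
                                     apply_regularization))
    return out
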