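"""Synthetic OCT B-scan phantoms with ground-truth adipose masks.

The human cardiac OCT data this pipeline targets is not publicly deposited,
so this module generates B-scan-like images that reproduce the statistical
structure the method has to cope with:

* a tissue/background surface boundary (tilted, gently waved),
* exponential depth attenuation of the backscattered signal below the
  surface, modulated by a Gaussian focal-plane gain,
* multiplicative gamma-distributed speckle whose texture is easy to confuse
  with adipose tissue,
* adipose deposits rendered as honeycomb texture (bright cell walls around
  dark lumens) inside elliptical blobs, darker and lower-contrast when deep,
* class imbalance: by default only ~11% of images contain adipose at all,
  and adipose pixels are a few percent of an adipose image.

Coordinates follow the B-scan convention: row 0 is the top of the image
(shallowest), row index increases with depth; all rectangles are 0-based and
half-open.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .interface import BScan, DatasetManifest, ManifestRecord, write_image, write_mask

__all__ = [
    "AdiposeBlobSpec",
    "PhantomSpec",
    "GroundTruth",
    "surface_curve",
    "axial_gain",
    "generate_bscan",
    "sample_spec",
    "generate_arrays",
    "generate_dataset",
]

# Intensity of the (air/saline) region above the tissue surface, before speckle.
BACKGROUND_DARK = 0.03
# Width of the focal gain profile as a fraction of image height.
FOCAL_SIGMA_FRAC = 0.125
# Honeycomb rendering: lumen darkening and wall brightening at full contrast.
LUMEN_DEPTH = 0.75
WALL_BOOST = 0.6
WALL_THICKNESS = 1.2  # pixels, Voronoi-edge band half-width


@dataclass(frozen=True)
class AdiposeBlobSpec:
    """One elliptical adipose deposit."""

    center_row: float
    center_col: float
    radius_row: float
    radius_col: float
    cell_diameter: float  # honeycomb period, pixels
    contrast: float       # wall-vs-lumen contrast in [0, 1]

    def validate(self) -> None:
        if min(self.radius_row, self.radius_col) < self.cell_diameter:
            raise ValueError("blob radii must be >= cell_diameter")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative knobs for one synthetic B-scan."""

    height: int = 512
    width: int = 800
    surface_row: float = 90.0          # mean surface depth, pixels
    surface_tilt: float = 0.0          # pixels per column
    surface_wave_amp: float = 0.0      # pixels
    attenuation_coeff: float = 0.004   # 1/pixel, exp decay below surface
    focal_row: float = 180.0
    focal_gain: float = 1.5            # >= 1
    speckle_scale: float = 0.25        # multiplicative noise dispersion; 0 = off
    blob_specs: tuple[AdiposeBlobSpec, ...] = field(default_factory=tuple)
    background_level: float = 0.5      # tissue intensity at the surface, in [0, 1]

    def validate(self) -> None:
        if not 0 < self.surface_row < self.height:
            raise ValueError("surface_row must lie strictly inside the image")
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff must be >= 0")
        if self.focal_gain < 1:
            raise ValueError("focal_gain must be >= 1")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        surf = surface_curve(self)
        for blob in self.blob_specs:
            blob.validate()
            r0 = blob.center_row - blob.radius_row
            r1 = blob.center_row + blob.radius_row
            c0 = blob.center_col - blob.radius_col
            c1 = blob.center_col + blob.radius_col
            if r0 < 0 or r1 >= self.height or c0 < 0 or c1 >= self.width:
                raise ValueError("blob ellipse exceeds image bounds")
            col = int(np.clip(round(blob.center_col), 0, self.width - 1))
            if blob.center_row <= surf[col]:
                raise ValueError("blob center must lie below the surface curve")


@dataclass(frozen=True)
class GroundTruth:
    """Pixel mask (1 = adipose) and the image-level presence label."""

    mask: np.ndarray          # uint8 {0,1}, same shape as the image
    image_label: int          # 1 iff mask contains any adipose pixel


def surface_curve(spec: PhantomSpec) -> np.ndarray:
    """Float row index of the tissue surface for every column."""
    cols = np.arange(spec.width, dtype=np.float64)
    curve = (spec.surface_row
             + spec.surface_tilt * (cols - spec.width / 2.0)
             + spec.surface_wave_amp * np.sin(2.0 * np.pi * cols / spec.width))
    return np.clip(curve, 1.0, spec.height - 2.0)


def axial_gain(spec: PhantomSpec, rows: np.ndarray) -> np.ndarray:
    """Gaussian focal-plane gain profile as a function of absolute row."""
    sigma = FOCAL_SIGMA_FRAC * spec.height
    return 1.0 + (spec.focal_gain - 1.0) * np.exp(
        -((np.asarray(rows, dtype=np.float64) - spec.focal_row) ** 2)
        / (2.0 * sigma ** 2))


def _honeycomb_multiplier(spec: PhantomSpec,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Texture multiplier field and the adipose mask for all blobs.

    Cell walls are the edges of a Voronoi partition of jittered
    hexagonal-lattice cell centers, smoothed with a small Gaussian; walls
    brighten the local signal and lumens darken it, scaled by the blob's
    contrast.
    """
    h, w = spec.height, spec.width
    mult = np.ones((h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=bool)
    surf = surface_curve(spec)
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    for blob in spec.blob_specs:
        ellipse = (((rows - blob.center_row) / blob.radius_row) ** 2
                   + ((cols - blob.center_col) / blob.radius_col) ** 2) <= 1.0
        ellipse &= rows > surf[None, :]
        if not ellipse.any():
            continue
        rr, cc = np.nonzero(ellipse)
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        d = blob.cell_diameter
        # jittered hexagonal lattice of cell centers covering the bbox
        ys = np.arange(r0 - d, r1 + d, d * np.sqrt(3.0) / 2.0)
        centers = []
        for i, y in enumerate(ys):
            xoff = (d / 2.0) if i % 2 else 0.0
            xs = np.arange(c0 - d + xoff, c1 + d, d)
            centers.append(np.column_stack([np.full_like(xs, y), xs]))
        centers = np.concatenate(centers)
        centers += rng.uniform(-0.15 * d, 0.15 * d, size=centers.shape)
        tree = cKDTree(centers)
        pts = np.column_stack([rr, cc]).astype(np.float64)
        dist, _ = tree.query(pts, k=2)
        wall = (dist[:, 1] - dist[:, 0]) < WALL_THICKNESS
        local = np.where(wall,
                         1.0 + WALL_BOOST * blob.contrast,
                         1.0 - LUMEN_DEPTH * blob.contrast)
        patch = np.ones((r1 - r0, c1 - c0), dtype=np.float64)
        patch[rr - r0, cc - c0] = local
        patch = gaussian_filter(patch, sigma=0.6, mode="nearest")
        sub = mult[r0:r1, c0:c1]
        sub[ellipse[r0:r1, c0:c1]] = patch[ellipse[r0:r1, c0:c1]]
        mask |= ellipse
    return mult, mask


def generate_bscan(spec: PhantomSpec, seed: int) -> tuple[BScan, GroundTruth]:
    """Render one phantom B-scan with its ground truth.

    Deterministic: identical ``(spec, seed)`` gives bit-identical output.
    With ``speckle_scale == 0`` and no blobs the image below the surface is
    exactly ``background_level * axial_gain(row) * exp(-mu * depth)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    surf = surface_curve(spec)
    rows = np.arange(h, dtype=np.float64)[:, None]
    depth = rows - surf[None, :]
    tissue = depth > 0

    base = (spec.background_level
            * axial_gain(spec, rows)
            * np.exp(-spec.attenuation_coeff * np.maximum(depth, 0.0)))
    image = np.where(tissue, base, BACKGROUND_DARK)

    mult, mask = _honeycomb_multiplier(spec, rng)
    image = image * mult

    if spec.speckle_scale > 0:
        shape = 1.0 / spec.speckle_scale ** 2
        speckle = rng.gamma(shape, 1.0 / shape, size=(h, w))
        image = image * speckle

    image = np.clip(image, 0.0, 1.0)
    gt = GroundTruth(mask=mask.astype(np.uint8), image_label=int(mask.any()))
    scan = BScan(pixels=image.astype(np.float32), source_path="", sample_id="")
    return scan, gt


def sample_spec(rng_seed: int | np.random.Generator,
                adipose_prob: float = 0.11,
                height: int = 512,
                width: int = 800) -> PhantomSpec:
    """Draw a random phantom spec.

    ``adipose_prob`` is the probability the image contains any adipose
    deposit; the default 0.11 reproduces the adipose-image rarity of the
    cardiac cohort this generator emulates. Surface and optics geometry
    scale with the image size, but fat-cell diameter and blob radii are
    anatomical: they are drawn in absolute pixels (at the reference digital
    resolution) and clipped to fit, so a small image behaves like a patch
    cropped from a full B-scan, with a higher relative adipose area.
    """
    if not 0.0 <= adipose_prob <= 1.0:
        raise ValueError("adipose_prob must lie in [0, 1]")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    h, w = height, width
    surface_row = rng.uniform(0.12, 0.25) * h
    spec_kwargs = dict(
        height=h,
        width=w,
        surface_row=surface_row,
        surface_tilt=rng.uniform(-0.02, 0.02) * h / w,
        surface_wave_amp=rng.uniform(0.0, 0.02) * h,
        attenuation_coeff=rng.uniform(1.0, 2.5) / (0.6 * h),
        focal_row=surface_row + rng.uniform(0.10, 0.30) * h,
        focal_gain=rng.uniform(1.2, 1.8),
        speckle_scale=rng.uniform(0.15, 0.30),
        background_level=rng.uniform(0.35, 0.55),
    )
    blobs: list[AdiposeBlobSpec] = []
    if rng.random() < adipose_prob:
        n_blobs = int(1 + min(rng.poisson(1.0), 2))
        wave = spec_kwargs["surface_wave_amp"]
        # deepest usable surface row across columns
        surf_max = surface_row + abs(spec_kwargs["surface_tilt"]) * w / 2 + wave
        for _ in range(n_blobs):
            # anatomical sizes in absolute pixels, clipped to the image
            max_rr = max(4.0, min(0.28 * h, (h - surf_max - 4.0) / 2.0))
            max_rc = max(4.0, 0.28 * w)
            radius_row = min(rng.uniform(26.0, 56.0), max_rr)
            radius_col = min(rng.uniform(40.0, 88.0), max_rc)
            cell_d = min(rng.uniform(6.0, 10.0),
                         max(3.0, min(radius_row, radius_col)))
            row_lo = surf_max + radius_row + 2.0
            row_hi = min(h - radius_row - 1.0, surface_row + 0.60 * h)
            if row_hi <= row_lo:
                row_hi = row_lo + 1.0
            center_row = rng.uniform(row_lo, max(min(row_hi, h - radius_row - 1.0),
                                                 row_lo + 0.5))
            center_col = rng.uniform(radius_col + 1.0, w - radius_col - 2.0)
            rel_depth = (center_row - surface_row) / h
            contrast = float(np.clip(rng.uniform(0.55, 0.9) * (1.0 - 0.4 * rel_depth),
                                     0.2, 1.0))
            blobs.append(AdiposeBlobSpec(
                center_row=float(center_row),
                center_col=float(center_col),
                radius_row=float(radius_row),
                radius_col=float(radius_col),
                cell_diameter=float(cell_d),
                contrast=contrast,
            ))
    spec = PhantomSpec(blob_specs=tuple(blobs), **spec_kwargs)
    spec.validate()
    return spec


def generate_arrays(n: int, adipose_prob: float, seed: int,
                    height: int = 512, width: int = 800,
                    images_per_sample: int = 9,
                    ) -> list[tuple[np.ndarray, np.ndarray, int, str]]:
    """Generate ``n`` phantoms in memory.

    Returns a list of ``(image, mask, label, sample_id)``. Images are grouped
    into pseudo-subjects of ``images_per_sample`` consecutive scans so that
    grouped cross-validation splits have something to group by (mirroring
    multiple B-scans acquired from the same heart).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        spec = sample_spec(rng, adipose_prob, height=height, width=width)
        render_seed = int(rng.integers(0, 2**31 - 1))
        scan, gt = generate_bscan(spec, render_seed)
        sample_id = f"S{i // images_per_sample:03d}"
        out.append((scan.pixels, gt.mask, gt.image_label, sample_id))
    return out


def generate_dataset(n: int, adipose_prob: float, out_dir: str | Path,
                     seed: int, height: int = 512, width: int = 800,
                     images_per_sample: int = 9) -> DatasetManifest:
    """Write ``n`` phantom images (16-bit TIFF), masks ({0,1} PNG) and a CSV manifest."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (image, mask, label, sample_id) in enumerate(
            generate_arrays(n, adipose_prob, seed, height, width,
                            images_per_sample)):
        img_path = img_dir / f"bscan_{i:04d}.tiff"
        msk_path = msk_dir / f"bscan_{i:04d}_mask.png"
        write_image(img_path, image)
        write_mask(msk_path, mask)
        records.append(ManifestRecord(image_path=str(img_path),
                                      mask_path=str(msk_path),
                                      label=int(label),
                                      sample_id=sample_id))
    manifest = DatasetManifest(records=records)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
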