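"""Data containers, file I/O, run configuration and patch crop/stitch.

Images travel through the pipeline as float arrays in [0, 1]; on disk they
are 16-bit grayscale TIFFs. Masks and seed maps are {0, 1} 8-bit PNGs.
The dataset manifest is a CSV with columns ``path,mask_path,label,sample_id``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "BScan",
    "ManifestRecord",
    "DatasetManifest",
    "RunConfig",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "crop_patches",
    "patch_offsets",
    "stitch_maps",
    "write_run_manifest",
]


@dataclass(frozen=True)
class BScan:
    """One grayscale OCT cross-section plus provenance metadata."""

    pixels: np.ndarray          # 2-D float array in [0, 1]
    source_path: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("BScan must be a 2-D image of at least 16x16 pixels")
        if not np.isfinite(px).all():
            raise ValueError("BScan contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    mask_path: str | None
    label: int
    sample_id: str


@dataclass
class DatasetManifest:
    """Rows of (image path, optional mask path, image label, sample id)."""

    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {r.label!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.image_path, r.mask_path or "", r.label, r.sample_id)
             for r in self.records],
            columns=["path", "mask_path", "label", "sample_id"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, check_paths: bool = True
                 ) -> "DatasetManifest":
        df = pd.read_csv(path, dtype={"path": str, "mask_path": str,
                                      "label": int, "sample_id": str},
                         keep_default_na=False)
        records = []
        for row in df.itertuples(index=False):
            if check_paths and not Path(row.path).exists():
                raise FileNotFoundError(f"manifest image missing: {row.path}")
            mask_path = row.mask_path or None
            if check_paths and mask_path and not Path(mask_path).exists():
                raise FileNotFoundError(f"manifest mask missing: {mask_path}")
            records.append(ManifestRecord(image_path=row.path,
                                          mask_path=mask_path,
                                          label=int(row.label),
                                          sample_id=str(row.sample_id)))
        return cls(records=records)


@dataclass
class RunConfig:
    """All pipeline knobs; every stage reads from one of these.

    Defaults follow the reference operating point: 512x128 overlapping
    patches, CAM background threshold 0.15, ~2000 superpixels on a full
    512x800 B-scan (``superpixel_count`` is rescaled by area for other image
    sizes when ``scale_superpixels`` is on), an 80% neighbour quorum for
    spatial regularization, and alpha2 = 0.5 for the Dice term.
    """

    patch_height: int = 512
    patch_width: int = 128
    patch_stride: int = 112
    superpixel_count: int = 2000
    scale_superpixels: bool = True
    superpixel_compactness: float = 0.1
    superpixel_sigma: float = 1.0
    cam_threshold: float = 0.15
    boundary_margin: int = 10
    surface_smooth_sigma: float = 3.0
    regularization_quorum: float = 0.8
    regularization_max_iter: int = 10
    alpha2: float = 0.5
    loc_channels: tuple[int, int, int] = (32, 32, 64)
    loc_epochs: int = 60
    loc_batch_size: int = 16
    loc_learning_rate: float = 1e-3
    seg_depth: int = 3
    seg_base_width: int = 8
    seg_epochs: int = 25
    seg_batch_size: int = 32
    seg_learning_rate: float = 1e-3
    seg_lr_decay_at: int | None = None   # epoch index; None = constant lr
    seg_lr_decay_factor: float = 0.3
    seg_weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cam_threshold < 1.0:
            raise ValueError("cam_threshold must lie in (0, 1)")
        if not 0.0 < self.regularization_quorum <= 1.0:
            raise ValueError("regularization_quorum must lie in (0, 1]")
        if self.patch_stride > self.patch_width:
            raise ValueError("patch_stride must be <= patch_width")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be >= 0")

    def superpixels_for(self, shape: tuple[int, int]) -> int:
        """Superpixel count for an image, preserving the reference density."""
        if not self.scale_superpixels:
            return self.superpixel_count
        ref_area = 512 * 800
        k = round(self.superpixel_count * (shape[0] * shape[1]) / ref_area)
        return max(2, int(k))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "loc_channels" in data:
            data["loc_channels"] = tuple(data["loc_channels"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["loc_channels"] = list(data["loc_channels"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# --------------------------------------------------------------------------
# image / mask I/O

def write_image(path: str | Path, image: np.ndarray) -> None:
    """Store a [0, 1] float image as 16-bit grayscale TIFF."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    tifffile.imwrite(str(path), np.round(arr * 65535.0).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image (TIFF or PNG, 8/16-bit) scaled to [0, 1]."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return arr.astype(np.float32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Store a binary mask as an 8-bit PNG with values {0, 1}."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    iio.imwrite(str(path), arr.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


# --------------------------------------------------------------------------
# patch cropping and stitching

def patch_offsets(width: int, patch_width: int, stride: int) -> list[int]:
    """Column offsets tiling ``width``; the last patch is right-aligned if
    the stride does not land flush."""
    if width < patch_width:
        raise ValueError("image narrower than patch_width")
    offsets = list(range(0, width - patch_width + 1, stride))
    if offsets[-1] + patch_width < width:
        offsets.append(width - patch_width)
    return offsets


def crop_patches(image: BScan | np.ndarray, cfg: RunConfig
                 ) -> list[tuple[np.ndarray, int]]:
    """Crop a B-scan into overlapping full-height patches.

    Returns ``(patch, column_offset)`` pairs covering every column. Patch
    height is min(cfg.patch_height, image height).
    """
    px = image.pixels if isinstance(image, BScan) else np.asarray(image)
    ph = min(cfg.patch_height, px.shape[0])
    pw = cfg.patch_width
    return [(px[:ph, off:off + pw], off)
            for off in patch_offsets(px.shape[1], pw, cfg.patch_stride)]


def stitch_maps(patch_maps: list[tuple[np.ndarray, int]], width: int,
                mode: str = "mean") -> np.ndarray:
    """Recombine per-patch maps into a full-width map.

    ``mode='mean'`` averages overlapping columns (probability maps);
    ``mode='or'`` takes the logical OR (binary seed maps).
    """
    if not patch_maps:
        raise ValueError("patch_maps is empty")
    height = patch_maps[0][0].shape[0]
    if mode == "or":
        out = np.zeros((height, width), dtype=bool)
        for pm, off in patch_maps:
            if off < 0 or off + pm.shape[1] > width:
                raise ValueError("patch offset outside target width")
            out[:, off:off + pm.shape[1]] |= pm.astype(bool)
        return out.astype(np.uint8)
    if mode == "mean":
        acc = np.zeros((height, width), dtype=np.float64)
        cnt = np.zeros(width, dtype=np.float64)
        for pm, off in patch_maps:
            if off < 0 or off + pm.shape[1] > width:
                raise ValueError("patch offset outside target width")
            acc[:, off:off + pm.shape[1]] += pm
            cnt[off:off + pm.shape[1]] += 1.0
        if (cnt == 0).any():
            raise ValueError("patches do not cover every column")
        return acc / cnt[None, :]
    raise ValueError(f"unknown stitch mode {mode!r}")


def write_run_manifest(path: str | Path, cfg: RunConfig, command: str,
                       extra: dict | None = None) -> None:
    """JSON provenance record written next to every CLI command's output."""
    import adiposeg
    payload = {
        "command": command,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "adiposeg": adiposeg.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
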