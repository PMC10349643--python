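"""Image-level adipose classifier, class activation maps and seed extraction.

A three-layer convolutional classifier (channels 32/32/64, ReLU, two
stride-2 convolutions giving a 1/4-resolution feature grid) ends in global
average pooling and a single linear layer to two logits. The class
activation map for the adipose class is the classifier-weight-weighted sum
of the final convolutional feature maps,

    M(w) = sum_j mu_j f_j(w),

computed at feature resolution, min-max normalized per image, bilinearly
upsampled to image resolution, and thresholded (default 0.15, inclusive) to
produce sparse adipose seed pixels. Seeds are gated on the classifier's own
predicted image label so that inference needs no ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from . import nn
from .interface import BScan, RunConfig, crop_patches, stitch_maps

__all__ = [
    "CamMap",
    "LocalizationNet",
    "train_localizer",
    "compute_cam",
    "normalize_and_upsample",
    "extract_seeds",
    "generate_seed_map",
]


@dataclass
class CamMap:
    """A class activation map; ``normalized`` marks min-max scaling to [0,1]."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValueError("CAM is empty")
        if not np.isfinite(self.values).all():
            raise ValueError("CAM contains non-finite values")


class LocalizationNet:
    """Small GAP classifier; fully convolutional up to the pooling head."""

    DOWNSAMPLE = 4

    def __init__(self, rng: np.random.Generator,
                 channels: tuple[int, int, int] = (32, 32, 64)) -> None:
        c1, c2, c3 = channels
        self.channels = tuple(channels)
        self.conv1 = nn.Conv2d(rng, 1, c1, stride=2, name="loc.conv1")
        self.conv2 = nn.Conv2d(rng, c1, c2, stride=2, name="loc.conv2")
        self.conv3 = nn.Conv2d(rng, c2, c3, stride=1, name="loc.conv3")
        self.relu1, self.relu2, self.relu3 = nn.ReLU(), nn.ReLU(), nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(rng, c3, 2, name="loc.fc")

    @property
    def params(self) -> list[nn.Param]:
        return (self.conv1.params + self.conv2.params + self.conv3.params
                + self.fc.params)

    @property
    def class_weights(self) -> np.ndarray:
        """mu_j for the adipose class (one weight per final-layer unit)."""
        return self.fc.W.value[1].copy()

    def forward_features(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.relu2.forward(self.conv2.forward(h, train), train)
        return self.relu3.forward(self.conv3.forward(h, train), train)

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        f = self.forward_features(x, train)
        return self.fc.forward(self.gap.forward(f, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.gap.backward(self.fc.backward(dlogits))
        d = self.conv3.backward(self.relu3.backward(d))
        d = self.conv2.backward(self.relu2.backward(d))
        self.conv1.backward(self.relu1.backward(d))

    # ---- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {p.name: p.value for p in self.params}
        np.savez(path, channels=np.array(self.channels), **arrays)

    @classmethod
    def load(cls, path) -> "LocalizationNet":
        data = np.load(path)
        net = cls(np.random.default_rng(0),
                  channels=tuple(int(c) for c in data["channels"]))
        for p in net.params:
            p.value[...] = data[p.name]
        return net


def _pad_to_multiple(px: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = px.shape
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        px = np.pad(px, ((0, ph), (0, pw)), mode="reflect")
    return px, (h, w)


def _as_batch(images: list[np.ndarray], mult: int) -> np.ndarray:
    padded = [_pad_to_multiple(np.asarray(im, dtype=np.float32), mult)[0]
              for im in images]
    return np.stack(padded)[:, None, :, :]


def train_localizer(data: list[tuple[np.ndarray, int]], cfg: RunConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[LocalizationNet, list[float]]:
    """Train the GAP classifier on (image, image_label) pairs.

    Cross-entropy on the two logits, Adam (lr ``cfg.loc_learning_rate``),
    Glorot-uniform init, batch ``cfg.loc_batch_size``. All images must share
    one shape (crop to patches first if they do not). Returns the trained
    network and the per-epoch mean loss trajectory.
    """
    labels = np.array([lab for _, lab in data], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training manifest must contain both classes")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    net = LocalizationNet(rng, cfg.loc_channels)
    opt = nn.Adam(net.params, lr=cfg.loc_learning_rate)
    x_all = _as_batch([im for im, _ in data], LocalizationNet.DOWNSAMPLE)
    n = len(data)
    bs = cfg.loc_batch_size
    history: list[float] = []
    for _ in range(cfg.loc_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = x_all[idx], labels[idx]
            logits = net.forward_logits(xb, train=True)
            probs = nn.softmax_logits(logits)
            eps = 1e-12
            losses.append(float(
                -np.log(np.maximum(probs[np.arange(len(idx)), yb], eps)).mean()))
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(idx)), yb] = 1.0
            dlogits = ((probs - onehot) / len(idx)).astype(np.float32)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
        history.append(float(np.mean(losses)))
    return net, history


def predict_label(net: LocalizationNet, image: BScan | np.ndarray
                  ) -> tuple[int, float]:
    """Predicted image label and softmax adipose probability.

    The decision threshold is 0.5 on the adipose probability; an exact tie
    goes to the non-adipose class.
    """
    px = image.pixels if isinstance(image, BScan) else np.asarray(image)
    x = _as_batch([px], LocalizationNet.DOWNSAMPLE)
    p1 = float(nn.softmax_logits(net.forward_logits(x, train=False))[0, 1])
    return int(p1 > 0.5), p1


def compute_cam(features: np.ndarray, class_weights: np.ndarray) -> CamMap:
    """Weighted sum of unit activations: M(w) = sum_j mu_j f_j(w).

    ``features`` is (J, h, w) at feature resolution; ``class_weights`` has
    one weight per unit.
    """
    features = np.asarray(features, dtype=np.float64)
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if features.ndim != 3 or class_weights.ndim != 1 \
            or features.shape[0] != class_weights.shape[0]:
        raise ValueError("need one class weight per feature unit")
    return CamMap(values=np.tensordot(class_weights, features, axes=(0, 0)),
                  normalized=False)


def normalize_and_upsample(cam: CamMap, image_shape: tuple[int, int]) -> CamMap:
    """Per-image min-max normalization to [0, 1], then bilinear upsampling.

    A constant CAM maps to all zeros. Upsampling aligns the corner samples
    of the two grids, so corner values are preserved exactly.
    """
    v = cam.values.astype(np.float64)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        norm = np.zeros_like(v)
    else:
        norm = (v - lo) / (hi - lo)
    H, W = image_shape
    h, w = norm.shape
    if (h, w) == (H, W):
        up = norm
    else:
        rr = np.linspace(0.0, h - 1.0, H)
        cc = np.linspace(0.0, w - 1.0, W)
        grid = np.meshgrid(rr, cc, indexing="ij")
        up = map_coordinates(norm, grid, order=1, mode="nearest")
    return CamMap(values=up, normalized=True)


def extract_seeds(cam: CamMap, predicted_label: int,
                  threshold: float = 0.15) -> np.ndarray:
    """Binary seed map: seed where cam >= threshold, gated on the label.

    Images classified non-adipose yield empty seed maps.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if not cam.normalized:
        raise ValueError("extract_seeds expects a normalized CAM")
    if predicted_label == 0:
        return np.zeros(cam.values.shape, dtype=np.uint8)
    return (cam.values >= threshold).astype(np.uint8)


def generate_seed_map(net: LocalizationNet, image: BScan | np.ndarray,
                      cfg: RunConfig) -> tuple[np.ndarray, int]:
    """Full-image seed map via overlapping patches, OR-fused.

    Each patch is classified independently; its CAM is normalized, upsampled
    and thresholded only if the patch is predicted adipose. Returns the
    stitched seed map and the image-level predicted label (1 if any patch
    fired).
    """
    px = image.pixels if isinstance(image, BScan) else np.asarray(image)
    patch_seeds = []
    any_label = 0
    for patch, off in crop_patches(px, cfg):
        label, _ = predict_label(net, patch)
        any_label |= label
        padded, orig = _pad_to_multiple(patch.astype(np.float32),
                                        LocalizationNet.DOWNSAMPLE)
        feats = net.forward_features(padded[None, None], train=False)[0]
        cam = normalize_and_upsample(compute_cam(feats, net.class_weights),
                                     padded.shape)
        cam = CamMap(values=cam.values[:orig[0], :orig[1]], normalized=True)
        patch_seeds.append((extract_seeds(cam, label, cfg.cam_threshold), off))
    seeds = stitch_maps(patch_seeds, px.shape[1], mode="or")
    return seeds, any_label
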