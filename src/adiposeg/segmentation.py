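"""Segmentation network and the combined cross-entropy / seed / Dice loss.

Adipose pixels are a few percent of a cardiac B-scan, and the pseudo labels
the first stage produces both miss adipose regions (false negatives) and
mark noise (false positives). The training objective combines three terms
over the per-pixel class probabilities p_k(w), k in {0, 1}, and the binary
pseudo label s(w):

* CEL, ordinary per-pixel cross entropy averaged over all pixels;
* ASL, the adipose seed loss: cross entropy restricted to pseudo-adipose
  pixels only, so the network is not punished for finding adipose the
  pseudo labels missed;
* DL, a two-class soft Dice loss for spatial context.

    Loss = alpha1 * CEL + (1 - alpha1) * ASL + alpha2 * DL

alpha1 is chosen from the adipose-image ratio of the training set (1.0 when
adipose images are rarer than 5%, else 0.5) and alpha2 defaults to 0.5.

Probability maps are (2, H, W) arrays with channels summing to 1; pseudo
labels are (H, W) arrays in {0, 1}. Each loss has a matching analytic
gradient with respect to p used by the trainer (and checked against finite
differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .interface import BScan, RunConfig

__all__ = [
    "LossWeights",
    "cross_entropy_loss",
    "adipose_seed_loss",
    "dice_loss",
    "combined_loss",
    "cross_entropy_grad",
    "adipose_seed_grad",
    "dice_grad",
    "combined_grad",
    "select_alpha1",
    "UNet",
    "train_segmenter",
    "predict_mask",
]


@dataclass(frozen=True)
class LossWeights:
    alpha1: float = 0.5   # CEL weight; ASL gets (1 - alpha1)
    alpha2: float = 0.5   # Dice weight
    epsilon: float = 1e-7  # probability floor inside logs

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha1 <= 1.0:
            raise ValueError("alpha1 must lie in [0, 1]")
        if self.alpha2 < 0:
            raise ValueError("alpha2 must be >= 0")


def _check(p: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    s = np.asarray(s)
    if p.ndim != 3 or p.shape[0] != 2 or p.shape[1:] != s.shape:
        raise ValueError("expected p of shape (2, H, W) and s of shape (H, W)")
    return p, s.astype(np.float64)


def cross_entropy_loss(p: np.ndarray, s: np.ndarray,
                       eps: float = 1e-7) -> float:
    """Mean per-pixel cross entropy, -(1/|O|) sum_w sum_k s_k log p_k."""
    p, s = _check(p, s)
    pc = np.clip(p, eps, 1.0)
    sk = np.stack([1.0 - s, s])
    return float(-(sk * np.log(pc)).sum() / s.size)


def adipose_seed_loss(p: np.ndarray, s: np.ndarray,
                      eps: float = 1e-7) -> float:
    """Cross entropy over pseudo-adipose pixels only; 0 if there are none."""
    p, s = _check(p, s)
    omega1 = s == 1.0
    if not omega1.any():
        return 0.0
    p1 = np.clip(p[1][omega1], eps, 1.0)
    return float(-np.log(p1).mean())


def dice_loss(p: np.ndarray, s: np.ndarray) -> float:
    """1 - mean over classes of the soft Dice fraction.

    A class whose denominator is zero (no probability mass and no label
    mass) contributes a perfect fraction of 1.
    """
    p, s = _check(p, s)
    sk = np.stack([1.0 - s, s])
    total = 0.0
    for k in (0, 1):
        denom = (p[k] ** 2).sum() + (sk[k] ** 2).sum()
        total += 1.0 if denom == 0.0 else 2.0 * (p[k] * sk[k]).sum() / denom
    return float(1.0 - 0.5 * total)


def combined_loss(p: np.ndarray, s: np.ndarray, w: LossWeights) -> float:
    """alpha1 * CEL + (1 - alpha1) * ASL + alpha2 * DL."""
    return (w.alpha1 * cross_entropy_loss(p, s, w.epsilon)
            + (1.0 - w.alpha1) * adipose_seed_loss(p, s, w.epsilon)
            + w.alpha2 * dice_loss(p, s))


def cross_entropy_grad(p: np.ndarray, s: np.ndarray,
                       eps: float = 1e-7) -> np.ndarray:
    p, s = _check(p, s)
    sk = np.stack([1.0 - s, s])
    pc = np.clip(p, eps, 1.0)
    g = -sk / pc / s.size
    g[p < eps] = 0.0  # clamped region: flat in p
    return g


def adipose_seed_grad(p: np.ndarray, s: np.ndarray,
                      eps: float = 1e-7) -> np.ndarray:
    p, s = _check(p, s)
    g = np.zeros_like(p)
    omega1 = s == 1.0
    n1 = int(omega1.sum())
    if n1 == 0:
        return g
    p1 = np.clip(p[1], eps, 1.0)
    g1 = np.where(omega1 & (p[1] >= eps), -1.0 / (n1 * p1), 0.0)
    g[1] = g1
    return g


def dice_grad(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    p, s = _check(p, s)
    sk = np.stack([1.0 - s, s])
    g = np.zeros_like(p)
    for k in (0, 1):
        denom = (p[k] ** 2).sum() + (sk[k] ** 2).sum()
        if denom == 0.0:
            continue
        num = 2.0 * (p[k] * sk[k]).sum()
        # d/dp of -(1/2) * 2A/B with A = sum(p s), B = sum(p^2) + sum(s^2)
        g[k] = -(sk[k] * denom - num * p[k]) / denom ** 2
    return g


def combined_grad(p: np.ndarray, s: np.ndarray, w: LossWeights) -> np.ndarray:
    return (w.alpha1 * cross_entropy_grad(p, s, w.epsilon)
            + (1.0 - w.alpha1) * adipose_seed_grad(p, s, w.epsilon)
            + w.alpha2 * dice_grad(p, s))


def select_alpha1(adipose_image_ratio: float) -> float:
    """CEL weight from the fraction of training images containing adipose.

    1.0 when that fraction is strictly below 5%, otherwise 0.5.
    """
    if not 0.0 <= adipose_image_ratio <= 1.0:
        raise ValueError("adipose_image_ratio must lie in [0, 1]")
    return 1.0 if adipose_image_ratio < 0.05 else 0.5


# --------------------------------------------------------------------------
# UNet

class UNet:
    """Encoder-decoder with skip connections and a 2-class softmax output.

    ``depth`` pooling stages, ``base`` channels at full resolution doubling
    at each stage; two 3x3 convolutions per block. On the way up, a
    nearest-neighbour upsample is followed by a 1x1 convolution that halves
    the channels (the cheap analogue of an up-convolution) before the skip
    concatenation; the head is a 1x1 convolution to two logits.
    """

    def __init__(self, rng: np.random.Generator, depth: int = 3,
                 base: int = 8, in_ch: int = 1) -> None:
        self.depth = depth
        self.base = base
        self.enc: list[list] = []
        ch_in = in_ch
        for d in range(depth):
            ch = base * 2 ** d
            self.enc.append([nn.Conv2d(rng, ch_in, ch, name=f"enc{d}a"), nn.ReLU(),
                             nn.Conv2d(rng, ch, ch, name=f"enc{d}b"), nn.ReLU()])
            ch_in = ch
        chb = base * 2 ** depth
        self.bottleneck = [nn.Conv2d(rng, ch_in, chb, name="botA"), nn.ReLU(),
                           nn.Conv2d(rng, chb, chb, name="botB"), nn.ReLU()]
        self.pools = [nn.MaxPool2x2() for _ in range(depth)]
        self.ups = [nn.Upsample2x() for _ in range(depth)]
        self.proj: list[nn.Conv2d] = []
        self.dec: list[list] = []
        ch_up = chb
        for d in reversed(range(depth)):
            ch = base * 2 ** d
            self.proj.append(nn.Conv2d(rng, ch_up, ch, ksize=1,
                                       name=f"proj{d}"))
            self.dec.append([nn.Conv2d(rng, ch + ch, ch, name=f"dec{d}a"),
                             nn.ReLU(),
                             nn.Conv2d(rng, ch, ch, name=f"dec{d}b"), nn.ReLU()])
            ch_up = ch
        self.head = nn.Conv2d(rng, ch_up, 2, ksize=1, name="head")

    @property
    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for block in self.enc + [self.bottleneck] + self.dec:
            for layer in block:
                out.extend(layer.params)
        for layer in self.proj:
            out.extend(layer.params)
        out.extend(self.head.params)
        return out

    @property
    def downsample(self) -> int:
        return 2 ** self.depth

    @staticmethod
    def _run_block(block: list, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in block:
            x = layer.forward(x, train)
        return x

    @staticmethod
    def _back_block(block: list, d: np.ndarray) -> np.ndarray:
        for layer in reversed(block):
            d = layer.backward(d)
        return d

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits of shape (N, 2, H, W); H, W must be divisible by 2**depth."""
        skips = []
        h = x
        for d in range(self.depth):
            h = self._run_block(self.enc[d], h, train)
            skips.append(h)
            h = self.pools[d].forward(h, train)
        h = self._run_block(self.bottleneck, h, train)
        self._skip_channels = []
        for i, d in enumerate(reversed(range(self.depth))):
            h = self.proj[i].forward(self.ups[i].forward(h, train), train)
            skip = skips[d]
            self._skip_channels.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h = self._run_block(self.dec[i], h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * self.depth
        # dec[j] consumed the skip from encoder level depth-1-j
        for j in reversed(range(self.depth)):
            lvl = self.depth - 1 - j
            dcat = self._back_block(self.dec[j], d)
            ch_up, _ = self._skip_channels[j]
            dskips[lvl] = dcat[:, ch_up:]
            d = self.ups[j].backward(
                self.proj[j].backward(np.ascontiguousarray(dcat[:, :ch_up])))
        d = self._back_block(self.bottleneck, d)
        for lvl in reversed(range(self.depth)):
            d = self.pools[lvl].backward(d)
            d = d + dskips[lvl]
            d = self._back_block(self.enc[lvl], d)

    def save(self, path) -> None:
        arrays = {p.name: p.value for p in self.params}
        np.savez(path, depth=self.depth, base=self.base, **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path)
        net = cls(np.random.default_rng(0), depth=int(data["depth"]),
                  base=int(data["base"]))
        for p in net.params:
            p.value[...] = data[p.name]
        return net


def _pad_to_multiple(px: np.ndarray, mult: int
                     ) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = px.shape
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        px = np.pad(px, ((0, ph), (0, pw)), mode="reflect")
    return px, (h, w)


def train_segmenter(images: list[np.ndarray], masks: list[np.ndarray],
                    cfg: RunConfig, weights: LossWeights,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[UNet, list[float]]:
    """Train the UNet on (image, pseudo mask) pairs with the combined loss.

    Adam with weight decay ``cfg.seg_weight_decay``, batch
    ``cfg.seg_batch_size``. All images must share one shape. Returns the
    network and the per-epoch mean loss trajectory.
    """
    if len(images) != len(masks) or not images:
        raise ValueError("need matching, nonempty image and mask lists")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    net = UNet(rng, depth=cfg.seg_depth, base=cfg.seg_base_width)
    opt = nn.Adam(net.params, lr=cfg.seg_learning_rate,
                  weight_decay=cfg.seg_weight_decay)
    mult = net.downsample
    x_list, s_list = [], []
    for im, mk in zip(images, masks):
        xp, orig = _pad_to_multiple(np.asarray(im, dtype=np.float32), mult)
        sp, _ = _pad_to_multiple(np.asarray(mk, dtype=np.float32), mult)
        x_list.append(xp)
        s_list.append(sp)
    x_all = np.stack(x_list)[:, None]
    s_all = np.stack(s_list)
    n = len(images)
    bs = cfg.seg_batch_size
    history: list[float] = []
    for epoch in range(cfg.seg_epochs):
        if cfg.seg_lr_decay_at is not None and epoch == cfg.seg_lr_decay_at:
            opt.lr *= cfg.seg_lr_decay_factor
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, sb = x_all[idx], s_all[idx]
            logits = net.forward(xb, train=True)
            probs = nn.softmax_channels(logits.astype(np.float64))
            batch_loss = 0.0
            dp = np.zeros_like(probs)
            for i in range(len(idx)):
                batch_loss += combined_loss(probs[i], sb[i], weights)
                dp[i] = combined_grad(probs[i], sb[i], weights)
            batch_loss /= len(idx)
            dp /= len(idx)
            losses.append(batch_loss)
            # chain rule through the per-pixel softmax
            inner = (dp * probs).sum(axis=1, keepdims=True)
            dlogits = (probs * (dp - inner)).astype(np.float32)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
        history.append(float(np.mean(losses)))
    return net, history


def predict_mask(net: UNet, image: BScan | np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Probability map (2, H, W) and binary mask for one image.

    Inputs whose shape is not divisible by the network's downsampling
    factor are reflect-padded on the bottom/right and the output cropped
    back. The mask is the per-pixel argmax with ties going to class 0.
    """
    px = image.pixels if isinstance(image, BScan) else np.asarray(image)
    xp, (h, w) = _pad_to_multiple(px.astype(np.float32), net.downsample)
    logits = net.forward(xp[None, None], train=False)
    probs = nn.softmax_channels(logits.astype(np.float64))[0, :, :h, :w]
    mask = (probs[1] > probs[0]).astype(np.uint8)
    return probs, mask
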