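"""Loss functions, their gradients, alpha1 selection and the UNet."""

import numpy as np
import pytest

import adiposeg as A
from adiposeg import nn
from adiposeg.segmentation import (adipose_seed_grad, adipose_seed_loss,
                                   combined_grad, cross_entropy_grad,
                                   dice_grad, UNet)


def random_prob_label(rng, shape=(6, 6)):
    z = rng.normal(size=(2,) + shape)
    e = np.exp(z)
    p = e / e.sum(axis=0)
    s = (rng.random(shape) < 0.3).astype(np.uint8)
    return p, s


def brute_force_cel(p, s, eps=1e-7):
    h, w = s.shape
    total = 0.0
    for r in range(h):
        for c in range(w):
            for k in (0, 1):
                sk = s[r, c] if k == 1 else 1 - s[r, c]
                total -= sk * np.log(np.clip(p[k, r, c], eps, 1.0))
    return total / (h * w)


def brute_force_asl(p, s, eps=1e-7):
    vals = [-np.log(np.clip(p[1, r, c], eps, 1.0))
            for r in range(s.shape[0]) for c in range(s.shape[1])
            if s[r, c] == 1]
    return float(np.mean(vals)) if vals else 0.0


def brute_force_dl(p, s):
    total = 0.0
    for k in (0, 1):
        sk = (s == 1) if k == 1 else (s == 0)
        num = 2.0 * float((p[k] * sk).sum())
        den = float((p[k] ** 2).sum() + sk.sum())
        total += 1.0 if den == 0 else num / den
    return 1.0 - total / 2.0


class TestLossValues:
    def test_perfect_prediction_near_zero_cel(self):
        s = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        p = np.stack([1.0 - s, s]).astype(float)
        assert A.cross_entropy_loss(p, s) <= 1e-6

    def test_uniform_prediction_gives_ln2(self, rng):
        s = (rng.random((5, 5)) < 0.5).astype(np.uint8)
        p = np.full((2, 5, 5), 0.5)
        assert A.cross_entropy_loss(p, s) == pytest.approx(np.log(2), rel=1e-9)
        if s.any():
            assert A.adipose_seed_loss(p, s) == pytest.approx(np.log(2),
                                                              rel=1e-9)

    def test_asl_empty_omega_is_zero(self):
        p = np.full((2, 4, 4), 0.5)
        assert A.adipose_seed_loss(p, np.zeros((4, 4), dtype=np.uint8)) == 0.0

    def test_asl_ignores_background_pixels(self):
        s = np.zeros((2, 4), dtype=np.uint8)
        s[0, :2] = 1
        p = np.full((2, 2, 4), 0.5)
        assert A.adipose_seed_loss(p, s) == pytest.approx(np.log(2))

    def test_dice_perfect_and_total_disagreement(self):
        s = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        p_match = np.stack([1.0 - s, s]).astype(float)
        p_flip = np.stack([s, 1.0 - s]).astype(float)
        assert A.dice_loss(p_match, s) == pytest.approx(0.0)
        assert A.dice_loss(p_flip, s) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_all_losses_match_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        p, s = random_prob_label(rng)
        assert A.cross_entropy_loss(p, s) == pytest.approx(
            brute_force_cel(p, s), abs=1e-7)
        assert A.adipose_seed_loss(p, s) == pytest.approx(
            brute_force_asl(p, s), abs=1e-7)
        assert A.dice_loss(p, s) == pytest.approx(brute_force_dl(p, s),
                                                  abs=1e-7)

    def test_loss_ranges(self, rng):
        for trial in range(20):
            p, s = random_prob_label(np.random.default_rng(trial))
            assert A.cross_entropy_loss(p, s) >= 0.0
            assert A.adipose_seed_loss(p, s) >= 0.0
            assert 0.0 <= A.dice_loss(p, s) <= 1.0


class TestCombinedLoss:
    def test_alpha1_one_drops_asl(self, rng):
        p, s = random_prob_label(rng)
        w = A.LossWeights(alpha1=1.0, alpha2=0.7)
        expect = A.cross_entropy_loss(p, s) + 0.7 * A.dice_loss(p, s)
        assert A.combined_loss(p, s, w) == pytest.approx(expect, abs=1e-12)

    def test_alpha_zero_zero_is_pure_asl(self, rng):
        p, s = random_prob_label(rng)
        w = A.LossWeights(alpha1=0.0, alpha2=0.0)
        assert A.combined_loss(p, s, w) == pytest.approx(
            A.adipose_seed_loss(p, s), abs=1e-12)

    def test_affine_in_both_weights(self, rng):
        p, s = random_prob_label(rng)
        cel = A.cross_entropy_loss(p, s)
        asl = A.adipose_seed_loss(p, s)
        dl = A.dice_loss(p, s)
        for a1 in (0.0, 0.25, 0.5, 1.0):
            for a2 in (0.0, 0.5, 2.0):
                w = A.LossWeights(alpha1=a1, alpha2=a2)
                expect = a1 * cel + (1 - a1) * asl + a2 * dl
                assert A.combined_loss(p, s, w) == pytest.approx(expect,
                                                                 abs=1e-9)


class TestGradients:
    """Analytic gradients vs central finite differences, away from clamps."""

    @pytest.mark.parametrize("loss,grad", [
        (A.cross_entropy_loss, cross_entropy_grad),
        (adipose_seed_loss, adipose_seed_grad),
        (A.dice_loss, dice_grad),
    ])
    def test_each_loss_gradient(self, loss, grad):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(2, 4, 4)) * 0.5
        e = np.exp(z)
        p = e / e.sum(axis=0)
        s = (rng.random((4, 4)) < 0.4).astype(np.uint8)
        g = grad(p, s)
        h = 1e-6
        for k in (0, 1):
            for r in range(4):
                for c in range(4):
                    pp, pm = p.copy(), p.copy()
                    pp[k, r, c] += h
                    pm[k, r, c] -= h
                    fd = (loss(pp, s) - loss(pm, s)) / (2 * h)
                    assert g[k, r, c] == pytest.approx(fd, abs=1e-4)

    def test_combined_grad_is_weighted_sum(self, rng):
        p, s = random_prob_label(rng, (4, 4))
        w = A.LossWeights(alpha1=0.3, alpha2=0.9)
        expect = (0.3 * cross_entropy_grad(p, s)
                  + 0.7 * adipose_seed_grad(p, s) + 0.9 * dice_grad(p, s))
        assert np.abs(A.combined_grad(p, s, w) - expect).max() < 1e-12


class TestSelectAlpha1:
    @pytest.mark.parametrize("ratio,expect", [
        (0.04, 1.0),
        (0.11, 0.5),
        (0.05, 0.5),   # boundary: "less than 5%" is strict
        (0.0, 1.0),
        (1.0, 0.5),
    ])
    def test_rule(self, ratio, expect):
        assert A.select_alpha1(ratio) == expect

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            A.select_alpha1(1.5)


class TestUNet:
    def test_output_shape_matches_input(self, rng):
        net = UNet(rng, depth=2, base=2)
        x = rng.random((1, 1, 16, 24)).astype(np.float32)
        logits = net.forward(x, train=False)
        assert logits.shape == (1, 2, 16, 24)

    def test_probabilities_sum_to_one(self, rng):
        net = UNet(rng, depth=2, base=2)
        img = rng.random((16, 16)).astype(np.float32)
        probs, _ = A.predict_mask(net, img)
        assert np.abs(probs.sum(axis=0) - 1.0).max() < 1e-6

    def test_predict_pads_odd_shapes(self, rng):
        net = UNet(rng, depth=2, base=2)
        img = rng.random((19, 21)).astype(np.float32)
        probs, mask = A.predict_mask(net, img)
        assert probs.shape == (2, 19, 21) and mask.shape == (19, 21)

    def test_mask_is_argmax_with_ties_to_background(self, rng):
        probs = rng.random((2, 8, 8))
        probs /= probs.sum(axis=0)
        probs[:, 0, 0] = 0.5  # exact tie
        mask = (probs[1] > probs[0]).astype(np.uint8)
        for r in range(8):
            for c in range(8):
                assert mask[r, c] == int(probs[1, r, c] > probs[0, r, c])
        assert mask[0, 0] == 0

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = UNet(rng, depth=2, base=2)
        net.save(tmp_path / "seg.npz")
        back = UNet.load(tmp_path / "seg.npz")
        x = rng.random((1, 1, 16, 16)).astype(np.float32)
        assert np.allclose(net.forward(x, train=False),
                           back.forward(x, train=False))


class TestTrainSegmenter:
    def toy_data(self, rng, n=4):
        imgs, masks = [], []
        for _ in range(n):
            im = rng.random((16, 16)).astype(np.float32)
            mk = np.zeros((16, 16), dtype=np.uint8)
            mk[4:10, 4:10] = 1
            im[mk == 1] += 0.5
            imgs.append(np.clip(im, 0, 1))
            masks.append(mk)
        return imgs, masks

    def test_smoke_two_epochs_finite_loss(self, rng):
        imgs, masks = self.toy_data(rng)
        cfg = A.RunConfig(seg_depth=2, seg_base_width=2, seg_epochs=2,
                          seg_batch_size=2)
        _, history = A.train_segmenter(imgs, masks, cfg, A.LossWeights(),
                                       np.random.default_rng(0))
        assert len(history) == 2
        assert np.isfinite(history).all()

    def test_same_seed_identical_checkpoints(self, rng):
        imgs, masks = self.toy_data(rng)
        cfg = A.RunConfig(seg_depth=2, seg_base_width=2, seg_epochs=2,
                          seg_batch_size=2)
        n1, _ = A.train_segmenter(imgs, masks, cfg, A.LossWeights(),
                                  np.random.default_rng(3))
        n2, _ = A.train_segmenter(imgs, masks, cfg, A.LossWeights(),
                                  np.random.default_rng(3))
        for p1, p2 in zip(n1.params, n2.params):
            assert np.array_equal(p1.value, p2.value)

    def test_learns_separable_toy_problem(self, rng):
        """Bright-square masks are learnable to high Dice in few epochs."""
        imgs, masks = self.toy_data(rng, n=8)
        cfg = A.RunConfig(seg_depth=2, seg_base_width=4, seg_epochs=30,
                          seg_batch_size=4)
        net, history = A.train_segmenter(imgs, masks, cfg, A.LossWeights(),
                                         np.random.default_rng(0))
        assert history[-1] < history[0]
        _, pred = A.predict_mask(net, imgs[0])
        dice = A.metrics_from_counts(A.confusion(pred, masks[0])).dice
        assert dice >= 0.8


def test_seed_loss_recovers_missed_adipose_and_cel_limits_fp(rng):
    """With half the true adipose pixels erased from the training labels,
    the ASL+DL objective detects more adipose (higher TPR) and the CEL+DL
    objective produces fewer false positives, in seeded paired runs."""
    imgs, full_masks, holey_masks = [], [], []
    for i in range(8):
        r = np.random.default_rng(50 + i)
        im = (0.3 + 0.1 * r.random((16, 16))).astype(np.float32)
        mk = np.zeros((16, 16), dtype=np.uint8)
        mk[3:12, 3:12] = 1
        im[mk == 1] += 0.4
        holey = mk & (r.random((16, 16)) < 0.5).astype(np.uint8)
        imgs.append(np.clip(im, 0, 1))
        full_masks.append(mk)
        holey_masks.append(holey)
    cfg = A.RunConfig(seg_depth=2, seg_base_width=4, seg_epochs=40,
                      seg_batch_size=4)

    def run(alpha1):
        net, _ = A.train_segmenter(imgs, holey_masks, cfg,
                                   A.LossWeights(alpha1=alpha1, alpha2=0.5),
                                   np.random.default_rng(9))
        c = [A.confusion(A.predict_mask(net, im)[1], mk)
             for im, mk in zip(imgs, full_masks)]
        tpr = sum(x.tp for x in c) / sum(x.tp + x.fn for x in c)
        fpr = sum(x.fp for x in c) / sum(x.fp + x.tn for x in c)
        return tpr, fpr

    tpr_asl, fpr_asl = run(alpha1=0.0)
    tpr_cel, fpr_cel = run(alpha1=1.0)
    assert tpr_asl >= tpr_cel
    assert fpr_cel <= fpr_asl
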