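"""Pixel metrics, grouped cross-validation and the ablation harness.

Adipose is the positive class throughout. Per image we report accuracy,
precision, true positive rate (detection rate), false positive rate and the
Dice coefficient; any metric whose denominator is zero is reported as NaN
and excluded from averages. Averages are reported both over all images and
over the adipose-containing subset, since most B-scans contain no adipose
at all and would otherwise dominate.

Cross-validation splits are grouped by ``sample_id`` (all B-scans of one
heart stay in one fold). The ablation harness re-runs the weakly supervised
pipeline end to end under named variants (boundary masking off, spatial
regularization off, single-loss objectives, fully supervised ceiling) on
identical phantom inputs and paired seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interface import RunConfig
from .localization import train_localizer, generate_seed_map
from .pseudolabel import generate_pseudolabels, pseudolabel_image
from .segmentation import (LossWeights, select_alpha1, train_segmenter,
                           predict_mask)

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "confusion",
    "metrics_from_counts",
    "evaluate_masks",
    "summarize_records",
    "grouped_folds",
    "cross_validate",
    "ABLATION_VARIANTS",
    "run_weak_pipeline",
    "ablation_run",
]

Dataset = list[tuple[np.ndarray, np.ndarray, int, str]]
# one record per image: (image, ground-truth mask, image label, sample id)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRecord:
    accuracy: float
    precision: float
    tpr: float
    fpr: float
    dice: float
    image_id: str = ""
    stratum: str = "all"


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel counts; both masks must be binary and the same shape."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    if not (np.isin(pred, (0, 1)).all() and np.isin(gt, (0, 1)).all()):
        raise ValueError("masks must be binary")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(tp=int((p & g).sum()), fp=int((p & ~g).sum()),
                           tn=int((~p & ~g).sum()), fn=int((~p & g).sum()))


def metrics_from_counts(c: ConfusionCounts, image_id: str = "",
                        stratum: str = "all") -> MetricsRecord:
    """Metrics with 0/0 cases reported as NaN (excluded from averages)."""
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return MetricsRecord(
        accuracy=ratio(c.tp + c.tn, c.total),
        precision=ratio(c.tp, c.tp + c.fp),
        tpr=ratio(c.tp, c.tp + c.fn),
        fpr=ratio(c.fp, c.fp + c.tn),
        dice=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        image_id=image_id,
        stratum=stratum,
    )


def evaluate_masks(preds: list[np.ndarray], gts: list[np.ndarray],
                   image_ids: list[str] | None = None) -> list[MetricsRecord]:
    ids = image_ids or [f"img{i:04d}" for i in range(len(preds))]
    return [metrics_from_counts(confusion(p, g), image_id=i)
            for p, g, i in zip(preds, gts, ids)]


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize_records(records: list[MetricsRecord],
                      adipose_flags: list[bool] | None = None) -> pd.DataFrame:
    """Mean metrics over all images and over adipose-containing images.

    By default an image counts as adipose-containing when its TPR is
    defined (its ground truth has at least one positive pixel).
    """
    df = records_to_frame(records)
    cols = ["accuracy", "precision", "tpr", "fpr", "dice"]
    if adipose_flags is None:
        adipose_flags = [~np.isnan(r.tpr) for r in records]
    rows = []
    for stratum, sel in (("all", np.ones(len(df), dtype=bool)),
                         ("adipose_only", np.asarray(adipose_flags))):
        sub = df.loc[sel, cols]
        rows.append([stratum] + [float(sub[c].mean()) for c in cols])
    return pd.DataFrame(rows, columns=["stratum"] + cols)


# --------------------------------------------------------------------------
# grouped cross-validation

def grouped_folds(sample_ids: list[str], folds: int, seed: int
                  ) -> list[list[str]]:
    """Partition distinct sample ids into ``folds`` near-equal groups."""
    unique = sorted(set(sample_ids))
    if len(unique) < folds:
        raise ValueError("fewer distinct samples than folds")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    return [list(chunk) for chunk in np.array_split(order, folds)]


def cross_validate(data: Dataset, cfg: RunConfig, folds: int = 5,
                   run_fn=None) -> pd.DataFrame:
    """Per-fold metrics for the weakly supervised pipeline (or ``run_fn``).

    ``run_fn(train, test, cfg)`` must return per-image
    :class:`MetricsRecord` lists; the default runs the full pipeline.
    """
    if run_fn is None:
        def run_fn(train, test, cfg):
            return run_weak_pipeline(train, test, cfg)["records"]
    sample_ids = [sid for *_, sid in data]
    fold_groups = grouped_folds(sample_ids, folds, cfg.seed)
    frames = []
    for k, group in enumerate(fold_groups):
        test = [rec for rec in data if rec[3] in group]
        train = [rec for rec in data if rec[3] not in group]
        records = run_fn(train, test, cfg)
        df = records_to_frame(records)
        df.insert(0, "fold", k)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# ablation harness

ABLATION_VARIANTS = ("full", "no_boundary_mask", "no_regularization",
                     "asl_dl", "cel_dl", "fully_supervised")


def _variant_settings(variant: str, adipose_ratio: float, cfg: RunConfig
                      ) -> tuple[bool, bool, LossWeights]:
    alpha1 = select_alpha1(adipose_ratio)
    boundary, reg = True, True
    if variant == "no_boundary_mask":
        boundary = False
    elif variant == "no_regularization":
        reg = False
    elif variant == "asl_dl":
        alpha1 = 0.0
    elif variant == "cel_dl":
        alpha1 = 1.0
    elif variant not in ("full", "fully_supervised"):
        raise ValueError(f"unknown ablation variant {variant!r}")
    return boundary, reg, LossWeights(alpha1=alpha1, alpha2=cfg.alpha2)


def run_weak_pipeline(train: Dataset, test: Dataset, cfg: RunConfig,
                      variant: str = "full",
                      loc_net=None) -> dict:
    """End-to-end run of one pipeline variant on in-memory phantom data.

    Trains the localizer (unless supplied or fully supervised), builds
    pseudo labels for the training images, trains the segmenter, predicts
    the held-out images and scores them against ground truth. Returns the
    per-image records, the summary frame and the trained networks.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}")
    adipose_ratio = float(np.mean([lab for _, _, lab, _ in train]))
    boundary, reg, weights = _variant_settings(variant, adipose_ratio, cfg)
    train_imgs = [im for im, *_ in train]
    if variant == "fully_supervised":
        masks = [mk for _, mk, *_ in train]
    else:
        if loc_net is None:
            loc_net, _ = train_localizer([(im, lab) for im, _, lab, _ in train],
                                         cfg, np.random.default_rng(cfg.seed))
        pls = generate_pseudolabels(train_imgs, loc_net, cfg,
                                    apply_boundary_mask=boundary,
                                    apply_regularization=reg)
        masks = [pl.labels for pl in pls]
    seg_net, history = train_segmenter(train_imgs, masks, cfg, weights,
                                       np.random.default_rng(cfg.seed + 1))
    preds = [predict_mask(seg_net, im)[1] for im, *_ in test]
    gts = [mk for _, mk, *_ in test]
    records = evaluate_masks(preds, gts)
    return {
        "records": records,
        "summary": summarize_records(records),
        "loc_net": loc_net,
        "seg_net": seg_net,
        "loss_history": history,
        "pseudo_masks": masks if variant != "fully_supervised" else None,
        "weights": weights,
    }


def ablation_run(data: Dataset, cfg: RunConfig,
                 variants: tuple[str, ...] = ABLATION_VARIANTS,
                 folds: int = 2) -> pd.DataFrame:
    """Paired end-to-end runs of every variant over shared grouped folds.

    The localizer (and its seed maps) is trained once per fold and shared
    across variants, so variant differences are attributable to the ablated
    component alone. Emits one row per (variant, fold) with mean tpr, fpr
    and dice over the fold's held-out images, plus mean±sd rows per variant.
    """
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {v!r}")
    sample_ids = [sid for *_, sid in data]
    fold_groups = grouped_folds(sample_ids, folds, cfg.seed)
    rows = []
    for k, group in enumerate(fold_groups):
        test = [rec for rec in data if rec[3] in group]
        train = [rec for rec in data if rec[3] not in group]
        loc_net = None
        needs_loc = any(v != "fully_supervised" for v in variants)
        if needs_loc:
            loc_net, _ = train_localizer(
                [(im, lab) for im, _, lab, _ in train], cfg,
                np.random.default_rng(cfg.seed))
        for variant in variants:
            res = run_weak_pipeline(train, test, cfg, variant=variant,
                                    loc_net=loc_net)
            summ = res["summary"]
            all_row = summ[summ.stratum == "all"].iloc[0]
            rows.append({"variant": variant, "fold": k,
                         "tpr": all_row.tpr, "fpr": all_row.fpr,
                         "dice": all_row.dice})
    df = pd.DataFrame(rows)
    agg = df.groupby("variant", sort=False).agg(
        tpr_mean=("tpr", "mean"), tpr_sd=("tpr", "std"),
        fpr_mean=("fpr", "mean"), fpr_sd=("fpr", "std"),
        dice_mean=("dice", "mean"), dice_sd=("dice", "std")).reset_index()
    return df.merge(agg, on="variant")


# --------------------------------------------------------------------------
# seed-quality scoring (first-stage diagnostics)

def seed_quality(seeds: np.ndarray, gt_mask: np.ndarray,
                 superpixel_count: int) -> MetricsRecord:
    """Score a seed map against ground truth dilated by one superpixel radius.

    Seeds need only land inside (or within one superpixel radius of) true
    adipose to seed the right superpixel, so the reference is dilated by
    the typical superpixel radius sqrt(area / K / pi) before counting.
    """
    from scipy.ndimage import binary_dilation
    from skimage.morphology import disk

    radius = max(1, int(round(np.sqrt(gt_mask.size / superpixel_count
                                      / np.pi))))
    dilated = binary_dilation(gt_mask.astype(bool),
                              structure=disk(radius)).astype(np.uint8)
    return metrics_from_counts(confusion(seeds, dilated), stratum="seeds")
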