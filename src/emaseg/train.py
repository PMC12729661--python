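"""Hybrid loss, augmentation, and the training/inference loops.

The loss is the equally weighted sum of soft Dice loss and binary
cross-entropy on per-pixel probabilities,

    L_total = L_Dice + L_BCE,
    L_Dice  = 1 - (2 sum(g p) + s) / (sum(g) + sum(p) + s),
    L_BCE   = -mean(g log p + (1-g) log(1-p)),

with Dice smoothing s = 1e-5 in numerator and denominator (the bare ratio is
undefined for empty masks) and probabilities clipped to [1e-7, 1 - 1e-7].
Dice is computed per image and averaged over the batch.

Augmentation applies geometric transforms identically to frame and mask
(mask resampled nearest so it stays binary) and intensity transforms to the
frame only; validation/test data are never augmented.  Training uses AdamW
at a constant learning rate, logs per-epoch mean losses to a history CSV and
keeps the checkpoint with the best validation Dice."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import ValidationError
from .configs import AugmentPolicy, RunConfig
from .data import (BinaryMask, SplitSpec, UltrasoundFrame, load_frame, load_mask,
                   preprocess, read_manifest, resize_mask, split_dataset)
from .metrics import confusion_counts, overlap_scores
from .model import MPGSwinUMamba, build_model, load_checkpoint, save_checkpoint
from .nn import autograd as ag
from .nn.autograd import Tensor, no_grad
from .nn.optim import AdamW

__all__ = ["LossValues", "total_loss", "dice_bce_loss", "augment_sample",
           "train", "predict", "TrainResult"]

DICE_SMOOTH = 1e-5
BCE_EPS = 1e-7


@dataclasses.dataclass(frozen=True)
class LossValues:
    l_dice: float
    l_bce: float
    l_total: float

    def __post_init__(self):
        if self.l_dice < 0 or self.l_bce < 0:
            raise ValidationError("loss terms must be nonnegative")
        if abs(self.l_total - (self.l_dice + self.l_bce)) > 1e-9:
            raise ValidationError("l_total must equal l_dice + l_bce")


def dice_bce_loss(probs: Tensor, labels: np.ndarray) -> tuple[Tensor, Tensor]:
    """Differentiable loss terms; probs (B, 1, H, W) or flat, labels {0,1}."""
    g = np.asarray(labels, dtype=probs.dtype)
    if g.shape != tuple(probs.shape):
        raise ValidationError(f"shape mismatch: probs {probs.shape} vs labels {g.shape}")
    p = ag.clip(probs, BCE_EPS, 1.0 - BCE_EPS)
    if p.ndim >= 2:
        B = p.shape[0]
        pf = ag.reshape(p, (B, -1))
        gf = g.reshape(B, -1)
        axis = 1
    else:
        pf, gf, axis = ag.reshape(p, (1, -1)), g.reshape(1, -1), 1
    inter = ag.tsum(pf * gf, axis=axis)
    denom = ag.tsum(pf, axis=axis) + gf.sum(axis=axis)
    dice = 1.0 - ((2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)).mean()
    bce = -(gf * ag.log(pf) + (1.0 - gf) * ag.log(1.0 - pf)).mean()
    return dice, bce


def total_loss(probabilities, labels) -> LossValues:
    """Numeric loss values for a probability map and its binary labels."""
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(
        np.asarray(probabilities, dtype=np.float64))
    with no_grad():
        dice, bce = dice_bce_loss(p.detach(), labels)
    return LossValues(l_dice=float(dice.data), l_bce=float(bce.data),
                      l_total=float(dice.data) + float(bce.data))


# ---------------------------------------------------------------- augmentation
def _geometric_warp(img: np.ndarray, order: int, angle: float, scale: float,
                    disp: tuple[np.ndarray, np.ndarray] | None) -> np.ndarray:
    out = img
    if angle != 0.0:
        if angle % 90 == 0:
            out = np.rot90(out, k=int(angle // 90) % 4)
        else:
            out = ndimage.rotate(out, angle, reshape=False, order=order,
                                 mode="nearest")
    if scale != 1.0:
        h, w = out.shape
        centre = (np.array(out.shape) - 1) / 2.0
        matrix = np.eye(2) / scale
        offset = centre - matrix @ centre
        out = ndimage.affine_transform(out, matrix, offset=offset, order=order,
                                       mode="nearest")
    if disp is not None:
        h, w = out.shape
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.array([yy + disp[0], xx + disp[1]])
        out = ndimage.map_coordinates(out, coords, order=order, mode="nearest")
    return out


def augment_sample(frame: UltrasoundFrame, mask: BinaryMask, policy: AugmentPolicy,
                   seed: int) -> tuple[UltrasoundFrame, BinaryMask]:
    """Deterministic per-sample augmentation; geometry shared, intensity
    frame-only."""
    if frame.shape != mask.shape:
        raise ValidationError("frame and mask shapes differ")
    rng = np.random.default_rng(seed)
    img = frame.pixels.astype(np.float64)
    lab = mask.labels.astype(np.float64)

    angle, scale, disp = 0.0, 1.0, None
    if rng.uniform() < policy.rotation_prob:
        angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
    if rng.uniform() < policy.scale_prob:
        scale = rng.uniform(*policy.scale_range)
    if rng.uniform() < policy.elastic_prob:
        h, w = img.shape
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                     policy.elastic_sigma) * policy.elastic_alpha
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                     policy.elastic_sigma) * policy.elastic_alpha
        disp = (dy, dx)

    if angle != 0.0 or scale != 1.0 or disp is not None:
        img = _geometric_warp(img, 1, angle, scale, disp)
        lab = _geometric_warp(lab, 0, angle, scale, disp)

    if rng.uniform() < policy.brightness_prob:
        img = img * rng.uniform(*policy.brightness_range)
    if rng.uniform() < policy.contrast_prob:
        f = rng.uniform(*policy.contrast_range)
        m = img.mean()
        img = (img - m) * f + m
    if rng.uniform() < policy.noise_prob:
        sigma = rng.uniform(0.0, policy.noise_sigma_max)
        img = img + rng.normal(0.0, sigma, size=img.shape)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return (UltrasoundFrame(pixels=img, spacing_mm=frame.spacing_mm, id=frame.id),
            BinaryMask(labels=(lab > 0.5).astype(np.uint8), id=mask.id))


# -------------------------------------------------------------------- training
@dataclasses.dataclass
class TrainResult:
    checkpoint: Path
    history: Path
    best_val_dsc: float
    steps: int
    final_train_dsc: float


def _load_pairs(manifest: pd.DataFrame, ids: list[str], size: int):
    frames, masks = [], []
    by_id = manifest.set_index("id")
    for i in ids:
        row = by_id.loc[i]
        fr = load_frame(row["image_path"],
                        (row["row_mm_per_px"], row["col_mm_per_px"]))
        mk = load_mask(row["mask_path"])
        fr = preprocess(fr, size)
        mk = resize_mask(mk, (size, size))
        frames.append(fr)
        masks.append(mk)
    return frames, masks


def _mean_dsc(model: MPGSwinUMamba, frames, masks, threshold: float,
              batch: int = 4) -> float:
    scores = []
    model.eval()
    with no_grad():
        for i in range(0, len(frames), batch):
            x = np.stack([f.pixels for f in frames[i:i + batch]])[:, None]
            probs = ag.sigmoid(model(Tensor(x))).data
            for p, m in zip(probs, masks[i:i + batch]):
                pred = (p[0] >= threshold).astype(np.uint8)
                scores.append(overlap_scores(confusion_counts(pred, m.labels)).dsc)
    model.train()
    return float(np.mean(scores))


def train(config: RunConfig, manifest_path, out_dir, split: SplitSpec | None = None,
          max_steps: int | None = None, target_train_dsc: float | None = None,
          eval_every: int = 20, log=print) -> TrainResult:
    """Fit the model on a manifest; returns checkpoint + history paths.

    ``max_steps`` caps total optimization steps (for scaled-down runs);
    ``target_train_dsc`` stops early once the training-set Dice reaches the
    target (checked every ``eval_every`` steps)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    ids = list(manifest["id"])
    if split is None:
        split = split_dataset(ids, (0.7, 0.2, 0.1), config.seed)
    if not split.train_ids:
        raise ValidationError("empty training split")

    size = config.input_size
    tr_frames, tr_masks = _load_pairs(manifest, split.train_ids, size)
    if split.val_ids:
        va_frames, va_masks = _load_pairs(manifest, split.val_ids, size)
    else:
        va_frames, va_masks = tr_frames, tr_masks  # fall back: monitor train set

    model = build_model(config)
    model.train()
    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)

    ckpt_path = out_dir / "best.npz"
    hist_path = out_dir / "history.csv"
    history = []
    best_val = -1.0
    step = 0
    stop = False
    n_train = len(tr_frames)

    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for b0 in range(0, n_train, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            xs, gs = [], []
            for j in idx:
                fr, mk = augment_sample(tr_frames[j], tr_masks[j], config.augment,
                                        seed=int(rng.integers(2 ** 31)))
                xs.append(fr.pixels)
                gs.append(mk.labels)
            x = Tensor(np.stack(xs)[:, None].astype(np.float32))
            g = np.stack(gs)[:, None]
            logits = model(x)
            probs = ag.sigmoid(logits)
            dice, bce = dice_bce_loss(probs, g)
            loss = dice + bce
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            step += 1
            if target_train_dsc is not None and step % eval_every == 0:
                dsc_now = _mean_dsc(model, tr_frames, tr_masks, config.threshold)
                log(f"step {step}: train loss {epoch_losses[-1]:.4f} "
                    f"train DSC {dsc_now:.4f}")
                if dsc_now >= target_train_dsc:
                    stop = True
            if max_steps is not None and step >= max_steps:
                stop = True
            if stop:
                break

        val_dsc = _mean_dsc(model, va_frames, va_masks, config.threshold)
        with no_grad():
            v_losses = []
            for i in range(0, len(va_frames), config.batch_size):
                x = np.stack([f.pixels for f in va_frames[i:i + config.batch_size]])[:, None]
                g = np.stack([m.labels for m in va_masks[i:i + config.batch_size]])[:, None]
                model.eval()
                pv = ag.sigmoid(model(Tensor(x.astype(np.float32))))
                model.train()
                d, c = dice_bce_loss(pv, g.astype(pv.dtype))
                v_losses.append(float(d.data + c.data))
        history.append({"epoch": epoch + 1,
                        "train_loss": float(np.mean(epoch_losses)),
                        "val_loss": float(np.mean(v_losses)),
                        "val_dsc": val_dsc})
        log(f"epoch {epoch + 1}: train {history[-1]['train_loss']:.4f} "
            f"val {history[-1]['val_loss']:.4f} val DSC {val_dsc:.4f}")
        if val_dsc > best_val:
            best_val = val_dsc
            save_checkpoint(model, config, ckpt_path)
        if stop:
            break

    pd.DataFrame(history).to_csv(hist_path, index=False)
    final_train_dsc = _mean_dsc(model, tr_frames, tr_masks, config.threshold)
    if not ckpt_path.exists():
        save_checkpoint(model, config, ckpt_path)
    return TrainResult(checkpoint=ckpt_path, history=hist_path,
                       best_val_dsc=best_val, steps=step,
                       final_train_dsc=final_train_dsc)


def predict(checkpoint, frame: UltrasoundFrame, threshold: float = 0.5,
            model: MPGSwinUMamba | None = None,
            config: RunConfig | None = None) -> BinaryMask:
    """Segment one frame: resize to the model grid, threshold the probability
    map, and resize the mask back to the frame's native grid (nearest)."""
    if model is None:
        model, config = load_checkpoint(checkpoint, config)
    if config is None:
        raise ValidationError("predict needs a config when given a bare model")
    pre = preprocess(frame, config.input_size)
    probs = model.predict_proba(Tensor(pre.pixels[None, None].astype(np.float32)))
    pred = BinaryMask(labels=(probs[0, 0] >= threshold).astype(np.uint8), id=frame.id)
    return resize_mask(pred, frame.shape)
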