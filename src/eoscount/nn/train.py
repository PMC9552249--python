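"""Training loop for the nested encoder-decoder segmenter.

Optimizes the weighted soft-Dice + BCE loss with Adam under a cosine-
annealed learning rate.  Deep-supervision heads contribute equally to
the loss; checkpoint selection uses a configurable per-image validation
metric (default the arithmetic mean of precision and recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..masks import CLASSES, LabelMaskStack
from ..metrics import ConfusionCounts, confusion_counts, selection_metric
from ..segmentation import cosine_annealing_lr, threshold_probabilities
from . import autograd as ag
from .model import UNetPP, softmax, _to_nchw


@dataclass
class TrainingConfig:
    """Hyperparameters of the segmentation training run.

    Defaults mirror the optimized schedule: 100 epochs, batches of 5
    448-px tiles cut at stride 376, cosine-annealed learning rate,
    Dice:BCE loss weights 1:0.5 and a 0.5 softmax threshold.  ``width``
    scales the network; toy-scale runs shrink it together with the tile
    size.
    """

    epochs: int = 100
    batch_size: int = 5
    input_tile: int = 448
    train_stride: int = 376
    lr_max: float = 1e-3
    lr_min: float = 0.0
    dice_weight: float = 1.0
    bce_weight: float = 0.5
    prob_threshold: float = 0.5
    seed: int = 0
    width: int = 8
    selection: str = "m(0.5P+0.5R)"
    val_every: int = 1
    dice_smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.width < 1:
            raise ValueError("epochs, batch_size and width must be positive")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.lr_max <= 0 or self.lr_min < 0:
            raise ValueError("learning rates must be positive / non-negative")


def _truth_planes(mask: LabelMaskStack) -> np.ndarray:
    return np.stack([mask.masks[c] for c in CLASSES]).astype(np.float32)


def loss_and_grad(
    probs: np.ndarray,
    truth: np.ndarray,
    dice_weight: float = 1.0,
    bce_weight: float = 0.5,
    smooth: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Combined loss and its gradient w.r.t. the probability map.

    ``probs`` is (N, 3, H, W) softmax output, ``truth`` is (N, 2, H, W)
    binary planes for the two eosinophil classes.  Dice and BCE act on
    the eosinophil channels only and are averaged over the two classes;
    the background channel receives zero direct gradient (it is still
    coupled through the softmax).
    """
    N = probs.shape[0]
    eps = 1e-7
    dprobs = np.zeros_like(probs)
    total = 0.0
    npix = probs[0, 0].size
    for n in range(N):
        dice_terms, bce_terms = [], []
        for j in range(2):
            p = probs[n, j + 1].astype(np.float64)
            g = truth[n, j].astype(np.float64)
            inter = (p * g).sum()
            psum, gsum = p.sum(), g.sum()
            den = psum + gsum + smooth
            dice_terms.append(1.0 - (2.0 * inter + smooth) / den)
            ddice = -(2.0 * g * den - (2.0 * inter + smooth)) / (den * den)
            pc = np.clip(p, eps, 1.0 - eps)
            bce_terms.append(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())
            dbce = (-(g / pc) + (1.0 - g) / (1.0 - pc)) / npix
            dprobs[n, j + 1] = (dice_weight * ddice + bce_weight * dbce) / 2.0
        total += dice_weight * float(np.mean(dice_terms)) + bce_weight * float(np.mean(bce_terms))
    return total / N, dprobs / N


def softmax_grad(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Pull a probability-space gradient back through the softmax."""
    inner = (probs * dprobs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)


class Adam:
    def __init__(self, params: dict[str, ag.Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedSegmenter:
    """Trained model wrapped as a segmenter (ignores the tile origin)."""

    model: UNetPP
    config: TrainingConfig

    def __call__(self, tile: np.ndarray, origin: tuple[int, int] = (0, 0)) -> np.ndarray:
        return self.model.predict_proba(tile)


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_score: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_score: float = float("-inf")


def evaluate_segmenter(
    segmenter,
    tiles: Sequence[tuple[np.ndarray, LabelMaskStack]],
    metric: str = "miou",
    threshold: float = 0.5,
) -> float:
    """Per-image selection metric of a segmenter over a tile set."""
    parts = []
    for tile, truth in tiles:
        pred = threshold_probabilities(segmenter(tile), threshold)
        parts.append(confusion_counts(pred, truth))
    return selection_metric(ConfusionCounts.concatenate(parts), metric)


def train_segmenter(
    dataset: Sequence[tuple[np.ndarray, LabelMaskStack]],
    config: TrainingConfig,
    val_dataset: Sequence[tuple[np.ndarray, LabelMaskStack]] | None = None,
    verbose: bool = False,
) -> tuple[TrainedSegmenter, TrainingHistory]:
    """Train the nested encoder-decoder on (RGB tile, truth mask) pairs.

    When ``val_dataset`` is given, the returned segmenter carries the
    weights of the epoch with the best validation selection metric;
    otherwise the final weights.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    shapes = {tile.shape[:2] for tile, _ in dataset}
    if len(shapes) != 1:
        raise ValueError(f"tiles must share a size, got {shapes}")
    (h, w) = shapes.pop()
    if h % 4 or w % 4:
        raise ValueError("tile size must be divisible by 4")

    rng = np.random.default_rng(config.seed)
    model = UNetPP(width=config.width, seed=config.seed)
    opt = Adam(model.params)
    history = TrainingHistory()
    best_state: dict[str, np.ndarray] | None = None

    images = np.stack([_to_nchw(tile)[0] for tile, _ in dataset])
    truths = np.stack([_truth_planes(mask) for _, mask in dataset])

    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(epoch, config.epochs, config.lr_max, config.lr_min)
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x, g = images[idx], truths[idx]
            heads = model.forward(x)
            ag.zero_grads(list(model.params.values()))
            seeds: dict[ag.Tensor, np.ndarray] = {}
            batch_loss = 0.0
            for head in heads:
                probs = softmax(head.data.astype(np.float64))
                loss, dprobs = loss_and_grad(
                    probs, g, config.dice_weight, config.bce_weight, config.dice_smooth
                )
                batch_loss += loss / len(heads)
                seeds[head] = softmax_grad(probs, dprobs).astype(np.float32) / len(heads)
            ag.backward(seeds)
            opt.step(lr)
            losses.append(batch_loss)
        history.epoch_loss.append(float(np.mean(losses)))

        if val_dataset and (epoch % config.val_every == 0 or epoch == config.epochs - 1):
            seg = TrainedSegmenter(model=model, config=config)
            score = evaluate_segmenter(seg, val_dataset, config.selection, config.prob_threshold)
            history.val_score.append(score)
            if score > history.best_score:
                history.best_score = score
                history.best_epoch = epoch
                best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  lr {lr:.2e}  loss {history.epoch_loss[-1]:.4f}")

    if best_state is not None:
        model.load_state(best_state)
    return TrainedSegmenter(model=model, config=config), history
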