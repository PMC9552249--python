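"""The segmenter contract, loss, probability thresholding and a ground-truth oracle.

A segmenter is any callable mapping an RGB tile (H, W, 3) to a 3-channel
probability map (background, intact, not-intact) of the same extent,
normalized per pixel (softmax convention).  It also receives the tile's
global ``origin`` so that position-aware test doubles (the oracle below)
can look up ground truth; trained models ignore it.

The training loss combines a soft Dice term and binary cross-entropy on
the two eosinophil channels, weighted 1.0 and 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .masks import CLASSES, Extent, LabelMaskStack

#: Probability channel order.
CHANNELS: tuple[str, str, str] = ("background", "intact", "not_intact")

DEFAULT_PROB_THRESHOLD = 0.5
DICE_SMOOTH = 1.0  # additive smoothing in the soft-Dice numerator and denominator


@runtime_checkable
class SegmenterContract(Protocol):
    """Callable: RGB tile (+ global origin) -> (3, H, W) probability map."""

    def __call__(self, tile: np.ndarray, origin: tuple[int, int] = (0, 0)) -> np.ndarray: ...


def validate_probability_map(probs: np.ndarray, extent: Extent | None = None) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 3 or probs.shape[0] != 3:
        raise ValueError(f"probability map must be (3, H, W), got {probs.shape}")
    if extent is not None and probs.shape[1:] != extent.shape:
        raise ValueError(f"probability map extent {probs.shape[1:]} != {extent.shape}")
    if probs.min() < -1e-9 or probs.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    return probs


def threshold_probabilities(
    probs: np.ndarray, threshold: float = DEFAULT_PROB_THRESHOLD
) -> LabelMaskStack:
    """Binarize a probability map: a pixel takes the argmax eosinophil
    class iff that class's probability reaches the threshold, else
    background.  At most one class is assigned per pixel."""
    probs = validate_probability_map(probs)
    intact_p, not_intact_p = probs[1], probs[2]
    # argmax over the two eosinophil channels; intact wins exact ties
    not_intact_best = not_intact_p > intact_p
    best_p = np.where(not_intact_best, not_intact_p, intact_p)
    assign = best_p >= threshold
    return LabelMaskStack(
        extent=Extent(probs.shape[1], probs.shape[2]),
        masks={
            "intact": assign & ~not_intact_best,
            "not_intact": assign & not_intact_best,
        },
    )


def combined_loss(
    pred: np.ndarray,
    truth: LabelMaskStack,
    weights: tuple[float, float] = (1.0, 0.5),
    smooth: float = DICE_SMOOTH,
) -> float:
    """Weighted soft-Dice + BCE loss over the two eosinophil channels.

    dice_loss_c = 1 - (2 * sum(p_c * g_c) + eps) / (sum(p_c) + sum(g_c) + eps)
    bce_loss_c  = -mean(g_c * log p_c + (1 - g_c) * log(1 - p_c))

    both averaged over classes; returns w_dice * dice + w_bce * bce.
    """
    pred = validate_probability_map(pred, truth.extent)
    w_dice, w_bce = weights
    eps_log = 1e-12
    dice_terms, bce_terms = [], []
    for j, cls in enumerate(CLASSES):
        p = pred[j + 1]
        g = truth.masks[cls].astype(np.float64)
        inter = float((p * g).sum())
        dice_terms.append(1.0 - (2.0 * inter + smooth) / (p.sum() + g.sum() + smooth))
        pc = np.clip(p, eps_log, 1.0 - eps_log)
        bce_terms.append(float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean()))
    return w_dice * float(np.mean(dice_terms)) + w_bce * float(np.mean(bce_terms))


def cosine_annealing_lr(t: int | float, T: int | float, lr_max: float, lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate at epoch t of T."""
    if t < 0 or t > T:
        raise ValueError(f"epoch {t} outside schedule [0, {T}]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / T))


# ---------------------------------------------------------------------------
# Ground-truth oracle segmenter (test double for the trained network)
# ---------------------------------------------------------------------------

def _hash_uniform(seed: int, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Deterministic per-pixel uniforms from global coordinates.

    SplitMix64-style integer mixing keyed on (seed, row, col), so a
    pixel draws the same value no matter which patch or window it is
    read through — overlapping tiles then stay consistent under OR
    fusion.
    """
    x = (rows.astype(np.uint64) << np.uint64(32)) ^ cols.astype(np.uint64)
    x ^= np.uint64((seed * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return (x >> np.uint64(11)).astype(np.float64) / float(1 << 53)


@dataclass
class OracleSegmenter:
    """Emits probability 1 for the true class of every pixel.

    With ``flip_rate`` > 0 each pixel independently corrupts with that
    probability: eosinophil pixels flip to background and background
    pixels flip to a uniformly chosen eosinophil class.  Corruption is a
    pure function of (seed, global pixel position).
    """

    truth: LabelMaskStack
    flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_rate < 1.0:
            raise ValueError("flip_rate must be in [0, 1)")

    def __call__(self, tile: np.ndarray, origin: tuple[int, int] = (0, 0)) -> np.ndarray:
        h, w = np.asarray(tile).shape[:2]
        r0, c0 = origin
        if r0 < 0 or c0 < 0 or r0 + h > self.truth.extent.height or c0 + w > self.truth.extent.width:
            raise ValueError(f"tile at {origin} with shape {(h, w)} outside truth extent")
        labels = np.zeros((h, w), dtype=np.int8)
        labels[self.truth.masks["not_intact"][r0 : r0 + h, c0 : c0 + w]] = 2
        labels[self.truth.masks["intact"][r0 : r0 + h, c0 : c0 + w]] = 1
        if self.flip_rate > 0:
            rows, cols = np.meshgrid(
                np.arange(r0, r0 + h), np.arange(c0, c0 + w), indexing="ij"
            )
            flip = _hash_uniform(self.seed, rows, cols) < self.flip_rate
            pick = _hash_uniform(self.seed ^ 0x5EED, rows, cols) < 0.5
            was_eos = labels > 0
            labels[flip & was_eos] = 0
            labels[flip & ~was_eos] = np.where(pick, 1, 2)[flip & ~was_eos]
        probs = np.zeros((3, h, w), dtype=np.float64)
        for k in range(3):
            probs[k][labels == k] = 1.0
        return probs


def oracle_segmenter(truth: LabelMaskStack, flip_rate: float = 0.0, seed: int = 0) -> OracleSegmenter:
    """Build a deterministic ground-truth segmenter for pipeline testing."""
    return OracleSegmenter(truth=truth, flip_rate=flip_rate, seed=seed)
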