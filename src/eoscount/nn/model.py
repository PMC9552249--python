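"""Nested encoder-decoder segmentation network with deep supervision.

A compact UNet++-style model: a three-level encoder whose skip
connections are re-designed as dense nested decoder nodes.  Node X(i,j)
receives the concatenation of all same-level nodes X(i, 0..j-1) and the
upsampled deeper node X(i+1, j-1).  Supervision heads (1x1 convolutions
to the three class logits) sit on every top-level decoder node; at
inference their softmax outputs are averaged — no head pruning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def _he_init(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (cin * k * k))
    return rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)


@dataclass
class UNetPP:
    """Depth-2 nested encoder-decoder over RGB tiles, 3 output classes."""

    width: int = 8
    in_channels: int = 3
    n_classes: int = 3
    seed: int = 0
    params: dict[str, Tensor] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.params:
            rng = np.random.default_rng(self.seed)
            w = self.width
            widths = [w, 2 * w, 4 * w]
            # encoder backbone X00, X10, X20
            self._add(rng, "x00", self.in_channels, widths[0], 3)
            self._add(rng, "x10", widths[0], widths[1], 3)
            self._add(rng, "x20", widths[1], widths[2], 3)
            # nested decoder nodes
            self._add(rng, "x01", widths[0] + widths[1], widths[0], 3)
            self._add(rng, "x11", widths[1] + widths[2], widths[1], 3)
            self._add(rng, "x02", 2 * widths[0] + widths[1], widths[0], 3)
            # deep-supervision heads
            self._add(rng, "head1", widths[0], self.n_classes, 1)
            self._add(rng, "head2", widths[0], self.n_classes, 1)

    def _add(self, rng: np.random.Generator, name: str, cin: int, cout: int, k: int) -> None:
        self.params[f"{name}.w"] = Tensor(_he_init(rng, cout, cin, k))
        self.params[f"{name}.b"] = Tensor(np.zeros(cout, dtype=np.float32))

    def _block(self, name: str, x: Tensor) -> Tensor:
        return ag.relu(ag.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"]))

    def _head(self, name: str, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def forward(self, x: np.ndarray) -> list[Tensor]:
        """Return the list of supervision-head logit tensors, (N, 3, H, W) each.

        Spatial dims must be divisible by 4 (two pooling levels).
        """
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("input spatial dims must be divisible by 4")
        t = Tensor(x, requires_grad=False)
        x00 = self._block("x00", t)
        x10 = self._block("x10", ag.maxpool2(x00))
        x20 = self._block("x20", ag.maxpool2(x10))
        x01 = self._block("x01", ag.concat([x00, ag.upsample2(x10)]))
        x11 = self._block("x11", ag.concat([x10, ag.upsample2(x20)]))
        x02 = self._block("x02", ag.concat([x00, x01, ag.upsample2(x11)]))
        return [self._head("head1", x01), self._head("head2", x02)]

    def predict_proba(self, tile: np.ndarray) -> np.ndarray:
        """Average softmax over the supervision heads for one RGB tile.

        Pads reflectively to a multiple of 4 and crops back, so the
        model is tile-size agnostic at inference.
        """
        img = _to_nchw(tile)
        _, _, H, W = img.shape
        ph, pw = (-H) % 4, (-W) % 4
        if ph or pw:
            img = np.pad(img, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        heads = self.forward(img)
        probs = np.mean([softmax(h.data) for h in heads], axis=0)[0]
        return probs[:, :H, :W].astype(np.float64)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float32)

    def save(self, path: str | Path, config: dict | None = None) -> None:
        """Serialize weights (+ embedded config) to an .npz checkpoint."""
        meta = {"width": self.width, "in_channels": self.in_channels,
                "n_classes": self.n_classes, "seed": self.seed,
                "config": config or {}}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> tuple["UNetPP", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        model = cls(width=meta["width"], in_channels=meta["in_channels"],
                    n_classes=meta["n_classes"], seed=meta["seed"])
        model.load_state(state)
        return model, meta.get("config", {})


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax of (N, C, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _to_nchw(tile: np.ndarray) -> np.ndarray:
    """RGB (H, W, 3) uint8/float -> normalized (1, 3, H, W) float32."""
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB tile, got {tile.shape}")
    if tile.dtype == np.uint8:
        tile = tile.astype(np.float32) / 255.0
    return tile.astype(np.float32).transpose(2, 0, 1)[None]
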