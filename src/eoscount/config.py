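"""Pipeline configuration: one flat key=value file drives every stage."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

from .masks import DEFAULT_MICRONS_PER_PIXEL, HPF_AREA_MM2


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their clinical defaults.

    Lengths are pixels unless suffixed otherwise.  The config
    round-trips unchanged through its key=value serialization.
    """

    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    hpf_area_mm2: float = HPF_AREA_MM2
    hpf_side: int = 2144
    scan_stride: int = 500
    patch: int = 448
    patch_stride: int = 424
    train_stride: int = 376
    min_area: int = 1800
    one_cell_max: int = 3000
    increment: int = 2000
    increment_mode: str = "floor"
    activity_threshold: int = 15
    prob_threshold: float = 0.5
    background_threshold: float = 0.15
    background_filter_mode: str = "drop_below"
    white_threshold: float = 0.90
    disk_diameter: int = 50
    connectivity: int = 8
    zero_division: str = "score"
    seed: int = 0

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        import ast

        known = {f.name: f for f in fields(cls)}
        values = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key = value, got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            values[key] = ast.literal_eval(val.strip())
        return cls(**values)

    def to_dict(self) -> dict:
        return asdict(self)
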