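"""Session manifests: named imaging blocks over one movie.

A session is divided into labelled, non-overlapping frame blocks
(e.g. Image1/Image2/Image3 under baseline perfusion plus an optional
terminal high-potassium viability block). The manifest makes block-based
quantities — "active neurons per 5-min block", the high-K response —
explicit and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["Block", "SessionManifest"]


@dataclass
class Block:
    label: str
    start_frame: int
    stop_frame: int  # exclusive
    high_k: bool = False

    @property
    def range(self) -> tuple[int, int]:
        return (self.start_frame, self.stop_frame)


@dataclass
class SessionManifest:
    blocks: list[Block]
    stage: str = ""
    animal_id: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        spans = sorted((b.start_frame, b.stop_frame) for b in self.blocks)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("manifest blocks overlap")
        for b in self.blocks:
            if b.stop_frame <= b.start_frame or b.start_frame < 0:
                raise ValueError(f"block {b.label}: invalid frame range")
        if sum(b.high_k for b in self.blocks) > 1:
            raise ValueError("at most one high-K block allowed")

    def validate_against(self, n_frames: int) -> None:
        for b in self.blocks:
            if b.stop_frame > n_frames:
                raise ValueError(
                    f"block {b.label} extends past movie end ({n_frames} frames)")

    @property
    def high_k_block(self) -> Block | None:
        for b in self.blocks:
            if b.high_k:
                return b
        return None

    @property
    def baseline_blocks(self) -> list[Block]:
        return [b for b in self.blocks if not b.high_k]

    @classmethod
    def default_blocks(cls, n_frames: int, block_frames: int = 300,
                       high_k_start: int | None = None) -> "SessionManifest":
        """Consecutive 5-min (300-frame at 1 Hz) baseline blocks, plus an
        optional high-K block from ``high_k_start`` to the end."""
        end = high_k_start if high_k_start is not None else n_frames
        blocks = []
        i = 1
        for s in range(0, end - block_frames + 1, block_frames):
            blocks.append(Block(f"Image{i}", s, s + block_frames))
            i += 1
        if high_k_start is not None:
            blocks.append(Block(f"Image{i}", high_k_start, n_frames, high_k=True))
        return cls(blocks=blocks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionManifest":
        data = yaml.safe_load(Path(path).read_text())
        blocks = [Block(label=b["label"], start_frame=int(b["start_frame"]),
                        stop_frame=int(b["stop_frame"]),
                        high_k=bool(b.get("high_k", False)))
                  for b in data["blocks"]]
        return cls(blocks=blocks, stage=data.get("stage", ""),
                   animal_id=data.get("animal_id", ""),
                   treatment=data.get("treatment", ""))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "stage": self.stage,
            "animal_id": self.animal_id,
            "treatment": self.treatment,
            "blocks": [
                {"label": b.label, "start_frame": b.start_frame,
                 "stop_frame": b.stop_frame, "high_k": b.high_k}
                for b in self.blocks
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
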