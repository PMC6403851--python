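"""Pipeline configuration: a flat, JSON-serializable parameter set.

Defaults are the image-processing settings used in the source study
(ridge scales 3 and 5 px, intensity window 15–255, particles under
35 px removed, hole filling off, calibration 4.76 pixel/µm) plus this
package's own classifier cut points.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

from .io import DEFAULT_PIXEL_SIZE_UM


@dataclass
class PipelineConfig:
    # segmentation
    ridge_scales_px: tuple[float, ...] = (3.0, 5.0)
    low_threshold: int = 15
    high_threshold: int = 255
    min_particle_px: int = 35
    fill_holes: bool = False
    # quantification
    box_sizes_px: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    # classification: ratio level cut points (very_low|low|median|high|very_high)
    level_cuts: tuple[float, float, float, float] = (0.75, 0.92, 1.08, 1.25)
    # absolute lacunarity band edges: low ≤ b0 < median ≤ b1 < high ≤ b2 < very_high
    band_edges: tuple[float, float, float] = (0.16, 0.27, 0.55)
    # pipeline plumbing
    reference_id: str = ""
    seed: int = 0
    out_dir: str = "results"
    channel: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.low_threshold < self.high_threshold <= 255:
            raise ValueError("need 0 <= low_threshold < high_threshold <= 255")
        if self.min_particle_px < 0:
            raise ValueError("min_particle_px must be >= 0")
        if any(s <= 0 for s in self.ridge_scales_px):
            raise ValueError("ridge scales must be positive")

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        doc = dataclasses.asdict(self)
        for key, value in doc.items():
            if isinstance(value, tuple):
                doc[key] = list(value)
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "PipelineConfig":
        """Load from a JSON document (a path or a raw JSON string)."""
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in doc:
                value = doc[f.name]
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[f.name] = value
        return cls(**kwargs)
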