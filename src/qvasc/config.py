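"""Run configuration shared across the pipeline stages.

A single serializable record of every tunable knob; its short hash is
embedded in all outputs so results can be traced back to the exact
settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field, fields


@dataclass
class RunConfig:
    # physical scale
    pixel_spacing: float = 0.05          # mm / px
    # binarization
    binarize_method: str = "otsu"        # "otsu" | "fixed"
    binarize_threshold: float | None = None
    # skeleton cleanup
    prune_len_px: float = 5.0
    # fractal dimension box ladder
    box_min_size: int = 2
    box_offsets: int = 4
    # branch geometry
    fit_len_px: float = 10.0
    # spatial vascularity
    center_fraction: float = 0.5
    svp_tie_value: int = 1               # SVP when VDR is exactly 1
    # statistics
    feature_set: str = "combined"
    bootstrap_reps: int = 2000
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read key = value lines (or JSON) and override the defaults."""
        text = open(path).read().strip()
        if text.startswith("{"):
            return cls.from_dict(json.loads(text))
        d: dict = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if val.lower() in ("none", ""):
                d[key] = None
            else:
                try:
                    d[key] = json.loads(val)
                except json.JSONDecodeError:
                    d[key] = val
        return cls.from_dict(d)

    @property
    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
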