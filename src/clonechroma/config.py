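"""Run configuration: validated parameters shared across pipeline stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .colorspace import NEGATIVE_POLICIES, SCALE_MAX_CYTOMETER
from .metrics import DEFAULT_FRACTIONS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable analysis parameters in one validated record.

    A single top-level ``seed`` feeds every random stage; per-stage
    generators are derived deterministically from it, so a rerun with an
    identical config reproduces every numeric output.
    """

    resolution_deg: float = 0.2
    channel_map: dict = field(default_factory=lambda: {"R": "r", "G": "g", "B": "b"})
    negative_policy: str = "clamp"
    scale_max: float = SCALE_MAX_CYTOMETER
    b_star: float = 20.0
    brightness_cutoff: float = 0.975
    stability_rule: str = "iqr"
    stability_fraction: float = 0.02
    fractions: tuple = DEFAULT_FRACTIONS
    landscape_fraction: float = 0.01
    policy: str = "majority"
    majority_threshold: float = 0.5
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        n = 90.0 / self.resolution_deg
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"resolution_deg={self.resolution_deg} does not divide 90°"
            )
        if self.negative_policy not in NEGATIVE_POLICIES:
            raise ValueError(f"negative_policy must be one of {NEGATIVE_POLICIES}")
        for f in (*self.fractions, self.landscape_fraction, self.stability_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError(f"fraction {f} outside (0, 1)")
        if not (0.0 < self.brightness_cutoff <= 1.0):
            raise ValueError("brightness_cutoff must lie in (0, 1]")
        if self.b_star <= 0:
            raise ValueError("b_star must be positive")
        if self.policy not in ("strict", "majority"):
            raise ValueError("policy must be 'strict' or 'majority'")
        if self.stability_rule not in ("iqr", "zscore"):
            raise ValueError("stability_rule must be 'iqr' or 'zscore'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        data = {k: v for k, v in (data or {}).items()}
        if "fractions" in data:
            data["fractions"] = tuple(data["fractions"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        return d

    def hash(self) -> str:
        """Stable digest of the logical configuration (key-order independent)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
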