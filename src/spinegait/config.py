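"""Analysis configuration: every tunable knob of the pipeline in one place."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Knobs of the descriptor/coupling pipeline with their defaults.

    Extremum thresholds default to the measurement accuracy of the
    rotoscoping method (1.5 deg, 0.1 cm); the smoothing window and
    correlation strength thresholds are conventional choices documented in
    docs/methods.md.  ``target_duty=None`` warps every stride to the trial's
    mean duty factor; a number fixes a cohort-wide target instead.
    """

    reference_limb: str = "LH"
    rotation_threshold_deg: float = 1.5
    translation_threshold_cm: float = 0.1
    smooth_window_pct: float = 5.0
    strength_mild: float = 0.4
    strength_strong: float = 0.7
    euler_order: str = "ZYX"
    target_duty: float | None = None
    detrend_mode: str = "none"
    noise_floor_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rotation_threshold_deg",
            "translation_threshold_cm",
            "smooth_window_pct",
            "strength_mild",
            "strength_strong",
            "noise_floor_frac",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.detrend_mode not in ("none", "linear-per-stride"):
            raise ValueError(f"unknown detrend_mode {self.detrend_mode!r}")
        if self.target_duty is not None and not (0.0 < self.target_duty < 1.0):
            raise ValueError("target_duty must be in (0, 1)")

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Stable short hash for provenance records."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
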