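"""Analysis configuration: one YAML-serialisable object for the whole run."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic import CohortSpec

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Pipeline parameters and their field-standard defaults.

    window: MTD moving-average window in TRs; k: number of connectivity
    states; discard_frames: initial volumes dropped per run; FD/DVARS
    thresholds in mm / percent with the 1-before / 2-after neighbour
    extension; cortisol AUCs on the natural-log scale by default.
    """

    seed: int = 0
    window: int = 7
    k: int = 5
    n_restarts: int = 10
    discard_frames: int = 4
    fd_threshold_mm: float = 0.2
    dvars_threshold_pct: float = 5.0
    extend_before: int = 1
    extend_after: int = 2
    max_marked_fraction: float = 0.5
    auc_log_scale: bool = True
    adjust_method: str = "holm"
    input_dir: str | None = None
    reference_centroids: str | None = None
    cohort: CohortSpec | None = field(default=None)

    def __post_init__(self) -> None:
        if self.window < 1 or self.k < 1 or self.n_restarts < 1:
            raise ValueError("window, k and n_restarts must be positive")
        if self.discard_frames < 0:
            raise ValueError("discard_frames must be non-negative")
        if self.fd_threshold_mm <= 0 or self.dvars_threshold_pct <= 0:
            raise ValueError("thresholds must be positive")
        if self.adjust_method not in {"holm", "bonferroni"}:
            raise ValueError("adjust_method must be 'holm' or 'bonferroni'")
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))

    def config_hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
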