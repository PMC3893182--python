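"""Run configuration and the pipeline's fixed constants.

The constants collected here are the method's operating points: the 0.85
correlation nomination threshold, the 75% same-channel overlap merge, the
three-member group survival rule, the 1 s cross-channel onset window, and
the ten-nomination review batch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

#: Internal processing sample rate (Hz); recordings are resampled to this.
TARGET_RATE = 100

#: Band-pass edges (Hz) applied before any template work.
BAND_LOW = 0.5
BAND_HIGH = 30.0

#: Correlation threshold above which an epoch is nominated (strict >).
DEFAULT_THRESHOLD = 0.85

#: Template duration range in seconds.
TEMPLATE_MIN_S = 0.212
TEMPLATE_MAX_S = 0.860

#: Grouping constants.
DEFAULT_OVERLAP = 0.75
DEFAULT_MIN_MEMBERS = 3
DEFAULT_MERGE_WINDOW_S = 1.0

#: Review batch size.
DEFAULT_BATCH_SIZE = 10

VALID_AGGREGATORS = ("noisy_or", "mean", "max")


@dataclasses.dataclass
class RunConfig:
    """Bundle of tunables shared by the CLI commands.

    Defaults are the method's published operating points; the aggregator
    name selects how member evidence combines into a group certainty.
    """

    db_path: str = "templates.h5"
    output_dir: str = "out"
    threshold: float = DEFAULT_THRESHOLD
    batch_size: int = DEFAULT_BATCH_SIZE
    overlap: float = DEFAULT_OVERLAP
    min_members: int = DEFAULT_MIN_MEMBERS
    merge_window_s: float = DEFAULT_MERGE_WINDOW_S
    aggregator: str = "noisy_or"
    min_true: int = 2
    laplace_smoothing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if not (0.0 < self.overlap < 1.0):
            raise ValueError(f"overlap must be in (0, 1), got {self.overlap}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.min_members < 1:
            raise ValueError("min_members must be >= 1")
        if self.merge_window_s <= 0:
            raise ValueError("merge_window_s must be > 0")
        if self.aggregator not in VALID_AGGREGATORS:
            raise ValueError(
                f"unknown aggregator {self.aggregator!r}; choose from {VALID_AGGREGATORS}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
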