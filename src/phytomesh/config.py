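"""Pipeline configuration: every tunable threshold in one serialisable object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All thresholds of the segmentation / measurement / tracking pipeline.

    Lengths in mm, angles in degrees unless noted.
    """

    # stem curve fitting
    n_height_bins: int = 40
    hist_cell: float = 5.0              # 2D histogram cell for the slice mode
    walk_window: float = 12.0           # planar search window while walking up the stem
    min_bin_count: int = 4
    min_stem_bins: int = 5
    min_stem_span: float = 20.0
    max_stem_radius: float = 12.0
    # coarse segmentation
    planar_radius_factor: float = 1.5   # M = within this factor of the estimated radius
    min_region_size: int = 60           # smaller fragments are folded into the nearest organ
    # stem tube / internodes
    tube_margin: float = 1.3            # inside-tube band as a factor of the fitted radius
    junction_gap: float = 0.02          # 1D gap threshold on normalised junction heights
    tube_max_iter: int = 50
    tube_tol: float = 1e-3
    # petiole separation
    petiole_bin: float = 3.0            # graph-distance bin width along the petiole curve
    petiole_tube_factor: float = 2.2
    # leaf stage
    merged_leaf_tau: float = 1.75       # area factor over the median leaf that triggers a split
    min_split_size: int = 20
    transversal_max_iter: int = 100
    # temporal matching
    angular_gate: float = 45.0          # leaf eligibility gate about the stem axis
    alpha_grid_step: float = 1.0        # deg, exhaustive rotation search step
    # validation
    trim_fraction: float = 0.05         # trimmed statistics drop this fraction at each tail
    # global
    up_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)
    unit_scale: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable content hash (key order independent)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "up_vector" in data:
            data["up_vector"] = tuple(data["up_vector"])
        return cls(**data)
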