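"""Run-time configuration for the prediction pipeline."""

from __future__ import annotations

from dataclasses import dataclass, fields

from .conservation import CONSERVATION_WEIGHT_DEFAULT
from .orientation import (
    GRID_POINTS_DEFAULT,
    MIN_SURROUNDING_DEFAULT,
    RADIUS_A_DEFAULT,
    THETA_CUTOFF_DEG_DEFAULT,
)

#: default guard on input size; the method targets single enzymes, not
#: whole assemblies of arbitrary size
MAX_RESIDUES_DEFAULT = 5000


@dataclass
class PipelineConfig:
    grid_points: int = GRID_POINTS_DEFAULT
    radius_A: float = RADIUS_A_DEFAULT
    theta_cutoff_deg: float = THETA_CUTOFF_DEG_DEFAULT
    min_surrounding: int = MIN_SURROUNDING_DEFAULT
    cons_weight: float = CONSERVATION_WEIGHT_DEFAULT
    max_residues: int = MAX_RESIDUES_DEFAULT

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read ``key = value`` lines ('#' comments) into a config."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise KeyError(f"unknown config key {key!r}")
                kwargs[key] = casts[types[key]](value.strip())
        return cls(**kwargs)
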