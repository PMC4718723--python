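"""YAML-backed configuration for the tracing pipeline defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class TraceConfig:
    """All user-tunable knobs of the rod-detection / assignment search.

    Distances in Å, angles in degrees.
    """

    threshold: float = 15.0          # satisfaction distance for a pair
    n_top: int = 90                  # top couplings kept (same chain)
    n_top_interchain: int = 6        # top couplings kept to a partner chain
    min_separation: int = 5          # same-chain |i-j| filter
    density_threshold: float = 0.5   # rod detection level, map units
    min_length: float = 12.0         # minimal rod extent
    anisotropy_min: float = 2.5      # rod elongation requirement
    register_range: int = 4          # axial search, whole-residue steps
    roll_samples: int = 8            # rotations about the helix axis
    exhaustive_cap: int = 8          # max segments for exhaustive search
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path) -> TraceConfig:
    """Load a config file; unknown keys raise, missing keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(TraceConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TraceConfig(**data)
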