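"""Run configuration: every tunable constant of the pipeline in one place,
echoed verbatim into output artifacts for provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional


@dataclass
class RunConfig:
    radius: float = 7.0               # A, packing-density cutoff
    window_fraction: float = 0.02     # sliding-window size as fraction of N
    min_window: int = 11              # window floor (atoms)
    min_oxygens: int = 20             # Asp/Glu oxygen eligibility floor
    min_control: int = 10             # Asn/Gln control floor
    kde_points: int = 100             # KDE grid points (99 trapeziums)
    percentile_window: int = 1000     # nearest-resolution window size
    bnet_flag: float = 3.0            # advisory B_net threshold
    percentile_flag: float = 0.95     # advisory percentile threshold
    output_dir: Path = Path(".")
    log_level: str = "INFO"
    seed: int = 0                     # fixtures only; the pipeline itself
                                      # is deterministic

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(d["output_dir"])
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load overrides from a YAML (or plain key: value) file."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" in data:
            data["output_dir"] = Path(data["output_dir"])
        return cls(**data)

    def merged(self, overrides: Optional[dict]) -> "RunConfig":
        if not overrides:
            return self
        d = self.to_dict()
        d.update({k: v for k, v in overrides.items() if v is not None})
        d["output_dir"] = Path(d["output_dir"])
        return RunConfig(**d)
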