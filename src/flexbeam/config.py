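"""Run configuration: one YAML document drives the whole study.

Every stage's random seed is derived from the single global seed, so a run
is reproducible from its config file alone.  Unspecified keys fall back to
desk-scale defaults (a reduced array, few acquisitions, a short curvature
sweep and brief training) sized for a workstation CPU; the full-scale study
configuration is the same document with larger numbers.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import TransducerSpec

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(global_seed: int, *tags) -> int:
    """Deterministically derive a stage seed (< 2**31) from the global seed.

    Tags are reduced with CRC32 (stable across processes, unlike ``hash``).
    """
    ss = np.random.SeedSequence(
        [int(global_seed) & 0x7FFFFFFF]
        + [zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tags]
    )
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Study configuration.

    ``transducer`` holds the array parameters (defaults: the reduced desk
    array); ``experiments`` the acquisition design (voltages, acquisitions
    per experiment, jitter and noise emulation); ``sweep`` the curvature
    radii; ``training`` the network/optimization settings shared by the
    three noise variants; ``evaluation`` the reporting options.
    """

    seed: int = 0
    transducer: dict = field(default_factory=lambda: {
        "n_elements": 16, "n_axial_samples": 464,
    })
    phantom: dict = field(default_factory=lambda: {
        "max_depth": 4.5, "lateral_span": 8.0,   # mm; sized for the desk array
    })
    experiments: dict = field(default_factory=lambda: {
        "voltages": [30.0, 50.0],
        "repeats_per_voltage": 1,       # repositioned repeats; 2 -> 4 experiments
        "acquisitions_per_experiment": 3,
        "noise_sigma": 0.002,
        "reposition_jitter": 0.5,       # mm
    })
    sweep: dict = field(default_factory=lambda: {
        "r_min": 300.0, "r_max": 800.0, "step": 125.0,
    })
    training: dict = field(default_factory=lambda: {
        "variants": ["INO", "GN0.001", "GN0.01"],
        "epochs": 10,
        "batch_size": 4,
        "lr": 1.0e-4,
        "lambda_l1": 10.0,
        "base_channels": 8,
        "n_focal": 128,
    })
    evaluation: dict = field(default_factory=lambda: {
        "dynamic_range": 60.0,
        "save_panels": True,
    })

    def spec(self) -> TransducerSpec:
        return TransducerSpec(**self.transducer)

    def n_experiments(self) -> int:
        e = self.experiments
        return len(e["voltages"]) * int(e.get("repeats_per_voltage", 1))

    def stage_seed(self, *tags) -> int:
        return derive_seed(self.seed, *tags)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for key, value in (d or {}).items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
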