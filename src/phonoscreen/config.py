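"""Run configuration: one YAML file drives every stage, one root seed.

Unknown keys are rejected so silent typos cannot change an analysis; every
run writes its fully resolved configuration next to its outputs.  All
randomness flows from ``seed`` through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SynthSection:
    n_pd_recordings: int = 60
    n_control_recordings: int = 60
    n_pd_participants: int = 30
    n_control_participants: int = 30
    duration: float = 5.0


@dataclass(frozen=True)
class QcSection:
    min_duration: float = 2.5
    min_voiced_fraction: float = 0.6
    max_clipping_fraction: float = 0.01
    min_snr_db: float = 10.0


@dataclass(frozen=True)
class PitchSection:
    f_min: float = 50.0
    f_max: float = 500.0
    voicing_threshold: float = 0.3


@dataclass(frozen=True)
class SelectionSection:
    ranker: str = "relief"          # gso | relief | simba
    top_k: int = 30
    vote_folds: int = 10


@dataclass(frozen=True)
class ModelSection:
    classifier: str = "svm"         # svm | forest | boost
    tune: bool = False


@dataclass(frozen=True)
class CvSection:
    n_per_class: int = 1500
    folds: int = 10
    iterations: int = 100
    k_max: int = 30


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    synth: SynthSection = field(default_factory=SynthSection)
    qc: QcSection = field(default_factory=QcSection)
    pitch: PitchSection = field(default_factory=PitchSection)
    selection: SelectionSection = field(default_factory=SelectionSection)
    model: ModelSection = field(default_factory=ModelSection)
    cv: CvSection = field(default_factory=CvSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {"synth": SynthSection, "qc": QcSection,
                    "pitch": PitchSection, "selection": SelectionSection,
                    "model": ModelSection, "cv": CvSection}
        allowed = set(sections) | {"seed"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {"seed": int(data.get("seed", 0))}
        for name, scls in sections.items():
            kwargs[name] = _build(scls, data.get(name, {}) or {})
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def substream(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)
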