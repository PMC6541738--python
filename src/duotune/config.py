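"""Run configuration: one YAML file describing circuit, measurement and
analysis settings for a reproducible simulate -> gate -> fit -> summarize run.

Defaults mirror the characterization protocol: an IPTG ladder of
0, 2, 4.5, 10, 22.4, 50, 111.8, 250, 559, 1250 uM (the ATc ladder is
1, 5, 25, 125 nM), 3 replicates, 30,000 events per sample, a one-third
density gate on a 64x64 smoothed scatter histogram, and 48 log bins for the
gamma fit.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from duotune.synth_circuit import CircuitParams, MeasurementParams

__all__ = ["RunConfig", "IPTG_LADDER_uM", "ATC_LADDER_nM"]

IPTG_LADDER_uM = (0.0, 2.0, 4.5, 10.0, 22.4, 50.0, 111.8, 250.0, 559.0, 1250.0)
ATC_LADDER_nM = (1.0, 5.0, 25.0, 125.0)


@dataclass
class RunConfig:
    """Everything needed to reproduce one single-channel run."""

    circuit: CircuitParams = field(default_factory=CircuitParams)
    measurement: MeasurementParams = field(default_factory=MeasurementParams)
    inducer_axis: str = "iptg"  # which inducer the ladder refers to
    ladder: tuple[float, ...] = IPTG_LADDER_uM
    replicates: int = 3
    n_events: int | None = None  # None -> measurement.n_events
    gate_fraction: float = 1.0 / 3.0
    gate_bins: int = 64
    gate_smooth: float = 1.0
    pdf_bins: int = 48
    control_size_cv2: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inducer_axis not in ("iptg", "atc"):
            raise ValueError("inducer_axis must be 'iptg' or 'atc'")
        ladder = tuple(float(x) for x in self.ladder)
        if len(ladder) == 0:
            raise ValueError("inducer ladder must be nonempty")
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("inducer ladder must be strictly increasing")
        object.__setattr__(self, "ladder", ladder)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 < self.gate_fraction <= 1.0):
            raise ValueError("gate_fraction must be in (0, 1]")

    def events_per_sample(self) -> int:
        return int(self.measurement.n_events if self.n_events is None else self.n_events)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ladder"] = list(self.ladder)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("circuit"), dict):
            d["circuit"] = CircuitParams(**d["circuit"])
        if isinstance(d.get("measurement"), dict):
            d["measurement"] = MeasurementParams(**d["measurement"])
        if "ladder" in d:
            d["ladder"] = tuple(d["ladder"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """SHA-256 of the canonical YAML form, for run provenance."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()
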