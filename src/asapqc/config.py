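"""Run configuration, manifests and structured logging for pipeline runs.

A :class:`RunConfig` collects the tunable parameters of every stage, loads
from / round-trips to YAML, and validates bounds up front so a bad value
fails a run before any data are touched. Every CLI stage writes a
:class:`RunManifest` next to its outputs: tool version, a hash of the
effective configuration, input checksums and per-stage summaries, enough to
re-run the stage. Data outputs are byte-identical for identical
config + inputs + seed; the manifest's timestamp is the one field outside
that determinism contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .errors import ValidationError


@dataclass
class SimulateConfig:
    two_day: bool = True
    n_patients: int = 6
    n_replicates_per_sample: int = 1
    user_offset_sd: float = 0.0
    within_sample_noise_sd: float = 1.0e-5
    scan_period_s: float = 0.9
    baseline_level: float = 100.0
    baseline_noise_sd: float = 0.05
    background_window_s: float = 30.0
    insertion_duration_s: float = 25.0
    insertion_amplitude: float = 1.0e4
    decay_time_constant_s: float = 6.0
    saturation: bool = False


@dataclass
class ProcessConfig:
    k_mad: float = 5.0
    baseline_fraction: float = 1.0
    min_window_s: float = 5.0
    merge_gap_s: float = 2.0
    clip_negative: bool = True
    tail_fraction: float = 0.2
    decay_ratio_max: float = 0.5
    mz_lo: float | None = None
    mz_hi: float | None = None


@dataclass
class AnalyzeConfig:
    n_pcs: int = 5
    coverage: float = 0.68
    group_by: str = "user"
    distance_test: str = "mann_whitney"


@dataclass
class BatchConfig:
    n_pcs: int = 3
    alpha: float = 0.05
    method: str = "both"  # combat | ica | both


@dataclass
class RunConfig:
    """Full pipeline configuration with a single RNG seed."""

    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    process: ProcessConfig = field(default_factory=ProcessConfig)
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)
    batch: BatchConfig = field(default_factory=BatchConfig)

    def validate(self) -> None:
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if self.simulate.scan_period_s <= 0:
            raise ValidationError("scan_period_s must be positive")
        if not (0 < self.analyze.coverage < 1):
            raise ValidationError("coverage must be in (0, 1)")
        if not (0 < self.batch.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.batch.method not in ("combat", "ica", "both"):
            raise ValidationError(f"unknown correction method {self.batch.method!r}")
        if self.process.k_mad <= 0:
            raise ValidationError("k_mad must be positive")
        if self.analyze.n_pcs < 1 or self.batch.n_pcs < 1:
            raise ValidationError("n_pcs must be at least 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        sections = {}
        for name, sub_cls in (
            ("simulate", SimulateConfig),
            ("process", ProcessConfig),
            ("analyze", AnalyzeConfig),
            ("batch", BatchConfig),
        ):
            sub = data.pop(name, {}) or {}
            known = {f.name for f in dataclasses.fields(sub_cls)}
            bad = set(sub) - known
            if bad:
                raise ValidationError(f"unknown keys in [{name}]: {sorted(bad)}")
            sections[name] = sub_cls(**sub)
        known = {"seed", "log_level"}
        bad = set(data) - known
        if bad:
            raise ValidationError(f"unknown top-level config keys: {sorted(bad)}")
        cfg = cls(**data, **sections)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every stage's outputs."""

    stage: str
    version: str
    config_hash: str
    seed: int
    inputs: dict
    summaries: dict
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        record = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_manifest(
    stage: str, config: RunConfig, inputs: dict, summaries: dict
) -> RunManifest:
    return RunManifest(
        stage=stage,
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        inputs=inputs,
        summaries=summaries,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
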