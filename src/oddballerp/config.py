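"""Pipeline configuration: one YAML document with per-stage sections.

Unknown keys are rejected and cross-field constraints (e.g. stepwise entry
threshold below removal threshold) are validated before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _strict(cls, mapping: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section "
            f"'{section}'; known keys: {sorted(known)}")
    return cls(**mapping)


@dataclass
class SimulatorConfig:
    n_animals: int = 4
    treatments: list = field(default_factory=lambda: ["sham", "alcohol_high"])
    n_standard: int = 1200
    n_deviant: int = 180
    isi_s: float = 1.0
    fs_hz: float = 3000.0
    noise_sd_uV: float = 5.0
    pink_fraction: float = 0.5
    artifact_rate: float = 0.02
    animal_gain_sd: float = 0.2
    animal_latency_jitter_sd_ms: float = 4.0
    trial_latency_jitter_sd_ms: float = 6.0
    seed: int = 0


@dataclass
class PreprocessingConfig:
    band_hz: list = field(default_factory=lambda: [0.1, 45.0])
    ripple: float = 0.001
    window_ms: list = field(default_factory=lambda: [-100.0, 700.0])
    baseline_ms: list = field(default_factory=lambda: [-100.0, 0.0])
    delta_uV: float = 400.0

    def __post_init__(self) -> None:
        if not 0 < self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band_hz must satisfy 0 < low < high")
        if self.delta_uV <= 0:
            raise ValueError("delta_uV must be positive")


@dataclass
class ERPConfig:
    alpha: float = 0.05
    fdr_q: float = 0.05
    sham_label: str = "sham"

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_q"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class ClassificationConfig:
    feature_windows_ms: list = field(
        default_factory=lambda: [[80.0, 105.0], [200.0, 500.0]])
    target_fs_hz: float = 64.0
    antialias_cutoff_hz: float = 32.0
    p_enter: float = 0.05
    p_remove: float = 0.1
    channel: str = "FC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_enter >= self.p_remove:
            raise ValueError(
                "stepwise entry threshold p_enter must be below the "
                "removal threshold p_remove")
        if self.antialias_cutoff_hz > self.target_fs_hz / 2:
            raise ValueError("anti-alias cutoff above the target Nyquist")


@dataclass
class PipelineConfig:
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    preprocessing: PreprocessingConfig = field(
        default_factory=PreprocessingConfig)
    erp: ERPConfig = field(default_factory=ERPConfig)
    classification: ClassificationConfig = field(
        default_factory=ClassificationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {"simulator": SimulatorConfig,
                    "preprocessing": PreprocessingConfig,
                    "erp": ERPConfig,
                    "classification": ClassificationConfig}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config section(s) {sorted(unknown)}")
        kwargs = {name: _strict(sec_cls, d.get(name, {}) or {}, name)
                  for name, sec_cls in sections.items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable under key reordering: hash of the canonical JSON."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def demo_config(seed: int = 0) -> PipelineConfig:
    """Reduced end-to-end demonstration: 4 animals, sham vs the high
    alcohol dose, 300-stimulus sessions (261 standards + 39 deviants,
    keeping the 13% deviant share)."""
    cfg = PipelineConfig()
    cfg.simulator.n_animals = 4
    cfg.simulator.n_standard = 261
    cfg.simulator.n_deviant = 39
    cfg.simulator.seed = seed
    cfg.classification.seed = seed
    return cfg
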