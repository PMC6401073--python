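"""Declarative run configuration.

All defaults equal the study's stated analysis parameters where stated
(0.5 Hz high-pass, 60 Hz notch, 64 Hz low-pass, 128 Hz analysis rate,
4 x IQR outlier rule with a 40 ms guard, 100 circular shifts, 128 gammatone
bands with 20/10 ms frames, 1 s / 5 s aggregation filters). Configs
round-trip losslessly through YAML and unknown keys are rejected as typo
guards.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "validate_config"]


def _from_mapping(cls, raw: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in raw:
            continue
        val = raw[f.name]
        if hasattr(f.type, "__dataclass_fields__") or f.name in _SECTIONS:
            val = _from_mapping(_SECTIONS[f.name], val or {})
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class PathsConfig:
    eeg_dir: str = ""
    audio_dir: str = ""
    out_dir: str = "iscmusic_out"


@dataclass
class PreprocessConfig:
    hp_cutoff_hz: float = 0.5
    notch_hz: float = 60.0
    lp_cutoff_hz: float = 64.0
    target_rate_hz: float = 128.0
    rpca_lambda: float | None = None  # None -> 1/sqrt(max(shape))
    rpca_tol: float = 1e-6
    run_rpca: bool = True
    outlier_iqr_multiplier: float = 4.0
    outlier_pad_ms: float = 40.0

    def validate(self) -> None:
        if self.hp_cutoff_hz <= 0:
            raise ValueError("hp_cutoff_hz must be positive")
        if self.lp_cutoff_hz <= self.hp_cutoff_hz:
            raise ValueError("lp_cutoff_hz must exceed hp_cutoff_hz")
        if self.target_rate_hz < 2 * self.lp_cutoff_hz:
            raise ValueError(
                "target_rate_hz must be >= 2 x lp_cutoff_hz (Nyquist)"
            )
        if self.outlier_iqr_multiplier <= 0:
            raise ValueError("outlier_iqr_multiplier must be positive")


@dataclass
class CorrcaConfig:
    k_max: int | None = None
    shrinkage: float = 0.1

    def validate(self) -> None:
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must be in [0, 1]")


@dataclass
class InferenceConfig:
    n_shuffles: int = 100
    cv_scheme: str = "leave-one-piece-out"

    def validate(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class SimulateConfig:
    n_subjects: int = 20
    n_pieces: int = 8
    n_repeats: int = 3
    segment_s: float = 60.0
    rate_hz: float = 256.0
    n_channels: int = 64
    include_distract: bool = True
    k: int = 3
    signal_amp_uv: float = 3.0
    noise_sd_uv: float = 10.0
    eog_strength: float = 0.4
    n_bad_channels: int = 1
    outlier_rate_per_min: float = 1.0
    outlier_amp_sd: float = 8.0


@dataclass
class SpectralConfig:
    n_bands: int = 128
    window_ms: float = 20.0
    hop_ms: float = 10.0
    percentile_window_s: float = 1.0
    median_window_s: float = 5.0


@dataclass
class ReportConfig:
    slope_scale: float = 1000.0  # slopes multiplied for readability


_SECTIONS = {
    "paths": PathsConfig,
    "preprocess": PreprocessConfig,
    "corrca": CorrcaConfig,
    "inference": InferenceConfig,
    "simulate": SimulateConfig,
    "spectral": SpectralConfig,
    "report": ReportConfig,
}


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    corrca: CorrcaConfig = field(default_factory=CorrcaConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    report: ReportConfig = field(default_factory=ReportConfig)
    seed: int = 0

    def validate(self) -> None:
        self.preprocess.validate()
        self.corrca.validate()
        self.inference.validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        cfg = _from_mapping(cls, raw or {})
        cfg.validate()
        return cfg


def validate_config(text: str) -> RunConfig:
    """Parse YAML text into a typed, defaulted, range-checked RunConfig."""
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    return RunConfig.from_mapping(raw)
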