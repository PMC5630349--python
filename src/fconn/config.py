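"""Study configuration: a validated, YAML-round-trippable parameter bundle."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from fconn.errors import ValidationError

__all__ = [
    "PrepConfig",
    "NetworkConfig",
    "MetricsConfig",
    "StatsConfig",
    "StudyConfig",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class PrepConfig:
    n_drop: int = 0
    fd_threshold_mm: float = 0.3
    low_hz: float = 0.01
    high_hz: float = 0.10
    regress_motion: bool = True
    regressors_dir: str | None = None  # optional per-subject nuisance columns

    def __post_init__(self) -> None:
        if self.n_drop < 0:
            raise ValidationError("n_drop must be non-negative")
        if not 0 <= self.low_hz < self.high_hz:
            raise ValidationError("need 0 <= low_hz < high_hz")
        if self.fd_threshold_mm <= 0:
            raise ValidationError("fd_threshold_mm must be positive")


@dataclass(frozen=True)
class NetworkConfig:
    sparsity_min: float | None = 0.11  # None -> mean-degree criterion
    sparsity_max: float = 0.44
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("step must be positive")
        if self.sparsity_min is not None and not 0 < self.sparsity_min < 1:
            raise ValidationError("sparsity_min must be in (0, 1)")
        if not 0 < self.sparsity_max < 1:
            raise ValidationError("sparsity_max must be in (0, 1)")
        if self.sparsity_min is not None and self.sparsity_min >= self.sparsity_max:
            raise ValidationError("sparsity_min must be below sparsity_max")


@dataclass(frozen=True)
class MetricsConfig:
    n_random: int = 100
    seed: int = 0
    swap_factor: int = 10

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValidationError("n_random must be >= 1")


@dataclass(frozen=True)
class StatsConfig:
    n_perm: int = 5000
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "mean_fd")
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class StudyConfig:
    timeseries_dir: str = "timeseries"
    motion_dir: str = "motion"
    manifest: str = "manifest.tsv"
    output_dir: str = "output"
    tr_seconds: float = 3.0
    prep: PrepConfig = field(default_factory=PrepConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if 1.0 / (2 * self.tr_seconds) < self.prep.high_hz:
            raise ValidationError(
                f"bandpass high cutoff {self.prep.high_hz} Hz exceeds the "
                f"Nyquist frequency at TR={self.tr_seconds} s"
            )

    def resolve(self, base: Path) -> "StudyConfig":
        """Return a copy with all paths made absolute relative to ``base``."""
        def absolute(p: str) -> str:
            path = Path(p)
            return str(path if path.is_absolute() else base / path)

        return StudyConfig(
            timeseries_dir=absolute(self.timeseries_dir),
            motion_dir=absolute(self.motion_dir),
            manifest=absolute(self.manifest),
            output_dir=absolute(self.output_dir),
            tr_seconds=self.tr_seconds,
            prep=self.prep,
            network=self.network,
            metrics=self.metrics,
            stats=self.stats,
        )


def _build(cls, mapping):
    if mapping is None:
        return cls()
    if not isinstance(mapping, dict):
        raise ValidationError(f"expected a mapping for {cls.__name__}")
    try:
        return cls(**mapping)
    except TypeError as exc:
        raise ValidationError(f"bad {cls.__name__} field: {exc}") from exc


def load_config(path: Path | str) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    blocks = {
        "prep": _build(PrepConfig, raw.pop("prep", None)),
        "network": _build(NetworkConfig, raw.pop("network", None)),
        "metrics": _build(MetricsConfig, raw.pop("metrics", None)),
        "stats": _build(StatsConfig, raw.pop("stats", None)),
    }
    try:
        return StudyConfig(**raw, **blocks)
    except TypeError as exc:
        raise ValidationError(f"bad StudyConfig field: {exc}") from exc


def dump_config(config: StudyConfig, path: Path | str) -> None:
    data = asdict(config)
    data["stats"]["covariates"] = list(config.stats.covariates)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
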