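"""Flat key-value pipeline configuration (YAML) with validated defaults.

Every stage reads its tunables from this record; the CLI threads one config
plus per-flag overrides so a full run is reproducible from a single file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import yaml

from .types import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters with their defaults.

    FDR thresholds follow the factor-specific calibration (Sirt6 0.1,
    RelA 0.2); window/probe parameters reflect the ~500 bp chromatin
    fragment size, the resolution limit of the assay.
    """

    # peak calling
    window_bp: int = 500
    min_probes: int = 4
    score_threshold: float = 0.4
    n_permutations: int = 25
    fdr_threshold_sirt6: float = 0.1
    fdr_threshold_rela: float = 0.2
    recovery_goal: float = 1.0
    # target mapping
    flank_bp: int = 4000
    # expression / epistasis
    detection_floor: float = 100.0
    up_fold: float = 1.5
    down_fold: float = 1.0 / 1.5
    # enrichment
    q_threshold: float = 0.05
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.min_probes < 1:
            raise ConfigError("window_bp must be > 0 and min_probes >= 1")
        for key in ("fdr_threshold_sirt6", "fdr_threshold_rela", "recovery_goal", "q_threshold"):
            val = getattr(self, key)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{key} must be in [0, 1], got {val}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not self.up_fold > 1.0 > self.down_fold > 0.0:
            raise ConfigError("need up_fold > 1 > down_fold > 0")
        if self.detection_floor < 0:
            raise ConfigError("detection_floor must be >= 0")

    def fdr_threshold(self, factor: str) -> float:
        if factor == "Sirt6":
            return self.fdr_threshold_sirt6
        if factor == "RelA":
            return self.fdr_threshold_rela
        raise ConfigError(f"no FDR threshold for factor {factor!r}")


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a flat YAML config; missing keys take defaults, unknown keys fail.

    ``load_config(None)`` (or an empty file) returns the full default record.
    Keyword overrides are applied after the file.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    known = set(_FIELD_TYPES)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    coerced = {}
    for key, value in data.items():
        expected = _FIELD_TYPES[key]
        try:
            if expected in ("int", int):
                if isinstance(value, float) and not value.is_integer():
                    raise ValueError
                coerced[key] = int(value)
            elif expected in ("float", float):
                coerced[key] = float(value)
            else:
                coerced[key] = value
        except (TypeError, ValueError):
            raise ConfigError(f"config key {key!r}: cannot interpret {value!r} as {expected}")
    return PipelineConfig(**coerced)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {f.name: getattr(config, f.name) for f in fields(PipelineConfig)},
            fh,
            sort_keys=True,
        )


def with_overrides(config: PipelineConfig, **overrides) -> PipelineConfig:
    return replace(config, **{k: v for k, v in overrides.items() if v is not None})
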