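"""Run configuration: every threshold and convention with its default.

Defaults equal the published analysis choices where one exists (1000-bp
bins, 2-kb promoters, padj ≤ 0.01 & ≥ 4-fold for enrichment, padj ≤ 0.05 &
≥ 2-fold for expression, 90-min intercalation window); geometry conventions
(V/T half-angle) default to the symmetric 30° sectors of the intercalation
literature and are config-exposed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields


@dataclass
class RunConfig:
    # tissue conventions
    pixel_size_um: float = 1.0
    frame_interval_min: float = 4.0
    ap_axis: str = "rows"
    v_half_angle_deg: float = 30.0
    window_min: float = 90.0
    # genomic thresholds
    bin_width: int = 1000
    promoter_len: int = 2000
    enrich_padj: float = 0.01
    enrich_fc: float = 4.0
    de_padj: float = 0.05
    de_fc: float = 2.0
    # reproducibility
    seed: int = 0

    @classmethod
    def field_names(cls):
        return {f.name for f in fields(cls)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ConfigError(ValueError):
    pass


def validate_config(config: RunConfig) -> list[str]:
    """Type/range checks on every field; returns a list of issues (report-only)."""
    issues = []
    c = config
    if c.pixel_size_um <= 0:
        issues.append("pixel_size_um must be > 0")
    if c.frame_interval_min <= 0:
        issues.append("frame_interval_min must be > 0")
    if c.ap_axis not in ("rows", "cols"):
        issues.append("ap_axis must be 'rows' or 'cols'")
    if not 0 < c.v_half_angle_deg < 45:
        issues.append("v_half_angle_deg must lie in (0, 45): sectors must not overlap")
    if c.window_min <= 0:
        issues.append("window_min must be > 0")
    if c.bin_width <= 0:
        issues.append("bin_width must be > 0")
    if c.promoter_len <= 0:
        issues.append("promoter_len must be > 0")
    for name in ("enrich_padj", "de_padj"):
        v = getattr(c, name)
        if not 0 < v <= 1:
            issues.append(f"{name} must lie in (0, 1]")
    for name in ("enrich_fc", "de_fc"):
        if getattr(c, name) < 1:
            issues.append(f"{name} must be >= 1")
    if not isinstance(c.seed, int) or c.seed < 0:
        issues.append("seed must be a non-negative integer")
    return issues
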