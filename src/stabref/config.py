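"""Run configuration shared by the discovery and validation arms."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Sequence

import yaml

__all__ = ["Config"]


@dataclass(frozen=True)
class Config:
    """Pipeline settings; every key can come from a YAML file or a CLI flag.

    ``comparisons`` maps a condition name to its list of (baseline,
    stress) sample-id pairs; when omitted, each non-first column of the
    count table is compared against the first column as its own
    condition.
    """

    pseudocount: float = 10.0
    var_threshold_pct: float = 7.0
    min_reads: float = 500.0
    variation_metric: str = "residual"  # or "direct"
    comparisons: dict[str, list[tuple[str, str]]] | None = None
    decimal_comma: bool = False
    tier_boundaries: tuple[float, float] = (2000.0, 100000.0)
    v_cutoff: float = 0.15
    m_cutoff: float = 0.5
    cv_cutoff: float = 0.2
    ref_cq: str = "min"  # or "mean"
    min_dilutions: int = 3
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "comparisons" in raw and raw["comparisons"] is not None:
            raw["comparisons"] = {
                cond: [tuple(p) for p in pairs] for cond, pairs in raw["comparisons"].items()
            }
        if "tier_boundaries" in raw:
            raw["tier_boundaries"] = tuple(raw["tier_boundaries"])
        return cls(**raw)

    def with_overrides(self, **overrides: Any) -> "Config":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["comparisons"] is not None:
            d["comparisons"] = {c: [list(p) for p in v] for c, v in d["comparisons"].items()}
        d["tier_boundaries"] = list(d["tier_boundaries"])
        return d

    def resolve_comparisons(self, sample_ids: Sequence[str]) -> dict[str, list[tuple[str, str]]]:
        """Comparison design, defaulting to each sample vs the first column."""
        if self.comparisons is not None:
            return {c: [tuple(p) for p in pairs] for c, pairs in self.comparisons.items()}
        if len(sample_ids) < 2:
            raise ValueError("need at least 2 samples to build a default comparison design")
        baseline = sample_ids[0]
        return {s: [(baseline, s)] for s in sample_ids[1:]}
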