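"""Pipeline configuration: every analysis threshold in one place.

Defaults encode the admissibility rules of the analysis framework: the
0.12 Hz respiratory-entrainment threshold, the 0.5 coherence gate for the
alpha index, and the 5% noise-component rule, together with the AR order
range, BRS sequence thresholds and the significance level.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    ar_order: int | None = None                 # None = AIC selection
    ar_order_range: tuple[int, int] = (8, 16)
    ar_method: str = "burg"                     # or "yule_walker"
    entrainment_threshold_hz: float = 0.12
    coherence_threshold: float = 0.5
    noise_component_fraction: float = 0.05
    brs_min_beats: int = 3
    brs_min_sap_step: float = 1.0               # mmHg per beat
    brs_min_rr_step: float = 4.0                # ms per beat
    brs_min_correlation: float = 0.85
    brs_lag: int = 1
    significance_level: float = 0.05
    holm_adjust: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ar_order_range" in raw:
            raw["ar_order_range"] = tuple(raw["ar_order_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ar_order_range"] = list(d["ar_order_range"])
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in every report."""
        payload = yaml.safe_dump(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
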