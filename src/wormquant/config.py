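"""Run configuration: a single structured file drives the whole pipeline.

The configuration round-trips losslessly through YAML; validation collects
every offending key and reports them together in one :class:`SchemaError`.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError
from .synthetic import HabituationModel, TapProtocol

__all__ = ["CalciumOptions", "BehaviorOptions", "StatsOptions", "RunConfig"]


@dataclass
class CalciumOptions:
    alpha: float = 0.0
    threshold_k: float = 3.0
    floor_pct: float = 5.0
    baseline_window: float = 3.0
    background_mode: str = "scaled"

    def _invalid(self) -> list[str]:
        bad = []
        if not 0 <= self.alpha < 1:
            bad.append("calcium.alpha")
        if self.threshold_k < 0:
            bad.append("calcium.threshold_k")
        if self.floor_pct < 0:
            bad.append("calcium.floor_pct")
        if self.baseline_window <= 0:
            bad.append("calcium.baseline_window")
        if self.background_mode not in ("scaled", "literal"):
            bad.append("calcium.background_mode")
        return bad


@dataclass
class BehaviorOptions:
    theta_c: float = 45.0
    hysteresis: float = 10.0
    reversal_window: float = 1.0
    min_back_duration: float = 0.2
    back_speed_threshold: float = 0.05
    swip_assay_time: float = 600.0
    swip_quiet_window: float = 5.0

    def _invalid(self) -> list[str]:
        bad = []
        if not self.theta_c > self.hysteresis > 0:
            bad.append("behavior.theta_c/hysteresis")
        if self.reversal_window <= 0:
            bad.append("behavior.reversal_window")
        if self.min_back_duration <= 0:
            bad.append("behavior.min_back_duration")
        if self.swip_quiet_window <= 0 or self.swip_quiet_window > self.swip_assay_time:
            bad.append("behavior.swip_quiet_window")
        return bad


@dataclass
class StatsOptions:
    ci_method: str = "wilson"
    level: float = 0.95
    endpoint_tap: int = 30
    qc_reference_strain: str = "N2"
    qc_min_initial_response: float = 0.80

    def _invalid(self) -> list[str]:
        bad = []
        if self.ci_method not in ("wilson", "clopper-pearson"):
            bad.append("stats.ci_method")
        if not 0 < self.level < 1:
            bad.append("stats.level")
        if self.endpoint_tap < 1:
            bad.append("stats.endpoint_tap")
        if not 0 <= self.qc_min_initial_response <= 1:
            bad.append("stats.qc_min_initial_response")
        return bad


@dataclass
class RunConfig:
    """Everything a pipeline run needs, including simulation ground truth."""

    seed: int = 0
    protocol: TapProtocol = field(default_factory=TapProtocol)
    strains: dict[str, HabituationModel] = field(
        default_factory=lambda: {
            "N2": HabituationModel(p0=0.9, p_inf=0.25, lam=0.15, dropout=0.1),
            "mutant": HabituationModel(p0=0.9, p_inf=0.55, lam=0.10, dropout=0.1),
        }
    )
    n_worms: int = 60
    #: per-strain swim-assay simulation: paralysis probability and thrash rate
    swim: dict[str, dict] = field(
        default_factory=lambda: {
            "N2": {"paralysis_prob": 0.10, "thrash_freq": 1.0},
            "mutant": {"paralysis_prob": 0.50, "thrash_freq": 0.8},
        }
    )
    #: per-strain calcium-imaging simulation: response probability, true peak,
    #: and number of stimulus trials to render
    calcium_sim: dict[str, dict] = field(
        default_factory=lambda: {
            "N2": {"response_prob": 0.5, "peak_dRR0": 30.0, "n_trials": 6},
            "mutant": {"response_prob": 0.1, "peak_dRR0": 30.0, "n_trials": 6},
        }
    )
    calcium: CalciumOptions = field(default_factory=CalciumOptions)
    behavior: BehaviorOptions = field(default_factory=BehaviorOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    outdir: str = "wormquant-run"
    inputs: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        bad: list[str] = []
        if not isinstance(self.seed, int):
            bad.append("seed")
        if self.n_worms < 1:
            bad.append("n_worms")
        try:
            TapProtocol(self.protocol.n_taps, self.protocol.isi, self.protocol.acclimatization)
        except Exception:
            bad.append("protocol")
        bad += self.calcium._invalid()
        bad += self.behavior._invalid()
        bad += self.stats._invalid()
        if bad:
            raise SchemaError(bad)
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocol"] = asdict(self.protocol)
        d["strains"] = {s: asdict(m) for s, m in self.strains.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(d) - known)
        if unknown:
            raise SchemaError(unknown, f"unknown configuration keys: {', '.join(unknown)}")
        try:
            if "protocol" in d:
                d["protocol"] = TapProtocol(**d["protocol"])
            if "strains" in d:
                d["strains"] = {s: HabituationModel(**m) for s, m in d["strains"].items()}
            if "calcium" in d:
                d["calcium"] = CalciumOptions(**d["calcium"])
            if "behavior" in d:
                d["behavior"] = BehaviorOptions(**d["behavior"])
            if "stats" in d:
                d["stats"] = StatsOptions(**d["stats"])
        except SchemaError:
            raise
        except Exception as exc:
            raise SchemaError(["<structure>"], f"malformed configuration: {exc}") from exc
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the canonical serialized configuration."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()
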