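"""Run configuration: YAML loading with strict validation and shipped defaults.

An empty configuration file yields the base-case economic inputs (device
21,100 EUR; index stay 5,398; hospitalisation 3,462.80; monthly therapy
23.89; GP 25.00 monthly; cardiologist 25.00 twice yearly; utilities
0.6575 / -0.1063; 2.5 % annual discount; 360 monthly cycles) and the
default analysis settings (WTP grid to 100,000 EUR/QALY, 500 bootstrap
iterations).  Unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields

import yaml

from .engine import EconParams

__all__ = ["AnalysisSettings", "RunConfig", "load_config", "save_config"]

_TRIALS = ("mitra_fr", "coapt", "synthetic")
_SOURCES_OS = ("calibrated", "fitted")
_SOURCES_HFH = ("calibrated", "fitted")


@dataclass(frozen=True)
class AnalysisSettings:
    wtp: float = 50_000.0
    wtp_grid_max: float = 100_000.0
    wtp_grid_step: float = 1_000.0
    n_bootstrap: int = 500
    seed: int = 0
    cost_variation: float = 0.20
    hosp_variation: float = 0.20
    utility_variation: float = 0.10
    os_hazard_variation: float = 0.20

    def __post_init__(self):
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.wtp < 0:
            raise ValueError("wtp must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    trial: str = "coapt"
    os_source: str = "calibrated"
    hfh_source: str = "calibrated"
    econ: EconParams = field(default_factory=EconParams)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    output_dir: str = "results"

    def __post_init__(self):
        if self.trial not in _TRIALS:
            raise ValueError(f"trial must be one of {_TRIALS}, got {self.trial!r}")
        if self.os_source not in _SOURCES_OS:
            raise ValueError(f"os_source must be one of {_SOURCES_OS}")
        if self.hfh_source not in _SOURCES_HFH:
            raise ValueError(f"hfh_source must be one of {_SOURCES_HFH}")

    def to_dict(self) -> dict:
        return {
            "trial": self.trial,
            "os_source": self.os_source,
            "hfh_source": self.hfh_source,
            "econ": asdict(self.econ),
            "analysis": asdict(self.analysis),
            "output_dir": self.output_dir,
        }


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in {section!r}: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys fall back to the shipped base-case defaults; unknown keys
    raise with the offending key named.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    known_top = {"trial", "os_source", "hfh_source", "econ", "analysis", "output_dir"}
    unknown = set(data) - known_top
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    econ = _build_section(EconParams, data.get("econ") or {}, "econ")
    analysis = _build_section(AnalysisSettings, data.get("analysis") or {}, "analysis")
    kw = {k: data[k] for k in ("trial", "os_source", "hfh_source", "output_dir") if k in data}
    return RunConfig(econ=econ, analysis=analysis, **kw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
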