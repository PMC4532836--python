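"""Run configuration: one structured document driving the whole pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from cuproforce.schemes import CONSTRUCTS, InstrumentConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class AnalysisSettings:
    min_drop: float = 15.0  # pN
    min_spacing: float = 5.0  # nm
    force_floor: float = 10.0  # pN
    persistence_length: float = 0.4  # nm
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        for name in ("min_drop", "min_spacing", "force_floor",
                     "persistence_length", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"analysis threshold {name} must be positive")


@dataclass
class StatsSettings:
    n_null: int = 2000  # dip-test null replicates
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_null < 1000:
            raise ValueError("n_null must be >= 1000")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RunConfig:
    """Configuration for a simulate -> analyze -> report run.

    Round-trips losslessly through YAML (:func:`save_config` /
    :func:`load_config`); ``config_hash`` fingerprints the canonical form
    for provenance stamping of outputs.
    """

    construct: str = "wt-azurin"
    scheme_file: str | None = None  # None -> built-in construct schemes
    n_traces: int = 20
    n_repeats: int = 4  # (protein-I27)_n
    seed: int = 0
    output_dir: str = "cuproforce-out"
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    tether_contour: float = 20.0  # nm

    def __post_init__(self) -> None:
        if self.scheme_file is None and self.construct not in CONSTRUCTS:
            raise ValueError(
                f"construct {self.construct!r} is not built in "
                f"({sorted(CONSTRUCTS)}) and no scheme_file was given"
            )
        if self.n_traces < 1 or self.n_repeats < 1:
            raise ValueError("n_traces and n_repeats must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        # fingerprint of the scientific configuration; the output location
        # does not change what is computed
        d = self.as_dict()
        d.pop("output_dir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _from_dict(data: dict) -> RunConfig:
    data = dict(data)
    if "instrument" in data and isinstance(data["instrument"], dict):
        data["instrument"] = InstrumentConfig(**data["instrument"])
    if "analysis" in data and isinstance(data["analysis"], dict):
        data["analysis"] = AnalysisSettings(**data["analysis"])
    if "stats" in data and isinstance(data["stats"], dict):
        data["stats"] = StatsSettings(**data["stats"])
    return RunConfig(**data)


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML, with explicit errors for unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    try:
        return _from_dict(data)
    except TypeError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from None


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=False))
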