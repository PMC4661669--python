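"""Shared domain vocabulary, ordered risk levels and configuration validation.

Every pipeline stage speaks in terms of the four ordered risk levels
(low < moderate < high < extreme), the four land-use classes of the
receptor environment, and a :class:`Config` object validated from a
YAML/JSON mapping.  A complete default configuration ships with the
package (``soilrisk/data/default_config.yaml``).
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

__all__ = [
    "RiskLevel",
    "LandUseClass",
    "RiskThresholds",
    "Config",
    "ConfigError",
    "validate_config",
    "load_config",
    "load_default_config",
    "default_config_dict",
    "classify_value",
    "compare_levels",
]


class ConfigError(ValueError):
    """Raised when a configuration mapping fails validation."""


class RiskLevel(enum.IntEnum):
    """Ordered risk level: rank 0..3 bijective with its label."""

    low = 0
    moderate = 1
    high = 2
    extreme = 3

    @property
    def label(self) -> str:
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "RiskLevel":
        try:
            return cls[label]
        except KeyError:
            raise ConfigError(
                f"unknown risk level {label!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


class LandUseClass(enum.Enum):
    """The four receptor land-use classes.  Closed enumeration."""

    industrial = "industrial"
    agriculture = "agriculture"
    residential = "residential"
    conservation = "conservation"

    @classmethod
    def from_label(cls, label: str) -> "LandUseClass":
        try:
            return cls(label)
        except ValueError:
            raise ConfigError(
                f"unknown land-use class {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


def compare_levels(a: RiskLevel, b: RiskLevel) -> int:
    """Three-way comparison of risk levels: -1, 0 or +1 by rank."""
    return (a.value > b.value) - (a.value < b.value)


def classify_value(x: float, breaks: tuple[float, ...]) -> RiskLevel:
    """Interval lookup with the lower-open/upper-closed convention.

    The lowest class is closed on both sides: a value equal to a break
    falls in the class *below* it, mirroring the printed pattern
    "(0 <= CRI <= 1)", "(1 < CRI <= 2)".
    """
    if x < 0:
        raise ValueError(f"cannot classify negative value {x}")
    # bisect_left counts breaks strictly below x, which is exactly the
    # rank under the upper-closed convention.
    return RiskLevel(min(bisect_left(breaks, x), len(breaks)))


def _require_increasing(seq, key: str) -> tuple[float, ...]:
    vals = tuple(float(v) for v in seq)
    if len(vals) != 3:
        raise ConfigError(f"{key}: expected exactly 3 breaks, got {len(vals)}")
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ConfigError(f"{key}: non-increasing breaks {vals}")
    return vals


@dataclass(frozen=True)
class RiskThresholds:
    """Class boundaries for the TCR and CRI four-class schemes."""

    tcr_breaks: tuple[float, float, float] = (1e-6, 1e-5, 1e-4)
    cri_breaks: tuple[float, float, float] = (1.0, 2.0, 2.5)

    def __post_init__(self):
        object.__setattr__(
            self, "tcr_breaks", _require_increasing(self.tcr_breaks, "tcr_breaks")
        )
        object.__setattr__(
            self, "cri_breaks", _require_increasing(self.cri_breaks, "cri_breaks")
        )
        if self.tcr_breaks[0] <= 0:
            raise ConfigError("tcr_breaks must be strictly positive")
        if not (0 < self.cri_breaks[0] and self.cri_breaks[-1] < 3):
            raise ConfigError("cri_breaks must lie strictly inside (0, 3)")


@dataclass
class Config:
    """Fully validated pipeline configuration.

    Attributes hold validated domain objects, not raw mappings; ``raw``
    keeps the original mapping for round-trip serialization and digests.
    """

    pollutants: dict  # id -> health.Pollutant
    scenarios: dict  # LandUseClass -> health.ExposureScenario
    ruleset: Any  # factory.IndicatorRuleset
    thresholds: RiskThresholds
    grid: dict  # cell_size, nodata
    idw: Any  # idw.IdwParams
    matrix: Any  # overlay.MatrixSpec
    scene: Any  # scene.SceneConfig
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)


_TOP_KEYS = {
    "seed",
    "thresholds",
    "pollutants",
    "scenarios",
    "factory_ruleset",
    "grid",
    "idw",
    "matrix",
    "scene",
}


def _check_keys(mapping: Mapping, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")


def validate_config(raw: Mapping[str, Any]) -> Config:
    """Validate a parsed YAML/JSON mapping into a :class:`Config`.

    Fails fast with a descriptive error naming the offending key for
    missing pollutant parameters, non-increasing breaks, unknown land-use
    labels, negative weights and unknown keys.
    """
    from .factory import parse_ruleset
    from .health import ExposureScenario, parse_registry
    from .idw import IdwParams
    from .overlay import default_matrix, parse_matrix
    from .scene import SceneConfig

    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    thresholds = RiskThresholds(**raw.get("thresholds", {}))

    pollutants = parse_registry(raw.get("pollutants", {}))

    scenarios: dict[LandUseClass, Any] = {}
    for label, sc in raw.get("scenarios", {}).items():
        lu = LandUseClass.from_label(label)
        scenarios[lu] = ExposureScenario.from_mapping(sc, context=f"scenarios.{label}")

    ruleset = parse_ruleset(raw.get("factory_ruleset", {}))

    grid_raw = raw.get("grid", {})
    _check_keys(grid_raw, {"cell_size", "nodata"}, "grid")
    grid = {
        "cell_size": float(grid_raw.get("cell_size", 500.0)),
        "nodata": float(grid_raw.get("nodata", -9999.0)),
    }
    if grid["cell_size"] <= 0:
        raise ConfigError("grid.cell_size must be positive")

    idw_params = IdwParams.from_mapping(raw.get("idw", {}))
    matrix = parse_matrix(raw.get("matrix")) if raw.get("matrix") else default_matrix()
    scn = SceneConfig.from_mapping(raw.get("scene", {}), pollutants=pollutants)

    seed = int(raw.get("seed", 0))

    cfg = Config(
        pollutants=pollutants,
        scenarios=scenarios,
        ruleset=ruleset,
        thresholds=thresholds,
        grid=grid,
        idw=idw_params,
        matrix=matrix,
        scene=scn,
        seed=seed,
        raw=dict(raw),
    )
    _cross_check(cfg)
    return cfg


def _cross_check(cfg: Config) -> None:
    # every scenario land use valid by construction; ensure all four covered
    missing = [lu.value for lu in LandUseClass if lu not in cfg.scenarios]
    if missing:
        raise ConfigError(f"scenarios: missing land-use class(es) {missing}")
    # scene background pollutants must exist in the registry
    for pid in cfg.scene.background:
        if pid not in cfg.pollutants:
            raise ConfigError(f"scene.background: pollutant {pid!r} not in registry")
    for plume in cfg.scene.plumes:
        if plume.pollutant not in cfg.pollutants:
            raise ConfigError(f"scene.plumes: pollutant {plume.pollutant!r} not in registry")


def load_config(path) -> Config:
    """Load and validate a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw or {})


def default_config_dict() -> dict:
    """The shipped default configuration as a plain mapping."""
    text = resources.files("soilrisk.data").joinpath("default_config.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def load_default_config() -> Config:
    """Validate and return the shipped default configuration."""
    return validate_config(default_config_dict())
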