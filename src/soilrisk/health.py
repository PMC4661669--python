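"""Human health risk engine: chronic doses, carcinogenic risk and hazard
quotients per pollutant and exposure pathway, aggregated to per-sample
TCR (total carcinogenic risk) and THI (total hazard index).

The dose model is the standard three-pathway soil exposure model
(incidental ingestion, dermal contact, inhalation of resuspended
particulates) used by US EPA RAGS and the Chinese site guideline
HJ 25.3:

    CDI_ing = C * IngR * EF * ED * CF / (BW * AT)
    CDI_derm = C * SA * AF * ABS * EF * ED * CF / (BW * AT)
    CDI_inh = C * InhR * EF * ED / (PEF * BW * AT)

with AT the carcinogenic or non-carcinogenic averaging time, CR =
CDI * SF for pathways with a slope factor and HQ = CDI / RfD for
pathways with a reference dose.  All toxicity and exposure parameters
live in configuration, never in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .config import ConfigError, RiskLevel, RiskThresholds, classify_value

PATHWAYS = ("ingestion", "dermal", "inhalation")


@dataclass(frozen=True)
class Pollutant:
    """Registry entry holding toxicity parameters per exposure pathway.

    ``sf`` maps pathway -> slope factor in (mg/(kg.d))^-1; ``rfd`` maps
    pathway -> reference dose in mg/(kg.d).  Either may be empty per
    pathway, but at least one of the two must be present overall.
    ``abs_dermal`` overrides the scenario-level dermal absorption
    fraction for this pollutant.
    """

    id: str
    group: str  # heavy_metal | organic
    sf: Mapping[str, float] = field(default_factory=dict)
    rfd: Mapping[str, float] = field(default_factory=dict)
    abs_dermal: Optional[float] = None

    def __post_init__(self):
        if self.group not in ("heavy_metal", "organic"):
            raise ConfigError(f"pollutant {self.id}: unknown group {self.group!r}")
        for name, table in (("sf", self.sf), ("rfd", self.rfd)):
            for pw, v in table.items():
                if pw not in PATHWAYS:
                    raise ConfigError(f"pollutant {self.id}: unknown pathway {pw!r} in {name}")
                if not (v > 0):
                    raise ConfigError(f"pollutant {self.id}: {name}.{pw} must be > 0, got {v}")
        if not self.sf and not self.rfd:
            raise ConfigError(f"pollutant {self.id}: needs at least one sf or rfd entry")
        if self.abs_dermal is not None and not (0 < self.abs_dermal <= 1):
            raise ConfigError(f"pollutant {self.id}: abs_dermal must be in (0, 1]")


def parse_registry(raw: Mapping[str, Mapping]) -> dict[str, Pollutant]:
    registry = {}
    for pid, entry in raw.items():
        allowed = {"group", "sf", "rfd", "abs_dermal"}
        unknown = set(entry) - allowed
        if unknown:
            raise ConfigError(f"pollutants.{pid}: unknown key(s) {sorted(unknown)}")
        try:
            registry[pid] = Pollutant(
                id=pid,
                group=entry.get("group", "heavy_metal"),
                sf={k: float(v) for k, v in (entry.get("sf") or {}).items()},
                rfd={k: float(v) for k, v in (entry.get("rfd") or {}).items()},
                abs_dermal=(None if entry.get("abs_dermal") is None else float(entry["abs_dermal"])),
            )
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"pollutants.{pid}: {exc}") from exc
    return registry


_SCENARIO_FIELDS = {
    "BW": "body weight, kg",
    "EF": "exposure frequency, d/yr",
    "ED": "exposure duration, yr",
    "IngR": "soil ingestion rate, mg/d",
    "SA": "exposed skin area, cm2",
    "AF": "adherence factor, mg/(cm2.d)",
    "ABS": "dermal absorption fraction",
    "InhR": "inhalation rate, m3/d",
    "PEF": "particulate emission factor, m3/kg",
    "AT_ca": "carcinogenic averaging time, d",
    "AT_nc": "non-carcinogenic averaging time, d",
    "CF": "mass conversion, kg/mg",
}


@dataclass(frozen=True)
class ExposureScenario:
    """Receptor exposure parameters for one land-use context."""

    BW: float
    EF: float
    ED: float
    IngR: float
    SA: float
    AF: float
    ABS: float
    InhR: float
    PEF: float
    AT_ca: float
    AT_nc: float
    CF: float = 1e-6

    def __post_init__(self):
        for name in _SCENARIO_FIELDS:
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigError(f"scenario parameter {name} must be > 0, got {v}")
        if self.AT_ca < self.AT_nc:
            raise ConfigError("AT_ca must be >= AT_nc")
        if self.ABS > 1:
            raise ConfigError("ABS must be in (0, 1]")

    @classmethod
    def from_mapping(cls, raw: Mapping, context: str = "scenario") -> "ExposureScenario":
        unknown = set(raw) - set(_SCENARIO_FIELDS)
        if unknown:
            raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
        missing = set(_SCENARIO_FIELDS) - set(raw) - {"CF"}
        if missing:
            raise ConfigError(f"{context}: missing parameter(s) {sorted(missing)}")
        return cls(**{k: float(v) for k, v in raw.items()})


@dataclass
class SoilSample:
    """A georeferenced soil measurement record.

    ``conc`` maps pollutant id -> concentration in mg/kg; an absent key
    is a nondetect.  Coordinates are planar meters.
    """

    id: str
    x: float
    y: float
    point_type: str = "census"  # census | encrypted
    pH: float = 7.0
    conc: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.point_type not in ("census", "encrypted"):
            raise ValueError(f"sample {self.id}: unknown point_type {self.point_type!r}")
        if not (0 <= self.pH <= 14):
            raise ValueError(f"sample {self.id}: pH {self.pH} outside [0, 14]")
        for pid, c in self.conc.items():
            if not (c >= 0):
                raise ValueError(f"sample {self.id}: negative concentration for {pid}")


@dataclass
class HealthRiskResult:
    sample_id: str
    tcr: float
    thi: float
    level: RiskLevel
    cr: dict  # pollutant id -> summed CR over pathways
    hq: dict  # pollutant id -> summed HQ over pathways
    detail: dict  # (pollutant, pathway) -> {"dose_ca","dose_nc","cr","hq"}


def chronic_daily_intake(C: float, pathway: str, s: ExposureScenario,
                         carcinogenic: bool, abs_dermal: Optional[float] = None) -> float:
    """Chronic daily intake in mg/(kg.d) for one pathway.

    Linear in C; zero concentration gives zero dose.  ``abs_dermal``
    overrides the scenario ABS for the dermal pathway.
    """
    if C < 0:
        raise ValueError(f"concentration must be >= 0, got {C}")
    AT = s.AT_ca if carcinogenic else s.AT_nc
    if pathway == "ingestion":
        return C * s.IngR * s.EF * s.ED * s.CF / (s.BW * AT)
    if pathway == "dermal":
        ab = s.ABS if abs_dermal is None else abs_dermal
        return C * s.SA * s.AF * ab * s.EF * s.ED * s.CF / (s.BW * AT)
    if pathway == "inhalation":
        return C * s.InhR * s.EF * s.ED / (s.PEF * s.BW * AT)
    raise ValueError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")


def carcinogenic_risk(dose: float, sf: float) -> float:
    """CR = dose x SF (dimensionless lifetime excess cancer risk)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if not sf > 0:
        raise ValueError("slope factor must be > 0")
    return dose * sf


def hazard_quotient(dose: float, rfd: float) -> float:
    """HQ = dose / RfD; HQ = 1 is the non-carcinogenic acceptability line."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if not rfd > 0:
        raise ValueError("reference dose must be > 0")
    return dose / rfd


def assess_sample(sample: SoilSample, registry: Mapping[str, Pollutant],
                  s: ExposureScenario, thresholds: RiskThresholds,
                  nondetect: str = "zero",
                  lod: Optional[Mapping[str, float]] = None) -> HealthRiskResult:
    """Aggregate per-pollutant, per-pathway CR and HQ into TCR and THI.

    TCR sums CR over every (pollutant, pathway) with a slope factor; THI
    sums HQ over every pair with a reference dose.  Nondetects (absent
    concentration keys) contribute zero by default; with
    ``nondetect="half_lod"`` they contribute LOD/2 using the ``lod``
    mapping (pollutants without an LOD entry still contribute zero).
    """
    if nondetect not in ("zero", "half_lod"):
        raise ValueError(f"unknown nondetect policy {nondetect!r}")
    unknown = set(sample.conc) - set(registry)
    if unknown:
        raise KeyError(
            f"sample {sample.id}: pollutant(s) {sorted(unknown)} missing from registry"
        )

    tcr = 0.0
    thi = 0.0
    cr_by_pollutant: dict[str, float] = {}
    hq_by_pollutant: dict[str, float] = {}
    detail: dict[tuple, dict] = {}

    for pid, pol in registry.items():
        if pid in sample.conc:
            C = sample.conc[pid]
        elif nondetect == "half_lod" and lod and pid in lod:
            C = lod[pid] / 2.0
        else:
            C = 0.0
        for pw in PATHWAYS:
            rec = {}
            if pw in pol.sf:
                dose_ca = chronic_daily_intake(C, pw, s, True, pol.abs_dermal)
                rec["dose_ca"] = dose_ca
                rec["cr"] = carcinogenic_risk(dose_ca, pol.sf[pw])
                tcr += rec["cr"]
                cr_by_pollutant[pid] = cr_by_pollutant.get(pid, 0.0) + rec["cr"]
            if pw in pol.rfd:
                dose_nc = chronic_daily_intake(C, pw, s, False, pol.abs_dermal)
                rec["dose_nc"] = dose_nc
                rec["hq"] = hazard_quotient(dose_nc, pol.rfd[pw])
                thi += rec["hq"]
                hq_by_pollutant[pid] = hq_by_pollutant.get(pid, 0.0) + rec["hq"]
            if rec:
                detail[(pid, pw)] = rec

    return HealthRiskResult(
        sample_id=sample.id,
        tcr=tcr,
        thi=thi,
        level=classify_health_risk(tcr, thresholds),
        cr=cr_by_pollutant,
        hq=hq_by_pollutant,
        detail=detail,
    )


def classify_health_risk(tcr: float, thresholds: RiskThresholds) -> RiskLevel:
    """Four-class TCR lookup (upper-closed intervals above the lowest)."""
    if tcr < 0:
        raise ValueError(f"TCR must be >= 0, got {tcr}")
    return classify_value(tcr, thresholds.tcr_breaks)


def assess_samples(samples: Iterable[SoilSample], registry: Mapping[str, Pollutant],
                   scenario_for, thresholds: RiskThresholds,
                   nondetect: str = "zero",
                   lod: Optional[Mapping[str, float]] = None) -> list[HealthRiskResult]:
    """Assess a batch; ``scenario_for`` maps a sample to its scenario
    (use a constant function for a single-scenario assessment)."""
    return [
        assess_sample(sm, registry, scenario_for(sm), thresholds, nondetect, lod)
        for sm in samples
    ]
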