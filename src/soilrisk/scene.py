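"""Synthetic study areas with known ground truth.

Emulates the field structure of an industrial/mining gathering area:
a ~40 x 30 km extent (about 1200 km2), census soil samples on a 3 km
systematic-random grid, 1 km "encrypted" infill grids inside
industrial/mining hotspot rectangles, a central masked reservoir,
four land-use classes, lognormal contaminant backgrounds with
plume-like hotspots added on the log scale near factory clusters,
heavily censored organics (and Hg) with a low detection probability,
and a factory census whose raw indicators are driven by a latent risk
tier recorded in the ground truth.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import ConfigError, LandUseClass
from .factory import FactoryRecord, IndicatorRuleset, ScoringRule
from .health import SoilSample
from .idw import GridSpec, Raster
from .overlay import CODE_OF_CLASS

TIERS = ("low", "moderate", "high", "extreme")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (x0, y0) lower-left to (x1, y1) upper-right."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ConfigError(f"degenerate rectangle {self}")

    def contains(self, x, y):
        return (self.x0 <= x) & (x <= self.x1) & (self.y0 <= y) & (y <= self.y1)

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class Plume:
    """Gaussian hotspot added on the log-concentration scale.

    ``amplitude`` is the peak log-scale boost (a value a multiplies the
    background by exp(a) at the center); ``length_scale`` is the
    Gaussian sigma in meters.
    """

    pollutant: str
    center: tuple[float, float]
    amplitude: float
    length_scale: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigError(f"plume amplitude must be >= 0, got {self.amplitude}")
        if not (self.length_scale > 0):
            raise ConfigError("plume length_scale must be > 0")

    def log_boost(self, x, y):
        d2 = (np.asarray(x) - self.center[0]) ** 2 + (np.asarray(y) - self.center[1]) ** 2
        return self.amplitude * np.exp(-d2 / (2.0 * self.length_scale ** 2))


@dataclass(frozen=True)
class Background:
    """Lognormal background: median in mg/kg, geometric standard
    deviation, and detection probability (1.0 = always detected)."""

    median: float
    gsd: float
    detect_prob: float = 1.0

    def __post_init__(self):
        if not (self.median > 0 and self.gsd >= 1):
            raise ConfigError("background needs median > 0 and gsd >= 1")
        if not (0 <= self.detect_prob <= 1):
            raise ConfigError("detect_prob must be in [0, 1]")


@dataclass(frozen=True)
class FactoryModel:
    count: int = 150
    scatter_fraction: float = 0.2
    tier_probs: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.0, "moderate": 0.50, "high": 0.46, "extreme": 0.04}
    )
    tier_score_means: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.5, "moderate": 1.5, "high": 2.25, "extreme": 2.8}
    )
    tier_score_sd: float = 0.4
    industries: tuple = (
        "electrical_power", "metallurgy", "non_ferrous_metals",
        "petrochemicals", "brick", "paper", "textiles", "food",
    )

    def __post_init__(self):
        if self.count < 1:
            raise ConfigError("factory count must be >= 1")
        if not (0 <= self.scatter_fraction <= 1):
            raise ConfigError("scatter_fraction must be in [0, 1]")
        total = sum(self.tier_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"tier_probs must sum to 1, got {total}")
        unknown = set(self.tier_probs) - set(TIERS)
        if unknown:
            raise ConfigError(f"unknown tier(s) {sorted(unknown)}")


@dataclass(frozen=True)
class SceneConfig:
    extent: tuple[float, float] = (40000.0, 30000.0)
    census_spacing: float = 3000.0
    infill_spacing: float = 1000.0
    jitter_frac: float = 0.3
    reservoir: Optional[Rect] = Rect(15000, 8000, 25000, 17000)
    hotspots: tuple = (
        Rect(26000, 17000, 34000, 23000),  # metallurgical industrial zone NE of the reservoir
        Rect(20000, 2000, 28000, 7000),    # oilfield industrial zone south of the reservoir
        Rect(4000, 18000, 10000, 24000),   # western mining cluster
    )
    landuse_zones: tuple = (
        (Rect(26000, 17000, 34000, 23000), LandUseClass.industrial),
        (Rect(20000, 2000, 28000, 7000), LandUseClass.industrial),
        (Rect(4000, 18000, 10000, 24000), LandUseClass.industrial),
        (Rect(30000, 23000, 38000, 29000), LandUseClass.residential),  # urban area NE
        (Rect(26000, 2000, 32000, 6500), LandUseClass.residential),    # oilfield living area
        (Rect(34000, 24000, 40000, 30000), LandUseClass.conservation), # forest park corner
    )
    background_class: LandUseClass = LandUseClass.agriculture
    background: Mapping[str, Background] = field(default_factory=dict)
    organic_detection: float = 0.08
    plumes: tuple = (
        Plume("As", (27000, 4500), 3.5, 1500),
        Plume("Cd", (31000, 26000), 2.0, 2000),
        Plume("Cr6", (7000, 21000), 1.5, 2000),
    )
    factories: FactoryModel = field(default_factory=FactoryModel)

    def __post_init__(self):
        if not (self.census_spacing > 0 and self.infill_spacing > 0):
            raise ConfigError("grid spacings must be > 0")
        if not (0 <= self.jitter_frac <= 0.5):
            raise ConfigError("jitter_frac must be in [0, 0.5]")
        if not (0 <= self.organic_detection <= 1):
            raise ConfigError("organic_detection must be in [0, 1]")
        w, h = self.extent
        if not (w > 0 and h > 0):
            raise ConfigError("extent must be positive")
        for hz in self.hotspots:
            if hz.x1 > w or hz.y1 > h or hz.x0 < 0 or hz.y0 < 0:
                raise ConfigError(f"hotspot zone {hz} outside extent {self.extent}")

    # -- parsing --------------------------------------------------------------

    @classmethod
    def from_mapping(cls, raw: Mapping, pollutants: Optional[Mapping] = None) -> "SceneConfig":
        if not raw:
            return cls(background=_default_backgrounds())
        allowed = {
            "extent", "census_spacing", "infill_spacing", "jitter_frac",
            "reservoir", "hotspots", "landuse_zones", "background_class",
            "background", "organic_detection", "plumes", "factories",
        }
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"scene: unknown key(s) {sorted(unknown)}")

        kwargs: dict = {}
        if "extent" in raw:
            kwargs["extent"] = tuple(float(v) for v in raw["extent"])
        for key in ("census_spacing", "infill_spacing", "jitter_frac", "organic_detection"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "reservoir" in raw:
            kwargs["reservoir"] = None if raw["reservoir"] is None else Rect(*map(float, raw["reservoir"]))
        if "hotspots" in raw:
            kwargs["hotspots"] = tuple(Rect(*map(float, r)) for r in raw["hotspots"])
        if "landuse_zones" in raw:
            kwargs["landuse_zones"] = tuple(
                (Rect(*map(float, z["rect"])), LandUseClass.from_label(z["class"]))
                for z in raw["landuse_zones"]
            )
        if "background_class" in raw:
            kwargs["background_class"] = LandUseClass.from_label(raw["background_class"])
        organic_detection = kwargs.get("organic_detection", 0.08)
        if "background" in raw:
            bg = {}
            for pid, entry in raw["background"].items():
                if isinstance(entry, (list, tuple)):
                    median, gsd = entry
                    detect = None
                else:
                    median, gsd = entry["median"], entry["gsd"]
                    detect = entry.get("detect_prob")
                if detect is None:
                    group = getattr(pollutants.get(pid), "group", "heavy_metal") if pollutants else "heavy_metal"
                    detect = organic_detection if (group == "organic" or pid == "Hg") else 1.0
                bg[pid] = Background(float(median), float(gsd), float(detect))
            kwargs["background"] = bg
        else:
            kwargs["background"] = _default_backgrounds()
        if "plumes" in raw:
            kwargs["plumes"] = tuple(
                Plume(p["pollutant"], tuple(map(float, p["center"])),
                      float(p["amplitude"]), float(p["length_scale"]))
                for p in raw["plumes"]
            )
        if "factories" in raw:
            f = raw["factories"]
            allowed_f = {"count", "scatter_fraction", "tier_probs",
                         "tier_score_means", "tier_score_sd", "industries"}
            unknown_f = set(f) - allowed_f
            if unknown_f:
                raise ConfigError(f"scene.factories: unknown key(s) {sorted(unknown_f)}")
            fm_kwargs = {}
            for key in ("count",):
                if key in f:
                    fm_kwargs[key] = int(f[key])
            for key in ("scatter_fraction", "tier_score_sd"):
                if key in f:
                    fm_kwargs[key] = float(f[key])
            for key in ("tier_probs", "tier_score_means"):
                if key in f:
                    fm_kwargs[key] = {str(k): float(v) for k, v in f[key].items()}
            if "industries" in f:
                fm_kwargs["industries"] = tuple(f["industries"])
            kwargs["factories"] = FactoryModel(**fm_kwargs)
        return cls(**kwargs)


def _default_backgrounds() -> dict[str, Background]:
    """Median/GSD roughly at the magnitudes typical for polluted
    industrial-area topsoils; organics and Hg censored at 8% detection."""
    metals = {
        "As": (15.0, 1.7), "Cd": (0.3, 1.8), "Cr6": (0.15, 1.5),
        "Co": (18.0, 1.25), "Cu": (27.0, 1.25), "Pb": (20.0, 1.4),
        "Ni": (35.0, 1.4), "V": (85.0, 1.15), "Zn": (90.0, 1.3),
    }
    censored = {
        "Hg": (0.05, 2.5),
        "pyrene": (0.02, 3.0), "carbon_tetrachloride": (0.01, 3.0),
        "dichloroethane_12": (0.02, 3.0), "trichloroethane_111": (0.05, 3.0),
        "benzene": (0.02, 3.0), "ethylbenzene": (0.1, 3.0),
        "fluoranthene": (0.03, 3.0), "xylenes": (0.2, 3.0),
    }
    bg = {pid: Background(m, g, 1.0) for pid, (m, g) in metals.items()}
    bg.update({pid: Background(m, g, 0.08) for pid, (m, g) in censored.items()})
    return bg


@dataclass
class SceneTruth:
    """Ground truth sufficient to score recovery tests."""

    plumes: tuple
    landuse_zones: tuple
    factory_tiers: dict  # factory id -> tier label
    seed: int = 0


@dataclass
class Scene:
    samples: list  # SoilSample
    factories: list  # FactoryRecord
    landuse: Raster
    truth: SceneTruth
    config: SceneConfig


# -- generators ---------------------------------------------------------------

def _in_reservoir(cfg: SceneConfig, x, y):
    if cfg.reservoir is None:
        return np.zeros(np.shape(x), dtype=bool)
    return cfg.reservoir.contains(x, y)


def generate_sampling_design(cfg: SceneConfig, rng: np.random.Generator) -> list[SoilSample]:
    """Census points on a jittered regular grid plus infill grids inside
    hotspot zones; no points inside the reservoir."""
    w, h = cfg.extent
    samples: list[SoilSample] = []

    def grid_points(spacing: float, zone: Optional[Rect]) -> np.ndarray:
        x0, y0 = (zone.x0, zone.y0) if zone else (0.0, 0.0)
        x1, y1 = (zone.x1, zone.y1) if zone else (w, h)
        nx = int(np.floor((x1 - x0) / spacing))
        ny = int(np.floor((y1 - y0) / spacing))
        if nx < 1 or ny < 1:
            return np.empty((0, 2))
        cx = x0 + (np.arange(nx) + 0.5) * spacing
        cy = y0 + (np.arange(ny) + 0.5) * spacing
        X, Y = np.meshgrid(cx, cy)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        jitter = rng.uniform(-cfg.jitter_frac, cfg.jitter_frac, size=pts.shape) * spacing
        return pts + jitter

    census = grid_points(cfg.census_spacing, None)
    keep = ~_in_reservoir(cfg, census[:, 0], census[:, 1]) if len(census) else np.array([], bool)
    for i, (x, y) in enumerate(census[keep]):
        samples.append(SoilSample(id=f"C{i:03d}", x=float(x), y=float(y), point_type="census"))

    n_enc = 0
    for zone in cfg.hotspots:
        pts = grid_points(cfg.infill_spacing, zone)
        if len(pts) == 0:
            continue
        keep = ~_in_reservoir(cfg, pts[:, 0], pts[:, 1])
        for x, y in pts[keep]:
            samples.append(SoilSample(id=f"E{n_enc:03d}", x=float(x), y=float(y),
                                      point_type="encrypted"))
            n_enc += 1
    return samples


def generate_concentrations(points: Sequence[SoilSample], cfg: SceneConfig,
                            rng: np.random.Generator) -> list[SoilSample]:
    """Fill concentrations: lognormal background, plume boosts added on
    the log scale (so values stay positive and the background CV
    structure survives), nondetects drawn by detection probability."""
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    n = len(points)

    boosts: dict[str, np.ndarray] = {}
    for plume in cfg.plumes:
        boosts.setdefault(plume.pollutant, np.zeros(n))
        boosts[plume.pollutant] = boosts[plume.pollutant] + plume.log_boost(xs, ys)

    conc: dict[str, np.ndarray] = {}
    detected: dict[str, np.ndarray] = {}
    for pid, bg in cfg.background.items():
        log_med = np.log(bg.median)
        noise = rng.normal(0.0, np.log(bg.gsd), size=n)
        values = np.exp(log_med + noise + boosts.get(pid, 0.0))
        conc[pid] = values
        detected[pid] = (rng.random(n) < bg.detect_prob) if bg.detect_prob < 1 else np.ones(n, bool)

    ph = np.clip(rng.normal(8.1, 0.35, size=n), 6.5, 10.0)
    out = []
    for i, p in enumerate(points):
        c = {pid: float(conc[pid][i]) for pid in conc if detected[pid][i]}
        out.append(SoilSample(id=p.id, x=p.x, y=p.y, point_type=p.point_type,
                              pH=float(ph[i]), conc=c))
    return out


def _sample_raw_for_score(rule: ScoringRule, target: float,
                          rng: np.random.Generator):
    """Draw a raw indicator value whose score is as close as the rule's
    granularity allows to ``target``."""
    if rule.kind == "boolean":
        return bool(abs(rule.score_true - target) <= abs(rule.score_false - target))
    if rule.kind == "categorical":
        items = list(rule.mapping.items())
        dists = np.array([abs(s - target) for _, s in items])
        best = np.flatnonzero(dists == dists.min())
        return items[int(rng.choice(best))][0]
    # bins: pick the interval whose score is closest, sample uniformly in it
    scores = np.asarray(rule.scores)
    dists = np.abs(scores - target)
    best = np.flatnonzero(dists == dists.min())
    idx = int(rng.choice(best))
    brks = rule.breaks
    span = (brks[-1] - brks[0]) if len(brks) > 1 else max(abs(brks[0]), 1.0)
    lo = brks[idx - 1] if idx > 0 else brks[0] - span
    hi = brks[idx] if idx < len(brks) else brks[-1] + span
    # intervals are lower-open/upper-closed: nudge off the open edge
    eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
    return float(rng.uniform(lo + eps, hi))


def generate_factories(cfg: SceneConfig, rng: np.random.Generator,
                       ruleset: IndicatorRuleset) -> tuple[list[FactoryRecord], dict]:
    """Place factories (mostly inside hotspot zones, a configurable
    fraction scattered outside) and draw raw indicator values from
    tier-conditional score distributions."""
    fm = cfg.factories
    w, h = cfg.extent
    tiers = [t for t in TIERS if fm.tier_probs.get(t, 0.0) > 0]
    probs = np.array([fm.tier_probs[t] for t in tiers])
    probs = probs / probs.sum()

    records: list[FactoryRecord] = []
    tier_of: dict[str, str] = {}
    for i in range(fm.count):
        fid = f"F{i:03d}"
        scattered = (rng.random() < fm.scatter_fraction) or not cfg.hotspots
        for _ in range(1000):
            if scattered:
                x, y = rng.uniform(0, w), rng.uniform(0, h)
            else:
                zone = cfg.hotspots[int(rng.integers(len(cfg.hotspots)))]
                x = rng.uniform(zone.x0, zone.x1)
                y = rng.uniform(zone.y0, zone.y1)
            if not bool(_in_reservoir(cfg, x, y)):
                break
        tier = tiers[int(rng.choice(len(tiers), p=probs))]
        mu = fm.tier_score_means[tier]
        raw = {}
        for sp in ruleset.indicators:
            target = float(np.clip(rng.normal(mu, fm.tier_score_sd), 0.0, 3.0))
            raw[sp.id] = _sample_raw_for_score(sp.rule, target, rng)
        records.append(FactoryRecord(
            id=fid, x=float(x), y=float(y),
            industry=str(rng.choice(fm.industries)), raw=raw,
        ))
        tier_of[fid] = tier
    return records, tier_of


def grid_spec_for(cfg: SceneConfig, cell_size: float, nodata: float = -9999.0) -> GridSpec:
    w, h = cfg.extent
    return GridSpec(
        x_origin=0.0, y_origin=0.0, cell_size=cell_size,
        n_cols=int(np.ceil(w / cell_size)), n_rows=int(np.ceil(h / cell_size)),
        nodata=nodata,
    )


def generate_landuse(cfg: SceneConfig, spec: GridSpec) -> Raster:
    """Rectangle-based land-use raster; overlaps resolved by priority
    conservation > residential > industrial > agriculture; reservoir
    cells are nodata.  Deterministic (pure geometry)."""
    X, Y = spec.cell_centers()
    codes = np.full(X.shape, CODE_OF_CLASS[cfg.background_class], dtype=float)
    priority = [LandUseClass.agriculture, LandUseClass.industrial,
                LandUseClass.residential, LandUseClass.conservation]
    for want in priority:
        for rect, lu in cfg.landuse_zones:
            if lu is want:
                codes[rect.contains(X, Y)] = CODE_OF_CLASS[lu]
    mask = np.asarray(_in_reservoir(cfg, X, Y), dtype=bool)
    values = codes.copy()
    values[mask] = spec.nodata
    return Raster(spec=spec, values=values, mask=mask)


def generate_scene(cfg: SceneConfig, seed: int, ruleset: IndicatorRuleset,
                   cell_size: float = 500.0) -> Scene:
    """Full synthetic study area from a single seed."""
    rng = np.random.default_rng(seed)
    design = generate_sampling_design(cfg, rng)
    samples = generate_concentrations(design, cfg, rng)
    factories, tier_of = generate_factories(cfg, rng, ruleset)
    spec = grid_spec_for(cfg, cell_size)
    landuse = generate_landuse(cfg, spec)
    truth = SceneTruth(
        plumes=cfg.plumes,
        landuse_zones=cfg.landuse_zones,
        factory_tiers=tier_of,
        seed=seed,
    )
    return Scene(samples=samples, factories=factories, landuse=landuse,
                 truth=truth, config=cfg)
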