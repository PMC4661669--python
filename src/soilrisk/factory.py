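"""Inherent risk of polluting factories: indicator scoring, weighted
aggregation into the Comprehensive Risk Index (CRI) and classification.

The index system has three criteria — inherent sudden environmental
risk (weight 0.30), cumulative environmental risk (0.30) and
environmental-risk supervision level (0.40) — each carrying a set of
weighted indicators.  Raw factory attributes are standardized onto a
[0, 3] score by per-indicator rules (interval bins, categorical
lookups or booleans), combined into per-criterion subscores and then
into CRI in [0, 3]:

    CRI = sum_c W_c * subscore_c,   subscore_c = sum_i w_i s_i / sum_i w_i

The weight-normalized subscore keeps every criterion on the same
[0, 3] scale even where the printed indicator weights of a criterion
do not sum to one; the raw-weight alternative is config-selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .config import ConfigError, RiskLevel, RiskThresholds, classify_value

CRITERIA = ("sudden", "cumulative", "supervision")
DEFAULT_CRITERION_WEIGHTS = {"sudden": 0.30, "cumulative": 0.30, "supervision": 0.40}

SCORE_MIN, SCORE_MAX = 0.0, 3.0


@dataclass(frozen=True)
class ScoringRule:
    """Standardization rule mapping a raw indicator value to a score in [0, 3].

    kind="bins": ``breaks`` (strictly increasing) split the real line into
    ``len(breaks)+1`` intervals, lower-open/upper-closed above the first;
    ``scores`` gives one score per interval (may be decreasing for
    "higher raw is better" indicators such as treatment rates).
    kind="categorical": total mapping label -> score.
    kind="boolean": score_true / score_false.
    """

    kind: str
    breaks: tuple = ()
    scores: tuple = ()
    mapping: Mapping[str, float] = field(default_factory=dict)
    score_true: float = 0.0
    score_false: float = 3.0

    def __post_init__(self):
        if self.kind == "bins":
            if len(self.scores) != len(self.breaks) + 1:
                raise ConfigError(
                    f"bins rule: need {len(self.breaks) + 1} scores for "
                    f"{len(self.breaks)} breaks, got {len(self.scores)}"
                )
            if any(b <= a for a, b in zip(self.breaks, self.breaks[1:])):
                raise ConfigError(f"bins rule: non-increasing breaks {self.breaks}")
            bad = [s for s in self.scores if not (SCORE_MIN <= s <= SCORE_MAX)]
        elif self.kind == "categorical":
            if not self.mapping:
                raise ConfigError("categorical rule: empty mapping")
            bad = [s for s in self.mapping.values() if not (SCORE_MIN <= s <= SCORE_MAX)]
        elif self.kind == "boolean":
            bad = [s for s in (self.score_true, self.score_false)
                   if not (SCORE_MIN <= s <= SCORE_MAX)]
        else:
            raise ConfigError(f"unknown rule kind {self.kind!r}")
        if bad:
            raise ConfigError(f"{self.kind} rule: score(s) {bad} outside [0, 3]")


@dataclass(frozen=True)
class IndicatorSpec:
    id: str
    criterion: str
    weight: float
    rule: ScoringRule

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ConfigError(f"indicator {self.id}: unknown criterion {self.criterion!r}")
        if not (self.weight >= 0):
            raise ConfigError(f"indicator {self.id}: negative weight {self.weight}")


@dataclass(frozen=True)
class IndicatorRuleset:
    """Criterion weights plus the indicator table.

    ``weight_mode`` selects normalized (weight-normalized mean, default)
    or raw (plain weighted sum) subscore aggregation; ``missing_policy``
    selects how an unscored indicator is handled: error (default),
    worst_case (score 3) or renormalize (drop it from the criterion).
    """

    criterion_weights: Mapping[str, float]
    indicators: tuple  # of IndicatorSpec
    weight_mode: str = "normalized"
    missing_policy: str = "error"

    def __post_init__(self):
        unknown = set(self.criterion_weights) - set(CRITERIA)
        if unknown:
            raise ConfigError(f"criterion_weights: unknown criterion(s) {sorted(unknown)}")
        for c, w in self.criterion_weights.items():
            if not (w >= 0):
                raise ConfigError(f"criterion_weights.{c}: negative weight {w}")
        total = sum(self.criterion_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"criterion weights must sum to 1, got {total}")
        for c in CRITERIA:
            if not any(sp.criterion == c for sp in self.indicators):
                raise ConfigError(f"criterion {c!r} has no indicators")
        ids = [sp.id for sp in self.indicators]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate indicator ids in ruleset")
        if self.weight_mode not in ("normalized", "raw"):
            raise ConfigError(f"unknown weight_mode {self.weight_mode!r}")
        if self.missing_policy not in ("error", "worst_case", "renormalize"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")

    def by_criterion(self, criterion: str) -> list:
        return [sp for sp in self.indicators if sp.criterion == criterion]

    def spec(self, indicator_id: str) -> IndicatorSpec:
        for sp in self.indicators:
            if sp.id == indicator_id:
                return sp
        raise KeyError(indicator_id)


@dataclass
class FactoryRecord:
    """Raw factory attributes keyed by indicator id."""

    id: str
    x: float
    y: float
    industry: str = ""
    raw: dict = field(default_factory=dict)


@dataclass
class CRIResult:
    factory_id: str
    subscores: dict  # criterion -> subscore in [0, 3]
    cri: float
    level: RiskLevel


def score_indicator(raw, rule: ScoringRule) -> float:
    """Deterministic lookup of a raw value through a scoring rule."""
    if rule.kind == "bins":
        try:
            v = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"bins rule needs a numeric raw value, got {raw!r}") from None
        from bisect import bisect_left
        return float(rule.scores[bisect_left(rule.breaks, v)])
    if rule.kind == "categorical":
        if raw not in rule.mapping:
            raise ValueError(
                f"label {raw!r} absent from categorical mapping {sorted(rule.mapping)}"
            )
        return float(rule.mapping[raw])
    # boolean: accept python bools and common textual spellings from CSV
    if isinstance(raw, str):
        low = raw.strip().lower()
        if low in ("true", "yes", "1"):
            raw = True
        elif low in ("false", "no", "0"):
            raw = False
        else:
            raise ValueError(f"cannot interpret {raw!r} as boolean")
    return float(rule.score_true if raw else rule.score_false)


def criterion_score(scores: Mapping[str, float], ruleset: IndicatorRuleset,
                    criterion: str) -> float:
    """Aggregate indicator scores for one criterion.

    Normalized mode returns sum(w_i s_i) / sum(w_i) so a constant score
    field is a fixed point regardless of the printed weight total.
    """
    specs = ruleset.by_criterion(criterion)
    use = [(sp.weight, scores[sp.id]) for sp in specs if sp.id in scores]
    missing = [sp.id for sp in specs if sp.id not in scores]
    if missing:
        if ruleset.missing_policy == "error":
            raise ValueError(f"criterion {criterion!r}: missing score(s) for {missing}")
        if ruleset.missing_policy == "worst_case":
            use += [(ruleset.spec(m).weight, SCORE_MAX) for m in missing]
        # renormalize: simply drop the missing indicators
    if not use:
        raise ValueError(f"criterion {criterion!r}: no scored indicators")
    wsum = sum(w for w, _ in use)
    ssum = sum(w * s for w, s in use)
    if ruleset.weight_mode == "raw":
        return ssum
    if wsum == 0:
        return 0.0
    return ssum / wsum


def comprehensive_risk_index(factory: FactoryRecord, ruleset: IndicatorRuleset,
                             thresholds: Optional[RiskThresholds] = None) -> CRIResult:
    """Score a factory's raw attributes and aggregate into CRI."""
    thresholds = thresholds or RiskThresholds()
    scores: dict[str, float] = {}
    for sp in ruleset.indicators:
        if sp.id not in factory.raw or factory.raw[sp.id] is None:
            continue  # handled by the ruleset's missing policy
        try:
            scores[sp.id] = score_indicator(factory.raw[sp.id], sp.rule)
        except ValueError as exc:
            raise ValueError(f"factory {factory.id}, indicator {sp.id}: {exc}") from exc
    try:
        subs = {c: criterion_score(scores, ruleset, c) for c in CRITERIA}
    except ValueError as exc:
        raise ValueError(f"factory {factory.id}: {exc}") from exc
    cri = sum(ruleset.criterion_weights.get(c, 0.0) * subs[c] for c in CRITERIA)
    return CRIResult(
        factory_id=factory.id,
        subscores=subs,
        cri=cri,
        level=classify_cri(cri, thresholds),
    )


def classify_cri(cri: float, thresholds: RiskThresholds) -> RiskLevel:
    """Four-class CRI lookup: low on [0,1], moderate (1,2], high (2,2.5],
    extreme (2.5,3] under default breaks."""
    if not (0 <= cri <= 3 + 1e-12):
        raise ValueError(f"CRI {cri} outside [0, 3]")
    return classify_value(min(cri, 3.0), thresholds.cri_breaks)


# -- config parsing -----------------------------------------------------------

def parse_rule(raw: Mapping) -> ScoringRule:
    allowed = {"kind", "breaks", "scores", "mapping", "score_true", "score_false"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"rule: unknown key(s) {sorted(unknown)}")
    kind = raw.get("kind")
    if kind == "bins":
        return ScoringRule(kind="bins",
                           breaks=tuple(float(b) for b in raw.get("breaks", ())),
                           scores=tuple(float(s) for s in raw.get("scores", ())))
    if kind == "categorical":
        return ScoringRule(kind="categorical",
                           mapping={str(k): float(v) for k, v in (raw.get("mapping") or {}).items()})
    if kind == "boolean":
        return ScoringRule(kind="boolean",
                           score_true=float(raw.get("score_true", 0.0)),
                           score_false=float(raw.get("score_false", 3.0)))
    raise ConfigError(f"rule: unknown kind {kind!r}")


def parse_ruleset(raw: Mapping) -> IndicatorRuleset:
    if not raw:
        return default_ruleset()
    allowed = {"criterion_weights", "weight_mode", "missing_policy", "indicators"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"factory_ruleset: unknown key(s) {sorted(unknown)}")
    weights = {str(k): float(v) for k, v in
               (raw.get("criterion_weights") or DEFAULT_CRITERION_WEIGHTS).items()}
    specs = []
    for iid, entry in (raw.get("indicators") or {}).items():
        allowed_i = {"criterion", "weight", "rule"}
        unknown_i = set(entry) - allowed_i
        if unknown_i:
            raise ConfigError(f"indicator {iid}: unknown key(s) {sorted(unknown_i)}")
        specs.append(IndicatorSpec(
            id=str(iid),
            criterion=entry.get("criterion", ""),
            weight=float(entry.get("weight", 0.0)),
            rule=parse_rule(entry.get("rule") or {}),
        ))
    return IndicatorRuleset(
        criterion_weights=weights,
        indicators=tuple(specs),
        weight_mode=raw.get("weight_mode", "normalized"),
        missing_policy=raw.get("missing_policy", "error"),
    )


def default_ruleset() -> IndicatorRuleset:
    """The shipped 22-indicator ruleset (printed weights; stand-in rules).

    The indicator list and weights follow the published index system;
    the standardization rules themselves are documented stand-ins built
    from typical emission/management gradations and are fully
    overridable in config.
    """
    from .config import default_config_dict
    return parse_ruleset(default_config_dict()["factory_ruleset"])
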