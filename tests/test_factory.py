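"""Factory inherent-risk index: scoring rules, weighted aggregation, CRI."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilrisk.config import ConfigError, RiskLevel, RiskThresholds
from soilrisk.factory import (CRITERIA, FactoryRecord, IndicatorRuleset,
                              IndicatorSpec, ScoringRule, classify_cri,
                              comprehensive_risk_index, criterion_score,
                              default_ruleset, score_indicator)

THRESH = RiskThresholds()


def _cat(label_scores):
    return ScoringRule(kind="categorical", mapping=label_scores)


def make_ruleset(weights_by_criterion, weight_mode="normalized",
                 missing_policy="error"):
    """Ruleset whose indicators are identity-like categorical rules so a
    factory's raw values are its scores ('s0'..'s3' -> 0..3)."""
    rule = _cat({"s0": 0.0, "s1": 1.0, "s2": 2.0, "s3": 3.0})
    specs = []
    for crit, ws in weights_by_criterion.items():
        for j, w in enumerate(ws):
            specs.append(IndicatorSpec(id=f"{crit}_{j}", criterion=crit,
                                       weight=w, rule=rule))
    return IndicatorRuleset(
        criterion_weights={"sudden": 0.30, "cumulative": 0.30, "supervision": 0.40},
        indicators=tuple(specs), weight_mode=weight_mode,
        missing_policy=missing_policy)


class TestScoreIndicator:
    def test_boolean(self):
        rule = ScoringRule(kind="boolean", score_true=0, score_false=3)
        assert score_indicator(True, rule) == 0
        assert score_indicator("no", rule) == 3

    @pytest.mark.parametrize("raw,expected", [
        (5, 0.0), (10, 0.0), (50, 1.5), (100, 1.5), (101, 3.0),
    ])
    def test_bins_interval_lookup(self, raw, expected):
        rule = ScoringRule(kind="bins", breaks=(10, 100), scores=(0, 1.5, 3))
        assert score_indicator(raw, rule) == expected

    def test_categorical_unknown_label(self):
        rule = _cat({"a": 0.0})
        with pytest.raises(ValueError, match="absent from categorical mapping"):
            score_indicator("b", rule)

    def test_bins_non_numeric_raw(self):
        rule = ScoringRule(kind="bins", breaks=(1,), scores=(0, 3))
        with pytest.raises(ValueError, match="numeric"):
            score_indicator("lots", rule)

    def test_default_ruleset_domains_stay_in_bounds(self):
        """Sweep every rule's declared domain; scores stay in [0, 3]."""
        import numpy as np
        for sp in default_ruleset().indicators:
            rule = sp.rule
            if rule.kind == "bins":
                lo, hi = rule.breaks[0] - 10, rule.breaks[-1] + 10
                raws = list(np.linspace(lo, hi, 37)) + list(rule.breaks)
            elif rule.kind == "categorical":
                raws = list(rule.mapping)
            else:
                raws = [True, False]
            for raw in raws:
                assert 0.0 <= score_indicator(raw, rule) <= 3.0, sp.id


class TestCriterionScore:
    def test_normalization_bounds(self):
        rs = make_ruleset({"sudden": [0.3, 0.7], "cumulative": [0.5], "supervision": [1.0]})
        assert criterion_score({"sudden_0": 0, "sudden_1": 0}, rs, "sudden") == 0.0
        assert criterion_score({"sudden_0": 3, "sudden_1": 3}, rs, "sudden") == pytest.approx(3.0)

    def test_constant_field_fixed_point_despite_partial_weights(self):
        """Weights summing to 0.65 still map an all-ones field to 1."""
        rs = make_ruleset({"sudden": [1.0],
                           "cumulative": [0.06, 0.02, 0.08, 0.04, 0.15, 0.15, 0.15],
                           "supervision": [1.0]})
        scores = {f"cumulative_{j}": 1.0 for j in range(7)}
        assert criterion_score(scores, rs, "cumulative") == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        rs = make_ruleset({"sudden": [0.35, 0.15], "cumulative": [1.0], "supervision": [1.0]})
        got = criterion_score({"sudden_0": 3, "sudden_1": 1}, rs, "sudden")
        assert got == pytest.approx((0.35 * 3 + 0.15 * 1) / 0.50)  # = 2.4

    def test_weight_scale_invariance(self):
        """Scaling one criterion's printed weights leaves the normalized
        subscore unchanged."""
        scores = {"sudden_0": 2.0, "sudden_1": 0.5, "sudden_2": 3.0}
        base = make_ruleset({"sudden": [0.5, 0.3, 0.2], "cumulative": [1.0],
                             "supervision": [1.0]})
        scaled = make_ruleset({"sudden": [5.0, 3.0, 2.0], "cumulative": [1.0],
                               "supervision": [1.0]})
        assert criterion_score(scores, base, "sudden") == pytest.approx(
            criterion_score(scores, scaled, "sudden"), rel=1e-12)

    def test_missing_policies(self):
        rs_err = make_ruleset({"sudden": [0.5, 0.5], "cumulative": [1.0],
                               "supervision": [1.0]})
        with pytest.raises(ValueError, match="missing score"):
            criterion_score({"sudden_0": 1.0}, rs_err, "sudden")
        rs_worst = make_ruleset({"sudden": [0.5, 0.5], "cumulative": [1.0],
                                 "supervision": [1.0]}, missing_policy="worst_case")
        assert criterion_score({"sudden_0": 1.0}, rs_worst, "sudden") == pytest.approx(2.0)
        rs_renorm = make_ruleset({"sudden": [0.5, 0.5], "cumulative": [1.0],
                                  "supervision": [1.0]}, missing_policy="renormalize")
        assert criterion_score({"sudden_0": 1.0}, rs_renorm, "sudden") == pytest.approx(1.0)


class TestComprehensiveRiskIndex:
    def _factory(self, labels_by_indicator):
        return FactoryRecord(id="F0", x=0, y=0, raw=labels_by_indicator)

    def test_all_zero_and_all_three(self):
        rs = make_ruleset({"sudden": [1.0], "cumulative": [1.0], "supervision": [1.0]})
        low = comprehensive_risk_index(
            self._factory({"sudden_0": "s0", "cumulative_0": "s0", "supervision_0": "s0"}), rs)
        assert low.cri == 0.0 and low.level is RiskLevel.low
        top = comprehensive_risk_index(
            self._factory({"sudden_0": "s3", "cumulative_0": "s3", "supervision_0": "s3"}), rs)
        assert top.cri == pytest.approx(3.0) and top.level is RiskLevel.extreme

    def test_hand_arithmetic_subscores_123(self):
        """Subscores (1, 2, 3) -> CRI = 0.30 + 0.60 + 1.20 = 2.1, high."""
        rs = make_ruleset({"sudden": [1.0], "cumulative": [1.0], "supervision": [1.0]})
        r = comprehensive_risk_index(
            self._factory({"sudden_0": "s1", "cumulative_0": "s2", "supervision_0": "s3"}), rs)
        assert r.cri == pytest.approx(2.1, rel=1e-12)
        assert r.level is RiskLevel.high

    def test_scoring_error_names_factory(self):
        rs = make_ruleset({"sudden": [1.0], "cumulative": [1.0], "supervision": [1.0]})
        with pytest.raises(ValueError, match="factory F0.*sudden_0"):
            comprehensive_risk_index(self._factory(
                {"sudden_0": "bogus", "cumulative_0": "s0", "supervision_0": "s0"}), rs)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_cri_bounds_and_monotonicity(self, data):
        """CRI stays in [0, 3] under random weights/scores and never
        decreases when a single indicator score increases."""
        n_per = {c: data.draw(st.integers(1, 4), label=c) for c in CRITERIA}
        weights = {c: [data.draw(st.floats(0.01, 2.0), label=f"w_{c}_{j}")
                       for j in range(n_per[c])] for c in CRITERIA}
        rs = make_ruleset(weights)
        levels = ["s0", "s1", "s2", "s3"]
        raw = {}
        for c in CRITERIA:
            for j in range(n_per[c]):
                raw[f"{c}_{j}"] = data.draw(st.sampled_from(levels), label=f"{c}_{j}")
        base = comprehensive_risk_index(FactoryRecord(id="F", x=0, y=0, raw=raw), rs)
        assert 0.0 <= base.cri <= 3.0
        # bump one indicator up a level
        bumpable = [k for k, v in raw.items() if v != "s3"]
        if bumpable:
            key = data.draw(st.sampled_from(sorted(bumpable)), label="bump")
            raw2 = dict(raw)
            raw2[key] = levels[levels.index(raw[key]) + 1]
            bumped = comprehensive_risk_index(FactoryRecord(id="F", x=0, y=0, raw=raw2), rs)
            assert bumped.cri >= base.cri - 1e-12
            assert bumped.level >= base.level


class TestClassifyCri:
    @pytest.mark.parametrize("cri,expected", [
        (0.0, RiskLevel.low), (1.0, RiskLevel.low),
        (1.000001, RiskLevel.moderate), (2.0, RiskLevel.moderate),
        (2.5, RiskLevel.high), (2.6, RiskLevel.extreme), (3.0, RiskLevel.extreme),
    ])
    def test_printed_boundaries(self, cri, expected):
        assert classify_cri(cri, THRESH) is expected

    def test_boundary_straddles(self):
        """classify(b) and classify(b + 1e-9) land in adjacent levels."""
        for b in THRESH.cri_breaks:
            below = classify_cri(b, THRESH)
            above = classify_cri(b + 1e-9, THRESH)
            assert above.value == below.value + 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_cri(3.5, THRESH)
        with pytest.raises(ValueError):
            classify_cri(-0.1, THRESH)


class TestDefaultRuleset:
    def test_printed_weight_hierarchy(self):
        rs = default_ruleset()
        assert rs.criterion_weights == {"sudden": 0.30, "cumulative": 0.30,
                                        "supervision": 0.40}
        sums = {c: sum(sp.weight for sp in rs.by_criterion(c)) for c in CRITERIA}
        assert sums["sudden"] == pytest.approx(1.0)
        assert sums["cumulative"] == pytest.approx(0.65)  # printed weights kept verbatim
        assert sums["supervision"] == pytest.approx(1.0)
        assert len(rs.indicators) == 22

    def test_invalid_rulesets_rejected(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            IndicatorRuleset(
                criterion_weights={"sudden": 0.5, "cumulative": 0.5, "supervision": 0.5},
                indicators=default_ruleset().indicators)
        with pytest.raises(ConfigError, match="non-increasing"):
            ScoringRule(kind="bins", breaks=(10, 5), scores=(0, 1, 2))
        with pytest.raises(ConfigError, match="outside"):
            ScoringRule(kind="boolean", score_true=0, score_false=5)
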