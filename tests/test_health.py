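"""Health-risk engine: dose formulas, CR/HQ, TCR/THI aggregation."""

import numpy as np
import pytest

from soilrisk.config import RiskLevel, RiskThresholds
from soilrisk.health import (PATHWAYS, ExposureScenario, Pollutant, SoilSample,
                             assess_sample, carcinogenic_risk,
                             chronic_daily_intake, classify_health_risk,
                             hazard_quotient)

THRESH = RiskThresholds()


def _random_registry(rng, n_pollutants=3):
    registry = {}
    for i in range(n_pollutants):
        sf = {pw: float(rng.uniform(0.01, 20)) for pw in PATHWAYS if rng.random() < 0.7}
        rfd = {pw: float(rng.uniform(1e-4, 1)) for pw in PATHWAYS if rng.random() < 0.7}
        if not sf and not rfd:
            sf = {"ingestion": 1.0}
        registry[f"P{i}"] = Pollutant(id=f"P{i}", group="heavy_metal", sf=sf, rfd=rfd,
                                      abs_dermal=float(rng.uniform(0.001, 0.2)))
    return registry


def _random_scenario(rng):
    ed = float(rng.uniform(10, 40))
    at_nc = ed * 365
    return ExposureScenario(
        BW=float(rng.uniform(40, 80)), EF=float(rng.uniform(100, 365)),
        ED=ed, IngR=float(rng.uniform(50, 200)), SA=float(rng.uniform(2000, 6000)),
        AF=float(rng.uniform(0.01, 0.5)), ABS=float(rng.uniform(0.001, 0.2)),
        InhR=float(rng.uniform(5, 25)), PEF=1.36e9,
        AT_ca=70 * 365, AT_nc=at_nc, CF=1e-6,
    )


def oracle_tcr_thi(sample, registry, s):
    """Independent nested-loop recomputation of TCR and THI."""
    tcr = thi = 0.0
    for pid, pol in registry.items():
        C = sample.conc.get(pid, 0.0)
        for pw in PATHWAYS:
            ab = pol.abs_dermal if pol.abs_dermal is not None else s.ABS
            if pw == "ingestion":
                base = C * s.IngR * s.EF * s.ED * s.CF / s.BW
            elif pw == "dermal":
                base = C * s.SA * s.AF * ab * s.EF * s.ED * s.CF / s.BW
            else:
                base = C * s.InhR * s.EF * s.ED / (s.PEF * s.BW)
            if pw in pol.sf:
                tcr += (base / s.AT_ca) * pol.sf[pw]
            if pw in pol.rfd:
                thi += (base / s.AT_nc) / pol.rfd[pw]
    return tcr, thi


class TestChronicDailyIntake:
    def test_zero_concentration_gives_zero(self, simple_scenario):
        for pw in PATHWAYS:
            for flag in (True, False):
                assert chronic_daily_intake(0.0, pw, simple_scenario, flag) == 0.0

    def test_ingestion_hand_value(self, simple_scenario):
        # 100*100*350*30*1e-6 / (60 * 365*70) evaluated independently
        expected = 105.0 / 1533000.0
        got = chronic_daily_intake(100.0, "ingestion", simple_scenario, True)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_dermal_and_inhalation_hand_values(self, simple_scenario):
        s = simple_scenario
        derm = chronic_daily_intake(50.0, "dermal", s, False)
        assert derm == pytest.approx(
            50 * 5000 * 0.07 * 0.1 * 350 * 30 * 1e-6 / (60 * 365 * 30), rel=1e-12)
        inh = chronic_daily_intake(50.0, "inhalation", s, True)
        assert inh == pytest.approx(
            50 * 15 * 350 * 30 / (1.36e9 * 60 * 365 * 70), rel=1e-12)

    @pytest.mark.parametrize("pathway", PATHWAYS)
    @pytest.mark.parametrize("carcinogenic", [True, False])
    def test_linearity_in_concentration(self, simple_scenario, pathway, carcinogenic):
        d1 = chronic_daily_intake(12.5, pathway, simple_scenario, carcinogenic)
        d2 = chronic_daily_intake(25.0, pathway, simple_scenario, carcinogenic)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_unknown_pathway_rejected(self, simple_scenario):
        with pytest.raises(ValueError, match="unknown pathway"):
            chronic_daily_intake(1.0, "groundwater", simple_scenario, True)


class TestCrHq:
    def test_definitions(self):
        assert carcinogenic_risk(0.0, 1.5) == 0.0
        assert carcinogenic_risk(1e-4, 1.5) == pytest.approx(1.5e-4)
        assert hazard_quotient(0.0, 0.3) == 0.0
        assert hazard_quotient(0.3, 0.3) == pytest.approx(1.0)  # acceptability line

    def test_cr_additive_over_pathways(self, rng):
        """Sum of per-pathway CRs equals CR of the summed dose at shared SF."""
        for _ in range(50):
            doses = rng.uniform(0, 1e-3, size=3)
            sf = float(rng.uniform(0.1, 10))
            total = sum(carcinogenic_risk(d, sf) for d in doses)
            assert total == pytest.approx(carcinogenic_risk(doses.sum(), sf), rel=1e-12)

    def test_hq_strictly_increasing_in_dose(self, rng):
        doses = np.sort(rng.uniform(0.001, 1, size=20))
        hqs = [hazard_quotient(d, 0.05) for d in doses]
        assert all(b > a for a, b in zip(hqs, hqs[1:]))


class TestAssessSample:
    def test_all_zero_concentrations(self, simple_scenario):
        reg = {"As": Pollutant(id="As", group="heavy_metal",
                               sf={"ingestion": 1.5}, rfd={"ingestion": 3e-4})}
        s = SoilSample(id="s0", x=0, y=0, conc={"As": 0.0})
        r = assess_sample(s, reg, simple_scenario, THRESH)
        assert r.tcr == 0.0 and r.thi == 0.0 and r.level is RiskLevel.low

    def test_single_pollutant_single_pathway_degenerate_sum(self, simple_scenario):
        reg = {"As": Pollutant(id="As", group="heavy_metal", sf={"ingestion": 1.5})}
        s = SoilSample(id="s0", x=0, y=0, conc={"As": 40.0})
        r = assess_sample(s, reg, simple_scenario, THRESH)
        dose = chronic_daily_intake(40.0, "ingestion", simple_scenario, True)
        assert r.tcr == pytest.approx(carcinogenic_risk(dose, 1.5), rel=1e-12)

    def test_agrees_with_nested_loop_oracle(self, rng):
        """TCR and THI match an independent recomputation on 100 random
        registries to 1e-12 relative."""
        for _ in range(100):
            reg = _random_registry(rng)
            s = _random_scenario(rng)
            sample = SoilSample(id="s", x=0, y=0,
                                conc={pid: float(rng.uniform(0, 500)) for pid in reg})
            r = assess_sample(sample, reg, s, THRESH)
            tcr_o, thi_o = oracle_tcr_thi(sample, reg, s)
            assert r.tcr == pytest.approx(tcr_o, rel=1e-12)
            assert r.thi == pytest.approx(thi_o, rel=1e-12)
            # internal consistency: TCR/THI are the sums of their components
            assert r.tcr == pytest.approx(sum(r.cr.values()), rel=1e-12)
            assert r.thi == pytest.approx(sum(r.hq.values()), rel=1e-12)

    def test_tcr_scales_linearly(self, rng):
        """TCR(alpha * C) = alpha * TCR(C)."""
        reg = _random_registry(rng)
        s = _random_scenario(rng)
        conc = {pid: float(rng.uniform(1, 100)) for pid in reg}
        base = assess_sample(SoilSample(id="a", x=0, y=0, conc=conc), reg, s, THRESH)
        for alpha in (0.0, 0.25, 3.0, 17.5):
            scaled = assess_sample(
                SoilSample(id="b", x=0, y=0,
                           conc={k: alpha * v for k, v in conc.items()}),
                reg, s, THRESH)
            assert scaled.tcr == pytest.approx(alpha * base.tcr, rel=1e-12, abs=1e-300)

    def test_tcr_additive_over_registry_partition(self, rng):
        reg = _random_registry(rng, n_pollutants=4)
        s = _random_scenario(rng)
        conc = {pid: float(rng.uniform(1, 100)) for pid in reg}
        pids = list(reg)
        part_a = {p: reg[p] for p in pids[:2]}
        part_b = {p: reg[p] for p in pids[2:]}
        full = assess_sample(SoilSample(id="f", x=0, y=0, conc=conc), reg, s, THRESH)
        a = assess_sample(SoilSample(id="a", x=0, y=0,
                                     conc={p: conc[p] for p in part_a}), part_a, s, THRESH)
        b = assess_sample(SoilSample(id="b", x=0, y=0,
                                     conc={p: conc[p] for p in part_b}), part_b, s, THRESH)
        assert full.tcr == pytest.approx(a.tcr + b.tcr, rel=1e-12)

    def test_nondetect_contributes_zero_by_default(self, simple_scenario):
        reg = {"As": Pollutant(id="As", group="heavy_metal", sf={"ingestion": 1.5}),
               "Cd": Pollutant(id="Cd", group="heavy_metal", sf={"ingestion": 6.1})}
        s = SoilSample(id="s", x=0, y=0, conc={"As": 10.0})  # Cd nondetect
        r = assess_sample(s, reg, simple_scenario, THRESH)
        assert "Cd" not in r.cr or r.cr["Cd"] == 0.0

    def test_half_lod_substitution(self, simple_scenario):
        reg = {"Cd": Pollutant(id="Cd", group="heavy_metal", sf={"ingestion": 6.1})}
        s = SoilSample(id="s", x=0, y=0, conc={})
        r = assess_sample(s, reg, simple_scenario, THRESH,
                          nondetect="half_lod", lod={"Cd": 0.1})
        expected = assess_sample(SoilSample(id="t", x=0, y=0, conc={"Cd": 0.05}),
                                 reg, simple_scenario, THRESH)
        assert r.tcr == pytest.approx(expected.tcr, rel=1e-12)
        assert r.tcr > 0

    def test_unregistered_pollutant_rejected(self, simple_scenario):
        reg = {"As": Pollutant(id="As", group="heavy_metal", sf={"ingestion": 1.5})}
        s = SoilSample(id="s", x=0, y=0, conc={"Xx": 1.0})
        with pytest.raises(KeyError, match="Xx"):
            assess_sample(s, reg, simple_scenario, THRESH)


class TestClassifyHealthRisk:
    @pytest.mark.parametrize("tcr,expected", [
        (5e-7, RiskLevel.low),        # below the 1e-6 acceptability line
        (5e-6, RiskLevel.moderate),
        (2e-4, RiskLevel.extreme),
    ])
    def test_default_breaks(self, tcr, expected):
        assert classify_health_risk(tcr, THRESH) is expected

    def test_monotone_around_breaks(self):
        """Classification never decreases as TCR crosses each break."""
        grid = []
        for b in THRESH.tcr_breaks:
            grid += [np.nextafter(b, 0), b, np.nextafter(b, np.inf)]
        grid = sorted(grid)
        levels = [classify_health_risk(t, THRESH) for t in grid]
        assert all(b >= a for a, b in zip(levels, levels[1:]))
        # break itself belongs to the lower class (upper-closed)
        for b in THRESH.tcr_breaks:
            assert classify_health_risk(b, THRESH) < classify_health_risk(
                np.nextafter(b, np.inf), THRESH)

    def test_negative_tcr_rejected(self):
        with pytest.raises(ValueError):
            classify_health_risk(-1e-9, THRESH)
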