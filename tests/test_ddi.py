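"""Drug-drug-interaction counts, the five scores, eligibility and verdicts.

Oracles here are deliberately naive: counts and scores are recomputed by
direct enumeration over explicit report lists and compared with the
package's table-based implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pvsignals.ddi import (
    DDICounts, additive_interaction, conviction, crr, ddi_counts, ddi_to_frame,
    lift, multiplicative_interaction, screen_ddi, select_eligible_triples,
)
from pvsignals.disproportionality import screen_signals
from pvsignals.preprocessing import (
    CaseDefinition, build_all_contingencies, flag_cases,
)
from pvsignals.simulate import DrugSpec, SimConfig, generate

from conftest import make_bundle


def bundle_from_triples(triples: list[tuple[bool, bool, bool]]):
    """Build a bundle from (has_A, has_B, has_AE) report descriptors."""
    reports = []
    for i, (has_a, has_b, has_ae) in enumerate(triples):
        drugs = []
        if has_a:
            drugs.append({"seq": len(drugs) + 1, "ingredient": "esketamine",
                          "role": "PS", "indication": "Depression"})
        if has_b:
            drugs.append({"seq": len(drugs) + 1, "ingredient": "drugb", "role": "SS"})
        if not drugs:
            drugs.append({"seq": 1, "ingredient": "filler", "role": "C"})
        reports.append({
            "primaryid": i + 1,
            "drugs": drugs,
            "pts": (["Vertigo"] if has_ae else []) + ["Headache"],
        })
    return make_bundle(reports)


def enumerate_counts(triples, universe):
    """Independent brute-force recount of the nine DDI quantities."""
    def in_uni(t):
        return t[0] if universe == "case_reports" else True

    n_AB1 = sum(1 for t in triples if in_uni(t) and t[0] and t[1] and t[2])
    n_A1 = sum(1 for t in triples if in_uni(t) and t[0] and not t[1] and t[2])
    n_AB_plus = sum(1 for t in triples if in_uni(t) and t[0] and t[1])
    n_B_plus = sum(1 for t in triples if in_uni(t) and t[1] and not t[0])
    n_pp = sum(1 for t in triples if in_uni(t))
    cells = {}
    for name, pred in (("11", lambda t: t[0] and t[1]),
                       ("10", lambda t: t[0] and not t[1]),
                       ("01", lambda t: t[1] and not t[0]),
                       ("00", lambda t: not t[0] and not t[1])):
        sub = [t for t in triples if pred(t)]
        cells[name] = (sum(1 for t in sub if t[2]), len(sub))
    return DDICounts(
        n_AB1=n_AB1, n_A1=n_A1, n_AB_plus=n_AB_plus, n_B_plus=n_B_plus,
        n_plusplus=n_pp,
        n11=cells["11"][0], N11=cells["11"][1],
        n10=cells["10"][0], N10=cells["10"][1],
        n01=cells["01"][0], N01=cells["01"][1],
        n00=cells["00"][0], N00=cells["00"][1],
    )


TEN_REPORTS = [
    (True, True, True), (True, True, True), (True, True, False),
    (True, False, True), (True, False, False),
    (False, True, True), (False, True, False),
    (False, False, True), (False, False, False), (False, False, False),
]


class TestCounts:
    @pytest.mark.parametrize("universe", ["all_reports", "case_reports"])
    def test_ten_report_hand_enumeration(self, universe):
        b = bundle_from_triples(TEN_REPORTS)
        flags = flag_cases(b, CaseDefinition("esketamine"))
        counts = ddi_counts(b, flags, "drugb", "Vertigo", universe=universe)
        assert counts == enumerate_counts(TEN_REPORTS, universe)
        # spot-check the all-reports numbers by hand
        if universe == "all_reports":
            assert (counts.n_AB1, counts.n_A1, counts.n_AB_plus,
                    counts.n_B_plus, counts.n_plusplus) == (2, 1, 3, 2, 10)
            assert (counts.n11, counts.N11) == (2, 3)
            assert (counts.n00, counts.N00) == (1, 3)

    def test_absent_drug_b_degenerate(self):
        b = bundle_from_triples(TEN_REPORTS)
        flags = flag_cases(b, CaseDefinition("esketamine"))
        counts = ddi_counts(b, flags, "phantom", "Vertigo", universe="all_reports")
        assert counts.n_AB1 == counts.n_AB_plus == counts.n_B_plus == 0

    def test_concomitant_only_role_is_not_b_exposure(self):
        b = make_bundle([
            {"primaryid": 1,
             "drugs": [
                 {"seq": 1, "ingredient": "esketamine", "role": "PS",
                  "indication": "Depression"},
                 {"seq": 2, "ingredient": "drugb", "role": "C"},
             ],
             "pts": ["Vertigo"]},
            {"primaryid": 2, "drugs": [{"ingredient": "other"}], "pts": ["Rash"]},
        ])
        flags = flag_cases(b, CaseDefinition("esketamine"))
        counts = ddi_counts(b, flags, "drugb", "Vertigo", universe="all_reports")
        assert counts.n_AB_plus == 0


class TestScores:
    def test_hand_arithmetic_on_ten_reports(self):
        counts = enumerate_counts(TEN_REPORTS, "all_reports")
        assert lift(counts) == pytest.approx((2 / 5) / (3 / 10))       # 4/3
        assert conviction(counts) == pytest.approx((1 - 0.3) / (1 - 0.4))
        assert additive_interaction(counts) == pytest.approx(
            2 / 3 - 1 / 2 - 1 / 2 + 1 / 3)
        assert multiplicative_interaction(counts) == pytest.approx(
            (2 / 3) * (1 / 3) / ((1 / 2) * (1 / 2)))
        # CRR from hand-computed PRRs
        prr_ab = (2 / 3) / (3 / 7)
        prr_a = (3 / 5) / (2 / 5)
        prr_b = (3 / 5) / (2 / 5)
        b = bundle_from_triples(TEN_REPORTS)
        flags = flag_cases(b, CaseDefinition("esketamine"))
        got = crr(ddi_counts(b, flags, "drugb", "Vertigo", universe="all_reports"))
        assert got == pytest.approx(prr_ab / max(prr_a, prr_b))

    def test_lift_hand_example(self):
        counts = DDICounts(n_AB1=4, n_A1=6, n_AB_plus=12, n_B_plus=8,
                           n_plusplus=100, n11=4, N11=12, n10=6, N10=30,
                           n01=2, N01=8, n00=3, N00=50)
        assert lift(counts) == pytest.approx((4 / 20) / (10 / 100))  # 2.0

    def test_conviction_hand_example_and_independence(self):
        # support=0.1, confidence=0.2 -> 0.9/0.8
        counts = DDICounts(n_AB1=4, n_A1=6, n_AB_plus=12, n_B_plus=8,
                           n_plusplus=100, n11=4, N11=12, n10=6, N10=30,
                           n01=2, N01=8, n00=3, N00=50)
        assert conviction(counts) == pytest.approx(0.9 / 0.8)
        # confidence == support -> conviction 1 (independence)
        ind = DDICounts(n_AB1=2, n_A1=8, n_AB_plus=10, n_B_plus=10,
                        n_plusplus=100, n11=2, N11=10, n10=8, N10=40,
                        n01=1, N01=10, n00=2, N00=40)
        assert lift(ind) == pytest.approx(1.0)
        assert conviction(ind) == pytest.approx(1.0)

    def test_conviction_perfect_rule_is_infinite(self):
        counts = DDICounts(n_AB1=10, n_A1=5, n_AB_plus=10, n_B_plus=0,
                           n_plusplus=100, n11=10, N11=10, n10=5, N10=40,
                           n01=0, N01=1, n00=1, N00=49)
        assert conviction(counts) == float("inf")

    def test_additive_boundary_and_sign(self):
        # p11=0.4, p10=0.2, p01=0.15, p00=0.05 -> AI = 0.10
        counts = DDICounts(n_AB1=0, n_A1=0, n_AB_plus=0, n_B_plus=0, n_plusplus=1,
                           n11=40, N11=100, n10=20, N10=100,
                           n01=15, N01=100, n00=5, N00=100)
        assert additive_interaction(counts) == pytest.approx(0.10)
        # exactly additive risks -> AI = 0
        add = DDICounts(n_AB1=0, n_A1=0, n_AB_plus=0, n_B_plus=0, n_plusplus=1,
                        n11=30, N11=100, n10=20, N10=100,
                        n01=15, N01=100, n00=5, N00=100)
        assert additive_interaction(add) == pytest.approx(0.0)

    def test_multiplicative_boundary(self):
        # p11=0.4, p10=0.2, p01=0.1, p00=0.05 -> MI = 8/(4*2) = 1
        counts = DDICounts(n_AB1=0, n_A1=0, n_AB_plus=0, n_B_plus=0, n_plusplus=1,
                           n11=40, N11=100, n10=20, N10=100,
                           n01=10, N01=100, n00=5, N00=100)
        assert multiplicative_interaction(counts) == pytest.approx(1.0)

    def test_crr_null_and_boundary(self):
        # B has no effect, no interaction: CRR ~ 1 (low exposure prevalence so
        # the combination PRR's comparator is not diluted by single-exposed reports)
        null_triples = []
        rng = np.random.default_rng(0)
        for _ in range(8000):
            a = rng.random() < 0.05
            b = rng.random() < 0.05
            ae = rng.random() < (0.3 if a else 0.1)  # A triples the risk, B nothing
            null_triples.append((a, b, ae))
        bnd = bundle_from_triples(null_triples)
        flags = flag_cases(bnd, CaseDefinition("esketamine"))
        got = crr(ddi_counts(bnd, flags, "drugb", "Vertigo", universe="all_reports"))
        assert got == pytest.approx(1.0, abs=0.5)

    def test_random_universes_match_enumeration_oracle(self):
        """All five scores agree with brute-force enumeration on random
        universes of <= 50 reports."""
        rng = np.random.default_rng(8)
        for trial in range(20):
            n = int(rng.integers(12, 50))
            triples = [(bool(rng.random() < 0.5), bool(rng.random() < 0.4),
                        bool(rng.random() < 0.4)) for _ in range(n)]
            b = bundle_from_triples(triples)
            flags = flag_cases(b, CaseDefinition("esketamine"))
            for universe in ("all_reports", "case_reports"):
                got = ddi_counts(b, flags, "drugb", "Vertigo", universe=universe)
                exp = enumerate_counts(triples, universe)
                assert got == exp
                for fn in (lift, conviction, additive_interaction,
                           multiplicative_interaction, crr):
                    g, e = fn(got), fn(exp)
                    if g != g:
                        assert e != e
                    else:
                        assert g == pytest.approx(e)


class TestEligibility:
    def _bundle(self):
        reports = []
        pid = 0
        # 6 cases with Vertigo + drugb(SS); 2 cases with Vertigo + drugc(C);
        # 2 cases with Vertigo + drugd(SS) (below min_co_cases=3)
        for ing, role, k in (("drugb", "SS", 6), ("drugc", "C", 2), ("drugd", "SS", 2)):
            for _ in range(k):
                pid += 1
                reports.append({
                    "primaryid": pid,
                    "drugs": [
                        {"seq": 1, "ingredient": "esketamine", "role": "PS",
                         "indication": "Depression"},
                        {"seq": 2, "ingredient": ing, "role": role},
                    ],
                    "pts": ["Vertigo", "Suicidal ideation"],
                })
        # cases without the AEs, so the case cells are not degenerate
        for _ in range(5):
            pid += 1
            reports.append({
                "primaryid": pid,
                "drugs": [{"ingredient": "esketamine", "role": "PS",
                           "indication": "Depression"}],
                "pts": ["Nausea"],
            })
        # background non-cases: a few carry the AEs so RORs are estimable
        for k in range(300):
            pid += 1
            pts = ["Rash"]
            if k < 3:
                pts = ["Vertigo"]
            elif k < 6:
                pts = ["Suicidal ideation"]
            reports.append({"primaryid": pid,
                            "drugs": [{"ingredient": "other"}], "pts": pts})
        return make_bundle(reports)

    def test_exclusion_role_and_floor_rules(self):
        b = self._bundle()
        flags = flag_cases(b, CaseDefinition("esketamine"))
        signals = screen_signals(build_all_contingencies(b, flags))
        assert any(s.pt == "Vertigo" and s.is_signal() for s in signals)
        assert any(s.pt == "Suicidal ideation" and s.is_signal() for s in signals)
        triples = select_eligible_triples(b, flags, signals, "esketamine")
        # indication-overlap AE excluded; concomitant-only and <3 co-cases excluded
        assert ("Suicidal ideation", "drugb") not in triples
        assert all(ae != "Suicidal ideation" for ae, _ in triples)
        assert ("Vertigo", "drugb") in triples
        assert ("Vertigo", "drugc") not in triples
        assert ("Vertigo", "drugd") not in triples

    def test_low_lift_fails_arm_verdict_regardless_of_others(self):
        counts = DDICounts(n_AB1=1, n_A1=50, n_AB_plus=10, n_B_plus=10,
                           n_plusplus=100, n11=1, N11=10, n10=50, N10=60,
                           n01=1, N01=10, n00=1, N00=20)
        from pvsignals.ddi import DDIResult
        r = DDIResult("b", "ae", counts, lift=0.9, conviction=5.0, ai=0.5,
                      mi=10.0, crr=10.0)
        assert not r.verdict_arm
        assert not r.verdict_all

    def test_nan_score_blocks_verdict_but_triple_reported(self):
        b = self._bundle()
        flags = flag_cases(b, CaseDefinition("esketamine"))
        res = screen_ddi(b, flags, [("Vertigo", "drugb"), ("Vertigo", "phantom")],
                         universe="case_reports")
        assert len(res) == 2
        phantom = next(r for r in res if r.drug_b == "phantom")
        assert phantom.lift != phantom.lift  # NaN
        assert not phantom.verdict_all
        frame = ddi_to_frame(res)
        assert len(frame) == 2


class TestPlantedInteractionRecovery:
    def test_multiplicative_strength_five_recovered(self):
        """A planted multiplicative interaction of strength 5 (n=5,000
        reports/replicate) yields MI inside [3, 8] and a full-criteria
        verdict in >= 80% of replicates."""
        catalog = (
            DrugSpec("esketamine", 0.30, (("PS", 0.95), ("SS", 0.05), ("I", 0.0), ("C", 0.0))),
            DrugSpec("drugb", 0.30, (("PS", 0.0), ("SS", 0.9), ("I", 0.1), ("C", 0.0))),
            DrugSpec("filler", 0.50, (("PS", 0.5), ("SS", 0.2), ("I", 0.1), ("C", 0.2))),
        )
        pts = (("Vertigo", 0.05), ("Headache", 0.10), ("Nausea", 0.08),
               ("Drug ineffective", 0.10))
        hits_mi, hits_all = 0, 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = SimConfig(
                n_reports=5000, seed=1000 + rep, pt_catalog=pts,
                drug_catalog=catalog,
                planted_interactions=(
                    ("esketamine", "drugb", "Vertigo", "multiplicative", 5.0),),
                caseid_dup_rate=0.0, fieldmatch_dup_rate=0.0, deleted_rate=0.0,
                target_excluded_indication_rate=0.0,
            )
            bundle, _ = generate(cfg)
            flags = flag_cases(bundle, CaseDefinition("esketamine"))
            counts = ddi_counts(bundle, flags, "drugb", "Vertigo",
                                universe="case_reports")
            mi = multiplicative_interaction(counts)
            hits_mi += (mi == mi) and 3.0 <= mi <= 8.0
            from pvsignals.ddi import DDIResult
            r = DDIResult("drugb", "Vertigo", counts, lift=lift(counts),
                          conviction=conviction(counts),
                          ai=additive_interaction(counts), mi=mi,
                          crr=crr(counts))
            hits_all += r.verdict_all
        assert hits_mi / n_rep >= 0.80
        assert hits_all / n_rep >= 0.80
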