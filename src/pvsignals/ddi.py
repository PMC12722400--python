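"""Drug-drug-interaction signal scoring for (target drug A, concomitant
drug B, adverse event) triples.

Five complementary scores are computed per triple:

* **lift** and **conviction** from association-rule mining, for the rule
  "drug B present → drug A with the AE".  Confidence is the probability
  of (A ∩ AE) among B-exposed reports; support is the marginal
  probability of (A ∩ AE) in the chosen report universe.  Lift is
  confidence/support, conviction is (1−support)/(1−confidence).
* **AI**, the additive-interaction score: the excess risk of the AE with
  the drug combination beyond the sum of the single-drug excess risks,
  AI = p11 − p10 − p01 + p00 on the risk scale.
* **MI**, the multiplicative-interaction score: the combination risk
  ratio over the product of single-drug risk ratios,
  MI = (p11·p00)/(p10·p01).
* **CRR**, the combination risk ratio: PRR of the (A and B) combination
  divided by the larger of the single-drug PRRs.

Decision rules: lift > 1 and conviction > 1 establish an association
rule (a stricter lift > 2 variant is also reported); AI > 0 and MI > 1
flag interaction on the additive and multiplicative scales; CRR > 2
flags a combination signal.  All thresholds are strict and applied to
unrounded values.

Exposure to drug B means a drug entry with role primary suspect,
secondary suspect or interacting; drugs recorded only as concomitant do
not count.  The risk-scale scores (AI, MI, CRR) always use the four
bundle-wide exposure cells (A&B / A only / B only / neither) because a
case-only universe leaves the B-only and neither cells empty; the
``universe`` option scopes only the association-rule quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bundle import ReportBundle
from .preprocessing import CASE, NON_CASE, ContingencyTable, pt_membership
from .disproportionality import SignalResult, prr

B_ROLES = frozenset({"PS", "SS", "I"})

DEFAULT_AE_EXCLUSIONS = frozenset({
    "anxiety", "depression", "panic attack",
    "completed suicide", "suicidal ideation", "suicide attempt",
})


@dataclass(frozen=True)
class DDICounts:
    """Count vector for one (drug B, AE) triple against the target drug A."""

    # association-rule counts, within the chosen universe
    n_AB1: int      # reports with A and B and the AE
    n_A1: int       # reports with A, without B, with the AE
    n_AB_plus: int  # reports with A and B, any AE
    n_B_plus: int   # reports with B, without A, any AE
    n_plusplus: int  # total reports in the universe
    # bundle-wide exposure cells (AE count / total) for the risk-scale scores
    n11: int
    N11: int
    n10: int
    N10: int
    n01: int
    N01: int
    n00: int
    N00: int

    def __post_init__(self) -> None:
        if self.n_AB1 > self.n_AB_plus:
            raise ValueError("n_AB1 cannot exceed n_AB_plus")
        for ae, total in ((self.n11, self.N11), (self.n10, self.N10),
                          (self.n01, self.N01), (self.n00, self.N00)):
            if ae > total:
                raise ValueError("AE count exceeds exposure total")

    def risk(self, cell: str) -> float:
        ae, total = {"11": (self.n11, self.N11), "10": (self.n10, self.N10),
                     "01": (self.n01, self.N01), "00": (self.n00, self.N00)}[cell]
        return ae / total if total else float("nan")


@dataclass(frozen=True)
class DDIResult:
    drug_b: str
    ae: str
    counts: DDICounts
    lift: float
    conviction: float
    ai: float
    mi: float
    crr: float
    lift_threshold: float = 1.0

    @property
    def verdict_arm(self) -> bool:
        return _gt(self.lift, self.lift_threshold) and _gt(self.conviction, 1.0)

    @property
    def verdict_arm_strict(self) -> bool:
        return _gt(self.lift, 2.0) and _gt(self.conviction, 1.0)

    @property
    def verdict_ai(self) -> bool:
        return _gt(self.ai, 0.0)

    @property
    def verdict_mi(self) -> bool:
        return _gt(self.mi, 1.0)

    @property
    def verdict_crr(self) -> bool:
        return _gt(self.crr, 2.0)

    @property
    def verdict_all(self) -> bool:
        return (self.verdict_arm and self.verdict_ai
                and self.verdict_mi and self.verdict_crr)


def _gt(value: float, threshold: float) -> bool:
    # NaN (non-estimable) never passes; +inf conviction does
    return value == value and value > threshold


def _confidence_support(counts: DDICounts) -> tuple[float, float]:
    denom_conf = counts.n_AB_plus + counts.n_B_plus
    if denom_conf == 0 or counts.n_plusplus == 0:
        return float("nan"), float("nan")
    confidence = counts.n_AB1 / denom_conf
    support = (counts.n_AB1 + counts.n_A1) / counts.n_plusplus
    return confidence, support


def lift(counts: DDICounts) -> float:
    """Confidence over support; NaN when a denominator is empty."""
    confidence, support = _confidence_support(counts)
    if not support or support != support:
        return float("nan")
    return confidence / support


def conviction(counts: DDICounts) -> float:
    """(1 − support) / (1 − confidence); +inf when the rule never fails."""
    confidence, support = _confidence_support(counts)
    if confidence != confidence:
        return float("nan")
    if confidence >= 1.0:
        return float("inf")
    return (1.0 - support) / (1.0 - confidence)


def additive_interaction(counts: DDICounts) -> float:
    """Risk-difference departure from additivity: p11 − p10 − p01 + p00."""
    risks = [counts.risk(c) for c in ("11", "10", "01", "00")]
    if any(r != r for r in risks):
        return float("nan")
    p11, p10, p01, p00 = risks
    return p11 - p10 - p01 + p00


def multiplicative_interaction(counts: DDICounts) -> float:
    """Risk-ratio departure from multiplicativity: (p11·p00)/(p10·p01)."""
    risks = [counts.risk(c) for c in ("11", "10", "01", "00")]
    if any(r != r for r in risks):
        return float("nan")
    p11, p10, p01, p00 = risks
    if p10 == 0 or p01 == 0:
        return float("nan")
    return (p11 * p00) / (p10 * p01)


def crr(counts: DDICounts) -> float:
    """Combination risk ratio: PRR(A∩B) / max(PRR(A), PRR(B)).

    Each PRR treats its exposure set as exposed and every other report in
    the bundle as the comparator.
    """
    total_ae = counts.n11 + counts.n10 + counts.n01 + counts.n00
    total_n = counts.N11 + counts.N10 + counts.N01 + counts.N00

    def prr_for(ae: int, n: int) -> float:
        rest_ae, rest_n = total_ae - ae, total_n - n
        t = ContingencyTable(a=ae, b=n - ae, c=rest_ae, d=rest_n - rest_ae)
        r = prr(t)
        return r.ror if r.estimable else float("nan")

    prr_ab = prr_for(counts.n11, counts.N11)
    prr_a = prr_for(counts.n11 + counts.n10, counts.N11 + counts.N10)
    prr_b = prr_for(counts.n11 + counts.n01, counts.N11 + counts.N01)
    if any(v != v for v in (prr_ab, prr_a, prr_b)):
        return float("nan")
    denom = max(prr_a, prr_b)
    if denom == 0:
        return float("nan")
    return prr_ab / denom


def _exposure_sets(bundle: ReportBundle, flags: pd.Series, drug_b: str):
    ing = bundle.drug["ingredient"].astype(str).str.strip().str.casefold()
    b_rows = (ing == drug_b.strip().casefold()) & bundle.drug["role_code"].isin(B_ROLES)
    b_pids = set(bundle.drug.loc[b_rows, "primaryid"])
    a_pids = set(flags.index[flags == CASE])
    universe_pids = set(flags.index[flags.isin([CASE, NON_CASE])])
    return a_pids, b_pids & universe_pids, universe_pids


def ddi_counts(
    bundle: ReportBundle,
    flags: pd.Series,
    drug_b: str,
    ae: str,
    universe: str = "case_reports",
) -> DDICounts:
    """Assemble the full count vector for one (drug B, AE) triple."""
    if universe not in ("case_reports", "all_reports"):
        raise ValueError(f"unknown universe {universe!r}")
    a_pids, b_pids, all_pids = _exposure_sets(bundle, flags, drug_b)
    mem = pt_membership(bundle, flags)
    ae_pids = set(mem.loc[mem["pt_key"] == ae.strip().casefold(), "primaryid"])

    uni = a_pids if universe == "case_reports" else all_pids
    ab = a_pids & b_pids
    n_AB1 = len(ab & ae_pids & uni)
    n_A1 = len((a_pids - b_pids) & ae_pids & uni)
    n_AB_plus = len(ab & uni)
    n_B_plus = len((b_pids - a_pids) & uni)

    def cell(pids: set) -> tuple[int, int]:
        return len(pids & ae_pids), len(pids)

    n11, N11 = cell(ab)
    n10, N10 = cell(a_pids - b_pids)
    n01, N01 = cell(b_pids - a_pids)
    n00, N00 = cell(all_pids - a_pids - b_pids)
    return DDICounts(
        n_AB1=n_AB1, n_A1=n_A1, n_AB_plus=n_AB_plus, n_B_plus=n_B_plus,
        n_plusplus=len(uni),
        n11=n11, N11=N11, n10=n10, N10=N10, n01=n01, N01=N01, n00=n00, N00=N00,
    )


def select_eligible_triples(
    bundle: ReportBundle,
    flags: pd.Series,
    signals: list[SignalResult],
    target_ingredient: str,
    exclusions: frozenset[str] = DEFAULT_AE_EXCLUSIONS,
    min_co_cases: int = 3,
    min_reports: int = 5,
) -> list[tuple[str, str]]:
    """(AE, drug B) pairs eligible for interaction scoring.

    The AE must be a screened signal outside the indication-overlap
    exclusion set; drug B must appear with a suspect/interacting role in
    at least ``min_co_cases`` case reports carrying that AE.
    """
    excl = {e.strip().casefold() for e in exclusions}
    signal_aes = [s.pt for s in signals
                  if s.is_signal(min_reports) and s.pt.strip().casefold() not in excl]
    target = target_ingredient.strip().casefold()

    drug = bundle.drug
    ing = drug["ingredient"].astype(str).str.strip().str.casefold()
    suspect = drug[drug["role_code"].isin(B_ROLES) & (ing != target)].copy()
    suspect["ingredient_key"] = (
        suspect["ingredient"].astype(str).str.strip().str.casefold()
    )
    case_pids = set(flags.index[flags == CASE])
    suspect = suspect[suspect["primaryid"].isin(case_pids)]
    mem = pt_membership(bundle, flags)

    triples: list[tuple[str, str]] = []
    for ae in signal_aes:
        ae_case_pids = set(
            mem.loc[(mem["pt_key"] == ae.strip().casefold()) & (mem["flag"] == CASE),
                    "primaryid"]
        )
        hits = suspect[suspect["primaryid"].isin(ae_case_pids)]
        co = hits.groupby("ingredient_key")["primaryid"].nunique()
        spelling = hits.groupby("ingredient_key")["ingredient"].first()
        for key, n in co.items():
            if n >= min_co_cases:
                triples.append((ae, str(spelling[key])))
    return sorted(triples)


def screen_ddi(
    bundle: ReportBundle,
    flags: pd.Series,
    triples: list[tuple[str, str]],
    universe: str = "case_reports",
    lift_threshold: float = 1.0,
) -> list[DDIResult]:
    """Score every eligible triple; every triple is reported with its verdicts."""
    out = []
    for ae, drug_b in triples:
        counts = ddi_counts(bundle, flags, drug_b, ae, universe=universe)
        out.append(DDIResult(
            drug_b=drug_b, ae=ae, counts=counts,
            lift=lift(counts), conviction=conviction(counts),
            ai=additive_interaction(counts),
            mi=multiplicative_interaction(counts),
            crr=crr(counts), lift_threshold=lift_threshold,
        ))
    return out


def ddi_to_frame(results: list[DDIResult]) -> pd.DataFrame:
    """Result table in the published layout: counts, the five scores, verdicts."""
    return pd.DataFrame({
        "ae": [r.ae for r in results],
        "drug_b": [r.drug_b for r in results],
        "n_ae_target": [r.counts.n11 + r.counts.n10 for r in results],
        "n_ae_drug_b": [r.counts.n11 + r.counts.n01 for r in results],
        "n_ae_both": [r.counts.n11 for r in results],
        "lift": [r.lift for r in results],
        "conviction": [r.conviction for r in results],
        "ai": [r.ai for r in results],
        "mi": [r.mi for r in results],
        "crr": [r.crr for r in results],
        "verdict_arm": [r.verdict_arm for r in results],
        "verdict_arm_strict": [r.verdict_arm_strict for r in results],
        "verdict_ai": [r.verdict_ai for r in results],
        "verdict_mi": [r.verdict_mi for r in results],
        "verdict_crr": [r.verdict_crr for r in results],
        "verdict_all": [r.verdict_all for r in results],
    })
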