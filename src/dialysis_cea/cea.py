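"""Cost-effectiveness and cost-utility summary measures.

QALYs from life years and utilities, cost per LY / per QALY, HD:CAPD cost
ratios, net monetary benefit, and the incremental cost-effectiveness ratio
(ICER) ladder with strict and extended dominance.

Reporting convention (matching the published tables, so that comparisons
against printed values are well defined): life years to 2 decimals, QALYs
to 3 decimals, RM amounts to whole ringgit, ratios to 2 decimals — rounding
half away from zero, except the QALY product which is formed in exact
decimal arithmetic with ties to even (see :func:`report_qaly`).
Intermediate arithmetic is carried at full precision unless a function is
explicitly asked to report rounded values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

__all__ = [
    "ModalitySummary",
    "StrategyOutcome",
    "RankedStrategy",
    "CEAResult",
    "qaly_from_ly",
    "cost_per_outcome",
    "cost_per_outcome_from_totals",
    "modality_summary",
    "cost_ratio",
    "net_monetary_benefit",
    "classify_threshold",
    "icer_ladder",
    "round_half_up",
    "report_qaly",
]

DEFAULT_THRESHOLDS: Mapping[str, float] = {
    "very_cost_effective": 40_000.0,
    "cost_effective": 120_000.0,
}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero on the double-precision value of ``x``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def report_qaly(life_years: float, utility: float, ndigits: int = 3) -> float:
    """LY x utility rounded for reporting, in exact decimal arithmetic.

    The product is formed from the decimal representations of the inputs
    (so printed inputs like 3.70 x 0.905 give exactly 3.3485, free of
    binary-float noise) and exact halves round to even, reproducing the
    published table values.
    """
    if not (0.0 <= utility <= 1.0):
        raise ValueError(f"utility must lie in [0, 1], got {utility}")
    product = Decimal(str(life_years)) * Decimal(str(utility))
    q = Decimal(1).scaleb(-ndigits)
    return float(product.quantize(q, rounding=ROUND_HALF_EVEN))


def qaly_from_ly(life_years: float, utility: float) -> float:
    """Quality-adjusted life years: LY weighted by the utility index."""
    if not (0.0 <= utility <= 1.0):
        raise ValueError(f"utility must lie in [0, 1], got {utility}")
    if life_years < 0:
        raise ValueError("life_years must be >= 0")
    return life_years * utility


def cost_per_outcome(
    annual_cost: float,
    life_years: float,
    qaly: float,
    *,
    rounded: bool = True,
) -> tuple[float, float]:
    """(cost per LY, cost per QALY).

    Cost per life year is reported as the mean annual treatment cost — the
    cost of sustaining one year of life on dialysis — and cost per QALY as
    ``annual_cost * LY / QALY``.  For the alternative ratio-of-totals
    definition applied to cohort-model output see
    :func:`cost_per_outcome_from_totals`.
    """
    if life_years <= 0 or qaly <= 0:
        raise ValueError("life_years and qaly must be > 0")
    per_ly = annual_cost
    per_qaly = annual_cost * life_years / qaly
    if rounded:
        return round_half_up(per_ly), round_half_up(per_qaly)
    return per_ly, per_qaly


def cost_per_outcome_from_totals(
    total_cost: float, total_ly: float, total_qaly: float, *, rounded: bool = True
) -> tuple[float, float]:
    """(cost per LY, cost per QALY) as ratios of accumulated cohort totals."""
    if total_ly <= 0 or total_qaly <= 0:
        raise ValueError("totals must be > 0")
    per_ly = total_cost / total_ly
    per_qaly = total_cost / total_qaly
    if rounded:
        return round_half_up(per_ly), round_half_up(per_qaly)
    return per_ly, per_qaly


@dataclass(frozen=True)
class ModalitySummary:
    """Table-style cost-effectiveness summary of one modality."""

    modality: str
    life_years: float
    qaly: float
    annual_cost: float
    cost_per_ly: float
    cost_per_qaly: float

    def __post_init__(self) -> None:
        if self.qaly > self.life_years + 1e-9:
            raise ValueError("QALY cannot exceed life years (utility <= 1)")
        if self.annual_cost <= 0:
            raise ValueError("annual cost must be positive")


def modality_summary(
    modality: str, life_years: float, utility: float, annual_cost: float
) -> ModalitySummary:
    """Build a reporting-rounded summary from raw inputs.

    Rounding is applied in the published order: LY to 2 dp, QALY to 3 dp,
    annual cost to whole RM, and cost/QALY computed *from the rounded
    figures* and then rounded to whole RM.
    """
    ly = round_half_up(life_years, 2)
    qaly = report_qaly(ly, utility)
    cost = round_half_up(annual_cost)
    per_ly, per_qaly = cost_per_outcome(cost, ly, qaly)
    return ModalitySummary(
        modality=modality,
        life_years=ly,
        qaly=qaly,
        annual_cost=cost,
        cost_per_ly=per_ly,
        cost_per_qaly=per_qaly,
    )


def cost_ratio(
    a: ModalitySummary, b: ModalitySummary, *, rounded: bool = True
) -> tuple[float, float]:
    """Cost ratio of a to b, per LY and per QALY (2 dp when rounded)."""
    if b.cost_per_ly <= 0 or b.cost_per_qaly <= 0:
        raise ValueError("denominator costs must be positive")
    per_ly = a.cost_per_ly / b.cost_per_ly
    per_qaly = a.cost_per_qaly / b.cost_per_qaly
    if rounded:
        return round_half_up(per_ly, 2), round_half_up(per_qaly, 2)
    return per_ly, per_qaly


def net_monetary_benefit(
    incr_qaly: float, incr_cost: float, threshold: float
) -> float:
    """NMB = incremental benefit x threshold - incremental cost (RM)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return incr_qaly * threshold - incr_cost


def classify_threshold(
    cost_per_unit: float, thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS
) -> str:
    """Classify a cost-effectiveness ratio against WTP thresholds.

    Below ~1x GDP per capita: very cost-effective; below ~3x: cost-effective;
    otherwise not cost-effective.  Negative ratios arise from dominance and
    should be flagged upstream rather than classified here.
    """
    if cost_per_unit < thresholds["very_cost_effective"]:
        return "very_cost_effective"
    if cost_per_unit < thresholds["cost_effective"]:
        return "cost_effective"
    return "not_cost_effective"


# ---------------------------------------------------------------------------
# ICER ladder


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-strategy totals entering the incremental analysis."""

    label: str
    cost: float
    qaly: float
    ly: float | None = None


@dataclass(frozen=True)
class RankedStrategy:
    """One strategy's position on the effectiveness-sorted ladder."""

    label: str
    cost: float
    qaly: float
    ly: float | None
    status: str  # nondominated | strictly_dominated | extendedly_dominated | equivalent
    icer_per_qaly: float | None = None
    icer_per_ly: float | None = None
    comparator: str | None = None
    threshold_class: str | None = None


@dataclass(frozen=True)
class CEAResult:
    """Full incremental comparison over a set of strategies."""

    strategies: tuple[RankedStrategy, ...]
    thresholds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    @property
    def frontier(self) -> tuple[RankedStrategy, ...]:
        return tuple(s for s in self.strategies if s.status == "nondominated")

    def status_of(self, label: str) -> str:
        for s in self.strategies:
            if s.label == label:
                return s.status
        raise KeyError(label)


def icer_ladder(
    strategies: Sequence[StrategyOutcome],
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    *,
    extended: bool = True,
) -> CEAResult:
    """Incremental cost-effectiveness ladder with dominance handling.

    Strategies are sorted by effectiveness (QALY) ascending; a strategy is
    strictly dominated if another has lower-or-equal cost and
    greater-or-equal effectiveness (one strict); extended dominance removes
    strategies whose ICER exceeds that of a more effective alternative
    (i.e. the frontier ICERs must be increasing).  ICERs are computed
    between successive surviving strategies and classified against the WTP
    thresholds.  Cost/effect ties are flagged ``equivalent`` and excluded
    from the frontier.  The result is invariant to the input order.
    """
    if len(strategies) < 2:
        raise ValueError("icer_ladder needs at least two strategies")

    order = sorted(strategies, key=lambda s: (s.qaly, s.cost, s.label))
    status: dict[str, str] = {}

    # equivalence: identical cost and effect (keep the lexicographically
    # first representative on the ladder)
    seen: dict[tuple[float, float], str] = {}
    for s in order:
        key = (round(s.cost, 9), round(s.qaly, 9))
        if key in seen:
            status[s.label] = "equivalent"
        else:
            seen[key] = s.label

    def dominated(s: StrategyOutcome) -> bool:
        return any(
            t.label != s.label
            and status.get(t.label) is None
            and t.cost <= s.cost
            and t.qaly >= s.qaly
            and (t.cost < s.cost or t.qaly > s.qaly)
            for t in order
        )

    for s in order:
        if status.get(s.label) is None and dominated(s):
            status[s.label] = "strictly_dominated"

    survivors = [s for s in order if status.get(s.label) is None]
    if extended:
        changed = True
        while changed and len(survivors) > 2:
            changed = False
            icers = [
                (survivors[i + 1].cost - survivors[i].cost)
                / (survivors[i + 1].qaly - survivors[i].qaly)
                for i in range(len(survivors) - 1)
            ]
            for i in range(len(icers) - 1):
                if icers[i] > icers[i + 1]:
                    status[survivors[i + 1].label] = "extendedly_dominated"
                    survivors.pop(i + 1)
                    changed = True
                    break

    ranked: list[RankedStrategy] = []
    frontier_labels = [s.label for s in survivors]
    for s in order:
        st = status.get(s.label, "nondominated")
        icer_q = icer_l = None
        comparator = None
        tclass = None
        if st == "nondominated":
            idx = frontier_labels.index(s.label)
            if idx > 0:
                prev = survivors[idx - 1]
                d_qaly = s.qaly - prev.qaly
                d_cost = s.cost - prev.cost
                icer_q = d_cost / d_qaly
                if s.ly is not None and prev.ly is not None and s.ly != prev.ly:
                    icer_l = d_cost / (s.ly - prev.ly)
                comparator = prev.label
                tclass = classify_threshold(icer_q, thresholds)
        ranked.append(
            RankedStrategy(
                label=s.label,
                cost=s.cost,
                qaly=s.qaly,
                ly=s.ly,
                status=st,
                icer_per_qaly=icer_q,
                icer_per_ly=icer_l,
                comparator=comparator,
                threshold_class=tclass,
            )
        )
    return CEAResult(strategies=tuple(ranked), thresholds=dict(thresholds))
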