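"""Incremental cost-effectiveness metrics.

ICER with dominance handling, net monetary benefit (NMB), willingness-to-pay
decisions, the efficient frontier for more than two strategies, and RMB/USD
presentation-layer conversion.

All modelling is carried out in RMB at full double precision; USD figures
and 2-decimal rounding (half away from zero) appear only at reporting
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .tree import StrategyOutcome

__all__ = [
    "WtpThreshold",
    "ExchangeRate",
    "IncrementalResult",
    "FrontierEntry",
    "DOMINANT",
    "DOMINATED",
    "EQUAL_EFFECT",
    "icer",
    "nmb",
    "incremental",
    "rmb_to_usd",
    "usd_to_rmb",
    "round_half_away",
    "dominance_frontier",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUAL_EFFECT = "equal-effect"


@dataclass(frozen=True)
class WtpThreshold:
    """Willingness-to-pay per QALY, RMB."""

    lambda_rmb_per_qaly: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.lambda_rmb_per_qaly <= 0:
            raise ValueError("WTP threshold must be positive")


@dataclass(frozen=True)
class ExchangeRate:
    rmb_per_100_usd: float

    def __post_init__(self) -> None:
        if self.rmb_per_100_usd <= 0:
            raise ValueError("exchange rate must be positive")


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round to `decimals` places, ties away from zero (reporting rule)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rmb_to_usd(amount_rmb: float, rate: ExchangeRate) -> float:
    """Convert RMB to USD at `rate`, rounded to cents half-away-from-zero."""
    return round_half_away(amount_rmb * 100.0 / rate.rmb_per_100_usd, 2)


def usd_to_rmb(amount_usd: float, rate: ExchangeRate) -> float:
    return round_half_away(amount_usd * rate.rmb_per_100_usd / 100.0, 2)


def nmb(cost: float, effect: float, wtp: WtpThreshold) -> float:
    """Net monetary benefit: lambda * effect - cost (RMB)."""
    return wtp.lambda_rmb_per_qaly * effect - cost


def icer(delta_cost: float, delta_effect: float) -> tuple[float | None, str]:
    """ICER = dC/dE with dominance handling.

    Returns ``(value, status)``: status ``"icer"`` with the numeric ratio
    when signs agree (or dC == 0), ``"dominant"`` when the intervention is
    cheaper and more effective (negative ratio suppressed by convention),
    ``"dominated"`` when costlier and less effective, ``"equal-effect"``
    when dE == 0 (no division).
    """
    if delta_effect == 0.0:
        return None, EQUAL_EFFECT
    if delta_effect > 0 and delta_cost < 0:
        return None, DOMINANT
    if delta_effect < 0 and delta_cost > 0:
        return None, DOMINATED
    return delta_cost / delta_effect, "icer"


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison of intervention vs comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    status: str  # "icer" | dominant | dominated | equal-effect
    wtp: float
    incremental_nmb: float
    cost_effective: bool


def incremental(
    intervention: StrategyOutcome,
    comparator: StrategyOutcome,
    wtp: WtpThreshold,
) -> IncrementalResult:
    """dC, dE, ICER-or-status and the incremental NMB decision at `wtp`.

    The intervention is deemed cost-effective at lambda iff its incremental
    NMB (lambda * dE - dC) is strictly positive; for dE > 0 this is the
    familiar ICER < lambda rule.
    """
    dc = intervention.expected_cost - comparator.expected_cost
    de = intervention.expected_effect - comparator.expected_effect
    value, status = icer(dc, de)
    inc_nmb = wtp.lambda_rmb_per_qaly * de - dc
    return IncrementalResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_effect=de,
        icer=value,
        status=status,
        wtp=wtp.lambda_rmb_per_qaly,
        incremental_nmb=inc_nmb,
        cost_effective=inc_nmb > 0,
    )


@dataclass(frozen=True)
class FrontierEntry:
    outcome: StrategyOutcome
    icer_vs_previous: float | None  # None for the least-effective frontier member


def dominance_frontier(outcomes: list[StrategyOutcome]) -> list[FrontierEntry]:
    """Efficient frontier with pairwise ICERs.

    Strategies are sorted by effect; strictly dominated options (another
    strategy no costlier and no less effective, one strictly) are removed,
    then extendedly dominated options (non-monotone ICER sequence) are
    removed iteratively.  Output is invariant to input order.
    """
    if not outcomes:
        raise ValueError("dominance_frontier requires at least one strategy")
    ordered = sorted(
        outcomes, key=lambda o: (o.expected_effect, o.expected_cost, o.strategy)
    )
    undominated = [
        o
        for o in ordered
        if not any(
            (p.expected_cost <= o.expected_cost and p.expected_effect >= o.expected_effect)
            and (p.expected_cost < o.expected_cost or p.expected_effect > o.expected_effect)
            for p in ordered
            if p is not o
        )
    ]
    # extended dominance: drop members until the ICER sequence is increasing
    frontier = list(undominated)
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            prev_, mid, nxt = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_in = _seq_icer(prev_, mid)
            icer_out = _seq_icer(mid, nxt)
            if icer_in is not None and icer_out is not None and icer_out < icer_in:
                del frontier[i]
                changed = True
                break
    entries: list[FrontierEntry] = []
    for i, o in enumerate(frontier):
        entries.append(
            FrontierEntry(o, None if i == 0 else _seq_icer(frontier[i - 1], o))
        )
    return entries


def _seq_icer(lo: StrategyOutcome, hi: StrategyOutcome) -> float | None:
    de = hi.expected_effect - lo.expected_effect
    if de == 0:
        return None
    return (hi.expected_cost - lo.expected_cost) / de
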