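"""Deterministic one-way sensitivity analysis.

Vary one parameter across its declared range (all others held at base),
re-evaluate the tree at every grid value, and report outcomes, the
incremental comparison and NMB.  Companion outputs: a tornado table ranking
parameters by the span they induce in a chosen outcome, and a
willingness-to-pay sweep of the base-case decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import WtpThreshold, icer, incremental, nmb
from .params import ParameterSet
from .tree import DecisionTree, StrategyOutcome, rollback

__all__ = ["OwsaResult", "one_way", "wtp_sweep", "tornado"]


@dataclass(frozen=True)
class OwsaResult:
    parameter: str
    grid: np.ndarray
    table: pd.DataFrame  # one row per grid value


def _grid_with_base(lo: float, hi: float, base: float, points: int) -> np.ndarray:
    grid = np.linspace(lo, hi, points)
    if not np.any(grid == base):
        grid = np.sort(np.append(grid, base))
    return grid


def one_way(
    tree: DecisionTree,
    params: ParameterSet,
    target: str,
    points: int = 11,
    wtp: WtpThreshold | None = None,
) -> OwsaResult:
    """Scan one parameter over its OWSA range.

    The grid is evenly spaced over the range, endpoints included, with the
    base value inserted if the even spacing misses it — so the base-case
    row reproduces base-case rollback exactly.
    """
    if target not in params:
        raise KeyError(f"unknown parameter {target!r}")
    spec = params[target]
    if spec.owsa_range is None:
        raise ValueError(f"parameter {target!r} has no owsa_range")
    lo, hi = spec.owsa_range
    grid = _grid_with_base(lo, hi, spec.base, points)
    base_values = params.base_values()
    strategies = [s.name for s in tree.strategies]
    rows = []
    for v in grid:
        values = dict(base_values)
        values[target] = float(v)
        outcomes = rollback(tree, values)
        row: dict[str, float | str | None] = {"value": float(v)}
        for o in outcomes:
            row[f"cost_{o.strategy}"] = o.expected_cost
            row[f"effect_{o.strategy}"] = o.expected_effect
            if wtp is not None:
                row[f"nmb_{o.strategy}"] = nmb(o.expected_cost, o.expected_effect, wtp)
        if len(outcomes) >= 2:
            dc = outcomes[0].expected_cost - outcomes[1].expected_cost
            de = outcomes[0].expected_effect - outcomes[1].expected_effect
            val, status = icer(dc, de)
            row["delta_cost"] = dc
            row["delta_effect"] = de
            row["icer"] = val
            row["icer_status"] = status
        rows.append(row)
    _ = strategies
    return OwsaResult(parameter=target, grid=grid, table=pd.DataFrame(rows))


def wtp_sweep(
    outcomes: list[StrategyOutcome],
    lambdas: np.ndarray | list[float],
) -> pd.DataFrame:
    """Base-case decision as a function of the willingness-to-pay threshold.

    Per lambda: each strategy's NMB, the NMB-maximizing strategy, and — for
    the first strategy against the second (intervention vs comparator) —
    the incremental decision by the ICER-vs-lambda rule.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    if len(outcomes) < 2:
        raise ValueError("wtp_sweep requires at least two strategies")
    rows = []
    for lam in lambdas:
        wtp = WtpThreshold(float(lam))
        row: dict[str, float | str | bool] = {"lambda": float(lam)}
        nmbs = {
            o.strategy: nmb(o.expected_cost, o.expected_effect, wtp) for o in outcomes
        }
        for s, v in nmbs.items():
            row[f"nmb_{s}"] = v
        row["best_strategy"] = max(nmbs, key=lambda s: (nmbs[s], s))
        inc = incremental(outcomes[0], outcomes[1], wtp)
        row["icer_status"] = inc.status
        row["cost_effective"] = inc.cost_effective
        rows.append(row)
    return pd.DataFrame(rows)


def tornado(
    tree: DecisionTree,
    params: ParameterSet,
    targets: list[str],
    wtp: WtpThreshold,
    outcome: str = "incremental_nmb",
) -> pd.DataFrame:
    """Tornado table: outcome at each parameter's range endpoints.

    ``outcome`` is one of ``incremental_nmb`` (default: first strategy vs
    second at `wtp`), ``cost_<strategy>`` or ``effect_<strategy>``.  Bars
    are sorted by descending span with the parameter name as a stable
    tie-break, so the ranking is invariant to the order of ``targets``.
    """
    base_values = params.base_values()

    def measure(values: dict[str, float]) -> float:
        outcomes = rollback(tree, values)
        if outcome == "incremental_nmb":
            if len(outcomes) < 2:
                raise ValueError("incremental_nmb requires two strategies")
            return incremental(outcomes[0], outcomes[1], wtp).incremental_nmb
        kind, _, strat = outcome.partition("_")
        for o in outcomes:
            if o.strategy == strat:
                return o.expected_cost if kind == "cost" else o.expected_effect
        raise ValueError(f"unknown outcome {outcome!r}")

    rows = []
    for t in targets:
        if t not in params:
            raise KeyError(f"unknown parameter {t!r}")
        spec = params[t]
        if spec.owsa_range is None:
            raise ValueError(f"parameter {t!r} has no owsa_range")
        lo, hi = spec.owsa_range
        vals_lo = dict(base_values)
        vals_lo[t] = lo
        vals_hi = dict(base_values)
        vals_hi[t] = hi
        out_lo = measure(vals_lo)
        out_hi = measure(vals_hi)
        rows.append(
            {
                "parameter": t,
                "low": lo,
                "high": hi,
                "outcome_low": out_lo,
                "outcome_high": out_hi,
                "span": abs(out_hi - out_lo),
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["span", "parameter"], ascending=[False, True])
        .reset_index(drop=True)
    )
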