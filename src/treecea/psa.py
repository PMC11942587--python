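"""Probabilistic sensitivity analysis.

Parameters are drawn from their declared uncertainty distributions, the
decision tree is re-evaluated per draw, and the resulting cloud of
(cost, effect) pairs is summarized as a cost-effectiveness plane, a
cost-effectiveness acceptability curve (CEAC) and empirical prediction
intervals.

Sampling contract: one NumPy Generator per run seeded from the caller;
parameter draws consume the stream in declaration order, so results are
reproducible independent of tree traversal order.  Multinomial branch sets
(Dirichlet blocks) are drawn jointly on the simplex — a block is sampled
once, when its first member is reached in declaration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet
from .tree import DecisionTree, rollback

__all__ = [
    "PsaCloud",
    "CeacCurve",
    "sample_parameters",
    "run_psa",
    "ceac",
    "prediction_interval",
]


@dataclass(frozen=True)
class PsaCloud:
    """Per-iteration (cost, effect) pairs for every strategy.

    costs/effects are (iterations, n_strategies) arrays in strategy order;
    ``samples`` retains the sampled parameter vectors for audit.
    """

    strategies: tuple[str, ...]
    costs: np.ndarray
    effects: np.ndarray
    samples: pd.DataFrame
    seed: int
    iterations: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, s in enumerate(self.strategies):
            rows.append(
                {
                    "strategy": s,
                    "mean_cost": float(self.costs[:, j].mean()),
                    "sd_cost": float(self.costs[:, j].std(ddof=1)),
                    "mean_effect": float(self.effects[:, j].mean()),
                    "sd_effect": float(self.effects[:, j].std(ddof=1)),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CeacCurve:
    """Probability each strategy has the highest NMB, per WTP value."""

    lambdas: np.ndarray
    probabilities: pd.DataFrame  # index: lambda, columns: strategies


def sample_parameters(params: ParameterSet, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` parameter vectors; family 'none' is held at base.

    Invalid hyperparameters raise ValueError (with every violation listed)
    before any sampling.  Dirichlet blocks are drawn jointly with the
    block's residual concentration appended, guaranteeing each draw lies on
    the simplex.
    """
    errs = [
        e
        for s in params
        for e in s.distribution.validate()
    ]
    if errs:
        raise ValueError("invalid distribution hyperparameters: " + "; ".join(errs))
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    groups = params.groups()
    done_groups: set[str] = set()
    for spec in params:
        d = spec.distribution
        if d.family == "none":
            cols[spec.name] = np.full(n, spec.base)
        elif d.family == "beta":
            cols[spec.name] = rng.beta(d.args[0], d.args[1], size=n)
        elif d.family == "gamma":
            cols[spec.name] = rng.gamma(d.args[0], d.args[1], size=n)
        elif d.family == "lognormal":
            cols[spec.name] = rng.lognormal(d.args[0], d.args[1], size=n)
        elif d.family == "uniform":
            cols[spec.name] = rng.uniform(d.args[0], d.args[1], size=n)
        elif d.family == "dirichlet":
            g = d.group
            if g in done_groups:
                continue
            members = groups[g]
            alphas = [params[m].distribution.args[0] for m in members]
            rest = params.dirichlet_rest.get(g, 0.0)
            if rest > 0:
                draw = rng.dirichlet(alphas + [rest], size=n)
            else:
                draw = rng.dirichlet(alphas, size=n)
            for k, m in enumerate(members):
                cols[m] = draw[:, k]
            done_groups.add(g)
        else:  # pragma: no cover - guarded by validate()
            raise ValueError(d.family)
    return pd.DataFrame(cols, columns=params.names)


def run_psa(
    tree: DecisionTree,
    params: ParameterSet,
    n: int,
    seed: int,
) -> PsaCloud:
    """Monte Carlo propagation: rollback on each of ``n`` sampled vectors.

    Each iteration re-runs the same expected-value rollback used for the
    base case, so a run with every distribution degenerate reproduces the
    base case bitwise.
    """
    samples = sample_parameters(params, n, seed)
    strategies = tuple(s.name for s in tree.strategies)
    costs = np.empty((n, len(strategies)))
    effects = np.empty((n, len(strategies)))
    records = samples.to_dict("records")
    for i, values in enumerate(records):
        outcomes = rollback(tree, values)
        for j, o in enumerate(outcomes):
            costs[i, j] = o.expected_cost
            effects[i, j] = o.expected_effect
    return PsaCloud(
        strategies=strategies,
        costs=costs,
        effects=effects,
        samples=samples,
        seed=seed,
        iterations=n,
    )


def ceac(cloud: PsaCloud, lambdas: np.ndarray | list[float]) -> CeacCurve:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay value: the fraction of iterations in which a
    strategy attains the strictly highest NMB; exact ties split equally
    among the tied strategies, so the probabilities sum to 1 at every
    lambda.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    if len(cloud.strategies) < 2:
        raise ValueError("CEAC requires at least two strategies")
    probs = np.empty((lambdas.size, len(cloud.strategies)))
    for i, lam in enumerate(lambdas):
        nmb = lam * cloud.effects - cloud.costs  # (iterations, strategies)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        share = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = share.mean(axis=0)
    return CeacCurve(
        lambdas=lambdas,
        probabilities=pd.DataFrame(probs, index=lambdas, columns=list(cloud.strategies)),
    )


def prediction_interval(
    cloud: PsaCloud,
    quantity: str,
    strategy: str,
    level: float = 0.95,
    wtp: float | None = None,
) -> tuple[float, float]:
    """Empirical central prediction interval for cost, effect or NMB.

    Endpoints are the (1 - level)/2 and (1 + level)/2 empirical quantiles
    with linear interpolation.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    j = cloud.strategies.index(strategy)
    if quantity == "cost":
        x = cloud.costs[:, j]
    elif quantity == "effect":
        x = cloud.effects[:, j]
    elif quantity == "nmb":
        if wtp is None:
            raise ValueError("nmb interval requires a wtp value")
        x = wtp * cloud.effects[:, j] - cloud.costs[:, j]
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    lo, hi = np.quantile(x, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)
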