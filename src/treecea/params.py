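"""Model parameters and their uncertainty distributions.

A cost-effectiveness model is driven by three kinds of named inputs:
probabilities (branch weights at chance nodes), costs (per-category RMB
amounts entering terminal payoffs) and utilities (per-state effectiveness
weights on the model's time horizon).  Each parameter carries a base value
used for deterministic analyses, an optional uncertainty distribution used
by probabilistic sensitivity analysis, and an optional one-way
sensitivity-analysis range.

Probabilities that belong to the same multinomial branch set (e.g. the
complication split at a chance node) are grouped into a Dirichlet block so
that probabilistic sampling draws them jointly on the simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Distribution",
    "ParameterSpec",
    "ParameterSet",
    "KINDS",
    "FAMILIES",
]

KINDS = ("probability", "cost", "utility")
FAMILIES = ("none", "beta", "gamma", "lognormal", "uniform", "dirichlet")


@dataclass(frozen=True)
class Distribution:
    """Uncertainty distribution of a single parameter.

    family
        One of ``none`` (held fixed at base), ``beta(alpha, beta)``,
        ``gamma(shape, scale)``, ``lognormal(mu, sigma)`` (log-scale
        parameters), ``uniform(lo, hi)`` or ``dirichlet(alpha)``.
    args
        Family hyperparameters, in the order above.  For ``dirichlet`` a
        single concentration for this component; the block is assembled at
        the ParameterSet level via ``group``.
    group
        Dirichlet block name; required iff family == "dirichlet".
    """

    family: str = "none"
    args: tuple[float, ...] = ()
    group: str | None = None

    def validate(self) -> list[str]:
        errs: list[str] = []
        if self.family not in FAMILIES:
            return [f"unknown distribution family {self.family!r}"]
        a = self.args
        if self.family == "none":
            if a:
                errs.append("family 'none' takes no hyperparameters")
        elif self.family == "beta":
            if len(a) != 2 or a[0] <= 0 or a[1] <= 0:
                errs.append(f"beta requires alpha > 0 and beta > 0, got {a}")
        elif self.family == "gamma":
            if len(a) != 2 or a[0] <= 0 or a[1] <= 0:
                errs.append(f"gamma requires shape > 0 and scale > 0, got {a}")
        elif self.family == "lognormal":
            if len(a) != 2 or a[1] <= 0:
                errs.append(f"lognormal requires sigma > 0, got {a}")
        elif self.family == "uniform":
            if len(a) != 2 or a[0] > a[1]:
                errs.append(f"uniform requires lo <= hi, got {a}")
        elif self.family == "dirichlet":
            if len(a) != 1 or a[0] <= 0:
                errs.append(f"dirichlet requires a single concentration > 0, got {a}")
            if not self.group:
                errs.append("dirichlet distribution requires a group name")
        return errs

    def mean(self, group_total: float | None = None) -> float | None:
        """Analytic mean, or None when family is 'none' (held at base).

        For a dirichlet component the block's total concentration must be
        supplied (the ParameterSet knows it).
        """
        a = self.args
        if self.family == "none":
            return None
        if self.family == "beta":
            return a[0] / (a[0] + a[1])
        if self.family == "gamma":
            return a[0] * a[1]
        if self.family == "lognormal":
            return math.exp(a[0] + a[1] ** 2 / 2.0)
        if self.family == "uniform":
            return (a[0] + a[1]) / 2.0
        if self.family == "dirichlet":
            if group_total is None:
                return None
            return a[0] / group_total
        raise ValueError(self.family)


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input.

    owsa_range, when given, is the (low, high) interval scanned by one-way
    sensitivity analysis; the base value must lie inside it.
    """

    name: str
    kind: str
    base: float
    distribution: Distribution = field(default_factory=Distribution)
    owsa_range: tuple[float, float] | None = None
    note: str = ""

    def validate(self, group_total: float | None = None) -> list[str]:
        errs = [f"{self.name}: {e}" for e in self.distribution.validate()]
        if self.kind not in KINDS:
            errs.append(f"{self.name}: unknown kind {self.kind!r}")
            return errs
        if self.kind == "probability" and not (0.0 <= self.base <= 1.0):
            errs.append(f"{self.name}: probability base {self.base} outside [0, 1]")
        if self.kind == "cost" and self.base < 0:
            errs.append(f"{self.name}: cost base {self.base} is negative")
        if self.kind == "utility" and not (0.0 <= self.base <= 1.0):
            errs.append(f"{self.name}: utility base {self.base} outside [0, 1]")
        if self.owsa_range is not None:
            lo, hi = self.owsa_range
            if lo > hi:
                errs.append(f"{self.name}: owsa_range low {lo} > high {hi}")
            if self.kind == "probability" and (lo < 0.0 or hi > 1.0):
                errs.append(f"{self.name}: owsa_range [{lo}, {hi}] outside [0, 1]")
            if not (lo <= self.base <= hi):
                errs.append(f"{self.name}: base {self.base} outside owsa_range [{lo}, {hi}]")
            mean = self.distribution.mean(group_total)
            if mean is not None and not (lo - 1e-12 <= mean <= hi + 1e-12):
                errs.append(
                    f"{self.name}: distribution mean {mean:.6g} outside "
                    f"owsa_range [{lo}, {hi}]"
                )
        return errs


class ParameterSet:
    """Ordered collection of ParameterSpec with Dirichlet block bookkeeping.

    Dirichlet blocks may carry a residual concentration (``rest_alpha``) for
    the complement branch that has no named parameter; the block then sums to
    less than one and the tree's complement expression picks up the rest.
    """

    def __init__(
        self,
        specs: Iterable[ParameterSpec],
        dirichlet_rest: Mapping[str, float] | None = None,
    ) -> None:
        self._specs: dict[str, ParameterSpec] = {}
        for s in specs:
            if s.name in self._specs:
                raise ValueError(f"duplicate parameter name {s.name!r}")
            self._specs[s.name] = s
        self.dirichlet_rest: dict[str, float] = dict(dirichlet_rest or {})

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def groups(self) -> dict[str, list[str]]:
        """Dirichlet block name -> member parameter names, declaration order."""
        out: dict[str, list[str]] = {}
        for s in self:
            if s.distribution.family == "dirichlet" and s.distribution.group:
                out.setdefault(s.distribution.group, []).append(s.name)
        return out

    def group_total(self, group: str) -> float:
        members = self.groups().get(group, [])
        tot = sum(self[m].distribution.args[0] for m in members)
        return tot + self.dirichlet_rest.get(group, 0.0)

    def base_values(self) -> dict[str, float]:
        return {s.name: s.base for s in self}

    def validate(self) -> list[str]:
        errs: list[str] = []
        for s in self:
            gt = None
            if s.distribution.family == "dirichlet" and s.distribution.group:
                gt = self.group_total(s.distribution.group)
            errs.extend(s.validate(gt))
        for g, rest in self.dirichlet_rest.items():
            if g not in self.groups():
                errs.append(f"dirichlet rest_alpha given for unknown group {g!r}")
            elif rest < 0:
                errs.append(f"dirichlet group {g!r}: rest_alpha {rest} is negative")
        return errs
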