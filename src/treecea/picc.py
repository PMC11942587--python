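"""Bundled case study: chlorhexidine-coated (AGBA) vs standard PICCs.

Builds the runnable two-strategy decision-tree model of catheter-related
complications over a 90-day horizon in a haematology population, from the
aggregate figures of the published two-arm trial it emulates: arm sizes
113 (AGBA) vs 111 (standard), second-puncture counts 1 vs 3, CLABSI counts
0 vs 3 (the zero cell gets the Jeffreys point estimate so probabilistic
uncertainty stays proper), and 36 unknown-fever cases whose per-arm split
was not published — by default they are pooled (the same per-arm rate),
and the split is a builder argument, not an asserted trial result.

Quantities the source publication does not itemize (local-complication
rate, resolution probabilities, per-category cost levels, utility
decrements) are package defaults flagged as assumptions in the model
metadata.  Two quantities per arm are calibrated so base-case rollback
reproduces the published per-patient means exactly: the residual "other
treatments" cost and the complication-free utility (state utilities keep a
fixed ordering: complication-free > resolved without removal > resolved
with removal > worsened).  The metadata labels this as calibration of
fixture construction, not independent validation.
"""

from __future__ import annotations

from statsmodels.stats.proportion import proportion_confint

from .cohort import ArmConfig, CohortConfig
from .metrics import ExchangeRate, WtpThreshold
from .model_io import Model
from .params import Distribution, ParameterSet, ParameterSpec
from .tree import (
    Branch,
    ChanceNode,
    Complement,
    CostTerm,
    DecisionTree,
    Ref,
    Strategy,
    TerminalNode,
    rollback,
)

__all__ = [
    "ARMS",
    "ARM_N",
    "TARGET_COST_RMB",
    "TARGET_QALY",
    "WTP_RMB",
    "RMB_PER_100_USD",
    "REPORTED_FIGURES",
    "build_picc_model",
    "default_cohort_config",
    "fixture_path",
]

ARMS = ("AGBA", "standard")
ARM_N = {"AGBA": 113, "standard": 111}
SECOND_PUNCTURE_COUNT = {"AGBA": 1, "standard": 3}
CLABSI_COUNT = {"AGBA": 0, "standard": 3}
UNKNOWN_FEVER_TOTAL = 36  # per-arm split not published

TARGET_COST_RMB = {"AGBA": 19696.23, "standard": 21987.32}
TARGET_QALY = {"AGBA": 0.73, "standard": 0.68}
WTP_RMB = 113_120.0
WTP_PROVENANCE = "1.76 x GDP per capita, non-life-saving technology"
RMB_PER_100_USD = 678.03
HORIZON_DAYS = 90

# package defaults for unpublished quantities (flagged in metadata)
LOCAL_RATE = 0.05
RESOLUTION_PROBS = {
    "resolved_no_removal": 0.70,
    "resolved_with_removal": 0.25,
    "worsened": 0.05,
}
RESOLUTION_ESS = 20.0  # effective sample size of the resolution Dirichlet
COST_MEANS = {
    "laboratory": 800.0,
    "inpatient": 12_000.0,
    "followup": 1_000.0,
    "maintenance": 1_500.0,
}
CATHETER_PRICE = {"AGBA": 2_500.0, "standard": 1_600.0}
INSERTION_FEE = 400.0
TREATMENT_COST = {"clabsi": 15_000.0, "unknown_fever": 2_500.0, "local": 1_500.0}
ESCALATION_COST = 8_000.0
UTILITY_DECREMENT = {
    "resolved_no_removal": 0.05,
    "resolved_with_removal": 0.10,
    "worsened": 0.30,
}
COST_CV = 0.3

# figures printed in the source publication, surfaced verbatim in reports;
# the printed ICER and USD saving are not the arithmetic of the printed
# means (2291.10/0.05 = 45,822.00 and 2291.10 RMB = USD 337.91) — both the
# computed and the printed values are shown, neither is altered.
REPORTED_FIGURES = {
    "cost_standard_rmb": 21987.32,
    "cost_standard_usd": 3242.82,
    "cost_agba_rmb": 19696.23,
    "cost_agba_usd": 2904.92,
    "qaly_standard": 0.68,
    "qaly_agba": 0.73,
    "incremental_cost_rmb": 2291.10,
    "incremental_cost_usd": 428.44,
    "icer_rmb_per_qaly": 4271.31,
    "icer_usd_per_qaly": 629.96,
    "wtp_rmb_per_qaly": 113120.0,
    "wtp_usd_methods_section": 16884.0,
    "wtp_usd_results_section": 16683.63,
    "note": (
        "Figures as printed in the source publication. The printed ICER "
        "(4271.31 RMB/QALY) does not equal the ratio of the printed "
        "incremental cost and effect (2291.10 / 0.05 = 45,822.00), and the "
        "printed USD saving (428.44) is not the currency conversion of RMB "
        "2291.10 (= 337.91); the two USD values printed for the WTP "
        "threshold also disagree. This report computes the self-consistent "
        "arithmetic and surfaces the printed figures verbatim."
    ),
}

COMPLICATIONS = ("clabsi", "unknown_fever", "local")
_SUFFIX = {"AGBA": "agba", "standard": "std"}


def _jeffreys(x: int, n: int) -> float:
    return (x + 0.5) / (n + 1)


def _wilson(x: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _pm(base: float, frac: float, lo_clip: float = 0.0, hi_clip: float | None = None):
    lo = max(lo_clip, base * (1 - frac))
    hi = base * (1 + frac)
    if hi_clip is not None:
        hi = min(hi_clip, hi)
    return (lo, hi)


def _gamma_cost(name: str, mean: float, note: str = "") -> ParameterSpec:
    shape = 1.0 / COST_CV**2
    return ParameterSpec(
        name=name,
        kind="cost",
        base=mean,
        distribution=Distribution("gamma", (shape, mean / shape)) if mean > 0
        else Distribution("none"),
        owsa_range=_pm(mean, 0.25),
        note=note,
    )


def build_picc_model(
    fever_probs: dict[str, float] | None = None,
    local_rate: float = LOCAL_RATE,
) -> Model:
    """Construct the calibrated AGBA-vs-standard PICC model.

    fever_probs
        Per-arm unknown-fever probability.  Default: the 36 published cases
        pooled over both arms (36/224 in each arm), because the per-arm
        split was not published.
    local_rate
        Per-arm local-complication probability (unpublished; package
        default).
    """
    if fever_probs is None:
        pooled = UNKNOWN_FEVER_TOTAL / sum(ARM_N.values())
        fever_probs = {arm: pooled for arm in ARMS}

    specs: list[ParameterSpec] = []
    rest: dict[str, float] = {}

    for arm in ARMS:
        s = _SUFFIX[arm]
        n = ARM_N[arm]
        x2 = SECOND_PUNCTURE_COUNT[arm]
        specs.append(
            ParameterSpec(
                name=f"p_second_{s}",
                kind="probability",
                base=x2 / n,
                distribution=Distribution("beta", (float(x2), float(n - x2))),
                owsa_range=_wilson(x2, n),
                note=f"second puncture, {x2}/{n} trial count; Wilson 95% OWSA range",
            )
        )
        xc = CLABSI_COUNT[arm]
        p_clabsi = _jeffreys(xc, n) if xc == 0 else xc / n
        p_fever = fever_probs[arm]
        probs = {"clabsi": p_clabsi, "unknown_fever": p_fever, "local": local_rate}
        group = f"complication_{s}"
        for c in COMPLICATIONS:
            notes = {
                "clabsi": (
                    f"CLABSI, {xc}/{n} trial count"
                    + (" (zero cell: Jeffreys point estimate)" if xc == 0 else "")
                ),
                "unknown_fever": (
                    "unknown fever; per-arm split unpublished, pooled 36/224 by default"
                ),
                "local": "local complication rate: package assumption, not a trial figure",
            }
            # the complement branch (no complication) must stay >= 0 when one
            # member is scanned with its siblings held at base
            hi_cap = 1.0 - (sum(probs.values()) - probs[c])
            owsa = _wilson(xc, n) if c == "clabsi" else _pm(probs[c], 0.5, hi_clip=hi_cap)
            if c == "clabsi" and xc == 0:
                owsa = (0.0, max(min(owsa[1], hi_cap), p_clabsi))
            specs.append(
                ParameterSpec(
                    name=f"p_{c}_{s}",
                    kind="probability",
                    base=probs[c],
                    distribution=Distribution("dirichlet", (probs[c] * n,), group=group),
                    owsa_range=owsa,
                    note=notes[c],
                )
            )
        rest[group] = (1.0 - sum(probs.values())) * n

    # resolution split shared across arms and complication types
    group = "resolution"
    for r in ("resolved_no_removal", "resolved_with_removal"):
        p = RESOLUTION_PROBS[r]
        other = sum(
            RESOLUTION_PROBS[x]
            for x in ("resolved_no_removal", "resolved_with_removal")
            if x != r
        )
        specs.append(
            ParameterSpec(
                name=f"p_{r}",
                kind="probability",
                base=p,
                distribution=Distribution("dirichlet", (p * RESOLUTION_ESS,), group=group),
                owsa_range=_pm(p, 0.5, hi_clip=1.0 - other),
                note="resolution pathway split: package assumption ('worsened' is the complement)",
            )
        )
    rest[group] = RESOLUTION_PROBS["worsened"] * RESOLUTION_ESS

    for cat, mean in COST_MEANS.items():
        specs.append(_gamma_cost(f"c_{cat}", mean, "per-patient category mean: package assumption"))
    for arm in ARMS:
        s = _SUFFIX[arm]
        specs.append(
            _gamma_cost(f"c_catheter_{s}", CATHETER_PRICE[arm], "device price per catheter: package assumption")
        )
    specs.append(_gamma_cost("c_insertion", INSERTION_FEE, "insertion procedure fee per catheter"))
    for c in COMPLICATIONS:
        specs.append(
            _gamma_cost(f"c_treat_{c}", TREATMENT_COST[c], "complication treatment mean: package assumption")
        )
    specs.append(_gamma_cost("c_escalation", ESCALATION_COST, "additional care when the situation worsens"))
    # residual category and utilities are calibrated below; placeholders first
    for arm in ARMS:
        s = _SUFFIX[arm]
        specs.append(_gamma_cost(f"c_other_{s}", 1.0))
        for state, dec in (("free", 0.0),) + tuple(
            (st, UTILITY_DECREMENT[st]) for st in UTILITY_DECREMENT
        ):
            name = f"u_{state}_{s}" if state == "free" else f"u_{state}_{s}"
            specs.append(
                ParameterSpec(
                    name=name,
                    kind="utility",
                    base=0.75 - dec,
                    distribution=Distribution("none"),
                    owsa_range=None,
                    note="placeholder before calibration",
                )
            )

    tree = _build_tree()
    params = ParameterSet(specs, dirichlet_rest=rest)

    # --- calibrate residual cost and utility level per arm ---------------
    values = params.base_values()
    for arm in ARMS:
        values[f"c_other_{_SUFFIX[arm]}"] = 0.0
    outcomes = {o.strategy: o for o in rollback(tree, values)}
    solved: dict[str, float] = {}
    for arm in ARMS:
        s = _SUFFIX[arm]
        strat = _strategy_name(arm)
        other = TARGET_COST_RMB[arm] - outcomes[strat].expected_cost
        if other < 0:
            raise ValueError(f"{arm}: calibration infeasible, residual {other:.2f} < 0")
        shift = TARGET_QALY[arm] - outcomes[strat].expected_effect
        solved[f"c_other_{s}"] = other
        solved[f"u_free_{s}"] = 0.75 + shift
        for state, dec in UTILITY_DECREMENT.items():
            solved[f"u_{state}_{s}"] = 0.75 + shift - dec

    final_specs: list[ParameterSpec] = []
    for spec in specs:
        if spec.name in solved:
            v = solved[spec.name]
            if spec.kind == "cost":
                final_specs.append(
                    _gamma_cost(spec.name, v, "residual 'other treatments': calibrated to published arm mean")
                )
            else:
                final_specs.append(
                    ParameterSpec(
                        name=spec.name,
                        kind="utility",
                        base=v,
                        distribution=Distribution("none"),
                        owsa_range=(max(0.0, v - 0.05), min(1.0, v + 0.05)),
                        note="state utility: level calibrated to published arm QALY, ordering fixed",
                    )
                )
        else:
            final_specs.append(spec)
    params = ParameterSet(final_specs, dirichlet_rest=rest)

    metadata = {
        "name": "picc_agba_vs_standard",
        "currency": "RMB",
        "horizon_days": HORIZON_DAYS,
        "calibration": {
            "label": (
                "calibrated: base-case rollback reproduces the published "
                "per-patient arm means by construction — a check of fixture "
                "construction, not independent validation"
            ),
            "targets_cost_rmb": TARGET_COST_RMB,
            "targets_qaly": TARGET_QALY,
            "calibrated_parameters": sorted(solved),
        },
        "assumptions": {
            "unknown_fever_split": "pooled 36/224 per arm (per-arm split unpublished)",
            "local_complication_rate": local_rate,
            "resolution_probs": RESOLUTION_PROBS,
            "cost_cv": COST_CV,
            "utility_decrements": UTILITY_DECREMENT,
        },
        "reported_figures": dict(REPORTED_FIGURES),
    }
    model = Model(
        tree=tree,
        params=params,
        wtp=WtpThreshold(WTP_RMB, provenance=WTP_PROVENANCE),
        exchange_rate=ExchangeRate(RMB_PER_100_USD),
        metadata=metadata,
    )
    errs = model.validate()
    if errs:  # pragma: no cover - construction guarantees validity
        raise ValueError("fixture failed validation: " + "; ".join(errs))
    return model


def _strategy_name(arm: str) -> str:
    return f"{arm} PICC"


def _build_tree() -> DecisionTree:
    nodes: dict = {}
    strategies = []
    for arm in ARMS:
        s = _SUFFIX[arm]
        root = f"{s}_puncture"
        strategies.append(Strategy(name=_strategy_name(arm), root=root))
        nodes[root] = ChanceNode(
            id=root,
            branches=(
                Branch(child=f"{s}_2_comp", prob=Ref(f"p_second_{s}")),
                Branch(child=f"{s}_1_comp", prob=Complement()),
            ),
        )
        for attempts in (1, 2):
            comp_id = f"{s}_{attempts}_comp"
            branches = []
            for c in COMPLICATIONS:
                res_id = f"{s}_{attempts}_{c}_res"
                branches.append(Branch(child=res_id, prob=Ref(f"p_{c}_{s}")))
                res_branches = []
                for r in ("resolved_no_removal", "resolved_with_removal"):
                    tid = f"{s}_{attempts}_{c}_{r}"
                    res_branches.append(Branch(child=tid, prob=Ref(f"p_{r}")))
                    nodes[tid] = _terminal(tid, s, attempts, c, r)
                tid = f"{s}_{attempts}_{c}_worsened"
                res_branches.append(Branch(child=tid, prob=Complement()))
                nodes[tid] = _terminal(tid, s, attempts, c, "worsened")
                nodes[res_id] = ChanceNode(id=res_id, branches=tuple(res_branches))
            tid = f"{s}_{attempts}_none"
            branches.append(Branch(child=tid, prob=Complement()))
            nodes[tid] = _terminal(tid, s, attempts, None, None)
            nodes[comp_id] = ChanceNode(id=comp_id, branches=tuple(branches))
    return DecisionTree(strategies=strategies, nodes=nodes)


def _terminal(tid: str, s: str, attempts: int, comp: str | None, res: str | None) -> TerminalNode:
    n_catheters = attempts + (1 if res == "resolved_with_removal" else 0)
    cost = [
        CostTerm("c_laboratory"),
        CostTerm("c_inpatient"),
        CostTerm("c_followup"),
        CostTerm("c_maintenance"),
        CostTerm(f"c_other_{s}"),
        CostTerm(f"c_catheter_{s}", times=float(n_catheters)),
        CostTerm("c_insertion", times=float(n_catheters)),
    ]
    if comp is not None:
        cost.append(CostTerm(f"c_treat_{comp}"))
        if res == "worsened":
            cost.append(CostTerm("c_escalation"))
    effect = f"u_free_{s}" if comp is None else f"u_{res}_{s}"
    return TerminalNode(id=tid, cost=tuple(cost), effect=effect)


def default_cohort_config(model: Model | None = None) -> CohortConfig:
    """Synthetic-cohort configuration matching the bundled PICC model.

    Probabilities, cost means and utilities are read off the calibrated
    model parameters, so the cohort's analytic expected per-patient totals
    equal the model's base-case expected costs.
    """
    if model is None:
        model = build_picc_model()
    values = model.params.base_values()
    arms = []
    for arm in ARMS:
        s = _SUFFIX[arm]
        arms.append(
            ArmConfig(
                name=arm,
                n=ARM_N[arm],
                p_second_puncture=values[f"p_second_{s}"],
                p_complication={c: values[f"p_{c}_{s}"] for c in COMPLICATIONS},
                p_resolution={
                    "resolved_no_removal": values["p_resolved_no_removal"],
                    "resolved_with_removal": values["p_resolved_with_removal"],
                    "worsened": 1.0
                    - values["p_resolved_no_removal"]
                    - values["p_resolved_with_removal"],
                },
                cost_means={
                    "laboratory": values["c_laboratory"],
                    "inpatient": values["c_inpatient"],
                    "followup": values["c_followup"],
                    "maintenance": values["c_maintenance"],
                    "other": values[f"c_other_{s}"],
                },
                catheter_unit_cost=values[f"c_catheter_{s}"] + values["c_insertion"],
                complication_treatment_cost={c: values[f"c_treat_{c}"] for c in COMPLICATIONS},
                escalation_cost=values["c_escalation"],
                utilities={
                    "complication_free": values[f"u_free_{s}"],
                    "resolved_no_removal": values[f"u_resolved_no_removal_{s}"],
                    "resolved_with_removal": values[f"u_resolved_with_removal_{s}"],
                    "worsened": values[f"u_worsened_{s}"],
                },
                cost_cv=COST_CV,
            )
        )
    return CohortConfig(
        arms=tuple(arms),
        metadata={"source_model": model.metadata.get("name", "")},
    )


def fixture_path():
    """Path of the bundled model file."""
    from importlib.resources import files

    return files("treecea.fixtures") / "picc_agba_vs_standard.json"
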