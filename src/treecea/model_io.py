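"""Model-file reading and writing, result reports and run manifests.

A model file is a JSON document with sections ``metadata``, ``wtp``,
``exchange_rate``, ``parameters``, ``dirichlet_groups``, ``strategies`` and
``nodes``.  Reading validates the whole document and reports every schema
violation at once (with its JSON path) rather than failing on the first;
unknown fields produce warnings for forward compatibility.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .metrics import (
    ExchangeRate,
    IncrementalResult,
    WtpThreshold,
    rmb_to_usd,
)
from .params import Distribution, ParameterSet, ParameterSpec
from .tree import (
    Branch,
    ChanceNode,
    Complement,
    CostTerm,
    DecisionTree,
    Product,
    Ref,
    Strategy,
    StrategyOutcome,
    TerminalNode,
    validate_tree,
)

__all__ = [
    "Model",
    "ModelSchemaError",
    "RunManifest",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
    "write_report",
]

_KNOWN_TOP = {
    "metadata",
    "wtp",
    "exchange_rate",
    "parameters",
    "dirichlet_groups",
    "strategies",
    "nodes",
}


class ModelSchemaError(ValueError):
    """Carries the complete list of schema violations for a model file."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass
class Model:
    tree: DecisionTree
    params: ParameterSet
    wtp: WtpThreshold
    exchange_rate: ExchangeRate
    metadata: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        errs = self.params.validate()
        errs.extend(str(v) for v in validate_tree(self.tree, self.params))
        return errs


@dataclass
class RunManifest:
    """Everything needed to regenerate a stochastic output bit-for-bit."""

    tool_version: str
    model_digest: str
    seeds: dict[str, int]
    iterations: dict[str, int]
    defaults_used: dict
    timestamp: str = ""

    def write(self, path: Path | str) -> None:
        d = dataclasses.asdict(self)
        d["timestamp"] = d["timestamp"] or datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


# ---------------------------------------------------------------- parsing


def _parse_prob(obj, where: str, errs: list[str]):
    if not isinstance(obj, dict):
        errs.append(f"{where}: branch probability must be an object")
        return Complement()
    if obj.get("complement"):
        return Complement()
    if "ref" in obj:
        if not isinstance(obj["ref"], str):
            errs.append(f"{where}.ref: must be a string")
            return Complement()
        return Ref(obj["ref"])
    if "product" in obj:
        names = obj["product"]
        if not isinstance(names, list) or not all(isinstance(x, str) for x in names):
            errs.append(f"{where}.product: must be a list of parameter names")
            return Complement()
        return Product(tuple(names))
    errs.append(f"{where}: expected one of 'ref', 'product', 'complement'")
    return Complement()


def _num(obj, where: str, errs: list[str], default=0.0) -> float:
    if isinstance(obj, bool) or not isinstance(obj, (int, float)):
        errs.append(f"{where}: expected a number, got {type(obj).__name__}")
        return default
    return float(obj)


def model_from_dict(doc: dict, source: str = "<dict>") -> Model:
    errs: list[str] = []
    if not isinstance(doc, dict):
        raise ModelSchemaError([f"{source}: top level must be a JSON object"])
    for k in doc:
        if k not in _KNOWN_TOP:
            warnings.warn(f"{source}: unknown top-level field {k!r} ignored", stacklevel=2)

    wtp_doc = doc.get("wtp", {})
    lam = _num(wtp_doc.get("lambda_rmb_per_qaly", 0.0), "wtp.lambda_rmb_per_qaly", errs)
    rate_doc = doc.get("exchange_rate", {})
    rate = _num(rate_doc.get("rmb_per_100_usd", 0.0), "exchange_rate.rmb_per_100_usd", errs)

    specs: list[ParameterSpec] = []
    for i, p in enumerate(doc.get("parameters", [])):
        where = f"parameters[{i}]"
        if not isinstance(p, dict):
            errs.append(f"{where}: must be an object")
            continue
        name = p.get("name")
        if not isinstance(name, str) or not name:
            errs.append(f"{where}.name: missing or not a string")
            continue
        dist_doc = p.get("distribution", {"family": "none"})
        dist = Distribution(
            family=dist_doc.get("family", "none"),
            args=tuple(
                _num(a, f"{where}.distribution.args", errs)
                for a in dist_doc.get("args", [])
            ),
            group=dist_doc.get("group"),
        )
        rng = p.get("owsa_range")
        owsa = None
        if rng is not None:
            if not (isinstance(rng, list) and len(rng) == 2):
                errs.append(f"{where}.owsa_range: must be [low, high]")
            else:
                owsa = (
                    _num(rng[0], f"{where}.owsa_range[0]", errs),
                    _num(rng[1], f"{where}.owsa_range[1]", errs),
                )
        specs.append(
            ParameterSpec(
                name=name,
                kind=p.get("kind", ""),
                base=_num(p.get("base", 0.0), f"{where}.base", errs),
                distribution=dist,
                owsa_range=owsa,
                note=str(p.get("note", "")),
            )
        )
    rest = {}
    for g, gdoc in (doc.get("dirichlet_groups") or {}).items():
        rest[g] = _num(gdoc.get("rest_alpha", 0.0), f"dirichlet_groups.{g}.rest_alpha", errs)
    try:
        params = ParameterSet(specs, dirichlet_rest=rest)
    except ValueError as e:
        errs.append(str(e))
        params = ParameterSet([], {})

    strategies = []
    for i, s in enumerate(doc.get("strategies", [])):
        where = f"strategies[{i}]"
        if not isinstance(s, dict) or "name" not in s or "root" not in s:
            errs.append(f"{where}: must be an object with 'name' and 'root'")
            continue
        strategies.append(Strategy(name=str(s["name"]), root=str(s["root"])))

    nodes: dict = {}
    for nid, nd in (doc.get("nodes") or {}).items():
        where = f"nodes.{nid}"
        if not isinstance(nd, dict):
            errs.append(f"{where}: must be an object")
            continue
        ntype = nd.get("type")
        if ntype == "chance":
            branches = []
            for j, b in enumerate(nd.get("branches", [])):
                bw = f"{where}.branches[{j}]"
                if not isinstance(b, dict) or "child" not in b:
                    errs.append(f"{bw}: must be an object with 'child'")
                    continue
                branches.append(
                    Branch(child=str(b["child"]), prob=_parse_prob(b.get("prob"), bw, errs))
                )
            nodes[nid] = ChanceNode(id=nid, branches=tuple(branches))
        elif ntype == "terminal":
            terms = []
            for j, t in enumerate(nd.get("cost", [])):
                tw = f"{where}.cost[{j}]"
                if not isinstance(t, dict) or "ref" not in t:
                    errs.append(f"{tw}: must be an object with 'ref'")
                    continue
                terms.append(
                    CostTerm(ref=str(t["ref"]), times=_num(t.get("times", 1.0), tw, errs, 1.0))
                )
            eff = nd.get("effect", {})
            eff_ref = eff.get("ref") if isinstance(eff, dict) else None
            if not isinstance(eff_ref, str):
                errs.append(f"{where}.effect: must be an object with a 'ref' string")
                eff_ref = ""
            nodes[nid] = TerminalNode(id=nid, cost=tuple(terms), effect=eff_ref)
        else:
            errs.append(f"{where}.type: must be 'chance' or 'terminal', got {ntype!r}")
    if errs:
        raise ModelSchemaError([f"{source}: {e}" for e in errs])

    try:
        wtp = WtpThreshold(lam, provenance=str(wtp_doc.get("provenance", "")))
        xrate = ExchangeRate(rate)
    except ValueError as e:
        raise ModelSchemaError([f"{source}: {e}"]) from None
    model = Model(
        tree=DecisionTree(strategies=strategies, nodes=nodes),
        params=params,
        wtp=wtp,
        exchange_rate=xrate,
        metadata=dict(doc.get("metadata", {})),
    )
    post = model.validate()
    if post:
        raise ModelSchemaError([f"{source}: {e}" for e in post])
    return model


def read_model(path: Path | str) -> Model:
    """Load and fully validate a model file.

    Raises ModelSchemaError carrying every violation found (JSON paths
    included); unknown fields are warnings, not errors.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ModelSchemaError([f"{path}: not valid JSON ({e})"]) from None
    return model_from_dict(doc, source=str(path))


# ------------------------------------------------------------ serialization


def _prob_to_dict(expr) -> dict:
    if isinstance(expr, Ref):
        return {"ref": expr.name}
    if isinstance(expr, Product):
        return {"product": list(expr.names)}
    return {"complement": True}


def model_to_dict(model: Model) -> dict:
    params = []
    for s in model.params:
        d: dict = {"name": s.name, "kind": s.kind, "base": s.base}
        if s.distribution.family != "none":
            dd: dict = {"family": s.distribution.family, "args": list(s.distribution.args)}
            if s.distribution.group:
                dd["group"] = s.distribution.group
            d["distribution"] = dd
        if s.owsa_range is not None:
            d["owsa_range"] = list(s.owsa_range)
        if s.note:
            d["note"] = s.note
        params.append(d)
    nodes = {}
    for nid, node in model.tree.nodes.items():
        if isinstance(node, ChanceNode):
            nodes[nid] = {
                "type": "chance",
                "branches": [
                    {"child": b.child, "prob": _prob_to_dict(b.prob)} for b in node.branches
                ],
            }
        else:
            nodes[nid] = {
                "type": "terminal",
                "cost": [
                    {"ref": t.ref, **({"times": t.times} if t.times != 1.0 else {})}
                    for t in node.cost
                ],
                "effect": {"ref": node.effect},
            }
    return {
        "metadata": model.metadata,
        "wtp": {
            "lambda_rmb_per_qaly": model.wtp.lambda_rmb_per_qaly,
            "provenance": model.wtp.provenance,
        },
        "exchange_rate": {"rmb_per_100_usd": model.exchange_rate.rmb_per_100_usd},
        "dirichlet_groups": {
            g: {"rest_alpha": r} for g, r in model.params.dirichlet_rest.items()
        },
        "parameters": params,
        "strategies": [{"name": s.name, "root": s.root} for s in model.tree.strategies],
        "nodes": nodes,
    }


def write_model(model: Model, path: Path | str) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


# ---------------------------------------------------------------- reports


def _fmt_icer(inc: IncrementalResult, rate: ExchangeRate) -> str:
    if inc.status == "icer":
        return f"{inc.icer:.2f} RMB/QALY (USD {rmb_to_usd(inc.icer, rate):.2f})"
    return inc.status


def write_report(
    outdir: Path | str,
    model: Model,
    outcomes: list[StrategyOutcome],
    inc: IncrementalResult | None = None,
    extra_sections: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write base-case results as CSV + JSON plus a human-readable summary.

    The summary shows RMB and USD side by side and, when the model's
    metadata carries a ``reported_figures`` block, surfaces those published
    figures verbatim next to the values computed here — both are shown,
    neither is altered.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rate = model.exchange_rate
    rows = [
        {
            "strategy": o.strategy,
            "expected_cost_rmb": round(o.expected_cost, 2),
            "expected_cost_usd": rmb_to_usd(o.expected_cost, rate),
            "expected_effect_qaly": round(o.expected_effect, 4),
        }
        for o in outcomes
    ]
    basecase_csv = outdir / "basecase.csv"
    pd.DataFrame(rows).to_csv(basecase_csv, index=False)
    basecase_json = outdir / "basecase.json"
    basecase_json.write_text(json.dumps(rows, indent=2) + "\n")

    lines = ["# Cost-effectiveness report", ""]
    name = model.metadata.get("name", "model")
    lines.append(f"Model: {name}")
    lines.append(f"WTP threshold: {model.wtp.lambda_rmb_per_qaly:.2f} RMB/QALY"
                 f" (USD {rmb_to_usd(model.wtp.lambda_rmb_per_qaly, rate):.2f})"
                 + (f" — {model.wtp.provenance}" if model.wtp.provenance else ""))
    lines.append(f"Exchange rate: RMB {rate.rmb_per_100_usd} = USD 100")
    lines.append("")
    lines.append("## Base case")
    lines.append("")
    for r in rows:
        lines.append(
            f"- {r['strategy']}: cost RMB {r['expected_cost_rmb']:.2f} "
            f"(USD {r['expected_cost_usd']:.2f}), effect {r['expected_effect_qaly']:.4f} QALY"
        )
    if inc is not None:
        lines.append("")
        lines.append("## Incremental analysis")
        lines.append("")
        lines.append(f"- {inc.intervention} vs {inc.comparator}")
        lines.append(
            f"- delta cost: {inc.delta_cost:.2f} RMB (USD {rmb_to_usd(inc.delta_cost, rate):.2f})"
        )
        lines.append(f"- delta effect: {inc.delta_effect:.4f} QALY")
        lines.append(f"- ICER: {_fmt_icer(inc, rate)}")
        lines.append(
            f"- incremental NMB at WTP: {inc.incremental_nmb:.2f} RMB — "
            + ("cost-effective" if inc.cost_effective else "not cost-effective")
        )
        inc_json = outdir / "incremental.json"
        inc_json.write_text(json.dumps(dataclasses.asdict(inc), indent=2) + "\n")
    reported = model.metadata.get("reported_figures")
    if reported:
        lines.append("")
        lines.append("## Published figures (verbatim, for comparison)")
        lines.append("")
        note = reported.get("note")
        if note:
            lines.append(note)
            lines.append("")
        for k, v in reported.items():
            if k != "note":
                lines.append(f"- {k}: {v}")
    for title, body in (extra_sections or {}).items():
        lines.append("")
        lines.append(f"## {title}")
        lines.append("")
        lines.append(body)
    summary = outdir / "summary.md"
    summary.write_text("\n".join(lines) + "\n")
    out = {"basecase_csv": basecase_csv, "basecase_json": basecase_json, "summary": summary}
    if inc is not None:
        out["incremental_json"] = outdir / "incremental.json"
    return out
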