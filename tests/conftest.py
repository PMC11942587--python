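import itertools

import numpy as np
import pytest

from treecea import (
    Branch,
    ChanceNode,
    Complement,
    CostTerm,
    DecisionTree,
    Distribution,
    ParameterSet,
    ParameterSpec,
    Ref,
    Strategy,
    TerminalNode,
    build_picc_model,
    rollback,
)


@pytest.fixture(scope="session")
def picc_model():
    return build_picc_model()


@pytest.fixture(scope="session")
def base_outcomes(picc_model):
    return rollback(picc_model.tree, picc_model.params.base_values())


def two_branch_tree():
    """Chance node: p=0.25 -> (1000, 0.6); complement -> (200, 0.8)."""
    params = ParameterSet(
        [
            ParameterSpec("p", "probability", 0.25),
            ParameterSpec("c_hi", "cost", 1000.0),
            ParameterSpec("c_lo", "cost", 200.0),
            ParameterSpec("u_hi", "utility", 0.6),
            ParameterSpec("u_lo", "utility", 0.8),
        ]
    )
    tree = DecisionTree(
        strategies=[Strategy("S", "root")],
        nodes={
            "root": ChanceNode(
                "root",
                (
                    Branch("hi", Ref("p")),
                    Branch("lo", Complement()),
                ),
            ),
            "hi": TerminalNode("hi", (CostTerm("c_hi"),), "u_hi"),
            "lo": TerminalNode("lo", (CostTerm("c_lo"),), "u_lo"),
        },
    )
    return tree, params


@pytest.fixture
def simple_tree():
    return two_branch_tree()


def random_tree(rng: np.random.Generator, max_depth: int = 6, max_branch: int = 4):
    """Random valid out-tree with one strategy; parameters carry the values.

    Chance nodes get Dirichlet-distributed branch probabilities with the
    last branch expressed as a complement; terminals get uniform costs (with
    integer multipliers) and utilities.
    """
    specs: list[ParameterSpec] = []
    nodes: dict = {}
    counter = itertools.count()

    def make(depth: int) -> str:
        nid = f"n{next(counter)}"
        if depth >= max_depth or (depth > 0 and rng.random() < 0.35):
            cname, uname = f"c_{nid}", f"u_{nid}"
            specs.append(ParameterSpec(cname, "cost", float(rng.uniform(0, 1000))))
            specs.append(ParameterSpec(uname, "utility", float(rng.uniform(0, 1))))
            nodes[nid] = TerminalNode(
                nid, (CostTerm(cname, times=float(rng.integers(1, 4))),), uname
            )
            return nid
        k = int(rng.integers(2, max_branch + 1))
        probs = rng.dirichlet(np.ones(k))
        branches = []
        for i in range(k - 1):
            pname = f"p_{nid}_{i}"
            specs.append(ParameterSpec(pname, "probability", float(probs[i])))
            branches.append(Branch(make(depth + 1), Ref(pname)))
        branches.append(Branch(make(depth + 1), Complement()))
        nodes[nid] = ChanceNode(nid, tuple(branches))
        return nid

    # force the root to be a chance node so the tree is never trivial
    k = int(rng.integers(2, max_branch + 1))
    probs = rng.dirichlet(np.ones(k))
    branches = []
    for i in range(k - 1):
        pname = f"p_root_{i}"
        specs.append(ParameterSpec(pname, "probability", float(probs[i])))
        branches.append(Branch(make(1), Ref(pname)))
    branches.append(Branch(make(1), Complement()))
    nodes["root"] = ChanceNode("root", tuple(branches))
    tree = DecisionTree(strategies=[Strategy("S", "root")], nodes=nodes)
    return tree, ParameterSet(specs)


@pytest.fixture
def degenerate_params(picc_model):
    """PICC parameter set with every distribution collapsed to 'none'."""
    specs = [
        ParameterSpec(s.name, s.kind, s.base, Distribution("none"), s.owsa_range, s.note)
        for s in picc_model.params
    ]
    return ParameterSet(specs)
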