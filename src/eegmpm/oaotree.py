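"""Pairwise MPM bank and the alpha-ordered one-against-one exclusion tree.

Voting over one-against-one classifiers can tie, producing classification
rejections.  The exclusion tree avoids that: each internal node holds one
pairwise MPM; whichever class loses the comparison is permanently excluded,
so any input reaches a leaf after exactly M-1 binary decisions.  Pairs with
a larger separability index alpha sit nearer the root, so the most reliable
comparisons are made first and error accumulation along the path is
reduced.

Child selection follows the winner-restricted rule: after class i is
excluded at a node whose comparison j beat, the child node uses the
highest-alpha remaining pair that involves j.  A ``global_max`` variant
(highest-alpha pair within the remaining candidate set, unrestricted) is
available via ``child_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientDataError, ShapeError
from .mpm import MPMModel, degenerate_model, mpm_decide, solve_mpm
from .rbfmap import estimate_moments
from .exceptions import InseparableMeansError

CHILD_RULES = ("winner_restricted", "global_max")


@dataclass(frozen=True)
class PairwiseBank:
    """One MPM per unordered class pair {i, j}, keyed by (i, j) with i < j."""

    models: dict[tuple[int, int], MPMModel]
    classes: tuple[int, ...]

    def __post_init__(self) -> None:
        m = len(self.classes)
        expected = {tuple(sorted(p)) for p in combinations(self.classes, 2)}
        if set(self.models) != expected:
            raise ConfigurationError(
                f"bank must hold exactly the {m * (m - 1) // 2} pairs of {self.classes}"
            )

    def alpha(self, i: int, j: int) -> float:
        return self.models[tuple(sorted((i, j)))].alpha

    def alpha_table(self) -> pd.DataFrame:
        """Long-format (class_i, class_j, alpha) table, one row per pair."""
        rows = [
            {"class_i": i, "class_j": j, "alpha": m.alpha}
            for (i, j), m in sorted(self.models.items())
        ]
        return pd.DataFrame(rows, columns=["class_i", "class_j", "alpha"])

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "models": {f"{i},{j}": m.to_dict() for (i, j), m in sorted(self.models.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairwiseBank":
        models = {}
        for key, md in d["models"].items():
            i, j = (int(v) for v in key.split(","))
            models[(i, j)] = MPMModel.from_dict(md)
        return cls(models, tuple(int(c) for c in d["classes"]))


def train_pairwise(
    Z: np.ndarray,
    y: np.ndarray,
    classes: Iterable[int] | None = None,
) -> PairwiseBank:
    """Fit one MPM per class pair from mapped vectors Z and labels y.

    Each pair's moments come from that pair's data only.  The lower class
    index of a pair is its "positive" side.  Pairs whose means coincide get
    a degenerate alpha = 0 model instead of failing.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y)
    if Z.shape[0] != y.size:
        raise ShapeError("Z and y length mismatch")
    cls_list = tuple(sorted(set(int(c) for c in (classes or np.unique(y)))))
    if len(cls_list) < 2:
        raise ConfigurationError("need at least 2 classes")
    moments = {}
    for c in cls_list:
        zc = Z[y == c]
        if zc.shape[0] < 2:
            raise InsufficientDataError(
                f"class {c} has {zc.shape[0]} training vector(s); need >= 2"
            )
        moments[c] = estimate_moments(zc)
    models = {}
    for i, j in combinations(cls_list, 2):
        try:
            models[(i, j)] = solve_mpm(moments[i], moments[j], class_pos=i, class_neg=j)
        except InseparableMeansError:
            models[(i, j)] = degenerate_model(moments[i].mean, moments[j].mean, i, j)
    return PairwiseBank(models, cls_list)


@dataclass(frozen=True)
class TreeLeaf:
    label: int


@dataclass(frozen=True)
class TreeNode:
    """Internal node: one pairwise comparison over the candidate set.

    ``children`` is keyed by the *excluded* class (the pair's loser on a
    given input); each child's candidate set is this node's minus that
    class.
    """

    candidates: tuple[int, ...]
    pair: tuple[int, int]
    model: MPMModel
    children: dict[int, Union["TreeNode", TreeLeaf]]


@dataclass(frozen=True)
class OAOTree:
    root: Union[TreeNode, TreeLeaf]
    classes: tuple[int, ...]
    child_rule: str = "winner_restricted"

    def n_leaves(self) -> int:
        """Distinct leaf nodes (equal subproblems share a node, so this is M)."""
        return len({id(leaf) for leaf in iter_leaves(self.root)})

    def path_lengths(self) -> list[int]:
        """Number of internal nodes on every root-to-leaf path."""
        out: list[int] = []

        def walk(node, depth):
            if isinstance(node, TreeLeaf):
                out.append(depth)
            else:
                for child in node.children.values():
                    walk(child, depth + 1)

        walk(self.root, 0)
        return out


def iter_leaves(node):
    if isinstance(node, TreeLeaf):
        yield node
    else:
        for child in node.children.values():
            yield from iter_leaves(child)


def _best_pair(
    bank: PairwiseBank,
    candidates: tuple[int, ...],
    must_involve: int | None,
) -> tuple[int, int]:
    """Max-alpha pair within the candidate set (ties: lexicographic order)."""
    best: tuple[int, int] | None = None
    best_alpha = -1.0
    for i, j in combinations(candidates, 2):
        if must_involve is not None and must_involve not in (i, j):
            continue
        a = bank.alpha(i, j)
        if a > best_alpha or (a == best_alpha and (best is None or (i, j) < best)):
            best, best_alpha = (i, j), a
    assert best is not None
    return best


def build_tree(bank: PairwiseBank, child_rule: str = "winner_restricted") -> OAOTree:
    """Assemble the exclusion tree from a complete pairwise bank.

    The root is the globally max-alpha pair.  Under ``winner_restricted``
    each child's comparison is the max-alpha remaining pair involving the
    parent comparison's winner; under ``global_max`` it is the max-alpha
    pair within the remaining candidate set.  Deterministic: alpha ties
    break lexicographically.
    """
    if child_rule not in CHILD_RULES:
        raise ConfigurationError(f"child_rule must be one of {CHILD_RULES}")

    # Equal subproblems (same candidate set and restriction) share one node,
    # so the structure is a rooted DAG with exactly M distinct leaves.
    cache: dict[tuple, Union[TreeNode, TreeLeaf]] = {}

    def build(candidates: tuple[int, ...], must_involve: int | None):
        key = (candidates, must_involve)
        if key in cache:
            return cache[key]
        if len(candidates) == 1:
            node: Union[TreeNode, TreeLeaf] = TreeLeaf(candidates[0])
        else:
            pair = _best_pair(bank, candidates, must_involve)
            i, j = pair
            children = {}
            for excluded, winner in ((i, j), (j, i)):
                remaining = tuple(c for c in candidates if c != excluded)
                restrict = winner if child_rule == "winner_restricted" else None
                children[excluded] = build(
                    remaining, restrict if len(remaining) > 1 else None
                )
            node = TreeNode(candidates, pair, bank.models[pair], children)
        cache[key] = node
        return node

    # leaves must be unique per label regardless of the restriction history
    for c in bank.classes:
        cache[((c,), None)] = TreeLeaf(c)

    return OAOTree(build(bank.classes, None), bank.classes, child_rule)


def classify(
    tree: OAOTree, z: np.ndarray, return_n_decisions: bool = False
) -> int | tuple[int, int]:
    """Walk the tree: M-1 binary decisions, no rejection possible."""
    node = tree.root
    n_decisions = 0
    while isinstance(node, TreeNode):
        winner = mpm_decide(node.model, z)
        i, j = node.pair
        loser = j if winner == i else i
        node = node.children[loser]
        n_decisions += 1
    return (node.label, n_decisions) if return_n_decisions else node.label


def _tree_to_dict(node) -> dict:
    if isinstance(node, TreeLeaf):
        return {"leaf": node.label}
    return {
        "candidates": list(node.candidates),
        "pair": list(node.pair),
        "children": {str(k): _tree_to_dict(v) for k, v in sorted(node.children.items())},
    }


def tree_to_dict(tree: OAOTree) -> dict:
    """Topology only; models are resolved from the bank on reload."""
    return {
        "classes": list(tree.classes),
        "child_rule": tree.child_rule,
        "root": _tree_to_dict(tree.root),
    }


def tree_from_dict(d: dict, bank: PairwiseBank) -> OAOTree:
    import json as _json

    cache: dict[str, Union[TreeNode, TreeLeaf]] = {}

    def build(nd: dict):
        key = _json.dumps(nd, sort_keys=True)  # identical subtrees share a node
        if key in cache:
            return cache[key]
        if "leaf" in nd:
            node: Union[TreeNode, TreeLeaf] = TreeLeaf(int(nd["leaf"]))
        else:
            pair = tuple(int(v) for v in nd["pair"])
            children = {int(k): build(v) for k, v in nd["children"].items()}
            node = TreeNode(tuple(int(c) for c in nd["candidates"]), pair,
                            bank.models[pair], children)
        cache[key] = node
        return node

    return OAOTree(build(d["root"]), tuple(int(c) for c in d["classes"]),
                   d.get("child_rule", "winner_restricted"))
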