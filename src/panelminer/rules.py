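"""Association-rule mining over a discretized candidate panel.

Min-max-scaled panel values are discretized into equal-width thirds
(low / medium / high), each sample becomes a transaction of
(feature, level) items plus one (subtype, label) class item, and frequent
itemsets are mined with FP-Growth.  Rules A -> C are generated from frequent
itemsets and scored by

    support(A -> C)    = count(A u C) / n
    confidence(A -> C) = support(A u C) / support(A)
    lift(A -> C)       = P(A u C) / (P(A) P(C))

Rules whose consequent is exactly one class item are the "class rules"; a
feature's repeat count is the number of class rules whose antecedent mentions
the feature at any level — the ranking statistic for significant molecules.
A subtype whose prevalence falls below the minimum support can never yield
class rules (support(A u {class}) <= prevalence), which reproduces the
suppression of the rarest subtype in strongly imbalanced cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datasets import LEVELS

__all__ = [
    "Item",
    "CLASS_FIELD",
    "TransactionDB",
    "FrequentItemset",
    "AssociationRule",
    "discretize",
    "mine_frequent",
    "class_association_rules",
    "generate_rules",
    "filter_class_rules",
    "repeat_counts",
    "dependency_network",
]

#: Items are (field, value) pairs; the class item uses this reserved field.
Item = tuple[str, str]
CLASS_FIELD = "subtype"

_EPS = 1e-12


@dataclass
class TransactionDB:
    """Per-sample item sets: one level-item per panel feature plus one class item."""

    transactions: list[frozenset[Item]]
    feature_ids: list[str]
    classes: list[str]

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def vocabulary(self) -> set[Item]:
        vocab: set[Item] = set()
        for t in self.transactions:
            vocab |= t
        return vocab


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[Item]
    count: int
    support: float


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    support: float
    confidence: float
    lift: float


def discretize(
    X_panel,
    edges: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> TransactionDB:
    """Bin min-max-scaled panel values into low/medium/high transactions.

    Bins are left-closed: [0, e1) -> low, [e1, e2) -> medium, [e2, 1] -> high.
    """
    values = np.asarray(X_panel.values, dtype=float)
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError("discretize expects min-max-scaled values in [0, 1]")
    if not 0.0 < edges[0] < edges[1] < 1.0:
        raise ValueError("bin edges must satisfy 0 < e1 < e2 < 1")
    levels = np.digitize(values, edges)  # 0=low, 1=medium, 2=high
    transactions = []
    for i in range(values.shape[0]):
        items = {
            (fid, LEVELS[levels[i, j]]) for j, fid in enumerate(X_panel.feature_ids)
        }
        items.add((CLASS_FIELD, str(X_panel.labels[i])))
        transactions.append(frozenset(items))
    return TransactionDB(
        transactions=transactions,
        feature_ids=list(X_panel.feature_ids),
        classes=sorted(set(map(str, X_panel.labels))),
    )


# ---------------------------------------------------------------------------
# FP-Growth


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: Item | None, parent: "_FPNode | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[Item, _FPNode] = {}


def _build_tree(
    transactions: list[tuple[list[Item], int]], min_count: float
) -> tuple[_FPNode, dict[Item, list[_FPNode]], dict[Item, int]]:
    counts: dict[Item, int] = {}
    for items, cnt in transactions:
        for it in items:
            counts[it] = counts.get(it, 0) + cnt
    frequent = {it: c for it, c in counts.items() if c >= min_count}
    # descending support, ties by item name: deterministic tree shape
    rank = {
        it: i
        for i, it in enumerate(sorted(frequent, key=lambda it: (-frequent[it], it)))
    }
    root = _FPNode(None, None)
    header: dict[Item, list[_FPNode]] = {it: [] for it in frequent}
    for items, cnt in transactions:
        ordered = sorted((it for it in items if it in rank), key=rank.__getitem__)
        node = root
        for it in ordered:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                header[it].append(child)
            child.count += cnt
            node = child
    return root, header, frequent


def _mine(
    transactions: list[tuple[list[Item], int]],
    min_count: float,
    max_length: int,
    suffix: tuple[Item, ...],
    out: list[FrequentItemset],
    n: int,
) -> None:
    root, header, frequent = _build_tree(transactions, min_count)
    for item in sorted(frequent, key=lambda it: (-frequent[it], it), reverse=True):
        support_count = frequent[item]
        itemset = frozenset((item,) + suffix)
        out.append(FrequentItemset(itemset, support_count, support_count / n))
        if len(itemset) >= max_length:
            continue
        # conditional pattern base of `item`
        conditional: list[tuple[list[Item], int]] = []
        for node in header[item]:
            path: list[Item] = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                conditional.append((path, node.count))
        if conditional:
            _mine(conditional, min_count, max_length, (item,) + suffix, out, n)


def mine_frequent(
    db: TransactionDB, min_support: float = 0.1, max_length: int = 4
) -> list[FrequentItemset]:
    """All itemsets with support >= ``min_support`` and size <= ``max_length``."""
    if min_support <= 0.0:
        raise ValueError("min_support must be positive")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    if db.n == 0:
        raise ValueError("empty transaction database")
    txns = [(sorted(t), 1) for t in db.transactions]
    min_count = min_support * db.n - _EPS
    out: list[FrequentItemset] = []
    _mine(txns, min_count, max_length, (), out, db.n)
    out.sort(key=lambda fs: (len(fs.items), sorted(fs.items)))
    return out


def class_association_rules(
    db: TransactionDB,
    subtype: str,
    min_support: float = 0.1,
    max_length: int = 4,
    min_lift: float = 1.1,
) -> list[AssociationRule]:
    """Class-consequent rules A -> {(subtype)} mined directly.

    Runs FP-Growth conditioned on the class item (only transactions of the
    subtype feed the tree, while supports stay relative to the full cohort),
    which enumerates exactly the frequent itemsets containing the class item.
    Each such itemset of size >= 2 yields the one rule the class-rule filter
    would keep; antecedent supports are counted on the boolean item matrix.
    Produces the same rule set as
    ``filter_class_rules(generate_rules(mine_frequent(db)))`` without
    expanding the full frequent-itemset lattice — which is intractable for
    correlated panels.
    """
    if min_support <= 0.0:
        raise ValueError("min_support must be positive")
    if max_length < 2:
        raise ValueError("max_length must be >= 2 to allow a non-empty antecedent")
    if db.n == 0:
        raise ValueError("empty transaction database")
    class_item: Item = (CLASS_FIELD, subtype)
    conditional = [
        (sorted(t - {class_item}), 1) for t in db.transactions if class_item in t
    ]
    prevalence = len(conditional) / db.n
    if prevalence < min_support - _EPS:
        return []  # the class item itself is not frequent: no rules possible
    min_count = min_support * db.n - _EPS
    found: list[FrequentItemset] = []
    _mine(conditional, min_count, max_length - 1, (), found, db.n)

    presence: dict[Item, np.ndarray] = {}

    def item_mask(item: Item) -> np.ndarray:
        if item not in presence:
            presence[item] = np.fromiter(
                (item in t for t in db.transactions), dtype=bool, count=db.n
            )
        return presence[item]

    consequent = frozenset({class_item})
    rules: list[AssociationRule] = []
    for fs in found:
        mask = np.ones(db.n, dtype=bool)
        for item in fs.items:
            mask &= item_mask(item)
        support_a = mask.mean()
        support_ac = fs.support
        confidence = support_ac / support_a
        lift = support_ac / (support_a * prevalence)
        if lift >= min_lift - _EPS:
            rules.append(AssociationRule(fs.items, consequent, support_ac, confidence, lift))
    rules.sort(key=lambda r: (-r.lift, -r.support, sorted(r.antecedent), sorted(r.consequent)))
    return rules


def generate_rules(
    itemsets: list[FrequentItemset], min_lift: float = 1.1
) -> list[AssociationRule]:
    """All rules A -> C over frequent itemsets with lift >= ``min_lift``."""
    if min_lift <= 0:
        raise ValueError("min_lift must be > 0")
    support = {fs.items: fs.support for fs in itemsets}
    rules: list[AssociationRule] = []
    for fs in itemsets:
        if len(fs.items) < 2:
            continue
        items = sorted(fs.items)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                a = frozenset(ante)
                c = fs.items - a
                sa, sc = support.get(a), support.get(c)
                if sa is None or sc is None:
                    # cannot happen for complete frequent-itemset input
                    # (anti-monotonicity), but guard against partial input
                    continue
                confidence = fs.support / sa
                lift = fs.support / (sa * sc)
                if lift >= min_lift - _EPS:
                    rules.append(AssociationRule(a, c, fs.support, confidence, lift))
    rules.sort(key=lambda r: (-r.lift, -r.support, sorted(r.antecedent), sorted(r.consequent)))
    return rules


def filter_class_rules(rules: list[AssociationRule], subtype: str) -> list[AssociationRule]:
    """Rules whose consequent is exactly the class item of ``subtype``."""
    target = frozenset({(CLASS_FIELD, subtype)})
    return [r for r in rules if r.consequent == target]


def repeat_counts(class_rules: list[AssociationRule]) -> pd.DataFrame:
    """Per-feature antecedent occurrence counts, sorted descending (ties by ID)."""
    counts: dict[str, int] = {}
    for rule in class_rules:
        for fid in {f for f, _lev in rule.antecedent if f != CLASS_FIELD}:
            counts[fid] = counts.get(fid, 0) + 1
    table = pd.DataFrame(
        {"feature_id": list(counts), "repeat_count": list(counts.values())}
    )
    if table.empty:
        return pd.DataFrame(columns=["feature_id", "repeat_count"])
    return (
        table.sort_values(["repeat_count", "feature_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def dependency_network(
    class_rules: list[AssociationRule],
    anchor_feature: str,
    min_support_cut: float = 0.0,
    min_lift_cut: float = 0.0,
) -> pd.DataFrame:
    """Co-occurrence edges between an anchor feature and its rule partners.

    Counts, over class rules whose antecedent mentions the anchor and which
    pass the support/lift cuts, how often each other feature co-occurs in the
    antecedent.  Returns (anchor, partner, count) rows ranked by count.
    """
    edges: dict[str, int] = {}
    seen_anchor = False
    for rule in class_rules:
        feats = {f for f, _lev in rule.antecedent if f != CLASS_FIELD}
        if anchor_feature not in feats:
            continue
        seen_anchor = True
        if rule.support < min_support_cut or rule.lift < min_lift_cut:
            continue
        for other in feats - {anchor_feature}:
            edges[other] = edges.get(other, 0) + 1
    if not seen_anchor:
        warnings.warn(
            f"anchor feature {anchor_feature!r} appears in no class rule", stacklevel=2
        )
    frame = pd.DataFrame(
        {
            "anchor": anchor_feature,
            "partner": list(edges),
            "count": list(edges.values()),
        }
    )
    if frame.empty:
        return pd.DataFrame(columns=["anchor", "partner", "count"])
    return frame.sort_values(["count", "partner"], ascending=[False, True]).reset_index(
        drop=True
    )
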