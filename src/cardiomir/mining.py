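"""Frequent-itemset and association-rule mining over disease transactions.

The dataset is recoded as one transaction per disease whose items are the
miRNAs reported in that disease (direction-agnostic by default; a signed
mode tags items with their direction). Frequent miRNA itemsets are mined
with FP-Growth — a compressed prefix tree (FP-tree) plus recursive
conditional-pattern-base projection — and rules A => B are kept when
support(A u B) and confidence support(A u B)/support(A) clear the thresholds
(defaults 0.2 and 0.6). A levelwise Apriori enumerator with identical
support semantics is provided as an independent test oracle.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import AssociationDataset, Direction

__all__ = [
    "TransactionDatabase",
    "ARMConfig",
    "FPTree",
    "FrequentItemset",
    "AssociationRule",
    "encode_transactions",
    "support_count_threshold",
    "mine_frequent_itemsets",
    "apriori_bruteforce",
    "generate_rules",
    "annotate_rule",
    "itemsets_to_frame",
    "rules_to_frame",
]


@dataclass(frozen=True)
class TransactionDatabase:
    """Disease transactions: disease id -> set of item tokens (miRNA ids)."""

    transactions: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for disease, items in self.transactions.items():
            if not items:
                raise ValueError(f"transaction {disease!r} is empty")

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def item_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for items in self.transactions.values():
            out |= items
        return frozenset(out)


@dataclass(frozen=True)
class ARMConfig:
    """Association-rule mining thresholds, both fractions in (0, 1]."""

    min_support: float = 0.2
    min_confidence: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError(f"min_support must be in (0, 1]: {self.min_support}")
        if not (0 < self.min_confidence <= 1):
            raise ValueError(f"min_confidence must be in (0, 1]: {self.min_confidence}")


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support_count: int
    support: float

    def sorted_items(self) -> tuple[str, ...]:
        return tuple(sorted(self.items))


@dataclass(frozen=True)
class AssociationRule:
    """A => B with support of the union and confidence support(AuB)/support(A).

    ``diseases`` lists the transactions containing every item of the rule;
    ``direction_pattern`` gives, per supporting disease, the direction of
    each item (sorted item order) in that disease: UP, DOWN or BOTH.
    """

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    support_count: int
    diseases: tuple[str, ...] = ()
    direction_pattern: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent


def encode_transactions(
    ds: AssociationDataset, signed_items: bool = False
) -> TransactionDatabase:
    """One transaction per disease; items are that disease's distinct miRNAs.

    A pair reported both UP and DOWN contributes one (unsigned) item. With
    ``signed_items=True`` items are ``mirna:UP`` / ``mirna:DOWN`` tokens, so
    the two directions mine as distinct items.
    """
    if ds.n_incidences == 0:
        raise ValueError("cannot encode an empty dataset as transactions")
    grouped: dict[str, set[str]] = {}
    for rec in ds.records:
        token = f"{rec.mirna_id}:{rec.direction.value}" if signed_items else rec.mirna_id
        grouped.setdefault(rec.disease_id, set()).add(token)
    return TransactionDatabase({d: frozenset(s) for d, s in sorted(grouped.items())})


def support_count_threshold(min_support: float, n_transactions: int) -> int:
    """ceil(min_support * n), guarded against float noise on exact products
    (e.g. 0.2 * 30 -> 6, not 7)."""
    return max(1, math.ceil(min_support * n_transactions - 1e-9))


class FPTree:
    """Frequent-pattern tree with a header table of node-link chains.

    Items along any root-to-leaf path follow the global order (descending
    support count, lexicographic tie-break). The sum of counts along an
    item's header chain equals the item's support among inserted
    transactions.
    """

    class Node:
        __slots__ = ("item", "count", "parent", "children", "link")

        def __init__(self, item: str | None, parent: "FPTree.Node | None") -> None:
            self.item = item
            self.count = 0
            self.parent = parent
            self.children: dict[str, FPTree.Node] = {}
            self.link: FPTree.Node | None = None

    def __init__(self, item_counts: Mapping[str, int]) -> None:
        self.order: tuple[str, ...] = tuple(
            sorted(item_counts, key=lambda i: (-item_counts[i], i))
        )
        self.rank: dict[str, int] = {item: r for r, item in enumerate(self.order)}
        self.root = FPTree.Node(None, None)
        self.header: dict[str, FPTree.Node | None] = {i: None for i in self.order}
        self._tails: dict[str, FPTree.Node] = {}

    def insert(self, items: Iterable[str], count: int = 1) -> None:
        """Insert a transaction (items outside the frequent order are dropped)."""
        path = sorted((i for i in set(items) if i in self.rank), key=self.rank.__getitem__)
        node = self.root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = FPTree.Node(item, node)
                node.children[item] = child
                if self.header[item] is None:
                    self.header[item] = child
                else:
                    self._tails[item].link = child
                self._tails[item] = child
            child.count += count
            node = child

    def prefix_paths(self, item: str) -> list[tuple[tuple[str, ...], int]]:
        """Conditional pattern base of ``item``: (prefix path, count) pairs."""
        out: list[tuple[tuple[str, ...], int]] = []
        node = self.header.get(item)
        while node is not None:
            path: list[str] = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                out.append((tuple(reversed(path)), node.count))
            node = node.link
        return out

    def header_counts(self) -> dict[str, int]:
        """Support of each item recomputed from its header chain."""
        out: dict[str, int] = {}
        for item in self.order:
            total = 0
            node = self.header[item]
            while node is not None:
                total += node.count
                node = node.link
            out[item] = total
        return out

    def single_path(self) -> list["FPTree.Node"] | None:
        """The node chain if the tree is one unbranched path, else None."""
        path: list[FPTree.Node] = []
        node = self.root
        while node.children:
            if len(node.children) > 1:
                return None
            node = next(iter(node.children.values()))
            path.append(node)
        return path


def _fp_mine(
    tree: FPTree,
    item_counts: Mapping[str, int],
    suffix: frozenset[str],
    min_count: int,
    out: dict[frozenset[str], int],
) -> None:
    path = tree.single_path()
    if path is not None:
        for r in range(1, len(path) + 1):
            for combo in combinations(path, r):
                # chain counts are non-increasing with depth: support = deepest
                out[frozenset(n.item for n in combo) | suffix] = combo[-1].count
        return
    for item in reversed(tree.order):  # least-frequent first, classic order
        new_suffix = suffix | {item}
        out[new_suffix] = item_counts[item]
        conditional = tree.prefix_paths(item)
        sub_counts: Counter[str] = Counter()
        for prefix, count in conditional:
            for i in prefix:
                sub_counts[i] += count
        frequent = {i: c for i, c in sub_counts.items() if c >= min_count}
        if frequent:
            subtree = FPTree(frequent)
            for prefix, count in conditional:
                subtree.insert(prefix, count)
            _fp_mine(subtree, frequent, new_suffix, min_count, out)


def _canonical(itemsets: Mapping[frozenset[str], int], n: int) -> list[FrequentItemset]:
    ordered = sorted(itemsets, key=lambda s: (len(s), tuple(sorted(s))))
    return [FrequentItemset(s, itemsets[s], itemsets[s] / n) for s in ordered]


def mine_frequent_itemsets(
    db: TransactionDatabase, cfg: ARMConfig | None = None
) -> list[FrequentItemset]:
    """All itemsets with support_count >= ceil(min_support * n_transactions),
    via FP-tree construction and recursive conditional mining. Output is
    deterministic: sorted by size, then lexicographically."""
    cfg = cfg or ARMConfig()
    n = db.n_transactions
    if n == 0:
        raise ValueError("transaction database is empty")
    min_count = support_count_threshold(cfg.min_support, n)
    counts: Counter[str] = Counter()
    for items in db.transactions.values():
        counts.update(items)
    frequent = {i: c for i, c in counts.items() if c >= min_count}
    if not frequent:
        return []
    tree = FPTree(frequent)
    for disease in sorted(db.transactions):
        tree.insert(db.transactions[disease])
    found: dict[frozenset[str], int] = {}
    _fp_mine(tree, frequent, frozenset(), min_count, found)
    return _canonical(found, n)


def apriori_bruteforce(
    db: TransactionDatabase, cfg: ARMConfig | None = None
) -> list[FrequentItemset]:
    """Independent levelwise Apriori oracle (candidate join + prune, direct
    subset-count supports). Guarded to item universes of <= 20 items."""
    cfg = cfg or ARMConfig()
    universe = sorted(db.item_universe())
    if len(universe) > 20:
        raise ValueError(f"item universe too large for brute force: {len(universe)} > 20")
    n = db.n_transactions
    min_count = support_count_threshold(cfg.min_support, n)
    transactions = list(db.transactions.values())
    found: dict[frozenset[str], int] = {}
    level: list[tuple[str, ...]] = [(i,) for i in universe]
    while level:
        frequent_level: list[tuple[str, ...]] = []
        for cand in level:
            cand_set = frozenset(cand)
            count = sum(1 for t in transactions if cand_set <= t)
            if count >= min_count:
                found[cand_set] = count
                frequent_level.append(cand)
        # join step: merge k-sets sharing a (k-1)-prefix; prune by subsets
        next_level: list[tuple[str, ...]] = []
        frequent_set = {frozenset(c) for c in frequent_level}
        for x, y in combinations(frequent_level, 2):
            if x[:-1] == y[:-1]:
                cand = x + (y[-1],) if x[-1] < y[-1] else y + (x[-1],)
                cand_set = frozenset(cand)
                if all(cand_set - {i} in frequent_set for i in cand):
                    next_level.append(cand)
        level = sorted(set(next_level))
    return _canonical(found, n)


def generate_rules(
    itemsets: Sequence[FrequentItemset],
    db: TransactionDatabase,
    cfg: ARMConfig | None = None,
) -> list[AssociationRule]:
    """Rules A => Z\\A for every frequent Z (|Z| >= 2) and non-empty proper
    subset A, kept when confidence >= min_confidence. Multi-item consequents
    allowed. Requires the complete frequent collection (subset supports)."""
    cfg = cfg or ARMConfig()
    n = db.n_transactions
    support_of: dict[frozenset[str], int] = {fs.items: fs.support_count for fs in itemsets}
    rules: list[AssociationRule] = []
    for fs in itemsets:
        if len(fs.items) < 2:
            continue
        items = fs.sorted_items()
        for r in range(1, len(items)):
            for ant in combinations(items, r):
                ant_set = frozenset(ant)
                if ant_set not in support_of:
                    raise ValueError(
                        f"incomplete itemset collection: missing support for {sorted(ant_set)}"
                    )
                confidence = fs.support_count / support_of[ant_set]
                if confidence + 1e-12 >= cfg.min_confidence:
                    rules.append(
                        AssociationRule(
                            antecedent=ant_set,
                            consequent=fs.items - ant_set,
                            support=fs.support_count / n,
                            confidence=confidence,
                            support_count=fs.support_count,
                        )
                    )
    rules.sort(
        key=lambda r: (
            len(r.antecedent) + len(r.consequent),
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
        )
    )
    return rules


def annotate_rule(rule: AssociationRule, ds: AssociationDataset) -> AssociationRule:
    """Fill a rule's supporting diseases and per-disease direction pattern.

    Diseases are those whose transaction contains every item of the rule,
    sorted; the pattern lists, per disease, each item's direction there
    (item order = sorted rule items), with BOTH when a pair is reported in
    both directions.
    """
    db = encode_transactions(ds)
    items = rule.items()
    unknown = items - db.item_universe()
    if unknown:
        raise KeyError(f"rule items absent from the dataset: {sorted(unknown)}")
    diseases = tuple(
        sorted(d for d, t in db.transactions.items() if items <= t)
    )
    directions: dict[tuple[str, str], set[Direction]] = {}
    for rec in ds.records:
        directions.setdefault((rec.mirna_id, rec.disease_id), set()).add(rec.direction)
    ordered_items = tuple(sorted(items))
    pattern = []
    for disease in diseases:
        row = []
        for item in ordered_items:
            dirs = directions[(item, disease)]
            row.append("BOTH" if len(dirs) == 2 else next(iter(dirs)).value)
        pattern.append(tuple(row))
    return replace(rule, diseases=diseases, direction_pattern=tuple(pattern))


def itemsets_to_frame(itemsets: Sequence[FrequentItemset]) -> pd.DataFrame:
    """Itemset table: ``items(;-joined)  support_count  support``."""
    return pd.DataFrame(
        {
            "items": [";".join(fs.sorted_items()) for fs in itemsets],
            "support_count": [fs.support_count for fs in itemsets],
            "support": [fs.support for fs in itemsets],
        }
    )


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Rule table: ``antecedent  consequent  support  confidence  diseases  pattern``."""
    return pd.DataFrame(
        {
            "antecedent": [";".join(sorted(r.antecedent)) for r in rules],
            "consequent": [";".join(sorted(r.consequent)) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "diseases": [",".join(r.diseases) for r in rules],
            "pattern": ["|".join(",".join(row) for row in r.direction_pattern) for r in rules],
        }
    )
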