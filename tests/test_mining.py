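"""Transaction encoding, FP-Growth, the Apriori oracle and rule generation."""
import numpy as np
import pytest

from cardiomir.mining import (
    ARMConfig,
    FPTree,
    TransactionDatabase,
    annotate_rule,
    apriori_bruteforce,
    encode_transactions,
    generate_rules,
    mine_frequent_itemsets,
    support_count_threshold,
)
from cardiomir.records import AssociationDataset, AssociationRecord, Direction
from cardiomir.synthetic import PlantedItemset, SyntheticConfig, generate_dataset


def _random_db(rng, n_items=10, n_trans=30):
    items = [chr(ord("a") + i) for i in range(rng.integers(3, n_items + 1))]
    trans = {}
    for t in range(rng.integers(2, n_trans + 1)):
        size = rng.integers(1, len(items) + 1)
        chosen = rng.choice(items, size=size, replace=False)
        trans[f"t{t}"] = frozenset(chosen)
    return TransactionDatabase(trans)


def _as_pairs(itemsets):
    return {(fs.items, fs.support_count) for fs in itemsets}


def test_encode_transactions_groups_by_disease():
    ds = AssociationDataset.from_records(
        [
            AssociationRecord("m1", "d1", Direction.UP),
            AssociationRecord("m2", "d1", Direction.DOWN),
            AssociationRecord("m1", "d2", Direction.UP),
        ]
    )
    db = encode_transactions(ds)
    assert db.transactions == {"d1": frozenset({"m1", "m2"}), "d2": frozenset({"m1"})}


def test_encode_both_directions_yield_one_item():
    ds = AssociationDataset.from_records(
        [
            AssociationRecord("m1", "d1", Direction.UP),
            AssociationRecord("m1", "d1", Direction.DOWN),
        ]
    )
    assert encode_transactions(ds).transactions["d1"] == frozenset({"m1"})
    signed = encode_transactions(ds, signed_items=True)
    assert signed.transactions["d1"] == frozenset({"m1:UP", "m1:DOWN"})


def test_encode_item_universe_matches_dataset():
    ds = generate_dataset(SyntheticConfig(seed=8, n_mirna=30, n_disease=8, target_incidences=70))
    db = encode_transactions(ds)
    assert db.item_universe() == frozenset(ds.mirna_ids())


def test_support_threshold_float_guard():
    assert support_count_threshold(0.2, 30) == 6  # not 7 from 0.2*30=6.000000000000001
    assert support_count_threshold(0.2, 6) == 2
    assert support_count_threshold(1.0, 4) == 4
    assert support_count_threshold(0.01, 4) == 1


def test_worked_example_five_frequent_itemsets(worked_transactions):
    itemsets = mine_frequent_itemsets(worked_transactions, ARMConfig(min_support=0.5))
    expected = {
        (frozenset("A"), 2),
        (frozenset("B"), 4),
        (frozenset("C"), 2),
        (frozenset("AB"), 2),
        (frozenset("BC"), 2),
    }
    assert _as_pairs(itemsets) == expected
    # brute-force check over all 7 non-empty subsets of {A,B,C}
    assert _as_pairs(apriori_bruteforce(worked_transactions, ARMConfig(min_support=0.5))) == expected


def test_worked_example_full_support_only_b(worked_transactions):
    itemsets = mine_frequent_itemsets(worked_transactions, ARMConfig(min_support=1.0))
    assert _as_pairs(itemsets) == {(frozenset("B"), 4)}


def test_worked_example_two_rules_at_point_six(worked_transactions):
    cfg = ARMConfig(min_support=0.5, min_confidence=0.6)
    itemsets = mine_frequent_itemsets(worked_transactions, cfg)
    rules = generate_rules(itemsets, worked_transactions, cfg)
    got = {(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent)), r.confidence) for r in rules}
    assert got == {(("A",), ("B",), 1.0), (("C",), ("B",), 1.0)}  # B=>A and B=>C fail at 0.5


def test_no_itemset_of_size_two_gives_no_rules():
    db = TransactionDatabase({"t1": frozenset("A"), "t2": frozenset("B")})
    cfg = ARMConfig(min_support=0.5)
    assert generate_rules(mine_frequent_itemsets(db, cfg), db, cfg) == []


def test_rules_confidence_recomputed_from_raw_transactions():
    rng = np.random.default_rng(5)
    db = _random_db(rng)
    cfg = ARMConfig(min_support=0.15, min_confidence=0.5)
    rules = generate_rules(mine_frequent_itemsets(db, cfg), db, cfg)
    for rule in rules:
        union = rule.antecedent | rule.consequent
        n_union = sum(1 for t in db.transactions.values() if union <= t)
        n_ant = sum(1 for t in db.transactions.values() if rule.antecedent <= t)
        assert rule.confidence == pytest.approx(n_union / n_ant)
        assert rule.support == pytest.approx(n_union / db.n_transactions)


def test_generate_rules_incomplete_collection_errors(worked_transactions):
    cfg = ARMConfig(min_support=0.5)
    itemsets = [fs for fs in mine_frequent_itemsets(worked_transactions, cfg) if len(fs.items) == 2]
    with pytest.raises(ValueError, match="incomplete"):
        generate_rules(itemsets, worked_transactions, cfg)


def test_single_transaction_single_item():
    db = TransactionDatabase({"t": frozenset("A")})
    assert _as_pairs(apriori_bruteforce(db, ARMConfig(min_support=1.0))) == {(frozenset("A"), 1)}


def test_apriori_universe_guard():
    db = TransactionDatabase({"t": frozenset(f"i{k}" for k in range(25))})
    with pytest.raises(ValueError):
        apriori_bruteforce(db)


def test_fpgrowth_equals_apriori_on_seeded_random_databases():
    rng = np.random.default_rng(123)
    for _ in range(30):
        db = _random_db(rng)
        cfg = ARMConfig(min_support=float(rng.choice([0.1, 0.2, 0.3, 0.5])))
        assert _as_pairs(mine_frequent_itemsets(db, cfg)) == _as_pairs(apriori_bruteforce(db, cfg))


def test_anti_monotonicity_of_mined_output():
    rng = np.random.default_rng(77)
    db = _random_db(rng, n_items=8, n_trans=25)
    itemsets = mine_frequent_itemsets(db, ARMConfig(min_support=0.1))
    support = {fs.items: fs.support_count for fs in itemsets}
    for fs in itemsets:
        for item in fs.items:
            subset = fs.items - {item}
            if subset:
                assert subset in support
                assert support[subset] >= fs.support_count


def test_fptree_header_chain_count_identity():
    rng = np.random.default_rng(31)
    for _ in range(10):
        db = _random_db(rng)
        counts = {}
        for t in db.transactions.values():
            for i in t:
                counts[i] = counts.get(i, 0) + 1
        tree = FPTree(counts)
        for name in sorted(db.transactions):
            tree.insert(db.transactions[name])
        assert tree.header_counts() == counts


def test_fptree_paths_follow_global_item_order():
    tree = FPTree({"a": 3, "b": 3, "c": 1})
    tree.insert("cab")
    tree.insert("ba")
    node = tree.root
    rank = tree.rank
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.children.values():
            if node.item is not None:
                assert rank[child.item] > rank[node.item]
            stack.append(child)


def test_output_invariant_under_transaction_permutation():
    rng = np.random.default_rng(9)
    db = _random_db(rng)
    items = list(db.transactions.items())
    shuffled = TransactionDatabase(dict(reversed(items)))
    cfg = ARMConfig(min_support=0.2)
    assert mine_frequent_itemsets(db, cfg) == mine_frequent_itemsets(shuffled, cfg)


def test_planted_itemset_recovery_support_equals_disease_count():
    planted = PlantedItemset(("miR-s0001", "miR-s0002"), ("D01", "D02", "D03"))
    cfg = SyntheticConfig(
        seed=55, n_mirna=40, n_disease=10, target_incidences=120,
        planted_itemsets=(planted,), background_degree_cap=2,
    )
    ds = generate_dataset(cfg)
    db = encode_transactions(ds)
    itemsets = mine_frequent_itemsets(db, ARMConfig(min_support=3 / db.n_transactions))
    support = {fs.items: fs.support_count for fs in itemsets}
    assert frozenset(planted.items) in support
    assert support[frozenset(planted.items)] >= 3


def test_annotate_rule_directions_and_diseases():
    ds = AssociationDataset.from_records(
        [
            AssociationRecord("m1", "d1", Direction.UP),
            AssociationRecord("m2", "d1", Direction.UP),
            AssociationRecord("m1", "d2", Direction.DOWN),
            AssociationRecord("m2", "d2", Direction.UP),
            AssociationRecord("m1", "d3", Direction.UP),
        ]
    )
    db = encode_transactions(ds)
    cfg = ARMConfig(min_support=0.5, min_confidence=0.5)
    rules = generate_rules(mine_frequent_itemsets(db, cfg), db, cfg)
    rule = next(r for r in rules if r.antecedent == {"m2"} and r.consequent == {"m1"})
    annotated = annotate_rule(rule, ds)
    assert annotated.diseases == ("d1", "d2")
    # item order is sorted(m1, m2); directions differ between the two diseases
    assert annotated.direction_pattern == (("UP", "UP"), ("DOWN", "UP"))


def test_annotate_rule_never_cooccurring_items_empty_disease_list():
    from cardiomir.mining import AssociationRule

    ds = AssociationDataset.from_records(
        [
            AssociationRecord("m1", "d1", Direction.UP),
            AssociationRecord("m2", "d2", Direction.DOWN),
        ]
    )
    rule = AssociationRule(frozenset({"m1"}), frozenset({"m2"}), 0.0, 0.0, 0)
    assert annotate_rule(rule, ds).diseases == ()


def test_annotate_rule_unknown_item_errors(toy_dataset):
    from cardiomir.mining import AssociationRule

    rule = AssociationRule(frozenset({"ghost"}), frozenset({"miR-a"}), 0.5, 1.0, 1)
    with pytest.raises(KeyError):
        annotate_rule(rule, toy_dataset)


def test_arm_config_validation():
    with pytest.raises(ValueError):
        ARMConfig(min_support=0.0)
    with pytest.raises(ValueError):
        ARMConfig(min_confidence=1.5)
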