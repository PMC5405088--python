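import pytest

from cardiomir.records import AssociationDataset, AssociationRecord, Direction


@pytest.fixture
def toy_dataset() -> AssociationDataset:
    """Five records, three miRNAs, two diseases, mixed directions."""
    return AssociationDataset.from_records(
        [
            AssociationRecord("miR-a", "HF", Direction.UP),
            AssociationRecord("miR-a", "CAD", Direction.DOWN),
            AssociationRecord("miR-b", "HF", Direction.UP),
            AssociationRecord("miR-c", "HF", Direction.DOWN),
            AssociationRecord("miR-c", "CAD", Direction.UP),
        ]
    )


@pytest.fixture
def worked_transactions():
    """The four-transaction worked example {A,B}, {B,C}, {A,B,C}, {B}."""
    from cardiomir.mining import TransactionDatabase

    return TransactionDatabase(
        {
            "t1": frozenset("AB"),
            "t2": frozenset("BC"),
            "t3": frozenset("ABC"),
            "t4": frozenset("B"),
        }
    )
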