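"""Core record types for miRNA-disease association data.

The universal input of the pipeline is a flat list of *disease incidences*:
one record per reported (miRNA, disease, dysregulation-direction) triple,
mirroring how curated databases such as HMDD export their associations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "parse_direction",
    "AssociationRecord",
    "AssociationDataset",
    "DatasetSummary",
    "summarize_dataset",
]


class Direction(str, Enum):
    """Reported dysregulation direction of a miRNA in a disease."""

    UP = "UP"
    DOWN = "DOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Accepted spellings on input; curated tables abbreviate DOWN as "D".
_DIRECTION_TOKENS: Mapping[str, Direction] = {
    "UP": Direction.UP,
    "U": Direction.UP,
    "DOWN": Direction.DOWN,
    "D": Direction.DOWN,
}


def parse_direction(token: str) -> Direction:
    """Normalize a direction token ({UP, U, DOWN, D}, case-insensitive)."""
    try:
        return _DIRECTION_TOKENS[token.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown dysregulation direction token: {token!r}") from None


@dataclass(frozen=True, slots=True)
class AssociationRecord:
    """One directed miRNA-disease incidence."""

    mirna_id: str
    disease_id: str
    direction: Direction

    def __post_init__(self) -> None:
        for name in ("mirna_id", "disease_id"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value.strip():
                raise ValueError(f"{name} must be a non-empty string, got {value!r}")
            if "\t" in value:
                raise ValueError(f"{name} must not contain tab characters: {value!r}")
            object.__setattr__(self, name, value.strip())
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", parse_direction(str(self.direction)))

    @property
    def key(self) -> tuple[str, str, Direction]:
        return (self.mirna_id, self.disease_id, self.direction)


@dataclass(frozen=True)
class AssociationDataset:
    """An ordered, exact-duplicate-free collection of association records.

    Exact duplicates (all three fields equal) are collapsed at construction
    time; records that differ only in direction are distinct incidences and
    are retained.
    """

    records: tuple[AssociationRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError(
                "AssociationDataset contains exact duplicate records; "
                "use AssociationDataset.from_records to collapse them"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[AssociationRecord], provenance: str = ""
    ) -> "AssociationDataset":
        """Build a dataset, collapsing exact duplicates (logged) in order."""
        seen: set[tuple[str, str, Direction]] = set()
        unique: list[AssociationRecord] = []
        dropped = 0
        for rec in records:
            if rec.key in seen:
                dropped += 1
                continue
            seen.add(rec.key)
            unique.append(rec)
        if dropped:
            logger.warning("collapsed %d exact duplicate association record(s)", dropped)
        return cls(tuple(unique), provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    @property
    def n_incidences(self) -> int:
        return len(self.records)

    @property
    def n_up(self) -> int:
        return sum(1 for r in self.records if r.direction is Direction.UP)

    @property
    def n_down(self) -> int:
        return sum(1 for r in self.records if r.direction is Direction.DOWN)

    def mirna_ids(self) -> tuple[str, ...]:
        """Distinct miRNA identifiers, sorted."""
        return tuple(sorted({r.mirna_id for r in self.records}))

    def disease_ids(self) -> tuple[str, ...]:
        """Distinct disease identifiers, sorted."""
        return tuple(sorted({r.disease_id for r in self.records}))

    def records_for_disease(self, disease_id: str) -> tuple[AssociationRecord, ...]:
        return tuple(r for r in self.records if r.disease_id == disease_id)


@dataclass(frozen=True, slots=True)
class DatasetSummary:
    """Headline counts of a dataset (distinct ids and incidence tallies)."""

    n_mirnas: int
    n_diseases: int
    n_incidences: int
    n_up: int
    n_down: int


def summarize_dataset(ds: AssociationDataset) -> DatasetSummary:
    """Count distinct miRNAs, distinct diseases, records, UP and DOWN events."""
    return DatasetSummary(
        n_mirnas=len(ds.mirna_ids()),
        n_diseases=len(ds.disease_ids()),
        n_incidences=ds.n_incidences,
        n_up=ds.n_up,
        n_down=ds.n_down,
    )
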