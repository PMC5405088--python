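"""Synthetic HMDD-like association data with controlled structure.

The generator emulates a curated miRNA-disease snapshot at the scale of the
cardiac subset of HMDD (~191 miRNAs, ~30 diseases, ~388 directed incidences
with a 224/164 UP/DOWN split): a heavy-tailed miRNA degree profile so hubs
arise naturally, optional explicitly-forced hub degrees, per-disease
up-probability biases, and planted co-dysregulation itemsets that the
mining stage must recover. Everything is deterministic given the seed.

Also packages two literature-derived fixtures: the per-disease dysregulation
count table (table1_fixture) and a small all-DOWN co-occurrence dataset
whose mined rules match the published cluster associations (table2_fixture).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .records import AssociationDataset, AssociationRecord, Direction

__all__ = [
    "PlantedItemset",
    "SyntheticConfig",
    "generate_dataset",
    "default_mirna_ids",
    "default_disease_ids",
    "Table1Row",
    "Table1Fixture",
    "table1_fixture",
    "table2_fixture",
]


def default_mirna_ids(n: int) -> tuple[str, ...]:
    return tuple(f"miR-s{i:04d}" for i in range(1, n + 1))


def default_disease_ids(n: int) -> tuple[str, ...]:
    return tuple(f"D{i:02d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class PlantedItemset:
    """A co-dysregulation pattern embedded verbatim: every item gets one
    incidence in every listed disease, with the stated direction."""

    items: tuple[str, ...]
    diseases: tuple[str, ...]
    direction: Direction = Direction.DOWN

    def __post_init__(self) -> None:
        if not self.items or not self.diseases:
            raise ValueError("planted itemset needs at least one item and one disease")
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "diseases", tuple(self.diseases))
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(str(self.direction).upper()))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generator.

    Defaults reproduce the published snapshot's scale: 191 miRNAs, 30
    diseases, 388 incidences with global up-fraction 224/388. ``hub_spec``
    is a list of (count, min_degree) requirements enforced exactly;
    ``background_degree_cap`` limits the distinct-disease degree of
    non-hub miRNAs; ``power_law_exponent`` shapes the background miRNA
    degree distribution (heavier tail for values near 1).
    """

    seed: int
    n_mirna: int = 191
    n_disease: int = 30
    target_incidences: int = 388
    global_up_fraction: float = 224 / 388
    hub_spec: tuple[tuple[int, int], ...] = ()
    disease_bias: Mapping[str, float] = field(default_factory=dict)
    planted_itemsets: tuple[PlantedItemset, ...] = ()
    background_degree_cap: int | None = None
    disease_weights: Mapping[str, float] | None = None
    power_law_exponent: float = 1.3
    ensure_coverage: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if min(self.n_mirna, self.n_disease) < 1 or self.target_incidences < 0:
            raise ValueError("sizes must be positive")
        if not (0 <= self.global_up_fraction <= 1):
            raise ValueError("global_up_fraction must be in [0, 1]")
        for disease, p in self.disease_bias.items():
            if not (0 <= p <= 1):
                raise ValueError(f"disease_bias[{disease!r}] outside [0, 1]: {p}")
        object.__setattr__(self, "hub_spec", tuple((int(c), int(d)) for c, d in self.hub_spec))
        object.__setattr__(self, "planted_itemsets", tuple(self.planted_itemsets))

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return default_mirna_ids(self.n_mirna)

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return default_disease_ids(self.n_disease)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        """Load a config from a YAML mapping (keys = field names; planted
        itemsets as {items: [...], diseases: [...], direction: UP|DOWN})."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        planted = tuple(
            PlantedItemset(
                items=tuple(p["items"]),
                diseases=tuple(p["diseases"]),
                direction=Direction(str(p.get("direction", "DOWN")).upper()),
            )
            for p in raw.pop("planted_itemsets", [])
        )
        hub_spec = tuple((int(c), int(d)) for c, d in raw.pop("hub_spec", []))
        return cls(planted_itemsets=planted, hub_spec=hub_spec, **raw)


def _validate_feasibility(cfg: SyntheticConfig) -> None:
    disease_universe = set(cfg.disease_ids)
    for planted in cfg.planted_itemsets:
        missing = set(planted.diseases) - disease_universe
        if missing:
            raise ValueError(f"planted diseases outside the universe: {sorted(missing)}")
    total_hubs = sum(count for count, _ in cfg.hub_spec)
    if total_hubs > cfg.n_mirna:
        raise ValueError("hub_spec requests more hubs than miRNAs")
    for _, min_degree in cfg.hub_spec:
        if min_degree > cfg.n_disease:
            raise ValueError(
                f"hub degree {min_degree} exceeds the number of diseases ({cfg.n_disease})"
            )
    for disease in cfg.disease_bias:
        if disease not in disease_universe:
            raise ValueError(f"disease_bias names unknown disease {disease!r}")


def generate_dataset(cfg: SyntheticConfig) -> AssociationDataset:
    """Generate a dataset of exactly ``target_incidences`` records.

    Planted itemsets are embedded first, then hub requirements are satisfied
    by targeted edge additions, then (with ``ensure_coverage``, the default)
    every still-unseen miRNA receives one incidence — a curated snapshot
    lists only miRNAs with at least one report — and finally background
    incidences are drawn: the disease by the configured weights (uniform by
    default), the miRNA by a truncated power-law over the miRNA index, the
    direction Bernoulli with the disease's bias (falling back to the global
    up-fraction). Sampled duplicates of an existing (miRNA, disease,
    direction) triple are resampled so the target count is met exactly.
    """
    _validate_feasibility(cfg)
    rng = np.random.default_rng(cfg.seed)
    mirnas = list(cfg.mirna_ids)
    diseases = list(cfg.disease_ids)

    records: list[AssociationRecord] = []
    seen: set[tuple[str, str, Direction]] = set()
    adjacency: dict[str, set[str]] = {}

    def up_probability(disease: str) -> float:
        return cfg.disease_bias.get(disease, cfg.global_up_fraction)

    def draw_direction(disease: str) -> Direction:
        return Direction.UP if rng.random() < up_probability(disease) else Direction.DOWN

    def add(mirna: str, disease: str, direction: Direction) -> bool:
        key = (mirna, disease, direction)
        if key in seen:
            return False
        seen.add(key)
        records.append(AssociationRecord(mirna, disease, direction))
        adjacency.setdefault(mirna, set()).add(disease)
        return True

    # 1. planted co-dysregulation itemsets, embedded verbatim
    for planted in cfg.planted_itemsets:
        for disease in planted.diseases:
            for item in planted.items:
                add(item, disease, planted.direction)

    # 2. forced hubs: targeted edges until each hub reaches its min degree
    hub_mirnas: list[str] = []
    total_hubs = sum(count for count, _ in cfg.hub_spec)
    if total_hubs:
        chosen = rng.choice(cfg.n_mirna, size=total_hubs, replace=False)
        pool = [mirnas[i] for i in sorted(chosen)]
        cursor = 0
        for count, min_degree in cfg.hub_spec:
            for _ in range(count):
                mirna = pool[cursor]
                cursor += 1
                hub_mirnas.append(mirna)
                current = adjacency.setdefault(mirna, set())
                while len(current) < min_degree:
                    candidates = sorted(set(diseases) - current)
                    disease = candidates[rng.integers(len(candidates))]
                    add(mirna, disease, draw_direction(disease))
    hub_set = set(hub_mirnas)

    if len(records) > cfg.target_incidences:
        raise ValueError(
            f"planted structure needs {len(records)} incidences, "
            f"exceeding target_incidences={cfg.target_incidences}"
        )

    if cfg.disease_weights is not None and set(cfg.disease_weights) - set(diseases):
        raise ValueError("disease_weights names diseases outside the universe")

    # 3. coverage: one incidence for every miRNA not yet reported
    if cfg.ensure_coverage:
        unseen = [m for m in mirnas if m not in adjacency]
        budget = cfg.target_incidences - len(records)
        if len(unseen) > budget:
            picked = rng.choice(len(unseen), size=max(budget, 0), replace=False)
            unseen = [unseen[i] for i in sorted(picked)]
        for mirna in unseen:
            disease = diseases[rng.integers(cfg.n_disease)]
            add(mirna, disease, draw_direction(disease))

    # 4. heavy-tailed background until the incidence target is met exactly
    ranks = np.arange(1, cfg.n_mirna + 1, dtype=float)
    mirna_weights = ranks ** (-cfg.power_law_exponent)
    mirna_weights /= mirna_weights.sum()
    if cfg.disease_weights is None:
        disease_weights = np.full(cfg.n_disease, 1.0 / cfg.n_disease)
    else:
        disease_weights = np.array(
            [float(cfg.disease_weights.get(d, 0.0)) for d in diseases]
        )
        if disease_weights.sum() <= 0:
            raise ValueError("disease_weights sum to zero")
        disease_weights /= disease_weights.sum()

    remaining = cfg.target_incidences - len(records)
    max_attempts = 500 * max(remaining, 1) + 1000
    attempts = 0
    while len(records) < cfg.target_incidences:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not reach target_incidences under the configured "
                "degree cap / universe sizes (config likely infeasible)"
            )
        mirna = mirnas[rng.choice(cfg.n_mirna, p=mirna_weights)]
        disease = diseases[rng.choice(cfg.n_disease, p=disease_weights)]
        if (
            cfg.background_degree_cap is not None
            and mirna not in hub_set
            and disease not in adjacency.get(mirna, set())
            and len(adjacency.get(mirna, set())) >= cfg.background_degree_cap
        ):
            continue
        add(mirna, disease, draw_direction(disease))

    return AssociationDataset.from_records(
        records, provenance=f"synthetic(seed={cfg.seed})"
    )


# ---------------------------------------------------------------------------
# Literature-derived fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Row:
    disease_id: str
    n_up: int
    n_down: int


@dataclass(frozen=True)
class Table1Fixture:
    """Published per-disease dysregulation counts plus dataset totals.

    Rows cover nine diseases from the printed dysregulation table plus
    atherosclerosis (19 of 24 events upregulated); dataset totals are 224
    UP / 164 DOWN over 388 incidences. The remaining diseases of the
    snapshot were not published row-by-row, so their pooled counts appear
    as a single remainder pseudo-disease when materialized as a dataset.
    """

    rows: tuple[Table1Row, ...]
    total_up: int = 224
    total_down: int = 164

    def remainder(self) -> tuple[int, int]:
        up = self.total_up - sum(r.n_up for r in self.rows)
        down = self.total_down - sum(r.n_down for r in self.rows)
        return up, down

    def to_dataset(
        self, include_remainder: bool = True, remainder_id: str = "OTH"
    ) -> AssociationDataset:
        """Materialize the counts as incidence records (one synthetic miRNA
        id per event: the table is about event tallies, not topology)."""
        records: list[AssociationRecord] = []
        rows = list(self.rows)
        if include_remainder:
            up, down = self.remainder()
            rows.append(Table1Row(remainder_id, up, down))
        for row in rows:
            for i in range(row.n_up):
                records.append(
                    AssociationRecord(f"{row.disease_id}-up-{i:03d}", row.disease_id, Direction.UP)
                )
            for i in range(row.n_down):
                records.append(
                    AssociationRecord(f"{row.disease_id}-dn-{i:03d}", row.disease_id, Direction.DOWN)
                )
        return AssociationDataset.from_records(records, provenance="table1_fixture")


def table1_fixture() -> Table1Fixture:
    """Published dysregulation counts: (disease, n_up, n_down) per row.

    DOWN counts are derived from each printed dominant fraction (e.g.
    coronary artery disease "75% (15/20) UP" -> 15 UP, 5 DOWN; thoracic
    aneurysm "60% (9/15) DOWN" -> 6 UP, 9 DOWN).
    """
    return Table1Fixture(
        rows=(
            Table1Row("CAD", 15, 5),   # coronary artery disease, 75% (15/20) UP
            Table1Row("HF", 70, 62),   # heart failure, 53% (70/132) UP
            Table1Row("HCM", 12, 11),  # hypertrophic cardiomyopathy, 52.1% (12/23) UP
            Table1Row("MI", 19, 17),   # myocardial infarction, 52.7% (19/36) UP
            Table1Row("MYI", 5, 2),    # myocardial ischemia, 71.4% (5/7) UP
            Table1Row("MRI", 5, 0),    # myocardial reperfusion injury, 100% (5/5) UP
            Table1Row("MC", 2, 0),     # myocarditis, 100% (2/2) UP
            Table1Row("ST", 8, 1),     # stroke, 88.8% (8/9) UP
            Table1Row("TAA", 6, 9),    # thoracic aneurysm, 60% (9/15) DOWN
            Table1Row("ATS", 19, 5),   # atherosclerosis, 79.1% (19/24) UP
        )
    )


#: Disease transactions realizing the published miRNA cluster associations
#: (all records downregulated). Co-occurrence design: {1-1, 1-2, 133a-1,
#: 133a-2} in TAA, CMG and HCM; 155 joins {133a-1, 133a-2} in HCM, LVH and
#: DCM; 133b co-occurs with 133a-1/133a-2 in AF.
_TABLE2_TRANSACTIONS: dict[str, tuple[str, ...]] = {
    "TAA": ("hsa-miR-1-1", "hsa-miR-1-2", "hsa-miR-133a-1", "hsa-miR-133a-2"),
    "CMG": ("hsa-miR-1-1", "hsa-miR-1-2", "hsa-miR-133a-1", "hsa-miR-133a-2"),
    "HCM": ("hsa-miR-1-1", "hsa-miR-1-2", "hsa-miR-133a-1", "hsa-miR-133a-2", "hsa-miR-155"),
    "AF": ("hsa-miR-133a-1", "hsa-miR-133a-2", "hsa-miR-133b"),
    "LVH": ("hsa-miR-133a-1", "hsa-miR-133a-2", "hsa-miR-155"),
    "DCM": ("hsa-miR-133a-1", "hsa-miR-133a-2", "hsa-miR-155"),
}


def table2_fixture() -> AssociationDataset:
    """Small all-DOWN dataset whose mined rules (support 0.2, confidence 0.6)
    reproduce the published cluster associations, e.g. {1-1, 1-2} => 133a-2
    in TAA/CMG/HCM and 155 => 133a-2 in DCM/HCM/LVH."""
    records = [
        AssociationRecord(mirna, disease, Direction.DOWN)
        for disease, mirnas in _TABLE2_TRANSACTIONS.items()
        for mirna in mirnas
    ]
    return AssociationDataset.from_records(records, provenance="table2_fixture")
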