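"""Per-disease dysregulation statistics.

For each disease we tally UP and DOWN incidence events, report the dominant
direction and its percentage (truncated, not rounded, at one decimal — the
convention curated summary tables use, e.g. 8/9 printed as 88.8), build the
2x2 contingency table of this disease against the rest of the dataset
(rows: disease vs rest; columns: UP vs DOWN events) and compute a two-tailed
Fisher exact test by full hypergeometric enumeration in exact integer
arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from math import comb
from typing import Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .records import AssociationDataset, Direction

__all__ = [
    "DiseaseDysregulationSummary",
    "ContingencyTable2x2",
    "trunc1",
    "summarize_disease",
    "build_contingency",
    "contingency_from_counts",
    "fisher_two_tailed",
    "run_all_diseases",
    "adjust_pvalues_bh",
    "summaries_to_frame",
]


def trunc1(numerator: int, denominator: int) -> float:
    """Percentage ``100*numerator/denominator`` truncated (floored) at the
    first decimal, computed in integer arithmetic: ``floor(1000*k/n)/10``.

    Truncation never rounds up: trunc1(k, n) <= 100*k/n.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return (1000 * numerator // denominator) / 10


@dataclass(frozen=True)
class DiseaseDysregulationSummary:
    """Tally of one disease's dysregulation events and its Fisher p-value."""

    disease_id: str
    n_up: int
    n_down: int
    dominant_direction: str  # "UP", "DOWN" or "TIE"
    percent_dominant: float
    p_value: float | None = None
    p_adjusted: float | None = None

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table: rows = this disease vs all other diseases, columns = UP vs
    DOWN incidence events."""

    a: int  # disease, UP
    b: int  # disease, DOWN
    c: int  # rest, UP
    d: int  # rest, DOWN

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)


def summarize_disease(
    ds: AssociationDataset, disease_id: str
) -> DiseaseDysregulationSummary:
    """Tally one disease's UP/DOWN events; p-value left unset."""
    recs = ds.records_for_disease(disease_id)
    if not recs:
        raise KeyError(f"disease {disease_id!r} has no incidence in the dataset")
    n_up = sum(1 for r in recs if r.direction is Direction.UP)
    n_down = len(recs) - n_up
    if n_up > n_down:
        dominant = "UP"
    elif n_down > n_up:
        dominant = "DOWN"
    else:
        dominant = "TIE"
    percent = trunc1(max(n_up, n_down), n_up + n_down)
    return DiseaseDysregulationSummary(
        disease_id=disease_id,
        n_up=n_up,
        n_down=n_down,
        dominant_direction=dominant,
        percent_dominant=percent,
    )


def build_contingency(ds: AssociationDataset, disease_id: str) -> ContingencyTable2x2:
    """Disease-vs-rest x UP-vs-DOWN contingency table over incidence events."""
    summary = summarize_disease(ds, disease_id)
    rest_up = ds.n_up - summary.n_up
    rest_down = ds.n_down - summary.n_down
    if rest_up + rest_down == 0:
        raise ValueError(
            f"disease {disease_id!r} covers the whole dataset; no comparison group"
        )
    return ContingencyTable2x2(summary.n_up, summary.n_down, rest_up, rest_down)


def contingency_from_counts(
    n_up: int, n_down: int, total_up: int, total_down: int
) -> ContingencyTable2x2:
    """Build a disease-vs-rest table from a disease's counts and dataset totals."""
    if n_up > total_up or n_down > total_down:
        raise ValueError("disease counts exceed dataset totals")
    return ContingencyTable2x2(n_up, n_down, total_up - n_up, total_down - n_down)


@lru_cache(maxsize=200_000)
def _hypergeom_weights(r1: int, r2: int, c1: int) -> tuple[int, tuple[int, ...]]:
    """Unnormalized hypergeometric weights C(r1,k)*C(r2,c1-k) over the support
    of k = table entry a, given fixed margins. Returns (k_min, weights)."""
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    weights = tuple(comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1))
    return k_min, weights


def fisher_two_tailed(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact test by full enumeration.

    With all margins fixed, sums the hypergeometric probabilities of every
    table whose probability is <= that of the observed table (the
    minimum-likelihood two-sided convention). Computed with exact integer
    weights, so ties are resolved exactly; the only inexactness is the final
    correctly-rounded float division.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    r1, r2 = table.row_margins
    c1, c2 = table.col_margins
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("Fisher test undefined: a margin of the 2x2 table is zero")
    k_min, weights = _hypergeom_weights(r1, r2, c1)
    w_obs = weights[table.a - k_min]
    numerator = sum(w for w in weights if w <= w_obs)
    return numerator / sum(weights)


def run_all_diseases(
    ds: AssociationDataset, bh_adjust: bool = False
) -> list[DiseaseDysregulationSummary]:
    """Summaries for every disease, with disease-vs-rest Fisher p-values,
    ordered by ascending p then disease id.

    If one direction is absent from the whole dataset, the column margin is
    zero and the hypergeometric distribution is degenerate (a single
    achievable table carrying all the mass); those diseases report p = 1.0.
    Optionally attaches Benjamini-Hochberg adjusted p-values.
    """
    diseases = ds.disease_ids()
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases for disease-vs-rest statistics")
    summaries = []
    for disease in diseases:
        summary = summarize_disease(ds, disease)
        table = build_contingency(ds, disease)
        if min(table.col_margins) == 0:
            p = 1.0
        else:
            p = fisher_two_tailed(table)
        summaries.append(replace(summary, p_value=p))
    if bh_adjust:
        adjusted = adjust_pvalues_bh([s.p_value for s in summaries])
        summaries = [replace(s, p_adjusted=q) for s, q in zip(summaries, adjusted)]
    return sorted(summaries, key=lambda s: (s.p_value, s.disease_id))


def adjust_pvalues_bh(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    if len(pvalues) == 0:
        return []
    for p in pvalues:
        if not (0 < p <= 1):
            raise ValueError(f"p-value outside (0, 1]: {p!r}")
    if len(pvalues) == 1:
        return [float(pvalues[0])]
    return list(multipletests(list(pvalues), method="fdr_bh")[1])


def summaries_to_frame(summaries: Sequence[DiseaseDysregulationSummary]) -> pd.DataFrame:
    """Result table: ``disease  n_up  n_down  percent  direction  p_raw[  p_bh]``."""
    rows = {
        "disease": [s.disease_id for s in summaries],
        "n_up": [s.n_up for s in summaries],
        "n_down": [s.n_down for s in summaries],
        "percent": [s.percent_dominant for s in summaries],
        "direction": [s.dominant_direction for s in summaries],
        "p_raw": [s.p_value for s in summaries],
    }
    if any(s.p_adjusted is not None for s in summaries):
        rows["p_bh"] = [s.p_adjusted for s in summaries]
    return pd.DataFrame(rows)
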